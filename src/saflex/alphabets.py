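"""Structural alphabets: encoding backbone conformations as letter strings.

Four alphabet families are supported:

* ``Sec3`` / ``Sec8`` — secondary structure in 3 or 8 classes, assigned with
  a simplified Kabsch–Sander hydrogen-bond procedure (or ingested from a
  precomputed DSSP file).
* ``PB`` — the 16-letter Protein Blocks alphabet: 5-residue fragments
  described by 8 consecutive backbone dihedrals, assigned by minimal
  angular RMSD (RMSDA) against the bundled reference prototype table.
* ``FragmentSA`` — a trainable Cartesian fragment alphabet (default 28
  prototypes of 7 Cα positions) assigned by minimal superposed RMSD.

Positions that cannot be assigned (chain termini inside the assignment
window, masked residues) carry the reserved mask symbol ``'-'``.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_random_state

from ._geometry import dihedral, kabsch_rmsd_coords, kabsch_rotation, wrap_angle
from .structure_io import BackboneStructure, InsufficientDataError

#: Reserved symbol for unassignable positions; never a member of an alphabet.
MASK = "-"

SEC8_LETTERS = ("H", "G", "I", "E", "B", "T", "S", "C")
SEC3_LETTERS = ("H", "E", "C")
#: 8-class → 3-class collapse: 3-10/α/π helices → H, strand/bridge → E.
SEC8_TO_SEC3 = {
    "H": "H", "G": "H", "I": "H",
    "E": "E", "B": "E",
    "T": "C", "S": "C", "C": "C",
}

#: Kabsch–Sander electrostatic H-bond model: E in kcal/mol, bond if E < -0.5.
_KS_COUPLING = 27.888
_KS_CUTOFF = -0.5
_NH_BOND = 1.01  # amide N-H length, Å


@dataclass
class Alphabet:
    """A named letter set with its assignment parameters.

    ``kind`` is one of ``dihedral-prototype`` (PB), ``fragment-prototype``
    (Cartesian fragment alphabets) or ``rule-based`` (secondary structure).
    """

    name: str
    letters: tuple
    kind: str
    prototypes: np.ndarray | None = None
    fragment_length: int = 5

    def __post_init__(self):
        if len(set(self.letters)) != len(self.letters):
            raise ValueError("alphabet letters must be unique")
        if MASK in self.letters:
            raise ValueError(f"mask symbol {MASK!r} cannot be an alphabet letter")
        if self.fragment_length % 2 != 1:
            raise ValueError("fragment_length must be odd")

    @property
    def size(self) -> int:
        return len(self.letters)

    def index(self, letter: str) -> int:
        return self.letters.index(letter)


@dataclass
class SAEncoding:
    """One alphabet letter (or mask) per residue of a structure."""

    alphabet: Alphabet
    letters: str

    def __post_init__(self):
        allowed = set(self.alphabet.letters) | {MASK}
        bad = set(self.letters) - allowed
        if bad:
            raise ValueError(f"symbols {sorted(bad)} not in alphabet {self.alphabet.name}")

    def __len__(self) -> int:
        return len(self.letters)

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the position carries a real letter."""
        return np.array([c != MASK for c in self.letters], dtype=bool)

    def indices(self) -> np.ndarray:
        """Letter indices per position, -1 at masked positions."""
        lut = {c: i for i, c in enumerate(self.alphabet.letters)}
        return np.array([lut.get(c, -1) for c in self.letters], dtype=int)


def sec3_alphabet() -> Alphabet:
    return Alphabet(name="Sec3", letters=SEC3_LETTERS, kind="rule-based", fragment_length=1)


def sec8_alphabet() -> Alphabet:
    return Alphabet(name="Sec8", letters=SEC8_LETTERS, kind="rule-based", fragment_length=1)


def load_pb_table() -> tuple[tuple, np.ndarray]:
    """Load the bundled 16×8 Protein Blocks dihedral prototype table."""
    text = resources.files("saflex").joinpath("data/pb_prototypes.txt").read_text()
    letters, rows = [], []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        letters.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    table = np.asarray(rows, dtype=float)
    if table.shape != (16, 8):
        raise ValueError(f"PB prototype table must be 16×8, got {table.shape}")
    return tuple(letters), table


def pb_alphabet() -> Alphabet:
    letters, table = load_pb_table()
    return Alphabet(
        name="PB", letters=letters, kind="dihedral-prototype",
        prototypes=table, fragment_length=5,
    )


# ---------------------------------------------------------------------------
# Dihedral geometry
# ---------------------------------------------------------------------------

def compute_dihedrals(s: BackboneStructure) -> tuple[np.ndarray, np.ndarray]:
    """Backbone (φ, ψ) per residue in degrees, NaN where undefined.

    φ(i) is the C(i-1)–N(i)–CA(i)–C(i) torsion, ψ(i) the
    N(i)–CA(i)–C(i)–N(i+1) torsion.  φ of the first residue, ψ of the last,
    and any angle touching an invalid residue are NaN.
    """
    n = len(s)
    if n < 2:
        raise InsufficientDataError("need at least 2 residues for dihedrals")
    phi = np.full(n, np.nan)
    psi = np.full(n, np.nan)
    v = s.valid
    idx = np.arange(1, n)
    ok_phi = v[idx - 1] & v[idx]
    if ok_phi.any():
        i = idx[ok_phi]
        phi[i] = dihedral(s.coords_c[i - 1], s.coords_n[i], s.coords_ca[i], s.coords_c[i])
    idx = np.arange(0, n - 1)
    ok_psi = v[idx] & v[idx + 1]
    if ok_psi.any():
        i = idx[ok_psi]
        psi[i] = dihedral(s.coords_n[i], s.coords_ca[i], s.coords_c[i], s.coords_n[i + 1])
    return phi, psi


def rmsda(frag: np.ndarray, proto: np.ndarray) -> float:
    """Root-mean-square angular deviation in degrees between two vectors of
    8 dihedrals, with 360° periodic wrapping; symmetric, in [0, 180]."""
    frag = np.asarray(frag, dtype=float)
    proto = np.asarray(proto, dtype=float)
    if frag.shape != (8,) or proto.shape != (8,):
        raise ValueError("rmsda expects two length-8 angle vectors")
    if not (np.all(np.isfinite(frag)) and np.all(np.isfinite(proto))):
        raise ValueError("rmsda is undefined for masked (NaN) angles")
    return float(_rmsda_to_protos(frag[None, :], proto[None, :])[0, 0])


def _rmsda_to_protos(frags: np.ndarray, protos: np.ndarray) -> np.ndarray:
    """(k, 8) fragments vs (m, 8) prototypes → (k, m) RMSDA matrix."""
    d = np.abs(frags[:, None, :] - protos[None, :, :])
    d = np.minimum(d, 360.0 - d)
    return np.sqrt(np.mean(d * d, axis=-1))


def pb_angle_windows(s: BackboneStructure) -> np.ndarray:
    """(n, 8) matrix of PB assignment windows, NaN rows where incomplete.

    Row i is (ψ(i-2), φ(i-1), ψ(i-1), φ(i), ψ(i), φ(i+1), ψ(i+1), φ(i+2)).
    """
    n = len(s)
    phi, psi = compute_dihedrals(s)
    win = np.full((n, 8), np.nan)
    for i in range(2, n - 2):
        win[i] = (
            psi[i - 2], phi[i - 1], psi[i - 1], phi[i],
            psi[i], phi[i + 1], psi[i + 1], phi[i + 2],
        )
    return win


def encode_pb(s: BackboneStructure, alphabet: Alphabet | None = None) -> SAEncoding:
    """Assign Protein Blocks letters by minimal RMSDA; ties break to the
    lowest prototype index.  The two residues at each terminus are masked."""
    if alphabet is None:
        alphabet = pb_alphabet()
    if alphabet.kind != "dihedral-prototype":
        raise ValueError("encode_pb requires a dihedral-prototype alphabet")
    n = len(s)
    letters = [MASK] * n
    if n >= 5:
        win = pb_angle_windows(s)
        complete = np.all(np.isfinite(win), axis=1)
        if complete.any():
            dmat = _rmsda_to_protos(win[complete], alphabet.prototypes)
            best = np.argmin(dmat, axis=1)
            for pos, j in zip(np.flatnonzero(complete), best):
                letters[pos] = alphabet.letters[j]
    return SAEncoding(alphabet=alphabet, letters="".join(letters))


# ---------------------------------------------------------------------------
# Secondary structure (simplified Kabsch–Sander)
# ---------------------------------------------------------------------------

def amide_hydrogen_positions(s: BackboneStructure) -> np.ndarray:
    """Geometric amide H per residue: 1.01 Å from N along the bisector
    opposite the C(i-1)→N and CA→N directions.  First residue and positions
    with an invalid predecessor get NaN."""
    n = len(s)
    h = np.full((n, 3), np.nan)
    for i in range(1, n):
        if not (s.valid[i] and s.valid[i - 1]):
            continue
        u1 = s.coords_c[i - 1] - s.coords_n[i]
        u2 = s.coords_ca[i] - s.coords_n[i]
        u1 = u1 / np.linalg.norm(u1)
        u2 = u2 / np.linalg.norm(u2)
        b = u1 + u2
        h[i] = s.coords_n[i] - _NH_BOND * b / np.linalg.norm(b)
    return h


def ks_hbond_energy(s: BackboneStructure) -> np.ndarray:
    """(n, n) Kabsch–Sander electrostatic energies in kcal/mol.

    Entry (i, j) is the energy of the C=O(i) ← H-N(j) interaction; +inf
    where undefined (|i-j| < 2, missing H, invalid residues).
    """
    n = len(s)
    hpos = amide_hydrogen_positions(s)
    energy = np.full((n, n), np.inf)
    donors = np.flatnonzero(np.all(np.isfinite(hpos), axis=1))
    acceptors = np.flatnonzero(s.valid)
    if donors.size == 0 or acceptors.size == 0:
        return energy
    o = s.coords_o[acceptors]
    c = s.coords_c[acceptors]
    nn = s.coords_n[donors]
    hh = hpos[donors]

    def dist(a, b):
        return np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)

    with np.errstate(divide="ignore"):
        e = _KS_COUPLING * (
            1.0 / dist(o, nn) + 1.0 / dist(c, hh)
            - 1.0 / dist(o, hh) - 1.0 / dist(c, nn)
        )
    ii, jj = np.meshgrid(acceptors, donors, indexing="ij")
    e[np.abs(ii - jj) < 2] = np.inf
    energy[np.ix_(acceptors, donors)] = e
    return energy


def _ks_assign8(s: BackboneStructure) -> list:
    n = len(s)
    hbond = ks_hbond_energy(s) < _KS_CUTOFF

    def turn(k):
        t = np.zeros(n, dtype=bool)
        if n > k:
            t[: n - k] = np.diag(hbond, k)[: n - k]
        return t

    turns = {k: turn(k) for k in (3, 4, 5)}

    helix = {3: np.zeros(n, bool), 4: np.zeros(n, bool), 5: np.zeros(n, bool)}
    for k in (3, 4, 5):
        tk = turns[k]
        for i in range(1, n - k):
            if tk[i - 1] and tk[i]:
                helix[k][i : i + k] = True

    # bridges between residues at least 3 apart
    is_bridge = np.zeros(n, bool)
    bridge_partner = [set() for _ in range(n)]
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            para = (hbond[i - 1, j] and hbond[j, i + 1]) or (
                hbond[j - 1, i] and hbond[i, j + 1]
            )
            anti = (hbond[i, j] and hbond[j, i]) or (
                hbond[i - 1, j + 1] and hbond[j - 1, i + 1]
            )
            if para or anti:
                is_bridge[i] = is_bridge[j] = True
                bridge_partner[i].add(j)
                bridge_partner[j].add(i)
    in_ladder = np.zeros(n, bool)
    for i in range(n):
        for j in bridge_partner[i]:
            neighbours = bridge_partner[i - 1] if i > 0 else set()
            neighbours = neighbours | (bridge_partner[i + 1] if i < n - 1 else set())
            if neighbours & {j - 1, j, j + 1}:
                in_ladder[i] = True

    in_turn = np.zeros(n, bool)
    for k in (3, 4, 5):
        for i in np.flatnonzero(turns[k]):
            in_turn[i + 1 : i + k] = True

    bend = np.zeros(n, bool)
    for i in range(2, n - 2):
        if not np.all(s.valid[i - 2 : i + 3]):
            continue
        u = s.coords_ca[i] - s.coords_ca[i - 2]
        v = s.coords_ca[i + 2] - s.coords_ca[i]
        cosk = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        if np.degrees(np.arccos(np.clip(cosk, -1, 1))) > 70.0:
            bend[i] = True

    out = []
    for i in range(n):
        if not s.valid[i]:
            out.append(MASK)
        elif helix[4][i]:
            out.append("H")
        elif is_bridge[i] and in_ladder[i]:
            out.append("E")
        elif helix[3][i]:
            out.append("G")
        elif helix[5][i]:
            out.append("I")
        elif is_bridge[i]:
            out.append("B")
        elif in_turn[i]:
            out.append("T")
        elif bend[i]:
            out.append("S")
        else:
            out.append("C")
    return out


def collapse_sec8(letters: str) -> str:
    """Map an 8-class secondary-structure string to 3 classes."""
    return "".join(SEC8_TO_SEC3.get(c, MASK if c == MASK else "C") for c in letters)


def assign_secondary_structure(s: BackboneStructure, classes: int = 3) -> SAEncoding:
    """Secondary-structure assignment from backbone H-bond geometry.

    Hydrogen bonds follow the Kabsch–Sander electrostatic criterion
    (E < -0.5 kcal/mol with a geometrically placed amide H); n-turns at
    i→i+3/4/5 give G/H/I helices (two consecutive turns required), bridge
    patterns give E/B, turns T, bends S, everything else C, with priority
    H > E > G > I > B > T > S > C.  ``classes=3`` collapses to {H, E, C}.
    """
    if classes not in (3, 8):
        raise ValueError("classes must be 3 or 8")
    letters8 = "".join(_ks_assign8(s))
    if classes == 8:
        return SAEncoding(alphabet=sec8_alphabet(), letters=letters8)
    return SAEncoding(alphabet=sec3_alphabet(), letters=collapse_sec8(letters8))


def read_dssp(path, sequence_length: int | None = None, classes: int = 8) -> SAEncoding:
    """Ingest a precomputed classic-format DSSP file as an encoding override.

    Residues are taken in file order from the first chain encountered;
    DSSP blanks map to C.
    """
    from Bio.PDB.DSSP import make_dssp_dict

    dssp_dict, keys = make_dssp_dict(str(path))
    first_chain = keys[0][0]
    letters = []
    for key in keys:
        if key[0] != first_chain:
            continue
        ss = dssp_dict[key][1]
        letters.append(ss if ss in SEC8_LETTERS else "C")
    if sequence_length is not None and len(letters) < sequence_length:
        letters += [MASK] * (sequence_length - len(letters))
    s8 = "".join(letters)
    if classes == 8:
        return SAEncoding(alphabet=sec8_alphabet(), letters=s8)
    return SAEncoding(alphabet=sec3_alphabet(), letters=collapse_sec8(s8))


# ---------------------------------------------------------------------------
# Trainable Cartesian fragment alphabet
# ---------------------------------------------------------------------------

def _fragment_letters(m: int) -> tuple:
    symbols = string.ascii_uppercase + string.ascii_lowercase
    if m > len(symbols):
        raise ValueError(f"at most {len(symbols)} fragment letters supported")
    return tuple(symbols[:m])


def extract_ca_fragments(structures, fragment_length: int) -> np.ndarray:
    """All fully valid Cα windows of the given odd length, centered at their
    centroid; shape (k, L, 3)."""
    frags = []
    for s in structures:
        ca = s.coords_ca
        for i in range(len(s) - fragment_length + 1):
            if np.all(s.valid[i : i + fragment_length]):
                w = ca[i : i + fragment_length]
                frags.append(w - w.mean(axis=0))
    if not frags:
        return np.empty((0, fragment_length, 3))
    return np.asarray(frags)


class FragmentAlphabetEstimator(BaseEstimator):
    """K-means-style clustering of Cα fragments under superposed RMSD.

    Fragments of ``fragment_length`` consecutive Cα atoms are pooled from
    the training structures, centered, and clustered: each iteration
    assigns every fragment to the prototype of minimal Kabsch RMSD, then
    rebuilds each prototype as the mean of its members after rotating them
    onto the current prototype (a generalized-Procrustes update).

    Parameters
    ----------
    n_prototypes : int, default 28
        Number of letters m in the trained alphabet.
    fragment_length : int, default 7
        Odd window length L in residues.
    n_iter : int, default 30
        Maximum assignment/update sweeps.
    random_state : int, default 0
        Seed for the initial prototype draw; training is deterministic
        given this seed.

    Attributes
    ----------
    prototypes_ : (m, L, 3) array
        Centered prototype fragments.
    labels_ : (k,) array
        Final cluster index of each training fragment.
    inertia_ : float
        Sum of squared superposed RMSDs to assigned prototypes.
    """

    def __init__(self, n_prototypes: int = 28, fragment_length: int = 7,
                 n_iter: int = 30, random_state: int = 0):
        self.n_prototypes = n_prototypes
        self.fragment_length = fragment_length
        self.n_iter = n_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        """Fit on a list of BackboneStructure (or a pre-extracted (k, L, 3)
        fragment array)."""
        if self.fragment_length % 2 != 1:
            raise ValueError("fragment_length must be odd")
        if isinstance(X, np.ndarray) and X.ndim == 3:
            frags = X - X.mean(axis=1, keepdims=True)
        else:
            frags = extract_ca_fragments(X, self.fragment_length)
        k = len(frags)
        m = self.n_prototypes
        if k < m:
            raise InsufficientDataError(
                f"need at least {m} fragments to train, got {k}"
            )
        rng = check_random_state(self.random_state)
        init = np.sort(rng.choice(k, size=m, replace=False))
        protos = frags[init].copy()
        labels = np.full(k, -1)
        for _ in range(self.n_iter):
            dists = kabsch_rmsd_coords(frags[:, None], protos[None, :])
            new_labels = np.argmin(dists, axis=1)
            best_d = dists[np.arange(k), new_labels]
            labels_stable = np.array_equal(new_labels, labels)
            labels = new_labels
            shift = 0.0
            for j in range(m):
                members = np.flatnonzero(labels == j)
                if members.size == 0:
                    # reseed an empty cluster with the worst-fit fragment
                    worst = int(np.argmax(best_d))
                    protos[j] = frags[worst]
                    best_d[worst] = 0.0
                    shift = np.inf
                    continue
                # iterate the Procrustes mean of the cluster to its fixed point
                mean = protos[j]
                for _ in range(100):
                    rot = kabsch_rotation(frags[members], mean[None, :, :])
                    new_mean = (frags[members] @ rot).mean(axis=0)
                    new_mean = new_mean - new_mean.mean(axis=0)
                    inner_shift = float(np.abs(new_mean - mean).max())
                    mean = new_mean
                    if inner_shift < 1e-10:
                        break
                shift = max(shift, float(np.abs(mean - protos[j]).max()))
                protos[j] = mean
            # stop once assignments are stable and the Procrustes means
            # have reached their fixed point
            if labels_stable and shift < 1e-9:
                break
        self.prototypes_ = protos
        self.labels_ = labels
        final = kabsch_rmsd_coords(frags[:, None], protos[None, :])
        self.inertia_ = float(np.sum(np.min(final, axis=1) ** 2))
        self.n_fragments_ = k
        return self

    def to_alphabet(self) -> Alphabet:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "prototypes_")
        return Alphabet(
            name="FragmentSA",
            letters=_fragment_letters(self.n_prototypes),
            kind="fragment-prototype",
            prototypes=self.prototypes_,
            fragment_length=self.fragment_length,
        )


def train_fragment_alphabet(structures, m: int = 28, fragment_length: int = 7,
                            seed: int = 0, n_iter: int = 30) -> Alphabet:
    """Train a Cartesian fragment alphabet (default 28 prototypes of 7
    residues) on a corpus of structures; deterministic given ``seed``."""
    est = FragmentAlphabetEstimator(
        n_prototypes=m, fragment_length=fragment_length,
        n_iter=n_iter, random_state=seed,
    )
    est.fit(structures)
    return est.to_alphabet()


def encode_fragment_alphabet(s: BackboneStructure, alphabet: Alphabet) -> SAEncoding:
    """Assign each residue with a full centered window the prototype of
    minimal superposed Cα RMSD; (L-1)/2 positions masked at each terminus."""
    if alphabet.kind != "fragment-prototype":
        raise ValueError("requires a fragment-prototype alphabet")
    L = alphabet.fragment_length
    half = (L - 1) // 2
    n = len(s)
    letters = [MASK] * n
    windows = []
    centers = []
    for i in range(half, n - half):
        lo, hi = i - half, i + half + 1
        if np.all(s.valid[lo:hi]):
            w = s.coords_ca[lo:hi]
            windows.append(w - w.mean(axis=0))
            centers.append(i)
    if windows:
        W = np.asarray(windows)
        d = kabsch_rmsd_coords(W[:, None], alphabet.prototypes[None, :])
        best = np.argmin(d, axis=1)
        for pos, j in zip(centers, best):
            letters[pos] = alphabet.letters[j]
    return SAEncoding(alphabet=alphabet, letters="".join(letters))


def write_encodings_fasta(encodings, labels, path) -> None:
    """Write structural-alphabet strings as FASTA, alphabet name in header."""
    lines = []
    for enc, label in zip(encodings, labels):
        lines.append(f">{label} alphabet={enc.alphabet.name}")
        lines.append(enc.letters)
    Path(path).write_text("\n".join(lines) + "\n")
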