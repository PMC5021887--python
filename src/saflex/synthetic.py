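"""Synthetic data with exact ground truth.

Everything the pipeline consumes can be generated here: ideal and perturbed
backbones built from canonical dihedrals, decoy ensembles whose
per-position local-conformation distributions (and hence entropies and
flexible/rigid labels) are known exactly, B-factor profiles that are a
noisy affine function of true entropy, and sequence profiles carrying a
planted, window-recoverable local-structure signal.

The decoy generator perturbs *local conformation classes* (dihedral swaps)
rather than adding Cartesian noise, so the generating letter distribution
at each position is exact and entropy recovery is directly testable.
Four classes are used:

====== ======================= =========================
class  (φ, ψ) degrees          role
====== ======================= =========================
``H``  (-57, -47)              α-helix
``E``  (-119, 113)             β-strand
``P``  (-75, 145)              polyproline-II-like coil
``X``  (-140, 150)             extended coil
====== ======================= =========================

``P`` and ``X`` both read as coil to a 3-class secondary-structure
alphabet (as does an isolated strand, which has no bridge partner), so
coil↔coil and strand↔coil flips are invisible at m=3 while a fine-grained
Cartesian fragment alphabet resolves them — the mechanism by which larger
alphabets detect more flexible residues.  Helix↔coil flips are visible to
every alphabet.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._geometry import place_atom
from .alphabets import MASK, Alphabet, SAEncoding
from .structure_io import BackboneStructure, Ensemble

# canonical local-conformation classes: name -> (phi, psi)
CONFORMATION_CLASSES = {
    "H": (-57.0, -47.0),
    "E": (-119.0, 113.0),
    "P": (-75.0, 145.0),
    "X": (-140.0, 150.0),
}

#: Alternative class used when a flexible position flips.
FLIP_MAP = {"H": "P", "E": "X", "P": "X", "X": "P"}

#: Alphabet over the generator's own conformation classes (ground truth).
def conformation_class_alphabet() -> Alphabet:
    return Alphabet(
        name="ConfClass",
        letters=tuple(CONFORMATION_CLASSES),
        kind="rule-based",
        fragment_length=1,
    )


# standard backbone internal coordinates (Å, degrees)
_BOND_N_CA = 1.46
_BOND_CA_C = 1.52
_BOND_C_N = 1.33
_BOND_C_O = 1.23
_ANGLE_N_CA_C = 111.0
_ANGLE_CA_C_N = 116.2
_ANGLE_C_N_CA = 121.7
_ANGLE_CA_C_O = 120.5
_OMEGA = 180.0

#: φ/ψ sampling boxes for the coil state of `make_ideal_backbone`.
_COIL_PHI_RANGE = (-100.0, -60.0)
_COIL_PSI_RANGE = (120.0, 170.0)

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class GeneratorSpec:
    """Study conditions for one synthetic decoy ensemble.

    ``variability[i]`` is the probability that a member flips position i
    from its base local-conformation class to the alternative class; a
    position is truly flexible iff its variability is positive.
    """

    n_residues: int
    ss_pattern: str
    variability: np.ndarray
    bfactor_noise_sd: float = 0.0
    n_members: int = 100
    seed: int = 0

    def __post_init__(self):
        if len(self.ss_pattern) != self.n_residues:
            raise ValueError("ss_pattern length must equal n_residues")
        if not set(self.ss_pattern) <= set("HEC"):
            raise ValueError("ss_pattern must be over {H, E, C}")
        self.variability = np.asarray(self.variability, dtype=float)
        if self.variability.shape != (self.n_residues,):
            raise ValueError("variability must have length n_residues")
        if np.any(self.variability < 0) or np.any(self.variability > 1):
            raise ValueError("variability entries must lie in [0, 1]")


def build_backbone(phi: np.ndarray, psi: np.ndarray,
                   sequence: str | None = None,
                   bfactor: np.ndarray | None = None) -> BackboneStructure:
    """Build an all-atom backbone from per-residue (φ, ψ) with standard
    bond lengths and angles and ω = 180°.

    φ[0] and ψ[-1] are not geometrically constrained for N/CA/C placement;
    ψ[-1] still orients the final carbonyl O.
    """
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    n = len(phi)
    if n < 1 or len(psi) != n:
        raise ValueError("phi and psi must be equal-length, nonempty")
    N = np.zeros((n, 3))
    CA = np.zeros((n, 3))
    C = np.zeros((n, 3))
    O = np.zeros((n, 3))
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (_BOND_N_CA, 0.0, 0.0)
    ang = np.radians(180.0 - _ANGLE_N_CA_C)
    C[0] = CA[0] + _BOND_CA_C * np.array([np.cos(np.pi - ang), np.sin(np.pi - ang), 0.0])
    for i in range(n):
        O[i] = place_atom(N[i], CA[i], C[i], _BOND_C_O, _ANGLE_CA_C_O,
                          psi[i] - 180.0)
        if i == n - 1:
            break
        N[i + 1] = place_atom(N[i], CA[i], C[i], _BOND_C_N, _ANGLE_CA_C_N, psi[i])
        CA[i + 1] = place_atom(CA[i], C[i], N[i + 1], _BOND_N_CA, _ANGLE_C_N_CA, _OMEGA)
        C[i + 1] = place_atom(C[i], N[i + 1], CA[i + 1], _BOND_CA_C, _ANGLE_N_CA_C,
                              phi[i + 1])
    if sequence is None:
        sequence = "A" * n
    if bfactor is None:
        bfactor = np.zeros(n)
    return BackboneStructure(
        residue_ids=[("A", i + 1, "") for i in range(n)],
        sequence=sequence,
        coords_n=N, coords_ca=CA, coords_c=C, coords_o=O,
        bfactor=np.asarray(bfactor, dtype=float),
        valid=np.ones(n, dtype=bool),
    )


def dihedrals_for_classes(classes: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue (φ, ψ) arrays for a string over the conformation classes."""
    phi = np.array([CONFORMATION_CLASSES[c][0] for c in classes])
    psi = np.array([CONFORMATION_CLASSES[c][1] for c in classes])
    return phi, psi


def make_ideal_backbone(ss_pattern: str, seed: int = 0) -> BackboneStructure:
    """Backbone built from canonical dihedrals for an H/E/C pattern.

    H and E use the canonical helix/strand dihedrals; C dihedrals are drawn
    per residue from a broad coil region (seeded, hence deterministic).
    """
    if not ss_pattern:
        raise ValueError("ss_pattern must be nonempty")
    if not set(ss_pattern) <= set("HEC"):
        raise ValueError("ss_pattern must be over {H, E, C}")
    rng = np.random.default_rng(seed)
    phi = np.empty(len(ss_pattern))
    psi = np.empty(len(ss_pattern))
    for i, c in enumerate(ss_pattern):
        if c in ("H", "E"):
            phi[i], psi[i] = CONFORMATION_CLASSES[c]
        else:
            phi[i] = rng.uniform(*_COIL_PHI_RANGE)
            psi[i] = rng.uniform(*_COIL_PSI_RANGE)
    seq = "".join(_AA20[i] for i in rng.integers(0, 20, size=len(ss_pattern)))
    return build_backbone(phi, psi, sequence=seq)


@dataclass
class DecoyEnsembleResult:
    """Decoy ensemble plus its exact generating ground truth.

    ``ensemble`` is None when the generator was asked for letter-level
    output only (``build_structures=False``)."""

    ensemble: Ensemble | None
    true_distributions: np.ndarray          # (n, 4) over conformation classes
    true_flex_labels: np.ndarray            # "flexible"/"rigid" per residue
    member_encodings: list = field(default_factory=list)  # ground-truth class strings

    def __iter__(self):
        # allows (ensemble, dists, labels) unpacking
        return iter((self.ensemble, self.true_distributions, self.true_flex_labels))


def base_class_string(ss_pattern: str) -> str:
    """Map an H/E/C pattern to base conformation classes (C → PPII-like P)."""
    return ss_pattern.replace("C", "P")


def true_letter_distributions(spec: GeneratorSpec) -> np.ndarray:
    """Exact generating distribution over the 4 conformation classes."""
    classes = tuple(CONFORMATION_CLASSES)
    base = base_class_string(spec.ss_pattern)
    dist = np.zeros((spec.n_residues, len(classes)))
    for i, c in enumerate(base):
        alt = FLIP_MAP[c]
        v = spec.variability[i]
        dist[i, classes.index(c)] += 1.0 - v
        dist[i, classes.index(alt)] += v
    return dist


def make_decoy_ensemble(spec: GeneratorSpec,
                        build_structures: bool = True) -> DecoyEnsembleResult:
    """Generate a decoy ensemble with known per-position letter distributions.

    Each member independently keeps each position's base conformation class
    with probability 1 - variability[i], otherwise swaps it to the
    alternative class, then the full backbone is rebuilt from the resulting
    dihedrals.  Deterministic given ``spec.seed``; the drawn class strings
    are identical whether or not the 3-D structures are materialized
    (``build_structures=False`` skips backbone construction for
    letter-level studies on large ensembles).
    """
    rng = np.random.default_rng(spec.seed)
    base = base_class_string(spec.ss_pattern)
    alt = "".join(FLIP_MAP[c] for c in base)
    seq_rng = np.random.default_rng(spec.seed + 1)
    sequence = "".join(_AA20[i] for i in seq_rng.integers(0, 20, size=spec.n_residues))
    class_alpha = conformation_class_alphabet()
    members, encodings = [], []
    for _ in range(spec.n_members):
        flips = rng.random(spec.n_residues) < spec.variability
        classes = "".join(a if f else b for f, a, b in zip(flips, alt, base))
        encodings.append(SAEncoding(alphabet=class_alpha, letters=classes))
        if build_structures:
            phi, psi = dihedrals_for_classes(classes)
            members.append(build_backbone(phi, psi, sequence=sequence))
    labels = np.where(spec.variability > 0, "flexible", "rigid")
    return DecoyEnsembleResult(
        ensemble=Ensemble(members=members) if build_structures else None,
        true_distributions=true_letter_distributions(spec),
        true_flex_labels=labels,
        member_encodings=encodings,
    )


def true_entropy(spec: GeneratorSpec) -> np.ndarray:
    """Exact per-position entropy (nats) of the generating distribution."""
    p = true_letter_distributions(spec)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    return -terms.sum(axis=1)


def make_synthetic_bfactors(true_entropy: np.ndarray, noise_sd: float,
                            seed: int = 0, scale: float = 20.0,
                            offset: float = 10.0) -> np.ndarray:
    """B-factors as a noisy increasing affine function of entropy:
    B_i = scale·H_i + offset + N(0, noise_sd)."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be ≥ 0")
    rng = np.random.default_rng(seed)
    h = np.asarray(true_entropy, dtype=float)
    return scale * h + offset + rng.normal(0.0, noise_sd, size=h.shape)


#: Default mixed secondary-structure unit for study-condition ensembles:
#: a helix, two strands and connecting coil, tiled to the requested length.
_DEFAULT_PATTERN_UNIT = "HHHHHHHHHHCCCCCCEEEEEECCCCEEEEEE"


def default_generator_spec(seed: int, n_residues: int = 60,
                           n_members: int = 40,
                           flip_prob: float = 0.4) -> GeneratorSpec:
    """Reference study conditions for one synthetic ensemble.

    A 60-residue protein with a helix, strands and coil linkers; every
    coil position plus one helix-interior and one strand-interior position
    is flexible with flip probability 0.4, the rest are rigid.  Coil
    positions flip between coil sub-conformations (invisible to a 3-class
    alphabet), the helix/strand positions melt to coil (visible to every
    alphabet).
    """
    pattern = (_DEFAULT_PATTERN_UNIT * (n_residues // len(_DEFAULT_PATTERN_UNIT) + 1))
    pattern = pattern[:n_residues]
    arr = np.array(list(pattern))
    variability = np.where(arr == "C", flip_prob, 0.0)
    helix = np.flatnonzero(arr == "H")
    strand = np.flatnonzero(arr == "E")
    if helix.size:
        variability[helix[len(helix) // 2]] = flip_prob
    if strand.size:
        variability[strand[len(strand) // 2]] = flip_prob
    return GeneratorSpec(n_residues=n_residues, ss_pattern=pattern,
                         variability=variability, n_members=n_members, seed=seed)


def random_segment_letters(rng: np.random.Generator, n_residues: int = 100,
                           letters: str = "HEC",
                           min_len: int = 4, max_len: int = 12) -> str:
    """Random segmental letter string (uniform class, uniform segment
    length in [min_len, max_len]) — planted neighbour correlation for
    predictor corpora."""
    out: list = []
    while len(out) < n_residues:
        c = letters[rng.integers(0, len(letters))]
        out.extend(c * int(rng.integers(min_len, max_len + 1)))
    return "".join(out[:n_residues])


def make_predictor_corpus(n_proteins: int = 20, n_residues: int = 100,
                          signal_strength: float = 0.25, seed: int = 0,
                          alphabet: Alphabet | None = None):
    """Matched (profiles, encodings) with a planted sequence→letter signal.

    Letters form random segments over the alphabet (default 3-class
    secondary structure), so neighbouring labels are strongly correlated;
    profiles carry the letter-dependent pattern of
    :func:`make_synthetic_profiles`.
    """
    from .alphabets import sec3_alphabet

    if alphabet is None:
        alphabet = sec3_alphabet()
    rng = np.random.default_rng(seed)
    encodings = [
        SAEncoding(alphabet=alphabet,
                   letters=random_segment_letters(rng, n_residues,
                                                  letters="".join(alphabet.letters)))
        for _ in range(n_proteins)
    ]
    profiles = make_synthetic_profiles(encodings, signal_strength=signal_strength,
                                       seed=seed + 1)
    return profiles, encodings


def make_synthetic_profiles(encodings, signal_strength: float = 0.25,
                            seed: int = 0, noise_sd: float = 1.0):
    """Sequence profiles with a planted letter→pattern signal.

    Each alphabet letter gets a fixed 20-dimensional offset pattern (drawn
    once from the seed); a residue's 20-vector is Gaussian base noise plus
    ``signal_strength`` times its letter's pattern, then squashed through
    the logistic function like a parsed PSSM.  Masked positions carry noise
    only.  Returns a list of SequenceProfile.
    """
    from .predictor import SequenceProfile, squash_logodds

    if signal_strength < 0:
        raise ValueError("signal_strength must be ≥ 0")
    rng = np.random.default_rng(seed)
    m = encodings[0].alphabet.size
    patterns = rng.normal(size=(m, 20))
    profiles = []
    for enc in encodings:
        n = len(enc)
        logodds = rng.normal(0.0, noise_sd, size=(n, 20))
        idx = enc.indices()
        present = idx >= 0
        logodds[present] += signal_strength * patterns[idx[present]]
        seq = "".join(_AA20[i] for i in rng.integers(0, 20, size=n))
        profiles.append(SequenceProfile(sequence=seq, scores=squash_logodds(logodds)))
    return profiles
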