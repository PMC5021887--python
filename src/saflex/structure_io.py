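"""Reading, writing and validating backbone coordinate data.

The central container is :class:`BackboneStructure`: per-residue backbone
atom coordinates (N, CA, C, O), one-letter sequence, Cα B-factors and a
validity mask.  Residues with missing backbone atoms or a chain break to a
neighbour are masked rather than dropped, so arrays always keep the full
chain length and masked positions propagate through every downstream
per-residue quantity.

Ensembles (multi-MODEL NMR files, decoy directories) are lists of
structures sharing one sequence.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.SeqUtils import seq1, seq3

from ._geometry import kabsch_rmsd_coords

logger = logging.getLogger(__name__)

#: Cα-Cα distance above which consecutive residues are treated as a chain
#: break (trans peptide ~3.8 Å; cis ~2.9 Å).
CHAIN_BREAK_CUTOFF = 4.5

BACKBONE_ATOMS = ("N", "CA", "C", "O")


class EmptyStructureError(ValueError):
    """No parsable residues / members were found."""


class InsufficientDataError(ValueError):
    """Too few usable positions for the requested computation."""


@dataclass
class BackboneStructure:
    """Backbone geometry and B-factors of one protein chain conformation.

    Attributes
    ----------
    residue_ids : list of (chain_id, resseq, icode)
        Author numbering, used for reporting only.
    sequence : str
        One-letter amino-acid sequence ('X' for nonstandard residues).
    coords_n, coords_ca, coords_c, coords_o : (n, 3) float arrays
        Backbone atom positions in Å; NaN where the atom is absent.
    bfactor : (n,) float array
        Cα temperature factor in Å²; NaN where Cα is absent.
    valid : (n,) bool array
        True where all four backbone atoms are present and the residue is
        not flanking a chain break.
    """

    residue_ids: list
    sequence: str
    coords_n: np.ndarray
    coords_ca: np.ndarray
    coords_c: np.ndarray
    coords_o: np.ndarray
    bfactor: np.ndarray
    valid: np.ndarray

    def __post_init__(self):
        n = len(self.sequence)
        if n < 1:
            raise EmptyStructureError("structure must contain at least one residue")
        for name in ("coords_n", "coords_ca", "coords_c", "coords_o"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n, 3):
                raise ValueError(f"{name} must have shape ({n}, 3), got {arr.shape}")
            setattr(self, name, arr)
        self.bfactor = np.asarray(self.bfactor, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.bfactor.shape != (n,) or self.valid.shape != (n,):
            raise ValueError("bfactor and valid must be length-n vectors")
        if len(self.residue_ids) != n:
            raise ValueError("residue_ids must have length n")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def n_residues(self) -> int:
        return len(self.sequence)


@dataclass
class Ensemble:
    """Conformational variants (models, decoys) of a single sequence."""

    members: list
    source_labels: list = field(default_factory=list)

    def __post_init__(self):
        if not self.members:
            raise EmptyStructureError("ensemble must contain at least one member")
        ref = self.members[0].sequence
        for m in self.members[1:]:
            if m.sequence != ref:
                raise ValueError("all ensemble members must share one sequence")
        if not self.source_labels:
            self.source_labels = [f"member_{i}" for i in range(len(self.members))]
        if len(self.source_labels) != len(self.members):
            raise ValueError("one source label per member required")

    def __len__(self) -> int:
        return len(self.members)

    @property
    def sequence(self) -> str:
        return self.members[0].sequence


def _apply_chain_break_mask(structure: BackboneStructure) -> BackboneStructure:
    """Invalidate both residues flanking any Cα-Cα gap ≥ CHAIN_BREAK_CUTOFF."""
    valid = structure.valid.copy()
    ca = structure.coords_ca
    for i in range(len(structure) - 1):
        if valid[i] and valid[i + 1]:
            d = np.linalg.norm(ca[i + 1] - ca[i])
            if not d < CHAIN_BREAK_CUTOFF:
                valid[i] = False
                valid[i + 1] = False
    structure.valid = valid
    return structure


def _structure_from_biopython_chain(chain) -> BackboneStructure | None:
    residue_ids = []
    seq_letters = []
    coords = {a: [] for a in BACKBONE_ATOMS}
    bfac = []
    valid = []
    for res in chain:
        hetflag, resseq, icode = res.get_id()
        if hetflag.strip():
            continue  # waters / ligands
        residue_ids.append((chain.get_id(), resseq, icode.strip()))
        try:
            letter = seq1(res.get_resname(), undef_code="X")
        except Exception:
            letter = "X"
        seq_letters.append(letter if letter.strip() else "X")
        ok = True
        for a in BACKBONE_ATOMS:
            if a in res:
                atom = res[a]
                # DisorderedAtom resolves to highest occupancy automatically
                coords[a].append(np.asarray(atom.get_coord(), dtype=float))
            else:
                coords[a].append(np.full(3, np.nan))
                ok = False
        bfac.append(float(res["CA"].get_bfactor()) if "CA" in res else np.nan)
        valid.append(ok)
    if not residue_ids:
        return None
    s = BackboneStructure(
        residue_ids=residue_ids,
        sequence="".join(seq_letters),
        coords_n=np.array(coords["N"]),
        coords_ca=np.array(coords["CA"]),
        coords_c=np.array(coords["C"]),
        coords_o=np.array(coords["O"]),
        bfactor=np.array(bfac),
        valid=np.array(valid),
    )
    return _apply_chain_break_mask(s)


def read_pdb(path, chain: str | None = None) -> Ensemble:
    """Read a PDB file into an :class:`Ensemble`, one member per MODEL.

    Residues are ordered by chain then residue number; alternate locations
    resolve to the highest-occupancy conformer.  Only the first chain is
    used unless `chain` names one explicitly.  B-factors come from the Cα
    atom.  Residues missing any of N/CA/C/O stay in the arrays but are
    flagged invalid.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure(path.stem, str(path))
    members = []
    labels = []
    for model in structure:
        chains = {c.get_id(): c for c in model}
        if not chains:
            continue
        if chain is not None:
            if chain not in chains:
                continue
            picked = chains[chain]
        else:
            picked = next(iter(model))
        s = _structure_from_biopython_chain(picked)
        if s is not None:
            members.append(s)
            labels.append(f"{path.name}:model{model.get_id()}")
    if not members:
        raise EmptyStructureError(f"no parsable residues in {path}")
    return Ensemble(members=members, source_labels=labels)


def read_decoy_dir(directory, chain: str | None = None) -> Ensemble:
    """Pool every ``*.pdb`` file in a directory into one decoy ensemble.

    Files whose sequence disagrees with the first readable file are skipped
    with a warning.
    """
    directory = Path(directory)
    files = sorted(directory.glob("*.pdb"))
    members = []
    labels = []
    ref_seq = None
    for f in files:
        try:
            ens = read_pdb(f, chain=chain)
        except (IOError, EmptyStructureError) as exc:
            logger.warning("skipping %s: %s", f.name, exc)
            continue
        for member, label in zip(ens.members, ens.source_labels):
            if ref_seq is None:
                ref_seq = member.sequence
            if member.sequence != ref_seq:
                logger.warning("skipping %s: sequence mismatch", label)
                continue
            members.append(member)
            labels.append(label)
    if not members:
        raise EmptyStructureError(f"no consistent decoy members found in {directory}")
    return Ensemble(members=members, source_labels=labels)


def write_pdb(obj, path) -> None:
    """Write a BackboneStructure or Ensemble as fixed-column PDB text.

    Multi-member ensembles get MODEL/ENDMDL blocks.  Atoms with NaN
    coordinates are omitted (re-reading flags those residues invalid).
    """
    if isinstance(obj, BackboneStructure):
        members = [obj]
    else:
        members = obj.members
    lines = []
    multi = len(members) > 1
    for k, s in enumerate(members, start=1):
        if multi:
            lines.append(f"MODEL     {k:4d}")
        serial = 1
        for i in range(len(s)):
            chain_id, resseq, icode = s.residue_ids[i]
            resname = seq3(s.sequence[i]).upper() if s.sequence[i] != "X" else "UNK"
            b = s.bfactor[i]
            b = 0.0 if not np.isfinite(b) else b
            for atom, arr in zip(
                BACKBONE_ATOMS, (s.coords_n, s.coords_ca, s.coords_c, s.coords_o)
            ):
                xyz = arr[i]
                if not np.all(np.isfinite(xyz)):
                    continue
                name = f" {atom:<3s}"
                lines.append(
                    f"ATOM  {serial:5d} {name}{'':1s}{resname:>3s} "
                    f"{str(chain_id)[:1] or 'A'}{int(resseq):4d}{(icode or ''):1s}   "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{b:6.2f}"
                    f"          {atom[0]:>2s}"
                )
                serial += 1
        lines.append("TER")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def kabsch_rmsd(a: BackboneStructure, b: BackboneStructure) -> float:
    """Minimal Cα RMSD (Å) between two equal-length structures after optimal
    rigid-body superposition, over positions valid in both."""
    if len(a) != len(b):
        raise ValueError("structures must have equal length")
    shared = a.valid & b.valid
    if int(shared.sum()) < 3:
        raise InsufficientDataError(
            f"need ≥3 shared valid positions, got {int(shared.sum())}"
        )
    return float(kabsch_rmsd_coords(a.coords_ca[shared], b.coords_ca[shared]))
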