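"""Per-position letter frequencies and conformational entropy.

Given an ensemble of structural-alphabet encodings of one protein, the
letter matrix holds a_ij — the frequency of alphabet letter j among the
conformations at position i — and the conformational entropy is the
Shannon entropy of each row in nats:

    H(i) = -Σ_j a_ij ln a_ij,       0·ln 0 := 0.

The same formula applies to a predictor's per-residue class distribution.
Entropy is never normalized: its ceiling ln m grows with alphabet size by
design, so thresholds are alphabet-specific.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import entropy as _scipy_entropy

from .alphabets import SAEncoding


class IncompatibleEncodingError(ValueError):
    """Encodings do not share one alphabet and length."""


class InvalidDistributionError(ValueError):
    """A class-distribution row does not sum to 1."""


@dataclass
class LetterMatrix:
    """n×m per-position letter frequency matrix from an ensemble.

    ``support[i]`` counts the unmasked conformations contributing at
    position i; rows with zero support are all-zero and masked downstream.
    """

    freq: np.ndarray
    support: np.ndarray
    letters: tuple

    def __post_init__(self):
        self.freq = np.asarray(self.freq, dtype=float)
        self.support = np.asarray(self.support, dtype=int)
        n, m = self.freq.shape
        if m != len(self.letters):
            raise ValueError("freq width must equal number of letters")
        if self.support.shape != (n,):
            raise ValueError("support must have length n")
        if np.any(self.freq < -1e-12) or np.any(self.freq > 1 + 1e-12):
            raise ValueError("frequencies must lie in [0, 1]")
        sums = self.freq[self.support > 0].sum(axis=1)
        if sums.size and not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("supported rows must sum to 1")

    @property
    def n(self) -> int:
        return self.freq.shape[0]

    @property
    def m(self) -> int:
        return self.freq.shape[1]


@dataclass
class EntropyProfile:
    """Per-residue entropy H(i) in nats with a validity mask."""

    values: np.ndarray
    mask: np.ndarray  # True where the value is defined

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask must have equal shape")

    def __len__(self) -> int:
        return len(self.values)

    def unmasked(self) -> np.ndarray:
        return self.values[self.mask]


@dataclass
class ClassDistribution:
    """One probability distribution over m letters per residue."""

    probs: np.ndarray

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2:
            raise ValueError("probs must be an n×m matrix")
        if np.any(self.probs < 0):
            raise InvalidDistributionError("probabilities must be ≥ 0")

    @property
    def n(self) -> int:
        return self.probs.shape[0]

    @property
    def m(self) -> int:
        return self.probs.shape[1]


def letter_matrix(encodings) -> LetterMatrix:
    """Per-position letter frequencies across an ensemble of encodings.

    Masked symbols are excluded from the denominator position by position
    (support-aware); a row seen in no conformation has zero support.
    """
    if not encodings:
        raise IncompatibleEncodingError("need at least one encoding")
    ref = encodings[0].alphabet
    n = len(encodings[0])
    for e in encodings:
        if e.alphabet.letters != ref.letters or len(e) != n:
            raise IncompatibleEncodingError(
                "all encodings must share one alphabet and length"
            )
    m = ref.size
    counts = np.zeros((n, m))
    for e in encodings:
        idx = e.indices()
        present = idx >= 0
        counts[np.flatnonzero(present), idx[present]] += 1.0
    support = counts.sum(axis=1)
    freq = np.zeros_like(counts)
    nz = support > 0
    freq[nz] = counts[nz] / support[nz, None]
    return LetterMatrix(freq=freq, support=support.astype(int), letters=ref.letters)


def _row_entropy(p: np.ndarray) -> np.ndarray:
    """Natural-log Shannon entropy of each row (rows assumed normalized)."""
    return _scipy_entropy(p, axis=1)


def conformational_entropy(mat: LetterMatrix) -> EntropyProfile:
    """Eq-style conformational entropy H(i) = -Σ_j a_ij ln a_ij per row;
    zero-support rows stay masked."""
    mask = mat.support > 0
    values = np.zeros(mat.n)
    if mask.any():
        values[mask] = _row_entropy(mat.freq[mask])
    values[~mask] = np.nan
    return EntropyProfile(values=values, mask=mask)


def prediction_entropy(d: ClassDistribution) -> EntropyProfile:
    """Entropy of a predicted per-residue class distribution (nats)."""
    sums = d.probs.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        bad = int(np.argmax(np.abs(sums - 1.0)))
        raise InvalidDistributionError(
            f"row {bad} sums to {sums[bad]:.8f}, expected 1"
        )
    values = _row_entropy(d.probs / sums[:, None])
    return EntropyProfile(values=values, mask=np.ones(d.n, dtype=bool))


def entropy_from_encodings(encodings) -> EntropyProfile:
    """Convenience: ensemble encodings → letter matrix → entropy profile."""
    return conformational_entropy(letter_matrix(encodings))


def write_entropy_table(mat: LetterMatrix, profile: EntropyProfile,
                        residue_ids, path) -> None:
    """Export per-residue frequencies and entropy as tab-separated text."""
    header = ["residue_id"] + [f"freq_{c}" for c in mat.letters] + ["entropy", "masked"]
    lines = ["\t".join(header)]
    for i in range(mat.n):
        rid = residue_ids[i] if residue_ids is not None else i
        row = [str(rid)] + [f"{x:.6f}" for x in mat.freq[i]]
        h = f"{profile.values[i]:.6f}" if profile.mask[i] else "NA"
        row += [h, "0" if profile.mask[i] else "1"]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")
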