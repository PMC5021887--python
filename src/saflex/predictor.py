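"""Dual-layer local-structure prediction from sequence profiles.

A first-layer probabilistic classifier maps a sliding window of
position-specific scoring matrix (PSSM) features to a distribution over
structural-alphabet letters; a second-layer classifier refines each
residue's distribution from a window of neighbouring first-layer outputs,
exploiting the strong correlation between adjacent local structures.  The
second layer is trained on cross-fitted first-layer outputs (grouped by
protein) so that it never sees optimistically overfit inputs.

Both layers default to L2-regularized multinomial logistic regression;
any probabilistic multiclass classifier with the sklearn interface can be
substituted via the ``base_estimator`` parameter.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, clone
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GroupKFold
from sklearn.utils.validation import check_is_fitted

from .alphabets import MASK, Alphabet, SAEncoding
from .entropy import ClassDistribution

_PSSM_AA_ORDER = "ARNDCQEGHILKMFPSTWYV"  # PSI-BLAST column order

_MODEL_FORMAT_VERSION = 1


class PSSMParseError(ValueError):
    pass


class DegenerateTrainingError(ValueError):
    """Fewer than two letter classes present in the training data."""


def squash_logodds(x: np.ndarray) -> np.ndarray:
    """Logistic squashing of PSSM log-odds into (0, 1)."""
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def unsquash(p: np.ndarray) -> np.ndarray:
    """Inverse of :func:`squash_logodds` (logit)."""
    p = np.asarray(p, dtype=float)
    return np.log(p / (1.0 - p))


@dataclass
class SequenceProfile:
    """Per-residue 20-column profile features in (0, 1) plus the sequence.

    ``scores`` holds logistic-squashed log-odds, in PSI-BLAST amino-acid
    column order (ARNDCQEGHILKMFPSTWYV).
    """

    sequence: str
    scores: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError("scores must be an n×20 matrix")
        if self.scores.shape[0] != len(self.sequence):
            raise ValueError("row count must equal sequence length")

    def __len__(self) -> int:
        return len(self.sequence)


def read_pssm(path) -> SequenceProfile:
    """Parse a PSI-BLAST ASCII PSSM (``-out_ascii_pssm`` layout).

    The 20 log-odds columns are squashed through the logistic function.
    Rows may carry the trailing weighted-percentage and information
    columns of real PSI-BLAST output; they are ignored.
    """
    lines = Path(path).read_text().splitlines()
    seq = []
    rows = []
    expected = 1
    for lineno, line in enumerate(lines, start=1):
        parts = line.split()
        if len(parts) < 22 or not parts[0].isdigit():
            continue
        if len(parts[1]) != 1 or not parts[1].isalpha():
            continue
        if int(parts[0]) != expected:
            raise PSSMParseError(
                f"line {lineno}: residue index {parts[0]}, expected {expected}"
            )
        try:
            values = [float(x) for x in parts[2:22]]
        except ValueError as exc:
            raise PSSMParseError(f"line {lineno}: malformed log-odds row: {exc}")
        seq.append(parts[1])
        rows.append(values)
        expected += 1
    if not rows:
        raise PSSMParseError(f"no PSSM rows found in {path}")
    return SequenceProfile(sequence="".join(seq),
                           scores=squash_logodds(np.asarray(rows)))


def write_pssm(profile: SequenceProfile, path) -> None:
    """Write a profile in PSI-BLAST-like ASCII layout (float log-odds)."""
    header = (
        "\nLast position-specific scoring matrix computed\n"
        "            " + "  ".join(_PSSM_AA_ORDER) + "\n"
    )
    lines = [header]
    logodds = unsquash(np.clip(profile.scores, 1e-12, 1 - 1e-12))
    for i, aa in enumerate(profile.sequence):
        row = " ".join(f"{v:10.6f}" for v in logodds[i])
        lines.append(f"{i + 1:5d} {aa} {row}")
    Path(path).write_text("\n".join(lines) + "\n")


def window_features(profile: SequenceProfile, i: int, window: int) -> np.ndarray:
    """Concatenated profile rows i-(W-1)/2 .. i+(W-1)/2, zero-padded at the
    chain ends; shape (window*20,)."""
    if window % 2 != 1:
        raise ValueError("window must be odd")
    half = (window - 1) // 2
    n = len(profile)
    out = np.zeros((window, 20))
    lo = max(0, i - half)
    hi = min(n, i + half + 1)
    out[lo - (i - half) : hi - (i - half)] = profile.scores[lo:hi]
    return out.ravel()


def _stack_windows(matrix: np.ndarray, window: int) -> np.ndarray:
    """All sliding windows of a per-residue feature matrix, zero-padded;
    (n, window*width)."""
    n, width = matrix.shape
    half = (window - 1) // 2
    padded = np.vstack([np.zeros((half, width)), matrix, np.zeros((half, width))])
    return np.stack([padded[i : i + window].ravel() for i in range(n)])


class DualLayerLocalStructurePredictor(BaseEstimator):
    """Two-stage sequence → structural-alphabet-letter classifier.

    Parameters
    ----------
    alphabet : Alphabet
        Target letter set; outputs are distributions over its m letters.
    window1 : odd int, default 15
        PSSM window width of the first layer.
    window2 : odd int, default 9
        Width of the second layer's window over first-layer distributions.
    base_estimator : sklearn classifier or None
        Prototype for both layers; must implement ``predict_proba``.
        Defaults to L2 multinomial logistic regression.
    cv : int, default 5
        Folds (grouped by protein) for cross-fitting layer-1 outputs used
        to train layer 2.
    random_state : int, default 0

    Attributes
    ----------
    layer1_, layer2_ : fitted classifiers
    classes_ : letter indices seen in training
    """

    def __init__(self, alphabet: Alphabet, window1: int = 15, window2: int = 9,
                 base_estimator=None, cv: int = 5, random_state: int = 0):
        self.alphabet = alphabet
        self.window1 = window1
        self.window2 = window2
        self.base_estimator = base_estimator
        self.cv = cv
        self.random_state = random_state

    def _make_estimator(self):
        if self.base_estimator is not None:
            est = clone(self.base_estimator)
        else:
            est = LogisticRegression(max_iter=500, C=1.0)
        if "random_state" in est.get_params():
            est.set_params(random_state=self.random_state)
        return est

    def _layer1_features(self, profiles):
        return [_stack_windows(p.scores, self.window1) for p in profiles]

    def _expand_proba(self, clf, proba: np.ndarray) -> np.ndarray:
        """Map classifier output onto all m alphabet letters."""
        full = np.zeros((proba.shape[0], self.alphabet.size))
        full[:, np.asarray(clf.classes_, dtype=int)] = proba
        return full

    def fit(self, X, y):
        """Fit on matched lists of SequenceProfile (X) and SAEncoding (y);
        masked positions are excluded from both layers' training."""
        if self.window1 % 2 != 1 or self.window2 % 2 != 1:
            raise ValueError("window sizes must be odd")
        if len(X) != len(y):
            raise ValueError("need one encoding per profile")
        feats = self._layer1_features(X)
        targets = [enc.indices() for enc in y]
        rows, labels, groups = [], [], []
        for g, (f, t) in enumerate(zip(feats, targets)):
            keep = t >= 0
            rows.append(f[keep])
            labels.append(t[keep])
            groups.append(np.full(int(keep.sum()), g))
        X1 = np.vstack(rows)
        y1 = np.concatenate(labels)
        groups = np.concatenate(groups)
        present = np.unique(y1)
        if present.size < 2:
            raise DegenerateTrainingError(
                f"training data contains {present.size} letter class(es); need ≥2"
            )
        self.layer1_ = self._make_estimator().fit(X1, y1)

        # cross-fitted layer-1 distributions per protein, then layer-2 windows
        n_groups = len(X)
        n_splits = int(min(self.cv, n_groups))
        cross = [np.zeros((len(p), self.alphabet.size)) for p in X]
        if n_splits >= 2:
            splitter = GroupKFold(n_splits=n_splits)
            group_ids = np.arange(n_groups)
            for train_idx, test_idx in splitter.split(group_ids, groups=group_ids):
                tr_rows = np.isin(groups, train_idx)
                if np.unique(y1[tr_rows]).size < 2:
                    raise DegenerateTrainingError("a cross-fit fold is single-class")
                fold_clf = self._make_estimator().fit(X1[tr_rows], y1[tr_rows])
                for g in test_idx:
                    proba = fold_clf.predict_proba(feats[g])
                    cross[g] = self._expand_proba(fold_clf, proba)
        else:
            # single protein: fall back to in-sample layer-1 outputs
            cross[0] = self._expand_proba(self.layer1_, self.layer1_.predict_proba(feats[0]))

        rows2, labels2 = [], []
        for g, t in enumerate(targets):
            w2 = _stack_windows(cross[g], self.window2)
            keep = t >= 0
            rows2.append(w2[keep])
            labels2.append(t[keep])
        self.layer2_ = self._make_estimator().fit(np.vstack(rows2), np.concatenate(labels2))
        self.classes_ = np.asarray(self.layer2_.classes_, dtype=int)
        return self

    def predict_layer1(self, profile: SequenceProfile) -> ClassDistribution:
        """First-layer distributions only (for single- vs dual-layer
        comparisons)."""
        check_is_fitted(self, "layer1_")
        f = _stack_windows(profile.scores, self.window1)
        return ClassDistribution(probs=self._expand_proba(self.layer1_, self.layer1_.predict_proba(f)))

    def predict_proba(self, profile: SequenceProfile) -> ClassDistribution:
        """Refined per-residue distribution over the full alphabet."""
        check_is_fitted(self, "layer2_")
        f1 = _stack_windows(profile.scores, self.window1)
        p1 = self._expand_proba(self.layer1_, self.layer1_.predict_proba(f1))
        f2 = _stack_windows(p1, self.window2)
        p2 = self._expand_proba(self.layer2_, self.layer2_.predict_proba(f2))
        return ClassDistribution(probs=p2)

    def predict(self, profile: SequenceProfile) -> SAEncoding:
        """Argmax letters (ties break to the lowest letter index)."""
        d = self.predict_proba(profile)
        letters = "".join(self.alphabet.letters[int(j)] for j in np.argmax(d.probs, axis=1))
        return SAEncoding(alphabet=self.alphabet, letters=letters)

    def save(self, path) -> None:
        check_is_fitted(self, "layer2_")
        payload = {"format_version": _MODEL_FORMAT_VERSION, "model": self}
        with open(path, "wb") as fh:
            pickle.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "DualLayerLocalStructurePredictor":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        if payload.get("format_version") != _MODEL_FORMAT_VERSION:
            raise ValueError("unsupported model archive version")
        return payload["model"]


def train_dual_layer(profiles, encodings, alphabet: Alphabet | None = None,
                     **kwargs) -> DualLayerLocalStructurePredictor:
    """Fit a dual-layer predictor on matched profiles and encodings."""
    if alphabet is None:
        alphabet = encodings[0].alphabet
    model = DualLayerLocalStructurePredictor(alphabet=alphabet, **kwargs)
    return model.fit(profiles, encodings)


def predict_distribution(model: DualLayerLocalStructurePredictor,
                         profile: SequenceProfile) -> ClassDistribution:
    return model.predict_proba(profile)


def q_score(pred: ClassDistribution, truth: SAEncoding) -> float:
    """Fraction of unmasked residues whose argmax predicted letter matches
    the assigned letter (generalizes Q3); argmax ties break low."""
    if pred.n != len(truth):
        raise ValueError("prediction and encoding length mismatch")
    idx = truth.indices()
    keep = idx >= 0
    if not keep.any():
        raise ValueError("no unmasked residues to score")
    best = np.argmax(pred.probs[keep], axis=1)
    return float(np.mean(best == idx[keep]))
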