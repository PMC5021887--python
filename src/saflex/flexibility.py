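"""Flexibility analysis: entropy–B-factor correlation, flexible-residue
labeling and classification, RMSD-uniform decoy selection, and evaluation
metrics (sensitivity, specificity, precision, ROC).

Ground-truth labels come from the ensemble rule: a residue whose
structural-alphabet letter differs between conformations is *flexible*,
otherwise *rigid*.  Predictions call a residue flexible when its entropy
exceeds a threshold T (strictly), with T defaulting to the pooled mean
entropy over a reference dataset.  Flexible is the positive class
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr
from sklearn.base import BaseEstimator
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .entropy import EntropyProfile
from .structure_io import BackboneStructure, Ensemble, InsufficientDataError, kabsch_rmsd

FLEXIBLE = "flexible"
RIGID = "rigid"
MASKED = "masked"

#: Default decoy RMSD bin edges in Å: <3, 3-4, 4-5, 5-6, >6.
DEFAULT_BIN_EDGES = (0.0, 3.0, 4.0, 5.0, 6.0, np.inf)


class UndefinedCorrelationError(ValueError):
    """Correlation is undefined (zero variance in a vector)."""


class UndefinedROCError(ValueError):
    """ROC is undefined (single-class truth)."""


@dataclass
class FlexLabels:
    """Per-residue flexible/rigid/masked labels."""

    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=object)
        bad = set(self.labels) - {FLEXIBLE, RIGID, MASKED}
        if bad:
            raise ValueError(f"unknown labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def evaluated(self) -> np.ndarray:
        return self.labels != MASKED

    def binary(self) -> np.ndarray:
        """1 for flexible, 0 for rigid, over evaluated positions only."""
        return (self.labels[self.evaluated] == FLEXIBLE).astype(int)


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class EvalResult:
    """Classification metrics plus the ROC sweep for one evaluation."""

    sensitivity: float
    specificity: float
    precision: float
    roc_points: np.ndarray
    roc_score: float
    threshold_T: float
    counts: ConfusionCounts


def bfactor_correlation(h: EntropyProfile, bfactor: np.ndarray) -> float:
    """Pearson correlation between entropy and B-factor over jointly
    unmasked positions."""
    b = np.asarray(bfactor, dtype=float)
    if len(b) != len(h):
        raise ValueError("entropy profile and B-factor length mismatch")
    joint = h.mask & np.isfinite(b)
    if int(joint.sum()) < 3:
        raise InsufficientDataError("need ≥3 jointly unmasked positions")
    x = h.values[joint]
    y = b[joint]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in entropy or B-factor")
    return float(pearsonr(x, y).statistic)


def label_flexible_from_ensemble(encodings) -> FlexLabels:
    """Flexible iff ≥2 distinct non-mask letters appear at a position across
    the conformations; rigid iff exactly one; masked if none."""
    if len(encodings) < 2:
        raise InsufficientDataError("need at least 2 conformations to label")
    n = len(encodings[0])
    ref = encodings[0].alphabet
    for e in encodings:
        if len(e) != n or e.alphabet.letters != ref.letters:
            raise ValueError("encodings must share alphabet and length")
    labels = []
    for i in range(n):
        seen = {e.letters[i] for e in encodings} - {"-"}
        if not seen:
            labels.append(MASKED)
        elif len(seen) == 1:
            labels.append(RIGID)
        else:
            labels.append(FLEXIBLE)
    return FlexLabels(labels=np.array(labels, dtype=object))


def mean_entropy_threshold(profiles) -> float:
    """Pooled mean entropy over all unmasked residues of all profiles
    (residue-weighted): the default decision threshold T."""
    pooled = np.concatenate([p.unmasked() for p in profiles]) if profiles else np.array([])
    if pooled.size == 0:
        raise InsufficientDataError("no unmasked residues to average")
    return float(pooled.mean())


def classify_by_threshold(h: EntropyProfile, threshold: float) -> FlexLabels:
    """Flexible iff H(i) > T (strict); boundary values count as rigid."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    labels = np.where(h.mask,
                      np.where(h.values > threshold, FLEXIBLE, RIGID),
                      MASKED)
    return FlexLabels(labels=labels.astype(object))


def confusion(pred: FlexLabels, truth: FlexLabels) -> ConfusionCounts:
    """TP/FP/TN/FN over positions unmasked in both; flexible = positive."""
    if len(pred) != len(truth):
        raise ValueError("label length mismatch")
    both = pred.evaluated & truth.evaluated
    p = pred.labels[both] == FLEXIBLE
    t = truth.labels[both] == FLEXIBLE
    return ConfusionCounts(
        TP=int(np.sum(p & t)),
        FP=int(np.sum(p & ~t)),
        TN=int(np.sum(~p & ~t)),
        FN=int(np.sum(~p & t)),
    )


def metrics(c: ConfusionCounts) -> dict:
    """Sensitivity, specificity and precision; NaN where the denominator
    is zero (undefined for that metric, not a global failure)."""
    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    return {
        "sensitivity": ratio(c.TP, c.TP + c.FN),
        "specificity": ratio(c.TN, c.TN + c.FP),
        "precision": ratio(c.TP, c.TP + c.FP),
    }


def roc_score(scores: np.ndarray, truth: FlexLabels) -> tuple[np.ndarray, float]:
    """ROC sweep over the entropy scores with flexible as positive.

    Thresholds group tied scores into single sweep steps; the score is the
    normalized (trapezoidal) area under the curve, 1 for perfect
    separation and 0 for perfectly inverted ranking.  Returns
    (roc_points, score) where roc_points are (FPR, TPR) pairs from (0,0)
    to (1,1).
    """
    scores = np.asarray(scores, dtype=float)
    if len(scores) != len(truth):
        raise ValueError("scores and truth length mismatch")
    keep = truth.evaluated & np.isfinite(scores)
    y = (truth.labels[keep] == FLEXIBLE).astype(int)
    s = scores[keep]
    if y.sum() == 0 or y.sum() == len(y):
        raise UndefinedROCError("ROC requires both a positive and a negative")
    fpr, tpr, _ = _sk_roc_curve(y, s)
    return np.column_stack([fpr, tpr]), float(_sk_auc(fpr, tpr))


def evaluate(scores: np.ndarray, truth: FlexLabels,
             threshold: float) -> EvalResult:
    """Full evaluation at a threshold: confusion counts, the three ratio
    metrics and the threshold-free ROC sweep."""
    profile = EntropyProfile(values=np.asarray(scores, dtype=float),
                             mask=np.isfinite(np.asarray(scores, dtype=float)))
    pred = classify_by_threshold(profile, threshold)
    c = confusion(pred, truth)
    m = metrics(c)
    points, score = roc_score(scores, truth)
    return EvalResult(
        sensitivity=m["sensitivity"], specificity=m["specificity"],
        precision=m["precision"], roc_points=points, roc_score=score,
        threshold_T=threshold, counts=c,
    )


def select_uniform_decoys(ensemble: Ensemble, native: BackboneStructure,
                          bin_edges=DEFAULT_BIN_EDGES, per_bin: int = 300,
                          seed: int = 0) -> Ensemble:
    """Approximately RMSD-uniform decoy subset.

    Members are binned by Cα RMSD to the native structure and at most
    ``per_bin`` are drawn per bin without replacement (seeded, hence
    deterministic); bins holding fewer members contribute all of them.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be strictly ascending")
    rmsds = np.array([kabsch_rmsd(m, native) for m in ensemble.members])
    bins = np.digitize(rmsds, edges[1:-1], right=False)
    rng = np.random.default_rng(seed)
    chosen = []
    for b in range(len(edges) - 1):
        idx = np.flatnonzero(bins == b)
        if idx.size == 0:
            continue
        if idx.size > per_bin:
            idx = rng.choice(idx, size=per_bin, replace=False)
        chosen.extend(sorted(idx.tolist()))
    chosen.sort()
    return Ensemble(
        members=[ensemble.members[i] for i in chosen],
        source_labels=[ensemble.source_labels[i] for i in chosen],
    )


class EntropyFlexibilityClassifier(BaseEstimator):
    """Threshold classifier over per-residue entropy, sklearn-style.

    ``fit`` learns the decision threshold as the pooled mean entropy of
    the supplied reference profiles (unless a fixed ``threshold`` is
    given); ``predict`` maps an entropy profile to flexible/rigid labels.
    """

    def __init__(self, threshold: float | None = None):
        self.threshold = threshold

    def fit(self, X, y=None):
        """X: list of EntropyProfile used to set the dataset-mean T."""
        if self.threshold is not None:
            self.threshold_ = float(self.threshold)
        else:
            self.threshold_ = mean_entropy_threshold(X)
        return self

    def predict(self, X: EntropyProfile) -> FlexLabels:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "threshold_")
        return classify_by_threshold(X, self.threshold_)
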