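"""Connectome-based predictive modeling (CPM).

CPM predicts a continuous phenotype from a per-subject feature vector
(edge controllability, edge strength, ...) with a deliberately simple,
leakage-free protocol repeated over k-fold cross-validation:

1. within each training fold, correlate every feature with the phenotype
   and keep features with two-sided Pearson p below a threshold (0.01),
   split by correlation sign into a positive and a negative mask;
2. collapse each subject's selected features into a single summary score
   (positive-sum minus negative-sum by default);
3. fit a one-variable linear regression of phenotype on the score, and
   apply it to the held-out fold.

Performance per repeat is the Pearson correlation between each subject's
single held-out prediction and the observed phenotype.  Fold splits are a
deterministic function of (seed, repeat index) so competing feature sets
can be compared on identical splits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.stats

__all__ = [
    "CPMModel",
    "CPMResult",
    "select_features",
    "summarize",
    "fit_cpm",
    "cross_validate",
    "compare_feature_sets",
]

log = logging.getLogger(__name__)

DEFAULT_P_THRESHOLD = 0.01
DEFAULT_K = 10
DEFAULT_N_REPEATS = 1000
SUMMARY_MODES = ("difference", "positive", "negative")


@dataclass
class CPMModel:
    """Masks and linear coefficients fitted on one training set."""

    feature_mask_pos: np.ndarray
    feature_mask_neg: np.ndarray
    slope: float
    intercept: float
    p_threshold: float
    mode: str


@dataclass
class CPMResult:
    """Held-out predictions and per-repeat performance of one feature set."""

    predictions: np.ndarray  # (n_repeats, n_subjects)
    performance: np.ndarray  # (n_repeats,) Pearson r(predicted, observed)
    folds: np.ndarray  # (n_repeats, n_subjects) fold id per subject
    seed: int
    k: int
    p_threshold: float
    mode: str

    @property
    def n_repeats(self) -> int:
        return self.predictions.shape[0]


def _pearson_with_p(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-column Pearson r and two-sided p against y."""
    n = len(y)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = Xc.std(axis=0)
    sy = yc.std()
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc.T @ yc) / (n * sx * sy)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * scipy.stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    invalid = (sx == 0) | ~np.isfinite(r)
    r = np.where(invalid, 0.0, r)
    p = np.where(invalid, 1.0, p)
    return r, p


def select_features(
    features: np.ndarray,
    phenotype: np.ndarray,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks of features correlated with the phenotype at p < threshold.

    Returns (positive mask, negative mask), disjoint by construction.
    Zero-variance features are never selected (counted in the log).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(phenotype, dtype=float).reshape(-1)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("features must be subjects x P aligned with phenotype")
    if X.shape[0] < 10:
        raise ValueError("need at least 10 subjects for feature selection")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values are not supported")
    r, p = _pearson_with_p(X, y)
    n_zero_var = int((X.std(axis=0) == 0).sum())
    if n_zero_var:
        log.info("excluded %d zero-variance features", n_zero_var)
    selected = p < p_threshold
    return selected & (r > 0), selected & (r < 0)


def summarize(
    features: np.ndarray,
    masks: tuple[np.ndarray, np.ndarray],
    mode: str = "difference",
) -> np.ndarray:
    """Collapse selected features into one score per subject.

    ``difference`` (default): positive-mask sum minus negative-mask sum;
    ``positive`` / ``negative``: the single-sign sums.
    """
    if mode not in SUMMARY_MODES:
        raise ValueError(f"mode must be one of {SUMMARY_MODES}")
    X = np.asarray(features, dtype=float)
    pos, neg = (np.asarray(m, dtype=bool) for m in masks)
    if not pos.any() and not neg.any():
        raise ValueError("no features selected")
    s_pos = X[:, pos].sum(axis=1)
    s_neg = X[:, neg].sum(axis=1)
    if mode == "positive":
        return s_pos
    if mode == "negative":
        return s_neg
    return s_pos - s_neg


def fit_cpm(
    features: np.ndarray,
    phenotype: np.ndarray,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    mode: str = "difference",
) -> CPMModel:
    """Select features, summarize, and fit the linear model on one training set."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(phenotype, dtype=float).reshape(-1)
    pos, neg = select_features(X, y, p_threshold)
    score = summarize(X, (pos, neg), mode)
    if score.std() == 0:
        slope, intercept = 0.0, float(y.mean())
    else:
        slope, intercept = np.polyfit(score, y, 1)
    return CPMModel(
        feature_mask_pos=pos,
        feature_mask_neg=neg,
        slope=float(slope),
        intercept=float(intercept),
        p_threshold=p_threshold,
        mode=mode,
    )


def _fold_assignment(n: int, k: int, seed: int, repeat: int) -> np.ndarray:
    """Deterministic fold ids for (seed, repeat): a permuted round-robin split."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, repeat]))
    fold = np.empty(n, dtype=np.int32)
    fold[rng.permutation(n)] = np.arange(n) % k
    return fold


def cross_validate(
    features: np.ndarray,
    phenotype: np.ndarray,
    k: int = DEFAULT_K,
    n_repeats: int = DEFAULT_N_REPEATS,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    mode: str = "difference",
    seed: int = 0,
) -> CPMResult:
    """Repeated k-fold cross-validated CPM.

    Every subject is predicted exactly once per repeat.  A fold whose
    training set selects no features (or a degenerate score) predicts the
    training-set mean, with a logged count.  If a repeat's predictions are
    constant its performance is recorded as 0.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(phenotype, dtype=float).reshape(-1)
    n = len(y)
    if X.shape[0] != n:
        raise ValueError("features and phenotype lengths differ")
    if n < k:
        raise ValueError(f"need at least k={k} subjects")
    predictions = np.empty((n_repeats, n))
    performance = np.empty(n_repeats)
    folds = np.empty((n_repeats, n), dtype=np.int32)
    n_empty_folds = 0
    for rep in range(n_repeats):
        fold = _fold_assignment(n, k, seed, rep)
        folds[rep] = fold
        pred = np.empty(n)
        for f in range(k):
            test = fold == f
            train = ~test
            try:
                model = fit_cpm(X[train], y[train], p_threshold, mode)
                if not model.feature_mask_pos.any() and not model.feature_mask_neg.any():
                    raise ValueError("no features selected")
                score_test = summarize(
                    X[test],
                    (model.feature_mask_pos, model.feature_mask_neg),
                    mode,
                )
                pred[test] = model.slope * score_test + model.intercept
            except ValueError:
                n_empty_folds += 1
                pred[test] = y[train].mean()
        predictions[rep] = pred
        if np.std(pred) == 0 or np.std(y) == 0:
            performance[rep] = 0.0
        else:
            performance[rep] = np.corrcoef(pred, y)[0, 1]
    if n_empty_folds:
        log.info(
            "%d folds selected no features; used training-mean predictions",
            n_empty_folds,
        )
    return CPMResult(
        predictions=predictions,
        performance=performance,
        folds=folds,
        seed=seed,
        k=k,
        p_threshold=p_threshold,
        mode=mode,
    )


def compare_feature_sets(result_a: CPMResult, result_b: CPMResult) -> float:
    """One-sided paired comparison: is feature set A better than B?

    Over repeats run on identical fold splits, returns
    p = P(r_a < r_b) + 0.5 P(r_a = r_b); a small p means A's predictions
    beat B's in almost every repeat.
    """
    if result_a.folds.shape != result_b.folds.shape or not np.array_equal(
        result_a.folds, result_b.folds
    ):
        raise ValueError("results were not computed on identical fold splits")
    ra, rb = result_a.performance, result_b.performance
    return float(np.mean(ra < rb) + 0.5 * np.mean(ra == rb))
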