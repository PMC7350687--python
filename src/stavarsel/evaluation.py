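"""ROC analysis, bootstrap confidence intervals and the permutation null.

The cross-validated probabilities from the nested CV outer loop are scored
by ROC analysis: AUC equals the Mann-Whitney U statistic scaled by the
number of between-class pairs (ties counted half), and 95% confidence
intervals for sensitivity and specificity at every threshold come from
stratified bootstrap resampling. Two operating points are reported: the
Youden-index maximiser (equal weight to sensitivity and specificity) and a
high-specificity point (maximum sensitivity subject to a specificity floor).

Significance of the observed cross-validated accuracy is judged against a
label-permutation null: the class labels are shuffled and the entire
pipeline -- label-dependent prefilters included -- is rerun per
permutation, with each run's accuracy measured at its own Youden threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from joblib import Parallel, delayed
from scipy import stats

from .ct import RatioMatrix, cov_filter, mwu_prefilter

__all__ = [
    "RocCurve",
    "OperatingPoint",
    "PermutationNull",
    "roc_curve",
    "bootstrap_roc_ci",
    "operating_points",
    "accuracy_at_youden",
    "permutation_null",
]


@dataclass
class RocCurve:
    """ROC point estimates with optional bootstrap CIs per threshold.

    A sample is called positive when its score strictly exceeds the
    threshold; thresholds are midpoints between sorted unique scores with
    -inf/+inf sentinels.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    sensitivity_ci: tuple[np.ndarray, np.ndarray] | None = None
    specificity_ci: tuple[np.ndarray, np.ndarray] | None = None
    n_bootstrap: int = 0

    def __post_init__(self) -> None:
        assert np.all((self.sensitivity >= 0) & (self.sensitivity <= 1))
        assert np.all((self.specificity >= 0) & (self.specificity <= 1))
        assert 0.0 <= self.auc <= 1.0

    def to_frame(self):
        import pandas as pd

        d = {
            "threshold": self.thresholds,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }
        if self.sensitivity_ci is not None:
            d["sensitivity_lo"], d["sensitivity_hi"] = self.sensitivity_ci
            d["specificity_lo"], d["specificity_hi"] = self.specificity_ci
        return pd.DataFrame(d)


@dataclass
class OperatingPoint:
    threshold: float
    sensitivity: float
    specificity: float
    criterion: str  # "youden" | "min_false_positive"


@dataclass
class PermutationNull:
    """Null distribution of cross-validated accuracy under label shuffling."""

    permuted_accuracies: np.ndarray
    observed_accuracy: float
    n_perm: int
    seed: int

    @property
    def p_value(self) -> float:
        c = int(np.sum(self.permuted_accuracies >= self.observed_accuracy - 1e-12))
        return (1 + c) / (self.n_perm + 1)

    @property
    def max_permuted(self) -> float:
        return float(self.permuted_accuracies.max())


def _sens_spec(scores: np.ndarray, labels: np.ndarray, thresholds: np.ndarray):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    sens = (pos[None, :] > thresholds[:, None]).mean(axis=1)
    spec = (neg[None, :] <= thresholds[:, None]).mean(axis=1)
    return sens, spec


def _auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC = U/(n1*n2) with ties counted 0.5, via midranks."""
    n1 = int(np.sum(labels == 1))
    n0 = int(np.sum(labels == 0))
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _thresholds(scores: np.ndarray) -> np.ndarray:
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    return np.concatenate([[-np.inf], mids, [np.inf]])


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    """ROC point estimates and AUC from per-sample scores."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) != 2:
        raise ValueError("both classes must be present for ROC analysis")
    thr = _thresholds(scores)
    sens, spec = _sens_spec(scores, labels, thr)
    return RocCurve(thr, sens, spec, _auc(scores, labels))


def bootstrap_roc_ci(
    scores: np.ndarray, labels: np.ndarray, B: int = 2000, seed: int = 0
) -> RocCurve:
    """Stratified bootstrap percentile 95% CIs for sensitivity and
    specificity at every original threshold (class counts preserved)."""
    base = roc_curve(scores, labels)
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    bpos = rng.choice(pos, size=(B, len(pos)), replace=True)
    bneg = rng.choice(neg, size=(B, len(neg)), replace=True)
    T = len(base.thresholds)
    sens_lo = np.empty(T)
    sens_hi = np.empty(T)
    spec_lo = np.empty(T)
    spec_hi = np.empty(T)
    for t in range(T):
        s = (bpos > base.thresholds[t]).mean(axis=1)
        sp = (bneg <= base.thresholds[t]).mean(axis=1)
        sens_lo[t], sens_hi[t] = np.percentile(s, [2.5, 97.5])
        spec_lo[t], spec_hi[t] = np.percentile(sp, [2.5, 97.5])
    # percentile CIs are clipped to contain the full-sample point estimate
    sens_lo = np.minimum(sens_lo, base.sensitivity)
    sens_hi = np.maximum(sens_hi, base.sensitivity)
    spec_lo = np.minimum(spec_lo, base.specificity)
    spec_hi = np.maximum(spec_hi, base.specificity)
    return RocCurve(
        base.thresholds,
        base.sensitivity,
        base.specificity,
        base.auc,
        sensitivity_ci=(sens_lo, sens_hi),
        specificity_ci=(spec_lo, spec_hi),
        n_bootstrap=B,
    )


def operating_points(
    roc: RocCurve, min_specificity: float = 0.95
) -> tuple[OperatingPoint, OperatingPoint]:
    """Youden-index point and the high-specificity point.

    Youden maximises sensitivity + specificity - 1 (ties -> higher
    specificity). The high-specificity point maximises sensitivity subject
    to specificity >= ``min_specificity``; if no threshold qualifies the
    maximum-specificity point is returned with a warning.
    """
    j = roc.sensitivity + roc.specificity - 1.0
    best = np.flatnonzero(j >= j.max() - 1e-12)
    yi = best[np.argmax(roc.specificity[best])]
    youden = OperatingPoint(
        float(roc.thresholds[yi]), float(roc.sensitivity[yi]),
        float(roc.specificity[yi]), "youden",
    )
    ok = np.flatnonzero(roc.specificity >= min_specificity)
    if ok.size == 0:
        warnings.warn(
            f"no threshold reaches specificity {min_specificity}; "
            "returning the maximum-specificity point", stacklevel=2,
        )
        ok = np.flatnonzero(roc.specificity >= roc.specificity.max() - 1e-12)
    cand = ok[roc.sensitivity[ok] >= roc.sensitivity[ok].max() - 1e-12]
    hi = cand[np.argmax(roc.specificity[cand])]
    highspec = OperatingPoint(
        float(roc.thresholds[hi]), float(roc.sensitivity[hi]),
        float(roc.specificity[hi]), "min_false_positive",
    )
    return youden, highspec


def accuracy_at_youden(scores: np.ndarray, labels: np.ndarray) -> float:
    """Accuracy at the score set's own Youden threshold."""
    roc = roc_curve(scores, labels)
    youden, _ = operating_points(roc)
    pred = (np.asarray(scores) > youden.threshold).astype(int)
    return float(np.mean(pred == np.asarray(labels)))


def _pipeline_youden_accuracy(
    ratios_unfiltered: RatioMatrix,
    y: np.ndarray,
    max_cov: float,
    alpha: float,
    stavarsel_kwargs: dict,
    seed: int,
) -> float:
    """Prefilters + StaVarSel + accuracy at the run's own Youden threshold.

    A failed run (e.g. no feature survives the prefilters) scores the
    majority-class rate.
    """
    from .model import run_stavarsel

    majority = float(max(np.mean(y), 1 - np.mean(y)))
    relabeled = RatioMatrix(
        features=list(ratios_unfiltered.features),
        values=ratios_unfiltered.values,
        sample_ids=list(ratios_unfiltered.sample_ids),
        y=np.asarray(y, dtype=int),
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            filtered = cov_filter(relabeled, max_cov)
            filtered, _ = mwu_prefilter(filtered, alpha)
            if filtered.n_features == 0:
                return majority
            _, preds = run_stavarsel(filtered, seed=seed, **stavarsel_kwargs)
        return accuracy_at_youden(preds.probability, preds.y_true)
    except (ValueError, RuntimeError):
        return majority


def permutation_null(
    ratios_unfiltered: RatioMatrix,
    n_perm: int = 2000,
    seed: int = 0,
    workers: int = 1,
    max_cov: float = 3.0,
    alpha: float = 0.05,
    precomputed: dict[int, float] | None = None,
    **stavarsel_kwargs,
) -> PermutationNull:
    """Label-permutation null for the cross-validated Youden accuracy.

    Every permutation shuffles the binary labels and reruns the entire
    pipeline from the label-dependent prefilters (CoV, Mann-Whitney)
    through StaVarSel's outer-loop predictions. Per-permutation seeds are
    counter-based (SeedSequence([seed, i])), so the null distribution is
    identical for any worker count, and a partially computed run can be
    resumed by passing ``precomputed`` accuracies keyed by permutation
    index.
    """
    y = ratios_unfiltered.y
    precomputed = precomputed or {}
    observed = _pipeline_youden_accuracy(
        ratios_unfiltered, y, max_cov, alpha, stavarsel_kwargs,
        int(np.random.SeedSequence([seed, 2**30]).generate_state(1)[0] % (2**31 - 1)),
    )

    def one(i: int) -> float:
        ss = np.random.SeedSequence([seed, i])
        rng = np.random.default_rng(ss)
        y_perm = rng.permutation(y)
        run_seed = int(ss.generate_state(2)[1] % (2**31 - 1))
        return _pipeline_youden_accuracy(
            ratios_unfiltered, y_perm, max_cov, alpha, stavarsel_kwargs, run_seed
        )

    todo = [i for i in range(n_perm) if i not in precomputed]
    if workers == 1:
        fresh = [one(i) for i in todo]
    else:
        fresh = Parallel(n_jobs=workers)(delayed(one)(i) for i in todo)
    acc = np.empty(n_perm)
    for i, a in precomputed.items():
        if 0 <= i < n_perm:
            acc[i] = a
    for i, a in zip(todo, fresh):
        acc[i] = a
    return PermutationNull(acc, observed, n_perm, seed)
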