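"""Housekeeping-gene selection, geometric-mean normalization, and
differential expression with Storey's q-value FDR.

The classifier arm works on within-sample ratios and needs no
normalization; this arm instead asks which individual assays are
differentially expressed once sample-level scaling is removed. A panel of
housekeeping assays -- abundant, class-neutral, low-variability, and
coherent with each other -- defines a per-sample geometric-mean reference;
expression is divided by it, then each assay is tested with a two-sided
Mann-Whitney U test and the false discovery rate is estimated by Storey's
method with a fixed tuning parameter lambda0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ct import CtMatrix, ExpressionMatrix, mannwhitney_pvalues

__all__ = [
    "HkgPanel",
    "DEResult",
    "select_housekeeping",
    "normalize_by_hkg",
    "de_prefilter",
    "de_test_storey",
    "differential_expression",
    "storey_qvalues",
]


@dataclass
class HkgPanel:
    """Selected housekeeping assays plus per-assay diagnostics."""

    assay_ids: list[str]
    diagnostics: pd.DataFrame | None = None  # indexed by candidate assay id


@dataclass
class DEResult:
    """Per-assay differential expression with Storey q-values."""

    table: pd.DataFrame  # assay, fold_change, p_value, q_value
    pi0: float
    lambda0: float

    def n_significant(self, q_cutoff: float = 0.05) -> int:
        """Assays called differentially expressed: q below the cutoff and,
        when the fold criterion is in play, a fold change past it."""
        sig = self.table["q_value"] < q_cutoff
        if "passes_fold" in self.table:
            sig &= self.table["passes_fold"]
        return int(sig.sum())


def _geometric_mean(x: np.ndarray, axis: int = 0) -> np.ndarray:
    return np.exp(np.mean(np.log(x), axis=axis))


def select_housekeeping(
    ct: CtMatrix,
    expr: ExpressionMatrix | None = None,
    max_median_ct: float = 30.0,
    mwu_floor: float = 0.1,
    outlier_fold: float = 5.0,
    cov_sd_mult: float = 2.0,
    min_correlation: float = 0.7,
) -> HkgPanel:
    """Select housekeeping assays by four criteria.

    (i) amplified in every sample with median Ct < ``max_median_ct``;
    (ii) no class difference (two-sided Mann-Whitney p > ``mwu_floor``);
    (iii) not highly variable -- expression CoV within ``cov_sd_mult``
    standard deviations above the mean CoV of the candidate assays -- and
    no sample outside ``outlier_fold`` of the assay mean;
    (iv) Pearson correlation (log2 scale) with the geometric mean of the
    current panel > ``min_correlation``, applied iteratively until stable.
    """
    if expr is None:
        from .ct import relative_expression

        expr = relative_expression(ct)
    y = expr.y
    n_assays = ct.n_assays
    detected_all = ~ct.missing.any(axis=1)
    median_ct = np.nanmedian(ct.ct, axis=1)
    pass_i = detected_all & (median_ct < max_median_ct)

    p = mannwhitney_pvalues(expr.expr, y)
    pass_ii = p > mwu_floor

    mean_expr = expr.expr.mean(axis=1)
    cov = expr.expr.std(axis=1, ddof=1) / mean_expr
    candidates = pass_i & pass_ii
    if candidates.any():
        cov_cand = cov[candidates]
        cov_limit = cov_cand.mean() + cov_sd_mult * cov_cand.std(ddof=1 if candidates.sum() > 1 else 0)
    else:
        cov_limit = np.inf
    ratio_to_mean = expr.expr / mean_expr[:, None]
    outlier = (ratio_to_mean > outlier_fold).any(axis=1) | (
        ratio_to_mean < 1.0 / outlier_fold
    ).any(axis=1)
    pass_iii = (cov <= cov_limit) & ~outlier

    panel = list(np.flatnonzero(pass_i & pass_ii & pass_iii))
    log_expr = np.log2(expr.expr)
    corr = np.full(n_assays, np.nan)
    # iterative pruning: each pass recomputes the panel geometric mean
    while True:
        if len(panel) == 0:
            break
        ref = log_expr[panel, :].mean(axis=0)  # log2 of geometric mean
        drop = []
        for j in panel:
            r = stats.pearsonr(log_expr[j], ref)[0] if np.std(ref) > 0 else 0.0
            corr[j] = r
            if not (r > min_correlation):
                drop.append(j)
        if not drop:
            break
        panel = [j for j in panel if j not in drop]

    if len(panel) < 3:
        raise ValueError(
            "housekeeping panel has fewer than 3 assays after selection; "
            "manual review of candidate assays is advised"
        )
    diagnostics = pd.DataFrame(
        {
            "median_ct": median_ct,
            "detected_in_all": detected_all,
            "mwu_p": p,
            "cov": cov,
            "outlier": outlier,
            "correlation_with_panel": corr,
            "selected": [i in panel for i in range(n_assays)],
        },
        index=ct.assay_ids,
    )
    return HkgPanel([ct.assay_ids[i] for i in panel], diagnostics)


def normalize_by_hkg(expr: ExpressionMatrix, panel: HkgPanel) -> ExpressionMatrix:
    """Divide each sample by its geometric mean over the panel assays."""
    idx = [expr.assay_ids.index(a) for a in panel.assay_ids]
    if not idx:
        raise ValueError("empty housekeeping panel")
    divisor = _geometric_mean(expr.expr[idx, :], axis=0)
    return ExpressionMatrix(
        assay_ids=list(expr.assay_ids),
        sample_ids=list(expr.sample_ids),
        expr=expr.expr / divisor[None, :],
        y=expr.y.copy(),
        group_of_sample=dict(expr.group_of_sample),
    )


def de_prefilter(
    normalized: ExpressionMatrix,
    ct: CtMatrix,
    min_detect_fraction: float = 0.5,
    max_cov: float = 2.0,
    min_fold: float | None = 1.3,
) -> list[str]:
    """Assays eligible for DE testing.

    (1) amplified in >= ``min_detect_fraction`` of samples in at least one
    class; (2) CoV < ``max_cov`` -- exceedance in both classes removes;
    (3) fold change (ratio of class geometric means) above ``min_fold`` in
    either direction (direction-symmetric; pass ``min_fold=None`` to skip,
    e.g. when the fold criterion is applied after FDR estimation instead).
    """
    y = normalized.y
    detected = ~ct.missing
    keep = []
    for i, assay in enumerate(normalized.assay_ids):
        ci = ct.assay_ids.index(assay)
        det1 = detected[ci, y == 1].mean()
        det0 = detected[ci, y == 0].mean()
        if det1 < min_detect_fraction and det0 < min_detect_fraction:
            continue
        exceed_both = True
        for cls in (0, 1):
            vals = normalized.expr[i, y == cls]
            if vals.std(ddof=1) / vals.mean() < max_cov:
                exceed_both = False
                break
        if exceed_both:
            continue
        if min_fold is not None:
            fold = _geometric_mean(normalized.expr[i, y == 1]) / _geometric_mean(
                normalized.expr[i, y == 0]
            )
            if not (fold > min_fold or fold < 1.0 / min_fold):
                continue
        keep.append(assay)
    return keep


def storey_qvalues(p: np.ndarray, lambda0: float = 0.5) -> tuple[np.ndarray, float]:
    """Storey q-values with a single fixed lambda0.

    pi0 = #{p > lambda0} / (m * (1 - lambda0)), capped at 1 (and forced to
    1 with a warning when m < 5); q of the i-th smallest p is
    min over j >= i of pi0 * m * p_(j) / j.
    """
    p = np.asarray(p, dtype=float)
    m = len(p)
    if m == 0:
        return p.copy(), 1.0
    if m < 5:
        warnings.warn("fewer than 5 p-values; pi0 forced to 1", stacklevel=2)
        pi0 = 1.0
    else:
        pi0 = min(1.0, float(np.sum(p > lambda0) / (m * (1.0 - lambda0))))
        if pi0 == 0.0:
            pi0 = 1.0 / (m * (1.0 - lambda0))
    order = np.argsort(p, kind="stable")
    q_sorted = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q, pi0


def de_test_storey(
    normalized: ExpressionMatrix,
    assays: list[str] | None = None,
    lambda0: float = 0.5,
) -> DEResult:
    """Mann-Whitney DE test per assay with Storey FDR."""
    if assays is None:
        assays = list(normalized.assay_ids)
    idx = [normalized.assay_ids.index(a) for a in assays]
    y = normalized.y
    vals = normalized.expr[idx, :]
    p = mannwhitney_pvalues(vals, y)
    fold = _geometric_mean(vals[:, y == 1], axis=1) / _geometric_mean(
        vals[:, y == 0], axis=1
    )
    q, pi0 = storey_qvalues(p, lambda0)
    table = pd.DataFrame(
        {"assay": assays, "fold_change": fold, "p_value": p, "q_value": q}
    ).sort_values("p_value", kind="stable", ignore_index=True)
    return DEResult(table, pi0, lambda0)


def differential_expression(
    normalized: ExpressionMatrix,
    ct: CtMatrix,
    min_detect_fraction: float = 0.5,
    max_cov: float = 2.0,
    min_fold: float = 1.3,
    lambda0: float = 0.5,
) -> DEResult:
    """DE analysis with calibrated FDR.

    p- and q-values are computed over every assay passing the
    detectability and variability screens; the fold-change criterion is
    part of the final differential-expression call (``passes_fold`` in the
    result table) rather than a pre-test filter. Filtering on the observed
    fold change before estimating pi0 would bias pi0 toward zero -- the
    filter is not independent of the test statistic under the null -- and
    wreck FDR calibration, so it is applied downstream of the q-values.
    """
    eligible = de_prefilter(
        normalized, ct, min_detect_fraction, max_cov, min_fold=None
    )
    result = de_test_storey(normalized, eligible, lambda0)
    fold = result.table["fold_change"].to_numpy()
    result.table["passes_fold"] = (fold > min_fold) | (fold < 1.0 / min_fold)
    return result
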