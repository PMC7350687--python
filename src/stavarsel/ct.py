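"""Ct data containers, the expression transform, ratio features and prefilters.

qPCR reports a cycle-threshold (Ct) per assay and sample: the PCR cycle at
which fluorescence crosses a detection threshold. Lower Ct means more
abundant target; a probe that never amplifies within the instrument's
40-cycle limit has no Ct ("Undetermined"). Relative expression is anchored
at that limit as ``2**(40 - Ct)``, so a just-detectable target has
expression 1 and each cycle earlier doubles it.

Within-sample ratios of two assays' expression cancel sample-level scaling
(input amount, extraction efficiency), which is why ordered expression
ratios -- not single assays -- are the feature space for classification.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CtMatrix",
    "ExpressionMatrix",
    "RatioFeature",
    "RatioMatrix",
    "read_ct_table",
    "relative_expression",
    "detectability_filter",
    "build_ratio_features",
    "cov_filter",
    "mwu_prefilter",
    "mannwhitney_pvalues",
]

#: Ct-table cell values treated as "not amplified".
MISSING_TOKENS = {"", "na", "nan", "undetermined", "undet", "null", "none"}

#: Cohort label that defines the positive (cancer) class.
POSITIVE_LABEL = "cancer"


def _check_unique(ids, kind: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {kind} id: {x!r}")
        seen.add(x)


@dataclass
class CtMatrix:
    """Raw Ct values for ``assays x samples`` with cohort labels.

    Missing (not amplified) measurements are ``NaN`` in :attr:`ct`.
    """

    assay_ids: list[str]
    sample_ids: list[str]
    ct: np.ndarray  # (n_assays, n_samples), NaN = not amplified
    group_of_sample: dict[str, str]

    def __post_init__(self) -> None:
        self.ct = np.asarray(self.ct, dtype=float)
        _check_unique(self.assay_ids, "assay")
        _check_unique(self.sample_ids, "sample")
        if self.ct.shape != (len(self.assay_ids), len(self.sample_ids)):
            raise ValueError(
                f"ct shape {self.ct.shape} does not match "
                f"{len(self.assay_ids)} assays x {len(self.sample_ids)} samples"
            )
        finite = self.ct[~np.isnan(self.ct)]
        if np.any(~np.isfinite(finite)):
            raise ValueError("non-finite Ct value (use NaN for not-amplified)")
        if np.any(finite <= 0):
            raise ValueError("Ct values must be positive PCR cycle counts")
        for s in self.sample_ids:
            if s not in self.group_of_sample:
                raise ValueError(f"sample {s!r} has no cohort label")

    @property
    def n_assays(self) -> int:
        return len(self.assay_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def missing(self) -> np.ndarray:
        """Boolean mask, True where the assay did not amplify."""
        return np.isnan(self.ct)

    def binary_labels(self, positive_label: str = POSITIVE_LABEL) -> np.ndarray:
        """0/1 class vector per sample; 1 = ``positive_label`` cohort."""
        return np.array(
            [int(self.group_of_sample[s] == positive_label) for s in self.sample_ids]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ct, index=self.assay_ids, columns=self.sample_ids)

    def subset_assays(self, assays: list[str]) -> "CtMatrix":
        idx = [self.assay_ids.index(a) for a in assays]
        return CtMatrix(
            assay_ids=list(assays),
            sample_ids=list(self.sample_ids),
            ct=self.ct[idx, :].copy(),
            group_of_sample=dict(self.group_of_sample),
        )


@dataclass
class ExpressionMatrix:
    """Relative expression ``2**(40 - Ct)``, strictly positive."""

    assay_ids: list[str]
    sample_ids: list[str]
    expr: np.ndarray  # (n_assays, n_samples), all > 0
    y: np.ndarray  # 0/1 per sample, 1 = cancer
    group_of_sample: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.expr = np.asarray(self.expr, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if np.any(~(self.expr > 0)):
            raise ValueError("expression values must all be positive")
        if self.y.shape != (len(self.sample_ids),):
            raise ValueError("one binary label per sample required")

    @property
    def n_assays(self) -> int:
        return len(self.assay_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.expr, index=self.assay_ids, columns=self.sample_ids)


@dataclass(frozen=True)
class RatioFeature:
    """Ordered assay pair; the feature value is expr(num)/expr(den)."""

    numerator_assay: str
    denominator_assay: str

    def __post_init__(self) -> None:
        if self.numerator_assay == self.denominator_assay:
            raise ValueError("ratio numerator and denominator must differ")

    @property
    def name(self) -> str:
        return f"{self.numerator_assay}/{self.denominator_assay}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


@dataclass
class RatioMatrix:
    """Per-sample values of ordered expression ratios (features x samples)."""

    features: list[RatioFeature]
    values: np.ndarray  # (n_features, n_samples), all > 0
    sample_ids: list[str]
    y: np.ndarray  # 0/1 per sample

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.values.shape != (len(self.features), len(self.sample_ids)):
            raise ValueError("values shape must be (n_features, n_samples)")
        if np.any(~(self.values > 0)):
            raise ValueError("ratio values must all be positive")

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def feature_names(self) -> list[str]:
        return [f.name for f in self.features]

    def design_matrix(self, log2: bool = False) -> np.ndarray:
        """Samples x features matrix for modelling (optionally log2)."""
        X = self.values.T
        return np.log2(X) if log2 else X.copy()

    def subset_features(self, keep: np.ndarray | list[int]) -> "RatioMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return RatioMatrix(
            features=[self.features[i] for i in keep],
            values=self.values[keep, :].copy(),
            sample_ids=list(self.sample_ids),
            y=self.y.copy(),
        )

    def subset_samples(self, keep: np.ndarray | list[int]) -> "RatioMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return RatioMatrix(
            features=list(self.features),
            values=self.values[:, keep].copy(),
            sample_ids=[self.sample_ids[i] for i in keep],
            y=self.y[keep].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_names, columns=self.sample_ids)


# ---------------------------------------------------------------------------
# reading


def _parse_ct_cell(raw, assay: str, sample: str) -> float:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return np.nan
    s = str(raw).strip()
    if s.lower() in MISSING_TOKENS:
        return np.nan
    try:
        val = float(s)
    except ValueError as exc:
        raise ValueError(
            f"unparseable Ct value {raw!r} for assay {assay!r}, sample {sample!r}"
        ) from exc
    if not np.isfinite(val) or val <= 0:
        raise ValueError(
            f"invalid Ct value {val} for assay {assay!r}, sample {sample!r}: "
            "Ct must be a positive cycle count"
        )
    return val


def read_ct_table(path, metadata_path) -> CtMatrix:
    """Read a Ct table (rows = assays, columns = samples) plus sample metadata.

    The Ct table is CSV or TSV (by extension; ``.tsv``/``.txt`` = tab) with a
    header row of sample ids and the assay id in the first column. Cells that
    are empty, ``NA`` or ``Undetermined`` become missing. The metadata table
    must contain columns ``sample_id`` and ``cohort`` covering every sample.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    assay_ids = [str(a) for a in raw.index]
    sample_ids = [str(s) for s in raw.columns]
    _check_unique(assay_ids, "assay")
    _check_unique(sample_ids, "sample")

    ct = np.empty((len(assay_ids), len(sample_ids)))
    for i, a in enumerate(assay_ids):
        for j, s in enumerate(sample_ids):
            ct[i, j] = _parse_ct_cell(raw.iat[i, j], a, s)

    msep = "\t" if str(metadata_path).endswith((".tsv", ".txt")) else ","
    meta = pd.read_csv(metadata_path, sep=msep, dtype=str)
    for col in ("sample_id", "cohort"):
        if col not in meta.columns:
            raise ValueError(f"metadata is missing required column {col!r}")
    groups = dict(zip(meta["sample_id"].astype(str), meta["cohort"].astype(str)))
    for s in sample_ids:
        if s not in groups:
            raise ValueError(f"no cohort metadata for sample {s!r}")
    group_of_sample = {s: groups[s] for s in sample_ids}
    return CtMatrix(assay_ids, sample_ids, ct, group_of_sample)


# ---------------------------------------------------------------------------
# transforms and filters


def relative_expression(
    ct: CtMatrix,
    undetected_ct: float = 40.0,
    positive_label: str = POSITIVE_LABEL,
) -> ExpressionMatrix:
    """Convert Ct to relative expression ``2**(40 - Ct)``.

    Missing Cts are imputed at ``undetected_ct`` (default 40, the
    instrument's cycle limit) before the transform, so a non-amplified
    probe gets expression ``2**(40 - undetected_ct)`` -- 1 by default.
    """
    observed = ct.ct[~np.isnan(ct.ct)]
    if observed.size and undetected_ct < observed.max():
        warnings.warn(
            f"undetected_ct={undetected_ct} is below the largest observed Ct "
            f"({observed.max():.2f}); imputed values will rank above real ones",
            stacklevel=2,
        )
    filled = np.where(np.isnan(ct.ct), undetected_ct, ct.ct)
    expr = np.power(2.0, 40.0 - filled)
    return ExpressionMatrix(
        assay_ids=list(ct.assay_ids),
        sample_ids=list(ct.sample_ids),
        expr=expr,
        y=ct.binary_labels(positive_label),
        group_of_sample=dict(ct.group_of_sample),
    )


def detectability_filter(
    ct: CtMatrix,
    min_fraction: float = 0.5,
    positive_label: str = POSITIVE_LABEL,
) -> list[str]:
    """Assays with detectable Cts in >= ``min_fraction`` of samples in at
    least one of the two comparison classes (cancer vs non-cancer)."""
    y = ct.binary_labels(positive_label)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both comparison classes must be non-empty")
    detected = ~ct.missing
    kept = []
    for i, assay in enumerate(ct.assay_ids):
        frac1 = detected[i, y == 1].mean()
        frac0 = detected[i, y == 0].mean()
        if frac1 >= min_fraction or frac0 >= min_fraction:
            kept.append(assay)
    return kept


def build_ratio_features(expr: ExpressionMatrix, assays: list[str] | None = None) -> RatioMatrix:
    """All ordered assay pairs: ``m`` assays give ``m*(m-1)`` ratio features."""
    if assays is None:
        assays = list(expr.assay_ids)
    if len(assays) < 2:
        raise ValueError("at least 2 assays are required to form ratios")
    idx = {a: expr.assay_ids.index(a) for a in assays}
    features: list[RatioFeature] = []
    rows: list[np.ndarray] = []
    for num, den in itertools.permutations(assays, 2):
        features.append(RatioFeature(num, den))
        rows.append(expr.expr[idx[num]] / expr.expr[idx[den]])
    return RatioMatrix(
        features=features,
        values=np.vstack(rows),
        sample_ids=list(expr.sample_ids),
        y=expr.y.copy(),
    )


def dedupe_reciprocals(ratios: RatioMatrix) -> RatioMatrix:
    """Keep one orientation per assay pair (a/b only, lexicographic)."""
    keep = [
        i
        for i, f in enumerate(ratios.features)
        if f.numerator_assay < f.denominator_assay
    ]
    return ratios.subset_features(keep)


def cov_filter(ratios: RatioMatrix, max_cov: float = 3.0) -> RatioMatrix:
    """Drop features whose coefficient of variation exceeds ``max_cov`` in
    BOTH classes (a feature highly variable in only one class is retained).

    CoV = sample standard deviation / mean, on raw ratios, per class.
    """
    y = ratios.y
    exceed_both = np.ones(ratios.n_features, dtype=bool)
    for cls in (0, 1):
        vals = ratios.values[:, y == cls]
        mean = vals.mean(axis=1)
        if np.any(mean == 0):
            raise ValueError("zero-mean ratio feature (values must be positive)")
        cv = vals.std(axis=1, ddof=1) / mean
        exceed_both &= cv > max_cov
    return ratios.subset_features(~exceed_both)


# ---------------------------------------------------------------------------
# Mann-Whitney U


def _exact_mwu_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact Mann-Whitney p by enumeration of rank assignments.

    Handles ties via midranks; feasible for per-group n <= 8
    (C(16, 8) = 12870 assignments).
    """
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    center = n1 * n2 / 2.0
    dev = abs(u_obs - center)
    count = 0
    total = 0
    base = n1 * (n1 + 1) / 2.0
    for comb in itertools.combinations(range(n1 + n2), n1):
        u = sum(ranks[k] for k in comb) - base
        if abs(u - center) >= dev - 1e-12:
            count += 1
        total += 1
    return count / total


def mannwhitney_pvalues(values: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sided Mann-Whitney U p-value for each row of ``values``.

    Exact enumeration when both groups have <= 8 samples; otherwise the
    normal approximation with midrank tie correction (scipy).
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    y = np.asarray(y)
    g1 = values[:, y == 1]
    g0 = values[:, y == 0]
    if g1.shape[1] == 0 or g0.shape[1] == 0:
        raise ValueError("both classes must be non-empty")
    if g1.shape[1] <= 8 and g0.shape[1] <= 8:
        return np.array([_exact_mwu_p(a, b) for a, b in zip(g1, g0)])
    with np.errstate(invalid="ignore"):
        res = stats.mannwhitneyu(g1, g0, axis=1, method="asymptotic", alternative="two-sided")
    p = np.asarray(res.pvalue, dtype=float)
    # all-tied rows produce zero variance -> NaN; they carry no information
    return np.where(np.isnan(p), 1.0, p)


def mwu_prefilter(
    ratios: RatioMatrix, alpha: float = 0.05
) -> tuple[RatioMatrix, np.ndarray]:
    """Keep ratio features with two-sided Mann-Whitney p < ``alpha``.

    Returns the filtered matrix and the p-value of every input feature
    (aligned with ``ratios.features``).
    """
    p = mannwhitney_pvalues(ratios.values, ratios.y)
    return ratios.subset_features(p < alpha), p


def preprocess_ct(
    ct: CtMatrix,
    undetected_ct: float = 40.0,
    min_detect_fraction: float = 0.5,
    max_cov: float = 3.0,
    alpha: float = 0.05,
    positive_label: str = POSITIVE_LABEL,
) -> tuple[RatioMatrix, RatioMatrix]:
    """Full feature-engineering path: detectability filter, expression
    transform, exhaustive ratios, CoV filter, Mann-Whitney prefilter.

    Returns ``(filtered, unfiltered)`` ratio matrices; the unfiltered one is
    what label-permutation analyses restart from (the CoV and Mann-Whitney
    filters depend on class labels and must be re-run per permutation).
    """
    assays = detectability_filter(ct, min_detect_fraction, positive_label)
    expr = relative_expression(ct.subset_assays(assays), undetected_ct, positive_label)
    ratios = build_ratio_features(expr)
    filtered = cov_filter(ratios, max_cov)
    filtered, _ = mwu_prefilter(filtered, alpha)
    return filtered, ratios
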