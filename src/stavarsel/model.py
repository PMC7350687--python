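"""Nested cross-validation model selection: two-stage baseline and StaVarSel.

Two-stage nested CV
    Outer loop: leave-one-out. For each training set the inner loop runs
    repeated (default 50x) stratified 10-fold CV to estimate the lasso
    penalty; a single lasso fitted at the mean of the repeat estimates
    (lambda.min rule, or lambda.1se for more stringent regularisation)
    predicts the held-out sample.

Stabilised selection (StaVarSel, three-stage)
    The lasso models fitted at each repeat's lambda.min on each outer
    training set are collated; every ratio feature is ranked by its percent
    selection frequency across those fits. A step-down search over percent
    cutoffs evaluates, by repeated stratified 10-fold CV of an unpenalized
    logistic model, the feature set at or above each cutoff, and keeps the
    cutoff with the lowest inner prediction error (ties break to the higher
    cutoff, i.e. the smaller model). The stable feature set is then refitted
    by plain logistic regression on each outer training set to predict its
    held-out sample, giving cross-validated probabilities for ROC analysis.

Selection frequency stabilises the variable set against both the random
fold splits within a training set and the sample-to-sample variation
across training sets, which is what distinguishes the method from simply
increasing the penalty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from ._logistic import fit_logistic
from .ct import RatioFeature, RatioMatrix
from .lasso import (
    LambdaEstimate,
    LambdaStability,
    fit_l1_logistic_at,
    fit_l1_logistic_path,
    lambda_grid,
    repeated_cv_lambda,
)

__all__ = [
    "OuterFit",
    "OuterPredictions",
    "SelectionFrequencyTable",
    "StableModel",
    "run_two_stage",
    "collate_selection_frequencies",
    "stepdown_cutoff_search",
    "run_stavarsel",
    "StaVarSel",
    "StaVarSelResults",
    "TwoStageCV",
    "TwoStageResults",
]


@dataclass
class OuterFit:
    """Bookkeeping for one outer leave-one-out fit."""

    held_out_sample: str
    training_sample_ids: list[str]
    lambda_used: float
    lambda_min_mean: float
    lambda_1se_mean: float
    stability: LambdaStability
    selected_features: list[RatioFeature]
    coef: np.ndarray
    intercept: float
    predicted_probability: float

    def __post_init__(self) -> None:
        assert self.held_out_sample not in self.training_sample_ids
        assert 0.0 <= self.predicted_probability <= 1.0


@dataclass
class OuterPredictions:
    """Held-out probability per sample from the outer loop."""

    sample_ids: list[str]
    y_true: np.ndarray
    probability: np.ndarray

    def __post_init__(self) -> None:
        assert len(set(self.sample_ids)) == len(self.sample_ids)
        self.y_true = np.asarray(self.y_true, dtype=int)
        self.probability = np.asarray(self.probability, dtype=float)

    def accuracy(self, threshold: float = 0.5) -> float:
        return float(np.mean((self.probability > threshold).astype(int) == self.y_true))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "true_class": self.y_true,
                "probability": self.probability,
            }
        )


@dataclass
class SelectionFrequencyTable:
    """Percent selection frequency per feature over collated lasso fits."""

    features: list[RatioFeature]
    counts: np.ndarray
    total_fits: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        assert np.all(self.counts >= 0) and np.all(self.counts <= self.total_fits)

    @property
    def percent(self) -> np.ndarray:
        return 100.0 * self.counts / self.total_fits

    def features_at_or_above(self, cutoff_percent: float) -> list[int]:
        """Indices (into ``features``) with frequency >= cutoff."""
        return list(np.flatnonzero(self.percent >= cutoff_percent - 1e-9))

    def to_frame(self) -> pd.DataFrame:
        order = np.argsort(-self.counts, kind="stable")
        return pd.DataFrame(
            {
                "feature": [self.features[i].name for i in order],
                "count": self.counts[order],
                "percent": self.percent[order],
                "total_fits": self.total_fits,
            }
        )


@dataclass
class StableModel:
    """StaVarSel output: the stable feature set and its full-data fit."""

    cutoff_percent: float
    features: list[RatioFeature]
    coef: np.ndarray
    intercept: float
    inner_cv_error: dict[float, float]
    frequency_table: SelectionFrequencyTable

    def __post_init__(self) -> None:
        best = min(self.inner_cv_error.values())
        assert abs(self.inner_cv_error[self.cutoff_percent] - best) < 1e-12

    def predict_proba(self, ratios: RatioMatrix, log2: bool = False) -> np.ndarray:
        X = _design_for(ratios, self.features, log2)
        eta = np.clip(X @ self.coef + self.intercept, -35, 35)
        return 1.0 / (1.0 + np.exp(-eta))


def _design_for(ratios: RatioMatrix, features: list[RatioFeature], log2: bool) -> np.ndarray:
    index = {f: i for i, f in enumerate(ratios.features)}
    rows = [ratios.values[index[f]] for f in features]
    X = np.vstack(rows).T if rows else np.empty((ratios.n_samples, 0))
    return np.log2(X) if log2 else X


def _outer_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31 - 1)


@dataclass
class _TrainingSetAnalysis:
    """Per-outer-training-set inner-loop results."""

    held_out: int
    estimates: list[LambdaEstimate]
    stability: LambdaStability
    selected_per_repeat: list[np.ndarray]  # nonzero feature indices per repeat


def _analyze_training_sets(
    X: np.ndarray,
    y: np.ndarray,
    repeats: int,
    k: int,
    seed: int,
    n_lambda: int = 100,
) -> list[_TrainingSetAnalysis]:
    """Run the inner loop on every LOO training set.

    For each training set: a shared lambda grid, ``repeats`` independent
    k-fold CV rounds, plus one full-training-set path used to read off the
    features selected at each repeat's lambda.min.
    """
    n = len(y)
    seeds = _outer_seeds(seed, n)
    out = []
    for i in range(n):
        tr = np.r_[0:i, i + 1 : n]
        Xtr, ytr = X[tr], y[tr]
        lambdas = lambda_grid(Xtr, ytr, n_lambda=n_lambda)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            path = fit_l1_logistic_path(
                Xtr, ytr, lambdas=lambdas, truncate_saturated=False
            )
            estimates, stab = repeated_cv_lambda(
                Xtr, ytr, k=k, repeats=repeats, seed=int(seeds[i]), lambdas=lambdas
            )
        if not stab.stable and repeats > 1:
            warnings.warn(
                f"unstable lambda estimates for training set excluding sample {i}",
                stacklevel=2,
            )
        selected = [path.nonzero_features(e.index_min) for e in estimates]
        out.append(_TrainingSetAnalysis(i, estimates, stab, selected))
    return out


def run_two_stage(
    ratios: RatioMatrix,
    rule: str = "lambda_min",
    repeats: int = 50,
    k: int = 10,
    seed: int = 0,
    log2: bool = False,
    n_lambda: int = 100,
    analyses: list[_TrainingSetAnalysis] | None = None,
) -> tuple[OuterPredictions, list[OuterFit]]:
    """Two-stage nested CV: LOO outer loop, repeated k-fold inner loop.

    ``rule`` is ``"lambda_min"`` or ``"one_se"``; the lasso refit on each
    training set uses the mean of the corresponding per-repeat estimates.
    """
    if rule not in ("lambda_min", "one_se"):
        raise ValueError(f"unknown rule {rule!r}")
    X = ratios.design_matrix(log2=log2)
    y = ratios.y.astype(float)
    n = len(y)
    if n < 10:
        raise ValueError("need at least 10 samples for nested CV")
    if analyses is None:
        analyses = _analyze_training_sets(X, y, repeats, k, seed, n_lambda)
    fits: list[OuterFit] = []
    probs = np.empty(n)
    for i, ana in enumerate(analyses):
        tr = np.r_[0:i, i + 1 : n]
        lam_min = float(np.mean([e.lambda_min for e in ana.estimates]))
        lam_1se = float(np.mean([e.lambda_1se for e in ana.estimates]))
        lam_use = lam_min if rule == "lambda_min" else lam_1se
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coef, icept = fit_l1_logistic_at(X[tr], y[tr], lam_use)
        eta = float(np.clip(X[i] @ coef + icept, -35, 35))
        prob = 1.0 / (1.0 + np.exp(-eta))
        probs[i] = prob
        nz = np.flatnonzero(coef != 0)
        fits.append(
            OuterFit(
                held_out_sample=ratios.sample_ids[i],
                training_sample_ids=[ratios.sample_ids[j] for j in tr],
                lambda_used=lam_use,
                lambda_min_mean=lam_min,
                lambda_1se_mean=lam_1se,
                stability=ana.stability,
                selected_features=[ratios.features[j] for j in nz],
                coef=coef[nz],
                intercept=icept,
                predicted_probability=prob,
            )
        )
    preds = OuterPredictions(list(ratios.sample_ids), ratios.y.copy(), probs)
    return preds, fits


def collate_selection_frequencies(
    ratios: RatioMatrix,
    repeats: int = 50,
    k: int = 10,
    seed: int = 0,
    log2: bool = False,
    n_lambda: int = 100,
    analyses: list[_TrainingSetAnalysis] | None = None,
) -> SelectionFrequencyTable:
    """Pool lasso selections over (outer training set x repeat) fits.

    Each fit is the full-training-set lasso at that repeat's lambda.min;
    frequency = 100 * selections / (n_training_sets * repeats). Features
    never selected are absent from the table.
    """
    if analyses is None:
        X = ratios.design_matrix(log2=log2)
        y = ratios.y.astype(float)
        analyses = _analyze_training_sets(X, y, repeats, k, seed, n_lambda)
    counts = np.zeros(ratios.n_features, dtype=int)
    total = 0
    for ana in analyses:
        for sel in ana.selected_per_repeat:
            counts[sel] += 1
            total += 1
    present = np.flatnonzero(counts > 0)
    return SelectionFrequencyTable(
        features=[ratios.features[i] for i in present],
        counts=counts[present],
        total_fits=total,
    )


def _cv_misclassification(
    X: np.ndarray, y: np.ndarray, repeats: int, k: int, seed: int, ridge: float = 1e-8
) -> float:
    """Repeated stratified k-fold CV misclassification of a logistic model."""
    n = len(y)
    errors = []
    seeds = _outer_seeds(seed, repeats)
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seeds[r]))
        for tr, te in skf.split(np.zeros(n), y):
            fit = fit_logistic(X[tr], y[tr].astype(float), ridge=ridge)
            pred = (fit.predict_proba(X[te]) > 0.5).astype(int)
            errors.append(np.mean(pred != y[te]))
    return float(np.mean(errors))


def default_cutoff_grid(step: float = 5.0) -> np.ndarray:
    return np.arange(100.0, 0.0, -step)


def stepdown_cutoff_search(
    freq: SelectionFrequencyTable,
    ratios: RatioMatrix,
    cutoff_grid: np.ndarray | None = None,
    repeats: int = 50,
    k: int = 10,
    seed: int = 0,
    p_max: int | None = None,
    log2: bool = False,
    ridge: float = 1e-8,
) -> StableModel:
    """Step down through percent cutoffs; keep the one with the lowest
    inner-loop CV misclassification error (ties -> highest cutoff).

    Cutoffs whose feature set exceeds ``p_max`` (default n/4) end the
    descent; cutoffs with an empty feature set are skipped.
    """
    if cutoff_grid is None:
        cutoff_grid = default_cutoff_grid()
    cutoff_grid = np.sort(np.asarray(cutoff_grid, dtype=float))[::-1]
    if p_max is None:
        p_max = max(2, ratios.n_samples // 4)
    y = ratios.y
    inner_error: dict[float, float] = {}
    feature_sets: dict[float, list[int]] = {}
    seeds = _outer_seeds(seed + 1, len(cutoff_grid))
    prev_set: tuple[int, ...] | None = None
    for ci, cutoff in enumerate(cutoff_grid):
        idx = freq.features_at_or_above(cutoff)
        if len(idx) == 0:
            continue
        if len(idx) > p_max:
            break
        key = tuple(idx)
        if key == prev_set:
            # identical feature set as the cutoff above: same error, the
            # higher cutoff already holds it, so the tie rule keeps that one
            continue
        prev_set = key
        feats = [freq.features[i] for i in idx]
        X = _design_for(ratios, feats, log2)
        err = _cv_misclassification(X, y, repeats, k, int(seeds[ci]))
        inner_error[float(cutoff)] = err
        feature_sets[float(cutoff)] = idx
    if not inner_error:
        raise ValueError("no cutoff produced a non-empty feature set within p_max")
    # lowest error; ties -> highest cutoff (grid iterated descending)
    best_cutoff = None
    best_err = np.inf
    for cutoff in sorted(inner_error, reverse=True):
        if inner_error[cutoff] < best_err - 1e-12:
            best_err = inner_error[cutoff]
            best_cutoff = cutoff
    feats = [freq.features[i] for i in feature_sets[best_cutoff]]
    X = _design_for(ratios, feats, log2)
    fit = fit_logistic(X, y.astype(float), ridge=ridge)
    return StableModel(
        cutoff_percent=float(best_cutoff),
        features=feats,
        coef=fit.coef,
        intercept=fit.intercept,
        inner_cv_error=inner_error,
        frequency_table=freq,
    )


def run_stavarsel(
    ratios: RatioMatrix,
    repeats: int = 50,
    k: int = 10,
    seed: int = 0,
    cutoff_grid: np.ndarray | None = None,
    p_max: int | None = None,
    log2: bool = False,
    ridge: float = 1e-8,
    n_lambda: int = 100,
    analyses: list[_TrainingSetAnalysis] | None = None,
    nested_selection: bool = False,
) -> tuple[StableModel, OuterPredictions]:
    """Full three-stage procedure.

    Derives the stable feature set (collation + step-down), then refits an
    unpenalized logistic model with that fixed feature set on every LOO
    training set to predict its held-out sample.

    With ``nested_selection=True`` the held-out predictions instead use a
    stable set re-derived inside each outer training set (frequency table
    from that training set's repeats only, cutoff tuned by CV on the
    training samples only). This strictly-nested variant exists for
    leakage-sensitivity analysis: the default global stable set sees every
    sample during selection, so comparing the two quantifies that optimism.
    The returned :class:`StableModel` is the global one in both modes.
    """
    X = ratios.design_matrix(log2=log2)
    y = ratios.y.astype(float)
    n = len(y)
    if analyses is None:
        analyses = _analyze_training_sets(X, y, repeats, k, seed, n_lambda)
    freq = collate_selection_frequencies(ratios, analyses=analyses)
    stable = stepdown_cutoff_search(
        freq,
        ratios,
        cutoff_grid=cutoff_grid,
        repeats=repeats,
        k=k,
        seed=seed,
        p_max=p_max,
        log2=log2,
        ridge=ridge,
    )
    probs = np.empty(n)
    if nested_selection:
        seeds = _outer_seeds(seed + 2, n)
        for i, ana in enumerate(analyses):
            tr = np.r_[0:i, i + 1 : n]
            sub = ratios.subset_samples(tr)
            counts = np.zeros(ratios.n_features, dtype=int)
            for sel in ana.selected_per_repeat:
                counts[sel] += 1
            present = np.flatnonzero(counts > 0)
            freq_i = SelectionFrequencyTable(
                features=[ratios.features[j] for j in present],
                counts=counts[present],
                total_fits=len(ana.selected_per_repeat),
            )
            try:
                stable_i = stepdown_cutoff_search(
                    freq_i, sub, cutoff_grid=cutoff_grid, repeats=repeats, k=k,
                    seed=int(seeds[i]), p_max=p_max, log2=log2, ridge=ridge,
                )
                feats_i = stable_i.features
            except ValueError:
                # every cutoff overflows p_max (few repeats -> coarse
                # frequencies); fall back to the top-frequency features
                cap = p_max if p_max is not None else max(2, sub.n_samples // 4)
                order = np.argsort(-freq_i.counts, kind="stable")[:cap]
                feats_i = [freq_i.features[j] for j in order]
            Xi = _design_for(ratios, feats_i, log2)
            fit = fit_logistic(Xi[tr], y[tr], ridge=ridge)
            probs[i] = float(fit.predict_proba(Xi[i : i + 1])[0])
    else:
        Xs = _design_for(ratios, stable.features, log2)
        for i in range(n):
            tr = np.r_[0:i, i + 1 : n]
            fit = fit_logistic(Xs[tr], y[tr], ridge=ridge)
            probs[i] = float(fit.predict_proba(Xs[i : i + 1])[0])
    preds = OuterPredictions(list(ratios.sample_ids), ratios.y.copy(), probs)
    return stable, preds


# ---------------------------------------------------------------------------
# model / results objects


class TwoStageCV:
    """Two-stage nested-CV lasso model (baseline for StaVarSel).

    Parameters
    ----------
    ratios : RatioMatrix
        Prefiltered ratio-feature matrix with binary labels.
    rule : str
        ``"lambda_min"`` or ``"one_se"``.
    repeats, k : int
        Inner-loop repeated CV configuration.
    """

    def __init__(self, ratios: RatioMatrix, rule: str = "lambda_min", repeats: int = 50,
                 k: int = 10, log2: bool = False, n_lambda: int = 100):
        self.ratios = ratios
        self.rule = rule
        self.repeats = repeats
        self.k = k
        self.log2 = log2
        self.n_lambda = n_lambda

    def fit(self, seed: int = 0) -> "TwoStageResults":
        preds, fits = run_two_stage(
            self.ratios, self.rule, self.repeats, self.k, seed,
            log2=self.log2, n_lambda=self.n_lambda,
        )
        return TwoStageResults(self, preds, fits, seed)


@dataclass
class TwoStageResults:
    model: TwoStageCV
    outer_predictions: OuterPredictions
    outer_fits: list[OuterFit]
    seed: int

    def roc(self, B: int | None = None, seed: int = 0):
        from .evaluation import bootstrap_roc_ci, roc_curve

        p = self.outer_predictions
        if B:
            return bootstrap_roc_ci(p.probability, p.y_true, B=B, seed=seed)
        return roc_curve(p.probability, p.y_true)

    @property
    def auc(self) -> float:
        return self.roc().auc

    def summary(self) -> str:
        p = self.outer_predictions
        lines = [
            "Two-stage nested cross-validation (lasso logistic)",
            "=" * 52,
            f"rule:               {self.model.rule}",
            f"samples:            {len(p.sample_ids)} (LOO outer loop)",
            f"inner CV:           {self.model.repeats} x {self.model.k}-fold",
            f"cross-validated AUC: {self.auc:.3f}",
            f"accuracy @0.5:       {p.accuracy():.3f}",
            f"median model size:   {np.median([len(f.selected_features) for f in self.outer_fits]):.0f} features",
        ]
        return "\n".join(lines)


class StaVarSel:
    """Stabilised variable selection over ratio features.

    Builds expression-ratio biomarker panels by collating lasso selections
    across a nested cross-validation design and keeping the features whose
    selection frequency clears a CV-tuned cutoff.

    Parameters
    ----------
    ratios : RatioMatrix
        Prefiltered ratio features (see :func:`stavarsel.ct.preprocess_ct`).
    repeats : int
        Inner-loop CV repeats (50 reproduces the original design; 10 is the
        desk-scale profile).
    k : int
        Inner CV folds.
    cutoff_step : float
        Step (percent) of the step-down cutoff grid.
    p_max : int
        Largest feature set the cutoff search may evaluate (default n/4).
    """

    def __init__(self, ratios: RatioMatrix, repeats: int = 50, k: int = 10,
                 cutoff_step: float = 5.0, p_max: int | None = None,
                 log2: bool = False, ridge: float = 1e-8, n_lambda: int = 100):
        self.ratios = ratios
        self.repeats = repeats
        self.k = k
        self.cutoff_step = cutoff_step
        self.p_max = p_max
        self.log2 = log2
        self.ridge = ridge
        self.n_lambda = n_lambda

    @classmethod
    def from_ct(cls, ct, undetected_ct: float = 40.0, min_detect_fraction: float = 0.5,
                max_cov: float = 3.0, alpha: float = 0.05, **kwargs) -> "StaVarSel":
        """Build directly from a :class:`~stavarsel.ct.CtMatrix`, applying the
        expression transform, ratio construction and prefilters."""
        from .ct import preprocess_ct

        filtered, _ = preprocess_ct(
            ct, undetected_ct=undetected_ct,
            min_detect_fraction=min_detect_fraction, max_cov=max_cov, alpha=alpha,
        )
        return cls(filtered, **kwargs)

    def fit(self, seed: int = 0) -> "StaVarSelResults":
        stable, preds = run_stavarsel(
            self.ratios, repeats=self.repeats, k=self.k, seed=seed,
            cutoff_grid=default_cutoff_grid(self.cutoff_step),
            p_max=self.p_max, log2=self.log2, ridge=self.ridge,
            n_lambda=self.n_lambda,
        )
        return StaVarSelResults(self, stable, preds, seed)


@dataclass
class StaVarSelResults:
    """Fitted StaVarSel model: stable panel + outer-loop predictions."""

    model: StaVarSel
    stable_model: StableModel
    outer_predictions: OuterPredictions
    seed: int

    @property
    def features(self) -> list[RatioFeature]:
        return self.stable_model.features

    @property
    def coef(self) -> np.ndarray:
        return self.stable_model.coef

    @property
    def cutoff_percent(self) -> float:
        return self.stable_model.cutoff_percent

    @property
    def frequency_table(self) -> SelectionFrequencyTable:
        return self.stable_model.frequency_table

    def roc(self, B: int | None = None, seed: int = 0):
        from .evaluation import bootstrap_roc_ci, roc_curve

        p = self.outer_predictions
        if B:
            return bootstrap_roc_ci(p.probability, p.y_true, B=B, seed=seed)
        return roc_curve(p.probability, p.y_true)

    @property
    def auc(self) -> float:
        return self.roc().auc

    def plot_roc(self, ax=None, B: int | None = None, seed: int = 0):
        """ROC curve of the outer-loop predictions (matplotlib Axes)."""
        import matplotlib.pyplot as plt

        roc = self.roc(B=B, seed=seed)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(1 - roc.specificity, roc.sensitivity, drawstyle="steps-post")
        if roc.sensitivity_ci is not None:
            ax.fill_between(
                1 - roc.specificity, roc.sensitivity_ci[0], roc.sensitivity_ci[1],
                alpha=0.2, step="post",
            )
        ax.plot([0, 1], [0, 1], "k:", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.set_title(f"StaVarSel cross-validated ROC (AUC = {roc.auc:.3f})")
        return ax

    def summary(self) -> str:
        from .evaluation import operating_points, roc_curve

        p = self.outer_predictions
        roc = roc_curve(p.probability, p.y_true)
        youden, highspec = operating_points(roc)
        lines = [
            "StaVarSel: stabilised nested cross-validation",
            "=" * 52,
            f"samples:              {len(p.sample_ids)} (LOO outer loop)",
            f"inner CV:             {self.model.repeats} x {self.model.k}-fold",
            f"collated lasso fits:  {self.frequency_table.total_fits}",
            f"selection cutoff:     {self.cutoff_percent:.0f}%",
            f"stable features:      {len(self.features)}",
            f"cross-validated AUC:  {roc.auc:.3f}",
            f"Youden point:         sens {youden.sensitivity:.2f} / spec {youden.specificity:.2f}"
            f" (threshold {youden.threshold:.3f})",
            f"high-spec point:      sens {highspec.sensitivity:.2f} / spec {highspec.specificity:.2f}",
            "",
            "stable panel (feature: coefficient):",
        ]
        for f, c in zip(self.features, self.coef):
            lines.append(f"  {f.name:<30s} {c:+.4g}")
        return "\n".join(lines)
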