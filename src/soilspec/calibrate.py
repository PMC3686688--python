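"""Multivariate calibration of SOC on pre-treated spectra.

The implemented core is a univariate-response partial least squares
regression (NIPALS): latent variables are extracted iteratively to maximise
the covariance between predictor scores and the response, the predictor
matrix is deflated after each component, and coefficients are returned on
the original predictor scale.  Model tuning uses ten random half-partitions
of the training set, reused across the whole parameter grid for
leave-one-group-out cross-validation, with the one-standard-error rule
(least complex model within one SE of the minimal CV RMSE).  Recursive
feature elimination ranks predictors by an importance measure from a full
model and evaluates a descending sequence of predictor counts.  Auxiliary
predictors (sand and/or clay) are fused with the spectral matrix either via
principal-component scores (>99 % variance) plus scaling, or — when RFE has
already reduced the matrix to its intrinsic dimensionality — by scaling
alone.

Other model families (random forest, boosted trees, support-vector
regression, ...) plug in through :class:`ModelFamily`; they are contracts
around external implementations, not re-implemented algorithms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .containers import SpectraMatrix, SpectralLibrary
from .errors import ConstantColumnError, SoilSpecError
from .preprocess import QcReport, build_design_matrix
from .select import SelectionResult, pca_fit, split_library
from .validate import ValidationStats, prediction_stats


# --------------------------------------------------------------------------
# PLS core
# --------------------------------------------------------------------------

class PLSRegressor(BaseEstimator, RegressorMixin):
    """Partial least squares regression, univariate response (NIPALS).

    Parameters
    ----------
    n_components : int
        Number of latent variables.
    scale : bool
        Scale predictor columns to unit variance before extraction.

    Attributes
    ----------
    coef_ : ndarray, shape (n_features,)
        Regression coefficients on the original predictor scale.
    intercept_ : float
    x_weights_, x_scores_, x_loadings_ : per-component NIPALS vectors.
    """

    def __init__(self, n_components: int = 10, scale: bool = False):
        self.n_components = n_components
        self.scale = scale

    def fit(self, X, y) -> "PLSRegressor":
        X = np.atleast_2d(np.asarray(X, float))
        y = np.asarray(y, float).ravel()
        n, p = X.shape
        if y.size != n:
            raise SoilSpecError("X and y have different sample counts")
        if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
            raise SoilSpecError("X and y must be finite")
        k = self.n_components
        if not 1 <= k <= min(n - 1, p):
            raise SoilSpecError(
                f"n_components={k} outside [1, min(n_samples-1, n_features)="
                f"{min(n - 1, p)}]"
            )

        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = float(y.mean())
        if y.std() == 0:
            # degenerate response: the model collapses to the mean
            self.x_std_ = np.ones(p)
            self.n_components_ = 0
            self.x_weights_ = np.empty((p, 0))
            self.x_loadings_ = np.empty((p, 0))
            self.x_scores_ = np.empty((n, 0))
            self.y_loadings_ = np.empty(0)
            self.coef_ = np.zeros(p)
            self.intercept_ = self.y_mean_
            return self
        if self.scale:
            sd = X.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            self.x_std_ = sd
        else:
            self.x_std_ = np.ones(p)
        Xc = (X - self.x_mean_) / self.x_std_
        yc = y - self.y_mean_

        W = np.empty((k, p))   # weights
        P = np.empty((k, p))   # x-loadings
        T = np.empty((n, k))   # scores
        q = np.empty(k)        # y-loadings
        eps = np.finfo(float).eps
        for a in range(k):
            w = Xc.T @ yc
            nw = np.linalg.norm(w)
            if nw < eps:  # residual X carries no covariance with y
                k = a
                break
            w /= nw
            t = Xc @ w
            tt = t @ t
            if tt < eps:
                k = a
                break
            pl = Xc.T @ t / tt
            qa = yc @ t / tt
            Xc = Xc - np.outer(t, pl)
            yc = yc - qa * t
            W[a], P[a], T[:, a], q[a] = w, pl, t, qa

        if k == 0:
            raise SoilSpecError("no extractable latent variable")
        self.n_components_ = k
        self.x_weights_ = W[:k].T
        self.x_loadings_ = P[:k].T
        self.x_scores_ = T[:, :k]
        self.y_loadings_ = q[:k]
        # B = W (P'W)^-1 q, mapped back to the original predictor scale
        beta = self.x_weights_ @ np.linalg.solve(
            self.x_loadings_.T @ self.x_weights_, self.y_loadings_
        )
        self.coef_ = beta / self.x_std_
        self.intercept_ = self.y_mean_ - float(self.x_mean_ @ self.coef_)
        return self

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[1] != self.coef_.size:
            raise SoilSpecError(
                f"expected {self.coef_.size} predictors, got {X.shape[1]}"
            )
        return self.intercept_ + X @ self.coef_


def pls_fit(X, y, n_lv: int, scale: bool = False) -> PLSRegressor:
    """Fit a PLS model with ``n_lv`` latent variables."""
    return PLSRegressor(n_components=n_lv, scale=scale).fit(X, y)


def pls_predict(model: PLSRegressor, X) -> np.ndarray:
    return model.predict(X)


# --------------------------------------------------------------------------
# Model family contract
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelFamily:
    """Contract a pluggable model family must satisfy.

    ``make(params)`` returns an unfitted estimator with fit/predict;
    ``complexity(params)`` orders grid points for the one-SE rule (smaller =
    simpler); ``importance(fitted, X, y)`` returns per-predictor importances
    (larger = more important), or may be None for families without one.
    """

    name: str
    make: Callable[[dict], BaseEstimator]
    complexity: Callable[[dict], float]
    importance: Callable[[BaseEstimator, np.ndarray, np.ndarray], np.ndarray] | None
    default_grid: tuple = ()


def _pls_importance(fitted: PLSRegressor, X: np.ndarray, y: np.ndarray
                    ) -> np.ndarray:
    """|standardized coefficient|: |coef_j| * sd(X_j)."""
    return np.abs(fitted.coef_) * X.std(axis=0, ddof=1)


def pls_family(max_lv: int = 20, scale: bool = False) -> ModelFamily:
    """The implemented core family: grid over 1..max_lv latent variables."""
    return ModelFamily(
        name="pls",
        make=lambda params: PLSRegressor(n_components=params["n_lv"], scale=scale),
        complexity=lambda params: params["n_lv"],
        importance=_pls_importance,
        default_grid=tuple({"n_lv": k} for k in range(1, max_lv + 1)),
    )


def random_forest_family(seed: int = 0) -> ModelFamily:
    """Plug-in family backed by sklearn's random forest."""
    from sklearn.ensemble import RandomForestRegressor

    def make(params):
        return RandomForestRegressor(
            n_estimators=params.get("n_estimators", 100),
            max_features=params.get("max_features", 1.0 / 3.0),
            random_state=seed, n_jobs=1,
        )

    return ModelFamily(
        name="random_forest",
        make=make,
        complexity=lambda p: p.get("n_estimators", 100),
        importance=lambda fitted, X, y: fitted.feature_importances_,
        default_grid=tuple({"max_features": f} for f in (0.33, 0.66, 1.0)),
    )


def svr_family() -> ModelFamily:
    """Plug-in family backed by sklearn's radial-basis SVR (no importance)."""
    from sklearn.svm import SVR

    return ModelFamily(
        name="svm",
        make=lambda p: SVR(kernel="rbf", C=p.get("C", 1.0), gamma="scale"),
        complexity=lambda p: p.get("C", 1.0),
        importance=None,
        default_grid=tuple({"C": c} for c in (0.25, 0.5, 1.0, 2.0, 4.0)),
    )


def gradient_boosting_family(seed: int = 0) -> ModelFamily:
    """Plug-in family backed by sklearn's gradient-boosted trees."""
    from sklearn.ensemble import GradientBoostingRegressor

    def make(params):
        return GradientBoostingRegressor(
            n_estimators=params.get("n_estimators", 100),
            max_depth=params.get("max_depth", 3), random_state=seed,
        )

    return ModelFamily(
        name="boosted_trees",
        make=make,
        complexity=lambda p: p.get("n_estimators", 100) * p.get("max_depth", 3),
        importance=lambda fitted, X, y: fitted.feature_importances_,
        default_grid=tuple({"n_estimators": n} for n in (50, 100, 200)),
    )


FAMILY_REGISTRY: dict[str, Callable[..., ModelFamily]] = {
    "pls": pls_family,
    "random_forest": random_forest_family,
    "svm": svr_family,
    "boosted_trees": gradient_boosting_family,
}


# --------------------------------------------------------------------------
# Cross-validated tuning
# --------------------------------------------------------------------------

@dataclass
class TuningResult:
    """Grid search record: per-point CV RMSE mean and SE over the reused
    half-partitions, plus the one-SE choice."""

    grid: list[dict]
    cv_rmse_mean: np.ndarray
    cv_rmse_se: np.ndarray
    partitions: np.ndarray          # (n_partitions, n) boolean: True = held out
    seed: int
    chosen: dict | None = None
    events: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "params": [repr(g) for g in self.grid],
            "cv_rmse_mean": self.cv_rmse_mean,
            "cv_rmse_se": self.cv_rmse_se,
        })


def _draw_partitions(n: int, n_partitions: int, holdout_fraction: float,
                     y: np.ndarray, rng: np.random.Generator,
                     events: list[str]) -> np.ndarray:
    parts = np.empty((n_partitions, n), dtype=bool)
    for b in range(n_partitions):
        for attempt in range(100):
            held = rng.random(n) < holdout_fraction
            # both halves must be non-degenerate
            if (2 <= held.sum() <= n - 2
                    and np.std(y[held]) > 0 and np.std(y[~held]) > 0):
                break
            events.append(f"partition {b}: degenerate draw redrawn")
        parts[b] = held
    return parts


def cv_tune(
    X, y,
    family: ModelFamily,
    grid: Sequence[dict] | None = None,
    n_partitions: int = 10,
    holdout_fraction: float = 0.5,
    seed: int = 0,
) -> TuningResult:
    """Grid evaluation by repeated half-split leave-group-out CV.

    ``n_partitions`` random partitions (each sample held out with
    probability ``holdout_fraction``) are drawn once from ``seed`` and
    reused for every grid point; each partition's held-out half is predicted
    once by a model fitted on the retained half.  Reported per grid point:
    mean RMSE and its standard error (SD / sqrt(n_partitions)).
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    grid = list(grid if grid is not None else family.default_grid)
    if not grid:
        raise SoilSpecError("empty tuning grid")
    events: list[str] = []
    rng = np.random.default_rng(seed)
    parts = _draw_partitions(len(y), n_partitions, holdout_fraction, y, rng, events)

    rmse = np.empty((len(grid), n_partitions))
    for b in range(n_partitions):
        held = parts[b]
        Xtr, ytr, Xho, yho = X[~held], y[~held], X[held], y[held]
        for g, params in enumerate(grid):
            est = family.make(params)
            try:
                est.fit(Xtr, ytr)
                resid = est.predict(Xho) - yho
                rmse[g, b] = np.sqrt(np.mean(resid**2))
            except SoilSpecError as exc:  # e.g. n_lv too large for the half
                rmse[g, b] = np.nan
                events.append(f"grid {params} partition {b}: {exc}")

    valid = np.isfinite(rmse)
    counts = valid.sum(axis=1)
    mean = np.where(valid, rmse, 0.0).sum(axis=1) / np.maximum(counts, 1)
    mean[counts == 0] = np.nan
    dev2 = np.where(valid, (rmse - mean[:, None]) ** 2, 0.0).sum(axis=1)
    sd = np.sqrt(dev2 / np.maximum(counts - 1, 1))
    se = np.where(counts > 1, sd / np.sqrt(np.maximum(counts, 1)), np.nan)
    result = TuningResult(grid, mean, se, parts, seed, events=events)
    result.chosen = one_se_select(result, family.complexity)
    return result


def one_se_select(t: TuningResult,
                  complexity: Callable[[dict], float]) -> dict:
    """One-standard-error rule: the least complex grid point whose mean CV
    RMSE is within one SE of the minimum."""
    ok = np.isfinite(t.cv_rmse_mean)
    if not ok.any():
        raise SoilSpecError("no grid point produced a valid CV estimate")
    means = np.where(ok, t.cv_rmse_mean, np.inf)
    best = int(np.argmin(means))
    bound = means[best] + (t.cv_rmse_se[best] if np.isfinite(t.cv_rmse_se[best]) else 0.0)
    candidates = [i for i in range(len(t.grid)) if means[i] <= bound]
    chosen = min(candidates, key=lambda i: (complexity(t.grid[i]), i))
    assert means[chosen] <= bound
    return t.grid[chosen]


# --------------------------------------------------------------------------
# Recursive feature elimination
# --------------------------------------------------------------------------

@dataclass
class RfeResult:
    """Backward-elimination record over a descending size sequence."""

    sizes: list[int]
    cv_rmse: list[float]
    tunings: list[TuningResult]
    ranking: np.ndarray             # predictor indices, most important first
    selected_size: int = 0
    selected_indices: np.ndarray = field(default_factory=lambda: np.empty(0, int))


def rfe(
    X, y,
    family: ModelFamily,
    sizes: Sequence[int] | None = None,
    grid: Sequence[dict] | None = None,
    n_partitions: int = 10,
    holdout_fraction: float = 0.5,
    seed: int = 0,
) -> RfeResult:
    """Backward predictor selection by importance ranking.

    A full model (tuned on all predictors) supplies the importance ranking;
    each candidate size ``p_i`` keeps the top-``p_i`` predictors and is
    scored by the same CV machinery; the size with the lowest CV RMSE wins
    (ties to the smaller size).
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    p = X.shape[1]
    if family.importance is None:
        raise SoilSpecError(
            f"family {family.name!r} exposes no importance measure; RFE "
            "requires one"
        )
    if sizes is None:
        sizes = [p] + [s for s in (100, 50, 25, 10) if s < p]
    sizes = list(sizes)
    if sorted(sizes, reverse=True) != sizes or max(sizes) > p or min(sizes) < 1:
        raise SoilSpecError("sizes must be a descending sequence within [1, p]")

    full_tuning = cv_tune(X, y, family, grid, n_partitions, holdout_fraction, seed)
    full_model = family.make(full_tuning.chosen).fit(X, y)
    imp = np.asarray(family.importance(full_model, X, y), float)
    ranking = np.argsort(-imp, kind="stable")

    cv_scores: list[float] = []
    tunings: list[TuningResult] = []
    for size in sizes:
        cols = np.sort(ranking[:size])
        t = cv_tune(X[:, cols], y, family, grid, n_partitions,
                    holdout_fraction, seed)
        idx = t.grid.index(t.chosen)
        cv_scores.append(float(t.cv_rmse_mean[idx]))
        tunings.append(t)

    best = min(range(len(sizes)), key=lambda i: (cv_scores[i], sizes[i]))
    return RfeResult(
        sizes=sizes, cv_rmse=cv_scores, tunings=tunings, ranking=ranking,
        selected_size=sizes[best],
        selected_indices=np.sort(ranking[: sizes[best]]),
    )


# --------------------------------------------------------------------------
# Auxiliary predictor fusion
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PredictorRecipe:
    """What enters the model: the spectra as-is or RFE-selected bands,
    optionally fused with sand and/or clay content.

    Fusion mode follows the source: full spectra are first compressed to
    principal-component scores (>99 % variance) so the single auxiliary
    column is not outweighed by hundreds of bands; an RFE-reduced matrix is
    assumed to be at its intrinsic dimensionality and is only scaled.
    """

    source: str = "spectra"          # {"spectra", "rfe"}
    auxiliary: str = "none"          # {"none", "sand", "clay", "both"}

    def __post_init__(self):
        if self.source not in ("spectra", "rfe"):
            raise SoilSpecError(f"unknown predictor source {self.source!r}")
        if self.auxiliary not in ("none", "sand", "clay", "both"):
            raise SoilSpecError(f"unknown auxiliary {self.auxiliary!r}")

    @property
    def fusion(self) -> str:
        if self.auxiliary == "none":
            return "none"
        return "scale_only" if self.source == "rfe" else "pca_scores_99"

    @property
    def aux_columns(self) -> tuple[str, ...]:
        return {"none": (), "sand": ("sand",), "clay": ("clay",),
                "both": ("sand", "clay")}[self.auxiliary]


class AuxiliaryFuser(BaseEstimator):
    """Fuse a spectra-derived matrix with auxiliary columns.

    fit computes (on training rows only) the PCA and the column
    centre/scale constants; transform projects new samples with the frozen
    constants.  All fused columns leave fit-time with mean 0 and SD 1.
    """

    def __init__(self, mode: str = "pca_scores_99", var_threshold: float = 0.99):
        self.mode = mode
        self.var_threshold = var_threshold

    def fit(self, X, aux) -> "AuxiliaryFuser":
        X = np.atleast_2d(np.asarray(X, float))
        aux = np.atleast_2d(np.asarray(aux, float))
        if aux.shape[0] != X.shape[0]:
            raise SoilSpecError("aux rows must align with X rows")
        if not np.all(np.isfinite(aux)):
            raise SoilSpecError("aux contains missing values")
        if self.mode == "pca_scores_99":
            self.pca_ = pca_fit(X, self.var_threshold)
            base = self.pca_.scores
        elif self.mode == "scale_only":
            self.pca_ = None
            base = X
        else:
            raise SoilSpecError(f"unknown fusion mode {self.mode!r}")
        fused = np.column_stack([base, aux])
        self.center_ = fused.mean(axis=0)
        sd = fused.std(axis=0, ddof=1)
        if np.any(sd == 0):
            j = int(np.flatnonzero(sd == 0)[0])
            raise ConstantColumnError(
                f"fused column {j} has zero variance; cannot scale"
            )
        self.scale_ = sd
        self.n_spectral_in_ = X.shape[1]
        return self

    def transform(self, X, aux) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        aux = np.atleast_2d(np.asarray(aux, float))
        base = self.pca_.project(X) if self.pca_ is not None else X
        fused = np.column_stack([base, aux])
        return (fused - self.center_) / self.scale_

    def fit_transform(self, X, aux) -> np.ndarray:
        return self.fit(X, aux).transform(X, aux)


def fuse_auxiliary(X, aux, recipe: PredictorRecipe,
                   var_threshold: float = 0.99
                   ) -> tuple[np.ndarray, AuxiliaryFuser]:
    """Functional wrapper: fused training matrix plus the frozen fuser."""
    fuser = AuxiliaryFuser(recipe.fusion, var_threshold)
    return fuser.fit_transform(X, aux), fuser


# --------------------------------------------------------------------------
# End-to-end training
# --------------------------------------------------------------------------

@dataclass
class CalibrationModel:
    """A fitted calibration with its full audit trail."""

    estimator: BaseEstimator
    family_name: str
    pretreatment: str
    recipe: PredictorRecipe
    tuning: TuningResult
    rfe_result: RfeResult | None
    fuser: AuxiliaryFuser | None
    selected_columns: np.ndarray | None
    selection: SelectionResult
    qc: QcReport
    wavelengths: np.ndarray
    stats: ValidationStats
    test_observed: np.ndarray
    test_predicted: np.ndarray
    test_properties: pd.DataFrame

    def predict(self, X, aux=None) -> np.ndarray:
        """Predict SOC from a pre-treated spectral matrix (and auxiliary
        columns if the recipe uses them)."""
        X = np.atleast_2d(np.asarray(X, float))
        if self.selected_columns is not None:
            X = X[:, self.selected_columns]
        if self.fuser is not None:
            if aux is None:
                raise SoilSpecError("recipe requires auxiliary columns")
            X = self.fuser.transform(X, aux)
        return self.estimator.predict(X)


def train_model(
    lib: SpectralLibrary,
    pretreatment: str = "SG1",
    recipe: PredictorRecipe = PredictorRecipe(),
    family: ModelFamily | None = None,
    grid: Sequence[dict] | None = None,
    rfe_sizes: Sequence[int] | None = None,
    train_fraction: float = 2.0 / 3.0,
    n_partitions: int = 10,
    holdout_fraction: float = 0.5,
    qc_threshold: float | None = 0.01,
    seed: int = 0,
) -> CalibrationModel:
    """Full calibration: design matrix -> Kennard-Stone split -> (RFE) ->
    (auxiliary fusion) -> CV tuning with the one-SE rule -> final fit ->
    test-set validation.  Test rows are never touched during tuning; all
    fusion constants are computed on training rows only.
    """
    family = family if family is not None else pls_family()
    if recipe.auxiliary != "none":
        material = lib.properties["material"].to_numpy()
        if (material == "organic").any():
            raise SoilSpecError(
                "auxiliary texture predictors are unavailable for organic "
                "samples (texture analyses are not performed on them)"
            )

    matrix, qc = build_design_matrix(lib, pretreatment, qc_threshold)
    keep_ids = set(matrix.sample_ids)
    keep_idx = np.flatnonzero(lib.properties["sample_id"].isin(keep_ids))
    sublib = lib.subset(keep_idx)
    props = sublib.properties
    y = props["soc"].to_numpy(float)

    selection, _ = split_library(sublib, fraction=train_fraction)
    tr, te = selection.train, selection.test
    X_all = matrix.values

    sel_cols: np.ndarray | None = None
    rfe_result: RfeResult | None = None
    if recipe.source == "rfe":
        rfe_result = rfe(X_all[tr], y[tr], family, rfe_sizes, grid,
                         n_partitions, holdout_fraction, seed)
        sel_cols = rfe_result.selected_indices
        X_train, X_test = X_all[tr][:, sel_cols], X_all[te][:, sel_cols]
    else:
        X_train, X_test = X_all[tr], X_all[te]

    fuser: AuxiliaryFuser | None = None
    if recipe.auxiliary != "none":
        aux_all = props.loc[:, list(recipe.aux_columns)].to_numpy(float)
        fuser = AuxiliaryFuser(recipe.fusion)
        X_train = fuser.fit_transform(X_train, aux_all[tr])
        X_test = fuser.transform(X_all[te][:, sel_cols] if sel_cols is not None
                                 else X_all[te], aux_all[te])

    tuning = cv_tune(X_train, y[tr], family, grid, n_partitions,
                     holdout_fraction, seed)
    final = family.make(tuning.chosen).fit(X_train, y[tr])

    pred = final.predict(X_test)
    stats = prediction_stats(y[te], pred)
    return CalibrationModel(
        estimator=final,
        family_name=family.name,
        pretreatment=pretreatment,
        recipe=recipe,
        tuning=tuning,
        rfe_result=rfe_result,
        fuser=fuser,
        selected_columns=sel_cols,
        selection=selection,
        qc=qc,
        wavelengths=matrix.wavelengths,
        stats=stats,
        test_observed=y[te],
        test_predicted=pred,
        test_properties=props.iloc[te].reset_index(drop=True),
    )
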