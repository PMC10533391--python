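"""The regression and machine-learning battery for invasion analysis.

Four response families, all sharing the same covariate handling
(continuous predictors z-scored, so coefficients are comparable):

* non-native **presence** — binomial GLM with logit link, fitted in two
  stages: a non-spatial fit whose response residuals are turned into a
  residual autocovariate (RAC) over the 250 km neighbourhood, then a final
  fit that includes the RAC term to absorb residual spatial structure;
* invasion **severity, richness** — binomial GLM on (non-native species
  count out of total species count), which weights plots by community size
  and avoids the denominator bias of modelling the raw proportion;
* invasion **severity, abundance** — beta regression (logit mean link,
  constant precision, direct maximum likelihood) on the relative
  non-native basal area, with boundary values squeezed;
* invasion **strategy** — Gaussian linear model with a quadratic
  temperature term and the MATxMAP, MATxports and MAPxports interactions,
  backward-pruned at alpha = 0.05 (interactions only; main effects stay).

Random forests (500 trees, sqrt mtry, minimum node size 5, bootstrap
resampling) provide variable importance as the sum of absolute sampled
Shapley values (permutation approximation, 100 simulations) and marginal
SHAP curves.  A pre-invasion sensitivity analysis estimates how much of an
apparent biotic-resistance signal could be richness loss caused by the
invasion itself, using plots with an uninvaded first census.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit  # noqa: F401  (re-exported for model factories)
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from statsmodels.othermod.betareg import BetaModel
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .errors import (
    ConvergenceError,
    InvalidArgumentError,
    SchemaError,
    UndefinedStatisticError,
)
from .rng import child_seed, stream
from .spatial import SpatialIndex, morans_i, residual_autocovariate

__all__ = [
    "ModelSpec",
    "ModelFit",
    "collinearity_screen",
    "design_matrix",
    "fit_presence_model",
    "fit_severity_models",
    "fit_strategy_model",
    "rf_shap_importance",
    "ShapImportance",
    "SensitivityResult",
    "sensitivity_preinvasion",
    "summarize_fits",
]

#: covariates the analysis always keeps, whatever the collinearity screen says
ALWAYS_KEEP = ("mat", "map", "dist_ports_km", "pop_density")


@dataclass
class ModelSpec:
    response: str
    family: str  # binomial-logit | binomial-counts | beta-logit | gaussian
    predictors: list
    interactions: list = field(default_factory=list)  # list of (a, b) tuples
    quadratic: list = field(default_factory=list)     # predictors squared after z
    standardize: bool = True
    trials: str | None = None  # denominator column for binomial-counts


@dataclass
class ModelFit:
    name: str
    family: str
    params: pd.Series
    bse: pd.Series
    statistic: pd.Series
    pvalues: pd.Series
    nobs: int
    llf: float
    converged: bool
    spec: ModelSpec | None = None
    extras: dict = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": self.name,
                "term": self.params.index,
                "estimate": self.params.to_numpy(),
                "se": self.bse.to_numpy(),
                "statistic": self.statistic.to_numpy(),
                "p": self.pvalues.to_numpy(),
            }
        )


# --------------------------------------------------------------------------
# covariate handling
# --------------------------------------------------------------------------

def collinearity_screen(
    covariates: pd.DataFrame,
    threshold: float = 0.7,
    always_keep: Sequence[str] = ALWAYS_KEEP,
) -> tuple[list, pd.DataFrame]:
    """Greedily drop one of each |r| >= threshold covariate pair.

    Columns in ``always_keep`` are never dropped (ties between two
    droppable columns keep the alphabetically earlier one).  Returns the
    retained column list and a report of dropped pairs.
    """
    if not all(np.issubdtype(covariates[c].dtype, np.number) for c in covariates):
        bad = [c for c in covariates
               if not np.issubdtype(covariates[c].dtype, np.number)]
        raise SchemaError(f"non-numeric covariate columns: {bad}")
    corr = covariates.corr().abs()
    retained = list(covariates.columns)
    report = []
    pairs = [
        (corr.loc[a, b], a, b)
        for i, a in enumerate(corr.columns)
        for b in corr.columns[i + 1:]
        if corr.loc[a, b] >= threshold
    ]
    for r, a, b in sorted(pairs, reverse=True):
        if a not in retained or b not in retained:
            continue
        if a in always_keep and b in always_keep:
            continue
        drop = b if a in always_keep else a if b in always_keep else max(a, b)
        retained.remove(drop)
        report.append({"kept": a if drop == b else b, "dropped": drop, "r": r})
    return retained, pd.DataFrame(report, columns=["kept", "dropped", "r"])


def design_matrix(data: pd.DataFrame, spec: ModelSpec,
                  extra: dict | None = None) -> pd.DataFrame:
    """Build the (standardized) design: mains, quadratics, interactions, const."""
    X = pd.DataFrame(index=data.index)
    for col in spec.predictors:
        v = data[col].astype(float)
        if spec.standardize:
            sd = v.std()
            if sd == 0:
                raise InvalidArgumentError(f"constant predictor: {col}")
            v = (v - v.mean()) / sd
        X[col] = v
    for col in spec.quadratic:
        X[f"{col}_sq"] = X[col] ** 2
    for a, b in spec.interactions:
        X[f"{a}:{b}"] = X[a] * X[b]
    if extra:
        for name, vals in extra.items():
            X[name] = np.asarray(vals, dtype=float)
    X.insert(0, "const", 1.0)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise InvalidArgumentError(
            f"design matrix rank-deficient ({rank} < {X.shape[1]})"
        )
    return X


def _wrap(name: str, spec: ModelSpec, res, extras: dict | None = None) -> ModelFit:
    stat_name = "tvalues" if hasattr(res, "tvalues") else "zvalues"
    return ModelFit(
        name=name,
        family=spec.family,
        params=res.params,
        bse=res.bse,
        statistic=getattr(res, stat_name),
        pvalues=res.pvalues,
        nobs=int(res.nobs),
        llf=float(res.llf),
        converged=bool(getattr(res, "converged", True)),
        spec=spec,
        extras=extras or {},
    )


# --------------------------------------------------------------------------
# presence (two-stage RAC)
# --------------------------------------------------------------------------

def fit_presence_model(
    data: pd.DataFrame,
    spec: ModelSpec,
    index: SpatialIndex,
    buffer_km: float = 250.0,
    morans_permutations: int = 0,
    seed: int = 0,
) -> ModelFit:
    """Binomial-logit presence model with a residual-autocovariate stage.

    Stage 1 fits without any spatial term; its response residuals
    (observed minus fitted probability) are inverse-distance averaged over
    the ``buffer_km`` neighbourhood into the RAC covariate; stage 2 refits
    with RAC included.  ``extras`` carries both stages' residual Moran's I.
    """
    y = data[spec.response].astype(float)
    if y.nunique() < 2:
        raise ConvergenceError("presence response has no variation")
    X1 = design_matrix(data, spec)
    res1 = _fit_glm(y, X1, sm.families.Binomial())
    resid1 = y.to_numpy() - res1.fittedvalues.to_numpy()
    rac = residual_autocovariate(resid1, index, radius_km=buffer_km)
    X2 = design_matrix(data, spec, extra={"rac": rac})
    res2 = _fit_glm(y, X2, sm.families.Binomial())
    resid2 = y.to_numpy() - res2.fittedvalues.to_numpy()
    extras = {
        "morans_i_stage1": _safe_moran(resid1, index, buffer_km,
                                       morans_permutations, seed),
        "morans_i_stage2": _safe_moran(resid2, index, buffer_km,
                                       morans_permutations, seed),
        "stage1": _wrap("presence_stage1", spec, res1),
    }
    return _wrap("presence", spec, res2, extras)


def _fit_glm(y, X, family):
    try:
        res = sm.GLM(y, X, family=family).fit()
    except PerfectSeparationError as exc:
        raise ConvergenceError(f"complete separation: {exc}") from exc
    if not np.all(np.isfinite(res.params)):
        raise ConvergenceError("non-finite GLM estimates")
    return res


def _safe_moran(resid, index, radius, n_perm, seed):
    try:
        i_val, p = morans_i(resid, index, radius, n_permutations=n_perm, seed=seed)
    except UndefinedStatisticError:
        return {"i": np.nan, "p": np.nan}
    return {"i": i_val, "p": p}


# --------------------------------------------------------------------------
# severity
# --------------------------------------------------------------------------

def fit_severity_models(
    data: pd.DataFrame,
    richness_spec: ModelSpec,
    abundance_spec: ModelSpec,
    rac: np.ndarray | None = None,
) -> tuple[ModelFit, ModelFit]:
    """Severity on invaded plots: binomial counts + beta regression.

    The richness model regresses (non-native count, native-side count) as
    a two-column binomial; the abundance model fits the relative basal
    area by beta likelihood with exact-boundary proportions squeezed by
    ``(y * (n - 1) + 0.5) / n`` (applied to values of exactly 0 or 1).
    """
    extra = {"rac": rac} if rac is not None else None

    if richness_spec.trials is None:
        raise InvalidArgumentError("richness_spec.trials must name the total count")
    nn = data[richness_spec.response].astype(int).to_numpy()
    total = data[richness_spec.trials].astype(int).to_numpy()
    if np.any(total <= 0):
        raise InvalidArgumentError("zero-species denominator in severity data")
    Xr = design_matrix(data, richness_spec, extra=extra)
    endog = np.column_stack([nn, total - nn])
    res_r = _fit_glm(endog, Xr, sm.families.Binomial())
    fit_r = _wrap("severity_richness", richness_spec, res_r)

    y = data[abundance_spec.response].astype(float).to_numpy().copy()
    if np.any((y < 0) | (y > 1)):
        raise InvalidArgumentError("proportions outside [0, 1]")
    if np.ptp(y) == 0:
        raise ConvergenceError("degenerate abundance response (all equal)")
    n = y.size
    boundary = (y == 0) | (y == 1)
    y[boundary] = (y[boundary] * (n - 1) + 0.5) / n
    Xa = design_matrix(data, abundance_spec, extra=extra)
    res_a = BetaModel(y, Xa, link_precision=sm.families.links.Log()).fit(disp=False)
    if not res_a.mle_retvals.get("converged", True):
        raise ConvergenceError("beta regression did not converge")
    fit_a = _wrap("severity_abundance", abundance_spec, res_a)
    fit_a.extras["n_squeezed"] = int(boundary.sum())
    return fit_r, fit_a


# --------------------------------------------------------------------------
# strategy with interaction pruning
# --------------------------------------------------------------------------

def fit_strategy_model(
    data: pd.DataFrame,
    spec: ModelSpec,
    rac: np.ndarray | None = None,
    alpha: float = 0.05,
) -> ModelFit:
    """Gaussian strategy model with backward elimination of interactions.

    Starting from the full interaction set, the least significant
    interaction (largest p) is removed and the model refitted while any
    interaction has p >= ``alpha``.  Main effects (including the quadratic
    temperature term) are never removed.  ``extras['elimination']`` records
    the trail.
    """
    y = data[spec.response].astype(float)
    interactions = list(spec.interactions)
    trail = []
    extra = {"rac": rac} if rac is not None else None
    while True:
        current = ModelSpec(
            response=spec.response, family="gaussian",
            predictors=spec.predictors, interactions=interactions,
            quadratic=spec.quadratic, standardize=spec.standardize,
        )
        X = design_matrix(data, current, extra=extra)
        res = sm.OLS(y, X).fit()
        inter_terms = {f"{a}:{b}": (a, b) for a, b in interactions}
        if not inter_terms:
            break
        pvals = res.pvalues[list(inter_terms)]
        worst = pvals.idxmax()
        if pvals[worst] < alpha:
            break
        interactions = [ab for t, ab in inter_terms.items() if t != worst]
        trail.append({"removed": worst, "p": float(pvals[worst])})
    fit = _wrap("strategy", spec, res)
    fit.extras["elimination"] = trail
    fit.extras["final_interactions"] = [f"{a}:{b}" for a, b in interactions]
    return fit


# --------------------------------------------------------------------------
# random forest + sampled Shapley importance
# --------------------------------------------------------------------------

@dataclass
class ShapImportance:
    importance: pd.DataFrame       # variable, importance (sum |SHAP|), rank
    shap_values: pd.DataFrame      # per-observation SHAP value per variable
    marginal: pd.DataFrame         # long: variable, x, shap
    base_value: float
    additivity_gap: float          # mean |f(x) - base - sum(shap)| diagnostic


def rf_shap_importance(
    data: pd.DataFrame,
    response: str,
    predictors: Sequence[str],
    seed: int = 0,
    task: str = "auto",
    n_estimators: int = 500,
    n_simulations: int = 100,
    shap_rows: int | None = None,
) -> ShapImportance:
    """Random forest importance via sampled Shapley values.

    The forest uses the standard defaults (500 trees, bootstrap resampling,
    sqrt(p) variables per split, minimum 5 observations per node).  SHAP
    values are estimated by the permutation-sampling scheme: for each of
    ``n_simulations`` random feature orderings, features are switched one
    by one from a random reference observation to the explained
    observation and the telescoping prediction differences are averaged.
    Importance is the per-variable sum of absolute SHAP values.
    ``shap_rows`` subsamples observations to bound the explanation cost.
    """
    predictors = list(predictors)
    if len(predictors) < 2:
        raise InvalidArgumentError("need at least 2 predictors")
    X = data[predictors].astype(float).to_numpy()
    y = data[response].to_numpy()
    binary = task == "classification" or (
        task == "auto" and pd.Series(y).nunique() == 2
    )
    common = dict(
        n_estimators=n_estimators,
        max_features="sqrt",
        min_samples_leaf=5,
        bootstrap=True,
        random_state=child_seed(seed, "random-forest"),
        n_jobs=1,
    )
    if binary:
        model = RandomForestClassifier(**common).fit(X, y.astype(int))
        predict = lambda M: model.predict_proba(M)[:, 1]
    else:
        model = RandomForestRegressor(**common).fit(X, y.astype(float))
        predict = model.predict

    rng = stream(seed, "shap-sampling")
    if shap_rows is not None and shap_rows < X.shape[0]:
        rows = np.sort(rng.choice(X.shape[0], size=shap_rows, replace=False))
    else:
        rows = np.arange(X.shape[0])
    Xe = X[rows]
    phi, base = _permutation_shap(predict, Xe, X, rng, n_simulations)

    shap_df = pd.DataFrame(phi, columns=predictors, index=rows)
    imp = (
        shap_df.abs().sum(axis=0).sort_values(ascending=False).rename("importance")
        .rename_axis("variable").reset_index()
    )
    imp["rank"] = np.arange(1, len(imp) + 1)
    marginal = pd.concat(
        [
            pd.DataFrame({"variable": v, "x": Xe[:, j], "shap": phi[:, j]})
            for j, v in enumerate(predictors)
        ],
        ignore_index=True,
    )
    gap = float(np.mean(np.abs(predict(Xe) - base - phi.sum(axis=1))))
    return ShapImportance(
        importance=imp, shap_values=shap_df, marginal=marginal,
        base_value=float(base), additivity_gap=gap,
    )


def _permutation_shap(
    predict: Callable, Xe: np.ndarray, Xref: np.ndarray, rng, n_sim: int
):
    """Telescoping permutation estimate of Shapley values.

    For a random feature order and random reference rows, switching
    features one at a time from reference to explained values attributes
    each prediction difference to the switched feature; averaging over
    orders yields the Shapley value.  The estimate is additive by
    construction up to reference-sampling noise.
    """
    n, p = Xe.shape
    phi = np.zeros((n, p))
    base_acc = 0.0
    for _ in range(n_sim):
        order = rng.permutation(p)
        ref = Xref[rng.integers(0, Xref.shape[0], size=n)]
        z = ref.copy()
        prev = predict(z)
        base_acc += prev.mean()
        for j in order:
            z[:, j] = Xe[:, j]
            cur = predict(z)
            phi[:, j] += cur - prev
            prev = cur
    return phi / n_sim, base_acc / n_sim


# --------------------------------------------------------------------------
# pre-invasion sensitivity
# --------------------------------------------------------------------------

@dataclass
class SensitivityResult:
    c: float
    c_lo: float
    c_hi: float
    change_fit: ModelFit
    beta_original: float
    beta_updated: dict      # at c, c_lo, c_hi
    relative_change: dict   # |b_orig - b_upd| / |b_orig| at c, c_lo, c_hi
    updated_richness: pd.Series


def sensitivity_preinvasion(
    two_census: pd.DataFrame,
    severity_data: pd.DataFrame,
    richness_spec: ModelSpec,
    richness_col: str = "native_richness",
    change_covariates: Sequence[str] = (),
    multiplicative: bool = True,
) -> SensitivityResult:
    """Quantify how much apparent biotic resistance is invasion-caused loss.

    Fits a Gaussian model of the fractional richness change between two
    censuses (first census fully native) on final invasion status plus
    covariates; the invasion coefficient ``c`` estimates the fractional
    richness change caused by invasion.  Invaded plots' richness in the
    severity dataset is then restored to its pre-invasion value
    (``S_pre = S * (1 - c)`` by default; ``S / (1 + c)`` with
    ``multiplicative=False`` — the two differ at O(c^2)), the severity
    model is refitted, and the relative change in the richness coefficient
    is reported at ``c`` and at each confidence bound.
    """
    if not two_census["invaded"].astype(bool).any():
        raise InvalidArgumentError("no invaded plots in the two-census subset")
    X = pd.DataFrame({"invaded": two_census["invaded"].astype(float)})
    for col in change_covariates:
        v = two_census[col].astype(float)
        X[col] = (v - v.mean()) / v.std()
    X.insert(0, "const", 1.0)
    res = sm.OLS(two_census["pct_change"].astype(float), X).fit()
    c = float(res.params["invaded"])
    ci = res.conf_int().loc["invaded"]
    c_lo, c_hi = float(ci[0]), float(ci[1])
    change_fit = _wrap(
        "richness_change",
        ModelSpec(response="pct_change", family="gaussian",
                  predictors=["invaded", *change_covariates]),
        res,
    )

    def refit(c_val: float) -> tuple[float, pd.Series]:
        upd = severity_data.copy()
        invaded_mask = upd["presence"].astype(bool) if "presence" in upd else \
            pd.Series(True, index=upd.index)
        s = upd[richness_col].astype(float)
        s_pre = s * (1.0 - c_val) if multiplicative else s / (1.0 + c_val)
        upd[richness_col] = s.where(~invaded_mask, s_pre)
        fit, _ = _refit_richness(upd, richness_spec)
        return float(fit.params[richness_col]), upd[richness_col]

    orig_fit, _ = _refit_richness(severity_data, richness_spec)
    beta_orig = float(orig_fit.params[richness_col])
    beta_upd, rel = {}, {}
    updated_series = None
    for label, c_val in (("c", c), ("c_lo", c_lo), ("c_hi", c_hi)):
        b, series = refit(c_val)
        beta_upd[label] = b
        rel[label] = abs(beta_orig - b) / abs(beta_orig) if beta_orig != 0 else np.nan
        if label == "c":
            updated_series = series
    return SensitivityResult(
        c=c, c_lo=c_lo, c_hi=c_hi, change_fit=change_fit,
        beta_original=beta_orig, beta_updated=beta_upd,
        relative_change=rel, updated_richness=updated_series,
    )


def _refit_richness(data: pd.DataFrame, spec: ModelSpec,
                    raw_cols: tuple = ("native_richness",)):
    # the richness predictor stays on its raw scale: the pre-invasion update
    # is multiplicative, and z-scoring would absorb it entirely
    nn = data[spec.response].astype(int).to_numpy()
    total = data[spec.trials].astype(int).to_numpy()
    X = pd.DataFrame(index=data.index)
    for col in spec.predictors:
        v = data[col].astype(float)
        if col not in raw_cols and spec.standardize:
            v = (v - v.mean()) / v.std()
        X[col] = v
    X.insert(0, "const", 1.0)
    res = _fit_glm(np.column_stack([nn, total - nn]), X, sm.families.Binomial())
    return res, X


def relative_coefficient_change(beta_orig: float, beta_updated: float) -> float:
    """``|beta_orig - beta_updated| / |beta_orig|``."""
    if beta_orig == 0:
        raise UndefinedStatisticError("original coefficient is zero")
    return abs(beta_orig - beta_updated) / abs(beta_orig)


# --------------------------------------------------------------------------
# reporting
# --------------------------------------------------------------------------

def summarize_fits(fits: Sequence[ModelFit]) -> pd.DataFrame:
    """Stack fits into one long coefficient table with deterministic order."""
    if not fits:
        raise InvalidArgumentError("no fits to summarize")
    return pd.concat([f.table() for f in fits], ignore_index=True)
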