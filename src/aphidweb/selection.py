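"""Linear and linear mixed models with AICc-based multimodel inference.

Direct effects of landscape composition, community diversity and food-web
structure on the parasitism and hyperparasitism rates are assessed with
identity-link Gaussian models: ordinary least squares when no random
effect is declared, a random-intercept mixed model (grouping factor
"year" in the study design) otherwise.  Mixed models are fitted by full
maximum likelihood, not REML, because models with different fixed effects
are compared on their likelihoods.

Multimodel inference enumerates every predictor subset (including the
intercept-only model), ranks them by the small-sample corrected Akaike
criterion

    AICc = -2 logL + 2k + 2k(k+1)/(n - k - 1),

retains candidates with delta-AICc below a cutoff (default 4), converts
deltas to Akaike weights w_i = exp(-delta_i/2) normalised over the
candidate set, and reports conditional model-averaged coefficients
(averaged over the candidate models that contain each predictor, weights
renormalised within that subset) along with per-predictor importance
(summed weight of candidate models containing the predictor).

The parameter count k includes the intercept, every slope, the residual
variance, and for mixed models the random-intercept variance.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "ModelSpec",
    "FittedModel",
    "MultiModelResult",
    "fit_linear_model",
    "aicc",
    "multimodel_inference",
    "vif",
]


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: response, predictors, optional random intercept."""

    response: str
    predictors: tuple[str, ...]
    random_effect: str | None = None

    def __post_init__(self) -> None:
        if len(set(self.predictors)) != len(self.predictors):
            raise ValueError("duplicate predictors in model spec")


@dataclass
class FittedModel:
    """A fitted Gaussian model with the quantities model selection needs."""

    spec: ModelSpec
    coefficients: pd.Series
    std_errors: pd.Series
    p_values: pd.Series
    loglik: float
    k: int
    n: int
    aicc: float
    r_squared: float


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion.

    AICc = -2 logL + 2k + 2k(k+1)/(n-k-1); requires n > k + 1 and k >= 1.
    """
    if k < 1:
        raise ValueError("k must count at least one estimated parameter")
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k}: need n > k + 1")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _check_design(data: pd.DataFrame, predictors: tuple[str, ...]) -> None:
    if not predictors:
        return
    X = np.column_stack([np.ones(len(data))] + [data[p].to_numpy(float) for p in predictors])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns by incremental rank
        aliased = []
        cols = [np.ones(len(data))]
        for p in predictors:
            trial = np.column_stack(cols + [data[p].to_numpy(float)])
            if np.linalg.matrix_rank(trial) == len(cols):
                aliased.append(p)
            else:
                cols.append(data[p].to_numpy(float))
        raise ValueError(f"rank-deficient design; aliased predictor(s): {aliased}")


def fit_linear_model(spec: ModelSpec, data: pd.DataFrame) -> FittedModel:
    """Fit one identity-link Gaussian model by maximum likelihood.

    Ordinary least squares without a random effect; a random-intercept
    mixed model (ML, not REML) when ``spec.random_effect`` names a
    grouping column.  Complete cases only; requires ``n > k + 1``.
    """
    cols = [spec.response, *spec.predictors]
    if spec.random_effect:
        cols.append(spec.random_effect)
    data = data[cols].dropna()
    n = len(data)
    _check_design(data, spec.predictors)

    if spec.random_effect is None:
        X = sm.add_constant(
            data[list(spec.predictors)].astype(float), has_constant="add"
        ) if spec.predictors else pd.DataFrame({"const": np.ones(n)}, index=data.index)
        res = sm.OLS(data[spec.response].astype(float), X).fit()
        k = len(res.params) + 1  # + residual variance
        if n <= k + 1:
            raise ValueError(f"too few observations (n={n}) for k={k} parameters")
        coefs = res.params
        ses = res.bse
        pvals = res.pvalues
        loglik = float(res.llf)
        r2 = float(res.rsquared) if spec.predictors else 0.0
    else:
        rhs = " + ".join(spec.predictors) if spec.predictors else "1"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(
                f"{spec.response} ~ {rhs}", data, groups=data[spec.random_effect]
            )
            res = model.fit(reml=False)
        k = len(res.fe_params) + 2  # + random-intercept variance + residual variance
        if n <= k + 1:
            raise ValueError(f"too few observations (n={n}) for k={k} parameters")
        coefs = res.fe_params.rename({"Intercept": "const"})
        ses = res.bse_fe.rename({"Intercept": "const"})
        pvals = res.pvalues.rename({"Intercept": "const"})[coefs.index]
        loglik = float(res.llf)
        fitted_fixed = res.model.exog @ res.fe_params.to_numpy()
        y = data[spec.response].to_numpy(float)
        r2 = float(1 - np.sum((y - fitted_fixed) ** 2) / np.sum((y - y.mean()) ** 2)) \
            if spec.predictors else 0.0

    return FittedModel(
        spec=spec,
        coefficients=coefs,
        std_errors=ses,
        p_values=pvals,
        loglik=loglik,
        k=k,
        n=n,
        aicc=aicc(loglik, k, n),
        r_squared=r2,
    )


@dataclass
class MultiModelResult:
    """All-subsets AICc table with weights, averages and importance."""

    response: str
    candidates: pd.DataFrame  # predictors, k, loglik, AICc, delta, weight
    best: FittedModel
    averaged_coefficients: pd.Series
    averaged_std_errors: pd.Series
    importance: pd.Series
    all_models: list[FittedModel] = field(default_factory=list, repr=False)

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "candidates": [
                {
                    "predictors": row["predictors"],
                    "k": int(row["k"]),
                    "loglik": float(row["loglik"]),
                    "aicc": float(row["aicc"]),
                    "delta": float(row["delta"]),
                    "weight": float(row["weight"]),
                }
                for _, row in self.candidates.iterrows()
            ],
            "best_predictors": list(self.best.spec.predictors),
            "averaged_coefficients": {
                k: float(v) for k, v in self.averaged_coefficients.items()
            },
            "importance": {k: float(v) for k, v in self.importance.items()},
        }


def multimodel_inference(
    response: str,
    predictor_pool: list[str],
    data: pd.DataFrame,
    random_effect: str | None = None,
    delta_max: float = 4.0,
) -> MultiModelResult:
    """All-subsets AICc model selection with conditional averaging.

    Fits every subset of ``predictor_pool`` (intercept-only included),
    forms the candidate set of models with delta-AICc below ``delta_max``,
    and reports Akaike weights, the best model, conditional
    model-averaged coefficients and per-predictor importance.  Ties in
    AICc are broken by fewer parameters, then lexicographic predictor
    names, so the ranking is deterministic.
    """
    if len(predictor_pool) > 12:
        raise ValueError("predictor pool too large for all-subsets enumeration")
    fits: list[FittedModel] = []
    for r in range(len(predictor_pool) + 1):
        for combo in itertools.combinations(sorted(predictor_pool), r):
            spec = ModelSpec(response=response, predictors=combo, random_effect=random_effect)
            fits.append(fit_linear_model(spec, data))
    if not fits:
        raise RuntimeError("no model could be fitted")

    fits.sort(key=lambda f: (f.aicc, f.k, f.spec.predictors))
    best = fits[0]
    deltas = np.array([f.aicc - best.aicc for f in fits])
    cand_idx = np.nonzero(deltas < delta_max)[0]
    w_raw = np.exp(-deltas[cand_idx] / 2.0)
    weights = w_raw / w_raw.sum()

    rows = []
    for j, i in enumerate(cand_idx):
        f = fits[i]
        rows.append(
            {
                "predictors": list(f.spec.predictors),
                "k": f.k,
                "loglik": f.loglik,
                "aicc": f.aicc,
                "delta": deltas[i],
                "weight": weights[j],
            }
        )
    table = pd.DataFrame(rows)

    avg_coef: dict[str, float] = {}
    avg_se: dict[str, float] = {}
    importance: dict[str, float] = {}
    for pred in sorted(predictor_pool):
        mask = np.array([pred in fits[i].spec.predictors for i in cand_idx])
        importance[pred] = float(weights[mask].sum())
        if mask.any():
            w_sub = weights[mask] / weights[mask].sum()
            betas = np.array(
                [fits[i].coefficients[pred] for i in cand_idx[mask]]
            )
            ses = np.array([fits[i].std_errors[pred] for i in cand_idx[mask]])
            avg_coef[pred] = float(w_sub @ betas)
            # model-averaged unconditional SE (Burnham-Anderson form)
            avg_se[pred] = float(
                w_sub @ np.sqrt(ses**2 + (betas - avg_coef[pred]) ** 2)
            )
        else:
            avg_coef[pred] = float("nan")
            avg_se[pred] = float("nan")

    return MultiModelResult(
        response=response,
        candidates=table,
        best=best,
        averaged_coefficients=pd.Series(avg_coef),
        averaged_std_errors=pd.Series(avg_se),
        importance=pd.Series(importance),
        all_models=fits,
    )


def vif(design: pd.DataFrame, flag_at: float = 2.0) -> pd.Series:
    """Variance inflation factors of a predictor table.

    VIF_j = 1/(1 - R^2_j) from regressing predictor j on all the others
    (with intercept).  Perfectly collinear predictors get ``inf``.  A
    warning is emitted for predictors at or above ``flag_at`` (the
    screening threshold used for these data), but nothing is excluded.
    """
    cols = list(design.columns)
    if len(cols) < 2:
        raise ValueError("VIF needs at least 2 predictors")
    if len(design) <= len(cols) + 1:
        raise ValueError("too few rows for VIF computation")
    out = {}
    for j, col in enumerate(cols):
        others = [c for c in cols if c != col]
        X = sm.add_constant(design[others].astype(float), has_constant="add")
        r2 = sm.OLS(design[col].astype(float), X).fit().rsquared
        out[col] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    s = pd.Series(out)
    high = s[s >= flag_at]
    if len(high):
        warnings.warn(
            f"predictors with VIF >= {flag_at}: {', '.join(high.index)}", stacklevel=2
        )
    return s
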