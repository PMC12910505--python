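"""Least-squares fitting of the five cascade functions, plus fit metrics.

Each of the five model functions (pollen beta curve, viability surface,
germination surface, seed link, mass link) is fitted independently and
sequentially to an observation table, mirroring how the calibration was
built: observations are averaged to treatment means, then each function's
free parameters minimise the squared error of that function alone.

Free parameters per function:

* pollen beta curve — the magnitude ``mu`` only; the shape exponents are
  re-derived from the peak constraint at every evaluation, and the peak
  value ``N_star`` is taken from the control-treatment mean unless given.
* fraction surfaces — the duration-interpolation pair (theta1, theta2);
  ``alpha_max`` is held at the measured control fraction.
* linear links — ordinary least squares slope and intercept.

Nonlinear fits use ``scipy.optimize.least_squares`` from five deterministic
starting points spread over plausible ranges, keeping the best optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import model
from .observations import ObservationError, validate_observations
from .params import (
    ConversionParams,
    FractionSurfaceParams,
    LinearLinkParams,
    ModelParams,
    PollenBetaParams,
)

__all__ = [
    "FitResult",
    "EstimationError",
    "fit_pollen_beta",
    "fit_fraction_surface",
    "fit_linear_link",
    "fit_all",
    "rmse",
    "aggregate_rmse",
    "r_squared",
]


class EstimationError(ValueError):
    """Raised when a fit is infeasible (degenerate design, unidentifiable)."""


@dataclass
class FitResult:
    """Outcome of one per-function least-squares fit.

    ``params`` maps parameter names to estimates; ``rmse`` is in the fitted
    function's own units; ``residuals`` has one row per usable observation
    (treatment mean) with observed, predicted and residual columns.
    """

    params: dict[str, float]
    rmse: float
    r2: float
    residuals: pd.DataFrame
    n_obs: int
    success: bool = True
    n_iter: int = 0
    objective: float = np.nan
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# metrics


def rmse(observed, predicted) -> float:
    """Root-mean-square error, in the units of the observations."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise EstimationError(
            f"length mismatch: {obs.shape} observed vs {pred.shape} predicted"
        )
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def aggregate_rmse(per_function: dict[str, float] | list[float]) -> float:
    """Unweighted mean of the per-function RMSEs.

    The five cascade functions are measured in different units (grains,
    fractions, seeds, grams), so the aggregate is a unit-incoherent summary
    score; always report the per-function values alongside.  A warning
    reminds callers of this.
    """
    values = list(per_function.values()) if isinstance(per_function, dict) else list(per_function)
    warnings.warn(
        "aggregate RMSE averages functions with different units; "
        "report per-function RMSEs alongside",
        stacklevel=2,
    )
    return float(np.mean(values))


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot about the observed mean.

    May be negative for predictions worse than the mean.  Raises for fewer
    than two observations or zero total variance.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise EstimationError("length mismatch between observed and predicted")
    if obs.size < 2:
        raise EstimationError("r_squared requires at least 2 observations")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise EstimationError("r_squared undefined: observations have zero variance")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


# ---------------------------------------------------------------------------
# helpers


def _stage_means(obs: pd.DataFrame, stage: str, by=("temperature_C", "duration_d")):
    sub = obs[obs["stage"] == stage]
    if sub.empty:
        raise EstimationError(f"no observations for stage {stage!r}")
    return sub.groupby(list(by), as_index=False)["value"].mean()


def _multistart_least_squares(residual_fn, starts, bounds):
    """Run least_squares from several starts; return the best result."""
    best = None
    for x0 in starts:
        try:
            res = optimize.least_squares(residual_fn, x0=x0, bounds=bounds)
        except ValueError:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise EstimationError("all optimizer starts failed")
    return best


# ---------------------------------------------------------------------------
# per-function fits


def fit_pollen_beta(
    obs: pd.DataFrame,
    fixed: PollenBetaParams | None = None,
    n_star: float | None = None,
    conversion: ConversionParams | None = None,
    pool_means: bool = True,
) -> FitResult:
    """Estimate the magnitude parameter ``mu`` of the pollen beta curve.

    ``fixed`` supplies the temperatures (T_b, T_c, T_opt, T_0); its ``mu``
    and ``N_star`` are ignored.  ``N_star`` is taken as the observed mean
    pollen number at T_opt unless ``n_star`` overrides it.  Raw haemocytometer
    counts (stage ``pollen_count``) are converted to pollen per flower before
    pooling.  Pollen number depends on temperature only, so observations are
    pooled to temperature means (durations averaged out), as in the original
    calibration.
    """
    validate_observations(obs)
    base = fixed if fixed is not None else PollenBetaParams()
    conv = conversion if conversion is not None else ConversionParams()

    sub = obs[obs["stage"] == "pollen_count"].copy()
    if sub.empty:
        raise EstimationError("no pollen_count observations")
    sub["n_pollen"] = model.pollen_count_to_number(sub["value"].to_numpy(), conv)
    if pool_means:
        pooled = sub.groupby("temperature_C", as_index=False)["n_pollen"].mean()
    else:
        pooled = sub[["temperature_C", "n_pollen"]]
    temps = pooled["temperature_C"].to_numpy(dtype=float)
    y = pooled["n_pollen"].to_numpy(dtype=float)
    if len(np.unique(temps)) < 3:
        raise EstimationError(
            "pollen beta fit needs observations at >= 3 distinct temperatures"
        )

    if n_star is None:
        at_opt = pooled[np.isclose(temps, base.T_opt)]
        if at_opt.empty:
            raise EstimationError(
                "N_star unset and no observations at T_opt; supply n_star"
            )
        n_star = float(at_opt["n_pollen"].iloc[0])

    def make_params(mu: float) -> PollenBetaParams:
        return PollenBetaParams(
            mu=mu, T_b=base.T_b, T_c=base.T_c, T_opt=base.T_opt,
            T_0=base.T_0, N_star=n_star,
        )

    def residual(x):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", model.ExtrapolationWarning)
            return model.pollen_number(temps, make_params(x[0])) - y

    starts = [[m] for m in (1.0, 4.0, 7.0, 10.0, 13.0)]
    best = _multistart_least_squares(residual, starts, bounds=([-5.0], [20.0]))
    mu_hat = float(best.x[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", model.ExtrapolationWarning)
        pred = model.pollen_number(temps, make_params(mu_hat))
    residuals = pd.DataFrame(
        {"temperature_C": temps, "observed": y, "predicted": pred,
         "residual": y - pred}
    )
    return FitResult(
        params={"mu": mu_hat, "N_star": n_star},
        rmse=rmse(y, pred),
        r2=r_squared(y, pred) if len(y) > 1 and np.var(y) > 0 else np.nan,
        residuals=residuals,
        n_obs=len(y),
        success=bool(best.success),
        n_iter=int(best.nfev),
        objective=float(best.cost),
    )


def fit_fraction_surface(
    obs: pd.DataFrame,
    stage: str,
    alpha_max: float | None = None,
    T_opt: float = 18.0,
    pool_means: bool = True,
) -> FitResult:
    """Estimate (theta1, theta2) of one fraction surface.

    ``stage`` selects ``"viability"`` or ``"germination"`` rows.  The vertex
    fraction ``alpha_max`` is held fixed at the control-treatment (T = T_opt)
    mean unless supplied.  Residuals are taken against the clamped surface,
    exactly as the model is defined; regimes where the surface clamps to 0
    contribute flat residuals rather than being excluded.
    """
    if stage not in ("viability", "germination"):
        raise EstimationError(f"stage must be viability or germination, got {stage!r}")
    validate_observations(obs)
    pooled = _stage_means(obs, stage) if pool_means else (
        obs[obs["stage"] == stage][["temperature_C", "duration_d", "value"]]
    )
    temps = pooled["temperature_C"].to_numpy(dtype=float)
    durs = pooled["duration_d"].to_numpy(dtype=float)
    y = pooled["value"].to_numpy(dtype=float)

    off_opt = ~np.isclose(temps, T_opt)
    if not off_opt.any():
        raise EstimationError(
            "surface unidentifiable: all observations at T_opt (vertex only)"
        )
    if len(np.unique(durs[off_opt])) < 2:
        raise EstimationError(
            "surface fit needs >= 2 distinct durations away from T_opt"
        )

    if alpha_max is None:
        at_opt = y[np.isclose(temps, T_opt)]
        if at_opt.size == 0:
            raise EstimationError(
                "alpha_max unset and no control (T_opt) observations; supply it"
            )
        alpha_max = float(np.mean(at_opt))

    def residual(x):
        p = FractionSurfaceParams(
            alpha_max=alpha_max, theta1=x[0], theta2=x[1], T_opt=T_opt
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", model.ExtrapolationWarning)
            return model.fraction_surface(temps, durs, p) - y

    starts = [(0.9, -0.2), (0.5, -0.1), (0.2, -0.02), (0.8, -0.5), (0.1, -0.005)]
    best = _multistart_least_squares(
        residual, starts, bounds=([-5.0, -5.0], [5.0, 5.0])
    )
    t1, t2 = (float(v) for v in best.x)
    fitted = FractionSurfaceParams(alpha_max=alpha_max, theta1=t1, theta2=t2, T_opt=T_opt)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", model.ExtrapolationWarning)
        pred = model.fraction_surface(temps, durs, fitted)
    residuals = pd.DataFrame(
        {"temperature_C": temps, "duration_d": durs, "observed": y,
         "predicted": pred, "residual": y - pred}
    )
    return FitResult(
        params={"alpha_max": alpha_max, "theta1": t1, "theta2": t2},
        rmse=rmse(y, pred),
        r2=r_squared(y, pred) if np.var(y) > 0 else np.nan,
        residuals=residuals,
        n_obs=len(y),
        success=bool(best.success),
        n_iter=int(best.nfev),
        objective=float(best.cost),
    )


def fit_linear_link(x, y) -> FitResult:
    """Ordinary least-squares slope/intercept between two cascade stages.

    Convention for degenerate response: if y has zero variance the fit is a
    flat line through the mean with R2 reported as 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise EstimationError("x and y must have equal length")
    if x.size < 3:
        raise EstimationError("linear link fit needs >= 3 points")
    if np.var(x) == 0:
        raise EstimationError("linear link fit needs non-zero predictor variance")

    if np.var(y) == 0:
        slope, intercept, r2 = 0.0, float(y.mean()), 0.0
        pred = np.full_like(y, y.mean())
    else:
        res = stats.linregress(x, y)
        slope, intercept = float(res.slope), float(res.intercept)
        pred = slope * x + intercept
        r2 = float(res.rvalue**2)

    residuals = pd.DataFrame(
        {"x": x, "observed": y, "predicted": pred, "residual": y - pred}
    )
    return FitResult(
        params={"slope": slope, "intercept": intercept},
        rmse=rmse(y, pred),
        r2=r2,
        residuals=residuals,
        n_obs=len(y),
    )


# ---------------------------------------------------------------------------
# full pipeline


def fit_all(
    obs: pd.DataFrame,
    fixed: PollenBetaParams | None = None,
    conversion: ConversionParams | None = None,
) -> tuple[ModelParams, dict[str, FitResult]]:
    """Fit all five functions sequentially and assemble a ModelParams.

    The two linear links are fitted on treatment means, pairing the mean
    germinated-pollen number reconstructed from the pollen assays (mean
    pollen number x mean viability x mean germination per treatment) with
    the mean seed count, and the mean seed count with the mean fruit mass —
    the pollen and fruit measurements come from different plants, so pairing
    happens at treatment level.
    """
    validate_observations(obs)
    base = fixed if fixed is not None else PollenBetaParams()
    conv = conversion if conversion is not None else ConversionParams()

    results: dict[str, FitResult] = {}
    results["pollen_beta"] = fit_pollen_beta(obs, fixed=base, conversion=conv)
    results["viability"] = fit_fraction_surface(obs, "viability", T_opt=base.T_opt)
    results["germination"] = fit_fraction_surface(obs, "germination", T_opt=base.T_opt)

    # treatment-mean cascade reconstruction for the links
    pc = obs[obs["stage"] == "pollen_count"].copy()
    pc["value"] = model.pollen_count_to_number(pc["value"].to_numpy(), conv)
    pc["stage"] = "pollen_number"
    keys = ["temperature_C", "duration_d"]
    n_pol = pc.groupby(keys)["value"].mean()
    f_v = obs[obs["stage"] == "viability"].groupby(keys)["value"].mean()
    f_g = obs[obs["stage"] == "germination"].groupby(keys)["value"].mean()
    seeds = obs[obs["stage"] == "seed"].groupby(keys)["value"].mean()
    mass = obs[obs["stage"] == "fruit_mass"].groupby(keys)["value"].mean()

    n_germ = (n_pol * f_v * f_g).rename("n_germ")
    seed_pairs = pd.concat([n_germ, seeds.rename("seeds")], axis=1).dropna()
    results["seed_link"] = fit_linear_link(
        seed_pairs["n_germ"].to_numpy(), seed_pairs["seeds"].to_numpy()
    )
    mass_pairs = pd.concat([seeds.rename("seeds"), mass.rename("mass")], axis=1).dropna()
    results["mass_link"] = fit_linear_link(
        mass_pairs["seeds"].to_numpy(), mass_pairs["mass"].to_numpy()
    )

    fitted = ModelParams(
        pollen_beta=PollenBetaParams(
            mu=results["pollen_beta"].params["mu"],
            T_b=base.T_b, T_c=base.T_c, T_opt=base.T_opt, T_0=base.T_0,
            N_star=results["pollen_beta"].params["N_star"],
        ),
        viability=FractionSurfaceParams(
            alpha_max=results["viability"].params["alpha_max"],
            theta1=results["viability"].params["theta1"],
            theta2=results["viability"].params["theta2"],
            T_opt=base.T_opt,
        ),
        germination=FractionSurfaceParams(
            alpha_max=results["germination"].params["alpha_max"],
            theta1=results["germination"].params["theta1"],
            theta2=results["germination"].params["theta2"],
            T_opt=base.T_opt,
        ),
        seed_link=LinearLinkParams(
            slope=results["seed_link"].params["slope"],
            intercept=results["seed_link"].params["intercept"],
        ),
        mass_link=LinearLinkParams(
            slope=results["mass_link"].params["slope"],
            intercept=results["mass_link"].params["intercept"],
        ),
        conversion=conv,
    )
    return fitted, results
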