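"""Deterministic evaluation of the five-stage reproduction cascade.

Temperature ``T`` (deg C) and stress duration ``D`` (days) enter; pollen
number per flower, the viable and germinated pollen fractions and counts,
seeds per fruit, and grams per fruit come out.  All functions accept scalars
or numpy arrays and broadcast.

Stage by stage:

1. ``pollen_number``     — skewed beta curve in T, zero outside (T_b, T_c).
2. ``fraction_surface``  — quadratic T x D surface, used twice (viability,
   germination); clamped to [0, 1].
3. ``viable_pollen``     — fraction x pollen number.
4. ``germinated_pollen`` — germination fraction x viable pollen.
5. ``seed_number`` / ``fruit_mass`` — two linear links.

``predict_fruit_mass`` composes the chain; ``predict_table`` evaluates every
intermediate for a list of regimes and returns a tidy DataFrame.
"""

from __future__ import annotations

import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .params import (
    ConversionParams,
    FractionSurfaceParams,
    FruitSetQuadParams,
    LinearLinkParams,
    ModelParams,
    ParameterError,
    PollenBetaParams,
    TemperatureRegime,
)

__all__ = [
    "ExtrapolationWarning",
    "derive_beta_shape",
    "pollen_number",
    "duration_interpolation",
    "fraction_surface",
    "viable_pollen",
    "germinated_pollen",
    "seed_number",
    "fruit_mass",
    "predict_fruit_mass",
    "truss_yield",
    "pollen_count_to_number",
    "predict_table",
]

# Calibrated range of the underlying experiment; outside it the model
# extrapolates and a warning is emitted.
CALIBRATED_T_RANGE = (14.0, 34.0)
CALIBRATED_D_RANGE = (0.0, 8.0)


class ExtrapolationWarning(UserWarning):
    """Regime lies outside the calibrated temperature/duration range."""


def _check_range(T, D=None) -> None:
    T = np.asarray(T, dtype=float)
    out = (T < CALIBRATED_T_RANGE[0]) | (T > CALIBRATED_T_RANGE[1])
    if D is not None:
        D = np.asarray(D, dtype=float)
        out = out | (D < CALIBRATED_D_RANGE[0]) | (D > CALIBRATED_D_RANGE[1])
    if np.any(out):
        warnings.warn(
            "regime outside the calibrated range "
            f"T in {CALIBRATED_T_RANGE} deg C, D in {CALIBRATED_D_RANGE} d; "
            "predictions are extrapolations",
            ExtrapolationWarning,
            stacklevel=3,
        )


def derive_beta_shape(params: PollenBetaParams) -> tuple[float, float]:
    """Shape exponents (alpha, beta) pinning the beta curve's peak.

    The constraint that the curve peaks at ``T_opt`` with value ``N_star``
    determines both exponents from the magnitude parameter ``mu``::

        beta  = (ln N_star - mu) / (delta3 * ln delta1 + ln delta2)
        alpha = beta * delta3

    with ``delta1 = (T_opt - T_b)/T_0``, ``delta2 = (T_c - T_opt)/T_0`` and
    ``delta3 = delta1/delta2``.

    Raises
    ------
    ParameterError
        If the denominator ``delta3*ln(delta1) + ln(delta2)`` vanishes, in
        which case no finite exponent satisfies the peak constraint.
    """
    d1, d2, d3 = params.delta1, params.delta2, params.delta3
    denom = d3 * math.log(d1) + math.log(d2)
    if denom == 0.0:
        raise ParameterError(
            "degenerate beta parameterization: delta3*ln(delta1) + ln(delta2) = 0"
        )
    beta = (math.log(params.N_star) - params.mu) / denom
    alpha = beta * d3
    return alpha, beta


def pollen_number(temperature, params: PollenBetaParams):
    """Pollen grains per flower as a function of temperature only.

    ``exp(mu) * ((T - T_b)/T_0)^alpha * ((T_c - T)/T_0)^beta`` inside the
    open interval (T_b, T_c); defined as 0 at and outside the boundaries,
    which also avoids fractional powers of negative bases.  Duration of the
    stress does not affect pollen number.
    """
    alpha, beta = derive_beta_shape(params)
    _check_range(temperature)
    T = np.asarray(temperature, dtype=float)
    inside = (T > params.T_b) & (T < params.T_c)
    x = np.where(inside, (T - params.T_b) / params.T_0, 1.0)
    y = np.where(inside, (params.T_c - T) / params.T_0, 1.0)
    n = np.where(inside, math.exp(params.mu) * x**alpha * y**beta, 0.0)
    return float(n) if np.ndim(temperature) == 0 else n


def duration_interpolation(duration, theta1: float, theta2: float):
    """Latent duration level ``p(D) = theta1 + theta2 * D**2``.

    May be negative (the published fits reach -0.98 at D = 4); clamping to a
    valid fraction happens downstream in :func:`fraction_surface`.
    """
    D = np.asarray(duration, dtype=float)
    p = theta1 + theta2 * D**2
    return float(p) if np.ndim(duration) == 0 else p


def fraction_surface(temperature, duration, params: FractionSurfaceParams):
    """Pollen fraction (viability or germination) on the T x D surface.

    ``f(T, D) = clamp01[ p(D) + 2*(a - p(D))*(T/T_opt) - (a - p(D))*(T/T_opt)^2 ]``

    where ``a = alpha_max``.  The quadratic in ``T/T_opt`` has its vertex at
    T = T_opt with value ``alpha_max`` for every duration, so the control
    fraction is recovered at the optimum regardless of D.  The lower clamp
    at 0 is part of the model; the upper clamp at 1 guards user-supplied
    parameter sets with ``alpha_max`` near 1 (a fraction above 1 would break
    the cascade ordering).
    """
    _check_range(temperature, duration)
    T = np.asarray(temperature, dtype=float)
    p = duration_interpolation(duration, params.theta1, params.theta2)
    u = T / params.T_opt
    f = p + 2.0 * (params.alpha_max - p) * u - (params.alpha_max - p) * u**2
    f = np.clip(f, 0.0, 1.0)
    scalar = np.ndim(temperature) == 0 and np.ndim(duration) == 0
    return float(f) if scalar else f


def viable_pollen(
    temperature,
    duration,
    beta_params: PollenBetaParams,
    viability_params: FractionSurfaceParams,
):
    """Viable pollen grains per flower: viability fraction x pollen number."""
    return fraction_surface(temperature, duration, viability_params) * pollen_number(
        temperature, beta_params
    )


def germinated_pollen(
    temperature,
    duration,
    beta_params: PollenBetaParams,
    viability_params: FractionSurfaceParams,
    germination_params: FractionSurfaceParams,
):
    """Germinated pollen grains per flower: germination fraction x viable pollen.

    By construction 0 <= N_germ <= N_viable <= N_pollen.
    """
    return fraction_surface(temperature, duration, germination_params) * viable_pollen(
        temperature, duration, beta_params, viability_params
    )


def seed_number(
    n_germinated,
    link: LinearLinkParams,
    conversion: ConversionParams | None = None,
):
    """Seeds per fruit from germinated pollen per flower.

    ``m1 * N_germ * c_flower_to_fruit + b1`` — the slope is seeds per
    germinated grain, the flower-to-fruit factor converts per-flower pollen
    into per-fruit pollen (1 by default: each flower is assumed to develop
    into one fruit), and the intercept is the baseline seed number.
    """
    c = 1.0 if conversion is None else conversion.c_flower_to_fruit
    n = np.asarray(n_germinated, dtype=float)
    s = link.slope * n * c + link.intercept
    return float(s) if np.ndim(n_germinated) == 0 else s


def fruit_mass(n_seeds, link: LinearLinkParams):
    """Grams per fruit from seeds per fruit: ``m2 * N_seeds + b2``.

    The intercept b2 is the baseline (parthenocarpic) fruit mass when no
    seeds develop.
    """
    n = np.asarray(n_seeds, dtype=float)
    m = link.slope * n + link.intercept
    return float(m) if np.ndim(n_seeds) == 0 else m


def predict_fruit_mass(temperature, duration, params: ModelParams):
    """Individual fruit mass (g) for a regime: the full cascade composed.

    Definitionally identical, value for value, to chaining
    ``pollen_number -> fraction_surface (x2) -> seed_number -> fruit_mass``.
    """
    n_germ = germinated_pollen(
        temperature, duration, params.pollen_beta, params.viability, params.germination
    )
    n_seeds = seed_number(n_germ, params.seed_link, params.conversion)
    return fruit_mass(n_seeds, params.mass_link)


def truss_yield(
    temperature,
    duration,
    params: ModelParams,
    n_flowers: float = 9.0,
    fruit_set: FruitSetQuadParams | None = None,
):
    """Yield per truss (g): flowers x fruit-set fraction x fruit mass.

    The fruit-set quadratic must be supplied (either here or in
    ``params.fruit_set``); no default coefficients exist.

    Raises
    ------
    ParameterError
        If no fruit-set coefficients are available, or n_flowers < 0.
    """
    if n_flowers < 0:
        raise ParameterError(f"n_flowers must be >= 0, got {n_flowers}")
    fs = fruit_set if fruit_set is not None else params.fruit_set
    if fs is None:
        raise ParameterError(
            "fruit-set coefficients required: supply FruitSetQuadParams "
            "(no defaults are shipped)"
        )
    return n_flowers * fs.fraction(temperature) * predict_fruit_mass(
        temperature, duration, params
    )


def pollen_count_to_number(count, conversion: ConversionParams | None = None):
    """Convert haemocytometer grain counts to pollen per flower.

    ``N = count / vol_chamber * vol_sample`` with the chamber volume in mm3
    and the suspension volume in ul (1 ul = 1 mm3, so the units cancel).
    With the default 0.2 mm3 chamber and 200 ul sample, one counted grain
    corresponds to 1000 grains per flower.
    """
    conv = conversion if conversion is not None else ConversionParams()
    n = np.asarray(count, dtype=float)
    if np.any(n < 0):
        raise ParameterError("pollen counts must be >= 0")
    out = n / conv.vol_chamber_mm3 * conv.vol_sample_ul
    return float(out) if np.ndim(count) == 0 else out


def predict_table(
    regimes: Sequence[TemperatureRegime] | Sequence[tuple],
    params: ModelParams | None = None,
) -> pd.DataFrame:
    """Evaluate every cascade stage for each regime.

    Returns a tidy DataFrame with one row per regime and columns
    temperature_C, duration_d, n_pollen, f_viable, n_viable, f_germ,
    n_germ, n_seeds, fruit_mass_g.
    """
    if params is None:
        params = ModelParams.default()
    regs = [
        r if isinstance(r, TemperatureRegime) else TemperatureRegime(*r)
        for r in regimes
    ]
    T = np.array([r.temperature for r in regs])
    D = np.array([r.duration for r in regs])
    n_pollen = pollen_number(T, params.pollen_beta)
    f_v = fraction_surface(T, D, params.viability)
    n_v = f_v * n_pollen
    f_g = fraction_surface(T, D, params.germination)
    n_g = f_g * n_v
    n_s = seed_number(n_g, params.seed_link, params.conversion)
    m = fruit_mass(n_s, params.mass_link)
    return pd.DataFrame(
        {
            "temperature_C": T,
            "duration_d": D,
            "n_pollen": np.atleast_1d(n_pollen),
            "f_viable": np.atleast_1d(f_v),
            "n_viable": np.atleast_1d(n_v),
            "f_germ": np.atleast_1d(f_g),
            "n_germ": np.atleast_1d(n_g),
            "n_seeds": np.atleast_1d(n_s),
            "fruit_mass_g": np.atleast_1d(m),
        }
    )
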