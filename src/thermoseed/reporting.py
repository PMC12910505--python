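"""Summary artifacts: response-surface grids, measured-vs-predicted tables,
and the yield decomposition.

All outputs are tidy DataFrames (long-format CSVs when written to disk);
plotting is an optional extra, the numbers are the canonical artifact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import model
from .estimation import r_squared, rmse
from .params import FruitSetQuadParams, ModelParams, ParameterError

__all__ = [
    "SurfaceGrid",
    "surface_grid",
    "yield_decomposition",
    "measured_vs_predicted",
]

_GRID_FUNCTIONS = ("pollen", "viability", "germination", "seeds", "fruit_mass")


@dataclass(frozen=True)
class SurfaceGrid:
    """A dense evaluation of one cascade quantity over a T x D grid."""

    function: str
    temperatures: np.ndarray
    durations: np.ndarray
    values: np.ndarray  # shape (len(temperatures), len(durations))

    def to_long_frame(self) -> pd.DataFrame:
        """Long format: one row per (temperature, duration) cell."""
        tt, dd = np.meshgrid(self.temperatures, self.durations, indexing="ij")
        return pd.DataFrame(
            {
                "temperature_C": tt.ravel(),
                "duration_d": dd.ravel(),
                "value": self.values.ravel(),
                "quantity": self.function,
            }
        )


def surface_grid(
    function: str,
    params: ModelParams,
    temperatures,
    durations,
) -> SurfaceGrid:
    """Evaluate one cascade quantity on a temperature x duration grid.

    ``function`` is one of pollen, viability, germination, seeds,
    fruit_mass.  Every cell is a direct cascade call — nothing is cached or
    interpolated, so grid values are pointwise identical to the model.
    """
    if function not in _GRID_FUNCTIONS:
        raise ParameterError(
            f"unknown grid function {function!r}; choose from {_GRID_FUNCTIONS}"
        )
    T = np.asarray(temperatures, dtype=float)
    D = np.asarray(durations, dtype=float)
    if T.size == 0 or D.size == 0:
        raise ParameterError("temperature and duration ranges must be non-empty")

    tt, dd = np.meshgrid(T, D, indexing="ij")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", model.ExtrapolationWarning)
        if function == "pollen":
            vals = np.broadcast_to(
                model.pollen_number(tt, params.pollen_beta), tt.shape
            ).copy()
        elif function == "viability":
            vals = model.fraction_surface(tt, dd, params.viability)
        elif function == "germination":
            vals = model.fraction_surface(tt, dd, params.germination)
        elif function == "seeds":
            n_germ = model.germinated_pollen(
                tt, dd, params.pollen_beta, params.viability, params.germination
            )
            vals = model.seed_number(n_germ, params.seed_link, params.conversion)
        else:
            vals = model.predict_fruit_mass(tt, dd, params)
    return SurfaceGrid(function, T, D, np.asarray(vals, dtype=float))


def yield_decomposition(
    regimes,
    params: ModelParams,
    fruit_set: FruitSetQuadParams | None = None,
    n_flowers: float = 9.0,
) -> pd.DataFrame:
    """Per-regime decomposition of truss yield into its factors.

    One row per regime with fruit mass (g), fruit-set fraction, flower
    count, and their product, the truss yield (g).  Separates the two routes
    by which non-optimal temperature cuts yield: fewer fruits (fruit set)
    versus smaller fruits (seed-driven fruit mass).

    Requires fruit-set coefficients (no defaults are shipped).
    """
    fs = fruit_set if fruit_set is not None else params.fruit_set
    if fs is None:
        raise ParameterError(
            "fruit-set coefficients required for yield decomposition"
        )
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", model.ExtrapolationWarning)
        for reg in regimes:
            T, D = (reg.temperature, reg.duration) if hasattr(reg, "temperature") else reg
            mass = model.predict_fruit_mass(T, D, params)
            set_frac = fs.fraction(T)
            rows.append(
                {
                    "temperature_C": T,
                    "duration_d": D,
                    "fruit_mass_g": mass,
                    "fruit_set_fraction": set_frac,
                    "n_flowers": n_flowers,
                    "truss_yield_g": n_flowers * set_frac * mass,
                }
            )
    return pd.DataFrame(rows)


def measured_vs_predicted(obs: pd.DataFrame, params: ModelParams) -> dict:
    """Compare treatment means of an observation table with cascade predictions.

    For each of the five cascade functions, observations are averaged per
    treatment and compared with the deterministic prediction; returns a dict
    with a long ``table`` (function, treatment, observed, predicted), a
    ``per_function`` frame of RMSE (function units) and R2, and the
    unit-incoherent ``aggregate_rmse`` (the mean of the five per-function
    RMSEs, reported alongside — never instead of — the per-function values).
    """
    keys = ["temperature_C", "duration_d"]
    conv = params.conversion

    pc = obs[obs["stage"] == "pollen_count"].copy()
    pc["value"] = model.pollen_count_to_number(pc["value"].to_numpy(), conv)
    means = {
        "n_pollen": pc.groupby(keys)["value"].mean(),
        "f_viable": obs[obs["stage"] == "viability"].groupby(keys)["value"].mean(),
        "f_germ": obs[obs["stage"] == "germination"].groupby(keys)["value"].mean(),
        "n_seeds": obs[obs["stage"] == "seed"].groupby(keys)["value"].mean(),
        "fruit_mass_g": obs[obs["stage"] == "fruit_mass"].groupby(keys)["value"].mean(),
    }

    records, per_fn = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", model.ExtrapolationWarning)
        for fn, series in means.items():
            if series.empty:
                continue
            T = series.index.get_level_values(0).to_numpy(dtype=float)
            D = series.index.get_level_values(1).to_numpy(dtype=float)
            if fn == "n_pollen":
                pred = np.broadcast_to(
                    model.pollen_number(T, params.pollen_beta), T.shape
                )
            elif fn == "f_viable":
                pred = model.fraction_surface(T, D, params.viability)
            elif fn == "f_germ":
                pred = model.fraction_surface(T, D, params.germination)
            elif fn == "n_seeds":
                n_germ = model.germinated_pollen(
                    T, D, params.pollen_beta, params.viability, params.germination
                )
                pred = model.seed_number(n_germ, params.seed_link, conv)
            else:
                pred = model.predict_fruit_mass(T, D, params)
            y = series.to_numpy(dtype=float)
            for t, d, o, p in zip(T, D, y, pred):
                records.append(
                    {"function": fn, "temperature_C": t, "duration_d": d,
                     "observed": o, "predicted": p}
                )
            per_fn.append(
                {
                    "function": fn,
                    "rmse": rmse(y, pred),
                    "r2": r_squared(y, pred) if y.size > 1 and np.var(y) > 0 else np.nan,
                    "n_treatments": y.size,
                }
            )

    per_function = pd.DataFrame(per_fn).set_index("function")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        agg = float(np.mean(per_function["rmse"])) if len(per_function) else np.nan
    return {
        "table": pd.DataFrame(records),
        "per_function": per_function,
        "aggregate_rmse": agg,
    }
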