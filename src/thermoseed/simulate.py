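"""Synthetic factorial temperature-stress experiments.

Generates observation tables with the statistical structure of the
calibration experiment: 10 treatments (an 18 degC control; 14 degC held for
4, 6 or 8 days; 30 degC and 34 degC each held for 1, 3 or 4 days), three
blocks (repetitions over time), four plants per block for the pollen assays
and six for the fruit traits, three trusses per plant, nine flowers per
truss.

Noise is layered on the deterministic cascade where the real measurement
process introduces it:

* haemocytometer grain counts — Poisson (optionally negative-binomial) at
  the counted-aliquot level, so the count-to-concentration conversion is
  exercised on integers;
* viability fraction — binomial on the grains actually counted in the
  chamber; germination fraction — binomial on an assay of fixed grain count;
* seeds per fruit — Poisson around the link-predicted mean;
* fruit mass — normal residual, truncated just above zero.

Setting every scale in :class:`NoiseSpec` to zero reproduces the cascade's
deterministic predictions exactly, which is what makes zero-noise parameter
recovery an exact test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import model
from .estimation import EstimationError, fit_all
from .observations import COLUMNS, validate_observations
from .params import ModelParams, ParameterError

__all__ = ["DesignSpec", "NoiseSpec", "generate_experiment", "recovery_study"]

DEFAULT_TREATMENTS: tuple[tuple[float, float], ...] = (
    (18.0, 0.0),
    (14.0, 4.0), (14.0, 6.0), (14.0, 8.0),
    (30.0, 1.0), (30.0, 3.0), (30.0, 4.0),
    (34.0, 1.0), (34.0, 3.0), (34.0, 4.0),
)


@dataclass(frozen=True)
class DesignSpec:
    """Layout of the factorial experiment.

    Defaults reproduce the calibration design: 10 treatments x 3 blocks,
    4 plants/block for pollen traits, 6 plants/block for fruit traits,
    trusses 1-3, 9 flowers per truss.
    """

    treatments: tuple[tuple[float, float], ...] = DEFAULT_TREATMENTS
    blocks: int = 3
    plants_pollen: int = 4
    plants_fruit: int = 6
    trusses: int = 3
    flowers_per_truss: int = 9

    def __post_init__(self) -> None:
        if not self.treatments:
            raise ParameterError("design needs at least one treatment")
        for t, d in self.treatments:
            if d < 0:
                raise ParameterError(f"treatment duration must be >= 0, got {d}")
        for name in ("blocks", "plants_pollen", "plants_fruit", "trusses",
                     "flowers_per_truss"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be >= 1")


@dataclass(frozen=True)
class NoiseSpec:
    """Noise scales for each measured stage; 0 disables that noise source.

    ``count_dispersion`` — 0: deterministic expected chamber count;
    1: Poisson; >1: negative-binomial with variance = dispersion x mean.
    ``viability_sampling`` / ``germination_sampling`` — 0 or 1 switches for
    binomial sampling of the two fraction assays.
    ``germination_assay_n`` — grains scored per germination assay (the in
    vitro assay scores a fixed field of view, independent of the chamber
    count).
    ``seed_dispersion`` — 0: exact mean; 1: Poisson; >1: negative-binomial.
    ``fruit_mass_sd`` — normal residual scale in grams per fruit.
    ``block_sd`` — relative block effect scale; each block draws one
    multiplier (1 + Normal(0, block_sd)) applied to pollen, seed and mass
    means.
    """

    count_dispersion: float = 1.0
    viability_sampling: float = 1.0
    germination_sampling: float = 1.0
    germination_assay_n: int = 100
    seed_dispersion: float = 1.0
    fruit_mass_sd: float = 0.9
    block_sd: float = 0.0

    def __post_init__(self) -> None:
        for name in ("count_dispersion", "viability_sampling",
                     "germination_sampling", "seed_dispersion",
                     "fruit_mass_sd", "block_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.germination_assay_n < 1:
            raise ParameterError("germination_assay_n must be >= 1")

    @classmethod
    def zero(cls) -> "NoiseSpec":
        """All noise off: simulated values equal the deterministic cascade."""
        return cls(
            count_dispersion=0.0,
            viability_sampling=0.0,
            germination_sampling=0.0,
            seed_dispersion=0.0,
            fruit_mass_sd=0.0,
            block_sd=0.0,
        )


def _draw_count(rng: np.random.Generator, mean: float, dispersion: float) -> float:
    """Poisson / negative-binomial / deterministic count with given mean."""
    if dispersion == 0.0:
        return mean
    if mean == 0.0:
        return 0.0
    if dispersion <= 1.0:
        return float(rng.poisson(mean))
    # NB parameterised by mean and variance = dispersion * mean
    p = 1.0 / dispersion
    r = mean * p / (1.0 - p)
    return float(rng.negative_binomial(r, p))


def generate_experiment(
    design: DesignSpec | None = None,
    truth: ModelParams | None = None,
    noise: NoiseSpec | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate one full experiment; returns a validated observation table.

    Deterministic under a fixed integer seed.  Rows follow the schema in
    :mod:`thermoseed.observations`.  ``fruit_set`` rows are emitted only when
    ``truth.fruit_set`` is supplied.
    """
    design = design if design is not None else DesignSpec()
    truth = truth if truth is not None else ModelParams.default()
    noise = noise if noise is not None else NoiseSpec()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    conv = truth.conversion
    rows: list[tuple] = []

    block_mult = {
        b: max(0.0, 1.0 + (rng.normal(0.0, noise.block_sd) if noise.block_sd > 0 else 0.0))
        for b in range(1, design.blocks + 1)
    }

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", model.ExtrapolationWarning)
        for T, D in design.treatments:
            n_pollen_true = model.pollen_number(T, truth.pollen_beta)
            f_v = model.fraction_surface(T, D, truth.viability)
            f_g = model.fraction_surface(T, D, truth.germination)
            for block in range(1, design.blocks + 1):
                bm = block_mult[block]
                # pollen-trait plants: chamber count, viability, germination
                for plant in range(1, design.plants_pollen + 1):
                    for truss in range(1, design.trusses + 1):
                        expect_count = (
                            n_pollen_true * bm * conv.vol_chamber_mm3 / conv.vol_sample_ul
                        )
                        count = _draw_count(rng, expect_count, noise.count_dispersion)
                        rows.append((T, D, block, truss, plant,
                                     "pollen_count", count, np.nan))

                        if noise.viability_sampling > 0:
                            n_assay = max(1, int(round(count)))
                            v = rng.binomial(n_assay, f_v) / n_assay
                        else:
                            n_assay, v = np.nan, f_v
                        rows.append((T, D, block, truss, plant,
                                     "viability", v, n_assay))

                        if noise.germination_sampling > 0:
                            n_g = noise.germination_assay_n
                            g = rng.binomial(n_g, f_g) / n_g
                        else:
                            n_g, g = np.nan, f_g
                        rows.append((T, D, block, truss, plant,
                                     "germination", g, n_g))

                # fruit-trait plants: seeds and individual fruit mass
                n_germ_true = n_pollen_true * bm * f_v * f_g
                seed_mean = model.seed_number(n_germ_true, truth.seed_link, conv)
                for plant in range(1, design.plants_fruit + 1):
                    for truss in range(1, design.trusses + 1):
                        n_seeds = _draw_count(rng, seed_mean, noise.seed_dispersion)
                        rows.append((T, D, block, truss, plant,
                                     "seed", n_seeds, np.nan))
                        mass_mean = model.fruit_mass(n_seeds, truth.mass_link)
                        if noise.fruit_mass_sd > 0:
                            mass = max(1e-3, rng.normal(mass_mean, noise.fruit_mass_sd))
                        else:
                            mass = mass_mean
                        rows.append((T, D, block, truss, plant,
                                     "fruit_mass", mass, np.nan))

                        if truth.fruit_set is not None:
                            fs = truth.fruit_set.fraction(T)
                            nf = design.flowers_per_truss
                            if noise.seed_dispersion > 0:
                                set_frac = rng.binomial(nf, fs) / nf
                            else:
                                set_frac = fs
                            rows.append((T, D, block, truss, plant,
                                         "fruit_set", set_frac, nf))

    obs = pd.DataFrame(rows, columns=list(COLUMNS))
    return validate_observations(obs, design_treatments=list(design.treatments))


def recovery_study(
    n_runs: int,
    design: DesignSpec | None = None,
    truth: ModelParams | None = None,
    noise: NoiseSpec | None = None,
    seed: int = 0,
) -> dict:
    """Monte-Carlo parameter recovery: generate -> fit, ``n_runs`` times.

    Returns a dict with ``errors`` (DataFrame of signed relative errors, one
    row per successful run), ``summary`` (per-parameter median absolute
    relative error and bias), and ``n_failed`` (fit failures are counted,
    not fatal).
    """
    if n_runs < 1:
        raise ParameterError(f"n_runs must be >= 1, got {n_runs}")
    design = design if design is not None else DesignSpec()
    truth = truth if truth is not None else ModelParams.default()
    noise = noise if noise is not None else NoiseSpec()
    rng = np.random.default_rng(seed)

    true_values = {
        "mu": truth.pollen_beta.mu,
        "theta_v1": truth.viability.theta1,
        "theta_v2": truth.viability.theta2,
        "theta_g1": truth.germination.theta1,
        "theta_g2": truth.germination.theta2,
        "m1": truth.seed_link.slope,
        "b1": truth.seed_link.intercept,
        "m2": truth.mass_link.slope,
        "b2": truth.mass_link.intercept,
    }

    records, n_failed = [], 0
    for _ in range(n_runs):
        run_seed = int(rng.integers(2**31))
        obs = generate_experiment(design, truth, noise, seed=run_seed)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fitted, _ = fit_all(obs, fixed=truth.pollen_beta,
                                    conversion=truth.conversion)
        except EstimationError:
            n_failed += 1
            continue
        est = {
            "mu": fitted.pollen_beta.mu,
            "theta_v1": fitted.viability.theta1,
            "theta_v2": fitted.viability.theta2,
            "theta_g1": fitted.germination.theta1,
            "theta_g2": fitted.germination.theta2,
            "m1": fitted.seed_link.slope,
            "b1": fitted.seed_link.intercept,
            "m2": fitted.mass_link.slope,
            "b2": fitted.mass_link.intercept,
        }
        records.append(
            {k: (est[k] - v) / v for k, v in true_values.items()}
        )

    errors = pd.DataFrame(records)
    if errors.empty:
        raise EstimationError("every recovery run failed to fit")
    summary = pd.DataFrame(
        {
            "median_abs_rel_error": errors.abs().median(),
            "bias": errors.mean(),
        }
    )
    return {"errors": errors, "summary": summary, "n_failed": n_failed}
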