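"""Observation-table schema shared by the simulator and the fitters.

One row per plant x truss x measured stage.  Columns:

==============  =======================================================
temperature_C   treatment temperature (deg C)
duration_d      treatment duration (days; 0 = control)
block           block id (the experiment's repetition over time)
truss           truss number on the plant (1-3)
plant           plant id within the block
stage           one of ``STAGES`` below
value           the observation (count, fraction or grams, per stage)
denominator     grains counted in the assay, for fraction stages; NaN
                otherwise
==============  =======================================================

Stage semantics: ``pollen_count`` rows carry the raw haemocytometer grain
count (convert with :func:`thermoseed.model.pollen_count_to_number`);
``viability`` and ``germination`` rows carry fractions in [0, 1]; ``seed``
rows carry seeds per fruit; ``fruit_mass`` rows carry grams per fruit;
``fruit_set`` rows carry the fruit-set fraction per truss.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["STAGES", "COLUMNS", "ObservationError", "validate_observations"]

STAGES = ("pollen_count", "viability", "germination", "seed", "fruit_mass", "fruit_set")

COLUMNS = (
    "temperature_C",
    "duration_d",
    "block",
    "truss",
    "plant",
    "stage",
    "value",
    "denominator",
)

FRACTION_STAGES = ("viability", "germination", "fruit_set")
COUNT_STAGES = ("pollen_count", "seed")


class ObservationError(ValueError):
    """Raised when an observation table violates its schema."""


def validate_observations(
    obs: pd.DataFrame, design_treatments: list[tuple[float, float]] | None = None
) -> pd.DataFrame:
    """Validate and return the table (unchanged) or raise ObservationError.

    Checks the column set, stage labels, value ranges per stage, and — when
    ``design_treatments`` is given — that every (temperature, duration) pair
    belongs to the declared design.
    """
    missing = set(COLUMNS) - set(obs.columns)
    if missing:
        raise ObservationError(f"missing observation columns: {sorted(missing)}")
    bad_stage = set(obs["stage"].unique()) - set(STAGES)
    if bad_stage:
        raise ObservationError(f"unknown stages: {sorted(bad_stage)}")

    frac = obs[obs["stage"].isin(FRACTION_STAGES)]["value"]
    if len(frac) and ((frac < 0) | (frac > 1)).any():
        raise ObservationError("fraction observations must lie in [0, 1]")

    counts = obs[obs["stage"].isin(COUNT_STAGES)]["value"]
    if len(counts) and (counts < 0).any():
        raise ObservationError("count observations must be non-negative")

    masses = obs[obs["stage"] == "fruit_mass"]["value"]
    if len(masses) and (masses <= 0).any():
        raise ObservationError("fruit masses must be positive")

    if not np.isfinite(obs["value"]).all():
        raise ObservationError("observation values must be finite")

    if design_treatments is not None:
        declared = {(float(t), float(d)) for t, d in design_treatments}
        present = {
            (float(t), float(d))
            for t, d in obs[["temperature_C", "duration_d"]].drop_duplicates().values
        }
        stray = present - declared
        if stray:
            raise ObservationError(
                f"treatments not in the declared design: {sorted(stray)}"
            )
    return obs
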