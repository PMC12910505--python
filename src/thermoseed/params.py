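"""Parameter groups for the pollen-to-fruit temperature-response cascade.

The model describes how a period of non-optimal temperature, applied while
tomato flower buds develop, propagates through five reproductive stages:
pollen number per flower, fraction of viable pollen, fraction of germinated
pollen, seeds per fruit, and individual fruit mass.  Each stage has its own
small parameter group; this module defines those groups, validates them, and
reads/writes them as JSON or YAML configuration files.

The shipped defaults (:func:`ModelParams.default` and
``data/default_params.json``) are the published calibration for the dwarf
tomato cultivar the model was developed on.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = [
    "TemperatureRegime",
    "PollenBetaParams",
    "FractionSurfaceParams",
    "LinearLinkParams",
    "ConversionParams",
    "FruitSetQuadParams",
    "ModelParams",
    "ParameterError",
    "load_params",
]


class ParameterError(ValueError):
    """Raised when a parameter group violates its invariants."""


def _require_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ParameterError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class TemperatureRegime:
    """A (temperature, stress duration) pair — the model's only environmental input.

    ``duration`` is the number of days the plant is held at ``temperature``;
    0 denotes the unstressed control grown continuously at the optimum.
    """

    temperature: float
    duration: float = 0.0

    def __post_init__(self) -> None:
        _require_finite("temperature", self.temperature)
        _require_finite("duration", self.duration)
        if self.duration < 0:
            raise ParameterError(f"duration must be >= 0, got {self.duration}")


@dataclass(frozen=True)
class PollenBetaParams:
    """Constrained beta function for pollen number per flower.

    The curve ``exp(mu) * ((T-T_b)/T_0)^alpha * ((T_c-T)/T_0)^beta`` rises
    from zero at the base temperature ``T_b``, peaks at ``T_opt`` with value
    ``N_star`` pollen grains per flower, and falls back to zero at the
    ceiling ``T_c``.  The shape exponents alpha and beta are not free: they
    are derived from the peak constraint (see
    :func:`thermoseed.model.derive_beta_shape`), leaving ``mu`` as the single
    magnitude parameter estimated from data.

    Parameters
    ----------
    mu : dimensionless magnitude parameter.
    T_b, T_c, T_opt : base, ceiling and optimal temperatures in deg C.
    T_0 : scaling constant (deg C) that makes temperature differences
        dimensionless; kept explicit rather than hard-coded.
    N_star : pollen grains per flower at the optimum.
    """

    mu: float = 5.0
    T_b: float = 13.0
    T_c: float = 48.0
    T_opt: float = 18.0
    T_0: float = 1.0
    N_star: float = 6.61e4

    def __post_init__(self) -> None:
        for name in ("mu", "T_b", "T_c", "T_opt", "T_0", "N_star"):
            _require_finite(name, getattr(self, name))
        if not (self.T_b < self.T_opt < self.T_c):
            raise ParameterError(
                f"require T_b < T_opt < T_c, got {self.T_b}, {self.T_opt}, {self.T_c}"
            )
        if self.T_0 <= 0:
            raise ParameterError(f"T_0 must be > 0, got {self.T_0}")
        if self.N_star <= 0:
            raise ParameterError(f"N_star must be > 0, got {self.N_star}")

    @property
    def delta1(self) -> float:
        return (self.T_opt - self.T_b) / self.T_0

    @property
    def delta2(self) -> float:
        return (self.T_c - self.T_opt) / self.T_0

    @property
    def delta3(self) -> float:
        return self.delta1 / self.delta2


@dataclass(frozen=True)
class FractionSurfaceParams:
    """Quadratic temperature x duration response surface for a pollen fraction.

    The surface is a downward parabola in T/T_opt whose vertex sits at
    ``alpha_max`` (the fraction measured in the unstressed control), anchored
    away from the optimum by the duration interpolation
    ``p(D) = theta1 + theta2 * D**2``.  Instantiated twice: once for pollen
    viability, once for pollen germination.

    theta2 carries units of day^-2 and is negative in the published fits
    (longer stress lowers the fraction); its sign is not enforced.
    """

    alpha_max: float
    theta1: float
    theta2: float
    T_opt: float = 18.0

    def __post_init__(self) -> None:
        for name in ("alpha_max", "theta1", "theta2", "T_opt"):
            _require_finite(name, getattr(self, name))
        if not (0 < self.alpha_max <= 1):
            raise ParameterError(
                f"alpha_max must be in (0, 1], got {self.alpha_max}"
            )
        if self.T_opt == 0:
            raise ParameterError("T_opt must be non-zero (surface divides by it)")


@dataclass(frozen=True)
class LinearLinkParams:
    """Slope/intercept of one linear link in the cascade.

    Instantiated twice: germinated pollen -> seeds per fruit, and seeds per
    fruit -> grams per fruit.  The published intercepts are positive (a
    baseline seed number / parthenocarpic baseline mass); a negative
    intercept is permitted but flagged, since it breaks the cascade's
    output-floor property.
    """

    slope: float
    intercept: float

    def __post_init__(self) -> None:
        _require_finite("slope", self.slope)
        _require_finite("intercept", self.intercept)
        if self.intercept < 0:
            warnings.warn(
                f"negative intercept {self.intercept}: the cascade's "
                "non-negativity floor no longer holds",
                stacklevel=2,
            )


@dataclass(frozen=True)
class ConversionParams:
    """Unit-conversion constants.

    ``vol_chamber_mm3`` and ``vol_sample_ul`` convert haemocytometer grain
    counts into pollen per flower (1 ul == 1 mm3, so the ratio is
    dimensionless x volume).  ``c_flower_to_fruit`` converts flowers to
    fruits under the assumption that each flower develops into one fruit.
    """

    c_flower_to_fruit: float = 1.0
    vol_chamber_mm3: float = 0.2
    vol_sample_ul: float = 200.0

    def __post_init__(self) -> None:
        for name in ("c_flower_to_fruit", "vol_chamber_mm3", "vol_sample_ul"):
            value = getattr(self, name)
            _require_finite(name, value)
            if value <= 0:
                raise ParameterError(f"{name} must be > 0, got {value}")


@dataclass(frozen=True)
class FruitSetQuadParams:
    """User-supplied quadratic fruit-set fraction vs temperature.

    ``fraction(T) = clamp01(a + b*T + c*T**2)``.  No default coefficients are
    shipped: the published calibration for this curve is not available, so
    any yield computation requires the user to supply their own.  See
    ``examples/fruit_set_example.json`` for an illustrative set constructed
    from reported point values.
    """

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            _require_finite(name, getattr(self, name))

    def fraction(self, temperature):
        """Evaluate the quadratic, clamped to [0, 1]. Accepts scalars or arrays."""
        import numpy as np

        t = np.asarray(temperature, dtype=float)
        f = self.a + self.b * t + self.c * t**2
        out = np.clip(f, 0.0, 1.0)
        return float(out) if np.ndim(temperature) == 0 else out


@dataclass(frozen=True)
class ModelParams:
    """All parameter groups of the cascade, bundled.

    ``fruit_set`` is optional and defaults to None; operations that need it
    (truss yield, yield decomposition) raise an explicit error when absent.
    """

    pollen_beta: PollenBetaParams = field(default_factory=PollenBetaParams)
    viability: FractionSurfaceParams = field(
        default_factory=lambda: FractionSurfaceParams(0.94, 0.78, -0.11, 18.0)
    )
    germination: FractionSurfaceParams = field(
        default_factory=lambda: FractionSurfaceParams(0.31, 0.34, -0.06, 18.0)
    )
    seed_link: LinearLinkParams = field(
        default_factory=lambda: LinearLinkParams(1.60e-3, 2.23)
    )
    mass_link: LinearLinkParams = field(
        default_factory=lambda: LinearLinkParams(7.80e-2, 2.06)
    )
    conversion: ConversionParams = field(default_factory=ConversionParams)
    fruit_set: FruitSetQuadParams | None = None
    mass_unit: str = "g per fruit"

    @classmethod
    def default(cls) -> "ModelParams":
        """The published calibration (no fruit-set quadratic)."""
        return cls()

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "pollen_beta": asdict(self.pollen_beta),
            "viability": asdict(self.viability),
            "germination": asdict(self.germination),
            "seed_link": asdict(self.seed_link),
            "mass_link": asdict(self.mass_link),
            "conversion": asdict(self.conversion),
            "mass_unit": self.mass_unit,
        }
        if self.fruit_set is not None:
            d["fruit_set"] = asdict(self.fruit_set)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        kwargs = {}
        mapping = {
            "pollen_beta": PollenBetaParams,
            "viability": FractionSurfaceParams,
            "germination": FractionSurfaceParams,
            "seed_link": LinearLinkParams,
            "mass_link": LinearLinkParams,
            "conversion": ConversionParams,
            "fruit_set": FruitSetQuadParams,
        }
        for key, typ in mapping.items():
            if key in d:
                kwargs[key] = typ(**d[key])
        if "mass_unit" in d:
            kwargs["mass_unit"] = d["mass_unit"]
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        d = self.to_dict()
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(d, sort_keys=False))
        else:
            path.write_text(json.dumps(d, indent=2) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "ModelParams":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            d = yaml.safe_load(text)
        else:
            d = json.loads(text)
        return cls.from_dict(d)


def load_params(path: str | Path | None = None) -> ModelParams:
    """Load a parameter file, or the shipped default calibration if None."""
    if path is None:
        return ModelParams.default()
    return ModelParams.from_file(path)
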