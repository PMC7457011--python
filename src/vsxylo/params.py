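"""Site configuration and Vaganov-Shashkin model parameters.

The VS model reduces a site's climatology to a small set of response
parameters: trapezoidal temperature and soil-moisture response nodes, a
degree-day forcing requirement for cambial resumption, a critical growth
rate below which the season ends, and the coefficients of a single-layer
soil water bucket with degree-day snowmelt.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


class ConfigError(ValueError):
    """Raised when a configuration violates a structural invariant."""


@dataclass(frozen=True)
class SiteConfig:
    """Location of a study site.

    Parameters
    ----------
    site_id : str
        Short label (e.g. ``"SIM"``).
    latitude : float
        Degrees north, in [-90, 90].
    longitude : float
        Degrees west (positive westward, following dendro convention for
        North American sites).
    elevation : float
        Metres above sea level, >= 0.
    """

    site_id: str
    latitude: float
    longitude: float = 0.0
    elevation: float = 0.0

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ConfigError(f"latitude {self.latitude} outside [-90, 90]")
        if self.elevation < 0:
            raise ConfigError(f"elevation {self.elevation} must be >= 0")


@dataclass(frozen=True)
class VSParameters:
    """Constants of the VS growth model and its soil water bucket.

    Temperature response is a trapezoid over ``(t_min, t_opt1, t_opt2,
    t_max)`` in deg C: zero at or below ``t_min``, one on the optimum
    plateau ``[t_opt1, t_opt2]``, zero at or above ``t_max``.  Soil
    moisture uses the analogous ``(w_min, w_opt1, w_opt2, w_max)`` nodes
    in volumetric fraction of saturation (V/Vs).

    ``t_beg`` is the degree-day sum (above ``t_min``, accumulated from
    1 January) required for growth initiation; ``v_cr`` is the critical
    integral growth rate below which the season ends.

    The bucket has depth ``root_depth`` (mm).  Precipitation on days with
    temperature <= ``t_snow`` accumulates as snowpack; when the soil
    melting block is active, snow melts at ``k_melt`` mm per degree-day
    and is released into the soil.  Rain is reduced by the canopy
    interception fraction ``k_intercept``.  Evapotranspiration is
    ``k_pet * max(T, 0) * daylength/12`` mm per day, and water above
    ``w_max`` drains at the linear rate ``k_drain`` per day.
    """

    t_min: float = 4.0
    t_opt1: float = 10.0
    t_opt2: float = 20.0
    t_max: float = 29.0
    w_min: float = 0.02
    w_opt1: float = 0.12
    w_opt2: float = 0.75
    w_max: float = 0.90
    t_beg: float = 100.0
    v_cr: float = 0.05
    root_depth: float = 400.0
    k_intercept: float = 0.15
    k_melt: float = 1.5
    t_snow: float = 0.0
    k_pet: float = 0.13
    k_drain: float = 1.0
    w_init: float = 0.30
    soil_melting_block: bool = True

    def __post_init__(self) -> None:
        if not (self.t_min < self.t_opt1 <= self.t_opt2 < self.t_max):
            raise ConfigError(
                "temperature nodes must satisfy t_min < t_opt1 <= t_opt2 < t_max, "
                f"got ({self.t_min}, {self.t_opt1}, {self.t_opt2}, {self.t_max})"
            )
        if not (self.w_min < self.w_opt1 <= self.w_opt2 < self.w_max <= 1.0):
            raise ConfigError(
                "moisture nodes must satisfy w_min < w_opt1 <= w_opt2 < w_max <= 1, "
                f"got ({self.w_min}, {self.w_opt1}, {self.w_opt2}, {self.w_max})"
            )
        if not 0.0 < self.v_cr < 1.0:
            raise ConfigError(f"v_cr {self.v_cr} outside (0, 1)")
        if not 0.0 <= self.k_intercept < 1.0:
            raise ConfigError(f"k_intercept {self.k_intercept} outside [0, 1)")
        if not 0.0 <= self.w_init <= 1.0:
            raise ConfigError(f"w_init {self.w_init} outside [0, 1]")
        for name in ("t_beg", "root_depth", "k_melt", "k_pet", "k_drain"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.root_depth <= 0:
            raise ConfigError("root_depth must be > 0")

    def replace(self, **changes: Any) -> "VSParameters":
        """Return a copy with ``changes`` applied (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "VSParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(d) - known
        if extra:
            raise ConfigError(f"unknown parameter names: {sorted(extra)}")
        return cls(**d)


def load_params(path: str | Path) -> VSParameters:
    """Read a :class:`VSParameters` YAML file (keys mirror field names)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return VSParameters.from_dict(data)


def save_params(params: VSParameters, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)


def load_site(path: str | Path) -> SiteConfig:
    """Read a site YAML file (``site_id, latitude, longitude, elevation``)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return SiteConfig(**data)


def save_site(site: SiteConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(site), fh, sort_keys=False)
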