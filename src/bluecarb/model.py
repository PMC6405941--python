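"""Shared data model for sediment-core carbonate accounting.

The package revolves around three kinds of objects:

* :class:`CoreSlice` — one depth interval of a sediment core, carrying the
  dry bulk density, total (and optionally supported) lead-210 activity and
  the CaCO3 content as percent of sediment dry weight.
* :class:`SedimentCore` — a cored profile: ordered slices plus the metadata
  needed downstream (ecosystem, coring year, climate zone, presence/absence
  of allochthonous CaCO3 sources, and the location grouping key).
* :class:`Constants` — the physical and accounting constants (lead-210 decay
  constant, carbon mass fraction of CaCO3, CO2-release ratio of
  calcification, global habitat areas).

Everything downstream consumes these types; only :mod:`bluecarb.io` reads
or writes files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "CoreSlice",
    "SedimentCore",
    "Constants",
    "ValidationError",
    "ECOSYSTEMS",
]

#: Habitat categories recognised in core metadata.
ECOSYSTEMS = ("seagrass", "mangrove", "saltmarsh", "unvegetated")

#: Half-life of lead-210 in years.
PB210_HALF_LIFE_YR = 22.3


class ValidationError(ValueError):
    """Raised when a core, slice or constant violates its invariants."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass(frozen=True)
class CoreSlice:
    """One depth interval of a sediment core.

    Depths are centimetres below the sediment surface; the interval is
    half-open ``[depth_top, depth_bottom)`` and the slice midpoint
    ``(top + bottom) / 2`` is used wherever a single depth is needed.

    Parameters
    ----------
    depth_top, depth_bottom
        Interval bounds in cm; ``0 <= depth_top < depth_bottom``.
    dry_bulk_density
        Dry mass per wet volume, g cm^-3; must be positive.
    pb210_total
        Total lead-210 activity, Bq kg^-1 dry sediment.
    pb210_total_err
        1-sigma counting error on the total activity (optional).
    pb210_supported
        Supported lead-210 (e.g. from radium-226), Bq kg^-1 (optional).
    caco3_pct
        CaCO3 content, percent of sediment dry weight, in [0, 100].
    corg_pct
        Organic-carbon content, percent dry weight (optional).
    """

    depth_top: float
    depth_bottom: float
    dry_bulk_density: float
    pb210_total: float
    caco3_pct: float
    pb210_total_err: float | None = None
    pb210_supported: float | None = None
    corg_pct: float | None = None

    def __post_init__(self) -> None:
        _require(self.depth_top >= 0.0, f"depth_top must be >= 0, got {self.depth_top}")
        _require(
            self.depth_bottom > self.depth_top,
            f"depth_bottom ({self.depth_bottom}) must exceed depth_top ({self.depth_top})",
        )
        _require(
            self.dry_bulk_density > 0.0,
            f"dry bulk density must be positive, got {self.dry_bulk_density}",
        )
        _require(self.pb210_total >= 0.0, f"pb210_total must be >= 0, got {self.pb210_total}")
        _require(
            0.0 <= self.caco3_pct <= 100.0,
            f"caco3_pct must lie in [0, 100], got {self.caco3_pct}",
        )
        for name in ("pb210_total_err", "pb210_supported", "corg_pct"):
            v = getattr(self, name)
            if v is not None:
                _require(v >= 0.0, f"{name} must be >= 0, got {v}")

    @property
    def midpoint(self) -> float:
        """Midpoint depth of the interval, cm."""
        return 0.5 * (self.depth_top + self.depth_bottom)

    @property
    def thickness(self) -> float:
        """Interval thickness, cm."""
        return self.depth_bottom - self.depth_top


@dataclass(frozen=True)
class SedimentCore:
    """A cored sediment profile with metadata.

    Slices must be in strictly increasing, non-overlapping depth order
    (gaps are allowed). ``location_key`` labels the site/area grouping:
    cores sharing a key and allochthonous-source state are treated as
    replicates of one global location.
    """

    core_id: str
    ecosystem: str
    latitude: float
    longitude: float
    coring_year: int
    location_key: str
    slices: tuple[CoreSlice, ...]
    climate_class: str = ""
    is_tropical: bool = False
    coral_reef_present: bool = False
    lithogenic_present: bool = False

    def __post_init__(self) -> None:
        _require(bool(self.core_id), "core_id must be non-empty")
        _require(bool(self.location_key), f"core {self.core_id}: location_key must be non-empty")
        _require(
            self.ecosystem in ECOSYSTEMS,
            f"core {self.core_id}: unknown ecosystem {self.ecosystem!r} "
            f"(expected one of {ECOSYSTEMS})",
        )
        _require(-90.0 <= self.latitude <= 90.0, f"core {self.core_id}: latitude out of range")
        _require(-180.0 <= self.longitude <= 180.0, f"core {self.core_id}: longitude out of range")
        object.__setattr__(self, "slices", tuple(self.slices))
        _require(len(self.slices) >= 1, f"core {self.core_id}: needs at least one slice")
        for prev, cur in zip(self.slices, self.slices[1:]):
            _require(
                cur.depth_top >= prev.depth_bottom,
                f"core {self.core_id}: slices overlap or are out of order at "
                f"depth {cur.depth_top} cm (previous slice ends at {prev.depth_bottom} cm)",
            )

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    @property
    def has_alloch_source(self) -> bool:
        """True when a coral-reef or lithogenic CaCO3 source is adjacent."""
        return self.coral_reef_present or self.lithogenic_present

    def with_slices(self, slices) -> "SedimentCore":
        """Copy of the core with a different slice list."""
        return replace(self, slices=tuple(slices))


@dataclass(frozen=True)
class Constants:
    """Physical and accounting constants.

    Attributes
    ----------
    lambda_pb210 : float
        Lead-210 decay constant, yr^-1. Default ln(2) / 22.3 yr.
    f_c : float
        Carbon mass fraction of CaCO3 (dimensionless). The accounting
        convention is a flat 12% (the molar-exact ratio 12.011/100.087 is
        available as ``Constants.molar_exact_f_c()``).
    psi : float
        Moles of CO2 released to the atmosphere-seawater system per mole
        of CaCO3 precipitated (~0.6).
    seagrass_area_low, seagrass_area_high : float
        Bounds on the global seagrass extent, km^2.
    mangrove_area : float
        Global mangrove extent, km^2.
    tropical_area_fraction : float
        Fraction of the seagrass area assumed to lie in the tropical and
        subtropical zone (2/3).
    caco3_molar_mass, carbon_molar_mass : float
        g mol^-1, used for molar-exact conversions.
    """

    lambda_pb210: float = math.log(2.0) / PB210_HALF_LIFE_YR
    f_c: float = 0.12
    psi: float = 0.6
    seagrass_area_low: float = 150_000.0
    seagrass_area_high: float = 600_000.0
    mangrove_area: float = 137_760.0
    tropical_area_fraction: float = 2.0 / 3.0
    caco3_molar_mass: float = 100.087
    carbon_molar_mass: float = 12.011

    def __post_init__(self) -> None:
        _require(self.lambda_pb210 > 0.0, "lambda_pb210 must be positive")
        _require(0.0 < self.f_c < 1.0, f"f_c must lie in (0, 1), got {self.f_c}")
        _require(0.0 < self.psi < 1.0, f"psi must lie in (0, 1), got {self.psi}")
        _require(self.seagrass_area_low > 0.0, "seagrass_area_low must be positive")
        _require(
            self.seagrass_area_low <= self.seagrass_area_high,
            "seagrass_area_low must not exceed seagrass_area_high",
        )
        _require(self.mangrove_area > 0.0, "mangrove_area must be positive")
        _require(
            0.0 < self.tropical_area_fraction < 1.0,
            "tropical_area_fraction must lie in (0, 1)",
        )
        _require(self.caco3_molar_mass > 0.0, "caco3_molar_mass must be positive")
        _require(self.carbon_molar_mass > 0.0, "carbon_molar_mass must be positive")

    @classmethod
    def molar_exact_f_c(cls) -> float:
        """Carbon fraction of CaCO3 from molar masses (12.011/100.087)."""
        d = cls()
        return d.carbon_molar_mass / d.caco3_molar_mass
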