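"""Per-core carbonate accounting: CaCO3 content to Cinorg burial rates.

The chain per dated core is:

1. average CaCO3 %DW over the slices deposited since 1900 (the
   contemporary window of the lead-210 chronology);
2. convert to an inorganic-carbon concentration
   ``Cinorg (gC cm^-3) = DBD * %CaCO3/100 * f_c`` with f_c the carbon
   mass fraction of CaCO3 (0.12);
3. multiply by the sediment accretion rate to obtain the burial rate
   ``gC m^-2 yr^-1 = SAR (cm yr^-1) * Cinorg (gC cm^-3) * 1e4``.

Cores with negligible CaCO3 yield a burial rate of zero and are retained.
Undated cores (no chronology) get concentration/%DW statistics only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chronology import Chronology, post1900_mask
from .model import Constants, SedimentCore

__all__ = [
    "CoreCarbonate",
    "CarbonateError",
    "mean_caco3_post1900",
    "cinorg_concentration",
    "burial_rate",
    "caco3_from_cinorg",
    "cinorg_from_caco3",
    "caco3_accretion",
    "core_carbonate",
]

CM2_PER_M2 = 1.0e4


class CarbonateError(ValueError):
    """Raised for invalid carbonate-accounting inputs."""


@dataclass(frozen=True)
class CoreCarbonate:
    """Carbonate accounting result for one core.

    Rates are None for undated cores. ``caco3_burial`` always equals
    ``cinorg_burial / f_c``.
    """

    core_id: str
    caco3_pct_post1900: float      # %DW, mean over the post-1900 window
    dbd_post1900: float            # g cm^-3, mean over the same window
    cinorg_conc: float             # gC cm^-3
    n_slices_used: int
    cinorg_burial: float | None = None   # gC m^-2 yr^-1
    caco3_burial: float | None = None    # gCaCO3 m^-2 yr^-1
    caco3_accretion: float | None = None  # cm yr^-1


def mean_caco3_post1900(core: SedimentCore, mask: np.ndarray) -> float:
    """Unweighted mean CaCO3 %DW over the masked-in (post-1900) slices."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (core.n_slices,):
        raise CarbonateError(
            f"core {core.core_id}: mask length {mask.size} != {core.n_slices} slices")
    vals = [s.caco3_pct for s, m in zip(core.slices, mask) if m]
    if not vals:
        raise CarbonateError(f"core {core.core_id}: no post-1900 slice with CaCO3 data")
    return float(np.mean(vals))


def cinorg_concentration(dbd_mean: float, caco3_pct: float,
                         constants: Constants | None = None) -> float:
    """Inorganic-carbon concentration, gC cm^-3.

    ``dbd_mean * caco3_pct/100 * f_c``: the mass of carbonate-bound carbon
    per unit wet sediment volume.
    """
    if constants is None:
        constants = Constants()
    if dbd_mean <= 0.0:
        raise CarbonateError(f"dry bulk density must be positive, got {dbd_mean}")
    if not 0.0 <= caco3_pct <= 100.0:
        raise CarbonateError(f"caco3_pct must lie in [0, 100], got {caco3_pct}")
    return dbd_mean * (caco3_pct / 100.0) * constants.f_c


def burial_rate(sar: float, cinorg_conc: float) -> float:
    """Cinorg burial rate, gC m^-2 yr^-1 = SAR * concentration * 1e4.

    Zero-carbonate cores yield 0 and are retained in downstream medians.
    """
    if sar <= 0.0:
        raise CarbonateError(f"SAR must be positive, got {sar}")
    if cinorg_conc < 0.0:
        raise CarbonateError(f"concentration must be >= 0, got {cinorg_conc}")
    return sar * cinorg_conc * CM2_PER_M2


def caco3_from_cinorg(cinorg_rate: float, constants: Constants | None = None) -> float:
    """Convert a Cinorg rate or mass to CaCO3 units (divide by f_c)."""
    if constants is None:
        constants = Constants()
    if cinorg_rate < 0.0:
        raise CarbonateError(f"rate must be >= 0, got {cinorg_rate}")
    return cinorg_rate / constants.f_c


def cinorg_from_caco3(caco3_rate: float, constants: Constants | None = None) -> float:
    """Convert a CaCO3 rate or mass to Cinorg units (multiply by f_c)."""
    if constants is None:
        constants = Constants()
    if caco3_rate < 0.0:
        raise CarbonateError(f"rate must be >= 0, got {caco3_rate}")
    return caco3_rate * constants.f_c


def caco3_accretion(caco3_burial: float, effective_density: float) -> float:
    """Vertical accretion rate of CaCO3, cm yr^-1.

    ``(caco3_burial / 1e4) / effective_density``. The effective density is
    a choice: bulk sediment density gives the carbonate share of seabed
    elevation, CaCO3 mineral density (~2.71 g cm^-3) a compact-mineral
    equivalent.
    """
    if effective_density <= 0.0:
        raise CarbonateError(f"effective density must be positive, got {effective_density}")
    if caco3_burial < 0.0:
        raise CarbonateError(f"burial must be >= 0, got {caco3_burial}")
    return (caco3_burial / CM2_PER_M2) / effective_density


def core_carbonate(core: SedimentCore, chron: Chronology | None,
                   constants: Constants | None = None) -> CoreCarbonate:
    """Full carbonate accounting for one core.

    With a chronology, CaCO3 %DW and DBD are averaged over the post-1900
    slices (the same window for both, so concentration and burial refer to
    the same sediment) and burial/accretion rates are computed. Without
    one (undated core), all slices enter the averages and rates are None.
    """
    if constants is None:
        constants = Constants()
    if chron is not None:
        mask = post1900_mask(core, chron)
        if not mask.any():
            raise CarbonateError(
                f"core {core.core_id}: no slice younger than 1900 in the chronology")
    else:
        mask = np.ones(core.n_slices, dtype=bool)

    caco3 = mean_caco3_post1900(core, mask)
    dbd = float(np.mean([s.dry_bulk_density for s, m in zip(core.slices, mask) if m]))
    conc = cinorg_concentration(dbd, caco3, constants)

    if chron is None:
        return CoreCarbonate(core.core_id, caco3, dbd, conc, int(mask.sum()))

    cinorg_b = burial_rate(chron.sar, conc)
    caco3_b = caco3_from_cinorg(cinorg_b, constants)
    accr = caco3_accretion(caco3_b, dbd)
    return CoreCarbonate(core.core_id, caco3, dbd, conc, int(mask.sum()),
                         cinorg_burial=cinorg_b, caco3_burial=caco3_b,
                         caco3_accretion=accr)
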