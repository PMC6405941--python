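"""CO2 accounting for carbonate dynamics in Blue Carbon ecosystems.

Calcification is, counterintuitively, a CO2 source: precipitating one
mole of CaCO3 shifts the seawater carbonate system so that ~0.6 mol of
CO2 (the ratio ``psi``) is released to the atmosphere-seawater pool.
Burying carbonate therefore only constitutes an emission to the extent
that the buried CaCO3 was produced *in situ*; carbonate imported from
adjacent reefs or lithogenic sources carries no local CO2 penalty, and
net dissolution of imported carbonate is a CO2 *sink*.

This module implements that accounting: emission from net calcification,
net CO2 sequestration against the uptake by primary production, the
percentage offset, and the burial-vs-calcification mass balance whose gap
is the allochthonous fraction of the buried carbonate. All carbon terms
are in gC m^-2 yr^-1 at site scale and TgC yr^-1 at global scale.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "BudgetTerms",
    "BudgetResult",
    "co2_emission",
    "net_sequestration",
    "offset_fraction",
    "allochthonous_fraction",
    "global_offset",
    "equivalence_ratio",
    "site_budget",
]


@dataclass(frozen=True)
class BudgetTerms:
    """Input terms of a site carbon budget, gC m^-2 yr^-1.

    ``net_calcification_c`` is calcification minus dissolution expressed
    in Cinorg (carbon) units; negative values mean net dissolution.
    ``corg_burial`` is an optional pass-through for burial-based ratios.
    """

    npp_uptake: float
    net_calcification_c: float
    cinorg_burial: float
    corg_burial: float | None = None
    psi: float = 0.6

    def __post_init__(self) -> None:
        if not 0.0 < self.psi < 1.0:
            raise ValueError(f"psi must lie in (0, 1), got {self.psi}")
        if self.cinorg_burial < 0.0:
            raise ValueError("cinorg_burial must be >= 0")


@dataclass(frozen=True)
class BudgetResult:
    """Derived site budget, gC m^-2 yr^-1 except where noted."""

    co2_emission: float
    net_sequestration: float
    offset_pct: float
    allochthonous_fraction: float | None
    classification: str                   # net_sink / net_source / neutral
    local_exceeds_burial: bool = False


def co2_emission(net_calcification_c: float, psi: float = 0.6) -> float:
    """CO2 emission from net calcification, gC m^-2 yr^-1.

    ``psi * net_calcification_c``; a negative net calcification (net
    dissolution) yields a negative emission, i.e. CO2 uptake — the sign
    is propagated, never clamped.
    """
    if not 0.0 < psi < 1.0:
        raise ValueError(f"psi must lie in (0, 1), got {psi}")
    return psi * net_calcification_c


def net_sequestration(npp_uptake: float, emission: float) -> float:
    """Net CO2 sequestration = uptake by primary production - emission."""
    return npp_uptake - emission


def offset_fraction(emission: float, reference_uptake: float) -> float:
    """Emission as a percentage of a reference CO2 uptake."""
    if reference_uptake <= 0.0:
        raise ValueError(f"reference uptake must be positive, got {reference_uptake}")
    return 100.0 * emission / reference_uptake


def allochthonous_fraction(net_calcification_c: float,
                           cinorg_burial: float) -> tuple[float, bool]:
    """Fraction of buried Cinorg that local calcification cannot supply.

    ``1 - max(net_calcification, 0) / burial`` clamped to [0, 1]. Returns
    ``(fraction, flag)`` where the flag marks local production exceeding
    burial (fraction 0; the surplus must be exported or dissolved).
    """
    if cinorg_burial <= 0.0:
        raise ValueError(f"cinorg_burial must be positive, got {cinorg_burial}")
    local = max(net_calcification_c, 0.0)
    frac = 1.0 - local / cinorg_burial
    if frac < 0.0:
        return 0.0, True
    return frac, False


def global_offset(cinorg_burial_tg: tuple[float, float],
                  corg_burial_tg: tuple[float, float],
                  psi: float = 0.6) -> dict:
    """Global emission bounds and offset percentages.

    Treats the global Cinorg burial range as if produced entirely in situ:
    emissions = psi * burial bounds. Offsets pair bounds index-wise (low
    emission over low Corg burial, high over high), the convention under
    which wide, positively-associated ranges give a conservative spread;
    ``envelope=True`` in :func:`equivalence_ratio`-style cross pairing is
    deliberately not the default.

    Returns a dict with ``emission_low/high`` (TgC yr^-1) and
    ``offset_low/high_pct``.
    """
    b_lo, b_hi = cinorg_burial_tg
    c_lo, c_hi = corg_burial_tg
    if b_lo < 0 or b_hi < b_lo:
        raise ValueError("cinorg burial range must satisfy 0 <= low <= high")
    if c_lo <= 0 or c_hi < c_lo:
        raise ValueError("corg burial range must satisfy 0 < low <= high")
    e_lo, e_hi = co2_emission(b_lo, psi), co2_emission(b_hi, psi)
    return {
        "emission_low": e_lo,
        "emission_high": e_hi,
        "offset_low_pct": offset_fraction(e_lo, c_lo),
        "offset_high_pct": offset_fraction(e_hi, c_hi),
    }


def equivalence_ratio(cinorg_tg: tuple[float, float],
                      corg_tg: tuple[float, float]) -> tuple[float, float]:
    """Cinorg burial as % of Corg burial, bound by bound (low/low, high/high)."""
    b_lo, b_hi = cinorg_tg
    c_lo, c_hi = corg_tg
    if b_lo < 0 or b_hi < b_lo:
        raise ValueError("cinorg range must satisfy 0 <= low <= high")
    if c_lo <= 0 or c_hi < c_lo:
        raise ValueError("corg range must satisfy 0 < low <= high")
    return 100.0 * b_lo / c_lo, 100.0 * b_hi / c_hi


def site_budget(terms: BudgetTerms) -> BudgetResult:
    """Full site budget from its input terms.

    Classification follows the sign of the net sequestration; the
    allochthonous fraction is defined only when burial is positive.
    """
    emission = co2_emission(terms.net_calcification_c, terms.psi)
    seq = net_sequestration(terms.npp_uptake, emission)
    offset = offset_fraction(emission, terms.npp_uptake) if terms.npp_uptake > 0 else 0.0
    if terms.cinorg_burial > 0:
        alloch, flag = allochthonous_fraction(terms.net_calcification_c,
                                              terms.cinorg_burial)
    else:
        alloch, flag = None, False
    tol = 1e-9 * max(1.0, abs(terms.npp_uptake))  # float-noise guard
    if seq > tol:
        cls = "net_sink"
    elif seq < -tol:
        cls = "net_source"
    else:
        cls = "neutral"
    return BudgetResult(co2_emission=emission, net_sequestration=seq,
                        offset_pct=offset, allochthonous_fraction=alloch,
                        classification=cls, local_exceeds_burial=flag)
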