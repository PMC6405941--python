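"""Lead-210 chronologies under the constant flux-constant sedimentation model.

The CF:CS model assumes a constant atmospheric flux of unsupported
(excess) lead-210 onto a sediment surface accreting at a constant mass
accumulation rate (MAR, g cm^-2 yr^-1). Excess activity then decays
exponentially with cumulative dry mass m (g cm^-2):

    A_xs(m) = A_xs(0) * exp(-lambda * m / MAR)

so a least-squares fit of ln A_xs on m has slope -lambda/MAR. The sediment
accretion rate (SAR, cm yr^-1) follows by dividing MAR by the mean dry
bulk density of the fitted interval, and the age of a slice at mass depth
m is m / MAR.

The regression is performed on cumulative mass by default; a linear-depth
variant (slope -lambda/SAR) is available for sensitivity checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model import Constants, SedimentCore

__all__ = [
    "Chronology",
    "ChronologyError",
    "estimate_supported",
    "cumulative_mass",
    "fit_cfcs",
    "post1900_mask",
]


class ChronologyError(ValueError):
    """Raised when a CF:CS fit or supported-activity estimate is impossible."""


@dataclass(frozen=True)
class Chronology:
    """Fitted CF:CS result for one core.

    Attributes
    ----------
    mar : float
        Mass accumulation rate, g cm^-2 yr^-1.
    sar : float
        Sediment accretion rate, cm yr^-1.
    surface_excess : float
        Back-transformed regression intercept, Bq kg^-1.
    slope : float
        Regression slope of ln(excess) vs cumulative mass, per g cm^-2
        (vs depth in cm when ``coordinate == "depth"``); negative.
    r_squared : float
    n_points : int
        Number of positive-excess slices used in the fit.
    supported_level : float
        Supported lead-210 subtracted before fitting, Bq kg^-1.
    slice_ages : tuple of float
        Age of each slice midpoint, years before coring (all slices,
        including any excluded from the fit, by model extrapolation).
    slice_years : tuple of float
        Calendar year CE of each slice midpoint.
    coordinate : str
        ``"mass"`` or ``"depth"`` — the regression abscissa.
    supported_warning : bool
        True when the supported level exceeds the smallest total activity
        in the upper half of the profile (possible over-subtraction).
    """

    mar: float
    sar: float
    surface_excess: float
    slope: float
    r_squared: float
    n_points: int
    supported_level: float
    slice_ages: tuple[float, ...]
    slice_years: tuple[float, ...]
    coordinate: str = "mass"
    supported_warning: bool = False


def estimate_supported(core: SedimentCore, method: str = "deep_plateau",
                       n_deep: int = 3) -> float:
    """Estimate the supported lead-210 level of a core, Bq kg^-1.

    ``method="given"`` averages the per-slice supported activities (e.g.
    radium-226 measurements), which must be present on every slice.
    ``method="deep_plateau"`` averages the total activity of the ``n_deep``
    deepest slices, the standard fallback when no radium column exists.
    """
    if method == "given":
        vals = [s.pb210_supported for s in core.slices]
        if any(v is None for v in vals):
            raise ChronologyError(
                f"core {core.core_id}: method='given' requires pb210_supported on every slice")
        return float(np.mean([float(v) for v in vals]))
    if method == "deep_plateau":
        if core.n_slices < n_deep:
            raise ChronologyError(
                f"core {core.core_id}: deep_plateau needs >= {n_deep} slices, "
                f"has {core.n_slices}")
        deepest = sorted(core.slices, key=lambda s: s.depth_top)[-n_deep:]
        return float(np.mean([s.pb210_total for s in deepest]))
    raise ValueError(f"unknown supported-activity method {method!r}")


def cumulative_mass(core: SedimentCore) -> np.ndarray:
    """Cumulative dry mass above each slice midpoint, g cm^-2.

    m_i = sum of DBD * thickness over shallower slices
          + DBD_i * (midpoint_i - top_i).

    Gaps between slices contribute no mass (their density is unknown);
    the result is strictly increasing regardless.
    """
    masses = np.empty(core.n_slices)
    acc = 0.0
    for i, s in enumerate(core.slices):
        masses[i] = acc + s.dry_bulk_density * (s.midpoint - s.depth_top)
        acc += s.dry_bulk_density * s.thickness
    return masses


def fit_cfcs(core: SedimentCore, constants: Constants | None = None,
             supported: float | None = None, coordinate: str = "mass",
             weighted: bool = False) -> Chronology:
    """Fit the CF:CS model to a core's excess lead-210 profile.

    Parameters
    ----------
    core
        The core; at least 3 slices with positive excess activity.
    constants
        Physical constants; defaults to :class:`Constants`.
    supported
        Supported activity to subtract, Bq kg^-1. When None it is
        estimated with :func:`estimate_supported` — from the per-slice
        supported column when complete, otherwise from the deep plateau.
    coordinate
        ``"mass"`` (default) regresses ln(excess) on cumulative mass and
        derives SAR through the mass-weighted mean dry bulk density of the
        fitted slices; ``"depth"`` regresses on midpoint depth and derives
        MAR through the same mean density.
    weighted
        If True, weight the regression by inverse relative variance of the
        activities (requires ``pb210_total_err``); default is ordinary
        least squares.

    Raises
    ------
    ChronologyError
        Fewer than 3 positive-excess slices, or a non-negative slope
        (no decay trend).
    """
    if constants is None:
        constants = Constants()
    if coordinate not in ("mass", "depth"):
        raise ValueError(f"coordinate must be 'mass' or 'depth', got {coordinate!r}")
    if supported is None:
        if all(s.pb210_supported is not None for s in core.slices):
            supported = estimate_supported(core, "given")
        else:
            supported = estimate_supported(core, "deep_plateau",
                                           n_deep=min(3, core.n_slices))

    totals = np.array([s.pb210_total for s in core.slices])
    masses = cumulative_mass(core)
    depths = np.array([s.midpoint for s in core.slices])
    x_all = masses if coordinate == "mass" else depths

    excess = totals - supported
    use = excess > 0.0
    if int(use.sum()) < 3:
        raise ChronologyError(
            f"core {core.core_id}: only {int(use.sum())} slices with positive excess "
            f"(supported = {supported:.3g} Bq/kg); need >= 3 for a CF:CS fit")

    x, y = x_all[use], np.log(excess[use])
    if weighted:
        errs = np.array([s.pb210_total_err for s in core.slices], dtype=float)[use]
        if np.any(~np.isfinite(errs)) or np.any(errs <= 0):
            raise ChronologyError(
                f"core {core.core_id}: weighted fit requires positive pb210_total_err")
        # var(ln A) ~ (sigma_A / A)^2 by the delta method
        w = (excess[use] / errs) ** 2
        W = np.sum(w)
        xb, yb = np.sum(w * x) / W, np.sum(w * y) / W
        sxx = np.sum(w * (x - xb) ** 2)
        slope = float(np.sum(w * (x - xb) * (y - yb)) / sxx)
        intercept = float(yb - slope * xb)
        ss_res = np.sum(w * (y - (intercept + slope * x)) ** 2)
        ss_tot = np.sum(w * (y - yb) ** 2)
        r2 = float(1.0 - ss_res / ss_tot) if ss_tot > 0 else 1.0
    else:
        res = stats.linregress(x, y)
        slope, intercept = float(res.slope), float(res.intercept)
        r2 = float(res.rvalue ** 2)

    if slope >= 0.0:
        raise ChronologyError(
            f"core {core.core_id}: no decay trend (slope = {slope:.3g} >= 0)")

    # mean DBD of the fitted slices, weighted by their dry mass per area
    sl_mass = np.array([s.dry_bulk_density * s.thickness for s in core.slices])[use]
    dbd = np.array([s.dry_bulk_density for s in core.slices])[use]
    mean_dbd = float(np.sum(dbd * sl_mass) / np.sum(sl_mass))

    lam = constants.lambda_pb210
    if coordinate == "mass":
        mar = lam / abs(slope)
        sar = mar / mean_dbd
    else:
        sar = lam / abs(slope)
        mar = sar * mean_dbd

    ages = masses / mar  # model extrapolation covers excluded slices too
    years = float(core.coring_year) - ages

    upper = totals[: max(1, core.n_slices // 2)]
    warn = bool(supported > np.min(upper))

    return Chronology(
        mar=float(mar), sar=float(sar),
        surface_excess=float(math.exp(intercept)),
        slope=slope, r_squared=r2, n_points=int(use.sum()),
        supported_level=float(supported),
        slice_ages=tuple(float(a) for a in ages),
        slice_years=tuple(float(y) for y in years),
        coordinate=coordinate, supported_warning=warn,
    )


def post1900_mask(core: SedimentCore, chron: Chronology) -> np.ndarray:
    """Boolean per slice: midpoint deposited in calendar year >= 1900."""
    return np.array([y >= 1900.0 for y in chron.slice_years])
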