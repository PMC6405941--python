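"""Effect sizes and group comparisons for vegetated-vs-unvegetated contrasts.

Hedges' g is the standardized mean difference between an experimental
(vegetated) and a control (unvegetated) group with the small-sample bias
correction J:

    g  = (X_E - X_C) * J / SD_pooled
    SD_pooled = sqrt(((n_E-1) SD_E^2 + (n_C-1) SD_C^2) / (n_E + n_C - 2))
    J  = 1 - 3 / (4 (n_E + n_C - 2) - 1)
    V_g = (n_E + n_C) / (n_E n_C) + g^2 / (2 (n_E + n_C))

Per-study effects are pooled with standard DerSimonian-Laird
random-effects weighting; a Mann-Whitney U test serves as the
nonparametric group comparison for the strongly non-normal carbonate
distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GroupStats",
    "EffectSize",
    "PooledEffect",
    "EffectSizeError",
    "hedges_g",
    "pool_random_effects",
    "mann_whitney",
    "paired_vegetation_contrast",
]


class EffectSizeError(ValueError):
    """Raised when an effect size is undefined for the given groups."""


@dataclass(frozen=True)
class GroupStats:
    """Summary statistics of one group: mean, SD and sample size.

    Single-core groups (n = 1) are representable — their SD is NaN — but
    carry no variance and are excluded from effect-size computation.
    """

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise EffectSizeError(f"group needs n >= 1, got n={self.n}")
        if self.n >= 2 and not self.sd >= 0:
            raise EffectSizeError(f"sd must be >= 0 when n >= 2, got {self.sd}")

    @classmethod
    def from_sample(cls, values: Sequence[float]) -> "GroupStats":
        arr = np.asarray(values, dtype=float)
        sd = float(arr.std(ddof=1)) if arr.size >= 2 else float("nan")
        return cls(mean=float(arr.mean()), sd=sd, n=int(arr.size))


@dataclass(frozen=True)
class EffectSize:
    """Hedges' g with its variance and intermediates for one study."""

    g: float
    v_g: float
    sd_pooled: float
    j: float
    study_id: str = ""


@dataclass(frozen=True)
class PooledEffect:
    """Random-effects pooled effect across k studies."""

    g_pooled: float
    se_pooled: float
    z_value: float
    p_value: float
    tau2: float
    k: int


def hedges_g(exp: GroupStats, ctrl: GroupStats, study_id: str = "") -> EffectSize:
    """Hedges' g of the experimental group relative to the control.

    Raises :class:`EffectSizeError` when either group is single-core or
    the pooled SD is zero (both groups constant), where the standardized
    difference is undefined.
    """
    if exp.n < 2 or ctrl.n < 2:
        raise EffectSizeError("both groups need n >= 2 for Hedges' g")
    n_e, n_c = exp.n, ctrl.n
    df = n_e + n_c - 2
    sd_pooled = math.sqrt(((n_e - 1) * exp.sd**2 + (n_c - 1) * ctrl.sd**2) / df)
    if sd_pooled == 0.0:
        raise EffectSizeError("pooled SD is zero; effect size undefined")
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    g = (exp.mean - ctrl.mean) * j / sd_pooled
    v_g = (n_e + n_c) / (n_e * n_c) + g**2 / (2.0 * (n_e + n_c))
    return EffectSize(g=g, v_g=v_g, sd_pooled=sd_pooled, j=j, study_id=study_id)


def pool_random_effects(effects: Sequence[EffectSize]) -> PooledEffect:
    """DerSimonian-Laird random-effects pooling of per-study effects.

    The between-study variance tau^2 is the DL moment estimator
    ``max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w))`` with fixed-effect
    weights ``w = 1/V_g``; studies are then reweighted by
    ``1/(V_g + tau^2)``. The z test is two-sided against the standard
    normal. With k = 1 the result degenerates to the single study.
    """
    if len(effects) < 1:
        raise EffectSizeError("need at least one study to pool")
    g = np.array([e.g for e in effects])
    v = np.array([e.v_g for e in effects])
    k = len(effects)
    w = 1.0 / v
    g_fixed = np.sum(w * g) / np.sum(w)
    q = float(np.sum(w * (g - g_fixed) ** 2))
    if k > 1:
        c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
        tau2 = max(0.0, (q - (k - 1)) / c)
    else:
        tau2 = 0.0
    w_star = 1.0 / (v + tau2)
    g_pooled = float(np.sum(w_star * g) / np.sum(w_star))
    se = float(1.0 / math.sqrt(np.sum(w_star)))
    z = g_pooled / se
    p = 2.0 * stats.norm.sf(abs(z))
    return PooledEffect(g_pooled=g_pooled, se_pooled=se, z_value=float(z),
                        p_value=float(p), tau2=float(tau2), k=k)


def mann_whitney(a: Sequence[float], b: Sequence[float],
                 alternative: str = "two-sided",
                 method: str = "auto") -> tuple[float, float]:
    """Mann-Whitney U test of two samples.

    Returns ``(U, p)`` with U the statistic of the first sample. With
    ``method="auto"`` the p-value comes from exact enumeration of the
    rank distribution for small tie-free samples (n_a + n_b <= 12) and
    from the tie-corrected, continuity-corrected normal approximation
    otherwise; ``"exact"``/``"asymptotic"`` force one path.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if method == "auto":
        has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
        method = "exact" if (a.size + b.size <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def paired_vegetation_contrast(
    studies: Sequence[tuple[str, GroupStats, GroupStats]],
) -> PooledEffect:
    """Pooled vegetated-vs-unvegetated effect over paired studies.

    Each study supplies ``(study_id, vegetated, unvegetated)`` group
    statistics. Studies where either habitat has a single core carry no
    SD and are excluded before pooling, as are studies whose pooled SD is
    zero; the returned ``k`` counts the studies that survived.
    """
    effects = []
    for study_id, veg, unveg in studies:
        if veg.n < 2 or unveg.n < 2:
            continue
        try:
            effects.append(hedges_g(veg, unveg, study_id=study_id))
        except EffectSizeError:
            continue
    if not effects:
        raise EffectSizeError("no study with computable effect size (all groups "
                              "single-core or zero-variance)")
    return pool_random_effects(effects)
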