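"""Effect sizes, random-effects pooling and the Mann-Whitney comparison."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bluecarb import (GroupStats, hedges_g, mann_whitney,
                      paired_vegetation_contrast, pool_random_effects)
from bluecarb.effects import EffectSizeError


def brute_force_effect(xe, xc, sde, sdc, ne, nc):
    """Independent re-evaluation of the printed effect-size formulas."""
    sd_pooled = math.sqrt(((ne - 1) * sde**2 + (nc - 1) * sdc**2) / (ne + nc - 2))
    j = 1 - 3 / (4 * (ne + nc - 2) - 1)
    g = (xe - xc) * j / sd_pooled
    v_g = (ne + nc) / (ne * nc) + g**2 / (2 * (ne + nc))
    return g, v_g, sd_pooled, j


def _enumerate_u(a, b):
    """U of the first group and the full permutation distribution of U."""
    pooled = np.concatenate([a, b])
    n_a = len(a)

    def u_of(idx):
        ga = pooled[list(idx)]
        gb = np.delete(pooled, list(idx))
        return sum((x > y) + 0.5 * (x == y) for x in ga for y in gb)

    u_obs = u_of(range(n_a))
    us = np.asarray([u_of(c)
                     for c in itertools.combinations(range(len(pooled)), n_a)])
    return u_obs, us


def exact_mw_two_sided_p(a, b):
    """Exact two-sided Mann-Whitney p by full enumeration of assignments."""
    u_obs, us = _enumerate_u(a, b)
    return min(1.0, 2 * min(np.mean(us <= u_obs), np.mean(us >= u_obs)))


def exact_mw_less_p(a, b):
    """Exact one-sided (first group stochastically smaller) p by enumeration."""
    u_obs, us = _enumerate_u(a, b)
    return float(np.mean(us <= u_obs))


class TestHedgesG:
    def test_hand_computed_example(self):
        e = hedges_g(GroupStats(10, 2, 5), GroupStats(8, 2, 5))
        assert e.sd_pooled == pytest.approx(2.0)
        assert e.j == pytest.approx(1 - 3 / 31)
        assert e.g == pytest.approx(0.90323, rel=1e-4)
        assert e.v_g == pytest.approx(0.4 + e.g**2 / 20, rel=1e-12)

    def test_equal_means_zero_effect(self):
        e = hedges_g(GroupStats(5, 1, 7), GroupStats(5, 3, 4))
        assert e.g == 0.0
        assert e.v_g == pytest.approx((7 + 4) / (7 * 4))

    def test_antisymmetry(self):
        a, b = GroupStats(12.0, 3.0, 6), GroupStats(9.0, 2.0, 8)
        assert hedges_g(a, b).g == pytest.approx(-hedges_g(b, a).g)
        assert hedges_g(a, b).v_g == pytest.approx(hedges_g(b, a).v_g)

    def test_zero_pooled_sd_undefined(self):
        with pytest.raises(EffectSizeError, match="pooled SD"):
            hedges_g(GroupStats(5, 0, 5), GroupStats(4, 0, 5))

    def test_single_core_group_rejected(self):
        with pytest.raises(EffectSizeError, match="n >= 2"):
            hedges_g(GroupStats(5, float("nan"), 1), GroupStats(4, 1, 5))

    @given(st.integers(3, 200), st.integers(3, 200))
    @settings(max_examples=50, derandomize=True)
    def test_j_approaches_one(self, ne, nc):
        e = hedges_g(GroupStats(1, 1, ne), GroupStats(0, 1, nc))
        assert 0 < e.j < 1
        big = hedges_g(GroupStats(1, 1, 10 * ne), GroupStats(0, 1, 10 * nc))
        assert abs(1 - big.j) < abs(1 - e.j)


class TestPooling:
    def test_single_study_degenerates(self):
        e = hedges_g(GroupStats(10, 2, 5), GroupStats(8, 2, 5))
        p = pool_random_effects([e])
        assert p.g_pooled == pytest.approx(e.g)
        assert p.se_pooled == pytest.approx(math.sqrt(e.v_g))
        assert p.z_value == pytest.approx(e.g / math.sqrt(e.v_g))
        assert p.tau2 == 0.0 and p.k == 1

    def test_homogeneous_studies(self):
        e = hedges_g(GroupStats(10, 2, 5), GroupStats(8, 2, 5))
        p = pool_random_effects([e, e])
        assert p.g_pooled == pytest.approx(e.g)
        assert p.tau2 == 0.0

    def test_matches_statsmodels_dl(self):
        """Cross-check the DerSimonian-Laird pooling against statsmodels.

        Heterogeneous true effects keep the moment estimate of tau^2
        positive, where the truncated (standard) and untruncated
        (statsmodels) DL estimators coincide.
        """
        from statsmodels.stats.meta_analysis import combine_effects
        rng = np.random.default_rng(8)
        effects = []
        for _ in range(6):
            delta = rng.normal(0.5, 0.6)
            effects.append(hedges_g(GroupStats.from_sample(rng.normal(delta, 1, 15)),
                                    GroupStats.from_sample(rng.normal(0.0, 1, 12))))
        mine = pool_random_effects(effects)
        res = combine_effects(np.array([e.g for e in effects]),
                              np.array([e.v_g for e in effects]),
                              method_re="dl")
        assert res.tau2 > 0
        assert mine.g_pooled == pytest.approx(res.mean_effect_re, rel=1e-10)
        assert mine.tau2 == pytest.approx(res.tau2, rel=1e-10)
        assert mine.se_pooled == pytest.approx(res.sd_eff_w_re, rel=1e-10)

    def test_truncates_negative_moment_estimate(self):
        # homogeneous-beyond-chance effects: raw DL moment estimate < 0
        effects = [hedges_g(GroupStats(0.5 + 0.01 * i, 1.0, 20),
                            GroupStats(0.0, 1.0, 20)) for i in range(4)]
        assert pool_random_effects(effects).tau2 == 0.0


class TestMannWhitney:
    def test_identical_constant_groups(self):
        u, p = mann_whitney([3, 3, 3, 3], [3, 3, 3])
        assert u == 4 * 3 / 2
        assert p > 0.99

    def test_fully_separated_small_groups(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # exact: 2/20

    def test_enumeration_oracle_matches_exact_path(self):
        rng = np.random.default_rng(17)
        a, b = rng.normal(size=5), rng.normal(1.0, 1.0, size=4)
        _, p = mann_whitney(a, b, method="exact")
        assert p == pytest.approx(exact_mw_two_sided_p(a, b), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(23)
        a, b = rng.normal(size=8), rng.normal(0.7, 1.2, size=9)
        u1, p1 = mann_whitney(a, b)
        u2, p2 = mann_whitney(np.exp(a), np.exp(b))
        assert (u1, p1) == (u2, p2)


class TestPairedContrast:
    @staticmethod
    def _study(rng, sid, n_unveg=5):
        veg = GroupStats.from_sample(rng.normal(50, 10, 6))
        unveg = GroupStats.from_sample(rng.normal(50, 10, n_unveg))
        return sid, veg, unveg

    def test_single_core_studies_excluded(self):
        rng = np.random.default_rng(4)
        studies = [self._study(rng, f"s{i}") for i in range(7)]
        studies += [self._study(rng, "s7", n_unveg=1), self._study(rng, "s8", n_unveg=1)]
        pooled = paired_vegetation_contrast(studies)
        assert pooled.k == 7

    def test_identical_means_null(self):
        studies = [(f"s{i}", GroupStats(40.0, 5.0, 6), GroupStats(40.0, 5.0, 6))
                   for i in range(5)]
        pooled = paired_vegetation_contrast(studies)
        assert pooled.g_pooled == 0.0
        assert pooled.p_value == pytest.approx(1.0)

    def test_no_usable_study_errors(self):
        with pytest.raises(EffectSizeError):
            paired_vegetation_contrast(
                [("s0", GroupStats(1.0, float("nan"), 1), GroupStats(2.0, 1.0, 5))])
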