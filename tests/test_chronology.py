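"""CF:CS chronology: supported-activity estimation, mass depth, model fits."""

import numpy as np
import pytest

from bluecarb import Constants, cumulative_mass, estimate_supported, fit_cfcs, post1900_mask
from bluecarb.chronology import ChronologyError

from conftest import exact_cfcs_core, make_core

LAM = Constants().lambda_pb210


class TestEstimateSupported:
    def test_deep_plateau_mean_of_deepest(self):
        core = make_core([210, 110, 60, 35, 26, 25, 25])
        assert estimate_supported(core, "deep_plateau", n_deep=2) == 25

    def test_given_uses_supported_column(self):
        core = make_core([210, 110, 60, 35])
        slices = tuple(
            type(s)(**{**s.__dict__, "pb210_supported": 20.0}) for s in core.slices
        )
        core = core.with_slices(slices)
        assert estimate_supported(core, "given") == 20

    def test_given_requires_all_slices(self):
        core = make_core([210, 110, 60])
        with pytest.raises(ChronologyError, match="given"):
            estimate_supported(core, "given")

    def test_too_few_slices(self):
        core = make_core([210, 110])
        with pytest.raises(ChronologyError, match="deep_plateau"):
            estimate_supported(core, "deep_plateau", n_deep=3)

    def test_flat_profile_kills_downstream_fit(self):
        core = make_core([30.0] * 6)
        supported = estimate_supported(core, "deep_plateau", n_deep=3)
        assert supported == 30
        with pytest.raises(ChronologyError, match="positive excess"):
            fit_cfcs(core, supported=supported)


class TestCumulativeMass:
    def test_uniform_unit_density(self):
        core = make_core([100, 80, 60, 40], dbd=1.0, thickness=1.0)
        assert cumulative_mass(core) == pytest.approx([0.5, 1.5, 2.5, 3.5])

    def test_varying_density_hand_computation(self):
        # DBD {0.5, 1.0}, 2-cm slices: m1 = 0.5*1 = 0.5; m2 = 0.5*2 + 1.0*1 = 2.0
        core = make_core([100, 60], dbd=[0.5, 1.0], thickness=2.0)
        assert cumulative_mass(core) == pytest.approx([0.5, 2.0])

    def test_strictly_increasing(self):
        rng = np.random.default_rng(3)
        core = make_core(rng.uniform(20, 200, 15), dbd=rng.uniform(0.3, 2.0, 15))
        m = cumulative_mass(core)
        assert np.all(np.diff(m) > 0)


class TestFitCfcs:
    def test_exact_recovery_noiseless(self):
        core = exact_cfcs_core(mar=0.10, supported=0.0)
        ch = fit_cfcs(core, supported=0.0)
        assert ch.mar == pytest.approx(0.10, rel=1e-6)
        assert ch.sar == pytest.approx(0.10, rel=1e-6)  # DBD = 1
        assert ch.r_squared == pytest.approx(1.0, abs=1e-12)
        assert ch.surface_excess == pytest.approx(500.0, rel=1e-6)

    def test_closed_form_slope(self):
        # excess(m) = 100 exp(-lam m / 0.05): slope must equal -lam/0.05
        core = exact_cfcs_core(mar=0.05, surface_excess=100.0, n_slices=5)
        ch = fit_cfcs(core, supported=0.0)
        assert ch.slope == pytest.approx(-LAM / 0.05, rel=1e-9)
        assert ch.mar == pytest.approx(0.05, rel=1e-9)

    @pytest.mark.parametrize("mar", [0.01, 0.1, 0.5, 2.0])
    def test_exact_recovery_any_mar(self, mar):
        core = exact_cfcs_core(mar=mar, supported=10.0)
        ch = fit_cfcs(core, supported=10.0)
        assert ch.mar == pytest.approx(mar, rel=1e-6)

    def test_scale_equivariance(self):
        core = exact_cfcs_core(mar=0.2, supported=0.0)
        scaled = core.with_slices(
            type(s)(**{**s.__dict__, "pb210_total": 7.0 * s.pb210_total})
            for s in core.slices)
        ch, chs = fit_cfcs(core, supported=0.0), fit_cfcs(scaled, supported=0.0)
        assert chs.mar == pytest.approx(ch.mar, rel=1e-9)
        assert chs.sar == pytest.approx(ch.sar, rel=1e-9)
        assert chs.surface_excess == pytest.approx(7.0 * ch.surface_excess, rel=1e-9)

    def test_ages_increase_with_depth(self):
        core = exact_cfcs_core(mar=0.15, supported=5.0)
        ch = fit_cfcs(core, supported=5.0)
        assert np.all(np.diff(ch.slice_ages) > 0)
        assert np.all(np.asarray(ch.slice_years) == core.coring_year - np.asarray(ch.slice_ages))

    def test_increasing_profile_is_no_decay_trend(self):
        core = make_core([30, 40, 60, 90, 140])
        with pytest.raises(ChronologyError, match="no decay trend"):
            fit_cfcs(core, supported=0.0)

    def test_excess_nonpositive_excluded_but_aged(self):
        core = exact_cfcs_core(mar=0.10, supported=25.0, n_slices=20)
        # subtracting a too-high supported level zeroes out the deep slices
        ch = fit_cfcs(core, supported=30.0)
        assert ch.n_points < core.n_slices
        assert len(ch.slice_ages) == core.n_slices

    def test_depth_coordinate_matches_on_uniform_density(self):
        core = exact_cfcs_core(mar=0.10, supported=0.0)
        chm = fit_cfcs(core, supported=0.0, coordinate="mass")
        chd = fit_cfcs(core, supported=0.0, coordinate="depth")
        assert chd.sar == pytest.approx(chm.sar, rel=1e-9)
        assert chd.mar == pytest.approx(chm.mar, rel=1e-9)

    def test_weighted_fit_matches_on_noiseless(self):
        core = exact_cfcs_core(mar=0.10, supported=0.0)
        core = core.with_slices(
            type(s)(**{**s.__dict__, "pb210_total_err": 0.05 * s.pb210_total})
            for s in core.slices)
        chw = fit_cfcs(core, supported=0.0, weighted=True)
        assert chw.mar == pytest.approx(0.10, rel=1e-6)


class TestPost1900Mask:
    def test_recent_vs_old(self):
        # MAR 0.05, unit DBD: midpoint masses {1, 3, ...} -> ages {20, 60, ...}
        exact = exact_cfcs_core(mar=0.05, n_slices=8, thickness=2.0, coring_year=2000)
        ch = fit_cfcs(exact, supported=0.0)
        mask = post1900_mask(exact, ch)
        ages = np.asarray(ch.slice_ages)
        assert np.array_equal(mask, (2000 - ages) >= 1900)
        assert mask[0] and not mask[-1]

    def test_all_recent(self):
        core = exact_cfcs_core(mar=1.0, coring_year=2010)
        ch = fit_cfcs(core, supported=0.0)
        assert post1900_mask(core, ch).all()
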