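import numpy as np
import pytest

from bluecarb import Constants, CoreScenario, CoreSlice, SedimentCore


@pytest.fixture(scope="session")
def constants() -> Constants:
    return Constants()


def make_core(totals, dbd=1.0, thickness=2.0, caco3=50.0, coring_year=2015,
              core_id="c1", ecosystem="seagrass", **kwargs):
    """Hand-built core with uniform slice geometry."""
    totals = np.atleast_1d(np.asarray(totals, dtype=float))
    dbd = np.broadcast_to(np.asarray(dbd, dtype=float), totals.shape)
    caco3 = np.broadcast_to(np.asarray(caco3, dtype=float), totals.shape)
    slices = tuple(
        CoreSlice(depth_top=i * thickness, depth_bottom=(i + 1) * thickness,
                  dry_bulk_density=float(dbd[i]), pb210_total=float(t),
                  caco3_pct=float(caco3[i]))
        for i, t in enumerate(totals)
    )
    defaults = dict(latitude=39.5, longitude=2.9, location_key="site-1")
    defaults.update(kwargs)
    return SedimentCore(core_id=core_id, ecosystem=ecosystem,
                        coring_year=coring_year, slices=slices, **defaults)


def exact_cfcs_core(mar=0.10, dbd=1.0, supported=0.0, surface_excess=500.0,
                    n_slices=10, thickness=1.0, constants=Constants(), **kwargs):
    """Core whose activities follow the CF:CS model exactly (no noise)."""
    lam = constants.lambda_pb210
    tops = np.arange(n_slices) * thickness
    mids = tops + 0.5 * thickness
    masses = dbd * mids  # uniform density: cumulative mass above midpoint
    totals = supported + surface_excess * np.exp(-lam * masses / mar)
    return make_core(totals, dbd=dbd, thickness=thickness, **kwargs)


@pytest.fixture
def noiseless_core():
    return exact_cfcs_core()


@pytest.fixture
def noiseless_scenario():
    return CoreScenario(noise_cv=0.0)
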