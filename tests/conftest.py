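import numpy as np
import pytest

from connectokin.cohort_io import ScanTimeSeries
from connectokin.preprocess import PreprocessConfig, preprocess_scan
from connectokin import synthetic as syn


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260918)


@pytest.fixture(scope="session")
def small_spec():
    """Tiny family-structured cohort used across modules."""
    return syn.SyntheticSpec(
        family_templates=(("MZ", 2), ("DZ", 2), ("sib", 4), ("singleton", 4)),
        M=12, frames=120, seed=7)


@pytest.fixture(scope="session")
def small_sim(small_spec):
    return syn.simulate_cohort(small_spec)


@pytest.fixture(scope="session")
def no_filter_cfg():
    """Preprocessing for synthetic data: AR(1) prewhitening only."""
    return PreprocessConfig(profile="custom", do_censor=False, do_filter=False,
                            ar_order=1)


@pytest.fixture(scope="session")
def small_residuals(small_sim, no_filter_cfg):
    return {sid: preprocess_scan(ts, cfg=no_filter_cfg)[0]
            for sid, ts in small_sim.timeseries.items()}


def random_ts(rng, frames=80, m=6, tr=2.0):
    return ScanTimeSeries(data=rng.standard_normal((frames, m)), tr=tr)
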