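import dataclasses

import numpy as np
import pytest

from rsnet import Band, CohortSpec, Recording, TopologySpec
from rsnet.pipeline import fast_demo_config


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(data, fs=256.0, reference="common-average", **kw):
    """Recording with generic channel labels for signal-level tests."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    names = kw.pop("channel_names",
                   [f"ch{i}" for i in range(data.shape[0])])
    return Recording(data=data, fs=fs, channel_names=names,
                     reference=reference, **kw)


def sinusoid(freq, fs, duration, phase=0.0, amp=1.0):
    t = np.arange(int(round(fs * duration))) / fs
    return amp * np.sin(2 * np.pi * freq * t + phase)


@pytest.fixture(scope="session")
def tiny_cohort_config():
    """3 subjects x 2 conditions, reduced scale: quick end-to-end runs."""
    cfg = fast_demo_config(seed=7, n_subjects=3, n_epochs=4)
    cohort = dataclasses.replace(cfg.cohort, conditions=("PRE", "ACUTE3"))
    return dataclasses.replace(cfg, cohort=cohort, compute_power=True)


def small_cohort_spec(**kw):
    """Valid small spec: 8 sources (9-channel montage), theta band only."""
    defaults = dict(
        n_subjects=1, conditions=("PRE",), duration_s=48.0, fs=128.0,
        n_channels=9,
        band_specs={"theta": TopologySpec(8, k=2,
                                          band=Band("theta", 4.0, 8.0))},
        seed=11,
    )
    band_kw = kw.pop("band_kw", {})
    defaults.update(kw)
    if band_kw:
        defaults["band_specs"] = {
            "theta": dataclasses.replace(defaults["band_specs"]["theta"],
                                         **band_kw)}
    return CohortSpec(**defaults)
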