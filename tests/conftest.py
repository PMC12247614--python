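import numpy as np
import pytest

import dianasim as ds

TARGET_TSNR = 350.0


@pytest.fixture(scope="session")
def params():
    return ds.SequenceParams()


@pytest.fixture(scope="session")
def plan(params):
    return ds.build_sampling_plan(params)


@pytest.fixture(scope="session")
def phantom_rois():
    return ds.build_phantom(seed=0)


@pytest.fixture(scope="session")
def phantom(phantom_rois):
    return phantom_rois[0]


@pytest.fixture(scope="session")
def rois(phantom_rois):
    return phantom_rois[1]


@pytest.fixture(scope="session")
def split(phantom, rois):
    return ds.split_kspace(phantom, rois)


@pytest.fixture(scope="session")
def noise(phantom, rois, plan):
    """Noise model calibrated once per session to the study's target tSNR."""
    return ds.calibrate_noise_sigma(TARGET_TSNR, phantom, rois, plan, seed=11)


@pytest.fixture(scope="session")
def mini():
    """Small 16x16 setup for fast structural tests."""
    p = ds.SequenceParams(n_pe=16, n_timepoints=8, stim_onset_ms=10.0, stim_dur_ms=5.0)
    spec = ds.ROISpec(active_center=(8.0, 8.0), control_center=(4.0, 4.0), radius=1.4)
    phantom, rois = ds.build_phantom((16, 16), spec, seed=3)
    return {
        "params": p,
        "plan": ds.build_sampling_plan(p),
        "phantom": phantom,
        "rois": rois,
        "split": ds.split_kspace(phantom, rois),
        "resp": ds.DianaResponse(onset_after_stim_end_ms=5.0, duration_ms=5.0),
    }
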