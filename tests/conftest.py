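import numpy as np
import pytest

import footmech as fm
from footmech.config import PipelineConfig


@pytest.fixture()
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def nofilter_config():
    cfg = PipelineConfig()
    cfg.filters.marker_cutoff_hz = None
    return cfg


@pytest.fixture(scope="session")
def clean_trial(nofilter_config):
    """Noise-free default running trial (bundle, truth)."""
    spec = fm.SyntheticTrialSpec(noise_sigma=0.0)
    return fm.generate_running_trial(spec, nofilter_config)


@pytest.fixture(scope="session")
def clean_multi_kinematics(clean_trial, nofilter_config):
    bundle, _ = clean_trial
    model = fm.make_model("MULTI", nofilter_config)
    return fm.compute_trial_kinematics(bundle, model, nofilter_config)


@pytest.fixture(scope="session")
def study_bundles():
    """Seven synthetic subjects under the default study conditions."""
    cfg = PipelineConfig()
    return [fm.generate_running_trial(s, cfg)[0] for s in fm.study_specs(7, seed=0)]


def random_rotations(rng, n):
    """Uniform random rotations (n, 3, 3) via normalised quaternions."""
    q = rng.standard_normal((n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    w, x, y, z = q.T
    return np.stack([
        np.stack([1 - 2 * (y**2 + z**2), 2 * (x * y - z * w), 2 * (x * z + y * w)], -1),
        np.stack([2 * (x * y + z * w), 1 - 2 * (x**2 + z**2), 2 * (y * z - x * w)], -1),
        np.stack([2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x**2 + y**2)], -1),
    ], axis=-2)
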