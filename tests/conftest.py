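import numpy as np
import pytest

import electrovar as ev


@pytest.fixture(scope="session")
def montage():
    return ev.default_montage()


@pytest.fixture(scope="session")
def head():
    return ev.DEFAULT_HEAD


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def noiseless_cohort_dir(tmp_path_factory):
    """A fully degenerate 4-subject cohort on disk (identical heads, no noise)."""
    out = tmp_path_factory.mktemp("noiseless_cohort")
    config = ev.SimulationConfig.noiseless(seed=3, n_subjects=4)
    manifest = ev.simulate_cohort(config, out, mask_shape=(72, 84, 72), mask_voxel_mm=2.5)
    return out, manifest, config


def make_point(label="CZ", coord=(0.0, 0.0, 100.0), subject="s00",
               surface=ev.SCALP, space="mni"):
    return ev.ElectrodePoint(subject, label, surface, space, np.asarray(coord, dtype=float))
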