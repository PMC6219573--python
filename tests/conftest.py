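import numpy as np
import pytest

from phasedect.pipeline import PipelineConfig, run_all
from phasedect.recon import bath_annulus_mask


@pytest.fixture(scope="session")
def noiseless_run(tmp_path_factory):
    """One noiseless end-to-end benchmark-phantom run, shared by the suite.

    Returns (config, products, roi_rows, slice_pair, output_dir).
    """
    from phasedect.io import read_slice_pair

    out = tmp_path_factory.mktemp("noiseless_run")
    cfg = PipelineConfig(noise=False, seed=7)
    products, rows = run_all(cfg, out)
    pair = read_slice_pair(out / "slice_pair.h5")
    return cfg, products, rows, pair, out


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def water_disk_mask():
    """Interior mask (r <= 10 mm) of the default 256 x 160 um grid."""
    return bath_annulus_mask(256, 160.0, 0.0, 10.0)
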