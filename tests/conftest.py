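import numpy as np
import pytest

from hfus_iqa import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small synthetic dataset shared by the cheaper integration tests."""
    cfg = SyntheticConfig(n_frames=120, seed=11)
    frames, triples = generate_dataset(cfg)
    X = np.stack([f.pixels for f in frames])
    return cfg, frames, triples, X


@pytest.fixture(scope="session")
def dataset_dir(tmp_path_factory):
    """The same kind of dataset written in the on-disk session layout."""
    root = tmp_path_factory.mktemp("hfus_synth")
    cfg = SyntheticConfig(n_frames=60, seed=5, session_ids=("08032021", "15022021"))
    frames, triples = generate_dataset(cfg, out_dir=root)
    return root, frames, triples
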