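import numpy as np
import pytest

from seizurenet.records import EEGRecord
from seizurenet.synthetic import generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """10 records/class, full Bonn record length, fixed seed."""
    return generate_dataset(n_per_class=10, n_points=4097, seed=11)


@pytest.fixture()
def tone_record():
    """A 10 Hz passband tone at the Bonn sampling rate."""
    fs = 173.61
    t = np.arange(4097) / fs
    return EEGRecord(np.sin(2 * np.pi * 10 * t), fs=fs, set_id="A",
                     source_id="tone10")


@pytest.fixture()
def bonn_dir(tmp_path):
    """Tiny Bonn-layout directory: 3 records per set."""
    from seizurenet.synthetic import write_bonn_layout

    records = generate_dataset(n_per_class=3, n_points=512, seed=5)
    write_bonn_layout(records, tmp_path)
    return tmp_path
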