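import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from repeatquant import RoiMask, SubjectRecord, ValueKind, VolumeImage


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


def make_volume(values, spacing=(2.0, 2.0, 2.0), kind=ValueKind.SUV):
    return VolumeImage(np.asarray(values, dtype=float), spacing, kind)


def make_mask(mask, spacing=(2.0, 2.0, 2.0)):
    return RoiMask(np.asarray(mask, dtype=bool), spacing)


def random_volume_and_mask(rng, shape=(10, 10, 10), spacing=(2.0, 2.0, 2.0), kind=ValueKind.SUV):
    """A random positive volume with a random blob-ish nonempty mask."""
    values = rng.gamma(2.0, 2.0, size=shape)
    mask = np.zeros(shape, dtype=bool)
    n = rng.integers(1, max(2, int(np.prod(shape) * 0.2)))
    idx = rng.choice(int(np.prod(shape)), size=n, replace=False)
    mask.reshape(-1)[idx] = True
    return make_volume(values, spacing, kind), make_mask(mask, spacing)


@pytest.fixture
def subject():
    return SubjectRecord(
        subject_id="S001",
        sex="female",
        weight_kg=82.5,
        height_cm=170.0,
        injected_dose_MBq=370.0,
        session=1,
        modality="PETCT",
    )
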