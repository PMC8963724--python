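import numpy as np
import pytest

from emsyn.core import CellType, CellTypeMap, SegmentationVolume
from emsyn.synthetic import SynthConfig

# Small, fast study conditions reused across tests that need a full volume.
SMALL_SYNTH = SynthConfig(
    dims=(96, 96, 48), n_pf=10, n_pc=2, n_in=2, n_cf=1, pc_wall=16, seed=7
)


@pytest.fixture
def small_config() -> SynthConfig:
    return SMALL_SYNTH


@pytest.fixture
def two_cubes() -> SegmentationVolume:
    """Two 10x10x10 cubes abutting on a full face along Z."""
    labels = np.ones((10, 10, 20), dtype=np.int32)
    labels[:, :, 10:] = 2
    return SegmentationVolume(labels)


@pytest.fixture
def three_in_row() -> SegmentationVolume:
    """Three segments stacked along X: pairs (1,2) and (2,3) touch, (1,3) not."""
    labels = np.ones((9, 4, 4), dtype=np.int32)
    labels[3:6] = 2
    labels[6:] = 3
    return SegmentationVolume(labels)


@pytest.fixture
def basic_types() -> CellTypeMap:
    return CellTypeMap(
        {
            1: CellType.PF,
            2: CellType.PC,
            3: CellType.IN,
            4: CellType.CF,
            5: CellType.PF,
        }
    )
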