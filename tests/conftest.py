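import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from synapsepol import SceneSpec, SegmentationConfig
from synapsepol.scene_synth import ActinProfile, generate_conjugate_scene, generate_timelapse


@pytest.fixture(scope="session")
def clean_spec() -> SceneSpec:
    """Noise-free, blur-free static conjugate."""
    return SceneSpec(seed=11, true_pol_index=0.5)


@pytest.fixture(scope="session")
def clean_scene(clean_spec):
    return generate_conjugate_scene(clean_spec)


@pytest.fixture(scope="session")
def zstack_scene():
    spec = SceneSpec(seed=13, n_z=24, shape_yx=(96, 96), true_depletion_ratio=0.25, n_vesicles=0)
    return generate_conjugate_scene(spec)


@pytest.fixture(scope="session")
def burst_timelapse():
    spec = SceneSpec(
        seed=17, n_t=19, frame_interval=5.0, shape_yx=(96, 96),
        actin_profile=ActinProfile(
            burst_start=10, burst_duration=30, burst_amplitude=2.0, clearance_ratio=0.5
        ),
    )
    return generate_timelapse(spec)


@pytest.fixture(scope="session")
def cytosol_seg_config() -> SegmentationConfig:
    """Segment the T cell from the cytosolic (organelle-channel) fill."""
    return SegmentationConfig(t_cell_role="organelle")


def iou(a: np.ndarray, b: np.ndarray) -> float:
    return (a & b).sum() / (a | b).sum()
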