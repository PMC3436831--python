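import logging

import numpy as np
import pytest

from colonytrack.registration import RegistrationParams
from colonytrack.segmentation import SegmentationParams
from colonytrack.synth import ColonySpec, ScenarioScript, generate_sequence
from colonytrack.tracking import TrackingParams

logging.getLogger("colonytrack").setLevel(logging.ERROR)
logging.getLogger("colonytrack.registration").setLevel(logging.ERROR)


def disc_mask(radius: int, pad: int = 5, value: int = 1) -> np.ndarray:
    """Rasterised disc: pixel centres within `radius` of the centre."""
    n = 2 * radius + 2 * pad + 1
    rr, cc = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    return np.where((rr - n // 2) ** 2 + (cc - n // 2) ** 2 <= radius**2, value, 0)


@pytest.fixture(scope="session")
def fast_registration() -> RegistrationParams:
    """Registration budget used for tracking tests: propagation only needs
    fields accurate to a pixel or two, not full convergence."""
    return RegistrationParams(max_steps=40, convergence_rel_change=5e-3)


@pytest.fixture(scope="session")
def fast_tracking(fast_registration) -> TrackingParams:
    return TrackingParams(
        direction="forward",
        registration=fast_registration,
        segmentation=SegmentationParams(ac_iterations=100),
    )


@pytest.fixture(scope="session")
def drift_scenario():
    """Two colonies drifting and growing, no merge/split events."""
    script = ScenarioScript(
        shape=(160, 160),
        n_frames=5,
        colonies=[
            ColonySpec(center=(50, 45), radius=20, texture_seed=1, growth=0.8,
                       velocity=(0.5, 0.2), colony_id=1),
            ColonySpec(center=(110, 110), radius=16, texture_seed=2, growth=0.5,
                       velocity=(-0.4, 0.3), colony_id=2),
        ],
        noise_sigma=0.03,
        seed=3,
    )
    return generate_sequence(script)


@pytest.fixture(scope="session")
def merge_scenario():
    """Two colonies translating toward each other, fusing at frame 6.

    Velocities are chosen so the contact is decisive: a 6 px gap at frame
    5 becomes a 4 px overlap at frame 6, so the event frame is unambiguous
    at rasterisation scale.
    """
    script = ScenarioScript(
        shape=(160, 160),
        n_frames=8,
        colonies=[
            ColonySpec(center=(80, 34), radius=18, texture_seed=1,
                       velocity=(0, 5.0), colony_id=1),
            ColonySpec(center=(80, 126), radius=18, texture_seed=2,
                       velocity=(0, -5.0), colony_id=2),
        ],
        noise_sigma=0.03,
        seed=5,
    )
    return generate_sequence(script)


@pytest.fixture(scope="session")
def split_scenario():
    """One colony splitting into two sub-colonies at frame 3."""
    script = ScenarioScript(
        shape=(160, 160),
        n_frames=8,
        colonies=[ColonySpec(center=(80, 80), radius=20, texture_seed=4, colony_id=1)],
        splits=[(3, 1, ((0, -16), (0, 16)))],
        noise_sigma=0.03,
        seed=7,
    )
    return generate_sequence(script)
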