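import dataclasses

import numpy as np
import pytest

from orgamapper import FieldImage, SimulationParams, generate_cell
from orgamapper.segment import LabelMask


@pytest.fixture(scope="session")
def baseline_params() -> SimulationParams:
    return SimulationParams()


@pytest.fixture(scope="session")
def baseline_cell(baseline_params):
    """Baseline simulated field and its ground truth (rendered once)."""
    return generate_cell(baseline_params)


def make_field(shape=(120, 160), background=10, pixel_size=1.0,
               nucleus=None, cytoplasm=None, organelle=None,
               measurement=None, field_id="test"):
    """Build a small synthetic FieldImage from optional per-channel overrides.

    Each override is either a full 2D array or a list of (mask, value) pairs
    painted over a constant background.
    """
    def channel(spec):
        img = np.full(shape, float(background))
        if spec is None:
            pass
        elif isinstance(spec, np.ndarray):
            img = spec.astype(float)
        else:
            for mask, value in spec:
                img[mask] = value
        return img

    channels = [channel(nucleus), channel(cytoplasm), channel(organelle)]
    roles = {"nucleus": 0, "cytoplasm": 1, "organelle": 2}
    if measurement is not None:
        channels.append(channel(measurement))
        roles["measurement"] = 3
    arr = np.clip(np.stack(channels), 0, 255).astype(np.uint8)
    return FieldImage(arr, roles, pixel_size=pixel_size, field_id=field_id)


def disk_mask(shape, center, radius):
    """Boolean disk; center is (x, y)."""
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius ** 2


def ellipse_mask(shape, center, half_axes):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    a, b = half_axes
    return ((xx - center[0]) / a) ** 2 + ((yy - center[1]) / b) ** 2 <= 1.0


def full_frame_cells(shape) -> LabelMask:
    """Single cell instance covering the whole frame (for detection tests)."""
    return LabelMask(np.ones(shape, dtype=np.int32))


def empty_labels(shape) -> LabelMask:
    return LabelMask(np.zeros(shape, dtype=np.int32))
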