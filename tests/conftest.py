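import numpy as np
import pytest

from padquant import BlankReference, compute_all_signals
from padquant.synthetic import ResponseModel, generate_rgb_dataset


@pytest.fixture()
def btb_dataset():
    """Synthetic BTB-like calibration dataset (6 levels x 3 replicates)."""
    return generate_rgb_dataset(ResponseModel(), seed=42)


@pytest.fixture()
def btb_zones(btb_dataset):
    return btb_dataset[0]


@pytest.fixture()
def btb_blank(btb_zones):
    return BlankReference.from_measurements(btb_zones)


@pytest.fixture()
def btb_signal_table(btb_zones, btb_blank):
    return compute_all_signals(btb_zones, btb_blank)


def brute_force_zone_mean(pixels: np.ndarray, cx: float, cy: float, r: float):
    """Independent per-pixel enumeration of the circular ROI mean."""
    total = np.zeros(3)
    n = 0
    height, width = pixels.shape[:2]
    for y in range(height):
        for x in range(width):
            if (x - cx) ** 2 + (y - cy) ** 2 <= r**2:
                total += pixels[y, x]
                n += 1
    return (total / n if n else total), n
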