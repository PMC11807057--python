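import numpy as np
import pytest

from cyanobench import LabeledMask, generate_filament_mask, generate_rod_mask


@pytest.fixture(scope="session")
def rod_mask() -> LabeledMask:
    return generate_rod_mask(25, 224, seed=42)


@pytest.fixture(scope="session")
def filament_mask() -> LabeledMask:
    return generate_filament_mask(3, image_size=224, seed=42)


def naive_pixel_counts(gt: np.ndarray, pred: np.ndarray) -> tuple[int, int, int]:
    """Double-loop tp/fp/fn pixel counter; the independent oracle."""
    tp = fp = fn = 0
    for r in range(gt.shape[0]):
        for c in range(gt.shape[1]):
            g = gt[r, c] > 0
            p = pred[r, c] > 0
            if g and p:
                tp += 1
            elif p:
                fp += 1
            elif g:
                fn += 1
    return tp, fp, fn


def random_mask_pair(rng: np.random.Generator, shape=(32, 32)):
    """A correlated random labeled-mask pair with partial overlaps."""
    gt = rng.integers(0, 4, size=shape).astype(np.int32)
    noise = rng.integers(0, 4, size=shape)
    pred = np.where(rng.random(shape) < 0.75, gt, noise).astype(np.int32)
    return LabeledMask(gt), LabeledMask(pred)
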