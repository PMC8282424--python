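import numpy as np
import pytest

from gliopipe.synthesis import (SyntheticCohortSpec, SyntheticImageSpec,
                                generate_cohort, generate_he_image)


@pytest.fixture(scope="session")
def he_tile():
    """A standard synthetic H&E tile with its exact mask and fields."""
    spec = SyntheticImageSpec(seed=11)
    rgb, mask, fields = generate_he_image(spec, return_fields=True)
    return rgb, mask, fields


@pytest.fixture(scope="session")
def small_cohort():
    """30-case cohort (10 per grade) for fast bookkeeping tests."""
    return generate_cohort(
        SyntheticCohortSpec(n_cases_per_class=(10, 10, 10), seed=7)
    )


@pytest.fixture(scope="session")
def default_cohort():
    """150-case cohort under the default study conditions."""
    return generate_cohort(
        SyntheticCohortSpec(n_cases_per_class=(50, 50, 50), seed=42)
    )


def brute_force_dilate(mask: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """Exhaustive neighborhood-max dilation oracle (clipped shifts)."""
    h, w = mask.shape
    fh, fw = footprint.shape
    cy, cx = fh // 2, fw // 2
    out = np.zeros_like(mask, dtype=bool)
    for i in range(fh):
        for j in range(fw):
            if not footprint[i, j]:
                continue
            dy, dx = i - cy, j - cx
            src = mask[
                max(0, -dy) : h - max(0, dy),
                max(0, -dx) : w - max(0, dx),
            ]
            out[
                max(0, dy) : h - max(0, -dy),
                max(0, dx) : w - max(0, -dx),
            ] |= src > 0
    return out
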