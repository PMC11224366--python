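"""Pixel-level erosion oracle shared by the morphology and acceptance tests."""

import numpy as np


def brute_force_erode(mask: np.ndarray, radius_px: int) -> np.ndarray:
    """Keep a pixel iff every disc offset (centre distance <= radius,
    ties inclusive) lands inside the mask — direct set-definition erosion."""
    r = radius_px
    out = np.zeros_like(mask)
    offsets = [(di, dj) for di in range(-r, r + 1) for dj in range(-r, r + 1)
               if di * di + dj * dj <= r * r]
    for i in range(mask.shape[0]):
        for j in range(mask.shape[1]):
            if not mask[i, j]:
                continue
            out[i, j] = all(
                0 <= i + di < mask.shape[0] and 0 <= j + dj < mask.shape[1]
                and mask[i + di, j + dj]
                for di, dj in offsets
            )
    return out
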