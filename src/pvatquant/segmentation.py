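"""PVAT segmentation by whole-image intensity thresholding.

The fat-saturated image is thresholded at two standard deviations above the
mean pixel intensity of the whole image; background and the very bright
superficial subcutaneous tissue are removed afterwards via a user-supplied
exclusion mask.  Image statistics use the population (n-divisor) SD and are
computed before any exclusion is applied — exclusions only censor the output
mask, never the threshold.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np

from .core import SegmentationMask

logger = logging.getLogger(__name__)

#: Number of standard deviations above the image mean defining fat.
THRESHOLD_K = 2.0


def segment_pvat(fat_image: np.ndarray,
                 exclusion: Optional[np.ndarray] = None) -> SegmentationMask:
    """Threshold a fat-saturated image at mean + 2 SD of the whole image.

    Pixels strictly above the threshold are fat; pixels under the exclusion
    mask (1 = excluded) are then removed.  A constant image has SD 0 and
    yields an empty mask (no pixel strictly exceeds the mean).

    Parameters
    ----------
    fat_image : 2-D array of pixel intensities.
    exclusion : optional binary array of the same shape marking background /
        subcutaneous-rim pixels to drop from the result.
    """
    img = np.asarray(fat_image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("fat_image must be a non-empty 2-D array")
    if exclusion is not None:
        exclusion = np.asarray(exclusion).astype(bool)
        if exclusion.shape != img.shape:
            raise ValueError(
                f"exclusion shape {exclusion.shape} does not match image "
                f"shape {img.shape}"
            )

    mu = float(img.mean())
    sigma = float(img.std())  # population SD: the whole pixel population
    threshold = mu + THRESHOLD_K * sigma
    if sigma == 0.0:
        logger.warning("constant fat image (SD = 0): segmentation is empty")

    mask = img > threshold  # strict: a uniform image stays empty
    desc = "none"
    if exclusion is not None:
        mask = mask & ~exclusion
        desc = f"{int(exclusion.sum())} px excluded"
    return SegmentationMask(mask, threshold=threshold, exclusion=desc)


def load_wall_mask(mask: np.ndarray,
                   reference_shape: Optional[tuple[int, int]] = None) -> SegmentationMask:
    """Validate an externally produced wall mask (truth or manual annotation).

    The wall is segmented outside this package — no automatic wall operator
    is defined here — so this only checks alignment and basic sanity.  A mask
    whose annulus is broken into several pieces is accepted with a warning.
    """
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValueError("wall mask must be 2-D")
    arr = arr.astype(bool)
    if reference_shape is not None and arr.shape != tuple(reference_shape):
        raise ValueError(
            f"wall mask shape {arr.shape} does not match image shape "
            f"{tuple(reference_shape)}"
        )
    if not arr.any():
        raise ValueError("empty wall mask")
    n_comp = _count_components(arr)
    if n_comp > 1:
        logger.warning("wall mask has %d connected components; expected one annulus",
                       n_comp)
    return SegmentationMask(arr, exclusion="external wall mask")


def _count_components(mask: np.ndarray) -> int:
    """4-connected component count via scipy labelling."""
    from scipy import ndimage

    _, n = ndimage.label(mask, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    return int(n)
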