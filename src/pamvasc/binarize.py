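"""The three candidate vessel binarizations and their Boolean combination.

MAP1 is a global threshold at a factor (default 1.1) times the estimated
mean background level; MAP2/MAP3 threshold small- and large-kernel
vesselness responses; the final mask is (MAP1 AND MAP3) OR MAP2.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy.ndimage import label as _nd_label
from skimage.filters import threshold_otsu

from pamvasc.imgio import BackgroundEstimate, IntensityImage
from pamvasc.vesselness import VesselnessImage


@dataclass
class ThresholdParams:
    """Global-threshold parameters: pixel is vessel iff value > factor * background."""

    factor: float = 1.1
    comparison: str = "strict_greater"

    def __post_init__(self) -> None:
        if not self.factor > 0:
            raise ValueError(f"factor must be > 0, got {self.factor}")
        if self.comparison != "strict_greater":
            raise ValueError("only 'strict_greater' comparison is supported")


@dataclass
class BinaryVesselMask:
    """A boolean vessel mask and the route that produced it."""

    mask: np.ndarray
    source: str  # MAP1 | MAP2 | MAP3 | MAPult
    params_digest: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.source not in ("MAP1", "MAP2", "MAP3", "MAPult"):
            raise ValueError(f"unknown mask source {self.source!r}")

    @property
    def shape(self):
        return self.mask.shape


def _digest(payload: dict) -> str:
    return hashlib.sha1(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def drop_small_objects(mask: np.ndarray, min_px: int) -> np.ndarray:
    """Remove 8-connected components with fewer than ``min_px`` pixels."""
    labels, n = _nd_label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return mask.copy()
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_px
    keep[0] = False
    return keep[labels]


def map1_global(
    image: IntensityImage,
    background: BackgroundEstimate,
    params: Optional[ThresholdParams] = None,
) -> BinaryVesselMask:
    """Global thresholding: vessel iff intensity strictly exceeds factor * background.

    The background estimate must come from the same (typically equalized)
    image the threshold is applied to.
    """
    params = params or ThresholdParams()
    threshold = params.factor * background.level
    if background.level == 0 and np.any(image.pixels > 0):
        warnings.warn(
            "map1_global: background level is 0, threshold degenerates to > 0"
        )
    mask = image.pixels > threshold
    return BinaryVesselMask(
        mask,
        source="MAP1",
        params_digest=_digest(
            {"factor": params.factor, "background": background.level}
        ),
    )


def map_from_vesselness(
    vimg: VesselnessImage,
    method: str = "otsu",
    level: Optional[float] = None,
    source: str = "MAP2",
    min_object_px: int = 0,
) -> BinaryVesselMask:
    """Binarize a vesselness response.

    With ``method="otsu"`` the level is chosen by Otsu's criterion over the
    nonzero responses; an all-zero response yields an empty mask.
    ``min_object_px`` optionally removes connected components smaller than
    that size (off by default).
    """
    v = vimg.values
    if method not in ("otsu", "fixed"):
        raise ValueError(f"method must be 'otsu' or 'fixed', got {method!r}")
    if method == "fixed":
        if level is None:
            raise ValueError("method='fixed' requires a level")
        thr = float(level)
    else:
        nonzero = v[v > 0]
        if nonzero.size == 0:
            return BinaryVesselMask(np.zeros_like(v, dtype=bool), source=source)
        if np.all(nonzero == nonzero[0]):
            thr = nonzero[0] / 2.0
        else:
            thr = float(threshold_otsu(nonzero))
    mask = v > thr
    if min_object_px > 0:
        mask = drop_small_objects(mask, min_object_px)
    return BinaryVesselMask(
        mask,
        source=source,
        params_digest=_digest(
            {
                "method": method,
                "level": thr,
                "kernel_px": vimg.params.kernel_px,
                "min_object_px": min_object_px,
            }
        ),
    )


def combine_maps(
    m1: Union[BinaryVesselMask, np.ndarray],
    m2: Union[BinaryVesselMask, np.ndarray],
    m3: Union[BinaryVesselMask, np.ndarray],
) -> BinaryVesselMask:
    """Combine the three maps per-pixel as (m1 AND m3) OR m2."""
    a1 = m1.mask if isinstance(m1, BinaryVesselMask) else np.asarray(m1, dtype=bool)
    a2 = m2.mask if isinstance(m2, BinaryVesselMask) else np.asarray(m2, dtype=bool)
    a3 = m3.mask if isinstance(m3, BinaryVesselMask) else np.asarray(m3, dtype=bool)
    if not (a1.shape == a2.shape == a3.shape):
        raise ValueError(
            f"shape mismatch: {a1.shape}, {a2.shape}, {a3.shape}"
        )
    return BinaryVesselMask((a1 & a3) | a2, source="MAPult")
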