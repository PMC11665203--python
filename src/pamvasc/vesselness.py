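"""Single-scale Hessian (Frangi-type) vesselness filtering.

The Hessian is formed by central finite differences of the Gaussian-smoothed
image, scale-normalized by sigma**2 so that responses are comparable across
kernel scales. Eigenvalues are computed in closed form for the symmetric 2x2
matrix; tests check the whole chain against an independent per-pixel
eigendecomposition oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple, Union

import numpy as np
from scipy.ndimage import gaussian_filter

from pamvasc.imgio import IntensityImage


@dataclass
class VesselnessParams:
    """Parameters of the single-scale vesselness filter.

    ``kernel_px`` is the filter scale in pixels (3 for the smallest vessels,
    30 for the largest); the Gaussian sigma used internally is
    ``kernel_px / 2``. ``beta`` controls ridge-anisotropy sensitivity; the
    structureness scale ``c`` is adaptive (half the maximum Hessian Frobenius
    norm over the image) unless fixed explicitly.
    """

    kernel_px: int = 3
    beta: float = 0.5
    c_mode: str = "adaptive"  # "adaptive" | "fixed"
    c_value: Optional[float] = None
    bright_on_dark: bool = True

    def __post_init__(self) -> None:
        if self.kernel_px < 1:
            raise ValueError(f"kernel_px must be >= 1, got {self.kernel_px}")
        if not self.beta > 0:
            raise ValueError(f"beta must be > 0, got {self.beta}")
        if self.c_mode not in ("adaptive", "fixed"):
            raise ValueError(f"c_mode must be 'adaptive' or 'fixed', got {self.c_mode!r}")
        if self.c_mode == "fixed" and (self.c_value is None or self.c_value <= 0):
            raise ValueError("c_mode='fixed' requires a positive c_value")

    @property
    def sigma_px(self) -> float:
        return self.kernel_px / 2.0


@dataclass
class VesselnessImage:
    """Pixel-wise tube-likeness in [0, 1] plus the parameters that made it."""

    values: np.ndarray
    params: VesselnessParams
    border_px: int = 0  # width of the boundary band considered unreliable

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("vesselness must be 2-D")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError("vesselness values must lie in [0, 1]")


def _as_array(image: Union[IntensityImage, np.ndarray]) -> np.ndarray:
    if isinstance(image, IntensityImage):
        return image.pixels
    return np.asarray(image, dtype=np.float64)


def hessian_components(
    image: Union[IntensityImage, np.ndarray], sigma: float
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scale-normalized Hessian (Hrr, Hcc, Hrc) of the smoothed image.

    Second derivatives are central finite differences of the reflect-padded
    Gaussian-smoothed image, multiplied by sigma**2 (gamma = 2 normalization).
    """
    if not sigma > 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    arr = _as_array(image)
    smooth = gaussian_filter(arr, sigma, mode="reflect")
    p = np.pad(smooth, 1, mode="reflect")
    hrr = p[2:, 1:-1] - 2.0 * p[1:-1, 1:-1] + p[:-2, 1:-1]
    hcc = p[1:-1, 2:] - 2.0 * p[1:-1, 1:-1] + p[1:-1, :-2]
    hrc = (p[2:, 2:] - p[2:, :-2] - p[:-2, 2:] + p[:-2, :-2]) / 4.0
    s2 = sigma * sigma
    return hrr * s2, hcc * s2, hrc * s2


def hessian_eigenvalues(
    image: Union[IntensityImage, np.ndarray], sigma: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-pixel eigenvalues of the scale-normalized Hessian, |lam1| <= |lam2|."""
    hrr, hcc, hrc = hessian_components(image, sigma)
    mean = (hrr + hcc) / 2.0
    disc = np.sqrt(((hrr - hcc) / 2.0) ** 2 + hrc**2)
    ea = mean + disc
    eb = mean - disc
    swap = np.abs(ea) > np.abs(eb)
    lam1 = np.where(swap, eb, ea)
    lam2 = np.where(swap, ea, eb)
    return lam1, lam2


def frangi(
    image: Union[IntensityImage, np.ndarray],
    params: VesselnessParams,
) -> VesselnessImage:
    """Single-scale 2-D vesselness.

    With bright-on-dark polarity the response is zero wherever lam2 > 0 and
    otherwise exp(-Rb^2 / 2 beta^2) * (1 - exp(-S^2 / 2 c^2)) with
    Rb = lam1/lam2 and S = sqrt(lam1^2 + lam2^2). Purely Hessian-based, so
    an additive intensity offset leaves the output unchanged; with adaptive
    c the output is also invariant to a positive multiplicative gain.
    """
    sigma = params.sigma_px
    lam1, lam2 = hessian_eigenvalues(image, sigma)
    s2 = lam1**2 + lam2**2
    s_max = float(np.sqrt(s2.max())) if s2.size else 0.0
    if s_max == 0.0:
        return VesselnessImage(
            np.zeros_like(lam1), params, border_px=int(np.ceil(2 * sigma))
        )
    if params.c_mode == "adaptive":
        c = 0.5 * s_max
    else:
        c = float(params.c_value)  # type: ignore[arg-type]
    with np.errstate(divide="ignore", invalid="ignore"):
        rb2 = np.where(lam2 != 0, (lam1 / np.where(lam2 == 0, 1.0, lam2)) ** 2, 0.0)
    v = np.exp(-rb2 / (2.0 * params.beta**2)) * (1.0 - np.exp(-s2 / (2.0 * c * c)))
    if params.bright_on_dark:
        v = np.where(lam2 > 0, 0.0, v)
    else:
        v = np.where(lam2 < 0, 0.0, v)
    v = np.where(lam2 == 0, 0.0, v)
    return VesselnessImage(
        np.clip(v, 0.0, 1.0), params, border_px=int(np.ceil(2 * sigma))
    )
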