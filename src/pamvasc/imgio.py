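"""Image I/O, volume projection, contrast enhancement, background estimation."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple, Union

import numpy as np
import tifffile
from scipy.signal import hilbert
from skimage import exposure

Roi = Union[np.ndarray, Tuple[slice, slice]]


@dataclass
class IntensityImage:
    """A 2-D non-negative scalar field with a physical pixel pitch.

    Parameters
    ----------
    pixels : ndarray
        2-D array of finite, non-negative intensities.
    pixel_pitch_um : float
        Isotropic pixel pitch in micrometres per pixel; must be > 0.
    modality : str
        ``"PAM"`` (photoacoustic) or ``"CFM"`` (confocal fluorescence).
    provenance : str
        Free-text description of where the image came from.
    """

    pixels: np.ndarray
    pixel_pitch_um: float
    modality: str = "PAM"
    provenance: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2-D image, got ndim={self.pixels.ndim}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite values")
        if np.any(self.pixels < 0):
            raise ValueError("image contains negative values")
        if not self.pixel_pitch_um > 0:
            raise ValueError(f"pixel_pitch_um must be > 0, got {self.pixel_pitch_um}")
        if self.modality not in ("PAM", "CFM"):
            raise ValueError(f"modality must be 'PAM' or 'CFM', got {self.modality!r}")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def area_mm2(self) -> float:
        h, w = self.pixels.shape
        return h * w * (self.pixel_pitch_um / 1000.0) ** 2

    def with_pixels(self, pixels: np.ndarray) -> "IntensityImage":
        return IntensityImage(
            pixels=pixels,
            pixel_pitch_um=self.pixel_pitch_um,
            modality=self.modality,
            provenance=self.provenance,
        )


@dataclass
class BackgroundEstimate:
    """An estimated background intensity level and how it was obtained."""

    level: float
    method: str  # "roi" | "darkest_quartile"
    roi: Optional[object] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.level < 0:
            raise ValueError(f"background level must be >= 0, got {self.level}")


def load_image(
    path: Union[str, Path],
    pixel_pitch_um: float,
    modality: str = "PAM",
) -> IntensityImage:
    """Load a single-channel TIFF as an :class:`IntensityImage`.

    Raises
    ------
    ValueError
        If the TIFF holds more than one channel (RGB or multi-sample data);
        select a channel before loading.
    """
    arr = tifffile.imread(str(path))
    if arr.ndim != 2:
        raise ValueError(
            f"{path}: expected a single-channel 2-D TIFF, got shape {arr.shape}; "
            "select one channel (e.g. arr[..., 0]) and re-save before loading"
        )
    return IntensityImage(
        pixels=arr.astype(np.float64),
        pixel_pitch_um=pixel_pitch_um,
        modality=modality,
        provenance=str(path),
    )


def save_image(image: IntensityImage, path: Union[str, Path]) -> None:
    """Write a single-channel TIFF.

    Integer-valued data in [0, 65535] is written as 16-bit so that a
    save/load round trip is bit-exact; anything else is written as float32.
    """
    px = image.pixels
    if np.issubdtype(px.dtype, np.integer) or (
        np.all(px == np.round(px)) and px.size and px.max(initial=0) <= 65535
    ):
        out = px.astype(np.uint16)
    else:
        out = px.astype(np.float32)
    tifffile.imwrite(str(path), out)


def project_volume(
    volume: np.ndarray,
    pixel_pitch_um: float,
    depth_axis: int = 0,
    modality: str = "PAM",
) -> IntensityImage:
    """Maximum-amplitude projection of a raw 3-D scan.

    The analytic-signal envelope (magnitude of the Hilbert transform) is taken
    along ``depth_axis`` and its per-pixel maximum returned as a 2-D image.

    A 2-D input passes through unchanged with a warning.
    """
    volume = np.asarray(volume, dtype=np.float64)
    if volume.ndim == 2:
        warnings.warn("project_volume received a 2-D array; passing through unchanged")
        return IntensityImage(np.abs(volume), pixel_pitch_um, modality=modality)
    if volume.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got ndim={volume.ndim}")
    envelope = np.abs(hilbert(volume, axis=depth_axis))
    proj = envelope.max(axis=depth_axis)
    return IntensityImage(proj, pixel_pitch_um, modality=modality, provenance="projection")


def equalize(image: IntensityImage, nbins: int = 256, clahe: bool = False) -> IntensityImage:
    """Global histogram equalization; output in [0, 1].

    The transform is a monotone non-decreasing function of pixel rank, so
    pixels with equal input values map to equal output values. A constant
    image has no defined equalization and is returned as all zeros with a
    warning. Set ``clahe=True`` for contrast-limited adaptive equalization
    (off by default).
    """
    px = image.pixels
    if px.max() == px.min():
        warnings.warn("equalize: constant image, returning all zeros")
        return image.with_pixels(np.zeros_like(px, dtype=np.float64))
    if clahe:
        rescaled = (px - px.min()) / (px.max() - px.min())
        out = exposure.equalize_adapthist(rescaled, nbins=nbins)
    else:
        out = exposure.equalize_hist(px, nbins=nbins)
    return image.with_pixels(np.clip(out, 0.0, 1.0))


def estimate_background(
    image: IntensityImage, roi: Optional[Roi] = None, method: str = "median"
) -> BackgroundEstimate:
    """Estimate the mean background intensity.

    With ``roi`` (a boolean mask or a ``(row_slice, col_slice)`` pair) the
    estimate is the arithmetic mean over the region. Without it, the image
    median is used: while vessels are a minority class the median sits on
    the background distribution and, unlike a darkest-quantile mean, is not
    biased low by the noise. ``method="darkest_quartile"`` is kept as an
    alternative automatic estimator.
    """
    px = image.pixels
    if roi is not None:
        if isinstance(roi, np.ndarray):
            if roi.shape != px.shape:
                raise ValueError("roi mask shape does not match image")
            values = px[roi.astype(bool)]
        else:
            values = px[roi[0], roi[1]].ravel()
        if values.size == 0:
            raise ValueError("empty roi")
        return BackgroundEstimate(level=float(values.mean()), method="roi", roi=roi)
    if method == "median":
        return BackgroundEstimate(level=float(np.median(px)), method="median")
    if method == "darkest_quartile":
        q25 = np.quantile(px, 0.25)
        dark = px[px <= q25]
        return BackgroundEstimate(level=float(dark.mean()), method="darkest_quartile")
    raise ValueError(f"unknown background method {method!r}")
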