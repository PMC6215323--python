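"""Stern-Volmer fluorescence oximetry.

An oxygen-sensitive dye (e.g. RTDP) is quenched by oxygen following

    I0 / I = 1 + Kq * [O2]

with I0 the intensity at 0 % O2 and Kq the quenching constant in 1/(%O2).
Calibration uses two image stacks taken at 0 % and ambient (21 %) oxygen at
the same location as the measurement, which cancels spatial variations in
illumination, refraction and absorption.  The image is split into strips
perpendicular to the gradient axis; I0 and Kq are fitted per strip, and the
measurement image is inverted strip-wise into an oxygen profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError


def forward_intensity(
    o2_percent: np.ndarray | float, i0: np.ndarray | float, kq: np.ndarray | float
) -> np.ndarray | float:
    """Quenched fluorescence intensity I = I0 / (1 + Kq [O2])."""
    return i0 / (1.0 + kq * np.asarray(o2_percent, dtype=float))


def average_stack(images: Sequence[np.ndarray]) -> np.ndarray:
    """Pixel-wise mean of an image stack (all images the same shape)."""
    images = [np.asarray(img, dtype=float) for img in images]
    if len(images) == 0:
        raise ValidationError("average_stack requires at least one image")
    shape = images[0].shape
    for k, img in enumerate(images):
        if img.shape != shape:
            raise ValidationError(
                f"image {k} has shape {img.shape}, expected {shape}"
            )
    return np.mean(images, axis=0)


def strip_bounds(n_pixels: int, strip_width: int) -> np.ndarray:
    """Strip edges along the gradient axis.

    Strips are ``strip_width`` pixels wide; a partial final strip is kept
    if it is at least half a strip wide, otherwise it is merged into its
    neighbour.  Returns an array of edges of length n_strips + 1.
    """
    if strip_width < 1:
        raise ValidationError("strip_width must be >= 1")
    if n_pixels < 1:
        raise ValidationError("image must be at least one pixel wide")
    edges = list(range(0, n_pixels, strip_width))
    edges.append(n_pixels)
    if len(edges) > 2 and (edges[-1] - edges[-2]) < strip_width / 2:
        del edges[-2]  # merge short remainder into the previous strip
    return np.asarray(edges, dtype=int)


@dataclass
class CalibrationTable:
    """Per-strip Stern-Volmer parameters.

    ``edges`` are strip boundaries in pixels along the gradient axis;
    strips where quenching was absent or inverted (ambient intensity not
    below I0) are flagged invalid and carry NaN Kq.
    """

    strip_width: int
    edges: np.ndarray
    i0: np.ndarray
    kq: np.ndarray
    valid: np.ndarray
    c_ambient: float = 21.0
    gradient_axis: int = 1

    @property
    def n_strips(self) -> int:
        return len(self.edges) - 1

    @property
    def centers_px(self) -> np.ndarray:
        return (self.edges[:-1] + self.edges[1:]) / 2.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "strip_index": np.arange(self.n_strips),
                "start_px": self.edges[:-1],
                "stop_px": self.edges[1:],
                "i0": self.i0,
                "kq": self.kq,
                "valid": self.valid,
            }
        )

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, strip_width: int, c_ambient: float = 21.0,
        gradient_axis: int = 1,
    ) -> "CalibrationTable":
        edges = np.concatenate([frame["start_px"].to_numpy(), [frame["stop_px"].iloc[-1]]])
        return cls(
            strip_width=int(strip_width),
            edges=edges.astype(int),
            i0=frame["i0"].to_numpy(float),
            kq=frame["kq"].to_numpy(float),
            valid=frame["valid"].to_numpy(bool),
            c_ambient=float(c_ambient),
            gradient_axis=int(gradient_axis),
        )


def _strip_means(img: np.ndarray, edges: np.ndarray, gradient_axis: int) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValidationError("expected a 2D intensity image")
    if not np.isfinite(img).all():
        raise ValidationError("image contains non-finite pixels")
    if gradient_axis == 0:
        img = img.T
    return np.array(
        [img[:, a:b].mean() for a, b in zip(edges[:-1], edges[1:])]
    )


def calibrate(
    img_0pct: np.ndarray,
    img_ambient: np.ndarray,
    strip_width: int = 10,
    c_ambient: float = 21.0,
    gradient_axis: int = 1,
) -> CalibrationTable:
    """Fit per-strip I0 and Kq from the 0 % and ambient calibration images.

    I0 is the strip mean of the 0 % image; Kq solves the Stern-Volmer
    relation at ambient oxygen: Kq = (I0 / I_ambient - 1) / c_ambient.
    Strips where the ambient intensity is not strictly below I0 show no
    quenching and are flagged invalid rather than raising.
    """
    img_0pct = np.asarray(img_0pct, dtype=float)
    img_ambient = np.asarray(img_ambient, dtype=float)
    if img_0pct.shape != img_ambient.shape:
        raise ValidationError(
            f"calibration image shapes differ: {img_0pct.shape} vs {img_ambient.shape}"
        )
    n_px = img_0pct.shape[1 if gradient_axis == 1 else 0]
    edges = strip_bounds(n_px, strip_width)
    i0 = _strip_means(img_0pct, edges, gradient_axis)
    i_amb = _strip_means(img_ambient, edges, gradient_axis)
    valid = (i0 > 0) & (i_amb > 0) & (i_amb < i0)
    kq = np.full_like(i0, np.nan)
    kq[valid] = (i0[valid] / i_amb[valid] - 1.0) / c_ambient
    if not valid.all():
        warnings.warn(
            f"{(~valid).sum()} of {len(valid)} strips show no quenching and "
            "were flagged invalid",
            stacklevel=2,
        )
    return CalibrationTable(
        strip_width=strip_width,
        edges=edges,
        i0=i0,
        kq=kq,
        valid=valid,
        c_ambient=c_ambient,
        gradient_axis=gradient_axis,
    )


def invert(
    img: np.ndarray,
    cal: CalibrationTable,
    mm_per_px: float | None = None,
) -> pd.DataFrame:
    """Invert a measurement image into a strip-wise oxygen profile.

    Applies [O2] = (I0 / I - 1) / Kq per strip with I the strip mean.
    Negative concentrations (noise at the hypoxic end) are reported as-is
    with a warning — clipping them would bias profile averages.

    Returns a DataFrame with columns ``strip_index``, ``center_px``
    (optionally ``center_mm``), ``o2_percent``, ``valid``.
    """
    img = np.asarray(img, dtype=float)
    n_px = img.shape[1 if cal.gradient_axis == 1 else 0]
    if n_px != cal.edges[-1]:
        raise ValidationError(
            f"image extent {n_px} px does not match calibration layout "
            f"({cal.edges[-1]} px)"
        )
    means = _strip_means(img, cal.edges, cal.gradient_axis)
    valid = cal.valid & (means > 0)
    o2 = np.full(cal.n_strips, np.nan)
    o2[valid] = (cal.i0[valid] / means[valid] - 1.0) / cal.kq[valid]
    n_negative = int((o2[valid] < 0).sum())
    if n_negative:
        warnings.warn(
            f"{n_negative} strips recovered negative O2 (noise below the "
            "0% calibration level); values reported unclipped",
            stacklevel=2,
        )
    out = pd.DataFrame(
        {
            "strip_index": np.arange(cal.n_strips),
            "center_px": cal.centers_px,
            "o2_percent": o2,
            "valid": valid,
        }
    )
    if mm_per_px is not None:
        out.insert(2, "center_mm", out["center_px"] * mm_per_px)
    return out
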