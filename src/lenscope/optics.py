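"""Focal-ratio quantification of spheroid z-stacks.

A transparent lens organoid behaves as a converging lens: transmitted
light is concentrated into a bright central spot at some objective
position below the focus.  The light-focusing readout used here is the
per-slice focal ratio

    R(z) = max intensity in a central ROI / mean intensity in the
           background field around the spheroid,

which is ~1 for a non-focusing (or opaque) object and rises well above 1
at the z-position where the organoid concentrates light.  The module
segments the spheroid to place ROIs automatically, computes R(z) curves,
summarises them (peak ratio, peak z, a boolean focusing call) and
compares conditions (e.g. increasing oxidative or osmotic stress doses)
by the mean +/- sd of the peak ratio with a monotone-trend statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import disk

from .errors import InputError, MeasurementError

__all__ = [
    "ZStack",
    "RoiPair",
    "FocalCurve",
    "FocusSummary",
    "SpheroidSegmentation",
    "ConditionComparison",
    "segment_spheroid",
    "auto_rois",
    "focal_ratio_curve",
    "focus_summary",
    "compare_conditions",
    "grid_contrast",
]


@dataclass
class ZStack:
    """A 3-D intensity grid with calibrated z-positions.

    Parameters
    ----------
    intensities
        Array of shape ``(n_slices, height, width)``, non-negative.
    z_positions
        Objective position of each slice in micrometres, strictly
        monotone.  z = 0 is the microscope focus; negative values are
        below the sample.
    pixel_size
        Lateral pixel size in micrometres, if known.
    """

    intensities: np.ndarray
    z_positions: np.ndarray
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        self.z_positions = np.asarray(self.z_positions, dtype=float)
        if self.intensities.ndim != 3:
            raise InputError("intensities must be a 3-D (slice, row, col) array")
        if self.intensities.shape[0] != self.z_positions.shape[0]:
            raise InputError(
                f"{self.intensities.shape[0]} slices but "
                f"{self.z_positions.shape[0]} z-positions"
            )
        if self.intensities.shape[0] == 0:
            raise InputError("empty stack")
        if np.any(np.asarray(self.intensities) < 0):
            raise InputError("intensities must be non-negative")
        dz = np.diff(self.z_positions)
        if dz.size and not (np.all(dz > 0) or np.all(dz < 0)):
            raise InputError("z_positions must be strictly monotone")

    @property
    def n_slices(self) -> int:
        return self.intensities.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape[1:]


@dataclass
class RoiPair:
    """Centre ROI (square over the spheroid centre) and background region.

    ``center`` is the (row, col) of the square's centre; ``half_side``
    its half-width in pixels.  The background is an explicit boolean
    mask over the field outside the spheroid.  The two regions must be
    non-empty and disjoint.
    """

    center: tuple[int, int]
    half_side: int
    background_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.half_side < 0:
            raise InputError("half_side must be >= 0")
        self.background_mask = np.asarray(self.background_mask, dtype=bool)
        if self.background_mask.ndim != 2:
            raise InputError("background_mask must be 2-D")
        if not self.background_mask.any():
            raise InputError("background region is empty")

    def center_slices(self, shape: tuple[int, int]) -> tuple[slice, slice]:
        r, c = self.center
        h = self.half_side
        r0, r1 = r - h, r + h + 1
        c0, c1 = c - h, c + h + 1
        if r0 < 0 or c0 < 0 or r1 > shape[0] or c1 > shape[1]:
            raise InputError(
                f"center ROI ({r},{c}) half-side {h} out of bounds for image {shape}"
            )
        return slice(r0, r1), slice(c0, c1)

    def validate_disjoint(self, shape: tuple[int, int]) -> None:
        rs, cs = self.center_slices(shape)
        if self.background_mask.shape != shape:
            raise InputError("background_mask shape does not match image")
        if self.background_mask[rs, cs].any():
            raise InputError("center and background ROIs overlap")


@dataclass
class FocalCurve:
    """Per-slice focal ratio R(z) with its two ingredients."""

    z_positions: np.ndarray
    ratio: np.ndarray
    max_center: np.ndarray
    mean_background: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "z_um": self.z_positions,
                "ratio": self.ratio,
                "max_center": self.max_center,
                "mean_background": self.mean_background,
            }
        )


@dataclass
class FocusSummary:
    """Peak of a focal curve and the light-focusing call."""

    peak_ratio: float
    peak_z: float
    focuses_light: bool
    threshold: float


@dataclass
class SpheroidSegmentation:
    mask: np.ndarray
    centroid: tuple[float, float]
    radius: float
    no_object: bool


@dataclass
class ConditionComparison:
    """Per-condition summaries of focal curves.

    Both aggregation conventions are reported: the mean/sd of
    per-organoid peak ratios (``summary``) and the per-z mean/sd curve
    (``mean_curves``).  If numeric doses are supplied, ``trend_rho`` is
    the Spearman correlation of peak ratio against dose.
    """

    summary: pd.DataFrame
    mean_curves: pd.DataFrame
    trend_rho: float | None = None
    trend_p: float | None = None


def segment_spheroid(
    stack: ZStack,
    reference_slice: int = 0,
    min_area: int = 64,
) -> SpheroidSegmentation:
    """Locate the spheroid on one slice of a stack.

    Thresholds the absolute deviation from the slice median (Otsu after
    lightly smoothing and log-compressing the deviation, so shot noise
    and a bright focal spot cannot dominate the threshold), keeps the
    largest connected component and fills holes.  Both darker-than-field
    objects and bright spots are picked up.  If no component reaches
    ``min_area`` pixels, falls back to the image centre with
    ``no_object=True``.
    """
    if not 0 <= reference_slice < stack.n_slices:
        raise InputError(f"reference_slice {reference_slice} out of range")
    img = np.asarray(stack.intensities[reference_slice], dtype=float)
    smooth = gaussian(img, sigma=1, preserve_range=True)
    dev = np.log1p(np.abs(smooth - np.median(smooth)))
    center = ((img.shape[0] - 1) / 2.0, (img.shape[1] - 1) / 2.0)
    fallback = SpheroidSegmentation(
        mask=np.zeros(img.shape, dtype=bool),
        centroid=center,
        radius=min(img.shape) / 8.0,
        no_object=True,
    )
    if np.allclose(dev, 0):
        return fallback
    mask = dev > threshold_otsu(dev)
    labels = label(mask)
    props = regionprops(labels)
    if not props:
        return fallback
    largest = max(props, key=lambda p: p.area)
    if largest.area < min_area:
        return fallback
    obj = ndimage.binary_fill_holes(labels == largest.label)
    area = obj.sum()
    cr, cc = ndimage.center_of_mass(obj)
    return SpheroidSegmentation(
        mask=obj,
        centroid=(cr, cc),
        radius=float(np.sqrt(area / np.pi)),
        no_object=False,
    )


def auto_rois(
    stack: ZStack,
    reference_slice: int = 0,
    center_fraction: float = 0.10,
    dilation_factor: float = 1.2,
    border_fraction: float = 0.10,
) -> RoiPair:
    """Place the centre/background ROI pair from an automatic segmentation.

    The centre square has half-side ``center_fraction`` of the spheroid
    radius (at least 1 px); the background is a frame-border band of
    relative width ``border_fraction``, excluding the spheroid mask
    dilated by ``dilation_factor``.
    """
    seg = segment_spheroid(stack, reference_slice)
    h, w = stack.shape
    half = max(1, int(round(center_fraction * seg.radius)))
    band = max(2, int(round(border_fraction * min(h, w))))
    bg = np.zeros((h, w), dtype=bool)
    bg[:band, :] = bg[-band:, :] = True
    bg[:, :band] = bg[:, -band:] = True
    if seg.mask.any():
        grow = max(1, int(round((dilation_factor - 1.0) * seg.radius)))
        bg &= ~ndimage.binary_dilation(seg.mask, structure=disk(grow).astype(bool))
    if not bg.any():
        raise InputError("no background pixels remain outside the dilated spheroid")
    center = (int(round(seg.centroid[0])), int(round(seg.centroid[1])))
    rois = RoiPair(center=center, half_side=half, background_mask=bg)
    rois.validate_disjoint((h, w))
    return rois


def focal_ratio_curve(stack: ZStack, rois: RoiPair) -> FocalCurve:
    """Compute R(z) = max(center ROI) / mean(background) per slice.

    The curve is returned in ascending z order regardless of acquisition
    direction.
    """
    rois.validate_disjoint(stack.shape)
    rs, cs = rois.center_slices(stack.shape)
    data = np.asarray(stack.intensities, dtype=float)
    max_center = data[:, rs, cs].max(axis=(1, 2))
    mean_bg = data[:, rois.background_mask].mean(axis=1)
    if np.any(mean_bg <= 0):
        raise MeasurementError("background mean is zero on at least one slice; ratio undefined")
    order = np.argsort(stack.z_positions)
    return FocalCurve(
        z_positions=stack.z_positions[order],
        ratio=(max_center / mean_bg)[order],
        max_center=max_center[order],
        mean_background=mean_bg[order],
    )


def focus_summary(curve: FocalCurve, threshold: float = 1.2) -> FocusSummary:
    """Peak ratio, the z attaining it (ties: smallest |z|), and the call."""
    if len(curve.ratio) == 0:
        raise InputError("empty focal curve")
    peak = float(np.max(curve.ratio))
    at_peak = np.flatnonzero(curve.ratio == peak)
    best = at_peak[np.argmin(np.abs(curve.z_positions[at_peak]))]
    return FocusSummary(
        peak_ratio=peak,
        peak_z=float(curve.z_positions[best]),
        focuses_light=bool(peak > threshold),
        threshold=threshold,
    )


def compare_conditions(
    curves_by_condition: Mapping[str, Sequence[FocalCurve]],
    doses: Mapping[str, float] | None = None,
    threshold: float = 1.2,
) -> ConditionComparison:
    """Summarise focal curves per condition and test a dose trend.

    Reports mean +/- sd of per-organoid peak ratios and the per-z
    mean +/- sd curve for every condition; with numeric ``doses``, adds
    the Spearman correlation of individual peak ratios against dose.
    """
    rows = []
    curve_rows = []
    all_peaks: list[float] = []
    all_doses: list[float] = []
    for cond, curves in curves_by_condition.items():
        if len(curves) == 0:
            raise InputError(f"condition {cond!r} has no curves")
        peaks = np.array([focus_summary(c, threshold).peak_ratio for c in curves])
        rows.append(
            {
                "condition": cond,
                "n": len(curves),
                "peak_ratio_mean": peaks.mean(),
                "peak_ratio_sd": peaks.std(ddof=1) if len(peaks) > 1 else 0.0,
            }
        )
        z = curves[0].z_positions
        ratios = np.vstack([c.ratio for c in curves])
        for j, zj in enumerate(z):
            col = ratios[:, j]
            curve_rows.append(
                {
                    "condition": cond,
                    "z_um": zj,
                    "ratio_mean": col.mean(),
                    "ratio_sd": col.std(ddof=1) if len(col) > 1 else 0.0,
                }
            )
        if doses is not None:
            all_peaks.extend(peaks)
            all_doses.extend([doses[cond]] * len(peaks))
    rho = p = None
    if doses is not None and len(set(all_doses)) > 1:
        res = stats.spearmanr(all_doses, all_peaks)
        rho, p = float(res.statistic), float(res.pvalue)
    return ConditionComparison(
        summary=pd.DataFrame(rows),
        mean_curves=pd.DataFrame(curve_rows),
        trend_rho=rho,
        trend_p=p,
    )


def grid_contrast(image: np.ndarray) -> float:
    """Auxiliary macroscopy contrast score (not a published readout).

    Michelson contrast between the 5th and 95th intensity percentiles of
    a single image; provided as a rough stand-in for visual grid
    scoring of transparency.  The focal ratio is the primary readout.
    """
    img = np.asarray(image, dtype=float)
    lo, hi = np.percentile(img, [5, 95])
    if hi + lo == 0:
        return 0.0
    return float((hi - lo) / (hi + lo))
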