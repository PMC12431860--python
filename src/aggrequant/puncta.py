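"""Puncta segmentation and overlap ("white") quantification.

Dual-channel reporter logic: aggregates appear in both the green and the
red channel while cytosolic, and lose green fluorescence upon lysosomal
delivery (GFP quenching at acidic pH).  The pool of non-degraded
aggregates is therefore proxied by the *white* area — pixels positive in
both channels — expressed as a fraction of the red area.

Segmentation follows the automated-acquisition recipe: a morphological
white top-hat with a disc structuring element (channel-specific radius in
µm), min–max normalization of the filtered image, a relative colour
threshold (default 0.7), and removal of sub-minimum objects.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skimage import measure, morphology

from .config import SegmentationParams
from .io import FrameStack, PixelCalibration

logger = logging.getLogger("aggrequant")

PUNCTA_COLUMNS = ["frame", "label", "centroid_y_px", "centroid_x_px",
                  "area_px", "area_um2", "mean_intensity", "channel"]


@dataclass
class PunctaSet:
    """Segmented objects of one frame: label, centroid, area, intensity."""

    frame: int
    data: pd.DataFrame  # columns PUNCTA_COLUMNS

    def __post_init__(self) -> None:
        missing = [c for c in PUNCTA_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"PunctaSet missing columns {missing}")
        if len(self.data) and (self.data["area_px"] <= 0).any():
            raise ValueError("object areas must be strictly positive")
        if self.data["label"].duplicated().any():
            raise ValueError("labels must be unique within a frame")

    def __len__(self) -> int:
        return len(self.data)

    def to_frame(self) -> pd.DataFrame:
        return self.data.loc[:, PUNCTA_COLUMNS]


@dataclass
class ROIIntensityResult:
    """Per-ROI intensities and per-condition fold changes vs a reference."""

    per_roi: pd.DataFrame        # condition, image, roi_label, mean_intensity
    condition_means: dict = field(default_factory=dict)
    fold_change: dict = field(default_factory=dict)
    reference_condition: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = [{"condition": c, "mean_intensity": m,
                 "fold_change_vs_reference": self.fold_change[c]}
                for c, m in self.condition_means.items()]
        return pd.DataFrame(rows)


@lru_cache(maxsize=32)
def _disk_sequence(radius_px: int):
    return morphology.disk(radius_px, decomposition="sequence")


def tophat_radius_px(radius_um: float, calibration: PixelCalibration) -> int:
    """Convert a µm structuring-element radius to pixels (ceil, >= 1)."""
    radius = radius_um / calibration.pixel_size_um
    if radius < 1:
        raise ValueError(
            f"top-hat radius {radius_um} um is below one pixel at "
            f"{calibration.pixel_size_um} um/px — check the calibration"
        )
    return math.ceil(radius)


def tophat_segment(image: np.ndarray, params: SegmentationParams,
                   calibration: PixelCalibration, channel: str) -> np.ndarray:
    """Segment bright puncta in a single frame.

    White top-hat with a disc element of the channel's radius, filtered
    output normalized by the raw image's min–max intensity range (so a
    featureless frame — flat or a smooth gradient — yields an empty mask
    instead of having its residuals amplified), threshold at
    ``params.colour_threshold``, small-object removal.  Returns a boolean
    mask.  Invariant to adding a constant to the whole image.
    """
    # float32: ample for camera counts, ~30% faster morphology
    image = np.asarray(image, dtype=np.float32)
    if image.ndim != 2:
        raise ValueError("tophat_segment expects a single 2-D frame")
    r_px = tophat_radius_px(params.radius_um(channel), calibration)
    # decomposed disc: ~40x faster for large radii, <=0.1% amplitude error
    footprint = _disk_sequence(r_px)
    filtered = morphology.white_tophat(image, footprint)
    span = float(image.max() - image.min())
    if span <= 0 or filtered.max() <= 0:
        return np.zeros(image.shape, dtype=bool)
    mask = filtered / span >= params.colour_threshold
    # keep objects with area >= min_area_px
    return morphology.remove_small_objects(mask,
                                           max_size=params.min_area_px - 1)


def detect_puncta(mask: np.ndarray, intensity_image: np.ndarray,
                  frame_index: int, calibration: PixelCalibration | None = None,
                  channel: str = "") -> PunctaSet:
    """Label connected components (8-connectivity) and measure them."""
    mask = np.asarray(mask, dtype=bool)
    intensity_image = np.asarray(intensity_image)
    if mask.shape != intensity_image.shape:
        raise ValueError("mask and intensity image shapes differ")
    labels = measure.label(mask, connectivity=2)
    px_area_um2 = calibration.pixel_size_um ** 2 if calibration else np.nan
    if labels.max() == 0:
        return PunctaSet(frame_index, pd.DataFrame(columns=PUNCTA_COLUMNS))
    props = measure.regionprops_table(
        labels, intensity_image=intensity_image.astype(float),
        properties=("label", "centroid", "area", "intensity_mean"))
    df = pd.DataFrame({
        "frame": frame_index,
        "label": props["label"],
        "centroid_y_px": props["centroid-0"],
        "centroid_x_px": props["centroid-1"],
        "area_px": props["area"].astype(float),
        "area_um2": props["area"] * px_area_um2,
        "mean_intensity": props["intensity_mean"],
        "channel": channel,
    })
    return PunctaSet(frame_index, df)


def white_overlap(green_mask: np.ndarray,
                  red_mask: np.ndarray) -> tuple[np.ndarray, float]:
    """Overlap mask and white-area fraction relative to the red area.

    The fraction is area(green ∩ red) / area(red); 0 with a warning when
    the red mask is empty.
    """
    green_mask = np.asarray(green_mask, dtype=bool)
    red_mask = np.asarray(red_mask, dtype=bool)
    if green_mask.shape != red_mask.shape:
        raise ValueError("green and red masks have different shapes")
    white = green_mask & red_mask
    red_area = int(red_mask.sum())
    if red_area == 0:
        logger.warning("white_overlap: empty red mask, fraction set to 0")
        return white, 0.0
    return white, white.sum() / red_area


def classify_white_puncta(red_puncta: PunctaSet, red_mask: np.ndarray,
                          green_mask: np.ndarray,
                          min_overlap: float = 0.5) -> np.ndarray:
    """Object-level white classification for per-punctum statistics.

    A red object counts as white when at least ``min_overlap`` of its
    pixels are green-positive.  Returns a boolean array aligned with
    ``red_puncta.data`` rows.
    """
    labels = measure.label(np.asarray(red_mask, dtype=bool), connectivity=2)
    green_mask = np.asarray(green_mask, dtype=bool)
    out = np.zeros(len(red_puncta), dtype=bool)
    for i, lab in enumerate(red_puncta.data["label"].to_numpy()):
        obj = labels == lab
        out[i] = green_mask[obj].mean() >= min_overlap
    return out


def average_object_size(puncta_sets: Sequence[PunctaSet]) -> pd.Series:
    """Mean object area (µm²) per frame; NaN for frames with no objects."""
    vals = {ps.frame: (ps.data["area_um2"].mean() if len(ps) else np.nan)
            for ps in puncta_sets}
    return pd.Series(vals, name="mean_area_um2")


def colocalize_puncta(puncta: PunctaSet, marker_mask: np.ndarray) -> float:
    """Fraction of objects whose centroid falls inside the marker mask."""
    marker_mask = np.asarray(marker_mask, dtype=bool)
    if len(puncta) == 0:
        return 0.0
    ys = np.clip(np.rint(puncta.data["centroid_y_px"]).astype(int),
                 0, marker_mask.shape[0] - 1)
    xs = np.clip(np.rint(puncta.data["centroid_x_px"]).astype(int),
                 0, marker_mask.shape[1] - 1)
    return float(marker_mask[ys, xs].mean())


def roi_intensity_foldchange(
        images_by_condition: Mapping[str, Sequence[tuple[np.ndarray, np.ndarray]]],
        roi_params: SegmentationParams, calibration: PixelCalibration,
        reference_condition: str,
        roi_channel: str = "red") -> ROIIntensityResult:
    """ROI-based signal-intensity fold change between conditions.

    Each condition maps to ``(roi_image, measured_image)`` pairs; ROIs are
    segmented from the ROI image (typically the mCherry channel) with the
    top-hat recipe, and the measured channel's mean intensity inside every
    ROI object is collected.  Fold change is the condition mean over ROIs
    divided by the reference condition's mean.
    """
    if reference_condition not in images_by_condition:
        raise ValueError(
            f"reference condition {reference_condition!r} not present")
    rows = []
    for condition, pairs in images_by_condition.items():
        if not len(pairs):
            raise ValueError(f"condition {condition!r} has no images")
        for img_idx, (roi_image, measured) in enumerate(pairs):
            mask = tophat_segment(roi_image, roi_params, calibration,
                                  roi_channel)
            puncta = detect_puncta(mask, measured, img_idx, calibration)
            for _, row in puncta.data.iterrows():
                rows.append({"condition": condition, "image": img_idx,
                             "roi_label": int(row["label"]),
                             "mean_intensity": row["mean_intensity"]})
    per_roi = pd.DataFrame(rows)
    means = {c: float(per_roi.loc[per_roi["condition"] == c,
                                  "mean_intensity"].mean())
             for c in images_by_condition}
    ref = means[reference_condition]
    fold = {c: m / ref for c, m in means.items()}
    return ROIIntensityResult(per_roi, means, fold, reference_condition)


def gfp_area_fraction(green_mask: np.ndarray, cell_mask: np.ndarray) -> float:
    """Green-positive area as a fraction of the cell surface area."""
    green_mask = np.asarray(green_mask, dtype=bool)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if green_mask.shape != cell_mask.shape:
        raise ValueError("mask shapes differ")
    cell_area = int(cell_mask.sum())
    if cell_area == 0:
        raise ValueError("cell mask is empty")
    return float((green_mask & cell_mask).sum() / cell_area)


def white_fraction_timeseries(green: FrameStack, red: FrameStack,
                              params: SegmentationParams) -> np.ndarray:
    """White-area fraction per frame (mask-only fast path).

    Segments both channels and computes area(green ∩ red)/area(red) per
    frame without per-object measurements; used for the degradation-rate
    readout.
    """
    if green.n_frames != red.n_frames:
        raise ValueError("green and red stacks differ in length")
    out = np.zeros(green.n_frames)
    for t in range(green.n_frames):
        g_mask = tophat_segment(green.data[t], params, green.calibration,
                                "green")
        r_mask = tophat_segment(red.data[t], params, red.calibration, "red")
        _, out[t] = white_overlap(g_mask, r_mask)
        assert 0.0 <= out[t] <= 1.0
    return out


def segment_timelapse(green: FrameStack, red: FrameStack,
                      params: SegmentationParams
                      ) -> tuple[list[PunctaSet], list[PunctaSet], np.ndarray]:
    """Run the full dual-channel quantification over a time-lapse.

    Returns per-frame green and red :class:`PunctaSet` lists and the
    white-area fraction per frame.  Asserts the overlap-containment
    invariant on every frame.
    """
    if green.n_frames != red.n_frames:
        raise ValueError("green and red stacks differ in length")
    green_sets, red_sets, white_frac = [], [], []
    for t in range(green.n_frames):
        g_mask = tophat_segment(green.data[t], params, green.calibration,
                                "green")
        r_mask = tophat_segment(red.data[t], params, red.calibration, "red")
        white, frac = white_overlap(g_mask, r_mask)
        assert not np.any(white & ~(g_mask & r_mask))
        assert 0.0 <= frac <= 1.0
        green_sets.append(detect_puncta(g_mask, green.data[t], t,
                                        green.calibration, "green"))
        red_sets.append(detect_puncta(r_mask, red.data[t], t,
                                      red.calibration, "red"))
        white_frac.append(frac)
    return green_sets, red_sets, np.asarray(white_frac)
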