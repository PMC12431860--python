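"""Aggregate-compactness quantification from grey-value cross-sections.

The grey value of an electron-tomography slice is proportional to local
protein concentration, so the dispersion of intensities along a
cross-section through an aggregate reports how tightly it is packed.
Each cross-section is normalized to its own mean, the normalized values
are pooled per condition into an equal-width-bin histogram, and the
spread statistic (standard deviation of the normalized values — i.e. the
mean-normalized coefficient of variation) makes conditions comparable:
loose inclusions show a much broader spread than compact aggregates.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage


@dataclass
class ProfileTrace:
    """A 1-D grey-value cross-section through one aggregate."""

    positions: np.ndarray     # px or nm, strictly increasing
    values: np.ndarray        # grey values, >= 0
    aggregate_id: int = 0
    condition: str = ""
    truth: object | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.positions) < 10:
            raise ValueError("a profile needs at least 10 samples")
        if self.positions.shape != self.values.shape:
            raise ValueError("positions and values differ in length")
        if not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("grey values must be finite and non-negative")

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position": self.positions,
                             "grey_value": self.values,
                             "aggregate_id": self.aggregate_id,
                             "condition": self.condition})


@dataclass
class SpreadResult:
    """Pooled normalized-intensity spread for one condition."""

    condition: str
    aggregate_means: dict               # aggregate id -> mean grey value
    normalized_values: np.ndarray       # pooled value / per-aggregate mean
    hist_counts: np.ndarray
    bin_edges: np.ndarray
    spread: float                       # SD of the normalized values

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "condition": self.condition,
            "bin_left": self.bin_edges[:-1],
            "bin_right": self.bin_edges[1:],
            "count": self.hist_counts,
        })


def extract_profile(image: np.ndarray,
                    line_endpoints: tuple[tuple[float, float],
                                          tuple[float, float]],
                    n_samples: int, aggregate_id: int = 0,
                    condition: str = "") -> ProfileTrace:
    """Sample grey values along a line segment by bilinear interpolation.

    ``line_endpoints`` are ``((y0, x0), (y1, x1))`` in pixel coordinates;
    both must lie inside the image; ``n_samples >= 10`` equally spaced
    points are returned.
    """
    image = np.asarray(image, dtype=float)
    if n_samples < 10:
        raise ValueError("n_samples must be >= 10")
    (y0, x0), (y1, x1) = line_endpoints
    for y, x in ((y0, x0), (y1, x1)):
        if not (0 <= y <= image.shape[0] - 1 and 0 <= x <= image.shape[1] - 1):
            raise ValueError(f"endpoint ({y}, {x}) outside the image")
    frac = np.linspace(0.0, 1.0, n_samples)
    ys = y0 + frac * (y1 - y0)
    xs = x0 + frac * (x1 - x0)
    values = ndimage.map_coordinates(image, np.vstack([ys, xs]), order=1,
                                     mode="nearest")
    positions = frac * np.hypot(y1 - y0, x1 - x0)
    if positions[-1] == 0:  # degenerate zero-length line
        positions = frac
    return ProfileTrace(positions=positions, values=values,
                        aggregate_id=aggregate_id, condition=condition)


def random_chord(mask: np.ndarray, rng: np.random.Generator,
                 min_length_px: float = 10.0, max_tries: int = 1000
                 ) -> tuple[tuple[float, float], tuple[float, float]]:
    """Draw a uniformly random cross-section chord within a mask."""
    ys, xs = np.nonzero(np.asarray(mask, dtype=bool))
    if len(ys) == 0:
        raise ValueError("mask is empty")
    for _ in range(max_tries):
        i, j = rng.integers(len(ys), size=2)
        p0 = (float(ys[i]), float(xs[i]))
        p1 = (float(ys[j]), float(xs[j]))
        if np.hypot(p1[0] - p0[0], p1[1] - p0[1]) >= min_length_px:
            return p0, p1
    raise ValueError("could not draw a long-enough chord in the mask")


def profile_mean_line(trace: ProfileTrace) -> float:
    """Mean grey value of the cross-section (the figure's black line)."""
    return float(trace.values.mean())


def normalized_spread(traces_by_condition: Mapping[str, Sequence[ProfileTrace]],
                      n_bins: int = 20) -> dict[str, SpreadResult]:
    """Per-aggregate mean normalization and pooled spread per condition.

    Every trace is divided by its own mean (error on non-positive means),
    pooled within its condition, and binned into ``n_bins`` equal-width
    bins over the shared range [0, max normalized value across all
    conditions].  The spread statistic is the standard deviation of the
    pooled normalized values.
    """
    normalized: dict[str, list[np.ndarray]] = {}
    agg_means: dict[str, dict] = {}
    for condition, traces in traces_by_condition.items():
        normalized[condition] = []
        agg_means[condition] = {}
        for trace in traces:
            m = trace.values.mean()
            if m <= 0:
                raise ValueError(
                    f"aggregate {trace.aggregate_id} has non-positive mean")
            agg_means[condition][trace.aggregate_id] = float(m)
            normalized[condition].append(trace.values / m)
    top = max(float(np.max(v)) for vs in normalized.values() for v in vs)
    edges = np.linspace(0.0, top, n_bins + 1)
    out = {}
    for condition, chunks in normalized.items():
        pooled = np.concatenate(chunks)
        counts, _ = np.histogram(pooled, bins=edges)
        out[condition] = SpreadResult(
            condition=condition, aggregate_means=agg_means[condition],
            normalized_values=pooled, hist_counts=counts, bin_edges=edges,
            spread=float(pooled.std(ddof=1)))
    return out
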