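"""Single-molecule localization pipeline and local-density clustering.

Implements the receptor-clustering analysis used for selective-autophagy
receptors on aggregates: temporal-median background removal, Gaussian
spot localization, Gaussian reconstruction rendering, cross-correlation
drift correction, and the per-aggregate local-density statistic.

The clustering statistic: within one aggregate ROI, the *local density*
of a molecule is the number of other localizations within a radius of
five times the aggregate's mean nearest-neighbour distance.  Molecules
with local density above a threshold (default 40) are cluster members;
clusters are the connected components of the thresholded set linked at
that same radius, requiring at least 3 members.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import ConvexHull, QhullError, cKDTree
from scipy.special import erf
from skimage.feature import peak_local_max
from skimage.registration import phase_cross_correlation

from .config import SmlmParams
from .io import FrameStack

logger = logging.getLogger("aggrequant")


@dataclass
class ClusterResult:
    """Per-molecule densities/labels and per-cluster summaries for one
    aggregate."""

    local_density: np.ndarray        # D_i, non-negative integer counts
    labels: np.ndarray               # cluster id per molecule, -1 unclustered
    mean_nn_nm: float                # d-bar
    radius_nm: float                 # multiplier * d-bar
    clusters: pd.DataFrame           # cluster, n_members, area_um2,
                                     # density_per_um2

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


# ---------------------------------------------------------------------------
# raw-movie processing


def temporal_median_filter(stack: FrameStack, window: int) -> FrameStack:
    """Subtract the per-pixel running temporal median (background).

    ``window`` must be odd and within [3, n_frames].  Negative residuals
    are clipped at zero.
    """
    n = stack.n_frames
    if window % 2 == 0 or not 3 <= window <= n:
        raise ValueError(f"window must be odd and in [3, {n}], got {window}")
    background = ndimage.median_filter(stack.data.astype(float),
                                       size=(window, 1, 1), mode="nearest")
    out = np.clip(stack.data.astype(float) - background, 0.0, None)
    return FrameStack(out, stack.calibration, channel=stack.channel)


def _gauss2d(coords, amplitude, y0, x0, sigma, offset):
    y, x = coords
    return (offset + amplitude *
            np.exp(-((y - y0) ** 2 + (x - x0) ** 2) / (2 * sigma ** 2))).ravel()


def gaussian_localize(stack: FrameStack, detection_threshold: float,
                      psf_sigma_guess: float = 1.3,
                      min_sigma_nm: float = 1.0) -> pd.DataFrame:
    """Detect spots and refine them by least-squares 2-D Gaussian fits.

    Local maxima above ``detection_threshold`` (on the background-
    subtracted stack) seed the fits; the localization error ``sigma_nm``
    is propagated from the fit covariance of the centre coordinates and
    floored at ``min_sigma_nm``.  Failed or diverged fits are discarded
    with a logged count.
    """
    if stack.n_frames == 0:
        raise ValueError("stack has no frames")
    px_nm = stack.calibration.pixel_size_nm
    half = max(3, int(np.ceil(3 * psf_sigma_guess)))
    rows, n_failed = [], 0
    for t in range(stack.n_frames):
        frame = stack.data[t].astype(float)
        peaks = peak_local_max(frame, min_distance=half,
                               threshold_abs=detection_threshold,
                               exclude_border=False)
        for py, px in peaks:
            y0, y1 = max(0, py - half), min(frame.shape[0], py + half + 1)
            x0, x1 = max(0, px - half), min(frame.shape[1], px + half + 1)
            win = frame[y0:y1, x0:x1]
            yy, xx = np.mgrid[y0:y1, x0:x1]
            p0 = (win.max() - win.min(), float(py), float(px),
                  psf_sigma_guess, win.min())
            try:
                popt, pcov = optimize.curve_fit(
                    _gauss2d, (yy, xx), win.ravel(), p0=p0, maxfev=400)
            except (RuntimeError, optimize.OptimizeWarning):
                n_failed += 1
                continue
            amp, fy, fx, fsigma, _ = popt
            if amp <= 0 or not (y0 - 1 <= fy <= y1 and x0 - 1 <= fx <= x1):
                n_failed += 1
                continue
            var = np.diag(pcov)[1:3]
            sigma_loc = float(np.sqrt(np.abs(var).mean())) * px_nm
            rows.append({"x_nm": fx * px_nm, "y_nm": fy * px_nm, "frame": t,
                         "sigma_nm": max(sigma_loc, min_sigma_nm),
                         "photons": float(amp * 2 * np.pi * fsigma ** 2)})
    if n_failed:
        logger.info("gaussian_localize: discarded %d failed fits", n_failed)
    return pd.DataFrame(rows, columns=["x_nm", "y_nm", "frame", "sigma_nm",
                                       "photons"])


# ---------------------------------------------------------------------------
# reconstruction and drift


def render_reconstruction(locs: pd.DataFrame, render_pixel_nm: float,
                          bounds: tuple[float, float, float, float] | None = None
                          ) -> tuple[np.ndarray, tuple[float, float]]:
    """Render localizations as a sum of unit-integral Gaussian kernels.

    Each molecule contributes a 2-D Gaussian with s.d. equal to its
    localization error.  Returns ``(image, (x_origin_nm, y_origin_nm))``
    where the origin is the centre of pixel (0, 0).
    """
    if render_pixel_nm <= 0:
        raise ValueError("render_pixel_nm must be positive")
    if len(locs) == 0:
        return np.zeros((1, 1)), (0.0, 0.0)
    sig = locs["sigma_nm"].to_numpy(dtype=float) if "sigma_nm" in locs \
        else np.full(len(locs), render_pixel_nm)
    x = locs["x_nm"].to_numpy(dtype=float)
    y = locs["y_nm"].to_numpy(dtype=float)
    if bounds is None:
        pad = 4 * float(sig.max())
        bounds = (x.min() - pad, x.max() + pad, y.min() - pad, y.max() + pad)
    xmin, xmax, ymin, ymax = bounds
    nx = int(np.ceil((xmax - xmin) / render_pixel_nm)) + 1
    ny = int(np.ceil((ymax - ymin) / render_pixel_nm)) + 1
    img = np.zeros((ny, nx))
    inv_sqrt2 = 1.0 / np.sqrt(2.0)
    for xi, yi, si in zip(x, y, sig):
        s_px = si / render_pixel_nm
        cx = (xi - xmin) / render_pixel_nm
        cy = (yi - ymin) / render_pixel_nm
        w = int(np.ceil(4 * s_px)) + 1
        x0, x1 = max(0, int(cx) - w), min(nx, int(cx) + w + 1)
        y0, y1 = max(0, int(cy) - w), min(ny, int(cy) + w + 1)
        if x0 >= x1 or y0 >= y1:
            continue
        # exact per-pixel mass (difference of Gaussian CDFs at the pixel
        # edges): the kernel integrates to 1 for any sigma, even << 1 px
        ey = erf((np.arange(y0, y1 + 1) - 0.5 - cy) / s_px * inv_sqrt2)
        ex = erf((np.arange(x0, x1 + 1) - 0.5 - cx) / s_px * inv_sqrt2)
        img[y0:y1, x0:x1] += 0.25 * np.outer(np.diff(ey), np.diff(ex))
    return img, (xmin, ymin)


def drift_correct(locs: pd.DataFrame, n_blocks: int = 2,
                  render_pixel_nm: float = 20.0,
                  upsample: int = 50) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Estimate and remove stage drift via block reconstructions.

    The table is split into ``n_blocks`` temporal blocks of equal
    localization count; each block is rendered on a common grid and its
    shift against the first block is estimated by the sub-pixel
    cross-correlation peak.  Each localization then has its own block's
    shift subtracted (piecewise-constant over frames — this keeps the
    correction idempotent for abrupt stage jumps; increase ``n_blocks``
    to follow smooth drift).

    Returns the corrected table and the drift trajectory (one row per
    block: centre frame, dx_nm, dy_nm).
    """
    if n_blocks < 2:
        raise ValueError("n_blocks must be >= 2")
    order = np.argsort(locs["frame"].to_numpy(), kind="stable")
    blocks = np.array_split(order, n_blocks)
    if any(len(b) == 0 for b in blocks):
        raise ValueError("empty temporal block — too few localizations")
    pad = 4 * (float(locs["sigma_nm"].max()) if "sigma_nm" in locs
               else render_pixel_nm)
    bounds = (locs["x_nm"].min() - pad, locs["x_nm"].max() + pad,
              locs["y_nm"].min() - pad, locs["y_nm"].max() + pad)
    ref, _ = render_reconstruction(locs.iloc[blocks[0]], render_pixel_nm,
                                   bounds)
    centre_frames, dxs, dys = [], [], []
    for b in blocks:
        sub = locs.iloc[b]
        img, _ = render_reconstruction(sub, render_pixel_nm, bounds)
        # plain (not phase-normalized) cross-correlation: whitening would
        # amplify the speckle of the disjoint point samples in each block
        shift, _, _ = phase_cross_correlation(ref, img,
                                              upsample_factor=upsample,
                                              normalization=None)
        # shift = (dy, dx) in render pixels mapping img onto ref
        centre_frames.append(float(sub["frame"].mean()))
        dys.append(-shift[0] * render_pixel_nm)
        dxs.append(-shift[1] * render_pixel_nm)
    traj = pd.DataFrame({"frame": centre_frames, "dx_nm": dxs, "dy_nm": dys})
    dx_i = np.empty(len(locs))
    dy_i = np.empty(len(locs))
    for bi, b in enumerate(blocks):
        dx_i[b] = dxs[bi]
        dy_i[b] = dys[bi]
    corrected = locs.copy()
    corrected["x_nm"] = locs["x_nm"] - dx_i
    corrected["y_nm"] = locs["y_nm"] - dy_i
    return corrected, traj


# ---------------------------------------------------------------------------
# local-density clustering


def mean_nn_distance(points: np.ndarray) -> float:
    """Mean distance from each point to its nearest other point (nm)."""
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        raise ValueError("mean_nn_distance needs at least 2 points")
    tree = cKDTree(points)
    dists, _ = tree.query(points, k=2)
    return float(dists[:, 1].mean())


def local_density(points: np.ndarray, radius: float) -> np.ndarray:
    """Count of *other* localizations within ``radius`` of each point.

    The ball is closed: a neighbour at exactly the radius counts.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    points = np.asarray(points, dtype=float)
    if len(points) == 0:
        return np.zeros(0, dtype=int)
    tree = cKDTree(points)
    counts = tree.query_ball_point(points, r=radius, return_length=True)
    return np.asarray(counts, dtype=int) - 1  # self excluded


def cluster_molecules(points: np.ndarray, densities: np.ndarray,
                      density_threshold: float = 40.0,
                      link_radius: float | None = None,
                      min_members: int = 3,
                      mean_nn_nm: float = np.nan,
                      radius_nm: float = np.nan) -> ClusterResult:
    """Group high-local-density molecules into receptor clusters.

    Molecules with ``D_i > density_threshold`` are cluster candidates;
    clusters are connected components of candidates linked within
    ``link_radius`` (defaults to the density radius), kept when they have
    at least ``min_members`` members.  Cluster area is the convex hull of
    its members (µm²); per-cluster density is members per hull area, NaN
    for degenerate hulls.
    """
    points = np.asarray(points, dtype=float)
    densities = np.asarray(densities)
    if link_radius is None:
        link_radius = radius_nm
    labels = np.full(len(points), -1, dtype=int)
    cand = np.nonzero(densities > density_threshold)[0]
    clusters = []
    if len(cand):
        tree = cKDTree(points[cand])
        pairs = tree.query_pairs(r=link_radius, output_type="ndarray")
        graph = coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
            shape=(len(cand), len(cand)))
        n_comp, comp = connected_components(graph, directed=False)
        next_id = 0
        for c in range(n_comp):
            members = cand[comp == c]
            if len(members) < min_members:
                continue
            labels[members] = next_id
            pts = points[members]
            area_um2, dens = np.nan, np.nan
            try:
                hull = ConvexHull(pts)
                area_um2 = hull.volume * 1e-6  # nm^2 -> um^2
                if area_um2 > 0:
                    dens = len(members) / area_um2
            except QhullError:
                pass
            clusters.append({"cluster": next_id, "n_members": len(members),
                             "area_um2": area_um2, "density_per_um2": dens})
            next_id += 1
    cluster_df = pd.DataFrame(clusters, columns=["cluster", "n_members",
                                                 "area_um2",
                                                 "density_per_um2"])
    return ClusterResult(local_density=densities, labels=labels,
                         mean_nn_nm=mean_nn_nm, radius_nm=radius_nm,
                         clusters=cluster_df)


def analyze_aggregate(points: np.ndarray,
                      params: SmlmParams | None = None) -> ClusterResult:
    """Full local-density clustering of one aggregate's localizations."""
    params = params or SmlmParams()
    d_bar = mean_nn_distance(points)
    radius = params.density_radius_multiplier * d_bar
    dens = local_density(points, radius)
    return cluster_molecules(points, dens,
                             density_threshold=params.density_threshold,
                             link_radius=radius,
                             min_members=params.min_members,
                             mean_nn_nm=d_bar, radius_nm=radius)


def aggregate_metrics(locs: pd.DataFrame, roi_labels: np.ndarray,
                      roi_pixel_nm: float,
                      params: SmlmParams | None = None
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-aggregate receptor-clustering metrics.

    ``roi_labels`` is a label image of aggregate footprints (0 =
    background) on a grid of ``roi_pixel_nm``; molecules are assigned to
    the ROI containing them (outside-all counted as background, logged).
    Aggregates outside the localization-count window
    [``min_localizations``, ``max_localizations``] are skipped.

    Returns ``(per_aggregate, per_molecule)`` tables.  Per aggregate:
    localization count, ROI area (µm²), overall density (µm⁻²), mean NN
    distance, cluster count and mean in-cluster density.
    """
    params = params or SmlmParams()
    roi_labels = np.asarray(roi_labels)
    px = np.stack([
        np.clip((locs["y_nm"].to_numpy() / roi_pixel_nm).astype(int),
                0, roi_labels.shape[0] - 1),
        np.clip((locs["x_nm"].to_numpy() / roi_pixel_nm).astype(int),
                0, roi_labels.shape[1] - 1),
    ])
    inside_y = (locs["y_nm"].to_numpy() >= 0) & \
        (locs["y_nm"].to_numpy() < roi_labels.shape[0] * roi_pixel_nm)
    inside_x = (locs["x_nm"].to_numpy() >= 0) & \
        (locs["x_nm"].to_numpy() < roi_labels.shape[1] * roi_pixel_nm)
    mol_roi = np.where(inside_y & inside_x, roi_labels[px[0], px[1]], 0)
    n_bg = int((mol_roi == 0).sum())
    if n_bg:
        logger.info("aggregate_metrics: %d localizations outside all ROIs "
                    "(background)", n_bg)
    px_area_um2 = (roi_pixel_nm * 1e-3) ** 2
    per_mol = locs.copy()
    per_mol["aggregate"] = mol_roi
    per_mol["local_density"] = -1
    per_mol["cluster"] = -1
    rows = []
    for roi_id in np.unique(roi_labels):
        if roi_id == 0:
            continue
        sel = np.nonzero(mol_roi == roi_id)[0]
        n = len(sel)
        if n < params.min_localizations or \
                (params.max_localizations is not None and
                 n > params.max_localizations):
            logger.info("aggregate_metrics: aggregate %d skipped "
                        "(%d localizations)", roi_id, n)
            continue
        area_um2 = float((roi_labels == roi_id).sum()) * px_area_um2
        pts = np.column_stack([locs["x_nm"].to_numpy()[sel],
                               locs["y_nm"].to_numpy()[sel]])
        result = analyze_aggregate(pts, params)
        per_mol.iloc[sel, per_mol.columns.get_loc("local_density")] = \
            result.local_density
        per_mol.iloc[sel, per_mol.columns.get_loc("cluster")] = result.labels
        rows.append({
            "aggregate": int(roi_id), "n_localizations": n,
            "roi_area_um2": area_um2,
            "density_per_um2": n / area_um2,
            "mean_nn_nm": result.mean_nn_nm,
            "density_radius_nm": result.radius_nm,
            "n_clusters": result.n_clusters,
            "mean_in_cluster_density_per_um2":
                float(result.clusters["density_per_um2"].mean())
                if result.n_clusters else np.nan,
        })
    per_agg = pd.DataFrame(rows, columns=[
        "aggregate", "n_localizations", "roi_area_um2", "density_per_um2",
        "mean_nn_nm", "density_radius_nm", "n_clusters",
        "mean_in_cluster_density_per_um2"])
    return per_agg, per_mol
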