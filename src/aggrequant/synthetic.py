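"""Synthetic-data generators with explicit ground truth.

Every input the pipeline consumes can be generated here with known truth:

* dual-colour aggrephagy time-lapses — aggregates visible in green and
  red while cytosolic, losing the green signal upon acidification
  (two-state Markov process at rate ``k_deg``), optionally fragmenting at
  rate ``k_frag``;
* receptor localizations on aggregate footprints with a tunable
  clustered fraction;
* grey-value cross-section profiles of compact vs loose aggregates;
* exponential FRAP recovery traces;
* raw blinking SMLM movies for the localization pipeline.

All generators are deterministic given their seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats

from .io import FrameStack, PixelCalibration
from .kinetics import TimeSeries


@dataclass
class GroundTruth:
    """Ground truth attached to a generated dataset (fields filled per
    generator; irrelevant ones stay None)."""

    # time-lapse
    white_fraction: np.ndarray | None = None
    times: np.ndarray | None = None
    k_deg: float | None = None
    k_frag: float | None = None
    events: pd.DataFrame | None = None
    # SMLM localizations
    cluster_labels: np.ndarray | None = None
    n_clusters: int | None = None
    clustered_fraction: float | None = None
    cluster_centers_nm: np.ndarray | None = None
    # FRAP
    mobile_fraction: float | None = None
    k_rec: float | None = None
    # profiles
    mean_level: float | None = None
    cv: float | None = None
    # raw SMLM movies
    drift: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.white_fraction is not None:
            wf = np.asarray(self.white_fraction)
            if np.any((wf < 0) | (wf > 1)):
                raise ValueError("white fraction must lie in [0, 1]")


# ---------------------------------------------------------------------------
# dual-colour aggrephagy time-lapse


@dataclass
class _Aggregate:
    agg_id: int
    parent_id: int
    birth_time: float
    y: float
    x: float
    sigma_um: float          # Gaussian blob s.d.; footprint area ~ sigma^2
    amplitude: float
    conversion_time: float   # absolute time of dual -> red_only


def _simulate_events(n_aggregates: int, k_deg: float, k_frag: float,
                     duration: float, field_um: tuple[float, float],
                     blob_sigma_um: float, amplitude: float,
                     amplitude_cv: float, rng: np.random.Generator
                     ) -> list[_Aggregate]:
    """Draw the aggregate population and its conversion/fragmentation
    events.  Children inherit the parent's acidification clock (the
    two-state process is memoryless), so the expected dual-area fraction
    stays exp(-k_deg * t) under fragmentation."""
    fy, fx = field_um
    # jittered grid placement keeps blobs separated
    n_side = int(np.ceil(np.sqrt(n_aggregates)))
    cell_y, cell_x = fy / n_side, fx / n_side
    order = rng.permutation(n_side * n_side)[:n_aggregates]
    aggs = []
    next_id = 0
    for cell in order:
        gy, gx = divmod(int(cell), n_side)
        y = (gy + 0.5) * cell_y + rng.uniform(-0.2, 0.2) * cell_y
        x = (gx + 0.5) * cell_x + rng.uniform(-0.2, 0.2) * cell_x
        conv = rng.exponential(1.0 / k_deg) if k_deg > 0 else np.inf
        amp = amplitude * max(0.1, 1.0 + amplitude_cv * rng.standard_normal())
        sigma = blob_sigma_um * np.exp(0.05 * rng.standard_normal())
        aggs.append(_Aggregate(next_id, -1, 0.0, y, x, sigma, amp, conv))
        next_id += 1
    if k_frag > 0:
        stack = list(aggs)
        aggs = []
        while stack:
            a = stack.pop()
            t_split = a.birth_time + rng.exponential(1.0 / k_frag)
            if t_split >= duration:
                aggs.append(a)
                continue
            # symmetric binary split conserving footprint area (~sigma^2)
            child_sigma = a.sigma_um / np.sqrt(2.0)
            theta = rng.uniform(0, 2 * np.pi)
            off = 2.0 * child_sigma
            a_end = _Aggregate(a.agg_id, a.parent_id, a.birth_time, a.y, a.x,
                               a.sigma_um, a.amplitude,
                               min(a.conversion_time, t_split))
            aggs.append(a_end)  # parent exists until the split
            for sgn in (+1, -1):
                child = _Aggregate(
                    next_id, a.agg_id, t_split,
                    a.y + sgn * off * np.sin(theta),
                    a.x + sgn * off * np.cos(theta),
                    child_sigma, a.amplitude, a.conversion_time)
                next_id += 1
                stack.append(child)
    return aggs


def simulate_aggrephagy_timelapse(
        n_aggregates: int = 200, k_deg: float = 0.1, k_frag: float = 0.0,
        duration: float = 24.0, frame_interval: float = 0.5,
        image_shape: tuple[int, int] = (240, 240),
        calibration: PixelCalibration | None = None,
        blob_sigma_um: float = 3.0, amplitude: float = 1000.0,
        amplitude_cv: float = 0.02, background: float = 100.0,
        read_noise: float = 2.0, noise: bool = True, render: bool = True,
        seed: int = 0) -> tuple[FrameStack | None, FrameStack | None,
                                GroundTruth]:
    """Simulate a dual-channel aggrephagy reporter time-lapse.

    Aggregates are 2-D Gaussian blobs, always present in the red channel
    and present in green only while still in the dual (non-acidified)
    state; each converts after an exponential waiting time with rate
    ``k_deg`` (per hour) and optionally splits at rate ``k_frag``.
    Pixel noise is Poisson shot noise on signal + background plus
    Gaussian read noise.

    The ground-truth white-area fraction per frame is computed from the
    noiseless half-maximum masks when rendering, and from analytic blob
    footprint areas with ``render=False`` (used for large-n checks of the
    decay law).
    """
    if k_deg < 0 or k_frag < 0:
        raise ValueError("rates must be non-negative")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if image_shape[0] <= 0 or image_shape[1] <= 0:
        raise ValueError("image shape must be positive")
    rng = np.random.default_rng(seed)
    calibration = calibration or PixelCalibration(1.5, frame_interval,
                                                  "um", "h")
    px = calibration.pixel_size_um
    field_um = (image_shape[0] * px, image_shape[1] * px)
    aggs = _simulate_events(n_aggregates, k_deg, k_frag, duration, field_um,
                            blob_sigma_um, amplitude, amplitude_cv, rng)
    times = np.arange(0.0, duration + 1e-9, frame_interval)
    events = pd.DataFrame([{
        "id": a.agg_id, "parent_id": a.parent_id, "birth_time": a.birth_time,
        "y_um": a.y, "x_um": a.x, "sigma_um": a.sigma_um,
        "conversion_time": a.conversion_time} for a in aggs])

    # fragment lifetimes: an aggregate with children ends at their birth
    end_time = {a.agg_id: np.inf for a in aggs}
    for a in aggs:
        if a.parent_id >= 0:
            end_time[a.parent_id] = min(end_time[a.parent_id], a.birth_time)

    def present(a: _Aggregate, t: float) -> bool:
        return a.birth_time <= t < end_time[a.agg_id]

    if not render:
        wf = np.array([
            (sum(a.sigma_um ** 2 for a in aggs
                 if present(a, t) and t < a.conversion_time) /
             max(sum(a.sigma_um ** 2 for a in aggs if present(a, t)), 1e-12))
            for t in times])
        return None, None, GroundTruth(white_fraction=wf, times=times,
                                       k_deg=k_deg, k_frag=k_frag,
                                       events=events)

    ny, nx = image_shape
    green = np.zeros((len(times), ny, nx))
    red = np.zeros((len(times), ny, nx))
    wf = np.zeros(len(times))
    half_ref = 0.5 * amplitude
    for ti, t in enumerate(times):
        g = np.zeros((ny, nx))
        r = np.zeros((ny, nx))
        for a in aggs:
            if not present(a, t):
                continue
            s_px = a.sigma_um / px
            cy, cx = a.y / px, a.x / px
            w = int(np.ceil(4 * s_px)) + 1
            y0, y1 = max(0, int(cy) - w), min(ny, int(cy) + w + 1)
            x0, x1 = max(0, int(cx) - w), min(nx, int(cx) + w + 1)
            if y0 >= y1 or x0 >= x1:
                continue
            gy = np.arange(y0, y1) - cy
            gx = np.arange(x0, x1) - cx
            blob = a.amplitude * np.exp(
                -(gy[:, None] ** 2 + gx[None, :] ** 2) / (2 * s_px ** 2))
            r[y0:y1, x0:x1] += blob
            if t < a.conversion_time:
                g[y0:y1, x0:x1] += blob
        r_mask = r >= half_ref
        g_mask = g >= half_ref
        red_area = r_mask.sum()
        wf[ti] = (g_mask & r_mask).sum() / red_area if red_area else 0.0
        if noise:
            g = rng.poisson(g + background).astype(float) + \
                rng.normal(0.0, read_noise, g.shape)
            r = rng.poisson(r + background).astype(float) + \
                rng.normal(0.0, read_noise, r.shape)
        green[ti], red[ti] = g, r
    truth = GroundTruth(white_fraction=wf, times=times, k_deg=k_deg,
                        k_frag=k_frag, events=events)
    return (FrameStack(green, calibration, "green"),
            FrameStack(red, calibration, "red"), truth)


# ---------------------------------------------------------------------------
# SMLM localizations on aggregate footprints


def _truncated_normal_2d(n: int, sigma: float, rng: np.random.Generator,
                         max_radius_sigma: float = 3.0) -> np.ndarray:
    """Isotropic Gaussian draws rejected beyond ``max_radius_sigma``."""
    out = np.empty((0, 2))
    while len(out) < n:
        draw = rng.normal(0.0, sigma, size=(2 * (n - len(out)) + 8, 2))
        keep = np.hypot(draw[:, 0], draw[:, 1]) <= max_radius_sigma * sigma
        out = np.vstack([out, draw[keep]])
    return out[:n]


def simulate_smlm_localizations(
        aggregate_masks: np.ndarray, pixel_size_nm: float,
        n_total: int = 250, clustered_fraction: float = 0.6,
        n_clusters: int = 3, cluster_sigma_nm: float = 20.0,
        localization_error_nm: float = 10.0, n_frames: int = 1000,
        min_separation_nm: float | None = None,
        seed: int = 0) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw receptor localizations on aggregate footprints.

    ``aggregate_masks`` is a label image (0 = background); per labelled
    region, ``round(clustered_fraction * n_total)`` molecules are split
    multinomially over ``n_clusters`` isotropic Gaussian clusters
    (s.d. ``cluster_sigma_nm``, truncated at 3 s.d.) centred well inside
    the footprint with pairwise separation at least ``min_separation_nm``
    (default 15x the cluster s.d.); the remainder is uniform on the
    footprint.  Every coordinate is jittered by a truncated Gaussian
    localization error.  Truth labels: cluster index, -1 for background.
    """
    if not 0 <= clustered_fraction <= 1:
        raise ValueError("clustered_fraction must lie in [0, 1]")
    if n_clusters < 0:
        raise ValueError("n_clusters must be >= 0")
    if n_clusters > 0 and cluster_sigma_nm <= 0:
        raise ValueError("cluster_sigma_nm must be positive with clusters")
    labels_img = np.asarray(aggregate_masks)
    roi_ids = [i for i in np.unique(labels_img) if i != 0]
    if not roi_ids:
        raise ValueError("aggregate mask is empty")
    if min_separation_nm is None:
        min_separation_nm = 15.0 * cluster_sigma_nm
    rng = np.random.default_rng(seed)
    rows, truth_labels, centers = [], [], []
    next_cluster = 0
    for roi in roi_ids:
        mask = labels_img == roi
        ys, xs = np.nonzero(mask)
        n_clustered = int(round(clustered_fraction * n_total)) \
            if n_clusters > 0 else 0
        n_bg = n_total - n_clustered
        # cluster centres: well inside the footprint, mutually separated
        if n_clustered > 0:
            margin_px = 3.0 * cluster_sigma_nm / pixel_size_nm
            edt = ndimage.distance_transform_edt(mask)
            cy, cx = np.nonzero(edt >= margin_px)
            if len(cy) == 0:
                cy, cx = ys, xs
            pts = []
            for _ in range(10000):
                if len(pts) == n_clusters:
                    break
                j = rng.integers(len(cy))
                cand = np.array([(cx[j] + 0.5) * pixel_size_nm,
                                 (cy[j] + 0.5) * pixel_size_nm])
                if all(np.hypot(*(cand - p)) >= min_separation_nm
                       for p in pts):
                    pts.append(cand)
            if len(pts) < n_clusters:
                raise ValueError("could not place separated cluster centres "
                                 "in the footprint; reduce min_separation_nm")
            counts = rng.multinomial(n_clustered,
                                     np.full(n_clusters, 1.0 / n_clusters))
            for ci, (centre, cnt) in enumerate(zip(pts, counts)):
                offs = _truncated_normal_2d(cnt, cluster_sigma_nm, rng)
                for o in offs:
                    rows.append(centre + o)
                    truth_labels.append(next_cluster + ci)
                centers.append(centre)
            next_cluster += n_clusters
        if n_bg > 0:
            j = rng.integers(len(ys), size=n_bg)
            u = rng.uniform(0.0, 1.0, size=(n_bg, 2))
            for jj, (uy, ux) in zip(j, u):
                rows.append(np.array([(xs[jj] + ux) * pixel_size_nm,
                                      (ys[jj] + uy) * pixel_size_nm]))
                truth_labels.append(-1)
    if rows:
        pts = np.asarray(rows)
        jitter = _truncated_normal_2d(len(pts), localization_error_nm, rng,
                                      max_radius_sigma=3.9) \
            if localization_error_nm > 0 else np.zeros_like(pts)
        pts = pts + jitter
        table = pd.DataFrame({
            "x_nm": pts[:, 0], "y_nm": pts[:, 1],
            "frame": rng.integers(0, n_frames, size=len(pts)),
            "sigma_nm": np.full(len(pts), max(localization_error_nm, 1.0)),
        })
    else:
        table = pd.DataFrame(columns=["x_nm", "y_nm", "frame", "sigma_nm"])
    truth = GroundTruth(
        cluster_labels=np.asarray(truth_labels, dtype=int),
        n_clusters=next_cluster,
        clustered_fraction=clustered_fraction,
        cluster_centers_nm=np.asarray(centers) if centers else None)
    return table, truth


# ---------------------------------------------------------------------------
# cross-section grey-value profiles


def _truncnorm_params(mean_level: float, cv: float) -> tuple[float, float]:
    """Parent (mu, sigma) of a zero-truncated normal whose truncated
    moments match the target mean and CV (moment-matched so the sample
    CV is unbiased even at large CV)."""
    target_sd = cv * mean_level

    def resid(p):
        mu, log_sigma = p
        sigma = np.exp(log_sigma)
        a = (0.0 - mu) / sigma
        m, v = stats.truncnorm.stats(a, np.inf, loc=mu, scale=sigma,
                                     moments="mv")
        return [m - mean_level, np.sqrt(v) - target_sd]

    sol = optimize.fsolve(resid, [mean_level, np.log(target_sd)],
                          full_output=False)
    return float(sol[0]), float(np.exp(sol[1]))


def simulate_profile(length: int, mean_level: float, cv: float,
                     seed: int = 0) -> "ProfileTrace":
    """Generate a 1-D grey-value cross-section profile.

    Values are positive draws from a zero-truncated normal whose mean is
    ``mean_level`` and coefficient of variation is ``cv`` (the parent
    parameters are moment-matched so truncation does not bias the CV).
    ``cv = 0`` gives a constant profile.
    """
    from .compaction import ProfileTrace  # local import, avoids cycle
    if mean_level <= 0:
        raise ValueError("mean_level must be positive")
    if cv < 0:
        raise ValueError("cv must be non-negative")
    rng = np.random.default_rng(seed)
    positions = np.arange(length, dtype=float)
    if cv == 0:
        values = np.full(length, mean_level)
    else:
        mu, sigma = _truncnorm_params(mean_level, cv)
        a = (0.0 - mu) / sigma
        values = stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sigma,
                                     size=length, random_state=rng)
    return ProfileTrace(positions=positions, values=values,
                        aggregate_id=0, condition="",
                        truth=GroundTruth(mean_level=mean_level, cv=cv))


# ---------------------------------------------------------------------------
# FRAP traces


def simulate_frap(i_pre: float = 1000.0, i_post: float = 300.0,
                  mobile_fraction: float = 0.7, k_rec: float = 0.02,
                  n_frames: int = 80, dt: float = 10.0, n_prebleach: int = 2,
                  noise_sd: float = 0.0,
                  seed: int = 0) -> tuple[TimeSeries, GroundTruth]:
    """Generate a FRAP intensity trace.

    Pre-bleach frames sit at ``i_pre``; after the bleach the intensity
    recovers as ``i_post + mobile_fraction * (i_pre - i_post) *
    (1 - exp(-k_rec * tau))`` with ``tau`` the time since the first
    post-bleach frame, plus optional Gaussian noise.
    """
    if not 0 <= mobile_fraction <= 1:
        raise ValueError("mobile_fraction must lie in [0, 1]")
    if i_post >= i_pre:
        raise ValueError("i_post must be below i_pre")
    if n_prebleach >= n_frames:
        raise ValueError("n_prebleach must be < n_frames")
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) * dt
    values = np.full(n_frames, float(i_pre))
    tau = t[n_prebleach:] - t[n_prebleach]
    values[n_prebleach:] = i_post + mobile_fraction * (i_pre - i_post) * \
        (1.0 - np.exp(-k_rec * tau))
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, n_frames)
    trace = TimeSeries(t, values, label="frap_intensity", unit="a.u.",
                       time_unit="s")
    return trace, GroundTruth(mobile_fraction=mobile_fraction, k_rec=k_rec)


# ---------------------------------------------------------------------------
# raw blinking SMLM movies


def simulate_raw_smlm_frames(
        localizations: pd.DataFrame, n_frames: int = 50,
        blink_rate: float = 0.05, psf_sigma_px: float = 1.3,
        pixel_size_nm: float = 100.0,
        image_shape: tuple[int, int] = (64, 64), photons: float = 2000.0,
        background: float = 20.0, background_drift: float = 0.0,
        drift_px: tuple[float, float] | None = None, noise: bool = True,
        seed: int = 0) -> tuple[FrameStack, GroundTruth]:
    """Render a raw blinking movie from true molecule positions.

    Each molecule emits in an independent Bernoulli(``blink_rate``) subset
    of frames as a Gaussian PSF spot; the background is flat plus an
    optional per-frame additive ramp (``background_drift`` per frame); an
    optional global stage drift of ``drift_px = (dy, dx)`` pixels is
    applied to the second half of the movie and recorded in the truth.
    """
    if psf_sigma_px <= 0:
        raise ValueError("psf_sigma_px must be positive")
    rng = np.random.default_rng(seed)
    ny, nx = image_shape
    frames = np.zeros((n_frames, ny, nx))
    x = localizations["x_nm"].to_numpy() / pixel_size_nm
    y = localizations["y_nm"].to_numpy() / pixel_size_nm
    drift_rows = []
    for t in range(n_frames):
        img = np.full((ny, nx), background, dtype=float)
        if background_drift:
            ramp = np.linspace(0, 1, nx)[None, :] * background_drift * t
            img += ramp
        dy = dx = 0.0
        if drift_px is not None and t >= n_frames // 2:
            dy, dx = drift_px
        drift_rows.append({"frame": t, "dy_px": dy, "dx_px": dx})
        if blink_rate > 0 and len(x):
            on = rng.random(len(x)) < blink_rate
            for xi, yi in zip(x[on], y[on]):
                cy, cx = yi + dy, xi + dx
                w = int(np.ceil(4 * psf_sigma_px)) + 1
                y0, y1 = max(0, int(cy) - w), min(ny, int(cy) + w + 1)
                x0, x1 = max(0, int(cx) - w), min(nx, int(cx) + w + 1)
                if y0 >= y1 or x0 >= x1:
                    continue
                gy = np.arange(y0, y1) - cy
                gx = np.arange(x0, x1) - cx
                spot = np.exp(-(gy[:, None] ** 2 + gx[None, :] ** 2) /
                              (2 * psf_sigma_px ** 2))
                img[y0:y1, x0:x1] += photons * spot / \
                    (2 * np.pi * psf_sigma_px ** 2)
        frames[t] = rng.poisson(img) if noise else img
    calib = PixelCalibration(pixel_size_nm, 1.0, "nm", "s")
    truth = GroundTruth(drift=pd.DataFrame(drift_rows))
    return FrameStack(frames, calib, "smlm_raw"), truth
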