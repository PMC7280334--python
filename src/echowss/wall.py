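"""Vessel-wall tracking and segmentation scoring.

The wall pipeline runs on the compounded image stack: an SVD-based
augmentation first separates tissue and blood and combines them into an
image in which the lumen is strongly negative and the wall strongly
positive; a narrow-band (sparse-field style) region-based level set
then tracks the lumen from frame to frame; directional peak fitting
(DPF) refines each boundary point outward to the half-maximum of the
wall's specular-reflection peak; boundaries are classified
(upper/lower, primary/secondary) and Savitzky-Golay smoothed.
Segmentations are scored by the Dice similarity coefficient and the
mean absolute distance between walls (MADW).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal
from scipy.spatial import cKDTree
from skimage import filters as _skfilters
from skimage import measure as _skmeasure

from .clutter import RankBand, select_blood_band, svd_decompose, svd_filter
from .containers import BoundaryLine, ImageStack

# ---------------------------------------------------------------------------
# image augmentation
# ---------------------------------------------------------------------------


def augment_images(stack: ImageStack, band: RankBand | None = None,
                   window: int = 10) -> ImageStack:
    """Tissue-minus-blood augmentation for wall/lumen distinguishability.

    The stack is SVD-split into tissue and blood reconstructions, the
    envelope (magnitude) of each is moving-window averaged over
    ``window`` frames, both are normalized by their per-stack maximum,
    and the blood image is subtracted from the tissue image.  Output
    values lie in [-1, 1]: lumen strongly negative, wall strongly
    positive.
    """
    if not np.any(stack.frames):
        raise ValueError("cannot augment an all-zero stack")
    decomp = svd_decompose(stack)
    if band is None:
        band = select_blood_band(decomp)
    tissue, blood = svd_filter(stack, band, decomp)

    floor = 1e-6 * np.abs(stack.frames).max()

    def norm_movavg(s: ImageStack) -> np.ndarray:
        env = np.abs(s.frames)
        if window > 1:
            env = ndimage.uniform_filter1d(env, size=min(window, s.n_frames),
                                           axis=0, mode="nearest")
        m = env.max()
        # a numerically empty component must not be amplified to O(1)
        return env / m if m > floor else np.zeros_like(env)

    aug = norm_movavg(tissue) - norm_movavg(blood)
    return ImageStack(aug, stack.pixel_spacing, stack.frame_interval,
                      stack.t0)


def initial_lumen_mask(stack: ImageStack, band: RankBand | None = None,
                       window: int = 10) -> np.ndarray:
    """Programmatic first-frame initialization: threshold of the
    moving-averaged blood envelope (largest connected component)."""
    decomp = svd_decompose(stack)
    if band is None:
        band = select_blood_band(decomp)
    _, blood = svd_filter(stack, band, decomp)
    env = np.abs(blood.frames[:min(window, blood.n_frames)]).mean(axis=0)
    # smooth through the speckle granularity before thresholding
    env = ndimage.gaussian_filter(env, 3.0)
    thr = _skfilters.threshold_otsu(env)
    mask = env > thr
    mask = ndimage.binary_closing(mask, iterations=2)
    lbl, n = ndimage.label(mask)
    if n == 0:
        raise ValueError("no lumen signal found for initialization")
    sizes = ndimage.sum_labels(np.ones_like(lbl), lbl, np.arange(1, n + 1))
    mask = lbl == (1 + int(np.argmax(sizes)))
    mask = ndimage.binary_fill_holes(mask)
    return ndimage.binary_erosion(mask, iterations=2)


# ---------------------------------------------------------------------------
# narrow-band level set
# ---------------------------------------------------------------------------


@dataclass
class LevelSetParams:
    """Region-based active contour settings.

    The speed combines a two-region mean-separation force with a
    curvature regularizer of weight ``curvature_weight``; the signed
    distance function is only updated inside a band of half-width
    ``band_half_width`` pixels around the zero level set.
    """

    curvature_weight: float = 0.2
    band_half_width: float = 2.0
    dt: float = 0.5
    max_iter: int = 500
    track_iter: int = 40
    tol: float = 0.005         # fraction of band px changing sign / iter
    reinit_every: int = 5


def _signed_distance(mask: np.ndarray, clip: float) -> np.ndarray:
    """SDF negative inside, clipped to +-clip (sparse-field storage)."""
    inside = ndimage.distance_transform_edt(mask)
    outside = ndimage.distance_transform_edt(~mask)
    return np.clip(outside - inside, -clip, clip)


def _curvature(phi: np.ndarray) -> np.ndarray:
    fy, fx = np.gradient(phi)
    fyy, fyx = np.gradient(fy)
    fxy, fxx = np.gradient(fx)
    num = fxx * fy ** 2 - 2.0 * fx * fy * fxy + fyy * fx ** 2
    den = (fx ** 2 + fy ** 2) ** 1.5 + 1e-12
    return num / den


def sparse_field_levelset(image: np.ndarray, init_mask: np.ndarray,
                          params: LevelSetParams | None = None,
                          max_iter: int | None = None) -> np.ndarray:
    """Narrow-band region-based level-set segmentation.

    Evolves the zero level set so that it separates the two-region
    means of ``image`` (Chan-Vese type force), updating the signed
    distance function only in the sparse band around the contour.
    Converges when fewer than ``params.tol`` of the band pixels change
    sign in an iteration.
    """
    if params is None:
        params = LevelSetParams()
    if max_iter is None:
        max_iter = params.max_iter
    init_mask = np.asarray(init_mask, dtype=bool)
    if not init_mask.any():
        raise ValueError("empty init mask")
    img = np.asarray(image, dtype=float)
    clip = params.band_half_width + 1.0
    phi = _signed_distance(init_mask, clip)

    converged = False
    check_mask = phi < 0
    for it in range(max_iter):
        band = np.abs(phi) <= params.band_half_width
        if not band.any():
            # saturated between re-inits (stationary front)
            phi = _signed_distance(phi < 0, clip)
            band = np.abs(phi) <= params.band_half_width
        inside = phi < 0
        if not inside.any() or inside.all():
            break
        mu_in = img[inside].mean()
        mu_out = img[~inside].mean()
        force = (img - mu_out) ** 2 - (img - mu_in) ** 2
        fmax = np.abs(force[band]).max()
        if fmax > 0:
            force = force / fmax
        kappa = _curvature(phi)

        upd = params.dt * (-force + params.curvature_weight * kappa)
        phi[band] = np.clip(phi[band] + upd[band], -clip, clip)
        if (it + 1) % params.reinit_every == 0:
            # convergence judged per re-init block: sign flips
            # accumulate over several sub-iterations of front drift
            new_mask = phi < 0
            changed = np.count_nonzero(new_mask != check_mask)
            phi = _signed_distance(new_mask, clip)
            check_mask = new_mask
            if changed < params.tol * max(1, int(band.sum())):
                converged = True
                break
    if not converged and max_iter >= 10:
        warnings.warn("level set did not converge within max_iter",
                      RuntimeWarning, stacklevel=2)
    return phi < 0


def track_sequence(stack: ImageStack, init_mask: np.ndarray,
                   params: LevelSetParams | None = None) -> np.ndarray:
    """Track the lumen through the stack; each frame is initialized
    from the previous frame's converged mask with a reduced iteration
    budget.  Returns a (T, H, W) boolean mask array."""
    if params is None:
        params = LevelSetParams()
    masks = np.empty(stack.frames.shape, dtype=bool)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        prev = sparse_field_levelset(stack.frames[0], init_mask, params)
        masks[0] = prev
        for t in range(1, stack.n_frames):
            prev = sparse_field_levelset(stack.frames[t], prev, params,
                                         max_iter=params.track_iter)
            masks[t] = prev
    return masks


# ---------------------------------------------------------------------------
# boundary extraction
# ---------------------------------------------------------------------------


def _component_contour(mask: np.ndarray) -> np.ndarray:
    """Closed outer contour of one connected component, (N, 2) (row, col)."""
    padded = np.pad(mask, 1).astype(float)
    contours = _skmeasure.find_contours(padded, 0.5)
    contour = max(contours, key=len) - 1.0
    if np.allclose(contour[0], contour[-1]):
        contour = contour[:-1]
    return contour


def _split_upper_lower(contour: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a closed contour at its extremal along-vessel points into
    the two wall arcs; returns (upper, lower) ordered by increasing x."""
    cols = contour[:, 1]
    i_lo, i_hi = int(np.argmin(cols)), int(np.argmax(cols))
    n = len(contour)
    if i_lo == i_hi:
        half = n // 2
        return contour[:half], contour[half:]

    def arc(i, j):
        if i <= j:
            return contour[i:j + 1]
        return np.concatenate([contour[i:], contour[:j + 1]])

    a = arc(i_lo, i_hi)
    b = arc(i_hi, i_lo)
    if a[:, 0].mean() <= b[:, 0].mean():
        upper, lower = a, b
    else:
        upper, lower = b, a
    # keep contour order (sorting would scramble vertical segments);
    # orient both arcs with increasing column
    if upper[-1, 1] < upper[0, 1]:
        upper = upper[::-1]
    if lower[-1, 1] < lower[0, 1]:
        lower = lower[::-1]
    return upper, lower


def _theta_from_points(points: np.ndarray) -> np.ndarray:
    if len(points) < 2:
        return np.zeros(len(points))
    dx = np.gradient(points[:, 0])
    dy = np.gradient(points[:, 1])
    return np.arctan2(dy, dx)


def _to_metres(rc: np.ndarray,
               pixel_spacing: tuple[float, float]) -> np.ndarray:
    """(row, col) pixel indices -> (x, y) metres, pixel-centre registered."""
    sp_ax, sp_lat = pixel_spacing
    x = (rc[:, 1] + 0.5) * sp_lat
    y = (rc[:, 0] + 0.5) * sp_ax
    return np.column_stack([x, y])


def classify_boundaries(mask: np.ndarray,
                        pixel_spacing: tuple[float, float],
                        transducer_side: str = "top",
                        min_size: int = 16) -> list[BoundaryLine]:
    """Label the wall boundaries of every lumen component.

    Each connected lumen component yields an upper (anterior, closer to
    the transducer) and a lower (posterior) polyline; the largest
    component is the primary vessel, the rest secondary.  Labels depend
    only on the mask geometry, never on image intensities.
    """
    lbl, n = ndimage.label(mask)
    if n == 0:
        return []
    sizes = ndimage.sum_labels(np.ones_like(lbl), lbl, np.arange(1, n + 1))
    order = np.argsort(sizes)[::-1]
    out: list[BoundaryLine] = []
    for rank, comp_idx in enumerate(order):
        if sizes[comp_idx] < min_size:
            continue
        comp = lbl == (comp_idx + 1)
        contour = _component_contour(comp)
        upper_rc, lower_rc = _split_upper_lower(contour)
        if transducer_side == "bottom":
            upper_rc, lower_rc = lower_rc, upper_rc
        vessel = "primary" if rank == 0 else "secondary"
        h, w = mask.shape
        for side, rc in (("upper", upper_rc), ("lower", lower_rc)):
            # drop points clipped to the image frame (mask truncation)
            ok = ((rc[:, 0] > 0) & (rc[:, 0] < h - 1)
                  & (rc[:, 1] > 0) & (rc[:, 1] < w - 1))
            if ok.sum() >= 2:
                rc = rc[ok]
            pts = _to_metres(rc, pixel_spacing)
            out.append(BoundaryLine(pts, _theta_from_points(pts),
                                    side, vessel))
    return out


# ---------------------------------------------------------------------------
# directional peak fitting
# ---------------------------------------------------------------------------


def half_max_crossing(profile: np.ndarray, prominence: float,
                      step: float = 1.0) -> float | None:
    """Wall position along one outward intensity profile.

    Finds the first local maximum with topographic prominence at least
    ``prominence`` (the wall's specular peak; low bumps from residual
    lumen signal are rejected) and returns the sub-pixel distance where
    the profile crosses half that peak's height on the lumen side.
    Returns ``None`` when no qualifying peak exists.
    """
    p = np.asarray(profile, dtype=float)
    n = p.size
    peaks, _ = signal.find_peaks(p, prominence=prominence)
    if peaks.size == 0:
        if n >= 2 and p[-1] >= prominence and p[-1] >= p[-2]:
            peak = n - 1            # still rising at the search end
        else:
            return None
    else:
        peak = int(peaks[0])
    half = 0.5 * p[peak]
    cross = 0.0
    for k in range(peak, -1, -1):
        if p[k] < half:
            frac = (half - p[k]) / (p[k + 1] - p[k])
            cross = (k + frac) * step
            break
    return cross


def directional_peak_fit(image: np.ndarray, mask: np.ndarray,
                         pixel_spacing: tuple[float, float],
                         search_len: float = 15.0,
                         prominence: float = 0.05,
                         step: float = 1.0) -> list[BoundaryLine]:
    """Refine mask boundaries outward to the wall's specular peak.

    For every boundary point, the intensity profile of ``image`` is
    sampled along the outward normal; the wall point is placed where
    the profile first crosses half the height of the first local
    maximum exceeding ``prominence`` x image max (sub-pixel, linear
    interpolation).  Points with no qualifying peak fall back to the
    mask contour and are flagged.
    """
    sp_ax, sp_lat = pixel_spacing
    boundaries = classify_boundaries(mask, pixel_spacing)
    img = np.asarray(image, dtype=float)
    prom = prominence * img.max() if img.max() > 0 else np.inf
    n_steps = int(np.ceil(search_len / step)) + 1
    dist = np.arange(n_steps) * step            # px along the normal
    refined: list[BoundaryLine] = []
    for b in boundaries:
        pts_px = np.column_stack([b.points[:, 0] / sp_lat - 0.5,
                                  b.points[:, 1] / sp_ax - 0.5])  # (x, y)
        tx, ty = np.cos(b.theta), np.sin(b.theta)
        # outward normal: away from the lumen (up for upper, down for lower)
        if b.side == "upper":
            nx_, ny_ = ty, -tx
        else:
            nx_, ny_ = -ty, tx
        flip = ny_ * (1 if b.side == "lower" else -1) < 0
        nx_ = np.where(flip, -nx_, nx_)
        ny_ = np.where(flip, -ny_, ny_)

        qx = pts_px[:, 0][:, None] + nx_[:, None] * dist[None, :]
        qy = pts_px[:, 1][:, None] + ny_[:, None] * dist[None, :]
        prof = ndimage.map_coordinates(img, [qy.ravel(), qx.ravel()],
                                       order=1, mode="nearest")
        prof = prof.reshape(qx.shape)           # (n_points, n_steps)

        new_pts = b.points.copy()
        fallback = np.ones(len(b.points), dtype=bool)
        for i in range(prof.shape[0]):
            cross = half_max_crossing(prof[i], prom, step)
            if cross is None:
                continue
            new_pts[i, 0] = b.points[i, 0] + nx_[i] * cross * sp_lat
            new_pts[i, 1] = b.points[i, 1] + ny_[i] * cross * sp_ax
            fallback[i] = False
        if fallback.all():
            warnings.warn("directional peak fit found no wall peak; "
                          "returning mask contour", RuntimeWarning,
                          stacklevel=2)
        refined.append(BoundaryLine(new_pts, _theta_from_points(new_pts),
                                    b.side, b.vessel, fallback))
    return refined


def smooth_boundary(boundary: BoundaryLine, window: int = 21,
                    order: int = 2,
                    spacing: float | None = None) -> BoundaryLine:
    """Savitzky-Golay smooth a boundary along arc length.

    The polyline is first resampled to uniform arc-length spacing
    (default: one pixel-scale unit inferred from the points), then each
    coordinate is filtered; endpoints use the filter's polynomial
    extension.  Boundaries shorter than the window are returned
    unfiltered with ``smoothed=False``.
    """
    if window % 2 == 0 or order >= window:
        raise ValueError("window must be odd and greater than order")
    pts = boundary.points
    if len(pts) < 2:
        return boundary
    arc = boundary.arc_length
    if spacing is None:
        spacing = np.median(np.diff(arc)) or (arc[-1] / max(len(pts) - 1, 1))
    n_new = max(int(np.floor(arc[-1] / spacing)) + 1, 2)
    s_new = np.linspace(0.0, arc[-1], n_new)
    x = np.interp(s_new, arc, pts[:, 0])
    y = np.interp(s_new, arc, pts[:, 1])
    if n_new < window:
        return BoundaryLine(np.column_stack([x, y]),
                            _theta_from_points(np.column_stack([x, y])),
                            boundary.side, boundary.vessel, smoothed=False)
    xs = signal.savgol_filter(x, window, order, mode="interp")
    ys = signal.savgol_filter(y, window, order, mode="interp")
    pts_s = np.column_stack([xs, ys])
    return BoundaryLine(pts_s, _theta_from_points(pts_s), boundary.side,
                        boundary.vessel, smoothed=True)


# ---------------------------------------------------------------------------
# segmentation metrics
# ---------------------------------------------------------------------------


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A n B| / (|A| + |B|)."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (sa + sb)


def madw(contour_m: np.ndarray, contour_gt: np.ndarray,
         symmetric: bool = False) -> float:
    """Mean absolute distance between walls (m).

    One-sided by default: the mean over ground-truth points of the
    distance to the closest point of the measured contour M.
    """
    m = np.asarray(contour_m, dtype=float)
    gt = np.asarray(contour_gt, dtype=float)
    if m.size == 0 or gt.size == 0:
        raise ValueError("empty contour")
    d_gt = cKDTree(m).query(gt)[0]
    if not symmetric:
        return float(np.mean(np.abs(d_gt)))
    d_m = cKDTree(gt).query(m)[0]
    return 0.5 * (float(np.mean(np.abs(d_gt))) + float(np.mean(np.abs(d_m))))


# ---------------------------------------------------------------------------
# diameter waveform
# ---------------------------------------------------------------------------


def _xcorr_shift(a: np.ndarray, b: np.ndarray, max_lag: int) -> float:
    """Sub-pixel lag of b relative to a by 1-D cross-correlation."""
    a = a - a.mean()
    b = b - b.mean()
    c = np.correlate(b, a, mode="full")
    mid = len(a) - 1
    lo, hi = mid - max_lag, mid + max_lag + 1
    seg = c[lo:hi]
    k = int(np.argmax(seg))
    lag = k - max_lag
    if 0 < k < len(seg) - 1:
        den = seg[k - 1] + seg[k + 1] - 2 * seg[k]
        if den < 0:
            lag += 0.5 * (seg[k - 1] - seg[k + 1]) / den
    return float(lag)


def diameter_waveform(stack: ImageStack, init_mask: np.ndarray,
                      n_positions: int = 10, window_half: int = 12,
                      max_lag: int = 5,
                      mode: str = "successive",
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Vessel diameter over time by 1-D wall tracking.

    At ``n_positions`` lateral stations, the axial envelope profiles
    around the upper and lower wall are aligned by 1-D
    cross-correlation; the diameter change is the lower-wall shift
    minus the upper-wall shift, averaged over stations.  With
    ``mode="successive"`` frame-to-frame shifts are accumulated over
    time; ``mode="reference"`` aligns every frame against the first
    frame instead, trading the assumption of a stable wall texture for
    immunity to cumulative drift (at high frame rates the per-frame
    wall motion is far below the correlator's resolution, and its
    random error accumulates into a sizeable artificial excursion).
    Returns ``(times, D)`` in seconds and metres.
    """
    sp_ax = stack.pixel_spacing[0]
    env = np.abs(stack.frames)
    h, w = env.shape[1:]
    cols_with_lumen = np.nonzero(init_mask.any(axis=0))[0]
    if cols_with_lumen.size == 0:
        raise ValueError("init mask has no lumen columns")
    stations = np.linspace(cols_with_lumen[0] + 2, cols_with_lumen[-1] - 2,
                           n_positions).round().astype(int)

    # per-column wall rows, median filtered across columns so that a
    # ragged initial mask cannot misplace a station's window
    up_rows = np.full(w, np.nan)
    lo_rows = np.full(w, np.nan)
    for c in cols_with_lumen:
        rows = np.nonzero(init_mask[:, c])[0]
        up_rows[c], lo_rows[c] = rows[0], rows[-1]
    k = min(9, 2 * (cols_with_lumen.size // 2) - 1)
    if k >= 3:
        up_rows[cols_with_lumen] = signal.medfilt(
            up_rows[cols_with_lumen], k)
        lo_rows[cols_with_lumen] = signal.medfilt(
            lo_rows[cols_with_lumen], k)

    d_changes = []
    d0s = []
    for c in stations:
        if not np.isfinite(up_rows[c]):
            warnings.warn(f"station column {c} outside vessel; skipped",
                          RuntimeWarning, stacklevel=2)
            continue
        up, lo = int(up_rows[c]), int(lo_rows[c])
        d0s.append((lo - up) * sp_ax)
        sl_up = slice(max(up - window_half, 0), min(up + window_half + 1, h))
        sl_lo = slice(max(lo - window_half, 0), min(lo + window_half + 1, h))
        prof_up = env[:, sl_up, c]
        prof_lo = env[:, sl_lo, c]
        shifts = np.zeros(stack.n_frames)
        for t in range(1, stack.n_frames):
            a_up, a_lo = ((prof_up[t - 1], prof_lo[t - 1])
                          if mode == "successive"
                          else (prof_up[0], prof_lo[0]))
            s_up = _xcorr_shift(a_up, prof_up[t], max_lag)
            s_lo = _xcorr_shift(a_lo, prof_lo[t], max_lag)
            shifts[t] = s_lo - s_up
        if mode == "successive":
            d_changes.append(np.cumsum(shifts) * sp_ax)
        else:
            d_changes.append(shifts * sp_ax)
    if not d_changes:
        raise ValueError("no usable stations inside the vessel")
    # median over stations: robust to the occasional station whose
    # window lands badly
    d = float(np.mean(d0s)) + np.median(np.stack(d_changes), axis=0)
    return stack.times, d
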