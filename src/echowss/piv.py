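"""Ultrasound image velocimetry: multipass, window-deforming,
ensemble-averaged normalized cross-correlation.

Frames are divided into interrogation windows (32 x 32 px by default)
whose zero-mean normalized cross-correlation yields one displacement
vector per window.  The window side is halved on every pass, with the
previous pass's field used both as a predictor and (optionally) to
deform the second frame, and the displacement refined to sub-pixel
precision by a three-point Gaussian peak fit.  With interleaved
plane-wave acquisitions, the correlation planes of all low-resolution
image pairs at one time instant are averaged before peak detection
(incoherent ensemble correlation), suppressing noise without blurring
the peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from .containers import ImageStack, VelocityField

_EPS_NMT = 0.1   # px, normalized-median-test noise floor


@dataclass
class PIVConfig:
    """Interrogation parameters.

    ``window`` is the first-pass window side (px); the side is halved
    ``passes - 1`` further times (32 -> 16 -> 8 -> 4 with the
    defaults — three halvings).  The 4 px final pass, stabilised by the
    deforming predictor, puts the first velocity estimate two pixels
    from the wall, which near-wall shear estimation depends on.
    """

    window: int = 32
    passes: int = 4
    overlap: float = 0.5
    ensemble_length: int = 1      # temporal pairs averaged per plane
    deformation: bool = True
    outlier_threshold: float = 2.0
    subpixel: str = "gaussian"

    def __post_init__(self) -> None:
        if self.passes < 1:
            raise ValueError("passes must be >= 1")
        if not (0.0 <= self.overlap <= 0.75):
            raise ValueError("overlap must lie in [0, 0.75]")
        if self.window // (2 ** (self.passes - 1)) < 4:
            raise ValueError("final window side would be < 4 px")
        if self.ensemble_length < 1:
            raise ValueError("ensemble_length must be >= 1")

    @property
    def window_sizes(self) -> list[int]:
        return [self.window // (2 ** p) for p in range(self.passes)]


@dataclass
class CorrelationPlanes:
    """Batch of correlation planes on a window grid.

    ``planes`` has shape (Ny, Nx, 2w-1, 2w-1) over lag offsets
    -(w-1)..(w-1) per axis (lag 0 at index w-1); ``valid`` flags nodes
    whose windows had nonzero variance.
    """

    planes: np.ndarray
    x: np.ndarray        # (Nx,) window-centre columns, px
    y: np.ndarray        # (Ny,) window-centre rows, px
    window: int
    valid: np.ndarray    # (Ny, Nx)


def window_grid(shape: tuple[int, int], window: int,
                overlap: float) -> tuple[np.ndarray, np.ndarray]:
    """Top-left starts of interrogation windows fully inside the frame."""
    step = max(1, int(round(window * (1.0 - overlap))))
    ys = np.arange(0, shape[0] - window + 1, step)
    xs = np.arange(0, shape[1] - window + 1, step)
    if ys.size == 0 or xs.size == 0:
        raise ValueError("frame smaller than interrogation window")
    return ys, xs


def _extract(frame: np.ndarray, ys: np.ndarray, xs: np.ndarray,
             window: int) -> np.ndarray:
    view = sliding_window_view(frame, (window, window))
    return view[np.ix_(ys, xs)]           # (Ny, Nx, w, w)


def correlate_windows(frame_a: np.ndarray, frame_b: np.ndarray,
                      grid: tuple[np.ndarray, np.ndarray],
                      window: int) -> CorrelationPlanes:
    """Zero-mean, unit-variance normalized cross-correlation per window.

    The peak lag equals the integer displacement of ``frame_b``
    relative to ``frame_a`` for pure translations; zero-variance
    (uniform) windows are flagged invalid rather than raising.
    """
    if frame_a.shape != frame_b.shape:
        raise ValueError("frames must share one shape")
    ys, xs = grid
    wa = _extract(np.asarray(frame_a, float), ys, xs, window)
    wb = _extract(np.asarray(frame_b, float), ys, xs, window)
    ny, nx = wa.shape[:2]
    n = window * window

    ma = wa.mean(axis=(-2, -1), keepdims=True)
    mb = wb.mean(axis=(-2, -1), keepdims=True)
    wa = wa - ma
    wb = wb - mb
    sa = np.sqrt((wa ** 2).mean(axis=(-2, -1)))
    sb = np.sqrt((wb ** 2).mean(axis=(-2, -1)))
    valid = (sa > 1e-12) & (sb > 1e-12)

    m = 2 * window
    pa = np.zeros((ny, nx, m, m))
    pb = np.zeros((ny, nx, m, m))
    pa[..., :window, :window] = wa
    pb[..., :window, :window] = wb
    fa = np.fft.rfft2(pa)
    fb = np.fft.rfft2(pb)
    corr = np.fft.irfft2(np.conj(fa) * fb, s=(m, m))
    corr = np.fft.fftshift(corr, axes=(-2, -1))[..., 1:, 1:]  # (2w-1, 2w-1)

    # unbiased estimate: divide by the per-lag overlap count, otherwise
    # the triangular weighting of the linear correlation drags the peak
    # (and the sub-pixel fit) towards zero lag
    lag = np.arange(-(window - 1), window)
    overlap = np.outer(window - np.abs(lag), window - np.abs(lag))
    corr = corr / overlap
    # the overlap-corrected values are only trustworthy within +-w/2
    search = np.abs(lag) <= window // 2
    corr = corr * (search[:, None] & search[None, :])

    denom = (sa * sb)
    denom = np.where(valid, denom, 1.0)
    corr = corr / denom[..., None, None]
    corr[~valid] = 0.0

    cy = ys + (window - 1) / 2.0
    cx = xs + (window - 1) / 2.0
    return CorrelationPlanes(corr, cx, cy, window, valid)


def ensemble_correlate(pairs, grid, window: int) -> CorrelationPlanes:
    """Arithmetic mean of the per-pair correlation planes."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("empty pair list")
    acc = None
    valid = None
    for a, b in pairs:
        cp = correlate_windows(a, b, grid, window)
        acc = cp.planes if acc is None else acc + cp.planes
        valid = cp.valid if valid is None else (valid & cp.valid)
    acc /= len(pairs)
    cy = grid[0] + (window - 1) / 2.0
    cx = grid[1] + (window - 1) / 2.0
    return CorrelationPlanes(acc, cx, cy, window, valid)


def subpixel_peak(plane: np.ndarray,
                  fit: str = "gaussian") -> tuple[float, float, bool]:
    """Sub-pixel peak lag of one correlation plane.

    Returns ``(lag_y, lag_x, on_border)``; a three-point Gaussian fit is
    applied independently per axis, falling back to a parabolic fit when
    the neighbouring values are non-positive.
    """
    lags, valid, border = _subpixel_batch(plane[None, ...], fit)
    return float(lags[0, 0]), float(lags[0, 1]), bool(border[0])


def _subpixel_batch(planes: np.ndarray, fit: str = "gaussian",
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized sub-pixel peak over a batch of (..., P, P) planes.

    Returns (lags (N, 2) as (lag_y, lag_x), peak_ok, on_border).
    """
    shp = planes.shape
    p = shp[-1]
    c0 = p // 2                      # lag-0 index of the (2w-1) plane
    flat = planes.reshape(-1, p * p)
    idx = np.argmax(flat, axis=1)
    iy, ix = np.divmod(idx, p)
    border = (iy == 0) | (iy == p - 1) | (ix == 0) | (ix == p - 1)
    iy_c = np.clip(iy, 1, p - 2)
    ix_c = np.clip(ix, 1, p - 2)
    rows = np.arange(flat.shape[0])
    planes2 = planes.reshape(-1, p, p)

    def axis_offset(cm, c0_, cp):
        off = np.zeros_like(cm)
        if fit == "gaussian":
            pos = (cm > 0) & (cp > 0) & (c0_ > 0)
        else:
            pos = np.zeros(cm.shape, dtype=bool)
        with np.errstate(divide="ignore", invalid="ignore"):
            lcm, lc0, lcp = np.log(cm), np.log(c0_), np.log(cp)
            den_g = lcm + lcp - 2 * lc0
            g = 0.5 * (lcm - lcp) / den_g
            den_p = cm + cp - 2 * c0_
            q = 0.5 * (cm - cp) / den_p
        g = np.where(np.abs(den_g) > 1e-300, g, 0.0)
        q = np.where(np.abs(den_p) > 1e-300, q, 0.0)
        off = np.where(pos, g, q)
        return np.clip(np.nan_to_num(off), -0.9999, 0.9999)

    cyv = planes2[rows, iy_c, ix_c]
    dy = axis_offset(planes2[rows, iy_c - 1, ix_c], cyv,
                     planes2[rows, iy_c + 1, ix_c])
    dx = axis_offset(planes2[rows, iy_c, ix_c - 1], cyv,
                     planes2[rows, iy_c, ix_c + 1])
    lag_y = (iy - c0) + np.where(border, 0.0, dy)
    lag_x = (ix - c0) + np.where(border, 0.0, dx)
    peak_ok = planes2[rows, iy, ix] > 0
    lags = np.stack([lag_y, lag_x], axis=1)
    return (lags.reshape(shp[:-2] + (2,)), peak_ok.reshape(shp[:-2]),
            border.reshape(shp[:-2]))


# ---------------------------------------------------------------------------
# outlier rejection
# ---------------------------------------------------------------------------


def _neighbor_stack(a: np.ndarray) -> np.ndarray:
    """(8, Ny, Nx) stack of 3x3 neighbours, NaN outside the grid."""
    pad = np.pad(a, 1, mode="constant", constant_values=np.nan)
    out = []
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dy == 0 and dx == 0:
                continue
            out.append(pad[1 + dy:1 + dy + a.shape[0],
                           1 + dx:1 + dx + a.shape[1]])
    return np.stack(out)


def normalized_median_residual(u: np.ndarray, v: np.ndarray,
                               valid: np.ndarray | None = None) -> np.ndarray:
    """Universal-outlier-detection residual, max over components."""
    import warnings as _warnings

    res = np.zeros(u.shape)
    for comp in (u, v):
        c = comp.astype(float).copy()
        if valid is not None:
            c[~valid] = np.nan
        nb = _neighbor_stack(c)
        with np.errstate(all="ignore"), _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            med = np.nanmedian(nb, axis=0)
            fluct = np.nanmedian(np.abs(nb - med), axis=0)
            r = np.abs(comp - med) / (fluct + _EPS_NMT)
        res = np.maximum(res, np.nan_to_num(r))
    return res


def _replace_by_neighbor_median(u, v, reject):
    """Median-of-valid-neighbours replacement for rejected vectors."""
    import warnings as _warnings

    for comp in (u, v):
        c = comp.copy()
        c[reject] = np.nan
        nb = _neighbor_stack(c)
        with np.errstate(all="ignore"), _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            med = np.nanmedian(nb, axis=0)
            glob = np.nanmedian(c) if np.isfinite(c).any() else 0.0
        med = np.where(np.isnan(med), glob, med)
        comp[reject] = med[reject]
    return u, v


def validate_vectors(field: VelocityField,
                     threshold: float = 2.0) -> VelocityField:
    """Normalized median test on 3x3 neighbourhoods.

    Rejected vectors are replaced by the median of their valid
    neighbours and flagged invalid (interpolated) in the mask.
    """
    out = field.copy()
    for t in range(out.n_frames):
        res = normalized_median_residual(out.u[t], out.v[t], out.valid[t])
        reject = (res > threshold) & out.valid[t]
        if reject.any():
            _replace_by_neighbor_median(out.u[t], out.v[t], reject)
            out.valid[t] = out.valid[t] & ~reject
    return out


# ---------------------------------------------------------------------------
# multipass driver
# ---------------------------------------------------------------------------


def _interp_node_field(values: np.ndarray, ys: np.ndarray, xs: np.ndarray,
                       qy: np.ndarray, qx: np.ndarray,
                       grid: bool = False) -> np.ndarray:
    """Bilinear interpolation of a node field to query points (px),
    clamped to the grid hull.  With ``grid=True`` the queries are axis
    vectors spanning a full output grid."""
    iy = np.interp(qy, ys, np.arange(ys.size))
    ix = np.interp(qx, xs, np.arange(xs.size))
    if grid:
        iy, ix = np.meshgrid(iy, ix, indexing="ij")
    return ndimage.map_coordinates(values, [iy, ix], order=1,
                                   mode="nearest")


def multipass(pairs: list[tuple[np.ndarray, np.ndarray]],
              config: PIVConfig,
              mask: np.ndarray | None = None,
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                         np.ndarray, np.ndarray]:
    """Multipass ensemble PIV of one time instant.

    ``pairs`` is the ensemble of (frame_a, frame_b) arrays sharing one
    shape.  Returns ``(u, v, valid, grid_y, grid_x)`` with displacements
    in px/pair on the final window grid.
    """
    if not pairs:
        raise ValueError("multipass requires at least one image pair")
    shape = pairs[0][0].shape
    pred_u = pred_v = None
    ys_c = xs_c = None

    for win in config.window_sizes:
        starts = window_grid(shape, win, config.overlap)
        cy = starts[0] + (win - 1) / 2.0
        cx = starts[1] + (win - 1) / 2.0

        if pred_u is None:
            pu = np.zeros((cy.size, cx.size))
            pv = np.zeros_like(pu)
        else:
            pu = _interp_node_field(pred_u, ys_c, xs_c, cy, cx, grid=True)
            pv = _interp_node_field(pred_v, ys_c, xs_c, cy, cx, grid=True)

        use_pairs = pairs
        if config.deformation and pred_u is not None and \
                (np.abs(pu).max() > 1e-3 or np.abs(pv).max() > 1e-3):
            yy, xx = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
            du = _interp_node_field(pred_u, ys_c, xs_c,
                                    yy.ravel(), xx.ravel()).reshape(shape)
            dv = _interp_node_field(pred_v, ys_c, xs_c,
                                    yy.ravel(), xx.ravel()).reshape(shape)
            use_pairs = [
                (a, ndimage.map_coordinates(b, [yy + dv, xx + du],
                                            order=1, mode="nearest"))
                for a, b in pairs
            ]

        cp = ensemble_correlate(use_pairs, starts, win)
        lags, peak_ok, border = _subpixel_batch(cp.planes, config.subpixel)
        du = lags[..., 1]
        dv = lags[..., 0]
        node_valid = cp.valid & peak_ok

        u = pu + du
        v = pv + dv
        res = normalized_median_residual(u, v, node_valid)
        reject = (res > config.outlier_threshold) | ~node_valid
        if reject.any():
            _replace_by_neighbor_median(u, v, reject)
        node_valid = ~reject

        pred_u, pred_v = u, v
        ys_c, xs_c = cy, cx

    valid = node_valid
    if mask is not None:
        my = np.clip(np.round(ys_c).astype(int), 0, shape[0] - 1)
        mx = np.clip(np.round(xs_c).astype(int), 0, shape[1] - 1)
        inside = mask[np.ix_(my, mx)]
        valid = valid & inside
    return pred_u, pred_v, valid, ys_c, xs_c


def piv_analyze(stacks: list[ImageStack], config: PIVConfig | None = None,
                mask: np.ndarray | None = None) -> VelocityField:
    """Run multipass ensemble PIV over a set of interleaved angle stacks.

    For every time index ``t`` the pairs ``(stack[a][t], stack[a][t+1])``
    over all angle stacks (and ``ensemble_length`` consecutive steps)
    form the correlation ensemble.  The output field is in m/s: px/pair
    times pixel spacing over the pair interval.
    """
    if config is None:
        config = PIVConfig()
    if not stacks:
        raise ValueError("piv_analyze requires at least one stack")
    n_frames = min(s.n_frames for s in stacks)
    n_pairs = n_frames - config.ensemble_length
    if n_pairs < 1:
        raise ValueError("fewer frames than ensemble length + 1")
    dt_pair = stacks[0].frame_interval
    sp_ax, sp_lat = stacks[0].pixel_spacing

    u_out = v_out = valid_out = None
    ys = xs = None
    times = np.empty(n_pairs)
    for t in range(n_pairs):
        pairs = [(s.frames[t + k], s.frames[t + k + 1])
                 for s in stacks for k in range(config.ensemble_length)]
        u, v, val, ys, xs = multipass(pairs, config, mask)
        if u_out is None:
            u_out = np.empty((n_pairs,) + u.shape)
            v_out = np.empty_like(u_out)
            valid_out = np.empty((n_pairs,) + u.shape, dtype=bool)
        u_out[t], v_out[t], valid_out[t] = u, v, val
        times[t] = (np.mean([s.t0 for s in stacks]) + (t + 0.5) * dt_pair
                    + (config.ensemble_length - 1) * dt_pair / 2.0)

    return VelocityField(
        u=u_out * sp_lat / dt_pair,
        v=v_out * sp_ax / dt_pair,
        x=xs, y=ys, valid=valid_out,
        pixel_spacing=(sp_ax, sp_lat), times=times,
    )
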