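"""Wall shear rate and stress along tracked boundaries.

WSS is the product of the blood's dynamic viscosity and the
wall-tangential fluid strain-rate component:

    tau_w = mu_b * eps'_12,     eps_ij = du_i/dx_j + du_j/dx_i,

where the image-oriented strain-rate tensor eps_ij is rotated into the
wall-oriented frame by the local tangent angle theta.  In practice the
near-wall gradient is estimated from the tangential velocity profile
sampled along the inward wall normal: the profile is Savitzky-Golay
filtered (third order, relative length n/D = 0.4) and the shear rate is
taken from the two closest points to the wall with the no-slip zero
imposed at the wall itself; the per-point shear is then median filtered
along the luminal border.  Cycle statistics follow:

    TAWSS_xz = (1/T) integral |tau_w| dt
    OSI_xz   = 1/2 (1 - |tau_mean,xz| / TAWSS_xz)  in [0, 0.5].
"""

from __future__ import annotations

from dataclasses import dataclass, field as _field

import numpy as np
from scipy import ndimage, signal

from .containers import BoundaryLine, VelocityField, WSSSeries

DEFAULT_VISCOSITY = 4.043e-3   # Pa s, blood at high shear rates


# ---------------------------------------------------------------------------
# strain-rate tensor and rotation
# ---------------------------------------------------------------------------


@dataclass
class StrainRateField:
    """Per-node symmetric 2x2 strain-rate tensor components (1/s).

    Index 1 is the lateral (x) direction and 2 the axial (y) direction;
    components follow the unhalved convention ``eps_ij = du_i/dx_j +
    du_j/dx_i`` (simple shear u = gamma*y gives eps_12 = gamma).
    """

    e11: np.ndarray
    e12: np.ndarray
    e22: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray | None = None


def strain_rate(field: VelocityField) -> StrainRateField:
    """Central-difference strain-rate tensor of a gridded velocity field."""
    if field.x.size < 2 or field.y.size < 2:
        raise ValueError("strain_rate needs at least a 2x2 grid")
    sp_ax, sp_lat = field.pixel_spacing
    x_m = field.x * sp_lat
    y_m = field.y * sp_ax
    dudy, dudx = np.gradient(field.u, y_m, x_m, axis=(1, 2))
    dvdy, dvdx = np.gradient(field.v, y_m, x_m, axis=(1, 2))
    return StrainRateField(
        e11=2.0 * dudx,
        e12=dudy + dvdx,
        e22=2.0 * dvdy,
        x=field.x, y=field.y, valid=field.valid,
    )


def rotate_tensor(e11, e12, e22, theta, full: bool = False):
    """Rotate strain-rate tensor components into the wall-oriented frame.

    Applies the full second-rank transformation ``eps'_mn = a_mi a_nj
    eps_ij`` with ``a = [[cos t, sin t], [-sin t, cos t]]``.  Returns
    ``eps'_12`` (tangential-normal component) or, with ``full=True``,
    the tuple ``(eps'_11, eps'_12, eps'_22)``.
    """
    c, s = np.cos(theta), np.sin(theta)
    e12p = (e22 - e11) * c * s + e12 * (c * c - s * s)
    if not full:
        return e12p
    e11p = e11 * c * c + 2.0 * e12 * c * s + e22 * s * s
    e22p = e11 * s * s - 2.0 * e12 * c * s + e22 * c * c
    return e11p, e12p, e22p


# ---------------------------------------------------------------------------
# near-wall shear from velocity profiles
# ---------------------------------------------------------------------------


def _sample_field_at(field: VelocityField, t: int, x_px: np.ndarray,
                     y_px: np.ndarray):
    """Bilinear sample of (u, v, validity) at pixel coordinates."""
    iy = np.interp(y_px, field.y, np.arange(field.y.size))
    ix = np.interp(x_px, field.x, np.arange(field.x.size))
    coords = [iy.ravel(), ix.ravel()]
    u = ndimage.map_coordinates(field.u[t], coords, order=1, mode="nearest")
    v = ndimage.map_coordinates(field.v[t], coords, order=1, mode="nearest")
    ok = ndimage.map_coordinates(field.valid[t].astype(float), coords,
                                 order=1, mode="constant", cval=0.0)
    # off-grid queries are not trustworthy
    inside = ((y_px.ravel() >= field.y[0]) & (y_px.ravel() <= field.y[-1])
              & (x_px.ravel() >= field.x[0]) & (x_px.ravel() <= field.x[-1]))
    ok = (ok > 0.999) & inside
    shape = x_px.shape
    return u.reshape(shape), v.reshape(shape), ok.reshape(shape)


def _sg_window(diameter: float, spacing: float, n_samples: int,
               rel_length: float = 0.4, order: int = 3) -> int:
    """Savitzky-Golay window: n = rel_length * D / spacing, forced odd
    and shrunk to the largest valid length for short profiles."""
    n = int(round(rel_length * diameter / spacing))
    n = n if n % 2 == 1 else n + 1
    n = min(n, n_samples if n_samples % 2 == 1 else n_samples - 1)
    return max(n, order + 2 if (order + 2) % 2 == 1 else order + 3)


def _wall_derivative(d1: float, u1: float, d2: float, u2: float) -> float:
    """Exact wall derivative of the quadratic through (0,0), (d1,u1),
    (d2,u2): the no-slip anchored two-closest-points estimator."""
    return (u1 * d2 ** 2 - u2 * d1 ** 2) / (d1 * d2 * (d2 - d1))


def _wall_derivative_poly(dist: np.ndarray, u: np.ndarray) -> float:
    """Wall derivative of the polynomial through the origin and the
    given near-wall samples (degree = number of samples)."""
    a = np.vander(dist, len(dist) + 1, increasing=True)[:, 1:]
    return float(np.linalg.solve(a, u)[0])


def near_wall_shear(field: VelocityField, boundary: BoundaryLine,
                    diameter: float, t: int,
                    median_width: int = 5,
                    sample_step: float | None = None,
                    wall_guard: int = 2,
                    fit_points: int = 2,
                    rel_filter_length: float = 0.4,
                    sg_order: int = 3) -> np.ndarray:
    """Wall shear rate (1/s) at every point of one boundary, one frame.

    The velocity is sampled along the inward wall normal over one
    radius at the velocity grid's own pitch (vectors closer together
    carry no independent information), projected onto the wall tangent,
    filtered by a third-order Savitzky-Golay filter of relative length
    ``rel_filter_length`` = n/D, and differentiated at the wall from
    the ``fit_points`` closest valid points with the no-slip zero
    anchored at the wall (exact wall derivative of the through-zero
    polynomial — the two-point default is exact on a parabolic
    profile; three points additionally track boundary-layer curvature
    at the cost of more noise).  ``wall_guard`` skips grid steps next
    to the wall: image velocities within roughly the axial PSF width
    of the boundary are biased toward the faster lumen side because
    their speckle sources are one-sided.  Positive shear corresponds
    to forward (along-tangent) flow.
    """
    sp_ax, sp_lat = field.pixel_spacing
    if sample_step is None:
        step_px = float(np.median(np.diff(field.y))) if field.y.size > 1 \
            else 1.0
        h = step_px * sp_ax
    else:
        h = sample_step
    depth = diameter / 2.0
    n_samp = max(int(np.floor(depth / h)), 4)
    dist = (np.arange(n_samp) + 1 + wall_guard) * h  # m, wall inward

    pts = boundary.points
    tx, ty = np.cos(boundary.theta), np.sin(boundary.theta)
    if boundary.side == "upper":
        nx_, ny_ = -ty, tx        # inward: downward for the upper wall
        ny_sign = 1.0
    else:
        nx_, ny_ = ty, -tx
        ny_sign = -1.0
    flip = ny_ * ny_sign < 0
    nx_ = np.where(flip, -nx_, nx_)
    ny_ = np.where(flip, -ny_, ny_)

    qx = (pts[:, 0][:, None] + nx_[:, None] * dist[None, :]) / sp_lat - 0.5
    qy = (pts[:, 1][:, None] + ny_[:, None] * dist[None, :]) / sp_ax - 0.5
    u, v, ok = _sample_field_at(field, t, qx, qy)
    u_t = u * tx[:, None] + v * ty[:, None]       # tangential component

    win = _sg_window(diameter, h, n_samp, rel_filter_length, sg_order)
    shear = np.full(len(pts), np.nan)
    for i in range(len(pts)):
        good = np.nonzero(ok[i])[0]
        if good.size < 2:
            continue
        # longest leading run of valid samples starting at the wall side
        k0 = good[0]
        run_end = k0
        for g in good:
            if g == run_end:
                run_end += 1
            else:
                break
        prof = u_t[i, k0:run_end]
        if prof.size >= 2:
            w = min(win, prof.size if prof.size % 2 == 1 else prof.size - 1)
            if w > sg_order + 1 and w >= 5:
                prof = signal.savgol_filter(prof, w, sg_order, mode="interp")
            npt = min(fit_points, prof.size)
            if npt == 2:
                shear[i] = _wall_derivative(dist[k0], prof[0],
                                            dist[k0 + 1], prof[1])
            else:
                shear[i] = _wall_derivative_poly(dist[k0:k0 + npt],
                                                 prof[:npt])
    valid = np.isfinite(shear)
    if valid.sum() >= median_width:
        filled = shear.copy()
        filled[~valid] = np.interp(np.nonzero(~valid)[0],
                                   np.nonzero(valid)[0], shear[valid])
        sm = signal.medfilt(filled, kernel_size=median_width)
        sm[~valid] = np.nan
        shear = sm
    return shear


# ---------------------------------------------------------------------------
# WSS series and cycle statistics
# ---------------------------------------------------------------------------


def wss_series(shear: dict, times: np.ndarray,
               viscosity: float = DEFAULT_VISCOSITY,
               arc_length: dict | None = None) -> WSSSeries:
    """Scale shear-rate series (keyed by (vessel, side), (T, N) arrays)
    to wall shear stress and assemble the series container."""
    if viscosity <= 0:
        raise ValueError("viscosity must be positive")
    tau = {k: viscosity * np.asarray(v, dtype=float)
           for k, v in shear.items()}
    series = WSSSeries(tau=tau, times=np.asarray(times, float),
                       viscosity=viscosity,
                       arc_length=dict(arc_length or {}))
    duration = series.times[-1] - series.times[0] if len(series.times) > 1 \
        else 1.0
    for key, t_arr in tau.items():
        series.tawss[key] = tawss(t_arr, duration, series.times)
        series.osi[key] = osi(t_arr, duration, series.times)
        series.mean_waveform[key] = np.nanmean(t_arr, axis=1)
    return series


def tawss(tau: np.ndarray, period: float,
          times: np.ndarray | None = None) -> np.ndarray:
    """Time-averaged |WSS| over the cycle, trapezoidal rule, per point."""
    tau = np.asarray(tau, dtype=float)
    if tau.size == 0:
        raise ValueError("empty WSS series")
    if tau.ndim == 1:
        tau = tau[:, None]
    a = np.abs(np.where(np.isfinite(tau), tau, 0.0))
    w = np.isfinite(tau).astype(float)
    if times is None:
        times = np.linspace(0.0, period, tau.shape[0])
    num = np.trapezoid(a, times, axis=0)
    den = np.trapezoid(w, times, axis=0)
    out = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return out if out.size > 1 else float(out[0])


def osi(tau: np.ndarray, period: float,
        times: np.ndarray | None = None) -> np.ndarray:
    """Oscillatory shear index 1/2 (1 - |mean tau| / TAWSS) in [0, 0.5].

    Points with zero TAWSS (degenerate, no shear at all) return 0.
    """
    tau = np.asarray(tau, dtype=float)
    if tau.ndim == 1:
        tau = tau[:, None]
    if times is None:
        times = np.linspace(0.0, period, tau.shape[0])
    s = np.where(np.isfinite(tau), tau, 0.0)
    w = np.isfinite(tau).astype(float)
    den_t = np.trapezoid(w, times, axis=0)
    den_t = np.where(den_t > 0, den_t, 1.0)
    mean_abs = np.trapezoid(np.abs(s), times, axis=0) / den_t
    abs_mean = np.abs(np.trapezoid(s, times, axis=0)) / den_t
    with np.errstate(invalid="ignore", divide="ignore"):
        val = 0.5 * (1.0 - abs_mean / mean_abs)
    val = np.where(mean_abs > 0, val, 0.0)
    val = np.clip(val, 0.0, 0.5)
    return val if val.size > 1 else float(val[0])


def poiseuille_wss(viscosity: float, v_mean, diameter):
    """Analytic Poiseuille WSS ``8 mu v_mean / D`` (Pa).

    With waveform arrays for ``v_mean`` (and optionally ``diameter``)
    the time average of |tau| (TAWSS_HP) is also meaningful via
    ``np.mean(np.abs(...))`` on the returned array.
    """
    diameter = np.asarray(diameter, dtype=float)
    if np.any(diameter <= 0):
        raise ValueError("diameter must be positive")
    return 8.0 * viscosity * np.asarray(v_mean, dtype=float) / diameter


@dataclass
class WaveformErrors:
    normalized_mean_error_pct: float
    rmse: float
    nrmse_pct: float
    pearson_r: float
    extras: dict = _field(default_factory=dict)


def waveform_metrics(measured: np.ndarray, reference: np.ndarray,
                     normalization: str = "max") -> WaveformErrors:
    """Agreement metrics between two waveforms on a common time base.

    normalized mean error = mean|m - r| / norm(r) * 100 with
    ``normalization`` in {"max" (default, max |r|), "mean", "range"};
    NRMSE = RMSE / (max r - min r) * 100; Pearson r on paired samples.
    """
    m = np.asarray(measured, dtype=float)
    r = np.asarray(reference, dtype=float)
    if m.shape != r.shape:
        raise ValueError("waveforms must share a common time base")
    err = m - r
    rmse = float(np.sqrt(np.mean(err ** 2)))
    rng = float(r.max() - r.min())
    if rng == 0:
        raise ValueError("constant reference: NRMSE undefined")
    norms = {"max": float(np.max(np.abs(r))),
             "mean": float(np.mean(np.abs(r))),
             "range": rng}
    if normalization not in norms:
        raise ValueError(f"unknown normalization {normalization!r}")
    nme = float(np.mean(np.abs(err))) / norms[normalization] * 100.0
    if np.std(m) == 0 or np.std(r) == 0:
        pearson = 1.0 if np.allclose(m, r) else 0.0
    else:
        pearson = float(np.corrcoef(m, r)[0, 1])
    return WaveformErrors(nme, rmse, rmse / rng * 100.0, pearson)
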