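"""Moving-wall pulsatile-flow speckle phantom with an exact flow oracle.

The phantom emulates a straight vessel segment (2.6--2.8 mm pulsating
diameter, three-layer 200 um wall) imaged at a 15 degree beam-to-flow
angle with plane-wave compounding (PRF 4500 Hz, 3 angles, 1500 fps).
Blood flow is an analytic Poiseuille or Womersley solution in a tube of
quasi-statically varying radius; point scatterers seeded in the lumen,
wall layers and surrounding tissue are advected by that field and
rendered into B-mode-like frames by convolution with a separable
Gaussian point-spread function.

Because the scatterers are displaced by the *same* analytic field whose
wall derivative is known in closed form, the generated image sequence
comes with an exact velocity and wall-shear-stress oracle — something a
discretized CFD solution cannot provide.

Coordinates
-----------
Vessel frame: ``s`` along the vessel axis (m), ``d`` signed distance
from the centreline (m).  Image frame: x lateral (columns), y axial
(rows, positive downward); the vessel axis passes through the image
centre at ``beam_to_flow_angle`` below the lateral axis.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import h5py
import numpy as np
import yaml
from scipy import ndimage, special

from .containers import ImageStack

# ---------------------------------------------------------------------------
# default waveforms
# ---------------------------------------------------------------------------


def _vm_bump(phase: np.ndarray | float, centre: float, kappa: float):
    """Periodic (von Mises shaped) unit-height bump on phase in [0, 1)."""
    return np.exp(kappa * (np.cos(2.0 * np.pi * (phase - centre)) - 1.0))


def default_mean_velocity_waveform(t, period: float):
    """Aorta-like spatial-mean axial velocity (m/s): systolic peak
    ~0.26 m/s with a brief early-diastolic reversal."""
    ph = np.asarray(t, dtype=float) / period
    v = (0.04 + 0.22 * _vm_bump(ph, 0.18, 14.0)
         - 0.045 * _vm_bump(ph, 0.38, 20.0))
    return v


def default_diameter_waveform(t, period: float,
                              d_min: float = 2.6e-3, d_max: float = 2.8e-3):
    """Diameter waveform (m): 2.6 mm diastolic to 2.8 mm systolic,
    distension lagging the velocity peak."""
    ph = np.asarray(t, dtype=float) / period
    w = _vm_bump(ph, 0.26, 18.0)
    return d_min + (d_max - d_min) * w


# Two-component mean magnitude +/- SD per scatterer compartment.
TABLE1_AMPLITUDES: dict[str, tuple[float, float]] = {
    "tissue": (2.5, 0.01),
    "intima": (0.0, 1.0),
    "media": (2.5, 0.01),
    "adventitia": (0.0, 0.01),
    "lumen": (1.4, 0.01),
}

_LABELS = ("lumen", "intima", "media", "adventitia", "tissue")
_LABEL_CODE = {name: i for i, name in enumerate(_LABELS)}


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class PhantomConfig:
    """Full description of one phantom acquisition.

    ``diameter_waveform`` and ``mean_velocity_waveform`` are callables
    ``f(t_seconds) -> value``; when left as ``None`` the defaults above
    (scaled to ``cycle_period``) are used.
    """

    cycle_period: float = 1.0 / 3.0
    diameter_waveform: Callable | None = None
    mean_velocity_waveform: Callable | None = None
    beam_to_flow_angle: float = 15.0          # degrees
    wall_thickness: float = 200e-6            # m, three equal layers
    layer_amplitudes: dict = field(default_factory=lambda: dict(TABLE1_AMPLITUDES))
    scatterer_density: float = 10.0           # per resolution cell
    image_shape: tuple[int, int] = (512, 128)  # (axial rows, lateral cols)
    pixel_spacing: tuple[float, float] = (3.0e-5, 3.0e-5)  # (axial, lateral) m/px
    frame_interval: float = 1.0 / 1500.0
    prf: float = 4500.0
    n_angles: int = 3
    blood_density: float = 1044.0             # kg/m^3
    blood_viscosity: float = 4.043e-3         # Pa s
    flow_model: str = "womersley"
    n_harmonics: int = 12
    specular_layers: tuple = ("media",)
    psf_sigma: tuple[float, float] = (2.0, 3.0)  # (axial, lateral) px
    noise_std: float = 0.02
    n_cycles: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cycle_period <= 0:
            raise ValueError("cycle_period must be positive")
        if self.wall_thickness <= 0:
            raise ValueError("wall_thickness must be positive")
        if self.n_angles >= 1 and self.prf > 0:
            expected = self.n_angles / self.prf
            if abs(self.frame_interval - expected) > 1e-12:
                raise ValueError(
                    "frame_interval must equal n_angles / prf "
                    f"({expected:.6g} s), got {self.frame_interval:.6g} s")
        if self.flow_model not in ("poiseuille", "womersley"):
            raise ValueError(f"unknown flow_model {self.flow_model!r}")
        if self.diameter_waveform is None:
            per = self.cycle_period
            self.diameter_waveform = lambda t: default_diameter_waveform(t, per)
        if self.mean_velocity_waveform is None:
            per = self.cycle_period
            self.mean_velocity_waveform = \
                lambda t: default_mean_velocity_waveform(t, per)
        d_chk = np.asarray(self.diameter_waveform(
            np.linspace(0, self.cycle_period, 64)))
        if np.any(d_chk <= 0):
            raise ValueError("diameter_waveform must be positive everywhere")
        self._womersley = None

    # -- geometry helpers ---------------------------------------------------

    @property
    def angle_rad(self) -> float:
        return np.deg2rad(self.beam_to_flow_angle)

    @property
    def axis_unit(self) -> np.ndarray:
        a = self.angle_rad
        return np.array([np.cos(a), np.sin(a)])  # (x, y)

    @property
    def normal_unit(self) -> np.ndarray:
        a = self.angle_rad
        return np.array([-np.sin(a), np.cos(a)])

    @property
    def image_extent(self) -> tuple[float, float]:
        """(height, width) of the image in metres."""
        h, w = self.image_shape
        return h * self.pixel_spacing[0], w * self.pixel_spacing[1]

    @property
    def centre(self) -> np.ndarray:
        hy, wx = self.image_extent
        return np.array([wx / 2.0, hy / 2.0])

    def radius(self, t) -> np.ndarray | float:
        return np.asarray(self.diameter_waveform(t)) / 2.0

    def dradius_dt(self, t) -> float:
        h = 1e-5 * self.cycle_period
        return float(self.radius(t + h) - self.radius(t - h)) / (2 * h)

    @property
    def max_radius(self) -> float:
        tt = np.linspace(0, self.cycle_period, 256)
        return float(np.max(self.radius(tt)))

    @property
    def resolution_cell_area(self) -> float:
        fwhm = 2.0 * np.sqrt(2.0 * np.log(2.0))
        ax = fwhm * self.psf_sigma[0] * self.pixel_spacing[0]
        la = fwhm * self.psf_sigma[1] * self.pixel_spacing[1]
        return ax * la

    def axis_half_length(self) -> float:
        """Half-extent of the simulated vessel axis (m)."""
        hy, wx = self.image_extent
        return (wx / 2.0) / np.cos(self.angle_rad) \
            + self.max_radius + self.wall_thickness + 3e-4

    def pixel_vessel_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """(s_map, d_map) vessel-frame coordinates of every pixel centre."""
        h, w = self.image_shape
        ys = (np.arange(h) + 0.5) * self.pixel_spacing[0]
        xs = (np.arange(w) + 0.5) * self.pixel_spacing[1]
        xg, yg = np.meshgrid(xs, ys)
        cx, cy = self.centre
        ex, ey = self.axis_unit
        nx, ny = self.normal_unit
        s = (xg - cx) * ex + (yg - cy) * ey
        d = (xg - cx) * nx + (yg - cy) * ny
        return s, d

    # -- (de)serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            if f.name in ("diameter_waveform", "mean_velocity_waveform"):
                continue
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = list(v)
            out[f.name] = v
        return out

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("image_shape", "pixel_spacing", "psf_sigma"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


# ---------------------------------------------------------------------------
# analytic flow
# ---------------------------------------------------------------------------


class _WomersleyModel:
    """Harmonic decomposition of the mean-velocity waveform with
    Womersley shape functions evaluated at the time-mean radius."""

    def __init__(self, config: PhantomConfig, n_rho: int = 1024):
        if config.cycle_period <= 0:
            raise ValueError("womersley flow requires a positive cycle_period")
        n_t = 1024
        tt = np.arange(n_t) * (config.cycle_period / n_t)
        v = np.asarray(config.mean_velocity_waveform(tt), dtype=float)
        coef = np.fft.rfft(v) / n_t
        self.omega = 2.0 * np.pi / config.cycle_period
        self.v0 = coef[0].real
        n_h = min(config.n_harmonics, len(coef) - 1)
        self.k = np.arange(1, n_h + 1)
        c_k = coef[1:n_h + 1]
        self.c_k = c_k

        r0 = float(np.mean(config.radius(tt)))
        alpha = r0 * np.sqrt(self.k * self.omega
                             * config.blood_density / config.blood_viscosity)
        beta = alpha * np.exp(1j * 3.0 * np.pi / 4.0)  # i^{3/2} alpha
        j0b = special.jv(0, beta)
        j1b = special.jv(1, beta)
        # cross-sectional mean of the shape function 1 - J0(beta rho)/J0(beta)
        m_k = 1.0 - 2.0 * j1b / (beta * j0b)
        self.a_k = c_k / m_k
        self.rho = np.linspace(0.0, 1.0, n_rho)
        # shape functions on the rho grid, (n_rho, n_h)
        self.shape = 1.0 - special.jv(0, np.outer(self.rho, beta)) / j0b
        # d(shape)/d(rho) at the wall
        self.dshape_wall = beta * j1b / j0b

    def _phase(self, t: float) -> np.ndarray:
        return np.exp(1j * self.k * self.omega * t)

    def mean_velocity(self, t: float) -> float:
        """Mean velocity realized by the truncated harmonic series."""
        return float(self.v0 + 2.0 * np.real(np.sum(self.c_k
                                                    * self._phase(t))))

    def profile(self, t: float) -> np.ndarray:
        """Axial velocity sampled on ``self.rho`` (m/s)."""
        ph = self._phase(t)
        u = 2.0 * self.v0 * (1.0 - self.rho ** 2)
        u = u + 2.0 * np.real(self.shape @ (self.a_k * ph))
        return u

    def wall_shear_rate(self, t: float, radius: float) -> float:
        """Shear rate magnitude -du/dr at r = R (positive for forward flow)."""
        ph = self._phase(t)
        g = 4.0 * self.v0 / radius
        g = g - 2.0 * np.real(np.sum(self.a_k * self.dshape_wall * ph)) / radius
        return float(g)


@dataclass
class FlowProfile:
    """Analytic in-plane flow state at one instant.

    ``u_axial(r)`` gives the axial velocity at radial distance ``|r|``
    from the centreline; ``v_radial(d)`` the signed radial velocity
    carrying the wall motion; ``wall_shear_rate`` is ``-du/dr`` at the
    wall (1/s, positive when flow is forward).
    """

    radius: float
    dradius_dt: float
    v_mean: float
    wall_shear_rate: float
    rho_grid: np.ndarray
    u_grid: np.ndarray

    def u_axial(self, r) -> np.ndarray:
        rho = np.abs(np.asarray(r, dtype=float)) / self.radius
        return np.interp(rho, self.rho_grid, self.u_grid, right=0.0)

    def v_radial(self, d) -> np.ndarray:
        return np.asarray(d, dtype=float) / self.radius * self.dradius_dt


def analytic_flow(config: PhantomConfig, t: float) -> FlowProfile:
    """Evaluate the configured flow model at time ``t``.

    Poiseuille: ``u(r) = 2 v_mean (1 - (r/R)^2)`` with wall shear rate
    ``4 v_mean / R``.  Womersley: Bessel-function solution for the
    harmonic decomposition of the mean-velocity waveform, quasi-static
    in the instantaneous radius.  A linear-in-r radial component moves
    the wall with dR/dt.
    """
    radius = float(config.radius(t))
    if radius <= 0:
        raise ValueError("nonpositive vessel radius")
    drdt = config.dradius_dt(t)
    if config.flow_model == "poiseuille":
        v_mean = float(config.mean_velocity_waveform(t))
        rho = np.linspace(0.0, 1.0, 1024)
        u = 2.0 * v_mean * (1.0 - rho ** 2)
        gamma = 4.0 * v_mean / radius
        return FlowProfile(radius, drdt, v_mean, gamma, rho, u)
    if config._womersley is None:
        config._womersley = _WomersleyModel(config)
    wm = config._womersley
    u = wm.profile(t)
    gamma = wm.wall_shear_rate(t, radius)
    return FlowProfile(radius, drdt, wm.mean_velocity(t), gamma, wm.rho, u)


# ---------------------------------------------------------------------------
# scatterers
# ---------------------------------------------------------------------------


@dataclass
class ScattererSet:
    """Point scatterers in the vessel frame.

    ``positions`` is (N, 2) with columns (s, d) in metres; ``labels``
    are integer codes into ``("lumen", "intima", "media", "adventitia",
    "tissue")``.
    """

    positions: np.ndarray
    amplitudes: np.ndarray
    labels: np.ndarray

    def __len__(self) -> int:
        return self.positions.shape[0]

    def select(self, name: str) -> np.ndarray:
        return self.labels == _LABEL_CODE[name]

    def copy(self) -> "ScattererSet":
        return ScattererSet(self.positions.copy(), self.amplitudes.copy(),
                            self.labels.copy())


def _draw_amplitudes(config: PhantomConfig, name: str, n: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Two-component amplitude model: magnitude mean +- SD with random
    sign (diffuse speckle).  Layers listed in ``specular_layers`` keep
    a fixed sign so they sum coherently, mimicking the specular
    reflection of the vessel wall."""
    mean, sd = config.layer_amplitudes[name]
    amp = mean + sd * rng.standard_normal(n)
    if name in config.specular_layers:
        return amp
    return rng.choice([-1.0, 1.0], size=n) * amp


def initialize_scatterers(config: PhantomConfig, t: float = 0.0,
                          rng: np.random.Generator | None = None,
                          ) -> ScattererSet:
    """Seed lumen, three wall layers and surrounding tissue uniformly at
    the configured density per resolution cell."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    r_t = float(config.radius(t))
    wt = config.wall_thickness
    s_half = config.axis_half_length()
    n_per_area = config.scatterer_density / config.resolution_cell_area

    hy, wx = config.image_extent
    d_max = 0.5 * np.hypot(hy, wx) + 3e-4
    s_half_t = s_half + 0.5 * (d_max - r_t) * np.tan(config.angle_rad)

    pos, amp, lab = [], [], []

    def band(name: str, d_lo: float, d_hi: float, s_h: float) -> None:
        area = 2.0 * (d_hi - d_lo) * 2.0 * s_h
        n = rng.poisson(n_per_area * area)
        s = rng.uniform(-s_h, s_h, n)
        mag = rng.uniform(d_lo, d_hi, n)
        sgn = rng.choice([-1.0, 1.0], size=n)
        pos.append(np.column_stack([s, sgn * mag]))
        amp.append(_draw_amplitudes(config, name, n, rng))
        lab.append(np.full(n, _LABEL_CODE[name]))

    # lumen: |d| in [0, R)
    n_lum = rng.poisson(n_per_area * 2.0 * r_t * 2.0 * s_half)
    s = rng.uniform(-s_half, s_half, n_lum)
    d = rng.uniform(-r_t, r_t, n_lum)
    pos.append(np.column_stack([s, d]))
    amp.append(_draw_amplitudes(config, "lumen", n_lum, rng))
    lab.append(np.full(n_lum, _LABEL_CODE["lumen"]))

    layer = wt / 3.0
    band("intima", r_t, r_t + layer, s_half)
    band("media", r_t + layer, r_t + 2 * layer, s_half)
    band("adventitia", r_t + 2 * layer, r_t + wt, s_half)
    band("tissue", r_t + wt, d_max, s_half_t)

    return ScattererSet(np.concatenate(pos), np.concatenate(amp),
                        np.concatenate(lab))


def advect_scatterers(scatterers: ScattererSet, config: PhantomConfig,
                      t: float, dt: float | None = None) -> ScattererSet:
    """Move scatterers from ``t`` to ``t + dt`` by the analytic field.

    Lumen scatterers advance axially by their local axial velocity and
    radially with the wall-conforming linear field (integrated exactly,
    so the fractional radial position is preserved and no scatterer can
    cross the wall).  Wall scatterers translate radially with the wall;
    tissue follows with a 1/|d| decaying radial displacement.
    """
    if dt is None:
        dt = config.frame_interval / config.n_angles
    flow = analytic_flow(config, t)
    r_now = flow.radius
    r_next = float(config.radius(t + dt))

    out = scatterers.copy()
    s = out.positions[:, 0]
    d = out.positions[:, 1]

    lum = out.select("lumen")
    s[lum] = s[lum] + flow.u_axial(d[lum]) * dt
    d[lum] = d[lum] * (r_next / r_now)     # exact for the linear radial field

    wall = (out.select("intima") | out.select("media")
            | out.select("adventitia"))
    d[wall] = np.sign(d[wall]) * (np.abs(d[wall]) + (r_next - r_now))

    tis = out.select("tissue")
    b = r_now + config.wall_thickness
    d[tis] = np.sign(d[tis]) * (
        np.abs(d[tis]) + (r_next - r_now) * b / np.abs(d[tis]))

    if np.any(np.abs(d[lum]) >= r_next):
        raise RuntimeError("lumen scatterer crossed the vessel wall")
    return out


def _subregion_edges(config: PhantomConfig, n: int = 20):
    h, w = config.image_shape
    return (np.linspace(0, h, n + 1) * config.pixel_spacing[0],
            np.linspace(0, w, n + 1) * config.pixel_spacing[1])


def replenish_scatterers(scatterers: ScattererSet, config: PhantomConfig,
                         t: float, rng: np.random.Generator,
                         _cache: dict | None = None) -> ScattererSet:
    """Top up lumen scatterers in depleted image sub-regions.

    The image is partitioned into a 20 x 20 grid of rectangles (each 5%
    of the image length x 5% of the width); any sub-region whose lumen
    scatterer count falls below the density target is refilled by
    uniform random insertion inside the lumen part of that rectangle.
    Counts are never reduced.
    """
    r_t = float(config.radius(t))
    y_edges, x_edges = _subregion_edges(config)
    cx, cy = config.centre
    ex, ey = config.axis_unit
    nx, ny = config.normal_unit

    if _cache is not None and "s_map" in _cache:
        s_map, d_map = _cache["s_map"], _cache["d_map"]
    else:
        s_map, d_map = config.pixel_vessel_coords()
        if _cache is not None:
            _cache["s_map"], _cache["d_map"] = s_map, d_map

    # lumen pixel area per sub-region
    inside = np.abs(d_map) < r_t
    h, w = config.image_shape
    yi = np.clip(np.searchsorted(y_edges, (np.arange(h) + 0.5)
                                 * config.pixel_spacing[0]) - 1, 0, 19)
    xi = np.clip(np.searchsorted(x_edges, (np.arange(w) + 0.5)
                                 * config.pixel_spacing[1]) - 1, 0, 19)
    px_area = config.pixel_spacing[0] * config.pixel_spacing[1]
    counts_area = np.zeros((20, 20))
    np.add.at(counts_area, (yi[:, None].repeat(w, 1)[inside],
                            xi[None, :].repeat(h, 0)[inside]), px_area)
    target = np.floor(counts_area / config.resolution_cell_area
                      * config.scatterer_density).astype(int)

    # current lumen scatterer count per sub-region (image coordinates)
    lum = scatterers.select("lumen")
    p = scatterers.positions[lum]
    px = cx + p[:, 0] * ex + p[:, 1] * nx
    py = cy + p[:, 0] * ey + p[:, 1] * ny
    have, _, _ = np.histogram2d(py, px, bins=[y_edges, x_edges])

    deficit = target - have.astype(int)
    rows, cols = np.nonzero(deficit > 0)
    if rows.size == 0:
        return scatterers

    new_pos = []
    for r_i, c_i in zip(rows, cols):
        need = int(deficit[r_i, c_i])
        got = 0
        for _ in range(50):
            m = max(4 * need, 16)
            qx = rng.uniform(x_edges[c_i], x_edges[c_i + 1], m)
            qy = rng.uniform(y_edges[r_i], y_edges[r_i + 1], m)
            qs = (qx - cx) * ex + (qy - cy) * ey
            qd = (qx - cx) * nx + (qy - cy) * ny
            ok = np.abs(qd) < r_t
            take = min(need - got, int(ok.sum()))
            if take > 0:
                sel = np.nonzero(ok)[0][:take]
                new_pos.append(np.column_stack([qs[sel], qd[sel]]))
                got += take
            if got >= need:
                break
    if not new_pos:
        return scatterers
    new_pos = np.concatenate(new_pos)
    n_new = new_pos.shape[0]
    return ScattererSet(
        np.concatenate([scatterers.positions, new_pos]),
        np.concatenate([scatterers.amplitudes,
                        _draw_amplitudes(config, "lumen", n_new, rng)]),
        np.concatenate([scatterers.labels,
                        np.full(n_new, _LABEL_CODE["lumen"])]),
    )


def _drop_washed_out(scatterers: ScattererSet,
                     config: PhantomConfig) -> ScattererSet:
    s_half = config.axis_half_length()
    keep = ~(scatterers.select("lumen")
             & (np.abs(scatterers.positions[:, 0]) > s_half))
    if keep.all():
        return scatterers
    return ScattererSet(scatterers.positions[keep],
                        scatterers.amplitudes[keep],
                        scatterers.labels[keep])


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def render_frame(scatterers: ScattererSet, config: PhantomConfig,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Render one RF-like frame: amplitude-weighted separable-Gaussian
    PSFs at the scatterer image positions plus additive Gaussian noise.

    The renderer is linear in the scatterer set; the speckle texture
    arises from the interference of the signed amplitudes.  Scatterers
    falling outside the image are silently clipped.
    """
    h, w = config.image_shape
    img = np.zeros((h, w))
    if len(scatterers):
        cx, cy = config.centre
        ex, ey = config.axis_unit
        nx, ny = config.normal_unit
        p = scatterers.positions
        px = (cx + p[:, 0] * ex + p[:, 1] * nx) / config.pixel_spacing[1] - 0.5
        py = (cy + p[:, 0] * ey + p[:, 1] * ny) / config.pixel_spacing[0] - 0.5
        ok = (px > -1) & (px < w) & (py > -1) & (py < h)
        px, py, amp = px[ok], py[ok], scatterers.amplitudes[ok]
        x0 = np.floor(px).astype(int)
        y0 = np.floor(py).astype(int)
        fx = px - x0
        fy = py - y0
        flat = np.zeros(h * w)
        for dy_, dx_, wgt in ((0, 0, (1 - fy) * (1 - fx)),
                              (0, 1, (1 - fy) * fx),
                              (1, 0, fy * (1 - fx)),
                              (1, 1, fy * fx)):
            yy = y0 + dy_
            xx = x0 + dx_
            good = (yy >= 0) & (yy < h) & (xx >= 0) & (xx < w)
            flat += np.bincount(yy[good] * w + xx[good],
                                weights=amp[good] * wgt[good],
                                minlength=h * w)
        img = flat.reshape(h, w)
        img = ndimage.gaussian_filter(img, sigma=config.psf_sigma,
                                      truncate=4.0)
        # scale so a unit scatterer has unit peak amplitude
        img *= 2.0 * np.pi * config.psf_sigma[0] * config.psf_sigma[1]
    if rng is not None and config.noise_std > 0:
        img = img + config.noise_std * rng.standard_normal((h, w))
    return img


# ---------------------------------------------------------------------------
# ground truth + sequence generation
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Exact kinematics of the phantom, sampled for validation.

    Velocity is stored at the inter-frame *pair* times (centre of the
    three-angle correlation ensemble); wall radius is stored both at
    pair times and at compounded frame times.  WSS is the analytic
    ``mu * wall shear rate`` waveform, identical at every point of the
    straight wall (signed positive for forward flow on both sides).
    """

    config: PhantomConfig
    pair_times: np.ndarray        # (T-1,)
    frame_times: np.ndarray       # (T,)
    velocity_u: np.ndarray        # (T-1, H, W) float32, lateral m/s
    velocity_v: np.ndarray        # (T-1, H, W) float32, axial m/s
    radius_pairs: np.ndarray      # (T-1,) m
    radius_frames: np.ndarray     # (T,) m
    wss_pairs: np.ndarray         # (T-1,) Pa (signed, forward positive)
    vmean_pairs: np.ndarray       # (T-1,) m/s

    def lumen_mask(self, radius: float) -> np.ndarray:
        _, d_map = self.config.pixel_vessel_coords()
        return np.abs(d_map) < radius

    def lumen_mask_frame(self, frame: int) -> np.ndarray:
        return self.lumen_mask(float(self.radius_frames[frame]))

    def lumen_mask_pair(self, pair: int) -> np.ndarray:
        return self.lumen_mask(float(self.radius_pairs[pair]))

    def wall_points(self, frame: int, side: str,
                    n_points: int = 200) -> np.ndarray:
        """Inner-wall polyline (n, 2) in metres, image coordinates (x, y)."""
        cfg = self.config
        r = float(self.radius_frames[frame])
        s_half = cfg.axis_half_length()
        s = np.linspace(-s_half, s_half, n_points)
        sign = -1.0 if side == "upper" else 1.0
        cx, cy = cfg.centre
        ex, ey = cfg.axis_unit
        nx, ny = cfg.normal_unit
        x = cx + s * ex + sign * r * nx
        y = cy + s * ey + sign * r * ny
        hy, wx = cfg.image_extent
        ok = (x >= 0) & (x < wx) & (y >= 0) & (y < hy)
        return np.column_stack([x[ok], y[ok]])

    def velocity_at(self, pair: int, x_px: np.ndarray,
                    y_px: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Bilinear sample of the true (u, v) at pixel coordinates."""
        coords = np.array([np.asarray(y_px, float).ravel(),
                           np.asarray(x_px, float).ravel()])
        u = ndimage.map_coordinates(self.velocity_u[pair], coords, order=1)
        v = ndimage.map_coordinates(self.velocity_v[pair], coords, order=1)
        shape = np.asarray(x_px).shape
        return u.reshape(shape), v.reshape(shape)

    def save(self, path: str | Path) -> None:
        with h5py.File(Path(path), "w") as f:
            f.create_dataset("velocity_u", data=self.velocity_u,
                             compression="gzip")
            f.create_dataset("velocity_v", data=self.velocity_v,
                             compression="gzip")
            f.create_dataset("pair_times", data=self.pair_times)
            f.create_dataset("frame_times", data=self.frame_times)
            f.create_dataset("radius_pairs", data=self.radius_pairs)
            f.create_dataset("radius_frames", data=self.radius_frames)
            f.create_dataset("wss", data=self.wss_pairs)
            f.create_dataset("vmean_pairs", data=self.vmean_pairs)
            wp = np.stack([self.wall_points(i, "upper", 64)
                           for i in range(len(self.frame_times))])
            f.create_dataset("wall_points", data=wp)
            f.attrs["config"] = yaml.safe_dump(self.config.to_dict())


@dataclass
class PhantomResult:
    angle_stacks: list[ImageStack]
    compound: ImageStack
    truth: GroundTruth
    scatterer_census: np.ndarray | None = None


def generate_sequence(config: PhantomConfig) -> PhantomResult:
    """Generate the full phantom acquisition.

    Scatterers are advected at the compounding PRF; each transmission
    substep renders one low-resolution frame into the corresponding
    angle stack, so consecutive frames of one angle stack are separated
    by ``n_angles / prf`` exactly as in interleaved plane-wave imaging.
    The compounded stack is the per-frame mean of the angle stacks.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_place, rng_noise, rng_repl = [np.random.default_rng(s)
                                      for s in ss.spawn(3)]
    n_frames = int(np.ceil(config.n_cycles * config.cycle_period
                           / config.frame_interval))
    n_sub = n_frames * config.n_angles
    dt = 1.0 / config.prf

    sc = initialize_scatterers(config, 0.0, rng_place)
    cache: dict = {}
    sc = replenish_scatterers(sc, config, 0.0, rng_repl, cache)

    h, w = config.image_shape
    stacks = [np.empty((n_frames, h, w), dtype=np.float32)
              for _ in range(config.n_angles)]
    census = np.empty(n_frames, dtype=int)

    for k in range(n_sub):
        t = k * dt
        frame, angle = divmod(k, config.n_angles)
        stacks[angle][frame] = render_frame(sc, config, rng_noise)
        if angle == 0:
            census[frame] = int(np.count_nonzero(sc.select("lumen")))
        if k < n_sub - 1:
            sc = advect_scatterers(sc, config, t, dt)
            sc = _drop_washed_out(sc, config)
            sc = replenish_scatterers(sc, config, t + dt, rng_repl, cache)

    frame_interval = config.frame_interval
    angle_stacks = [
        ImageStack(stacks[a], config.pixel_spacing, frame_interval,
                   t0=a * dt)
        for a in range(config.n_angles)
    ]
    compound = ImageStack(
        np.mean(np.stack([s.frames for s in angle_stacks]), axis=0),
        config.pixel_spacing, frame_interval, t0=dt * (config.n_angles - 1) / 2)

    truth = _ground_truth(config, n_frames, cache)
    return PhantomResult(angle_stacks, compound, truth, census)


def _ground_truth(config: PhantomConfig, n_frames: int,
                  cache: dict) -> GroundTruth:
    dt = 1.0 / config.prf
    frame_times = (np.arange(n_frames) * config.n_angles
                   + (config.n_angles - 1) / 2.0) * dt
    pair_times = frame_times[:-1] + config.frame_interval / 2.0

    if "s_map" in cache:
        d_map = cache["d_map"]
    else:
        _, d_map = config.pixel_vessel_coords()
    h, w = config.image_shape
    ex, ey = config.axis_unit
    nx, ny = config.normal_unit

    vel_u = np.zeros((len(pair_times), h, w), dtype=np.float32)
    vel_v = np.zeros_like(vel_u)
    r_pairs = np.empty(len(pair_times))
    wss = np.empty(len(pair_times))
    vmean = np.empty(len(pair_times))
    mu = config.blood_viscosity
    for i, t in enumerate(pair_times):
        flow = analytic_flow(config, float(t))
        r_pairs[i] = flow.radius
        wss[i] = mu * flow.wall_shear_rate
        vmean[i] = flow.v_mean
        inside = np.abs(d_map) < flow.radius
        ua = flow.u_axial(d_map[inside])
        vr = flow.v_radial(d_map[inside])
        vel_u[i][inside] = ua * ex + vr * nx
        vel_v[i][inside] = ua * ey + vr * ny

    r_frames = np.asarray(config.radius(frame_times), dtype=float)
    return GroundTruth(config, pair_times, frame_times, vel_u, vel_v,
                       r_pairs, r_frames, wss, vmean)
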