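"""SVD clutter filtering of image stacks and POD denoising of velocity
fields.

Tissue, blood and noise occupy different spatiotemporal subspaces of
the Casorati matrix (pixels x frames): slowly moving, spatially
coherent tissue concentrates in the leading singular components, blood
speckle in a middle band, and noise in the tail.  Reconstructing from
the blood band strongly increases the contrast-to-tissue ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import ImageStack, VelocityField


@dataclass
class SVDDecomposition:
    """Economy SVD of the Casorati matrix X (pixels x frames) = U S V^T."""

    u: np.ndarray                 # (pixels, k) spatial singular vectors
    s: np.ndarray                 # (k,) non-increasing singular values
    vt: np.ndarray                # (k, frames) temporal singular vectors
    casorati_shape: tuple[int, int]
    image_shape: tuple[int, int]

    @property
    def n_components(self) -> int:
        return self.s.size

    def reconstruct(self, low: int, high: int) -> np.ndarray:
        """Stack rebuilt from components ``low..high`` inclusive, (T,H,W)."""
        sl = slice(low, high + 1)
        x = (self.u[:, sl] * self.s[sl]) @ self.vt[sl]
        t = self.casorati_shape[1]
        return np.ascontiguousarray(
            x.reshape(self.image_shape + (t,)).transpose(2, 0, 1))


@dataclass
class RankBand:
    """Inclusive index bounds into the singular value ordering."""

    low: int
    high: int

    def __post_init__(self) -> None:
        if not (0 <= self.low <= self.high):
            raise ValueError(f"invalid rank band [{self.low}, {self.high}]")


def svd_decompose(stack: ImageStack, method: str = "auto",
                  ) -> SVDDecomposition:
    """Factorize the Casorati matrix of an image stack.

    For the typical tall matrix (pixels >> frames) the decomposition is
    computed from the frames x frames Gram matrix, which is much faster
    than a direct SVD and accurate to working precision for the
    well-separated components the clutter filter uses.
    """
    frames = np.asarray(stack.frames, dtype=np.float64)
    t = frames.shape[0]
    if t < 2:
        raise ValueError("svd_decompose requires at least 2 frames")
    h, w = frames.shape[1:]
    x = frames.reshape(t, h * w).T        # pixels x frames

    if method == "auto":
        method = "gram" if x.shape[0] > 20 * x.shape[1] else "direct"
    if method == "gram":
        g = x.T @ x                       # frames x frames
        evals, v = np.linalg.eigh(g)
        order = np.argsort(evals)[::-1]
        evals = np.clip(evals[order], 0.0, None)
        v = v[:, order]
        s = np.sqrt(evals)
        nz = s > s[0] * 1e-12 if s[0] > 0 else s > -1
        u = np.zeros((x.shape[0], t))
        u[:, nz] = (x @ v[:, nz]) / s[nz]
        vt = v.T
    else:
        u, s, vt = np.linalg.svd(x, full_matrices=False)
    return SVDDecomposition(u, s, vt, x.shape, (h, w))


def select_blood_band(decomp: SVDDecomposition, threshold: float = 0.5,
                      noise_energy_fraction: float = 1.0,
                      min_energy_fraction: float = 1e-8) -> RankBand:
    """Choose the blood subspace from the spatial similarity of U-vectors.

    Tissue components share the anatomy of the dominant component, so
    their |U| patterns correlate strongly with |U_0|; blood components
    live on the lumen and do not.  The low cut is placed at the first
    component whose Pearson correlation with |U_0| drops below
    ``threshold``.  A candidate blood band whose energy is a negligible
    fraction of the stack (``min_energy_fraction``) means the stack is
    effectively static and raises.  The high cut keeps components up to
    ``noise_energy_fraction`` of the cumulative post-low-cut energy
    (default: keep the whole tail).  ``threshold <= 0`` keeps
    everything (low cut 0).
    """
    k = decomp.n_components
    if k < 2:
        raise ValueError("need at least 2 components to select a band")
    au = np.abs(decomp.u)
    au = au - au.mean(axis=0)
    norms = np.linalg.norm(au, axis=0)
    norms[norms == 0] = 1.0
    au = au / norms
    sim = np.abs(au.T @ au[:, 0])          # (k,), sim[0] = 1
    if threshold <= 0:
        low = 0
    else:
        below = np.nonzero(sim[1:] < threshold)[0]
        low = int(below[0]) + 1 if below.size else k  # k => empty band
    if low >= k:
        raise ValueError("no blood subspace found (stack looks static)")
    band_energy = np.sum(decomp.s[low:] ** 2)
    total_energy = np.sum(decomp.s ** 2)
    if total_energy > 0 and band_energy < min_energy_fraction * total_energy:
        raise ValueError("no blood subspace found (stack looks static)")

    if noise_energy_fraction >= 1.0:
        return RankBand(low, k - 1)
    tail_energy = np.cumsum(decomp.s[low:] ** 2)
    total = tail_energy[-1]
    if total <= 0:
        high = low
    else:
        idx = np.searchsorted(tail_energy / total, noise_energy_fraction)
        high = low + min(int(idx), k - 1 - low)
    return RankBand(low, high)


def svd_filter(stack: ImageStack, band: RankBand,
               decomp: SVDDecomposition | None = None,
               ) -> tuple[ImageStack, ImageStack]:
    """Split a stack into (tissue, blood) reconstructions.

    Blood is rebuilt from the band; tissue from the components below
    the low cut.  Blood + tissue + residual (noise tail) equals the
    original stack exactly.
    """
    if decomp is None:
        decomp = svd_decompose(stack)
    if band.high >= decomp.n_components:
        raise ValueError("rank band exceeds number of components")
    blood = decomp.reconstruct(band.low, band.high)
    if band.low > 0:
        tissue = decomp.reconstruct(0, band.low - 1)
    else:
        tissue = np.zeros_like(blood)
    mk = lambda fr: ImageStack(fr, stack.pixel_spacing,
                               stack.frame_interval, stack.t0)
    return mk(tissue), mk(blood)


# ---------------------------------------------------------------------------
# POD filtering of velocity-field series
# ---------------------------------------------------------------------------


def _fill_invalid(comp: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Replace invalid grid values by the local median of valid
    neighbours (3x3, growing to global median if isolated)."""
    import warnings

    from scipy.ndimage import generic_filter  # local import: rarely needed

    out = comp.copy()
    for t in range(comp.shape[0]):
        bad = ~valid[t]
        if not bad.any():
            continue
        a = out[t]
        if valid[t].any():
            glob = np.median(a[valid[t]])
        else:
            glob = 0.0
        masked = np.where(valid[t], a, np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            med = generic_filter(masked, np.nanmedian, size=3,
                                 mode="constant", cval=np.nan)
        fill = np.where(np.isnan(med), glob, med)
        a[bad] = fill[bad]
    return out


def pod_filter(fields: VelocityField, mode_count: int | None = None,
               energy_fraction: float = 0.95) -> VelocityField:
    """Denoise a velocity-field time series by proper orthogonal
    decomposition.

    Each frame's (u, v) components are concatenated into one state
    vector; the decomposition acts on the fluctuations about the
    temporal mean (the standard POD convention — the mean flow would
    otherwise swallow nearly all the energy and a fraction-based
    truncation would discard the dynamics).  The series is rebuilt from
    the mean plus the leading fluctuation modes holding
    ``energy_fraction`` of the fluctuation energy (or exactly
    ``mode_count`` modes).  Invalid vectors are filled by local medians
    before the decomposition and re-masked afterwards.
    """
    if mode_count is None and not (0.0 < energy_fraction <= 1.0):
        raise ValueError("energy_fraction must lie in (0, 1]")
    t = fields.n_frames
    if t < 2:
        raise ValueError("pod_filter requires at least 2 frames")

    u = _fill_invalid(fields.u, fields.valid)
    v = _fill_invalid(fields.v, fields.valid)
    state = np.concatenate([u.reshape(t, -1), v.reshape(t, -1)], axis=1).T
    mean_state = state.mean(axis=1, keepdims=True)
    state = state - mean_state

    uu, ss, vvt = np.linalg.svd(state, full_matrices=False)
    energy = ss ** 2
    if mode_count is None:
        csum = np.cumsum(energy)
        total = csum[-1]
        if total <= 0:
            mode_count = t
        else:
            mode_count = int(np.searchsorted(csum / total,
                                             energy_fraction)) + 1
    mode_count = max(1, min(mode_count, ss.size))
    rec = mean_state + (uu[:, :mode_count] * ss[:mode_count]) \
        @ vvt[:mode_count]

    n = fields.u[0].size
    out = fields.copy()
    out.u = rec[:n].T.reshape(fields.u.shape)
    out.v = rec[n:].T.reshape(fields.v.shape)
    return out


def pod_energy_spectrum(fields: VelocityField) -> np.ndarray:
    """Normalized POD mode energies (descending)."""
    t = fields.n_frames
    u = _fill_invalid(fields.u, fields.valid)
    v = _fill_invalid(fields.v, fields.valid)
    state = np.concatenate([u.reshape(t, -1), v.reshape(t, -1)], axis=1).T
    s = np.linalg.svd(state, compute_uv=False)
    e = s ** 2
    return e / e.sum() if e.sum() > 0 else e
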