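"""Common data containers shared by every stage of the pipeline.

All physical quantities are SI: positions in metres, velocities in m/s,
time in seconds, shear stress in Pa.  Image arrays follow the convention
``(frame, row, column)`` with row = axial (y, positive downward, towards
increasing depth) and column = lateral (x).  Pixel indices are 0-based and
registered at pixel centres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class ImageStack:
    """Time-resolved 2-D intensity frames plus acquisition geometry.

    Parameters
    ----------
    frames : ndarray, shape (T, H, W)
        Intensity frames (float).
    pixel_spacing : tuple of float
        ``(axial, lateral)`` metres per pixel.
    frame_interval : float
        Seconds between consecutive frames of this stack.
    t0 : float
        Time stamp of the first frame (s).
    """

    frames: np.ndarray
    pixel_spacing: tuple[float, float]
    frame_interval: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.frame_interval * np.arange(self.n_frames)

    def save(self, path: str | Path) -> None:
        """Write as a multi-page 32-bit float TIFF with a JSON sidecar."""
        path = Path(path)
        tifffile.imwrite(path, self.frames.astype(np.float32))
        meta = {
            "pixel_spacing": list(self.pixel_spacing),
            "frame_interval": self.frame_interval,
            "t0": self.t0,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ImageStack":
        path = Path(path)
        frames = tifffile.imread(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            frames=np.asarray(frames, dtype=np.float64),
            pixel_spacing=tuple(meta["pixel_spacing"]),
            frame_interval=meta["frame_interval"],
            t0=meta.get("t0", 0.0),
        )


@dataclass
class VelocityField:
    """Gridded 2-D velocity time series.

    ``u`` is the lateral (x) component and ``v`` the axial (y) component,
    both in m/s, sampled at grid nodes ``(y[i], x[j])`` in pixel units of
    the originating image.  ``valid`` flags measured vectors; vectors that
    were rejected and replaced by interpolation carry ``valid = False``.
    """

    u: np.ndarray          # (T, Ny, Nx) m/s
    v: np.ndarray          # (T, Ny, Nx) m/s
    x: np.ndarray          # (Nx,) grid columns, px
    y: np.ndarray          # (Ny,) grid rows, px
    valid: np.ndarray      # (T, Ny, Nx) bool
    pixel_spacing: tuple[float, float]
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.u.shape != self.v.shape or self.u.shape != self.valid.shape:
            raise ValueError("u, v and valid must share one shape")

    @property
    def n_frames(self) -> int:
        return self.u.shape[0]

    @property
    def speed(self) -> np.ndarray:
        return np.hypot(self.u, self.v)

    def copy(self) -> "VelocityField":
        return VelocityField(
            self.u.copy(), self.v.copy(), self.x.copy(), self.y.copy(),
            self.valid.copy(), tuple(self.pixel_spacing),
            None if self.times is None else np.asarray(self.times).copy(),
        )

    def save(self, path: str | Path) -> None:
        np.savez_compressed(
            Path(path), u=self.u, v=self.v, x=self.x, y=self.y,
            valid=self.valid, pixel_spacing=np.asarray(self.pixel_spacing),
            times=np.asarray([] if self.times is None else self.times),
        )

    @classmethod
    def load(cls, path: str | Path) -> "VelocityField":
        z = np.load(Path(path))
        times = z["times"] if z["times"].size else None
        return cls(z["u"], z["v"], z["x"], z["y"], z["valid"].astype(bool),
                   tuple(z["pixel_spacing"]), times)


@dataclass
class BoundaryLine:
    """One ordered wall polyline for one frame.

    ``points`` are (N, 2) physical coordinates in metres, ordered along
    the wall (monotone arc length); ``theta`` is the local tangent angle
    (radians) between the wall-oriented and image-oriented frames.
    """

    points: np.ndarray
    theta: np.ndarray
    side: str            # "upper" | "lower"
    vessel: str = "primary"
    fallback: np.ndarray | None = None  # per-point flag: mask-contour fallback
    smoothed: bool = False

    @property
    def arc_length(self) -> np.ndarray:
        d = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(d)])


@dataclass
class WallBoundary:
    """Per-frame collection of labelled wall polylines."""

    frames: list[list[BoundaryLine]] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def lines(self, frame: int, side: str | None = None,
              vessel: str | None = None) -> list[BoundaryLine]:
        out = self.frames[frame]
        if side is not None:
            out = [b for b in out if b.side == side]
        if vessel is not None:
            out = [b for b in out if b.vessel == vessel]
        return out


@dataclass
class WSSSeries:
    """Per-boundary-point wall shear stress time series and derived maps.

    ``tau`` maps (vessel, side) -> (T, N) signed WSS in Pa at N arc-length
    stations; ``tawss`` and ``osi`` hold per-point cycle statistics.
    ``mean_waveform`` maps side -> (T,) spatial mean waveform.
    """

    tau: dict
    times: np.ndarray
    viscosity: float
    arc_length: dict = field(default_factory=dict)
    tawss: dict = field(default_factory=dict)
    osi: dict = field(default_factory=dict)
    mean_waveform: dict = field(default_factory=dict)

    def overall_mean_waveform(self) -> np.ndarray:
        """Signed WSS averaged over every boundary, per frame."""
        stacks = [np.nanmean(t, axis=1) for t in self.tau.values()]
        return np.nanmean(np.stack(stacks), axis=0)
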