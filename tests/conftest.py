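"""Shared fixtures: small speckle images and reduced-scale phantoms."""

import numpy as np
import pytest
from scipy import ndimage

from echowss import PhantomConfig, generate_sequence


@pytest.fixture(scope="session")
def speckle_pair_factory():
    """Factory for correlated speckle frame pairs with a known shift."""

    def make(shift=(0.0, 0.0), shape=(256, 128), sigma=2.0, seed=0,
             noise=0.0):
        rng = np.random.default_rng(seed)
        pad = 16
        big = ndimage.gaussian_filter(
            rng.standard_normal((shape[0] + 2 * pad, shape[1] + 2 * pad)),
            sigma)
        a = big[pad:pad + shape[0], pad:pad + shape[1]].copy()
        shifted = ndimage.shift(big, shift, order=3)
        b = shifted[pad:pad + shape[0], pad:pad + shape[1]].copy()
        if noise > 0:
            a = a + noise * rng.standard_normal(a.shape)
            b = b + noise * rng.standard_normal(b.shape)
        return a, b

    return make


def small_phantom_config(**overrides) -> PhantomConfig:
    """Reduced-scale phantom: short vessel segment, small image, single
    transmit angle, a fraction of one cardiac cycle."""
    kw = dict(
        image_shape=(192, 64),
        n_angles=1,
        prf=1500.0,
        frame_interval=1.0 / 1500.0,
        cycle_period=1.0 / 3.0,
        n_cycles=0.06,
        seed=7,
    )
    kw.update(overrides)
    return PhantomConfig(**kw)


def steady_config(**overrides) -> PhantomConfig:
    """Steady Poiseuille flow in a static tube (full-size image)."""
    kw = dict(
        flow_model="poiseuille",
        mean_velocity_waveform=lambda t: 0.1 * np.ones_like(
            np.asarray(t, dtype=float)),
        diameter_waveform=lambda t: 2.7e-3 * np.ones_like(
            np.asarray(t, dtype=float)),
        n_cycles=0.08,
        seed=2,
    )
    kw.update(overrides)
    return PhantomConfig(**kw)


@pytest.fixture(scope="session")
def small_pulsatile_result():
    """One reduced-scale pulsatile phantom shared across tests."""
    cfg = small_phantom_config(n_cycles=0.12, seed=11)
    return generate_sequence(cfg)
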