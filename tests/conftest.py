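"""Shared fixtures: geometry, phantom builders, a session-scoped trained
pixel classifier (training is the slowest step, so it is shared)."""

from __future__ import annotations

import math

import numpy as np
import pytest

from ezquant.enface import csf_mask
from ezquant.geometry import make_geometry
from ezquant.pipeline import train_default_classifier


@pytest.fixture(scope="session")
def cirrus():
    return make_geometry("cirrus6mm")


@pytest.fixture(scope="session")
def cirrus_csf(cirrus):
    return csf_mask(cirrus)


@pytest.fixture(scope="session")
def trained_model(cirrus):
    """Pixel classifier trained on 8 phantom maps at moderate noise."""
    return train_default_classifier(cirrus, n_train=8, seed=11, noise_sd=0.1)


def make_flat_bscan(
    geometry,
    ez_inner: float = 200.0,
    rpe_inner: float = 230.0,
    band_sigma: float = 2.0,
    background: float = 0.05,
    ez_amp: float = 0.8,
    ez_gap_cols: tuple[int, int] | None = None,
):
    """Synthetic B-scan with flat bands whose *inner borders* (half-max
    rising edges) sit exactly at the requested rows.  Includes an inner
    retinal surface band so the tracker's surface detection behaves as it
    does on full phantoms."""
    n_axial, n_ascans = geometry.n_axial, geometry.n_ascans
    z = np.arange(n_axial, dtype=np.float64)[:, None]
    off = band_sigma * math.sqrt(2.0 * math.log(2.0))

    def band(inner, amp):
        return amp * np.exp(-0.5 * ((z - (inner + off)) / band_sigma) ** 2)

    img = np.full((n_axial, n_ascans), background)
    img += band(100.0, 0.55)  # surface
    ez = band(ez_inner, ez_amp) * np.ones((1, n_ascans))
    if ez_gap_cols is not None:
        lo, hi = ez_gap_cols
        ez[:, lo:hi] = 0.0
    img += ez
    img += band(rpe_inner, 1.0)
    return img


@pytest.fixture()
def flat_bscan(cirrus):
    return make_flat_bscan(cirrus)
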