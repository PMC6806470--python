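"""Shared fixtures: a full-scale beam model and a small fast test beam."""

import numpy as np
import pytest

from proton_interplay import (
    BraggPeakModel,
    CTVGeometry,
    FieldGeometry,
    MotionTrace,
    build_layer_set,
    build_plan,
    default_grid_for,
    solve_layer_weights,
)


@pytest.fixture(scope="session")
def peak_model():
    return BraggPeakModel(range_gcm2=30.1)


@pytest.fixture(scope="session")
def layers14(peak_model):
    """The clinical field: range 30.1, modulation 8.4, 14 layers, solved weights."""
    return solve_layer_weights(peak_model, build_layer_set(30.1, 8.4, 0.6))


@pytest.fixture(scope="session")
def small_model():
    return BraggPeakModel(range_gcm2=16.0)


@pytest.fixture(scope="session")
def small_layers(small_model):
    """8-layer test field: range 16, modulation 4.8, spacing 0.6.

    Short modulations carry a physically real proximal-shoulder dip, so the
    flatness tolerance is looser than for the 14-layer clinical field.
    """
    return solve_layer_weights(small_model, build_layer_set(16.0, 4.8, 0.6), flatness_tol=0.08)


@pytest.fixture(scope="session")
def small_ctv():
    return CTVGeometry(semi_axes_mm=(12.0, 10.0, 11.0), sample_spacing_mm=4.0)


@pytest.fixture(scope="session")
def small_plan(small_model, small_layers, small_ctv):
    grid = default_grid_for(small_ctv, pad_mm=25.0, spacing_mm=2.0)
    return build_plan(small_model, small_layers, small_ctv, grid)


def constant_trace(offset, n_seconds, rate_hz=1.0):
    """1 Hz trace holding a constant (LR, SI, AP) displacement."""
    t = np.arange(n_seconds) / rate_hz
    disp = np.tile(np.asarray(offset, dtype=float), (n_seconds, 1))
    return MotionTrace(t, disp, rate_hz)


@pytest.fixture
def make_constant_trace():
    return constant_trace
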