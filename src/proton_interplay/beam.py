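"""Analytic SOBP beam model: pristine Bragg peaks, energy layers, dose grids.

A spread-out Bragg peak (SOBP) is the weighted superposition of pristine
Bragg peaks whose ranges step proximally from the distal layer in fixed
increments.  This module provides an analytic pristine-peak surrogate for a
planning system's per-layer dose matrices: a constant entrance plateau that
terminates just proximal of the peak, plus an asymmetric Gaussian peak with
a sharp distal edge.  Layer weights flattening the SOBP are solved by
nonnegative least squares on a fine depth grid.

Dose grids are separable: a depth profile along the (lateral) beam axis
times a flat lateral fluence with an error-function penumbra around the
aperture, in a homogeneous water-equivalent medium (1 g/cm^3, so 10 mm of
tissue equals 1 g/cm^2 of range).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq, nnls
from scipy.special import erfc
from scipy.stats import norm

from .geometry import CTVGeometry, DoseGrid, GridSpec

#: millimetres of water-equivalent tissue per g/cm^2 of proton range
MM_PER_GCM2 = 10.0

# distal falloff sigma as a fraction of the proximal peak sigma; real Bragg
# peaks fall much faster distally than they rise proximally
_DISTAL_SIGMA_FRACTION = 0.5

# 80%-20% penumbra width of an erf profile, in units of its sigma
_P8020_PER_SIGMA = 2.0 * float(norm.ppf(0.8))


@dataclass(frozen=True)
class BraggPeakModel:
    """Analytic pristine Bragg peak, normalised to unit peak dose.

    Parameters
    ----------
    range_gcm2
        Beam range in g/cm^2 water-equivalent; the peak sits at this depth.
    peak_width_gcm2
        Proximal Gaussian sigma of the peak; the distal sigma is half of it.
    entrance_ratio
        Entrance-to-peak dose ratio in [0, 1); the plateau mixing weight is
        solved numerically so this ratio holds exactly.
    """

    range_gcm2: float
    peak_width_gcm2: float = 0.6
    entrance_ratio: float = 0.35

    def __post_init__(self) -> None:
        if self.range_gcm2 <= 0:
            raise ValueError("range_gcm2 must be > 0")
        if self.peak_width_gcm2 <= 0:
            raise ValueError("peak_width_gcm2 must be > 0")
        if not (0.0 <= self.entrance_ratio < 1.0):
            raise ValueError("entrance_ratio must be in [0, 1)")

    # -- raw (un-normalised) components -------------------------------------

    def _peak(self, depth: np.ndarray) -> np.ndarray:
        s_prox = self.peak_width_gcm2
        s_dist = _DISTAL_SIGMA_FRACTION * s_prox
        d = depth - self.range_gcm2
        sig = np.where(d <= 0, s_prox, s_dist)
        return np.exp(-0.5 * (d / sig) ** 2)

    def _plateau(self, depth: np.ndarray) -> np.ndarray:
        # constant entrance plateau rolling off just proximal of the peak so
        # it adds nothing beyond the range
        edge = self.range_gcm2 - self.peak_width_gcm2
        w = 0.5 * self.peak_width_gcm2
        return 0.5 * erfc((depth - edge) / (math.sqrt(2.0) * w))

    def _mix_and_peakmax(self) -> tuple[float, float]:
        """Plateau mixing weight A and resulting curve maximum.

        A is solved so that dose(0)/max dose == entrance_ratio.
        """
        zz = np.linspace(
            max(0.0, self.range_gcm2 - 4 * self.peak_width_gcm2),
            self.range_gcm2 + 2 * self.peak_width_gcm2,
            801,
        )

        def raw_max(a: float) -> float:
            return float(np.max(a * self._plateau(zz) + (1 - a) * self._peak(zz)))

        if self.entrance_ratio == 0.0:
            return 0.0, raw_max(0.0)

        def f(a: float) -> float:
            d0 = a * float(self._plateau(np.array([0.0]))[0])
            return d0 / raw_max(a) - self.entrance_ratio

        a = brentq(f, 1e-9, 0.999, xtol=1e-12)
        return a, raw_max(a)

    def depth_dose(self, depth_gcm2) -> np.ndarray | float:
        """Relative dose at water-equivalent depth(s); peak dose is 1."""
        depth = np.asarray(depth_gcm2, dtype=float)
        if np.any(depth < 0):
            raise ValueError("depth must be >= 0")
        a, peakmax = _mix_cache(self)
        out = (a * self._plateau(depth) + (1 - a) * self._peak(depth)) / peakmax
        return float(out) if np.isscalar(depth_gcm2) else out


def _mix_cache(model: BraggPeakModel) -> tuple[float, float]:
    key = (model.range_gcm2, model.peak_width_gcm2, model.entrance_ratio)
    hit = _MIX_CACHE.get(key)
    if hit is None:
        hit = _MIX_CACHE[key] = model._mix_and_peakmax()
    return hit


_MIX_CACHE: dict[tuple[float, float, float], tuple[float, float]] = {}


def bragg_depth_dose(model: BraggPeakModel, depth_gcm2):
    """Pristine-peak relative dose at the given water-equivalent depth(s)."""
    return model.depth_dose(depth_gcm2)


@dataclass(frozen=True)
class LayerSet:
    """Energy layers composing one SOBP field, ordered distal to proximal."""

    range_gcm2: float
    modulation_gcm2: float
    spacing_gcm2: float
    n_layers: int
    weights: np.ndarray | None = None  # per-layer, sums to 1, distal first

    def __post_init__(self) -> None:
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (self.n_layers,):
                raise ValueError("weights length must equal n_layers")
            if np.any(w < 0):
                raise ValueError("weights must be nonnegative")
            if abs(w.sum() - 1.0) > 1e-9:
                raise ValueError("weights must sum to 1")

    @property
    def layer_ranges(self) -> np.ndarray:
        """Range of each layer: distal layer first, stepping by spacing."""
        return self.range_gcm2 - self.spacing_gcm2 * np.arange(self.n_layers)


def build_layer_set(range_gcm2: float, modulation_gcm2: float, spacing_gcm2: float) -> LayerSet:
    """Decompose a (range, modulation) prescription into energy layers.

    The layer count is ceil(modulation / spacing) with a relative guard
    against binary round-off (8.4 / 0.6 is slightly above 14 in floating
    point).
    """
    if spacing_gcm2 <= 0:
        raise ValueError("spacing_gcm2 must be > 0")
    if not (0 < modulation_gcm2 <= range_gcm2):
        raise ValueError(
            "modulation must satisfy 0 < modulation <= range "
            f"(got modulation={modulation_gcm2}, range={range_gcm2})"
        )
    ratio = modulation_gcm2 / spacing_gcm2
    n = int(math.ceil(ratio - 1e-9))
    return LayerSet(range_gcm2, modulation_gcm2, spacing_gcm2, n)


def solve_layer_weights(
    model: BraggPeakModel,
    layers: LayerSet,
    flatness_tol: float = 0.02,
    depth_step_gcm2: float = 0.1,
) -> LayerSet:
    """Solve per-layer weights that flatten the SOBP over the modulation region.

    Nonnegative least squares fits the weighted pristine-peak superposition
    to a constant over [range - modulation, range] on a fine depth grid; the
    achieved flatness (max relative deviation from the plateau mean) must be
    within ``flatness_tol`` or a ValueError reports it.
    """
    if layers.n_layers < 1:
        raise ValueError("need at least one layer")
    if layers.n_layers == 1:
        return replace(layers, weights=np.array([1.0]))

    r = layers.range_gcm2
    zz = np.arange(r - layers.modulation_gcm2, r + depth_step_gcm2 / 2, depth_step_gcm2)
    peaks = [replace(model, range_gcm2=rk) for rk in layers.layer_ranges]
    design = np.column_stack([p.depth_dose(zz) for p in peaks])
    w, _ = nnls(design, np.ones_like(zz))

    sobp = design @ w
    plateau = float(sobp.mean())
    achieved = float(np.max(np.abs(sobp / plateau - 1.0)))
    if achieved > flatness_tol:
        raise ValueError(
            f"SOBP flatness {achieved:.4f} exceeds tolerance {flatness_tol:.4f} "
            f"for {layers.n_layers} layers at spacing {layers.spacing_gcm2} g/cm^2"
        )
    return replace(layers, weights=w / w.sum())


@dataclass(frozen=True)
class FieldGeometry:
    """Lateral treatment field: beam direction, aperture and range margins.

    ``beam_axis`` is +1 for a beam travelling in +x (entering from the
    patient's right, i.e. the left-lateral field) and -1 for the mirrored
    field.  Range margins place the SOBP so its distal edge sits
    ``distal_margin_mm`` beyond the CTV and its modulation reaches
    ``proximal_margin_mm`` upstream of it.
    """

    beam_axis: int = +1
    aperture_margin_mm: float = 10.0
    penumbra_80_20_mm: float = 6.0
    distal_margin_mm: float = 5.0
    proximal_margin_mm: float = 10.0

    def __post_init__(self) -> None:
        if self.beam_axis not in (+1, -1):
            raise ValueError("beam_axis must be +1 or -1")
        for name in ("aperture_margin_mm", "penumbra_80_20_mm", "distal_margin_mm", "proximal_margin_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def depth_gcm2(self, x_mm: np.ndarray, layers: LayerSet, ctv: CTVGeometry) -> np.ndarray:
        """Water-equivalent depth at lateral position x for this field.

        Depth is anchored so the distal layer's range falls on the plane
        ``distal_margin_mm`` beyond the far side of the CTV.
        """
        lo, hi = ctv.extent(0)
        if self.beam_axis > 0:
            x_distal = hi + self.distal_margin_mm
            d = layers.range_gcm2 - (x_distal - np.asarray(x_mm)) / MM_PER_GCM2
        else:
            x_distal = lo - self.distal_margin_mm
            d = layers.range_gcm2 - (np.asarray(x_mm) - x_distal) / MM_PER_GCM2
        # points upstream of the water surface do not occur for physical
        # grids; clamp so the entrance plateau extends to the grid edge
        return np.maximum(d, 0.0)


def _lateral_profile(grid: GridSpec, geom: FieldGeometry, ctv: CTVGeometry) -> np.ndarray:
    """Flat-in-aperture lateral fluence with an erf penumbra, on the (y,z) plane.

    The aperture is the beam's-eye-view projection of the ellipsoidal CTV
    (an ellipse in AP/SI) expanded by the aperture margin; the signed
    distance to the expanded ellipse is approximated radially.
    """
    sigma = geom.penumbra_80_20_mm / _P8020_PER_SIGMA
    ay = ctv.semi_axes_mm[1] + geom.aperture_margin_mm
    az = ctv.semi_axes_mm[2] + geom.aperture_margin_mm
    y = grid.coords(1) - ctv.center_mm[1]
    z = grid.coords(2) - ctv.center_mm[2]
    yy, zz = np.meshgrid(y, z, indexing="ij")
    r = np.hypot(yy, zz)
    rho = np.sqrt((yy / ay) ** 2 + (zz / az) ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        dist = np.where(rho > 0, r * (1.0 - 1.0 / rho), -min(ay, az))
    return 0.5 * erfc(dist / (math.sqrt(2.0) * sigma))


def build_layer_dose_grid(
    model: BraggPeakModel,
    layers: LayerSet,
    layer_index: int,
    geom: FieldGeometry,
    ctv: CTVGeometry,
    grid: GridSpec,
) -> DoseGrid:
    """Unweighted 3D dose grid of one energy layer (peak dose 1 on axis).

    Separable product of the pristine depth-dose of this layer's range along
    the beam axis and the aperture-collimated lateral profile; the layer
    weight is applied at composition time.
    """
    if not (0 <= layer_index < layers.n_layers):
        raise ValueError(f"layer_index {layer_index} out of range")
    for ax in range(3):
        lo, hi = ctv.extent(ax)
        if lo < grid.origin_mm[ax] or hi > grid.upper_mm[ax]:
            raise ValueError("CTV extends outside the dose grid")
    peak = replace(model, range_gcm2=float(layers.layer_ranges[layer_index]))
    depth = geom.depth_gcm2(grid.coords(0), layers, ctv)
    profile_x = peak.depth_dose(depth)
    lateral = _lateral_profile(grid, geom, ctv)
    values = profile_x[:, None, None] * lateral[None, :, :]
    return DoseGrid(grid, values)


def _check_same_lattice(grids: list[DoseGrid]) -> None:
    g0 = grids[0]
    for g in grids[1:]:
        if not g0.same_lattice(g):
            raise ValueError("layer grids must share origin, spacing and shape")


def composition_scale(
    layer_grids: list[DoseGrid], weights: np.ndarray, norm_point_mm
) -> float:
    """Scale factor mapping the weighted layer sum to percent of prescription.

    Chosen so the composed beam evaluates to 100% at ``norm_point_mm``
    (typically the CTV centre, inside the flat plateau).
    """
    _check_same_lattice(layer_grids)
    w = np.asarray(weights, dtype=float)
    if w.shape != (len(layer_grids),):
        raise ValueError("one weight per layer grid required")
    composed = sum(wk * g.values for wk, g in zip(w, layer_grids))
    val = _trilinear_at(layer_grids[0].grid, composed, np.asarray(norm_point_mm, float))
    if val <= 0:
        raise ValueError("normalisation point receives no dose")
    return 100.0 / val


def _trilinear_at(grid: GridSpec, values: np.ndarray, point: np.ndarray) -> float:
    from scipy.interpolate import RegularGridInterpolator

    interp = RegularGridInterpolator(
        tuple(grid.coords(i) for i in range(3)), values, method="linear"
    )
    return float(interp(point[None, :])[0])


def compose_beam_dose(
    layer_grids: list[DoseGrid], weights: np.ndarray, norm_point_mm
) -> DoseGrid:
    """Voxelwise weighted sum of layer grids, normalised to 100% at a point."""
    scale = composition_scale(layer_grids, weights, norm_point_mm)
    w = np.asarray(weights, dtype=float)
    composed = sum(wk * g.values for wk, g in zip(w, layer_grids))
    return DoseGrid(layer_grids[0].grid, scale * composed)


def weighted_layer_grids(
    layer_grids: list[DoseGrid], weights: np.ndarray, norm_point_mm
) -> list[DoseGrid]:
    """Per-layer dose contributions in percent of prescription.

    Uses the same normalisation constant as :func:`compose_beam_dose`, so the
    voxelwise sum of the returned grids reproduces the composed beam to
    machine precision.
    """
    scale = composition_scale(layer_grids, weights, norm_point_mm)
    w = np.asarray(weights, dtype=float)
    return [DoseGrid(g.grid, scale * wk * g.values) for wk, g in zip(w, layer_grids)]
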