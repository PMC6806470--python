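"""Shared spatial types: dose-grid specification and CTV geometry.

Patient axes are fixed throughout the package: x = left-right (LR),
y = anterior-posterior (AP), z = superior-inferior (SI).  All lengths are
millimetres; dose grids are indexed ``values[ix, iy, iz]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

AXES = ("LR", "AP", "SI")


@dataclass(frozen=True)
class GridSpec:
    """Regular 3D grid: origin of the first voxel centre, spacing, shape."""

    origin_mm: tuple[float, float, float]
    spacing_mm: tuple[float, float, float]
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("grid spacing components must be > 0")
        if any(n < 2 for n in self.shape):
            raise ValueError("grid needs >= 2 voxels per axis")

    def coords(self, axis: int) -> np.ndarray:
        """Voxel-centre coordinates along one axis."""
        return self.origin_mm[axis] + self.spacing_mm[axis] * np.arange(self.shape[axis])

    @property
    def upper_mm(self) -> tuple[float, float, float]:
        return tuple(
            self.origin_mm[i] + self.spacing_mm[i] * (self.shape[i] - 1) for i in range(3)
        )


@dataclass(frozen=True)
class DoseGrid:
    """Dose sampled on a regular grid, in percent of the fraction prescription."""

    grid: GridSpec
    values: np.ndarray  # shape grid.shape, indexed [ix, iy, iz]

    def __post_init__(self) -> None:
        if tuple(self.values.shape) != tuple(self.grid.shape):
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if np.any(self.values < -1e-12):
            raise ValueError("dose values must be nonnegative")

    def same_lattice(self, other: "DoseGrid") -> bool:
        return (
            self.grid.origin_mm == other.grid.origin_mm
            and self.grid.spacing_mm == other.grid.spacing_mm
            and self.grid.shape == other.grid.shape
        )


@dataclass(frozen=True)
class CTVGeometry:
    """Ellipsoidal clinical target volume, rigidly translated during delivery.

    The CTV is represented by the voxel centres of a regular lattice clipped
    to the ellipsoid; every voxel carries equal volume, so DVH statistics are
    simple sample statistics over the centres.
    """

    semi_axes_mm: tuple[float, float, float]  # (LR, AP, SI)
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    sample_spacing_mm: float = 2.0

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes_mm):
            raise ValueError("CTV semi-axes must be > 0")
        if self.sample_spacing_mm <= 0:
            raise ValueError("CTV sample spacing must be > 0")

    def voxel_centers(self) -> np.ndarray:
        """(n, 3) array of CTV sample points at the nominal setup position."""
        c = np.asarray(self.center_mm)
        a = np.asarray(self.semi_axes_mm)
        h = self.sample_spacing_mm
        axes = [np.arange(-ai, ai + 1e-9, h) + ci for ai, ci in zip(a, c)]
        xx, yy, zz = np.meshgrid(*axes, indexing="ij")
        pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
        rel = (pts - c) / a
        inside = np.einsum("ij,ij->i", rel, rel) <= 1.0 + 1e-12
        pts = pts[inside]
        if pts.shape[0] == 0:
            raise ValueError("CTV sampling produced no voxels; reduce sample spacing")
        return pts

    def extent(self, axis: int) -> tuple[float, float]:
        """Nominal-position CTV bounding interval along one axis."""
        return (
            self.center_mm[axis] - self.semi_axes_mm[axis],
            self.center_mm[axis] + self.semi_axes_mm[axis],
        )


def default_grid_for(ctv: CTVGeometry, pad_mm: float = 25.0, spacing_mm: float = 1.0) -> GridSpec:
    """Isotropic grid enclosing the CTV with symmetric padding on every side.

    The pad must exceed the largest credible intrafraction displacement plus
    the interpolation stencil; accumulation raises if a shifted CTV voxel
    leaves the grid.
    """
    origin = []
    shape = []
    for i in range(3):
        half = ctv.semi_axes_mm[i] + pad_mm
        n_half = int(np.ceil(half / spacing_mm))
        # centre the lattice on the CTV so its centre is an exact grid point
        origin.append(ctv.center_mm[i] - n_half * spacing_mm)
        shape.append(2 * n_half + 1)
    return GridSpec(tuple(origin), (spacing_mm,) * 3, tuple(shape))
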