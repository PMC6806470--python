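"""Dose-grid persistence as NRRD with origin/spacing metadata.

SimpleITK handles the NRRD container; this module only maps between the
package's ``values[ix, iy, iz]`` (x=LR, y=AP, z=SI) indexing and ITK's
z-fastest-last array layout.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .geometry import DoseGrid, GridSpec


def write_dose_grid(grid: DoseGrid, path: str | Path) -> None:
    """Write a dose grid to NRRD (or any container SimpleITK infers)."""
    img = sitk.GetImageFromArray(np.ascontiguousarray(grid.values.T))
    img.SetOrigin(tuple(float(v) for v in grid.grid.origin_mm))
    img.SetSpacing(tuple(float(v) for v in grid.grid.spacing_mm))
    sitk.WriteImage(img, str(path), useCompression=False)


def read_dose_grid(path: str | Path) -> DoseGrid:
    """Read a dose grid written by :func:`write_dose_grid`."""
    img = sitk.ReadImage(str(path))
    values = sitk.GetArrayFromImage(img).T
    spec = GridSpec(
        tuple(float(v) for v in img.GetOrigin()),
        tuple(float(v) for v in img.GetSpacing()),
        tuple(int(n) for n in values.shape),
    )
    return DoseGrid(spec, np.ascontiguousarray(values))
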