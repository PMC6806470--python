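"""Delivery timelines and 4D dose accumulation on a moving CTV.

Double scattering (DS) sweeps the whole modulation in one 0.1 s modulator
revolution, so at any instant the full SOBP exists and the per-second dose
matrix is the composed beam rescaled to one second.  Uniform scanning (US)
delivers energy layers sequentially, distal to proximal, with a beam-off
gap while the modulator steps between layers; the per-second dose matrix
is the active layer's contribution rescaled to one second.

The accumulated single-fraction CTV dose is the sum over seconds of the
active dose matrix sampled at the rigidly shifted CTV voxel positions:

    D_CTV(v) = sum_t  dt(v + u(t))

where u(t) is the 1 Hz down-sampled displacement at second t and dt is the
active source grid scaled by its per-second output and the sub-second
overlap of segment and second.  No dose accrues during the pre-beam delay,
but the target keeps moving through it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .beam import (
    BraggPeakModel,
    FieldGeometry,
    LayerSet,
    build_layer_dose_grid,
    compose_beam_dose,
    weighted_layer_grids,
)
from .geometry import CTVGeometry, DoseGrid, GridSpec, default_grid_for
from .motion import MotionTrace

logger = logging.getLogger(__name__)

#: IBA range-modulator rotation speed in double scattering
MODULATOR_RPM = 600.0

FULL_BEAM = "full_beam"
BEAM_OFF = "beam_off"


def modulator_period_s(rpm: float = MODULATOR_RPM) -> float:
    """One modulator revolution (the DS full-SOBP sweep period)."""
    if rpm <= 0:
        raise ValueError("rpm must be > 0")
    return 60.0 / rpm


@dataclass(frozen=True)
class Segment:
    """One contiguous timeline interval driving a single dose source.

    ``source`` is 'full_beam', 'beam_off', or an integer layer index;
    ``scale`` multiplies the source grid per second of beam time.
    """

    start_s: float
    end_s: float
    source: str | int
    scale: float


@dataclass(frozen=True)
class DeliveryTimeline:
    """Per-second delivery schedule for one fraction of one field."""

    technique: str                      # 'DS' or 'US'
    segments: tuple[Segment, ...]
    fraction_dose_gy: float
    dose_rate_gy_per_min: float
    delay_s: float
    switch_s: float

    @property
    def beam_on_s(self) -> float:
        return self.fraction_dose_gy / self.dose_rate_gy_per_min * 60.0

    @property
    def end_s(self) -> float:
        return self.segments[-1].end_s

    @property
    def delivery_span_s(self) -> float:
        """Beam start to final layer end (beam-on plus switching gaps)."""
        return self.end_s - self.delay_s


def build_timeline(
    technique: str,
    fraction_dose_gy: float,
    dose_rate_gy_per_min: float,
    layers: LayerSet | None = None,
    delay_s: float = 25.0,
    switch_s: float = 0.5,
) -> DeliveryTimeline:
    """Build the delivery timeline for one fraction.

    DS: one continuous full-beam segment of duration fraction_dose/dose_rate
    after the pre-beam delay.  US: per-layer segments in distal-to-proximal
    order with beam-on time proportional to layer weight (constant beam
    current at fixed dose rate), separated by ``switch_s`` beam-off gaps.
    """
    technique = technique.upper()
    if technique not in ("DS", "US"):
        raise ValueError("technique must be 'DS' or 'US'")
    if fraction_dose_gy <= 0 or dose_rate_gy_per_min <= 0:
        raise ValueError("fraction dose and dose rate must be > 0")
    if delay_s < 0 or switch_s < 0:
        raise ValueError("delay_s and switch_s must be >= 0")
    beam_on = fraction_dose_gy / dose_rate_gy_per_min * 60.0

    segments: list[Segment] = []
    if delay_s > 0:
        segments.append(Segment(0.0, delay_s, BEAM_OFF, 0.0))

    if technique == "DS":
        segments.append(Segment(delay_s, delay_s + beam_on, FULL_BEAM, 1.0 / beam_on))
    else:
        if layers is None or layers.weights is None:
            raise ValueError("US timeline requires a LayerSet with solved weights")
        t = delay_s
        for k, wk in enumerate(layers.weights):
            dur = float(wk) * beam_on
            if dur == 0.0:
                logger.info("layer %d has zero weight: zero-duration segment", k)
                segments.append(Segment(t, t, k, 0.0))
            else:
                segments.append(Segment(t, t + dur, k, 1.0 / dur))
                t += dur
            if k < layers.n_layers - 1 and switch_s > 0:
                segments.append(Segment(t, t + switch_s, BEAM_OFF, 0.0))
                t += switch_s
    return DeliveryTimeline(
        technique, tuple(segments), fraction_dose_gy, dose_rate_gy_per_min, delay_s, switch_s
    )


@dataclass(frozen=True)
class FractionDose:
    """Accumulated dose at CTV voxels for one fraction (% of fraction Rx)."""

    values: np.ndarray           # (n_ctv_voxels,)
    fraction_index: int
    field: str                   # 'LAO' or 'RAO'
    technique: str               # 'DS' or 'US'

    def __post_init__(self) -> None:
        if np.any(self.values < -1e-9):
            raise ValueError("fraction dose must be nonnegative")


@dataclass(frozen=True)
class CourseDose:
    """Fraction-cumulative CTV dose as % of the total prescription.

    With equal fraction prescriptions this equals the arithmetic mean of
    the per-fraction percent doses.
    """

    values: np.ndarray
    n_fractions: int
    technique: str


def _source_grids_for(
    grids: Mapping, needed: set
) -> dict:
    missing = [s for s in needed if s not in grids]
    if missing:
        raise ValueError(f"missing dose grids for sources: {missing}")
    return {s: grids[s] for s in needed}


def accumulate_fraction(
    grids: Mapping[str | int, DoseGrid],
    timeline: DeliveryTimeline,
    trace: MotionTrace,
    ctv: CTVGeometry,
    fraction_index: int = 0,
    field: str = "LAO",
) -> FractionDose:
    """Accumulate one fraction of CTV dose through a moving target.

    ``grids`` maps timeline sources to dose grids in percent of the
    fraction prescription: 'full_beam' for DS and integer layer indices for
    US (the per-layer *contribution* grids, i.e. weight times pristine grid
    under the composed-beam normalisation).  ``trace`` must be down-sampled
    to 1 Hz and cover the timeline; displacement within second t is the
    trace sample at index t.  Seconds straddling segment boundaries
    apportion dose by sub-second overlap.  A shifted CTV voxel outside the
    grid raises (the grid must be padded for the largest expected motion).
    """
    if abs(trace.rate_hz - 1.0) > 1e-9:
        raise ValueError("trace must be down-sampled to 1 Hz before accumulation")
    n_seconds = int(math.ceil(timeline.end_s - 1e-9))
    if trace.times_s.size < n_seconds:
        raise ValueError(
            f"trace covers {trace.times_s.size} s but timeline needs {n_seconds} s"
        )
    points = ctv.voxel_centers()
    disp = trace.disp_xyz()

    active = [s for s in timeline.segments if s.source != BEAM_OFF and s.scale > 0]
    interp: dict[str | int, RegularGridInterpolator] = {}
    for seg in active:
        if seg.source not in interp:
            g = grids.get(seg.source)
            if g is None:
                raise ValueError(f"no dose grid provided for source {seg.source!r}")
            interp[seg.source] = RegularGridInterpolator(
                tuple(g.grid.coords(i) for i in range(3)),
                g.values,
                method="linear",
                bounds_error=True,
            )

    dose = np.zeros(points.shape[0])
    for t in range(n_seconds):
        lo, hi = float(t), float(t + 1)
        weights: dict[str | int, float] = {}
        for seg in active:
            overlap = min(seg.end_s, hi) - max(seg.start_s, lo)
            if overlap > 1e-12:
                weights[seg.source] = weights.get(seg.source, 0.0) + overlap * seg.scale
        if not weights:
            continue
        shifted = points + disp[t]
        try:
            for src, w in weights.items():
                dose += w * interp[src](shifted)
        except ValueError as err:
            raise ValueError(
                f"shifted CTV voxel left the dose grid at second {t} "
                f"(displacement {disp[t]} mm); pad the grid"
            ) from err
    return FractionDose(dose, fraction_index, field, timeline.technique)


@dataclass(frozen=True)
class TreatmentPlan:
    """Shared beam/target geometry used for every simulated patient.

    Holds, per field label, the source dose grids consumed by
    :func:`accumulate_fraction`: 'full_beam' (composed SOBP, plateau
    normalised to 100%) and one contribution grid per energy layer, all on
    the same lattice.
    """

    ctv: CTVGeometry
    layers: LayerSet
    grid: GridSpec
    field_grids: Mapping[str, Mapping[str | int, DoseGrid]]

    def static_ctv_dose(self, field: str) -> np.ndarray:
        """Zero-motion CTV dose of one field (% of prescription)."""
        g = self.field_grids[field][FULL_BEAM]
        interp = RegularGridInterpolator(
            tuple(g.grid.coords(i) for i in range(3)), g.values, method="linear"
        )
        return interp(self.ctv.voxel_centers())


def build_plan(
    model: BraggPeakModel,
    layers: LayerSet,
    ctv: CTVGeometry,
    grid: GridSpec | None = None,
    fields: Mapping[str, FieldGeometry] | None = None,
) -> TreatmentPlan:
    """Compose per-field full-beam and per-layer contribution grids.

    The default field set is the lateral pair used for prostate treatment:
    LAO entering from the patient's left (beam axis -x under the package
    axis convention) and RAO from the right, both normalised so the
    composed beam is 100% at the CTV centre.
    """
    if layers.weights is None:
        raise ValueError("layer weights must be solved before building a plan")
    if grid is None:
        grid = default_grid_for(ctv)
    if fields is None:
        fields = {
            "LAO": FieldGeometry(beam_axis=-1),
            "RAO": FieldGeometry(beam_axis=+1),
        }
    field_grids: dict[str, dict[str | int, DoseGrid]] = {}
    for label, geom in fields.items():
        layer_grids = [
            build_layer_dose_grid(model, layers, k, geom, ctv, grid)
            for k in range(layers.n_layers)
        ]
        composed = compose_beam_dose(layer_grids, layers.weights, ctv.center_mm)
        contrib = weighted_layer_grids(layer_grids, layers.weights, ctv.center_mm)
        sources: dict[str | int, DoseGrid] = {FULL_BEAM: composed}
        sources.update({k: g for k, g in enumerate(contrib)})
        field_grids[label] = sources
    return TreatmentPlan(ctv, layers, grid, field_grids)


def simulate_course(
    plan: TreatmentPlan,
    traces: Sequence[MotionTrace],
    technique: str,
    fraction_dose_gy: float,
    dose_rate_gy_per_min: float = 2.0,
    delay_s: float = 25.0,
    switch_s: float = 0.5,
    field_order: tuple[str, str] = ("LAO", "RAO"),
) -> tuple[CourseDose, list[FractionDose]]:
    """Simulate a full course: one alternating lateral field per fraction.

    Fraction f (1-based) uses ``field_order[0]`` when f is odd.  Each
    fraction delivers the full fraction prescription through its single
    field; traces must already be down-sampled to 1 Hz, one per fraction.
    The course dose is the voxelwise mean of per-fraction percent doses
    (equal fraction weighting), i.e. percent of the total prescription.
    """
    n_fractions = len(traces)
    if n_fractions < 1:
        raise ValueError("at least one fraction trace is required")
    timeline = build_timeline(
        technique, fraction_dose_gy, dose_rate_gy_per_min, plan.layers, delay_s, switch_s
    )
    fraction_doses = []
    for f, trace in enumerate(traces):
        field = field_order[f % 2]
        fd = accumulate_fraction(
            plan.field_grids[field], timeline, trace, plan.ctv,
            fraction_index=f + 1, field=field,
        )
        fraction_doses.append(fd)
    course = np.mean([fd.values for fd in fraction_doses], axis=0)
    return CourseDose(course, n_fractions, timeline.technique), fraction_doses
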