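"""Structured run configuration with YAML round-trip.

A ``RunConfig`` fully determines a cohort run: beam model, field margins,
CTV geometry, motion cohort, fractionation schedule and seed.  Defaults
reproduce the study conditions: a 30.1 g/cm^2 range / 8.4 g/cm^2
modulation lateral field (14 layers at 0.6 g/cm^2 spacing), a 17-patient
by 14-fraction cohort of 300 s traces at 10 Hz, 2 Gy fractions at
2 Gy/min with a 25 s pre-beam delay and 0.5 s layer switching, and an
SBRT alternative of 5 x 7.25 Gy.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .beam import BraggPeakModel, FieldGeometry, LayerSet, build_layer_set, solve_layer_weights
from .geometry import CTVGeometry, GridSpec, default_grid_for
from .motion import CohortSpec


@dataclass(frozen=True)
class BeamConfig:
    range_gcm2: float = 30.1
    modulation_gcm2: float = 8.4
    spacing_gcm2: float = 0.6
    peak_width_gcm2: float = 0.6
    entrance_ratio: float = 0.35
    flatness_tol: float = 0.02

    def model(self) -> BraggPeakModel:
        return BraggPeakModel(self.range_gcm2, self.peak_width_gcm2, self.entrance_ratio)

    def layer_set(self) -> LayerSet:
        layers = build_layer_set(self.range_gcm2, self.modulation_gcm2, self.spacing_gcm2)
        return solve_layer_weights(self.model(), layers, self.flatness_tol)


@dataclass(frozen=True)
class TargetConfig:
    semi_axes_mm: tuple[float, float, float] = (25.0, 20.0, 22.5)  # (LR, AP, SI)
    sample_spacing_mm: float = 2.0
    grid_pad_mm: float = 25.0
    grid_spacing_mm: float = 1.0

    def ctv(self) -> CTVGeometry:
        return CTVGeometry(tuple(self.semi_axes_mm), (0.0, 0.0, 0.0), self.sample_spacing_mm)

    def grid(self) -> GridSpec:
        return default_grid_for(self.ctv(), self.grid_pad_mm, self.grid_spacing_mm)


@dataclass(frozen=True)
class FieldConfig:
    aperture_margin_mm: float = 10.0
    penumbra_80_20_mm: float = 6.0
    distal_margin_mm: float = 5.0
    proximal_margin_mm: float = 10.0

    def geometry(self, beam_axis: int) -> FieldGeometry:
        return FieldGeometry(
            beam_axis,
            self.aperture_margin_mm,
            self.penumbra_80_20_mm,
            self.distal_margin_mm,
            self.proximal_margin_mm,
        )


@dataclass(frozen=True)
class FractionationConfig:
    """One fractionation arm: standard 2 Gy x 14 or SBRT 7.25 Gy x 5."""

    name: str = "std_2gy"
    n_fractions: int = 14
    fraction_dose_gy: float = 2.0
    dose_rate_gy_per_min: float = 2.0
    delay_s: float = 25.0
    switch_s: float = 0.5


STD_2GY = FractionationConfig("std_2gy", 14, 2.0)
SBRT = FractionationConfig("sbrt", 5, 7.25)


@dataclass(frozen=True)
class RunConfig:
    beam: BeamConfig = field(default_factory=BeamConfig)
    target: TargetConfig = field(default_factory=TargetConfig)
    field_geometry: FieldConfig = field(default_factory=FieldConfig)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    fractionation: FractionationConfig = field(default_factory=lambda: STD_2GY)
    seed: int = 0
    paired_test: bool = True
    significance: float = 0.05

    def __post_init__(self) -> None:
        if self.cohort.n_fractions < self.fractionation.n_fractions:
            raise ValueError(
                "cohort must provide at least one trace per treatment fraction"
            )
        span = (
            self.fractionation.delay_s
            + self.fractionation.fraction_dose_gy
            / self.fractionation.dose_rate_gy_per_min
            * 60.0
        )
        if self.cohort.duration_s < span + 10:
            raise ValueError("cohort trace duration too short for the timeline")

    # -- YAML round trip ----------------------------------------------------

    def to_dict(self) -> dict:
        def listify(obj):
            if isinstance(obj, dict):
                return {k: listify(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [listify(v) for v in obj]
            return obj

        return listify(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        def build(typ, sub):
            if sub is None:
                return typ()
            fields = {f.name for f in dataclasses.fields(typ)}
            unknown = set(sub) - fields
            if unknown:
                raise ValueError(f"unknown {typ.__name__} keys: {sorted(unknown)}")
            sub = {
                k: tuple(v) if isinstance(v, list) else v for k, v in sub.items()
            }
            return typ(**sub)

        return cls(
            beam=build(BeamConfig, d.get("beam")),
            target=build(TargetConfig, d.get("target")),
            field_geometry=build(FieldConfig, d.get("field_geometry")),
            cohort=build(CohortSpec, d.get("cohort")),
            fractionation=build(FractionationConfig, d.get("fractionation")),
            seed=int(d.get("seed", 0)),
            paired_test=bool(d.get("paired_test", True)),
            significance=float(d.get("significance", 0.05)),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)


def sbrt_variant(config: RunConfig) -> RunConfig:
    """The same run with the SBRT fractionation arm."""
    return dataclasses.replace(config, fractionation=SBRT)
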