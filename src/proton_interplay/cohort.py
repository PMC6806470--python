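"""Cohort-scale orchestration: traces -> DS/US simulation -> metrics -> report.

Every patient shares one beam/CTV geometry (the study isolates intrafraction
motion from planning differences); for each (patient, fraction) the *same*
down-sampled trace drives both the DS and the US simulation, so the
DS-vs-US comparison is intrinsically paired.  Summaries mirror the usual
reporting layout: mean / STD / max / min per metric and technique, at the
single-fraction and fraction-cumulative (course) level, with a two-sided
paired t-test per metric.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig
from .delivery import (
    FULL_BEAM,
    TreatmentPlan,
    accumulate_fraction,
    build_plan,
    build_timeline,
)
from .dvh import DVHMetrics, compute_dvh, dvh_metrics
from .motion import MotionTrace, downsample_trace, generate_cohort

logger = logging.getLogger(__name__)

TECHNIQUES = ("DS", "US")
METRICS = DVHMetrics.METRIC_ORDER


def trace_hash(trace: MotionTrace) -> str:
    """Stable content hash of a trace, for the paired-design manifest."""
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(trace.times_s).tobytes())
    h.update(np.ascontiguousarray(trace.disp_mm).tobytes())
    return h.hexdigest()[:16]


@dataclass(frozen=True)
class CohortSummary:
    """Mean/STD/Max/Min per metric and technique, plus per-metric p-values."""

    record_level: str            # 'single_fraction' or 'course'
    fractionation: str           # 'std_2gy' or 'sbrt'
    stats: pd.DataFrame          # index (stat, technique), columns METRICS
    p_values: pd.Series          # per metric
    n_records: int

    def table(self) -> pd.DataFrame:
        """Report-style table: stat rows x metric columns, p-values last."""
        rows = self.stats.copy()
        rows.loc[("P value", ""), :] = self.p_values
        return rows


@dataclass(frozen=True)
class CohortResult:
    """All outputs of one cohort run."""

    config: RunConfig
    plan: TreatmentPlan
    records: pd.DataFrame         # per (patient, fraction, technique) metrics
    course_records: pd.DataFrame  # per (patient, technique) course metrics
    summaries: dict[str, CohortSummary]
    static_metrics: DVHMetrics    # zero-motion baseline of the shared plan
    course_doses: dict[tuple[int, str], np.ndarray]
    manifest: dict


def compare_techniques(
    ds_values: Sequence[float], us_values: Sequence[float], paired: bool = True
) -> float:
    """Two-sided Student t-test p-value between DS and US metric samples.

    Paired by default (the same traces drive both techniques).  A paired
    set of identical samples has zero mean difference with zero variance;
    by convention that returns p = 1 (logged), and a zero-variance nonzero
    mean difference returns p = 0.
    """
    ds = np.asarray(ds_values, dtype=float)
    us = np.asarray(us_values, dtype=float)
    if ds.size < 2 or us.size < 2:
        raise ValueError("need at least two records per technique")
    if paired:
        if ds.size != us.size:
            raise ValueError("paired test requires equal sample sizes")
        diff = ds - us
        if np.allclose(diff.std(ddof=1), 0.0):
            p = 1.0 if np.allclose(diff.mean(), 0.0) else 0.0
            logger.info("zero-variance differences: p = %.1f by convention", p)
            return p
        return float(stats.ttest_rel(ds, us).pvalue)
    if np.allclose(ds.std(ddof=1), 0.0) and np.allclose(us.std(ddof=1), 0.0):
        p = 1.0 if np.allclose(ds.mean(), us.mean()) else 0.0
        logger.info("zero-variance samples: p = %.1f by convention", p)
        return p
    return float(stats.ttest_ind(ds, us).pvalue)


def _summarize(
    df: pd.DataFrame, record_level: str, fractionation: str, paired: bool
) -> CohortSummary:
    rows = {}
    for stat, fn in (("Mean", "mean"), ("STD", "std"), ("Max", "max"), ("Min", "min")):
        for tech in TECHNIQUES:
            sub = df[df["technique"] == tech][list(METRICS)]
            rows[(stat, tech)] = getattr(sub, fn)()
    table = pd.DataFrame(rows).T
    table.index = pd.MultiIndex.from_tuples(table.index, names=["stat", "technique"])
    key = ["patient"] if record_level == "course" else ["patient", "fraction"]
    ds = df[df["technique"] == "DS"].sort_values(key)
    us = df[df["technique"] == "US"].sort_values(key)
    p = pd.Series(
        {m: compare_techniques(ds[m].to_numpy(), us[m].to_numpy(), paired) for m in METRICS}
    )
    n = len(ds)
    return CohortSummary(record_level, fractionation, table, p, n)


def run_cohort(config: RunConfig) -> CohortResult:
    """Run the full pipeline under one configuration.

    Generates the synthetic cohort, simulates every (patient, fraction)
    under both DS and US with the identical trace, extracts per-fraction
    and course DVH metrics, and assembles summary tables with paired
    t-tests.  Any stage failure is re-raised with the failing (patient,
    fraction) identified.
    """
    frac = config.fractionation
    model = config.beam.model()
    layers = config.beam.layer_set()
    ctv = config.target.ctv()
    plan = build_plan(
        model,
        layers,
        ctv,
        config.target.grid(),
        {
            "LAO": config.field_geometry.geometry(-1),
            "RAO": config.field_geometry.geometry(+1),
        },
    )
    static = dvh_metrics(plan.static_ctv_dose("LAO"))

    cohort = generate_cohort(config.cohort, config.seed)
    timelines = {
        tech: build_timeline(
            tech, frac.fraction_dose_gy, frac.dose_rate_gy_per_min,
            layers, frac.delay_s, frac.switch_s,
        )
        for tech in TECHNIQUES
    }

    records: list[dict] = []
    course_records: list[dict] = []
    course_doses: dict[tuple[int, str], np.ndarray] = {}
    hashes: dict[str, str] = {}
    for p_idx, patient_traces in enumerate(cohort, start=1):
        fraction_traces = [
            downsample_trace(tr) for tr in patient_traces[: frac.n_fractions]
        ]
        if len(fraction_traces) < frac.n_fractions:
            raise ValueError(
                f"patient {p_idx}: {len(fraction_traces)} traces for "
                f"{frac.n_fractions} fractions"
            )
        for f_idx, tr in enumerate(fraction_traces, start=1):
            hashes[f"{p_idx}/{f_idx}"] = trace_hash(tr)
        for tech in TECHNIQUES:
            per_fraction = []
            for f_idx, tr in enumerate(fraction_traces, start=1):
                fld = ("LAO", "RAO")[(f_idx - 1) % 2]
                try:
                    fd = accumulate_fraction(
                        plan.field_grids[fld], timelines[tech], tr, ctv,
                        fraction_index=f_idx, field=fld,
                    )
                except Exception as err:
                    raise RuntimeError(
                        f"simulation failed at patient {p_idx}, fraction {f_idx}, "
                        f"technique {tech}: {err}"
                    ) from err
                per_fraction.append(fd)
                m = dvh_metrics(fd.values)
                records.append(
                    {
                        "patient": p_idx, "fraction": f_idx, "technique": tech,
                        "field": fld, "trace_hash": hashes[f"{p_idx}/{f_idx}"],
                        **m.as_dict(),
                        "hot_flag": m.hot_flag, "cold_flag": m.cold_flag,
                    }
                )
            course = np.mean([fd.values for fd in per_fraction], axis=0)
            course_doses[(p_idx, tech)] = course
            cm = dvh_metrics(course)
            course_records.append(
                {
                    "patient": p_idx, "technique": tech, **cm.as_dict(),
                    "hot_flag": cm.hot_flag, "cold_flag": cm.cold_flag,
                }
            )

    records_df = pd.DataFrame(records)
    course_df = pd.DataFrame(course_records)
    summaries = {
        "single_fraction": _summarize(
            records_df, "single_fraction", frac.name, config.paired_test
        ),
        "course": _summarize(course_df, "course", frac.name, config.paired_test),
    }
    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "n_patients": config.cohort.n_patients,
        "n_fractions": frac.n_fractions,
        "trace_hashes": hashes,
        "static_baseline": static.as_dict(),
    }
    return CohortResult(
        config, plan, records_df, course_df, summaries, static, course_doses, manifest
    )


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def _summary_csv(summary: CohortSummary, static: DVHMetrics, path: Path) -> None:
    table = summary.table()
    flat = table.copy()
    flat.index = [" ".join(str(p) for p in ix if p != "") for ix in table.index]
    baseline = pd.DataFrame([static.as_dict()], index=["Static baseline"])
    pd.concat([baseline, flat]).round(6).to_csv(path, index_label="stat")


def _dvh_overlay(result: CohortResult, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    worst = (
        result.course_records.groupby("patient")["D95"].min().idxmin()
    )
    fig, ax = plt.subplots(figsize=(6, 4))
    static = compute_dvh(result.plan.static_ctv_dose("LAO"))
    ax.plot(static.dose_levels, static.volume_fraction, "k-", label="static plan")
    for tech, style in (("DS", "C0--"), ("US", "C3-.")):
        curve = compute_dvh(result.course_doses[(worst, tech)])
        ax.plot(curve.dose_levels, curve.volume_fraction, style, label=f"{tech} course")
    ax.set(
        xlabel="dose (% of prescription)", ylabel="CTV volume (%)",
        xlim=(80, 120), ylim=(0, 105),
        title=f"Course DVH, patient {worst} ({result.config.fractionation.name})",
    )
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _planar_difference(result: CohortResult, path: Path) -> None:
    """Transverse-plane DS-vs-US single-fraction dose difference image."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cfg = result.config
    frac = cfg.fractionation
    layers = result.plan.layers
    cohort = generate_cohort(cfg.cohort, cfg.seed)
    trace = downsample_trace(cohort[0][0])
    grid = result.plan.grid
    # keep the sampled plane well inside the grid so displaced points
    # cannot leave it
    margin = 12.0
    xs = grid.coords(0)
    ys = grid.coords(1)
    xs = xs[(xs > xs[0] + margin) & (xs < xs[-1] - margin)]
    ys = ys[(ys > ys[0] + margin) & (ys < ys[-1] - margin)]
    xx, yy = np.meshgrid(xs[::2], ys[::2], indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(xx.size)])
    plane = _PointSet(pts)
    images = {}
    for tech in TECHNIQUES:
        tl = build_timeline(
            tech, frac.fraction_dose_gy, frac.dose_rate_gy_per_min,
            layers, frac.delay_s, frac.switch_s,
        )
        fd = accumulate_fraction(result.plan.field_grids["RAO"], tl, trace, plane)
        images[tech] = fd.values.reshape(xx.shape)
    diff = images["US"] - images["DS"]
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    span = max(1.0, float(np.abs(diff).max()))
    im = ax.pcolormesh(xx, yy, diff, cmap="RdBu_r", vmin=-span, vmax=span)
    fig.colorbar(im, ax=ax, label="US - DS dose (% of Rx)")
    ax.set(xlabel="LR (mm)", ylabel="AP (mm)", title="Transverse plane through isocentre")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


class _PointSet:
    """Duck-typed stand-in for CTVGeometry sampling arbitrary points."""

    def __init__(self, points: np.ndarray):
        self._points = points

    def voxel_centers(self) -> np.ndarray:
        return self._points


def render_report(result: CohortResult, outdir: str | Path) -> list[Path]:
    """Write record tables, summary tables and figures under ``outdir``.

    CSV outputs are deterministic: regeneration from the same result is
    byte-identical.  Figure failures are logged, never fatal.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    p = out / "records_single_fraction.csv"
    result.records.round(6).to_csv(p, index=False)
    written.append(p)
    p = out / "records_course.csv"
    result.course_records.round(6).to_csv(p, index=False)
    written.append(p)
    for level, summary in result.summaries.items():
        p = out / f"summary_{summary.fractionation}_{level}.csv"
        _summary_csv(summary, result.static_metrics, p)
        written.append(p)
    p = out / "manifest.json"
    p.write_text(json.dumps(result.manifest, indent=2, sort_keys=True))
    written.append(p)

    for name, fn in (
        ("dvh_overlay.png", _dvh_overlay),
        ("planar_difference.png", _planar_difference),
    ):
        try:
            fn(result, out / name)
            written.append(out / name)
        except Exception:  # pragma: no cover - plotting is best-effort
            logger.exception("failed to render %s", name)
    return written
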