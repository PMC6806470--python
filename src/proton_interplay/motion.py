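"""Synthetic intrafraction prostate motion traces and cohort statistics.

Emulates electromagnetic-transponder (Calypso-style) tracking of the
prostate at 10 Hz over 4-10 minute sessions.  Real traces show four
behaviours that the generator reproduces: slow quasi-linear drifts,
transient excursions that return to baseline, persistent offsets sustained
to the end of the session, and high-frequency jitter; superior-inferior and
anterior-posterior motion are positively correlated.

Trace displacement columns are ordered (LR, SI, AP) in millimetres,
matching the trace CSV format; the delivery module converts to grid axes.

Cohort-level motion is summarised by the standard two-component model:
the *systematic* component is the SD across patients of the per-patient
mean displacement, and the *random* component is the root-mean-square of
the per-patient displacement SDs, per axis.  The cohort sampler is
parameterised directly by target systematic and random components and maps
them internally to drift / persistent-offset / excursion / jitter scales.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

TRACE_AXES = ("lr", "si", "ap")
TRACE_COLUMNS = ("time_s", "lr_mm", "si_mm", "ap_mm")


@dataclass(frozen=True)
class MotionTrace:
    """Timestamped rigid 3D target displacement from the setup position."""

    times_s: np.ndarray        # (n,), strictly increasing, starting at 0
    disp_mm: np.ndarray        # (n, 3) displacement in (LR, SI, AP)
    rate_hz: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        d = np.asarray(self.disp_mm, dtype=float)
        if t.ndim != 1 or t.size == 0:
            raise ValueError("times_s must be a nonempty 1D array")
        if d.shape != (t.size, 3):
            raise ValueError("disp_mm must have shape (len(times_s), 3)")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("times_s must be strictly increasing")
        if not np.all(np.isfinite(d)):
            raise ValueError("disp_mm must be finite")

    @property
    def duration_s(self) -> float:
        """Tracked time span (first to last sample)."""
        return float(self.times_s[-1] - self.times_s[0])

    def disp_xyz(self) -> np.ndarray:
        """Displacement reordered to grid axes (x=LR, y=AP, z=SI)."""
        return self.disp_mm[:, [0, 2, 1]]


@dataclass(frozen=True)
class MotionModelParams:
    """Parameters of one trace realisation.

    ``regime`` selects which components are active; 'mixed' enables all.
    Vector quantities are in (LR, SI, AP) order.  ``excursion_amplitude_mm``
    may be a scalar or a per-axis 3-vector; each excursion's direction is a
    correlated standard-normal draw scaled by it.
    """

    regime: str = "mixed"
    drift_rate_mm_per_min: Sequence[float] = (0.0, 0.0, 0.0)
    excursion_amplitude_mm: float | Sequence[float] = 0.0
    excursion_duration_s: float = 25.0
    excursion_rate_per_min: float = 0.0
    persistent_offset_mm: Sequence[float] = (0.0, 0.0, 0.0)
    persistent_onset_s: float | None = None   # None: uniform in [0.15, 0.55] x duration
    persistent_tau_s: float = 8.0
    jitter_sd_mm: Sequence[float] = (0.0, 0.0, 0.0)
    si_ap_correlation: float = 0.6

    def __post_init__(self) -> None:
        if self.regime not in ("stable", "drift", "transient", "persistent", "mixed"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if not -1.0 <= self.si_ap_correlation <= 1.0:
            raise ValueError("|si_ap_correlation| must be <= 1")
        for name in ("excursion_duration_s", "excursion_rate_per_min", "persistent_tau_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if np.any(np.asarray(self.excursion_amplitude_mm, dtype=float) < 0):
            raise ValueError("excursion_amplitude_mm must be >= 0")
        if np.any(np.asarray(self.jitter_sd_mm, dtype=float) < 0):
            raise ValueError("jitter_sd_mm must be >= 0")


def _correlation_cholesky(rho: float) -> np.ndarray:
    """Cholesky factor of the (LR, SI, AP) correlation with corr(SI, AP)=rho."""
    c = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, rho], [0.0, rho, 1.0]])
    # for |rho| = 1 the matrix is singular; nudge for a valid factorisation
    if abs(rho) == 1.0:
        c[1, 2] = c[2, 1] = math.copysign(1.0 - 1e-12, rho)
    return np.linalg.cholesky(c)


def generate_trace(
    params: MotionModelParams,
    duration_s: float,
    rate_hz: float = 10.0,
    seed: int | np.random.Generator | None = None,
) -> MotionTrace:
    """Generate one displacement trace; reproducible for a fixed seed.

    Active components by regime -- stable: jitter only; drift: linear drift;
    transient: raised-cosine excursions; persistent: sigmoid-onset offset;
    mixed: all of the above.  SI and AP random draws are correlated at
    ``params.si_ap_correlation``.
    """
    if duration_s <= 0 or rate_hz <= 0:
        raise ValueError("duration_s and rate_hz must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # endpoint inclusive: a 300 s trace at 10 Hz has samples at 0 .. 300.0,
    # so a pure drift reaches exactly rate x duration at the last sample
    n = int(round(duration_s * rate_hz)) + 1
    t = np.arange(n) / rate_hz
    disp = np.zeros((n, 3))
    chol = _correlation_cholesky(params.si_ap_correlation)
    active = params.regime

    if active in ("drift", "mixed"):
        rate = np.asarray(params.drift_rate_mm_per_min, dtype=float)
        disp += np.outer(t / 60.0, rate)

    if active in ("persistent", "mixed"):
        offset = np.asarray(params.persistent_offset_mm, dtype=float)
        if np.any(offset != 0.0):
            t0 = params.persistent_onset_s
            if t0 is None:
                t0 = rng.uniform(0.15, 0.55) * duration_s
            gate = 1.0 / (1.0 + np.exp(-(t - t0) / params.persistent_tau_s))
            disp += np.outer(gate, offset)

    if active in ("transient", "mixed"):
        amp = np.broadcast_to(
            np.asarray(params.excursion_amplitude_mm, dtype=float), (3,)
        )
        if params.excursion_rate_per_min > 0 and np.any(amp > 0):
            dur = params.excursion_duration_s
            n_ev = rng.poisson(params.excursion_rate_per_min * duration_s / 60.0)
            for _ in range(n_ev):
                t0 = rng.uniform(0.0, max(duration_s - dur, 0.0))
                vec = amp * (chol @ rng.standard_normal(3))
                sel = (t >= t0) & (t < t0 + dur)
                pulse = 0.5 * (1.0 - np.cos(2.0 * math.pi * (t[sel] - t0) / dur))
                disp[sel] += np.outer(pulse, vec)

    jitter = np.asarray(params.jitter_sd_mm, dtype=float)
    if np.any(jitter > 0):
        disp += (rng.standard_normal((n, 3)) @ chol.T) * jitter

    return MotionTrace(t, disp, rate_hz)


def downsample_trace(trace: MotionTrace, window_s: float = 1.0) -> MotionTrace:
    """Block-average a trace to one sample per window (default 1 s).

    Each output sample is the arithmetic mean of the raw samples in its
    window; a trailing partial window is dropped, so the output length is
    floor(duration / window).
    """
    if trace.times_s.size == 0:
        raise ValueError("cannot down-sample an empty trace")
    per = int(round(trace.rate_hz * window_s))
    if per < 1:
        raise ValueError("trace rate must be at least one sample per window")
    n_out = trace.times_s.size // per
    if n_out == 0:
        raise ValueError("trace shorter than one window")
    d = trace.disp_mm[: n_out * per].reshape(n_out, per, 3).mean(axis=1)
    return MotionTrace(np.arange(n_out) * window_s, d, 1.0 / window_s)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Study-condition defaults for the synthetic tracking cohort.

    Targets are the cohort motion components the generator is calibrated
    to, in (LR, SI, AP) order: systematic = SD across patients of the
    per-patient mean displacement; random = RMS of per-patient displacement
    SDs.  ``patient_heterogeneity`` is the log-normal sigma of a per-patient
    activity multiplier (some patients move much more than others), with
    the mean-square fixed at 1 so the cohort targets are preserved.
    """

    n_patients: int = 17
    n_fractions: int = 14
    duration_s: float = 300.0
    rate_hz: float = 10.0
    systematic_mm: tuple[float, float, float] = (0.3, 0.5, 0.6)
    random_mm: tuple[float, float, float] = (0.7, 1.4, 1.9)
    si_ap_correlation: float = 0.6
    patient_heterogeneity: float = 0.5
    excursion_duration_s: float = 25.0
    excursion_rate_per_min: float = 0.5
    jitter_sd_mm: float | None = None   # None: derived from random_mm

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_fractions < 1:
            raise ValueError("n_patients and n_fractions must be >= 1")
        if self.duration_s <= 0 or self.rate_hz <= 0:
            raise ValueError("duration_s and rate_hz must be > 0")


# variance shares of the random component across generator mechanisms
_SHARE_DRIFT = 0.35
_SHARE_PERSISTENT = 0.30
_SHARE_EXCURSION = 0.25
_SHARE_JITTER = 0.10
# systematic-component split between patient-level drift bias and
# patient-level persistent-offset bias
_SYS_SHARE_DRIFT = 0.4
# moments of the persistent-offset sigmoid gate for onset ~ U(0.15, 0.55)T
_GATE_MEAN = 0.65
_GATE_MEANSQ = 0.4358


def _component_scales(spec: CohortSpec) -> dict[str, np.ndarray]:
    """Map cohort targets to per-axis mechanism scales.

    The mapping inverts first-order expressions for the pooled per-patient
    variance and the across-patient mean variance of each mechanism, and
    shrinks the patient-level biases so that the finite-fraction sampling
    inflation of the systematic estimator is cancelled in expectation.
    """
    T = spec.duration_s
    sigma = np.asarray(spec.random_mm, dtype=float)
    Sigma = np.asarray(spec.systematic_mm, dtype=float)
    var = sigma**2

    # per-fraction random scales
    tau_drift = np.sqrt(_SHARE_DRIFT * var) / (T / math.sqrt(10800.0))
    # pooled variance factor of the gated offset: within-fraction gate
    # variance (mean - mean_sq) plus across-fraction gate-mean variance
    gate_pool = (_GATE_MEAN - _GATE_MEANSQ) + _GATE_MEANSQ
    tau_pers = np.sqrt(_SHARE_PERSISTENT * var / gate_pool)
    duty = spec.excursion_rate_per_min / 60.0 * spec.excursion_duration_s
    exc_pool = max(duty, 1e-12) * 0.375
    amp_exc = np.sqrt(_SHARE_EXCURSION * var / exc_pool)
    if spec.jitter_sd_mm is None:
        jitter = np.sqrt(_SHARE_JITTER * var)
    else:
        jitter = np.full(3, float(spec.jitter_sd_mm))

    # expected across-fraction variance of the per-fraction trace mean,
    # which inflates the systematic estimator by V_fm / n_fractions
    v_fm = (
        tau_drift**2 * T**2 / 14400.0
        + tau_pers**2 * _GATE_MEANSQ
        + (spec.excursion_rate_per_min * T / 60.0)
        * (0.5 * spec.excursion_duration_s / max(T, 1e-12)) ** 2
        * amp_exc**2
    )
    shrink_sq = 1.0 - v_fm / (spec.n_fractions * np.maximum(Sigma**2, 1e-12))
    shrink = np.sqrt(np.clip(shrink_sq, 0.0, None))

    g_drift_mean = T / 120.0
    s_drift = shrink * Sigma * math.sqrt(_SYS_SHARE_DRIFT) / g_drift_mean
    s_pers = shrink * Sigma * math.sqrt(1.0 - _SYS_SHARE_DRIFT) / _GATE_MEAN
    return {
        "tau_drift": tau_drift,
        "tau_pers": tau_pers,
        "amp_exc": amp_exc,
        "jitter": jitter,
        "s_drift": s_drift,
        "s_pers": s_pers,
    }


def _default_patient_sampler(spec: CohortSpec):
    """Per-patient parameter sampler: draws a patient once, then per-fraction."""
    scales = _component_scales(spec)
    chol = _correlation_cholesky(spec.si_ap_correlation)
    xi = spec.patient_heterogeneity

    def draw_patient(rng: np.random.Generator):
        activity = math.exp(xi * rng.standard_normal() - xi**2)  # E[a^2] = 1
        drift_bias = scales["s_drift"] * (chol @ rng.standard_normal(3))
        pers_bias = scales["s_pers"] * (chol @ rng.standard_normal(3))

        def draw_fraction(frng: np.random.Generator) -> MotionModelParams:
            drift = drift_bias + activity * scales["tau_drift"] * (
                chol @ frng.standard_normal(3)
            )
            pers = pers_bias + activity * scales["tau_pers"] * (
                chol @ frng.standard_normal(3)
            )
            return MotionModelParams(
                regime="mixed",
                drift_rate_mm_per_min=tuple(drift),
                excursion_amplitude_mm=tuple(activity * scales["amp_exc"]),
                excursion_duration_s=spec.excursion_duration_s,
                excursion_rate_per_min=spec.excursion_rate_per_min,
                persistent_offset_mm=tuple(pers),
                jitter_sd_mm=tuple(scales["jitter"]),
                si_ap_correlation=spec.si_ap_correlation,
            )

        return draw_fraction

    return draw_patient


def generate_cohort(
    spec: CohortSpec,
    seed: int,
    patient_sampler: Callable | None = None,
) -> list[list[MotionTrace]]:
    """Generate the full cohort: one trace per (patient, fraction).

    Patient-level motion character (activity, drift and offset biases) is
    drawn once per patient and reused across that patient's fractions with
    per-fraction noise, so within-patient consistency holds.  Seeding uses
    ``numpy.random.SeedSequence(seed)`` spawned once per patient and then
    once per fraction (child 0 is the patient-parameter stream), so any
    single trace is reproducible in isolation.
    """
    sampler = patient_sampler if patient_sampler is not None else _default_patient_sampler(spec)
    root = np.random.SeedSequence(seed)
    cohort: list[list[MotionTrace]] = []
    for pss in root.spawn(spec.n_patients):
        streams = pss.spawn(spec.n_fractions + 1)
        draw_fraction = sampler(np.random.default_rng(streams[0]))
        traces = []
        for fss in streams[1:]:
            frng = np.random.default_rng(fss)
            params = draw_fraction(frng)
            traces.append(generate_trace(params, spec.duration_s, spec.rate_hz, frng))
        cohort.append(traces)
    return cohort


# ---------------------------------------------------------------------------
# cohort statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotionSummary:
    """Two-component motion statistics plus exceedance-of-threshold times."""

    systematic_mm: np.ndarray          # (3,) in (LR, SI, AP)
    random_mm: np.ndarray              # (3,)
    thresholds_mm: tuple[float, ...]
    exceedance_fractions: np.ndarray   # (n_patients, n_thresholds)

    def patients_exceeding(self, min_fraction: float = 0.1) -> np.ndarray:
        """Number of patients beyond each threshold for >= min_fraction of time."""
        return (self.exceedance_fractions >= min_fraction).sum(axis=0)


def motion_components(
    cohort: Sequence[Sequence[MotionTrace]],
    thresholds_mm: tuple[float, ...] = (3.0, 5.0, 7.0),
) -> MotionSummary:
    """Estimate systematic/random components and exceedance fractions.

    Per axis: the patient mean is taken over all samples of all that
    patient's traces; systematic is the (n-1)-denominator SD of those means
    across patients; random is the RMS of the per-patient sample SDs.
    Exceedance is the per-patient fraction of tracked time with 3D
    displacement beyond each threshold.
    """
    if len(cohort) < 2:
        raise ValueError("systematic component needs at least 2 patients")
    means, sds, exceed = [], [], []
    for traces in cohort:
        if len(traces) == 0:
            raise ValueError("every patient needs at least one trace")
        d = np.vstack([tr.disp_mm for tr in traces])
        means.append(d.mean(axis=0))
        sds.append(d.std(axis=0, ddof=1))
        r = np.linalg.norm(d, axis=1)
        exceed.append([np.mean(r > thr) for thr in thresholds_mm])
    means = np.asarray(means)
    sds = np.asarray(sds)
    return MotionSummary(
        systematic_mm=means.std(axis=0, ddof=1),
        random_mm=np.sqrt(np.mean(sds**2, axis=0)),
        thresholds_mm=tuple(thresholds_mm),
        exceedance_fractions=np.asarray(exceed),
    )


# ---------------------------------------------------------------------------
# trace CSV I/O
# ---------------------------------------------------------------------------

def write_trace_csv(trace: MotionTrace, path: str | Path) -> None:
    """Write a trace as CSV with columns time_s, lr_mm, si_mm, ap_mm."""
    df = pd.DataFrame(
        {
            "time_s": trace.times_s,
            "lr_mm": trace.disp_mm[:, 0],
            "si_mm": trace.disp_mm[:, 1],
            "ap_mm": trace.disp_mm[:, 2],
        }
    )
    df.to_csv(path, index=False)


def read_trace_csv(path: str | Path) -> MotionTrace:
    """Read a trace CSV; errors name missing columns or the offending line."""
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {', '.join(missing)}")
    if len(df) == 0:
        raise ValueError(f"{path}: trace file has no samples")
    t = df["time_s"].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        # +3: 1-based line numbering, header row, and diff offset
        raise ValueError(f"{path}: time_s not strictly increasing at line {bad[0] + 3}")
    disp = df[["lr_mm", "si_mm", "ap_mm"]].to_numpy(dtype=float)
    if t.size > 1:
        rate = 1.0 / float(np.median(np.diff(t)))
    else:
        rate = 1.0
    return MotionTrace(t, disp, rate)
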