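"""Synthetic fetal color tissue Doppler traces and transfusion cohorts.

The generator produces AV-plane myocardial velocity traces with the
structure the downstream analysis assumes, together with exact ground
truth for every beat, so that event detection, peak extraction and the
cohort statistics can be validated against known answers.

Beat model
----------
One cardiac cycle is tiled by six phases in fixed order: atrial
contraction, pre-ejection, ejection, post-ejection, rapid ventricular
filling, slow ventricular filling.  Each velocity wave is a raised-cosine
(Hann) lobe with compact support: the ejection wave (Sm) is positive in
the canonical sign convention, the early-filling (Em) and atrial (Am)
waves negative.  With the default wave width the A, S and E lobes exactly
fill their phases, so phase boundaries are exact zero points of the
waveform.

The template's ``phase_fractions`` define *absolute* phase durations at
the template's own ``heart_rate``.  When a beat is rendered at a higher
rate, slow filling shortens first; once it is exhausted, rapid filling
and atrial contraction are compressed while the wave widths keep their
nominal absolute durations.  The E and A lobes then physically overlap
and eventually merge into a single diastolic extremum: E/A fusion arises
from the geometry, not from a flag.  Per-beat cycle-length jitter scales
all phases and widths proportionally and therefore never causes fusion
by itself.

All sample-level geometry is quantized to the sampling grid, so with
zero noise the rendered peak samples equal the template amplitudes
exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, peak_prominences

from .reference import ReferenceModel, compute_zscore, inverse_zscore
from .trace_io import ExamRecord, VelocityTrace, WALLS

PHASES = (
    "atrial_contraction",
    "pre_ejection",
    "ejection",
    "post_ejection",
    "rapid_filling",
    "slow_filling",
)

DEFAULT_PHASE_FRACTIONS = (0.15, 0.05, 0.35, 0.05, 0.20, 0.20)


class DegenerateSamplingError(ValueError):
    """A wave would be rendered with fewer than 3 samples."""


# ---------------------------------------------------------------------------
# configuration types


@dataclass(frozen=True)
class BeatTemplateParams:
    """Morphological template of one cardiac cycle.

    Amplitudes are magnitudes in cm/s; the default values are typical
    left-ventricular means in mid-gestation fetuses (Am 4.27, Sm 2.77,
    Em 3.55 cm/s).  ``phase_fractions`` are the six phase durations as
    fractions of the cycle at ``heart_rate`` (atrial contraction,
    pre-ejection, ejection, post-ejection, rapid filling, slow filling).
    ``wave_width_frac`` is the half-width of each wave relative to its
    phase; at the default 0.5 each wave exactly fills its phase.
    """

    heart_rate: float = 140.0
    sm_amp: float = 2.77
    em_amp: float = 3.55
    am_amp: float = 4.27
    iso_amp: float = 0.0
    phase_fractions: tuple[float, ...] = DEFAULT_PHASE_FRACTIONS
    wave_width_frac: float = 0.5

    def __post_init__(self) -> None:
        if not (80.0 <= self.heart_rate <= 220.0):
            raise ValueError("heart_rate must be within [80, 220] bpm")
        for name in ("sm_amp", "em_amp", "am_amp", "iso_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        fr = tuple(float(f) for f in self.phase_fractions)
        if len(fr) != 6 or any(f < 0 for f in fr):
            raise ValueError("phase_fractions must be six nonnegative numbers")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError("phase_fractions must sum to 1 within 1e-9")
        object.__setattr__(self, "phase_fractions", fr)
        if not (0 < self.wave_width_frac <= 1.0):
            raise ValueError("wave_width_frac must be in (0, 1]")


@dataclass(frozen=True)
class TraceSimConfig:
    """Rendering configuration for a simulated trace."""

    frame_rate: float = 200.0
    duration: float = 4.0
    orientation: str = "apical"
    noise_sd: float = 0.0
    beat_jitter_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate < 100:
            raise ValueError("frame_rate must be >= 100 frames/s")
        if self.noise_sd < 0 or self.beat_jitter_cv < 0:
            raise ValueError("noise_sd and beat_jitter_cv must be >= 0")
        if self.orientation not in ("apical", "basal"):
            raise ValueError("orientation must be 'apical' or 'basal'")


@dataclass(frozen=True)
class CohortSimConfig:
    """Statistical structure of a simulated before/after transfusion cohort.

    ``slope_em_z_per_mom`` imposes a linear dependence of the true Em
    z-score on the anemia severity (1 - Hb MoM).  When
    ``target_rho_em_am`` is set, the pair (Hb MoM, LV Em/Am z) is instead
    drawn through a Gaussian copula whose population Spearman correlation
    equals the target exactly.  ``residual_z_sd`` is both the
    between-fetus residual SD of the true z-scores and the SD of the
    within-pair disturbance added to the post-transfusion shift, so the
    paired-difference noise SD equals ``residual_z_sd``.
    """

    n_fetuses: int = 32
    ga_range: tuple[float, float] = (20.0, 36.0)
    hb_mom_range: tuple[float, float] = (0.30, 1.10)
    slope_em_z_per_mom: float = 1.5
    post_iut_delta_z: dict = field(
        default_factory=lambda: {"Am": -0.6, "Sm": -0.7, "Em": -0.35}
    )
    hr_before_mean: float = 140.4
    hr_before_sd: float = 9.1
    hr_after_mean: float = 132.7
    hr_after_sd: float = 14.4
    residual_z_sd: float = 1.0
    base_z: dict = field(default_factory=lambda: {"Am": 0.25, "Sm": 0.40, "Em": 0.30})
    target_rho_em_am: float | None = None
    seed: int = 0
    # trace rendering (study acquisition conditions)
    frame_rate_mean: float = 207.7
    frame_rate_sd: float = 13.1
    frame_rate_min: float = 173.0
    duration: float = 4.0
    noise_sd: float = 0.25
    beat_jitter_cv: float = 0.02
    p_apical: float = 0.43
    walls: tuple[str, ...] = WALLS

    def __post_init__(self) -> None:
        if self.n_fetuses < 3:
            raise ValueError("n_fetuses must be >= 3")
        if self.residual_z_sd <= 0:
            raise ValueError("residual_z_sd must be > 0")
        if not self.ga_range[0] < self.ga_range[1]:
            raise ValueError("ga_range must be a nonempty interval")


# ---------------------------------------------------------------------------
# ground-truth containers


@dataclass
class BeatTruth:
    """Exact per-beat ground truth, in sample indices of the trace."""

    index: int
    start: int
    end: int
    phase_bounds: tuple[tuple[int, int], ...]  # six [start, end) intervals
    peak_samples: dict
    peak_values: dict
    fused: bool = False


@dataclass
class TraceTruth:
    """Ground truth for a whole simulated trace."""

    heart_rate: float
    frame_rate: float
    beats: list[BeatTruth]
    clipped_amplitudes: bool = False

    @property
    def n_beats(self) -> int:
        return len(self.beats)


# ---------------------------------------------------------------------------
# beat geometry (integer-sample layout)


@dataclass
class _BeatLayout:
    n_total: int
    n_phase: tuple[int, ...]  # six sample counts
    bounds: tuple[int, ...]  # seven cumulative offsets, bounds[0]=0
    waves: list  # (label, center_offset, half_width_samples, signed_amp)


def _beat_layout(
    params: BeatTemplateParams,
    frame_rate: float,
    heart_rate: float,
    scale: float = 1.0,
) -> _BeatLayout:
    """Integer-sample layout of one beat rendered at ``heart_rate``.

    Phase durations are taken as absolute times defined by the template
    fractions at the template's nominal rate; slow filling absorbs the
    cycle-length difference, then rapid filling and atrial contraction
    compress while wave widths stay nominal (fusion regime).  ``scale``
    applies proportional cycle-length jitter to everything.
    """
    f_ac, f_pe, f_ej, f_post, f_rf, f_sf = params.phase_fractions
    t_nom = 60.0 / params.heart_rate
    t_cycle = scale * 60.0 / heart_rate
    d = {k: scale * frac * t_nom for k, frac in
         zip(("ac", "pe", "ej", "post", "rf"), (f_ac, f_pe, f_ej, f_post, f_rf))}
    d_sf = t_cycle - sum(d.values())
    if d_sf < 0:
        # fusion regime: compress rapid filling and atrial contraction
        shrink = 1.0 + d_sf / (d["ac"] + d["rf"])
        if shrink <= 0:
            raise DegenerateSamplingError(
                "cycle too short for the template's systolic phase durations"
            )
        d["ac"] *= shrink
        d["rf"] *= shrink
        d_sf = 0.0

    n_total = round(t_cycle * frame_rate)

    # continuous phase edges, then wave anchors: the A wave ends at the
    # pre-ejection onset, the S wave is centered in ejection, the E wave
    # starts at the rapid-filling onset
    t_b = np.cumsum([d["ac"], d["pe"], d["ej"], d["post"], d["rf"]])
    wwf = params.wave_width_frac
    w_a = wwf * scale * f_ac * t_nom
    w_s = wwf * d["ej"]
    w_e = wwf * scale * f_rf * t_nom
    h_a, h_s, h_e = (round(w * frame_rate) for w in (w_a, w_s, w_e))
    for label, h in (("am", h_a), ("sm", h_s), ("em", h_e)):
        if 2 * h + 1 < 3:
            raise DegenerateSamplingError(
                f"{label} wave would have fewer than 3 samples"
            )
    c_a = round((t_b[0] - w_a) * frame_rate)
    c_s = round((t_b[1] + t_b[2]) / 2 * frame_rate)
    c_e = round((t_b[3] + w_e) * frame_rate)

    # ground-truth phase boundaries are the integer wave support edges,
    # so boundaries are exact zero points of the rendered waveform
    inner = np.array([c_a + h_a, c_s - h_s, c_s + h_s, c_e - h_e, c_e + h_e])
    inner = np.maximum.accumulate(np.clip(inner, 0, n_total))
    bounds = (0, *inner.tolist(), n_total)
    n = tuple(bounds[j + 1] - bounds[j] for j in range(6))

    waves = [
        ("am", c_a, h_a, -params.am_amp),
        ("sm", c_s, h_s, params.sm_amp),
        ("em", c_e, h_e, -params.em_amp),
    ]
    if params.iso_amp > 0:
        # biphasic isovolumic wiggles centered in the residual intervals
        for label, lo, hi in (("iso_pre", bounds[1], bounds[2]),
                              ("iso_post", bounds[3], bounds[4])):
            h = max(1, round(wwf * (hi - lo)))
            c = (lo + hi) // 2
            waves.append((label + "+", c - h // 2, max(1, h // 2), params.iso_amp))
            waves.append((label + "-", c + h // 2, max(1, h // 2), -params.iso_amp))
    return _BeatLayout(n_total=n_total, n_phase=n, bounds=bounds, waves=waves)


def _add_lobe(buf: np.ndarray, center: int, half_width: int, amp: float) -> None:
    """Add a raised-cosine lobe to ``buf`` at integer sample positions."""
    if amp == 0.0 or half_width < 1:
        return
    lo = max(0, center - half_width)
    hi = min(buf.size - 1, center + half_width)
    if hi < lo:
        return
    k = np.arange(lo, hi + 1)
    buf[k] += amp * 0.5 * (1.0 + np.cos(np.pi * (k - center) / half_width))


# ---------------------------------------------------------------------------
# single-beat and trace simulation


def simulate_beat(
    params: BeatTemplateParams,
    frame_rate: float,
    heart_rate: float | None = None,
) -> tuple[np.ndarray, np.ndarray, BeatTruth]:
    """Render one cardiac cycle in canonical orientation.

    Returns ``(t, v, truth)``: sample times (s), velocities (cm/s) and
    the exact ground truth.  With zero noise (always, for a single beat)
    the recorded peak values equal the template amplitudes exactly.
    """
    hr = params.heart_rate if heart_rate is None else heart_rate
    lay = _beat_layout(params, frame_rate, hr)
    v = np.zeros(lay.n_total)
    for _, c, h, a in lay.waves:
        _add_lobe(v, c, h, a)
    t = np.arange(lay.n_total) / frame_rate
    truth = BeatTruth(
        index=0,
        start=0,
        end=lay.n_total,
        phase_bounds=tuple(
            (lay.bounds[j], lay.bounds[j + 1]) for j in range(6)
        ),
        peak_samples={lbl: c for lbl, c, h, a in lay.waves if lbl in ("am", "sm", "em")},
        peak_values={
            "am": params.am_amp,
            "sm": params.sm_amp,
            "em": params.em_amp,
        },
    )
    return t, v, truth


def _count_separated_minima(segment: np.ndarray, prom_frac: float = 0.10) -> int:
    """Number of clearly separated negative extrema in a diastolic segment.

    Two extrema count as separate when the trough between the two largest
    minima has prominence >= ``prom_frac`` of the smaller one.  This is
    the geometric oracle used to define ground-truth E/A fusion.
    """
    seg = -np.asarray(segment, dtype=float)
    floor = 0.05 * max(seg.max(), 1e-12)
    peaks, _ = find_peaks(seg, height=floor)
    if peaks.size < 2:
        return int(peaks.size)
    order = np.argsort(seg[peaks])[::-1]
    p1, p2 = sorted(peaks[order[:2]])
    trough = seg[p1:p2 + 1].min()
    smaller = min(seg[p1], seg[p2])
    return 2 if (smaller - trough) >= prom_frac * smaller else 1


def _simulate(
    params: BeatTemplateParams, cfg: TraceSimConfig, heart_rate: float
) -> tuple[VelocityTrace, TraceTruth]:
    t_cycle = 60.0 / heart_rate
    if cfg.duration < 2 * t_cycle:
        raise ValueError("duration must cover at least 2 cardiac cycles")
    rng = np.random.default_rng(cfg.seed)
    n_total = round(cfg.duration * cfg.frame_rate)
    v = np.zeros(n_total)

    beats: list[BeatTruth] = []
    start = 0
    idx = 0
    while True:
        jit = 0.0
        if cfg.beat_jitter_cv > 0:
            jit = float(np.clip(cfg.beat_jitter_cv * rng.standard_normal(),
                                -3 * cfg.beat_jitter_cv, 3 * cfg.beat_jitter_cv))
        lay = _beat_layout(params, cfg.frame_rate, heart_rate, scale=1.0 + jit)
        complete = start + lay.n_total <= n_total
        for _, c, h, a in lay.waves:
            _add_lobe(v, start + c, h, a)
        if not complete:
            break  # trailing partial beat: rendered (clipped) but not ground truth
        beats.append(
            BeatTruth(
                index=idx,
                start=start,
                end=start + lay.n_total,
                phase_bounds=tuple(
                    (start + lay.bounds[j], start + lay.bounds[j + 1])
                    for j in range(6)
                ),
                peak_samples={
                    lbl: start + c
                    for lbl, c, h, a in lay.waves
                    if lbl in ("am", "sm", "em")
                },
                peak_values={
                    "am": params.am_amp,
                    "sm": params.sm_amp,
                    "em": params.em_amp,
                },
            )
        )
        start += lay.n_total
        idx += 1

    # ground-truth fusion from the rendered noiseless diastoles
    for k in range(len(beats) - 1):
        lo = beats[k].phase_bounds[4][0]  # rapid-filling onset
        hi = beats[k + 1].phase_bounds[0][1]  # end of next atrial contraction
        pair_fused = _count_separated_minima(v[lo:hi + 1]) < 2
        if pair_fused:
            beats[k].fused = True
            beats[k + 1].fused = True

    noise = rng.normal(0.0, cfg.noise_sd, n_total) if cfg.noise_sd > 0 else 0.0
    signed = v + noise
    if cfg.orientation == "basal":
        signed = -signed

    trace = VelocityTrace(
        exam_id="sim",
        wall="LV",
        orientation=cfg.orientation,
        frame_rate=cfg.frame_rate,
        samples=signed,
    )
    return trace, TraceTruth(
        heart_rate=heart_rate, frame_rate=cfg.frame_rate, beats=beats
    )


def simulate_trace(
    params: BeatTemplateParams, cfg: TraceSimConfig
) -> tuple[VelocityTrace, TraceTruth]:
    """Simulate a multi-beat trace at the template's own heart rate."""
    return _simulate(params, cfg, params.heart_rate)


def simulate_fused_trace(
    params: BeatTemplateParams, cfg: TraceSimConfig, hr_high: float
) -> tuple[VelocityTrace, TraceTruth]:
    """Render the template at an overridden heart rate.

    The template keeps its nominal absolute wave widths, so a rate above
    the geometric overlap point compresses diastole until the E and A
    waves physically merge.  (At low rates this is simply a rate
    override and produces no fusion.)
    """
    return _simulate(params, cfg, hr_high)


# ---------------------------------------------------------------------------
# cohort simulation


def pearson_for_spearman(rho_s: float) -> float:
    """Pearson correlation of a bivariate Gaussian with given Spearman rho."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


@dataclass
class SimulatedCohort:
    """A paired before/after transfusion cohort with full ground truth."""

    records: list[ExamRecord]
    traces: dict  # exam_id -> {wall: VelocityTrace}
    trace_truth: dict  # exam_id -> {wall: TraceTruth}
    truth: pd.DataFrame  # one row per exam, true z/amplitudes per variable/wall


def _draw_hb_and_ratio_z(cfg: CohortSimConfig, rng: np.random.Generator):
    """Draw (Hb MoM, LV Em/Am z) for one fetus.

    In copula mode both are monotone transforms of a correlated Gaussian
    pair, so their population Spearman correlation equals
    ``cfg.target_rho_em_am`` exactly.
    """
    from scipy.stats import norm

    lo, hi = cfg.hb_mom_range
    if cfg.target_rho_em_am is None:
        return lo + (hi - lo) * rng.uniform(), None
    r = pearson_for_spearman(cfg.target_rho_em_am)
    g = rng.multivariate_normal([0.0, 0.0], [[1.0, r], [r, 1.0]])
    hb_mom = lo + (hi - lo) * norm.cdf(g[0])
    ratio_z = 0.2 + cfg.residual_z_sd * g[1]
    return float(hb_mom), float(ratio_z)


def simulate_cohort(
    cfg: CohortSimConfig,
    ref: ReferenceModel,
    render_traces: bool = True,
) -> SimulatedCohort:
    """Simulate a paired before/after transfusion cohort.

    Each fetus receives one transfusion with exams before and after.
    True z-scores are drawn per variable and wall, converted to absolute
    amplitudes through the reference model's inverse, and (optionally)
    rendered into per-wall velocity traces.  The ground-truth table
    contains everything needed for parameter-recovery tests.
    """
    lo_ga, hi_ga = cfg.ga_range
    if lo_ga < ref.ga_support[0] or hi_ga > ref.ga_support[1]:
        raise ValueError("ga_range must lie within the reference model's support")
    rng = np.random.default_rng(cfg.seed)

    records: list[ExamRecord] = []
    traces: dict = {}
    trace_truth: dict = {}
    rows: list[dict] = []

    for i in range(cfg.n_fetuses):
        fetus = f"F{i + 1:04d}"
        ga = float(rng.uniform(lo_ga, hi_ga))
        hb_mom, lv_ratio_z = _draw_hb_and_ratio_z(cfg, rng)
        hb = hb_mom * float(ref.hb_median_at(ga))
        mca_mom = 1.0 + 0.8 * (1.0 - hb_mom) + 0.05 * rng.standard_normal()
        mca_psv = mca_mom * float(ref.mca_psv_median_at(ga))

        z_before: dict[tuple[str, str], float] = {}
        for wall in cfg.walls:
            for var in ("Am", "Sm", "Em"):
                z = cfg.base_z.get(var, 0.0) + cfg.residual_z_sd * rng.standard_normal()
                if var == "Em":
                    z += cfg.slope_em_z_per_mom * (1.0 - hb_mom)
                z_before[(var, wall)] = z

        hr_before = float(np.clip(rng.normal(cfg.hr_before_mean, cfg.hr_before_sd), 100, 180))
        hr_after = float(np.clip(rng.normal(cfg.hr_after_mean, cfg.hr_after_sd), 100, 180))

        z_after = {
            (var, wall): z_before[(var, wall)]
            + cfg.post_iut_delta_z.get(var, 0.0)
            + cfg.residual_z_sd * rng.standard_normal()
            for (var, wall) in z_before
        }

        for timing, z_true, hr in (
            ("before", z_before, hr_before),
            ("after", z_after, hr_after),
        ):
            rec = ExamRecord(
                fetus_id=fetus,
                iut_number=1,
                timing=timing,
                ga_weeks=ga,
                hb_g_per_L=hb if timing == "before" else None,
                mca_psv_cm_per_s=mca_psv if timing == "before" else None,
                minutes_after_iut=None if timing == "before" else 60.0,
            )
            records.append(rec)
            row = {
                "exam_id": rec.exam_id,
                "fetus_id": fetus,
                "iut_number": 1,
                "timing": timing,
                "ga_weeks": ga,
                "hb_mom": hb_mom,
                "hb_g_per_L": hb,
                "mca_psv_mom": mca_mom,
                "mca_psv_cm_per_s": mca_psv,
                "heart_rate_true": hr,
                "clipped": False,
            }

            frame_rate = float(
                max(cfg.frame_rate_min, rng.normal(cfg.frame_rate_mean, cfg.frame_rate_sd))
            )
            orientation = "apical" if rng.uniform() < cfg.p_apical else "basal"
            exam_traces: dict = {}
            exam_truth: dict = {}
            for wall in cfg.walls:
                amps = {}
                for var in ("Am", "Sm", "Em"):
                    a = float(inverse_zscore(z_true[(var, wall)], ga, var, wall, ref))
                    if a < 0.05:
                        a = 0.05  # clip: z implies a (near-)negative amplitude
                        row["clipped"] = True
                    amps[var] = a
                if (
                    timing == "before"
                    and wall == "LV"
                    and lv_ratio_z is not None
                ):
                    # copula mode: the LV Em amplitude realizes the drawn ratio z
                    ratio = float(inverse_zscore(lv_ratio_z, ga, "EmAm", "LV", ref))
                    amps["Em"] = max(0.05, ratio * amps["Am"])
                ratio_amp = amps["Em"] / amps["Am"]
                row[f"amp_Am_{wall}"] = amps["Am"]
                row[f"amp_Sm_{wall}"] = amps["Sm"]
                row[f"amp_Em_{wall}"] = amps["Em"]
                row[f"z_Am_{wall}"] = float(compute_zscore(amps["Am"], ga, "Am", wall, ref))
                row[f"z_Sm_{wall}"] = float(compute_zscore(amps["Sm"], ga, "Sm", wall, ref))
                row[f"z_Em_{wall}"] = float(compute_zscore(amps["Em"], ga, "Em", wall, ref))
                row[f"z_EmAm_{wall}"] = float(
                    compute_zscore(ratio_amp, ga, "EmAm", wall, ref)
                )

                if render_traces:
                    template = BeatTemplateParams(
                        heart_rate=hr,
                        sm_amp=amps["Sm"],
                        em_amp=amps["Em"],
                        am_amp=amps["Am"],
                    )
                    tcfg = TraceSimConfig(
                        frame_rate=frame_rate,
                        duration=cfg.duration,
                        orientation=orientation,
                        noise_sd=cfg.noise_sd,
                        beat_jitter_cv=cfg.beat_jitter_cv,
                        seed=int(rng.integers(0, 2**31 - 1)),
                    )
                    trace, truth = simulate_trace(template, tcfg)
                    trace = trace.copy_with(
                        exam_id=rec.exam_id, wall=wall, ga_weeks=ga
                    )
                    exam_traces[wall] = trace
                    exam_truth[wall] = truth
            if render_traces:
                traces[rec.exam_id] = exam_traces
                trace_truth[rec.exam_id] = exam_truth
            rows.append(row)

    return SimulatedCohort(
        records=records,
        traces=traces,
        trace_truth=trace_truth,
        truth=pd.DataFrame(rows),
    )
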