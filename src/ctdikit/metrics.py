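"""Peak myocardial velocities per beat and per wall segment.

Extracts the peak velocity during atrial contraction (Am), ventricular
ejection (Sm) and rapid ventricular filling (Em) from each classified
beat, omits Em/Am on fused beats (they cannot be separated), and
averages across all available cardiac cycles of the trace.  Peaks are
reported as magnitudes (cm/s); the Em/Am ratio is the ratio of the
averaged peaks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .events import (
    BeatPhaseMap,
    QUALITY_MIN,
    classify_phases,
    detect_beats,
    detect_fusion,
    normalize_orientation,
)
from .trace_io import VelocityTrace

log = logging.getLogger(__name__)


class EmptySummaryError(ValueError):
    """No usable beats to summarize."""


@dataclass
class BeatPeaks:
    """Peak velocity magnitudes of one beat; Em/Am absent when fused."""

    beat_index: int
    sm: float
    am: float | None = None
    em: float | None = None
    fused: bool = False
    usable: bool = True


@dataclass
class SegmentSummary:
    """Averaged metrics for one wall segment of one exam."""

    exam_id: str
    wall: str
    sm_mean: float
    am_mean: float | None
    em_mean: float | None
    em_am_ratio: float | None
    heart_rate: float
    n_beats_total: int
    n_beats_used: int
    n_fused: int


def extract_peaks(
    trace: VelocityTrace,
    maps: Sequence[BeatPhaseMap],
    quality_min: float = QUALITY_MIN,
) -> list[BeatPeaks]:
    """Per-beat peak magnitudes from a canonical-orientation trace.

    Sm is the largest |velocity| in the ejection interval, Em in rapid
    filling, Am in atrial contraction.  Fused beats report Sm only.
    Beats below the consensus-quality threshold are kept in the output
    but marked unusable.
    """
    v = np.abs(trace.samples)
    out: list[BeatPeaks] = []
    for m in maps:
        (ac0, ac1), _, (ej0, ej1), _, (rf0, rf1), _ = m.phase_bounds
        if ej1 <= ej0:
            log.warning(
                "beat %d of %s: empty ejection interval, skipped", m.beat_index, trace.exam_id
            )
            continue
        sm = float(v[ej0:ej1].max())
        am = em = None
        if not m.fused:
            if ac1 > ac0:
                am = float(v[ac0:ac1].max())
            if rf1 > rf0:
                em = float(v[rf0:rf1].max())
        out.append(
            BeatPeaks(
                beat_index=m.beat_index,
                sm=sm,
                am=am,
                em=em,
                fused=m.fused,
                usable=m.quality >= quality_min,
            )
        )
    return out


def summarize_segment(
    beat_peaks: Sequence[BeatPeaks],
    heart_rate: float,
    exam_id: str = "",
    wall: str = "LV",
) -> SegmentSummary:
    """Average peaks over all usable cardiac cycles.

    Am/Em means use non-fused usable beats only; the Em/Am ratio is the
    ratio of the means (robust when individual beats lack one peak).
    """
    usable = [p for p in beat_peaks if p.usable]
    if not usable:
        raise EmptySummaryError("zero usable beats")
    sm_mean = float(np.mean([p.sm for p in usable]))
    ams = [p.am for p in usable if p.am is not None]
    ems = [p.em for p in usable if p.em is not None]
    am_mean = float(np.mean(ams)) if ams else None
    em_mean = float(np.mean(ems)) if ems else None
    ratio = (
        em_mean / am_mean
        if (am_mean is not None and em_mean is not None and am_mean > 0)
        else None
    )
    return SegmentSummary(
        exam_id=exam_id,
        wall=wall,
        sm_mean=sm_mean,
        am_mean=am_mean,
        em_mean=em_mean,
        em_am_ratio=ratio,
        heart_rate=heart_rate,
        n_beats_total=len(beat_peaks),
        n_beats_used=len(usable),
        n_fused=sum(p.fused for p in beat_peaks),
    )


#: minimum ratio of a mean peak amplitude to the trace's noise floor for
#: the value to be reported rather than omitted as unmeasurable
SNR_MIN = 3.0


def estimate_noise_sd(trace: VelocityTrace) -> float:
    """Robust noise floor (cm/s) from first differences of the samples.

    For white noise the median absolute first difference equals
    ``sqrt(2) * 0.6745 * sd``; the smooth myocardial waveform contributes
    little to this statistic.
    """
    d = np.abs(np.diff(trace.samples))
    return float(np.median(d) / (math.sqrt(2) * 0.6745))


def omit_low_snr_peaks(
    summary: SegmentSummary, trace: VelocityTrace, snr_min: float = SNR_MIN
) -> SegmentSummary:
    """Omit diastolic peak values that are indistinguishable from noise.

    A mean Am or Em below ``snr_min`` times the trace's estimated noise
    floor cannot be measured reliably; the value (and the Em/Am ratio)
    is omitted, mirroring the quality-based omission of unreliable
    values in clinical trace review.
    """
    floor = snr_min * estimate_noise_sd(trace)
    am = summary.am_mean if (summary.am_mean or 0) >= floor else None
    em = summary.em_mean if (summary.em_mean or 0) >= floor else None
    if am is summary.am_mean and em is summary.em_mean:
        return summary
    log.info(
        "%s %s: diastolic peaks below %.2f cm/s noise floor omitted",
        summary.exam_id, summary.wall, floor,
    )
    ratio = em / am if (am is not None and em is not None and am > 0) else None
    return replace(summary, am_mean=am, em_mean=em, em_am_ratio=ratio)


def analyze_trace(
    trace: VelocityTrace,
    quality_min: float = QUALITY_MIN,
    snr_min: float = SNR_MIN,
) -> tuple[SegmentSummary, list[BeatPhaseMap]]:
    """Full single-trace pipeline: orientation, beats, phases, fusion, peaks."""
    canonical, _ = normalize_orientation(trace)
    bounds, heart_rate = detect_beats(canonical)
    maps = classify_phases(canonical, bounds, quality_min=quality_min)
    maps = detect_fusion(maps, canonical)
    peaks = extract_peaks(canonical, maps, quality_min=quality_min)
    summary = summarize_segment(
        peaks, heart_rate, exam_id=trace.exam_id, wall=trace.wall
    )
    return omit_low_snr_peaks(summary, canonical, snr_min=snr_min), maps
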