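"""Automated cardiac-cycle event detection on myocardial velocity traces.

The algorithm mirrors fully automated tissue-Doppler trace analysis:

1. orientation normalization to a canonical sign convention (ejection
   positive, diastolic waves negative) — fetal recordings are acquired
   in apical or basal four-chamber views, which flip the velocity sign;
2. beat identification from the dominant periodicity of the trace's
   autocovariance (80–220 bpm admissible band), each cycle anchored at
   the onset of atrial contraction, the zero crossing immediately
   preceding the pre-ejection upstroke;
3. six-phase classification (atrial contraction, pre-ejection, ejection,
   post-ejection, rapid filling, slow filling) using a cross-beat
   consensus template: beats are resampled to a common length, the
   sample-wise median fixes the template event times, and per-beat
   boundaries are the nearest matching zero crossings;
4. E/A fusion flagging: a diastolic interval whose two main negative
   extrema are not separated by a trough of sufficient prominence is
   fused, and Em/Am cannot be measured on it;
5. optional cross-segment refinement when several walls of the same exam
   share a time base (per-beat median cycle boundaries across walls).

No ECG is available in fetal tissue Doppler, so beats are anchored on
the ejection wave, the largest and most stereotyped deflection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .trace_io import VelocityTrace

log = logging.getLogger(__name__)

#: admissible fetal heart-rate band, beats/min
HR_BAND = (80.0, 220.0)

#: consensus-quality threshold below which a beat is excluded
QUALITY_MIN = 0.6

#: trough prominence (fraction of the smaller diastolic peak) separating E from A
FUSION_PROMINENCE = 0.10

_RESAMPLE_LEN = 400


class OrientationError(ValueError):
    """Orientation could not be resolved from the waveform."""


class NoBeatsError(ValueError):
    """No periodicity in the admissible heart-rate band."""


class InsufficientQualityError(ValueError):
    """Fewer than three beats of usable quality in the trace."""


@dataclass
class BeatPhaseMap:
    """Six-phase segmentation of one detected cardiac cycle.

    ``phase_bounds`` holds six half-open ``[start, end)`` sample-index
    intervals in fixed order (atrial contraction, pre-ejection, ejection,
    post-ejection, rapid filling, slow filling) that tile
    ``cycle_bounds`` exactly.  ``quality`` is the Pearson correlation of
    the beat against the consensus template.
    """

    beat_index: int
    cycle_bounds: tuple[int, int]
    phase_bounds: tuple[tuple[int, int], ...]
    fused: bool = False
    quality: float = 1.0

    @property
    def start(self) -> int:
        return self.cycle_bounds[0]

    @property
    def end(self) -> int:
        return self.cycle_bounds[1]


def _smooth(v: np.ndarray, win: int) -> np.ndarray:
    win = max(3, int(win) | 1)
    kernel = np.ones(win) / win
    return np.convolve(v, kernel, mode="same")


def _dominant_period(v: np.ndarray, fs: float) -> int:
    """Dominant cycle length (samples) from the autocovariance, in HR_BAND."""
    x = v - v.mean()
    if np.std(x) < 1e-9:
        raise NoBeatsError("trace is constant")
    n = x.size
    spec = np.abs(np.fft.rfft(x, 2 * n)) ** 2
    ac = np.fft.irfft(spec)[:n]
    lo = int(np.floor(fs * 60.0 / HR_BAND[1]))
    hi = int(np.ceil(fs * 60.0 / HR_BAND[0]))
    hi = min(hi, n - 1)
    if lo >= hi:
        raise NoBeatsError("trace too short for the admissible heart-rate band")
    lag = lo + int(np.argmax(ac[lo : hi + 1]))
    if ac[lag] <= 0.1 * ac[0]:
        raise NoBeatsError("no dominant periodicity in the 80-220 bpm band")
    return lag


# ---------------------------------------------------------------------------
# orientation


def normalize_orientation(trace: VelocityTrace) -> tuple[VelocityTrace, str]:
    """Return the trace in canonical sign convention plus its orientation.

    Canonical convention: the ejection wave is positive, the diastolic
    (E/A) waves negative.  Declared orientation metadata is honored;
    otherwise the orientation is inferred from which sign carries the
    widest suprathreshold wave (the ejection wave has the longest duty
    cycle).  The returned trace's ``orientation`` field records the
    resolved acquisition orientation.
    """
    if trace.duration < 2.0:
        raise OrientationError("need at least 2 s of data to normalize orientation")
    v = trace.samples
    if trace.orientation == "apical":
        return trace.copy_with(samples=v.copy()), "apical"
    if trace.orientation == "basal":
        return trace.copy_with(samples=-v), "basal"

    if np.max(np.abs(v)) < 1e-9:
        raise OrientationError("zero trace: orientation cannot be resolved")
    v_s = _smooth(v, round(0.015 * trace.frame_rate))

    def widest_run(x: np.ndarray) -> int:
        m = np.max(x)
        if m <= 0:
            return 0
        above = x > 0.35 * m
        best = cur = 0
        for flag in above:
            cur = cur + 1 if flag else 0
            best = max(best, cur)
        return best

    pos, neg = widest_run(v_s), widest_run(-v_s)
    if max(pos, neg) == 0 or abs(pos - neg) <= 0.15 * max(pos, neg):
        raise OrientationError("symmetric waveform energy: orientation unresolved")
    if pos > neg:
        return trace.copy_with(samples=v.copy(), orientation="apical"), "apical"
    return trace.copy_with(samples=-v, orientation="basal"), "basal"


# ---------------------------------------------------------------------------
# beat detection


def detect_beats(trace: VelocityTrace) -> tuple[list[tuple[int, int]], float]:
    """Identify all complete cardiac cycles in a canonical-orientation trace.

    The cycle length is first estimated globally from the autocovariance,
    then each cycle boundary is placed at the onset of the atrial
    contraction wave (the zero crossing preceding the pre-ejection
    upstroke).  Returns the list of half-open ``[start, end)`` bounds and
    the heart rate (60 / median cycle length).
    """
    v = trace.samples
    fs = trace.frame_rate
    lag = _dominant_period(v, fs)
    v_s = _smooth(v, round(0.015 * fs))

    hmax = float(np.percentile(v_s, 99.5))
    if hmax <= 0:
        raise NoBeatsError("no positive ejection waves found")
    peaks, _ = find_peaks(v_s, distance=max(2, int(0.6 * lag)), height=0.45 * hmax)
    if peaks.size < 2:
        raise NoBeatsError("fewer than two ejection waves detected")

    neg_max = float(np.percentile(-v_s, 99.5))
    theta_up = 0.1 * hmax
    theta_neg = 0.25 * max(neg_max, 1e-12)
    min_run = max(2, int(0.01 * fs))

    def _a_wave_onset(p: int) -> int | None:
        """Candidate atrial-contraction onset preceding ejection peak ``p``."""
        w0 = max(0, p - int(0.75 * lag))
        # last sub-threshold sample before the ejection upstroke
        below = np.nonzero(v_s[w0:p] <= theta_up)[0]
        i_up = w0 + int(below[-1]) if below.size else w0
        neg = v_s[w0 : i_up + 1] < -theta_neg
        # last contiguous negative run of sufficient duration (the A wave)
        first = None
        run = 0
        for j in range(neg.size - 1, -1, -1):
            if neg[j]:
                run += 1
                if run >= min_run:
                    first = j
            elif first is not None:
                break
            else:
                run = 0
        if first is None:
            return None
        i = w0 + first
        while i - 1 >= w0 and v_s[i - 1] < 0:
            i -= 1
        run_start = max(0, i - 1)
        # when E and A supports overlap without merging, the run holds two
        # minima; the A wave then starts at the trough between them
        seg = v_s[run_start : i_up + 1]
        minima, _ = find_peaks(
            -seg,
            prominence=0.15 * max(-seg.min(), 1e-12),
            distance=max(3, int(0.08 * lag)),
        )
        if minima.size >= 2:
            lo, hi = minima[-2], minima[-1]
            return run_start + lo + int(np.argmax(seg[lo : hi + 1]))
        return run_start

    def _upstroke_anchor(p: int) -> float | None:
        """Sub-sample half-height crossing on the ejection upstroke."""
        href = 0.5 * v_s[p]
        if href <= 0:
            return None
        i = p
        lo = max(1, p - int(0.5 * lag))
        while i - 1 >= lo and v_s[i - 1] >= href:
            i -= 1
        if i - 1 < lo or v_s[i] == v_s[i - 1]:
            return None
        return (i - 1) + (href - v_s[i - 1]) / (v_s[i] - v_s[i - 1])

    anchored = [(p, _upstroke_anchor(p)) for p in peaks]
    anchors = [a for _, a in anchored if a is not None]
    if len(anchors) < 2:
        raise NoBeatsError("could not anchor ejection upstrokes")
    offsets = [
        a - o
        for (p, a) in anchored
        if a is not None and (o := _a_wave_onset(p)) is not None
    ]
    if not offsets:
        raise NoBeatsError("no atrial-contraction waves found before ejections")
    delta = float(np.median(offsets))
    # shared upstroke-to-onset offset suppresses per-beat noise; snap each
    # boundary to the zero sample opening the A wave on the raw signal
    onsets = [
        _refine_boundary(v, max(0, int(round(a - delta))), "neg_start", radius=2)
        for a in anchors
    ]

    onsets = sorted(set(onsets))
    if len(onsets) < 2:
        raise NoBeatsError("could not place cycle boundaries")
    t_med = float(np.median(np.diff(onsets)))
    if onsets[-1] + t_med <= v.size:
        onsets.append(int(round(onsets[-1] + t_med)))

    bounds = [
        (onsets[k], onsets[k + 1])
        for k in range(len(onsets) - 1)
        if 0.5 * t_med <= onsets[k + 1] - onsets[k] <= 1.5 * t_med
    ]
    if not bounds:
        raise NoBeatsError("no complete cycles")
    # heart rate from the sub-sample upstroke anchors: far more accurate
    # than integer cycle bounds
    diffs = np.diff(anchors)
    med = np.median(diffs)
    good = diffs[np.abs(diffs - med) <= 0.25 * med]
    heart_rate = 60.0 * fs / float(good.mean())
    return bounds, heart_rate


# ---------------------------------------------------------------------------
# phase classification


def _walk_zero(x: np.ndarray, start: int, direction: int, eps: float) -> int:
    """From ``start`` inside a wave, walk to the zero sample bounding it."""
    i = start
    if direction < 0:
        while i - 1 >= 0 and x[i - 1] > eps:
            i -= 1
        return max(0, i - 1)
    while i + 1 < x.size and x[i + 1] > eps:
        i += 1
    return min(x.size - 1, i + 1)


def _template_boundaries(template: np.ndarray) -> np.ndarray:
    """Fractional positions of the five internal phase boundaries.

    Order: AC/PE, PE/EJ, EJ/POST, POST/RF, RF/SF (cycle start and end are
    the sixth pair).  Derived from the zero crossings flanking the
    dominant positive (ejection) wave, the first negative wave after it
    (rapid filling) and the negative wave opening the cycle (atrial
    contraction).
    """
    L = template.size
    tpl = _smooth(template, max(3, L // 80))
    pmax = float(tpl.max())
    if pmax <= 0:
        raise InsufficientQualityError("consensus template has no ejection wave")
    eps_p = 0.02 * pmax
    p_idx = int(np.argmax(tpl))
    ej_start = _walk_zero(tpl, p_idx, -1, eps_p)
    ej_end = _walk_zero(tpl, p_idx, +1, eps_p)

    neg = -tpl
    nmax = float(neg.max())
    eps_n = 0.02 * max(nmax, 1e-12)

    # A wave: first negative run of the cycle (before the ejection wave)
    a_body = np.nonzero(neg[:ej_start] > 0.1 * nmax)[0]
    if a_body.size:
        b1 = _walk_zero(neg, int(a_body[0]), +1, eps_n)
    else:
        b1 = max(1, ej_start // 2)

    # E wave: first negative run after the ejection wave
    e_body = np.nonzero(neg[ej_end:] > 0.1 * nmax)[0]
    if e_body.size:
        e0 = ej_end + int(e_body[0])
        rf_start = _walk_zero(neg, e0, -1, eps_n)
        rf_end = _walk_zero(neg, e0, +1, eps_n)
    else:
        rf_start = ej_end + (L - ej_end) // 3
        rf_end = ej_end + 2 * (L - ej_end) // 3

    b = np.array([b1, ej_start, ej_end, rf_start, rf_end], dtype=float)
    b = np.maximum.accumulate(np.clip(b, 1, L - 1))
    return b / (L - 1)


# wave-edge type of each internal boundary: the A wave ends at AC/PE, the
# ejection wave spans PE/EJ..EJ/POST, the E wave spans POST/RF..RF/SF
_CROSSINGS = ("neg_end", "pos_start", "pos_end", "neg_start", "neg_end")


def _refine_boundary(v: np.ndarray, idx: int, kind: str, radius: int = 3) -> int:
    """Nearest matching wave-edge zero crossing to a mapped template time.

    Operates on the raw samples; each kind is exact at a compact-support
    wave edge (the zero sample bounding the wave).
    """
    n = v.size
    for d in sorted(range(-radius, radius + 1), key=abs):
        i = idx + d
        if i < 1 or i >= n - 1:
            continue
        if kind == "neg_end" and v[i - 1] < 0 <= v[i]:
            return i
        if kind == "pos_start" and v[i] <= 0 < v[i + 1]:
            return i
        if kind == "pos_end" and v[i - 1] > 0 >= v[i]:
            return i
        if kind == "neg_start" and v[i] >= 0 > v[i + 1]:
            return i
    return idx


def _resample(v: np.ndarray, length: int) -> np.ndarray:
    n = v.size
    return np.interp(np.linspace(0.0, n - 1.0, length), np.arange(n), v)


def classify_phases(
    trace: VelocityTrace,
    cycle_bounds: Sequence[tuple[int, int]],
    quality_min: float = QUALITY_MIN,
) -> list[BeatPhaseMap]:
    """Classify each detected cycle into the six cardiac phases.

    A consensus template (sample-wise median of the length-normalized
    beats) fixes the event times; per-beat boundaries are the nearest
    matching zero crossings to the mapped template times.  Beats whose
    correlation against the template falls below ``quality_min`` are
    excluded from the consensus and marked; traces with fewer than three
    usable beats are rejected.
    """
    if len(cycle_bounds) < 2:
        raise InsufficientQualityError("need at least 2 detected beats")
    v = trace.samples
    mat = np.vstack([_resample(v[s:e], _RESAMPLE_LEN) for s, e in cycle_bounds])

    def qualities(tpl: np.ndarray) -> np.ndarray:
        t0 = tpl - tpl.mean()
        denom_t = np.sqrt((t0**2).sum())
        out = np.zeros(mat.shape[0])
        for k, row in enumerate(mat):
            r0 = row - row.mean()
            denom = np.sqrt((r0**2).sum()) * denom_t
            out[k] = (r0 @ t0) / denom if denom > 0 else 0.0
        return out

    template = np.median(mat, axis=0)
    q = qualities(template)
    usable = q >= quality_min
    if usable.sum() >= 3:
        template = np.median(mat[usable], axis=0)
        q = qualities(template)
        usable = q >= quality_min
    if usable.sum() < 3:
        raise InsufficientQualityError(
            "fewer than 3 beats of usable quality; trace rejected"
        )

    fracs = _template_boundaries(template)

    maps: list[BeatPhaseMap] = []
    for k, (s, e) in enumerate(cycle_bounds):
        n = e - s
        inner = []
        for frac, kind in zip(fracs, _CROSSINGS):
            idx = s + int(round(frac * (n - 1)))
            idx = _refine_boundary(v, idx, kind)
            inner.append(idx)
        inner = np.clip(np.maximum.accumulate(inner), s, e)
        cuts = [s, *inner.tolist(), e]
        phase_bounds = tuple((cuts[j], cuts[j + 1]) for j in range(6))
        maps.append(
            BeatPhaseMap(
                beat_index=k,
                cycle_bounds=(s, e),
                phase_bounds=phase_bounds,
                quality=float(q[k]),
            )
        )
    return maps


# ---------------------------------------------------------------------------
# fusion detection


def _two_separated_minima(seg: np.ndarray, prom_frac: float) -> bool:
    """True when the segment holds two negative extrema separated by a
    trough of prominence >= ``prom_frac`` of the smaller extremum."""
    x = -seg
    top = float(x.max())
    if top <= 0:
        return False
    peaks, _ = find_peaks(x, height=0.05 * top)
    if peaks.size < 2:
        return False
    order = np.argsort(x[peaks])[::-1]
    p1, p2 = sorted(peaks[order[:2]])
    trough = float(x[p1 : p2 + 1].min())
    smaller = min(x[p1], x[p2])
    return (smaller - trough) >= prom_frac * smaller


def detect_fusion(
    maps: Sequence[BeatPhaseMap],
    trace: VelocityTrace,
    prom_frac: float = FUSION_PROMINENCE,
) -> list[BeatPhaseMap]:
    """Flag beats whose E and A waves are fused.

    The diastolic interval runs from one beat's rapid-filling onset
    through the next beat's atrial contraction.  When it contains fewer
    than two negative extrema whose separating trough has prominence >=
    ``prom_frac`` of the smaller extremum, the E and A waves cannot be
    separated; both beats sharing the interval are flagged, and their
    Em/Am are omitted downstream.
    """
    v_s = _smooth(trace.samples, round(0.015 * trace.frame_rate))
    out = [replace(m) for m in maps]
    for k in range(len(maps) - 1):
        lo = maps[k].phase_bounds[4][0]
        hi = maps[k + 1].phase_bounds[0][1]
        if hi - lo < 3:
            fused = True
        else:
            fused = not _two_separated_minima(v_s[lo : hi + 1], prom_frac)
        if fused:
            out[k].fused = True
            out[k + 1].fused = True
    return out


# ---------------------------------------------------------------------------
# cross-segment refinement


def cross_segment_refine(
    traces_by_wall: dict[str, VelocityTrace],
    maps_by_wall: dict[str, list[BeatPhaseMap]],
    quality_min: float = QUALITY_MIN,
) -> dict[str, list[BeatPhaseMap]]:
    """Sharpen cycle boundaries using walls recorded on a shared time base.

    Per beat, cycle boundaries are replaced by the median boundary across
    the available walls and phases are re-derived per wall from the
    shared cycle bounds.  If the walls disagree on the number of beats
    the refinement is skipped with a warning.
    """
    walls = [w for w in maps_by_wall if maps_by_wall[w]]
    if len(walls) < 2:
        return dict(maps_by_wall)
    counts = {w: len(maps_by_wall[w]) for w in walls}
    if len(set(counts.values())) != 1:
        log.warning("inconsistent beat counts across walls %s; refinement skipped", counts)
        return dict(maps_by_wall)

    n_beats = counts[walls[0]]
    shared = []
    for k in range(n_beats):
        start = int(round(np.median([maps_by_wall[w][k].start for w in walls])))
        end = int(round(np.median([maps_by_wall[w][k].end for w in walls])))
        shared.append((start, end))

    refined: dict[str, list[BeatPhaseMap]] = {}
    for w in walls:
        maps = classify_phases(traces_by_wall[w], shared, quality_min=quality_min)
        refined[w] = detect_fusion(maps, traces_by_wall[w])
    for w in maps_by_wall:
        refined.setdefault(w, maps_by_wall[w])
    return refined
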