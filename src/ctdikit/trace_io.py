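"""Reading and writing of myocardial velocity traces and cohort metadata.

A velocity trace is the text export of one color tissue Doppler recording:
a uniformly sampled velocity time series (cm/s) for one wall segment
(LV free wall, interventricular septum, or RV free wall) with its region
of interest at the atrioventricular plane.  The on-disk dialect is a small
``# key: value`` header block followed by two tab-separated columns
(``time_s``, ``velocity_cm_s``).  Units are fixed: seconds and cm/s.

Cohort metadata is a plain CSV with one row per exam (fetus, transfusion
number, before/after flag, gestational age, hemoglobin, MCA PSV).
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np

log = logging.getLogger(__name__)

WALLS = ("LV", "IVS", "RV")
ORIENTATIONS = ("apical", "basal", "unknown")

#: maximum plausible myocardial velocity magnitude, cm/s
VELOCITY_LIMIT = 50.0

_HEADER_KEYS = ("exam_id", "wall", "orientation", "frame_rate")


class TraceFormatError(ValueError):
    """Raised for malformed or implausible trace files."""


class CohortFormatError(ValueError):
    """Raised for malformed cohort metadata."""


@dataclass
class VelocityTrace:
    """Uniformly sampled AV-plane velocity time series for one wall segment.

    Parameters
    ----------
    exam_id : str
        Identifier of the examination the recording belongs to.
    wall : {"LV", "IVS", "RV"}
        Wall segment the region of interest was placed on.
    orientation : {"apical", "basal", "unknown"}
        Insonation direction of the four-chamber view.  ``basal`` traces
        have inverted velocity signs relative to ``apical`` ones.
    frame_rate : float
        Sampling rate in frames per second.
    samples : numpy.ndarray
        Velocities in cm/s, sampled at ``1 / frame_rate`` intervals.
    t0 : float, optional
        Time of the first sample in seconds.
    ga_weeks : float or None, optional
        Gestational age at the exam, in weeks.
    """

    exam_id: str
    wall: str
    orientation: str
    frame_rate: float
    samples: np.ndarray
    t0: float = 0.0
    ga_weeks: float | None = None

    def __post_init__(self) -> None:
        if self.wall not in WALLS:
            raise TraceFormatError(f"wall must be one of {WALLS}, got {self.wall!r}")
        if self.orientation not in ORIENTATIONS:
            raise TraceFormatError(
                f"orientation must be one of {ORIENTATIONS}, got {self.orientation!r}"
            )
        if not (self.frame_rate > 0):
            raise TraceFormatError("frame_rate must be positive")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise TraceFormatError("samples must be one-dimensional")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Trace duration in seconds."""
        return self.n_samples / self.frame_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.n_samples) / self.frame_rate

    def copy_with(self, **changes) -> "VelocityTrace":
        return replace(self, **changes)


@dataclass
class ExamRecord:
    """One echocardiographic exam, before or after an intrauterine transfusion."""

    fetus_id: str
    iut_number: int
    timing: str  # "before" | "after"
    ga_weeks: float
    hb_g_per_L: float | None = None
    mca_psv_cm_per_s: float | None = None
    minutes_after_iut: float | None = None

    def __post_init__(self) -> None:
        if self.iut_number < 1:
            raise CohortFormatError("iut_number must be >= 1")
        if self.timing not in ("before", "after"):
            raise CohortFormatError("timing must be 'before' or 'after'")

    @property
    def exam_id(self) -> str:
        return f"{self.fetus_id}-IUT{self.iut_number}-{self.timing}"


def write_trace(trace: VelocityTrace, path: str | Path) -> Path:
    """Write a trace in the header + tab-separated dialect.

    Velocities are written with seven significant digits, which round-trips
    to well below measurement resolution.
    """
    if trace.n_samples == 0:
        raise TraceFormatError("refusing to write an empty trace")
    path = Path(path)
    lines = [
        f"# exam_id: {trace.exam_id}",
        f"# wall: {trace.wall}",
        f"# orientation: {trace.orientation}",
        f"# frame_rate: {trace.frame_rate!r}",
        f"# t0: {trace.t0!r}",
    ]
    if trace.ga_weeks is not None:
        lines.append(f"# ga_weeks: {trace.ga_weeks!r}")
    lines.append("time_s\tvelocity_cm_s")
    t = trace.times
    for ti, vi in zip(t, trace.samples):
        lines.append(f"{ti:.9g}\t{vi:.7g}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_trace(path: str | Path) -> VelocityTrace:
    """Read and validate a trace file.

    Raises
    ------
    TraceFormatError
        If required header keys are missing, the time column is not
        uniformly increasing at the declared frame rate, or velocities
        exceed the plausibility limit of +/-50 cm/s.
    """
    path = Path(path)
    header: dict[str, str] = {}
    times: list[float] = []
    vels: list[float] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    header[key.strip()] = val.strip()
                continue
            if line.startswith("time_s"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise TraceFormatError(f"{path}: expected 2 columns, got {len(parts)}")
            times.append(float(parts[0]))
            vels.append(float(parts[1]))

    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise TraceFormatError(f"{path}: missing header keys {missing}")
    frame_rate = float(header["frame_rate"])
    if frame_rate <= 0:
        raise TraceFormatError(f"{path}: frame_rate must be positive")
    if not times:
        raise TraceFormatError(f"{path}: no samples")

    t = np.asarray(times)
    v = np.asarray(vels)
    dt = np.diff(t)
    if t.size > 1:
        if np.any(dt <= 0):
            raise TraceFormatError(f"{path}: time column is not strictly increasing")
        if not np.allclose(dt, 1.0 / frame_rate, rtol=1e-4, atol=1e-6):
            raise TraceFormatError(
                f"{path}: samples are not uniformly spaced at 1/frame_rate"
            )
    if np.any(np.abs(v) > VELOCITY_LIMIT):
        raise TraceFormatError(
            f"{path}: velocities outside +/-{VELOCITY_LIMIT} cm/s are implausible"
        )

    ga = header.get("ga_weeks")
    return VelocityTrace(
        exam_id=header["exam_id"],
        wall=header["wall"],
        orientation=header["orientation"],
        frame_rate=frame_rate,
        samples=v,
        t0=float(header.get("t0", t[0])),
        ga_weeks=float(ga) if ga is not None else None,
    )


_COHORT_COLUMNS = [
    "fetus_id",
    "iut_number",
    "timing",
    "ga_weeks",
    "hb_g_per_L",
    "mca_psv_cm_per_s",
    "minutes_after_iut",
]


def write_cohort_metadata(records: Iterable[ExamRecord], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_COHORT_COLUMNS)
        writer.writeheader()
        for rec in records:
            writer.writerow(
                {
                    "fetus_id": rec.fetus_id,
                    "iut_number": rec.iut_number,
                    "timing": rec.timing,
                    "ga_weeks": rec.ga_weeks,
                    "hb_g_per_L": "" if rec.hb_g_per_L is None else rec.hb_g_per_L,
                    "mca_psv_cm_per_s": ""
                    if rec.mca_psv_cm_per_s is None
                    else rec.mca_psv_cm_per_s,
                    "minutes_after_iut": ""
                    if rec.minutes_after_iut is None
                    else rec.minutes_after_iut,
                }
            )
    return path


def _opt_float(s: str) -> float | None:
    s = s.strip()
    if not s or s.lower() == "nan":
        return None
    return float(s)


def read_cohort(
    metadata_path: str | Path, traces_dir: str | Path
) -> list[tuple[ExamRecord, dict[str, VelocityTrace]]]:
    """Read cohort metadata and join each exam with its per-wall traces.

    Trace files are looked up as ``<traces_dir>/<exam_id>_<wall>.tsv``.
    Missing walls are permitted and logged; duplicate exam ids are an
    error; trace files not referenced by any exam produce a warning.
    """
    metadata_path = Path(metadata_path)
    traces_dir = Path(traces_dir)
    records: list[ExamRecord] = []
    with open(metadata_path, newline="") as fh:
        for row in csv.DictReader(fh):
            records.append(
                ExamRecord(
                    fetus_id=row["fetus_id"],
                    iut_number=int(row["iut_number"]),
                    timing=row["timing"],
                    ga_weeks=float(row["ga_weeks"]),
                    hb_g_per_L=_opt_float(row.get("hb_g_per_L", "") or ""),
                    mca_psv_cm_per_s=_opt_float(row.get("mca_psv_cm_per_s", "") or ""),
                    minutes_after_iut=_opt_float(row.get("minutes_after_iut", "") or ""),
                )
            )

    seen: set[str] = set()
    for rec in records:
        if rec.exam_id in seen:
            raise CohortFormatError(f"duplicate exam id {rec.exam_id}")
        seen.add(rec.exam_id)

    out: list[tuple[ExamRecord, dict[str, VelocityTrace]]] = []
    used_files: set[Path] = set()
    for rec in records:
        traces: dict[str, VelocityTrace] = {}
        for wall in WALLS:
            f = traces_dir / f"{rec.exam_id}_{wall}.tsv"
            if f.exists():
                traces[wall] = read_trace(f)
                used_files.add(f)
            else:
                log.info("exam %s: no %s trace", rec.exam_id, wall)
        out.append((rec, traces))

    for f in sorted(traces_dir.glob("*.tsv")):
        if f not in used_files:
            log.warning("orphan trace file not referenced by metadata: %s", f)
    return out
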