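"""End-to-end pipeline: simulate -> detect -> metrics -> normalize -> stats.

Each stage writes plain-text artifacts (trace files, CSV tables, a JSON
manifest with checksums and a run log with per-trace beat/fusion/quality
accounting) so that every number in the final tables can be traced back
through the intermediate files by exam id.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import events, metrics, reference, simulate, stats, trace_io

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Run configuration; every analysis threshold is surfaced here."""

    out_dir: str = "ctdi_out"
    traces_dir: str | None = None
    metadata_path: str | None = None
    reference_path: str | None = None
    quality_min: float = events.QUALITY_MIN
    fusion_prominence: float = events.FUSION_PROMINENCE
    snr_min: float = metrics.SNR_MIN
    first_iut_only: bool = False
    cross_segment: bool = True
    outlier_z_threshold: float = 4.0
    seed: int = 0
    cohort: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def load_reference(self) -> reference.ReferenceModel:
        if self.reference_path:
            return reference.load_reference(self.reference_path)
        return reference.default_reference()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(out_dir: Path, files: list[Path]) -> Path:
    manifest = {
        str(f.relative_to(out_dir)): _sha256(f) for f in sorted(files)
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


# ---------------------------------------------------------------------------
# simulate


def cmd_simulate(config: PipelineConfig, force: bool = False) -> Path:
    """Write a complete synthetic cohort (traces, metadata, ground truth)."""
    out_dir = Path(config.out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FileExistsError(f"{out_dir} is not empty; use force to overwrite")
    traces_dir = out_dir / "traces"
    traces_dir.mkdir(parents=True, exist_ok=True)

    cohort_kwargs = dict(config.cohort)
    cohort_kwargs.setdefault("seed", config.seed)
    cfg = simulate.CohortSimConfig(**cohort_kwargs)
    ref = config.load_reference()
    sim = simulate.simulate_cohort(cfg, ref)

    written: list[Path] = []
    for exam_id, walls in sim.traces.items():
        for wall, trace in walls.items():
            written.append(
                trace_io.write_trace(trace, traces_dir / f"{exam_id}_{wall}.tsv")
            )
    meta = trace_io.write_cohort_metadata(sim.records, out_dir / "metadata.csv")
    written.append(meta)
    truth_path = out_dir / "ground_truth.csv"
    sim.truth.to_csv(truth_path, index=False)
    written.append(truth_path)
    _write_manifest(out_dir, written)
    log.info("simulated cohort: %d exams, %d trace files", len(sim.records), len(written) - 2)
    return out_dir


# ---------------------------------------------------------------------------
# analyze


def analyze_exam(
    traces: dict[str, trace_io.VelocityTrace],
    quality_min: float = events.QUALITY_MIN,
    fusion_prominence: float = events.FUSION_PROMINENCE,
    snr_min: float = metrics.SNR_MIN,
    cross_segment: bool = True,
) -> tuple[list[metrics.SegmentSummary], list[dict]]:
    """Analyze all walls of one exam, optionally with cross-segment refinement."""
    canonical: dict[str, trace_io.VelocityTrace] = {}
    maps_by_wall: dict[str, list[events.BeatPhaseMap]] = {}
    hr_by_wall: dict[str, float] = {}
    log_rows: list[dict] = []
    for wall, trace in traces.items():
        try:
            canon, _ = events.normalize_orientation(trace)
            bounds, hr = events.detect_beats(canon)
            maps = events.classify_phases(canon, bounds, quality_min=quality_min)
            maps = events.detect_fusion(maps, canon, prom_frac=fusion_prominence)
        except (events.OrientationError, events.NoBeatsError,
                events.InsufficientQualityError) as exc:
            log.warning("exam %s wall %s skipped: %s", trace.exam_id, wall, exc)
            log_rows.append(
                {"exam_id": trace.exam_id, "wall": wall, "status": f"skipped: {exc}"}
            )
            continue
        canonical[wall] = canon
        maps_by_wall[wall] = maps
        hr_by_wall[wall] = hr

    if cross_segment and len(maps_by_wall) >= 2:
        maps_by_wall = events.cross_segment_refine(
            canonical, maps_by_wall, quality_min=quality_min
        )

    summaries = []
    for wall, maps in maps_by_wall.items():
        peaks = metrics.extract_peaks(canonical[wall], maps, quality_min=quality_min)
        try:
            s = metrics.summarize_segment(
                peaks, hr_by_wall[wall],
                exam_id=canonical[wall].exam_id, wall=wall,
            )
        except metrics.EmptySummaryError as exc:
            log.warning("exam %s wall %s: %s", canonical[wall].exam_id, wall, exc)
            continue
        s = metrics.omit_low_snr_peaks(s, canonical[wall], snr_min=snr_min)
        summaries.append(s)
        log_rows.append(
            {
                "exam_id": s.exam_id,
                "wall": wall,
                "status": "ok",
                "n_beats": s.n_beats_total,
                "n_used": s.n_beats_used,
                "n_fused": s.n_fused,
                "heart_rate": round(s.heart_rate, 1),
                "min_quality": round(min(m.quality for m in maps), 3),
            }
        )
    return summaries, log_rows


def cmd_analyze(config: PipelineConfig) -> Path:
    """Run detection, metrics, normalization and statistics over a cohort."""
    out_dir = Path(config.out_dir)
    traces_dir = Path(config.traces_dir or out_dir / "traces")
    metadata = Path(config.metadata_path or out_dir / "metadata.csv")
    analysis_dir = out_dir / "analysis"
    analysis_dir.mkdir(parents=True, exist_ok=True)
    ref = config.load_reference()

    cohort = trace_io.read_cohort(metadata, traces_dir)
    if not cohort:
        raise ValueError("empty cohort")

    all_summaries: list[metrics.SegmentSummary] = []
    run_log: list[dict] = []
    records = []
    for rec, traces in cohort:
        records.append(rec)
        ok_traces = {}
        for wall, tr in traces.items():
            ok_traces[wall] = tr
        summaries, rows = analyze_exam(
            ok_traces,
            quality_min=config.quality_min,
            fusion_prominence=config.fusion_prominence,
            snr_min=config.snr_min,
            cross_segment=config.cross_segment,
        )
        all_summaries.extend(summaries)
        run_log.extend(rows)

    written: list[Path] = []
    summaries_df = pd.DataFrame([dataclasses.asdict(s) for s in all_summaries])
    p = analysis_dir / "segment_summaries.csv"
    summaries_df.to_csv(p, index=False)
    written.append(p)

    table = stats.build_cohort_table(all_summaries, records, ref)
    audited, flags = stats.outlier_audit(table, threshold=config.outlier_z_threshold)
    p = analysis_dir / "cohort.csv"
    audited.to_csv(p, index=False)
    written.append(p)
    p = analysis_dir / "outlier_flags.csv"
    flags.to_csv(p, index=False)
    written.append(p)

    for label, first_only in (("all_iut", False), ("first_iut", True)):
        if config.first_iut_only and not first_only:
            continue
        tables = stats.build_tables(audited, first_iut_only=first_only)
        for name, df in tables.items():
            p = analysis_dir / f"{name}_{label}.csv"
            df.to_csv(p, index=False)
            written.append(p)

    p = analysis_dir / "run_log.csv"
    pd.DataFrame(run_log).to_csv(p, index=False)
    written.append(p)
    _write_manifest(analysis_dir, written)
    return analysis_dir


# ---------------------------------------------------------------------------
# report


def cmd_report(config: PipelineConfig) -> Path:
    """Render human-readable tables and figures from analyze outputs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(config.out_dir)
    analysis_dir = out_dir / "analysis"
    report_dir = out_dir / "report"
    report_dir.mkdir(parents=True, exist_ok=True)
    ref = config.load_reference()

    cohort = pd.read_csv(analysis_dir / "cohort.csv")

    lines = ["# Cohort analysis report", ""]
    for label in ("all_iut", "first_iut"):
        for name in ("before_summary", "paired_changes", "correlations"):
            path = analysis_dir / f"{name}_{label}.csv"
            if not path.exists():
                continue
            df = pd.read_csv(path)
            lines += [f"## {name} ({label})", "", df.to_string(index=False), ""]
    (report_dir / "report.md").write_text("\n".join(lines))

    # velocity vs GA with reference centiles, per variable, LV wall
    before = cohort[(cohort["timing"] == "before") & (cohort["wall"] == "LV")]
    ga_grid = np.linspace(*ref.ga_support, 50)
    fig, axes = plt.subplots(2, 2, figsize=(9, 7))
    for ax, var in zip(axes.ravel(), ("Am", "Sm", "Em", "EmAm")):
        grp = before[before["variable"] == var]
        mean = reference._polyval(ref.curves[(var, "LV")][0], ga_grid)
        sd = reference._polyval(ref.curves[(var, "LV")][1], ga_grid)
        ax.plot(ga_grid, mean, "k--", lw=1)
        ax.plot(ga_grid, mean + 1.645 * sd, "k:", lw=0.8)
        ax.plot(ga_grid, mean - 1.645 * sd, "k:", lw=0.8)
        sev = grp["anemia_grade"] == "severe"
        ax.plot(grp.loc[~sev, "ga_weeks"], grp.loc[~sev, "value"], "o", ms=3)
        ax.plot(grp.loc[sev, "ga_weeks"], grp.loc[sev, "value"], "rs", ms=3)
        ax.set_xlabel("GA (weeks)")
        ax.set_ylabel(f"LV {var}" + (" (cm/s)" if var != "EmAm" else ""))
    fig.tight_layout()
    fig.savefig(report_dir / "velocities_vs_ga.png", dpi=120)
    plt.close(fig)

    # Hb MoM vs LV Em/Am z-score, first transfusions
    first = cohort[
        (cohort["timing"] == "before")
        & (cohort["iut_number"] == 1)
        & (cohort["wall"] == "LV")
        & (cohort["variable"] == "EmAm")
    ].dropna(subset=["hb_mom", "z"])
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(first["hb_mom"], first["z"], "o", ms=4)
    if len(first) >= 2:
        coef = np.polyfit(first["hb_mom"], first["z"], 1)
        xg = np.linspace(first["hb_mom"].min(), first["hb_mom"].max(), 10)
        ax.plot(xg, np.polyval(coef, xg), "r-", lw=1)
    ax.set_xlabel("Hb MoM")
    ax.set_ylabel("LV Em/Am z-score")
    fig.tight_layout()
    fig.savefig(report_dir / "hb_mom_vs_emam_z.png", dpi=120)
    plt.close(fig)

    return report_dir
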