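"""Cohort-level inference for the pre/post-transfusion analysis.

Builds the exam-level cohort table (absolute metrics, gestational-age
z-scores, Hb and MCA PSV multiples of the median, anemia grade) and
reproduces the study-style inferential stage: mean z-scores with 95%
confidence intervals before transfusion, Spearman correlations of
z-scores with Hb MoM and MCA PSV MoM, and paired Wilcoxon signed-rank
comparisons of before versus after.

No multiple-testing correction is applied (significance at p < 0.05,
with the paired-change tables marked at p < 0.01); repeated transfusions
of the same fetus are treated as independent in the all-transfusions
analyses, with a first-transfusion-only switch as mitigation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .metrics import SegmentSummary
from .reference import ReferenceModel, classify_anemia, compute_mom, compute_zscore
from .trace_io import ExamRecord

VARIABLE_VALUES = {"Am": "am_mean", "Sm": "sm_mean", "Em": "em_mean", "EmAm": "em_am_ratio"}


class InsufficientDataError(ValueError):
    pass


class DegenerateDataError(ValueError):
    pass


@dataclass
class StatResult:
    """One estimate with its uncertainty interval.

    ``interval`` is a 95% confidence interval for means and correlations
    and the interquartile range for medians of paired differences.
    """

    estimate: float
    interval: tuple[float, float]
    n: int
    p_value: float | None = None
    significant: bool | None = None
    kind: str = ""


# ---------------------------------------------------------------------------
# elementary inference


def mean_z_with_ci(values: Sequence[float], alpha: float = 0.05) -> StatResult:
    """Mean z-score with a t-based confidence interval.

    The estimate is flagged significant when the interval excludes zero
    (the reference population mean).
    """
    x = np.asarray([v for v in values if v is not None and np.isfinite(v)], dtype=float)
    if x.size < 3:
        raise InsufficientDataError("need at least 3 values for a mean and CI")
    mean = float(x.mean())
    sem = float(x.std(ddof=1) / np.sqrt(x.size))
    if sem == 0.0:
        lo = hi = mean
    else:
        tcrit = float(sps.t.ppf(1 - alpha / 2, x.size - 1))
        lo, hi = mean - tcrit * sem, mean + tcrit * sem
    return StatResult(
        estimate=mean,
        interval=(lo, hi),
        n=int(x.size),
        significant=bool(lo > 0 or hi < 0),
        kind="mean_z",
    )


def spearman_corr(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Spearman rank correlation with a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 4:
        raise InsufficientDataError("need at least 4 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateDataError("constant input: correlation undefined")
    rho, p = sps.spearmanr(x, y)
    # Fisher-transform CI (approximate for ranks)
    z = np.arctanh(np.clip(rho, -0.999999, 0.999999))
    se = 1.06 / np.sqrt(x.size - 3) if x.size > 3 else np.inf
    lo, hi = np.tanh(z - 1.959964 * se), np.tanh(z + 1.959964 * se)
    return StatResult(
        estimate=float(rho),
        interval=(float(lo), float(hi)),
        n=int(x.size),
        p_value=float(p),
        significant=bool(p < 0.05),
        kind="spearman",
    )


def paired_wilcoxon(before: Sequence[float], after: Sequence[float]) -> StatResult:
    """Wilcoxon signed-rank test on paired differences (after - before).

    Uses the exact null distribution for n <= 25 without ties, otherwise
    the normal approximation with continuity correction.  Reports the
    median difference with its interquartile range.
    """
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.shape != a.shape:
        raise InsufficientDataError("before/after must be paired")
    keep = np.isfinite(b) & np.isfinite(a)
    d = a[keep] - b[keep]
    nz = d[d != 0]
    if nz.size == 0:
        raise DegenerateDataError("all paired differences are zero")
    if nz.size < 5:
        raise InsufficientDataError("need at least 5 non-zero differences")
    exact = nz.size <= 25 and np.unique(np.abs(nz)).size == nz.size
    res = sps.wilcoxon(
        nz, method="exact" if exact else "approx", correction=not exact
    )
    q25, q75 = np.percentile(d, [25, 75])
    return StatResult(
        estimate=float(np.median(d)),
        interval=(float(q25), float(q75)),
        n=int(d.size),
        p_value=float(res.pvalue),
        significant=bool(res.pvalue < 0.05),
        kind="wilcoxon",
    )


# ---------------------------------------------------------------------------
# cohort table


def build_cohort_table(
    summaries: Sequence[SegmentSummary],
    records: Sequence[ExamRecord],
    ref: ReferenceModel,
) -> pd.DataFrame:
    """Join segment summaries with exam metadata into the long cohort table.

    One row per exam x wall x variable with the absolute value, its
    gestational-age z-score, Hb and MCA PSV MoM and the anemia grade.
    """
    recs = {r.exam_id: r for r in records}
    rows = []
    for s in summaries:
        rec = recs.get(s.exam_id)
        if rec is None:
            continue
        ga = rec.ga_weeks
        hb_mom = (
            float(compute_mom(rec.hb_g_per_L, ga, ref, "hb"))
            if rec.hb_g_per_L is not None
            else np.nan
        )
        mca_mom = (
            float(compute_mom(rec.mca_psv_cm_per_s, ga, ref, "mca_psv"))
            if rec.mca_psv_cm_per_s is not None
            else np.nan
        )
        grade = classify_anemia(hb_mom) if np.isfinite(hb_mom) else None
        for var, attr in VARIABLE_VALUES.items():
            value = getattr(s, attr)
            z = (
                float(compute_zscore(value, ga, var, s.wall, ref))
                if value is not None
                else np.nan
            )
            rows.append(
                {
                    "fetus_id": rec.fetus_id,
                    "iut_number": rec.iut_number,
                    "timing": rec.timing,
                    "exam_id": s.exam_id,
                    "wall": s.wall,
                    "variable": var,
                    "value": np.nan if value is None else float(value),
                    "z": z,
                    "ga_weeks": ga,
                    "hb_mom": hb_mom,
                    "mca_psv_mom": mca_mom,
                    "anemia_grade": grade,
                    "heart_rate": s.heart_rate,
                    "n_beats_used": s.n_beats_used,
                    "n_fused": s.n_fused,
                }
            )
    df = pd.DataFrame(rows)
    if not df.empty:
        dup = df.duplicated(["fetus_id", "iut_number", "timing", "wall", "variable"])
        if dup.any():
            raise InsufficientDataError("duplicate exam x wall x variable rows")
    return df


# ---------------------------------------------------------------------------
# audit and summary tables


def outlier_audit(
    cohort: pd.DataFrame,
    threshold: float = 4.0,
    drop: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag extreme z-scores for inspection, mirroring manual trace review.

    Returns ``(audited_cohort, flags)``; with ``drop=True`` the flagged
    rows are removed from the returned cohort (otherwise only reported).
    """
    z_abs = cohort["z"].abs()
    flags = cohort.loc[z_abs > threshold].copy()
    out = cohort.drop(index=flags.index) if drop else cohort
    return out, flags


def _before(cohort: pd.DataFrame, first_iut_only: bool) -> pd.DataFrame:
    sel = cohort["timing"] == "before"
    if first_iut_only:
        sel &= cohort["iut_number"] == 1
    return cohort.loc[sel]


def build_tables(
    cohort: pd.DataFrame, first_iut_only: bool = False
) -> dict[str, pd.DataFrame]:
    """Study-style summary tables from the normalized cohort.

    Returns ``before_summary`` (absolute mean +/- SD and mean z with 95%
    CI per wall and variable, before transfusion), ``paired_changes``
    (median and IQR of before/after differences with Wilcoxon p, marked
    at p < 0.01) and ``correlations`` (Spearman rho of z against Hb MoM
    and MCA PSV MoM before transfusion).
    """
    walls = sorted(cohort["wall"].unique())
    variables = [v for v in VARIABLE_VALUES if v in set(cohort["variable"])]
    before = _before(cohort, first_iut_only)

    rows = []
    for wall in walls:
        for var in variables:
            grp = before[(before["wall"] == wall) & (before["variable"] == var)]
            vals = grp["value"].dropna()
            zs = grp["z"].dropna()
            row = {"wall": wall, "variable": var, "n": int(len(grp))}
            row["abs_mean"] = float(vals.mean()) if len(vals) else np.nan
            row["abs_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else np.nan
            try:
                r = mean_z_with_ci(zs.tolist())
                row.update(
                    z_mean=r.estimate,
                    z_ci_low=r.interval[0],
                    z_ci_high=r.interval[1],
                    significant=r.significant,
                )
            except InsufficientDataError:
                row.update(z_mean=np.nan, z_ci_low=np.nan, z_ci_high=np.nan, significant=None)
            rows.append(row)
    before_summary = pd.DataFrame(rows)

    rows = []
    key = ["fetus_id", "iut_number", "wall", "variable"]
    pivot = cohort.pivot_table(
        index=key, columns="timing", values=["value", "z"], aggfunc="first"
    )
    for wall in walls:
        for var in variables:
            try:
                sub = pivot.xs((wall, var), level=("wall", "variable"))
            except KeyError:
                continue
            if first_iut_only:
                sub = sub[sub.index.get_level_values("iut_number") == 1]
            row = {"wall": wall, "variable": var}
            for field, label in (("value", "abs"), ("z", "z")):
                try:
                    b = sub[(field, "before")].to_numpy()
                    a = sub[(field, "after")].to_numpy()
                    r = paired_wilcoxon(b, a)
                    row.update(
                        {
                            f"{label}_median_delta": r.estimate,
                            f"{label}_iq_low": r.interval[0],
                            f"{label}_iq_high": r.interval[1],
                            f"{label}_p": r.p_value,
                            f"{label}_n": r.n,
                        }
                    )
                except (KeyError, InsufficientDataError, DegenerateDataError):
                    row.update(
                        {
                            f"{label}_median_delta": np.nan,
                            f"{label}_iq_low": np.nan,
                            f"{label}_iq_high": np.nan,
                            f"{label}_p": np.nan,
                            f"{label}_n": 0,
                        }
                    )
            p = row.get("z_p", np.nan)
            row["significant"] = bool(p < 0.01) if np.isfinite(p) else None
            rows.append(row)
    paired_changes = pd.DataFrame(rows)

    rows = []
    for wall in walls:
        for var in variables:
            grp = before[(before["wall"] == wall) & (before["variable"] == var)]
            row = {"wall": wall, "variable": var}
            for col, label in (("hb_mom", "hb"), ("mca_psv_mom", "mca_psv")):
                try:
                    r = spearman_corr(grp[col].to_numpy(), grp["z"].to_numpy())
                    row.update(
                        {
                            f"rho_{label}": r.estimate,
                            f"p_{label}": r.p_value,
                            f"n_{label}": r.n,
                        }
                    )
                except (InsufficientDataError, DegenerateDataError):
                    row.update({f"rho_{label}": np.nan, f"p_{label}": np.nan, f"n_{label}": 0})
            rows.append(row)
    correlations = pd.DataFrame(rows)

    return {
        "before_summary": before_summary,
        "paired_changes": paired_changes,
        "correlations": correlations,
    }
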