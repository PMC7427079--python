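"""Gestational-age normalization: z-scores, multiples of the median, anemia grades.

Myocardial velocities grow with gestational age, so absolute values are
converted to z-scores against gestational-age-specific reference curves,

    z = (measurement - predicted_mean(GA)) / predicted_SD(GA),

and hemoglobin / middle-cerebral-artery peak systolic velocity are
expressed as multiples of the gestational-age median (MoM).  Anemia
severity is graded from the Hb MoM:  severe < 0.55 <= moderate < 0.65
<= mild < 0.84 <= none (intervals half-open upward; the boundary
convention is configurable because published interval endpoints overlap).

Reference curves are low-degree polynomials in GA, loaded from YAML.
The packaged default (``data/synthetic_reference.yaml``) is a synthetic
stand-in with plausible magnitudes; it is NOT a published clinical
reference and must be replaced with real reference coefficients for any
clinical use.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .trace_io import WALLS

VARIABLES = ("Am", "Sm", "Em", "EmAm")

ANEMIA_GRADES = ("none", "mild", "moderate", "severe")

#: default (severe, moderate, mild) upper Hb MoM bounds
DEFAULT_ANEMIA_BOUNDS = (0.55, 0.65, 0.84)


class ReferenceError(ValueError):
    """Raised for invalid reference models or out-of-support queries."""


def _polyval(coeffs, x):
    """Evaluate a polynomial with ascending coefficients."""
    return np.polynomial.polynomial.polyval(x, np.asarray(coeffs, dtype=float))


@dataclass
class ReferenceModel:
    """Gestational-age reference curves for velocities, Hb and MCA PSV.

    Parameters
    ----------
    curves : dict
        ``(variable, wall) -> (mean_coeffs, sd_coeffs)`` with polynomial
        coefficients in ascending order over GA in weeks.  Variables are
        ``Am``, ``Sm``, ``Em`` (cm/s) and ``EmAm`` (dimensionless ratio).
    hb_median : sequence
        Coefficients of the GA -> median hemoglobin curve (g/L).
    mca_psv_median : sequence
        Coefficients of the GA -> median MCA PSV curve (cm/s).
    ga_support : tuple of float
        Closed GA interval (weeks) on which all curves are valid.
    """

    curves: dict[tuple[str, str], tuple[tuple[float, ...], tuple[float, ...]]]
    hb_median: tuple[float, ...]
    mca_psv_median: tuple[float, ...]
    ga_support: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.ga_support
        if not lo < hi:
            raise ReferenceError("ga_support must be a nonempty interval")
        grid = np.linspace(lo, hi, 101)
        for (var, wall), (mc, sc) in self.curves.items():
            if var not in VARIABLES or wall not in WALLS:
                raise ReferenceError(f"unknown curve key {(var, wall)}")
            if np.any(_polyval(sc, grid) <= 0):
                raise ReferenceError(f"sd curve for {(var, wall)} must be > 0 on support")
        for name, coeffs in (("hb_median", self.hb_median), ("mca_psv_median", self.mca_psv_median)):
            if np.any(_polyval(coeffs, grid) <= 0):
                raise ReferenceError(f"{name} curve must be > 0 on support")

    # -- curve evaluation -------------------------------------------------
    def _check_ga(self, ga) -> None:
        ga = np.asarray(ga, dtype=float)
        lo, hi = self.ga_support
        if np.any((ga < lo) | (ga > hi)):
            raise ReferenceError(
                f"gestational age outside reference support [{lo}, {hi}] weeks"
            )

    def mean(self, variable: str, wall: str, ga):
        self._check_ga(ga)
        return _polyval(self.curves[(variable, wall)][0], ga)

    def sd(self, variable: str, wall: str, ga):
        self._check_ga(ga)
        return _polyval(self.curves[(variable, wall)][1], ga)

    def hb_median_at(self, ga):
        self._check_ga(ga)
        return _polyval(self.hb_median, ga)

    def mca_psv_median_at(self, ga):
        self._check_ga(ga)
        return _polyval(self.mca_psv_median, ga)


# ---------------------------------------------------------------------------
# normalization operations


def compute_zscore(value, ga, variable: str, wall: str, ref: ReferenceModel):
    """z = (value - predicted mean at GA) / predicted SD at GA."""
    return (np.asarray(value, dtype=float) - ref.mean(variable, wall, ga)) / ref.sd(
        variable, wall, ga
    )


def inverse_zscore(z, ga, variable: str, wall: str, ref: ReferenceModel):
    """Absolute value whose z-score at ``ga`` equals ``z`` (used by the simulator)."""
    return ref.mean(variable, wall, ga) + np.asarray(z, dtype=float) * ref.sd(
        variable, wall, ga
    )


def delta_zscore(z_after, z_before):
    """Change in z-score across a transfusion: after minus before."""
    return np.asarray(z_after, dtype=float) - np.asarray(z_before, dtype=float)


def compute_mom(value, ga, ref: ReferenceModel, which: str = "hb"):
    """Multiple of the gestational-age median for Hb (g/L) or MCA PSV (cm/s)."""
    if which == "hb":
        med = ref.hb_median_at(ga)
    elif which == "mca_psv":
        med = ref.mca_psv_median_at(ga)
    else:
        raise ValueError("which must be 'hb' or 'mca_psv'")
    med = np.asarray(med, dtype=float)
    if np.any(med <= 0):
        raise ReferenceError("median curve is nonpositive at requested GA")
    return np.asarray(value, dtype=float) / med


def classify_anemia(hb_mom: float, bounds: tuple[float, float, float] = DEFAULT_ANEMIA_BOUNDS) -> str:
    """Grade fetal anemia from the Hb multiple of the median.

    severe < bounds[0] <= moderate < bounds[1] <= mild < bounds[2] <= none.
    """
    severe, moderate, mild = bounds
    if not severe < moderate < mild:
        raise ValueError("anemia bounds must increase")
    if hb_mom < 0:
        raise ValueError("Hb MoM cannot be negative")
    if hb_mom < severe:
        return "severe"
    if hb_mom < moderate:
        return "moderate"
    if hb_mom < mild:
        return "mild"
    return "none"


# ---------------------------------------------------------------------------
# YAML serialization


def load_reference(path: str | Path) -> ReferenceModel:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return _reference_from_dict(doc)


def save_reference(ref: ReferenceModel, path: str | Path) -> Path:
    doc = {
        "ga_support": list(ref.ga_support),
        "hb_median": list(ref.hb_median),
        "mca_psv_median": list(ref.mca_psv_median),
        "variables": {
            var: {
                wall: {
                    "mean": list(ref.curves[(var, wall)][0]),
                    "sd": list(ref.curves[(var, wall)][1]),
                }
                for wall in WALLS
                if (var, wall) in ref.curves
            }
            for var in VARIABLES
        },
    }
    path = Path(path)
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def _reference_from_dict(doc: dict) -> ReferenceModel:
    try:
        curves = {}
        for var, walls in doc["variables"].items():
            for wall, spec in walls.items():
                curves[(var, wall)] = (tuple(spec["mean"]), tuple(spec["sd"]))
        return ReferenceModel(
            curves=curves,
            hb_median=tuple(doc["hb_median"]),
            mca_psv_median=tuple(doc["mca_psv_median"]),
            ga_support=tuple(doc["ga_support"]),
        )
    except KeyError as exc:
        raise ReferenceError(f"reference YAML missing key: {exc}") from exc


def default_reference() -> ReferenceModel:
    """The packaged synthetic reference model (NOT a clinical reference)."""
    resource = importlib.resources.files("ctdikit.data") / "synthetic_reference.yaml"
    return _reference_from_dict(yaml.safe_load(resource.read_text()))
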