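"""External-standard quantification and analytical method validation.

Quantification follows the conventional external-standard route: an
unweighted ordinary-least-squares calibration line (area vs ng/mL, seven
points spanning 0.05–100 ng/mL, accepted when R² > 0.99), back-calculation
of the solution concentration at the sample's quantifier peak area, and
conversion to a tissue concentration in ng/g dry weight through the
extract volume and dry mass.

Method-performance statistics mirror standard validation practice:
spiked-replicate recoveries (sample SD, n−1), matrix effect as the
matrix-spike/solvent-standard area ratio, the instrument detection limit
(IDL) as the smallest on-column mass giving five detected replicates with
RSD ≤ 20%, and the method detection limit (MDL) from n ≥ 7 replicate
spiked analyses as t(0.99, n−1) × SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .screening import DetectionResult

__all__ = [
    "CalibrationCurve",
    "QuantResult",
    "ValidationStats",
    "CohortSummary",
    "fit_calibration",
    "quantify",
    "recovery",
    "recovery_stats",
    "matrix_effect",
    "estimate_idl",
    "estimate_mdl",
    "summarize_cohort",
]


@dataclass(frozen=True)
class CalibrationCurve:
    compound: str
    slope: float  # counts per (ng/mL)
    intercept: float  # counts
    r_squared: float
    conc_range: tuple[float, float]  # ng/mL
    n_points: int
    accepted: bool  # R^2 > 0.99

    def solution_conc(self, area: float) -> float:
        """Back-calculated solution concentration, ng/mL."""
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive to quantify")
        return (area - self.intercept) / self.slope


@dataclass
class QuantResult:
    compound: str
    conc_ng_g: float  # ng/g dry weight
    conc_solution_ng_ml: float
    flags: list[str] = field(default_factory=list)


@dataclass
class ValidationStats:
    compound: str
    recovery_mean: float | None = None  # %
    recovery_sd: float | None = None  # %
    matrix_effect: dict[float, float] = field(default_factory=dict)  # level -> ratio
    idl_pg: float | None = None
    mdl_ng_g: float | None = None


@dataclass
class CohortSummary:
    overall: pd.DataFrame  # one row per compound
    by_group: pd.DataFrame  # compound x species x year


def fit_calibration(points: list[tuple[float, float]], compound: str = "",
                    min_points: int = 5, weighted: bool = False) -> CalibrationCurve:
    """Unweighted OLS fit Y = a + b·X of area against concentration.

    ``weighted=True`` switches to 1/x weighting (useful when low-end
    accuracy matters more than the top of the range); the default matches
    plain linear calibration. Curves with R² ≤ 0.99 are returned with
    ``accepted=False``.
    """
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if np.unique(x).size < min_points:
        raise ValueError(f"calibration needs >= {min_points} distinct concentrations")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in concentrations")
    if np.ptp(y) == 0:
        raise ValueError("degenerate calibration: all areas equal")
    if weighted:
        w = 1.0 / np.where(x > 0, x, x[x > 0].min())
        b, a = np.polyfit(x, y, 1, w=np.sqrt(w))
        yhat = a + b * x
        ss_res = np.sum(w * (y - yhat) ** 2)
        ss_tot = np.sum(w * (y - np.average(y, weights=w)) ** 2)
        r2 = 1.0 - ss_res / ss_tot
    else:
        fit = stats.linregress(x, y)
        a, b, r2 = fit.intercept, fit.slope, fit.rvalue ** 2
    return CalibrationCurve(compound=compound, slope=float(b), intercept=float(a),
                            r_squared=float(r2),
                            conc_range=(float(x.min()), float(x.max())),
                            n_points=int(x.size), accepted=bool(r2 > 0.99))


def quantify(result: DetectionResult, curve: CalibrationCurve,
             extract_volume_ml: float, dry_mass_g: float) -> QuantResult:
    """Convert a detection's quantifier area to ng/g dry weight.

    Solution concentration is ``(area − intercept) / slope``; tissue
    concentration scales by ``extract_volume_ml / dry_mass_g``. Areas
    outside the calibration range are flagged as extrapolated; negative
    back-calculations are floored at zero with a flag.
    """
    if not result.detected:
        raise ValueError(f"{result.compound}: cannot quantify a non-detection")
    if dry_mass_g <= 0 or extract_volume_ml <= 0:
        raise ValueError("dry mass and extract volume must be positive")
    flags = []
    sol = curve.solution_conc(result.quantifier_area)
    if not curve.conc_range[0] <= sol <= curve.conc_range[1]:
        flags.append("outside calibration range")
    if sol < 0:
        sol = 0.0
        flags.append("negative back-calculation floored at 0")
    conc = sol * extract_volume_ml / dry_mass_g
    return QuantResult(compound=result.compound, conc_ng_g=conc,
                       conc_solution_ng_ml=sol, flags=flags)


def recovery(measured_ng: float, spiked_ng: float) -> float:
    """Single-replicate recovery in percent."""
    if spiked_ng <= 0:
        raise ValueError("spiked amount must be positive")
    return 100.0 * measured_ng / spiked_ng


def recovery_stats(measured_ng: list[float], spiked_ng: float) -> tuple[float, float]:
    """Mean and sample SD (n−1) of replicate recoveries, in percent."""
    rec = np.array([recovery(m, spiked_ng) for m in measured_ng])
    sd = float(rec.std(ddof=1)) if rec.size > 1 else 0.0
    return float(rec.mean()), sd


def matrix_effect(area_matrix_spike: float, area_solvent_standard: float) -> float:
    """Post-extraction matrix-spike area over solvent-standard area at the
    same concentration; 1.0 means no suppression or enhancement."""
    if area_solvent_standard <= 0:
        raise ValueError("solvent standard area must be positive")
    return area_matrix_spike / area_solvent_standard


def estimate_idl(replicate_series: dict[float, list[float | None]],
                 max_rsd: float = 0.20) -> float | None:
    """Instrument detection limit from replicate injections.

    *replicate_series* maps injected mass (pg) to five replicate peak
    areas, with ``None`` marking replicates where no peak passed the
    S/N ≥ 3 gate. The IDL is the smallest mass whose replicates are all
    detected with relative SD ≤ *max_rsd*. Returns ``None`` when no level
    qualifies (IDL above the highest tested mass).
    """
    if len(replicate_series) < 2:
        raise ValueError("at least two mass levels are required")
    for mass in sorted(replicate_series):
        areas = replicate_series[mass]
        if len(areas) < 5:
            raise ValueError(f"level {mass} pg has fewer than 5 replicates")
        if any(a is None for a in areas):
            continue
        arr = np.asarray(areas, dtype=float)
        if arr.mean() > 0 and arr.std(ddof=1) / arr.mean() <= max_rsd:
            return float(mass)
    return None


def estimate_mdl(replicate_concs: list[float], confidence: float = 0.99) -> float:
    """Method detection limit from n ≥ 7 replicate spiked analyses:
    one-sided Student t(confidence, n−1) × sample SD. At the conventional
    99% level with n = 10, the multiplier is t(0.99, 9) = 2.821."""
    concs = np.asarray(replicate_concs, dtype=float)
    if concs.size < 7:
        raise ValueError("MDL estimation requires at least 7 replicates")
    t = stats.t.ppf(confidence, concs.size - 1)
    return float(t * concs.std(ddof=1))


def summarize_cohort(results: pd.DataFrame, mdl: dict[str, float]) -> CohortSummary:
    """Per-compound detection frequencies and concentration statistics.

    *results* needs columns ``compound, sample_id, species, year, detected,
    conc_ng_g``. A sample counts as a detection only when the screening
    criteria passed and the concentration is at or above the compound's
    MDL. Ranges, means and medians are computed over detected samples only
    — non-detects are excluded, not substituted.
    """
    required = {"compound", "sample_id", "species", "year", "detected", "conc_ng_g"}
    if results.empty:
        raise ValueError("no results to summarize")
    if not required.issubset(results.columns):
        raise ValueError(f"results must have columns {sorted(required)}")
    df = results.copy()
    df["mdl"] = df["compound"].map(mdl)
    if df["mdl"].isna().any():
        missing = sorted(df.loc[df["mdl"].isna(), "compound"].unique())
        raise ValueError(f"no MDL provided for: {', '.join(missing)}")
    df["is_detect"] = df["detected"] & (df["conc_ng_g"] >= df["mdl"])

    def _stats(g: pd.DataFrame) -> pd.Series:
        det = g.loc[g["is_detect"], "conc_ng_g"]
        n = g["sample_id"].nunique()
        return pd.Series({
            "n_samples": n,
            "n_detected": int(g["is_detect"].sum()),
            "detection_frequency_pct": 100.0 * g["is_detect"].sum() / n,
            "conc_min": det.min() if len(det) else np.nan,
            "conc_median": det.median() if len(det) else np.nan,
            "conc_mean": det.mean() if len(det) else np.nan,
            "conc_max": det.max() if len(det) else np.nan,
        })

    overall = df.groupby("compound", sort=True).apply(_stats, include_groups=False)
    by_group = df.groupby(["compound", "species", "year"], sort=True).apply(
        _stats, include_groups=False)
    return CohortSummary(overall=overall.reset_index(),
                         by_group=by_group.reset_index())
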