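"""Bioanalytical validation statistics for LC-MS/MS quantification.

Covers the standard validation battery for a plasma assay: linear
calibration with t-based confidence intervals and a replicate lack-of-fit
test, residual-sd based detection and quantification limits (LOD k=3,
LOQ k=10), on-column mass conversion, intra-/inter-day precision and
accuracy from QC replicates, and the three-set (R1/R2/R3) extraction
recovery and matrix-effect comparison with the 85%/115%
suppression/enhancement classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationModel",
    "CalibrationResults",
    "DetectionLimits",
    "detection_limits",
    "on_column_mass",
    "QCBatch",
    "PrecisionAccuracyResult",
    "precision_accuracy",
    "MatrixEffectLevel",
    "MatrixEffectSummary",
    "recovery_matrix_effect",
    "round_half_away",
]


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (report-table convention)."""
    factor = 10.0**ndigits
    return float(np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor)


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

class CalibrationModel:
    """Linear calibration of detector response on concentration.

    Unweighted OLS of peak area on concentration (ng/mL); optional 1/x or
    1/x^2 weights for heteroscedastic data.  Replicate areas at a level
    enable the ANOVA lack-of-fit test.
    """

    def __init__(self, levels, areas, analyte: str = "", weighting: str | None = None):
        self.levels = np.asarray(levels, dtype=float)
        self.areas = np.asarray(areas, dtype=float)
        self.analyte = analyte
        if self.levels.shape != self.areas.shape:
            raise ValueError("levels and areas must have equal length")
        if np.unique(self.levels).size < 3:
            raise ValueError("need >= 3 distinct concentration levels")
        if np.ptp(self.levels) == 0:
            raise ValueError("zero variance in levels")
        if weighting not in (None, "1/x", "1/x2"):
            raise ValueError(f"unknown weighting {weighting!r}")
        self.weighting = weighting

    def _weights(self) -> np.ndarray:
        if self.weighting is None:
            return np.ones_like(self.levels)
        if self.weighting == "1/x":
            return 1.0 / self.levels
        return 1.0 / self.levels**2

    def fit(self, alpha: float = 0.05) -> "CalibrationResults":
        x, y, w = self.levels, self.areas, self._weights()
        n = x.size
        sw = np.sqrt(w)
        X = np.column_stack([np.ones(n), x])
        beta, _, _, _ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
        intercept, slope = float(beta[0]), float(beta[1])
        resid = y - (intercept + slope * x)
        df = n - 2
        s_yx = float(np.sqrt(np.sum(w * resid**2) / df)) if df > 0 else 0.0
        sxx = float(np.sum(w * (x - np.average(x, weights=w)) ** 2))
        se_slope = s_yx / np.sqrt(sxx)
        se_intercept = s_yx * np.sqrt(np.sum(w * x**2) / (np.sum(w) * sxx))
        tcrit = float(stats.t.ppf(1 - alpha / 2, df)) if df > 0 else np.nan
        r = float(np.corrcoef(x, y)[0, 1])
        lof = self._lack_of_fit(intercept, slope)
        return CalibrationResults(
            analyte=self.analyte, levels=x, areas=y,
            slope=slope, intercept=intercept,
            slope_se=se_slope, intercept_se=se_intercept,
            slope_ci_halfwidth=tcrit * se_slope,
            intercept_ci_halfwidth=tcrit * se_intercept,
            r=r, s_yx=s_yx, df=df, alpha=alpha,
            lack_of_fit_f=lof[0], lack_of_fit_p=lof[1],
        )

    def _lack_of_fit(self, intercept: float, slope: float):
        """F test of linearity against replicate pure error, if replicates exist."""
        x, y = self.levels, self.areas
        ss_pe = 0.0
        df_pe = 0
        for lv in np.unique(x):
            vals = y[x == lv]
            if vals.size > 1:
                ss_pe += float(np.sum((vals - vals.mean()) ** 2))
                df_pe += vals.size - 1
        if df_pe == 0:
            return np.nan, np.nan
        resid = y - (intercept + slope * x)
        ss_res = float(np.sum(resid**2))
        df_lof = (x.size - 2) - df_pe
        ss_lof = max(ss_res - ss_pe, 0.0)
        if df_lof <= 0 or ss_pe == 0.0:
            return np.nan, np.nan
        f = (ss_lof / df_lof) / (ss_pe / df_pe)
        return float(f), float(stats.f.sf(f, df_lof, df_pe))


@dataclass
class CalibrationResults:
    """Fitted calibration line with t-based interval half-widths."""

    analyte: str
    levels: np.ndarray
    areas: np.ndarray
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    slope_ci_halfwidth: float
    intercept_ci_halfwidth: float
    r: float
    s_yx: float
    df: int
    alpha: float
    lack_of_fit_f: float
    lack_of_fit_p: float

    @property
    def crosses_origin(self) -> bool:
        """True when the intercept CI includes zero."""
        return abs(self.intercept) <= self.intercept_ci_halfwidth

    def predict(self, conc):
        return self.intercept + self.slope * np.asarray(conc, dtype=float)

    def inverse(self, area):
        """Back-calculate concentration from a measured area."""
        return (np.asarray(area, dtype=float) - self.intercept) / self.slope

    def summary(self) -> str:
        lines = [
            f"Calibration: {self.analyte or '(analyte)'}",
            f"  slope     b = {self.slope:.4g} +/- {self.slope_ci_halfwidth:.3g} "
            f"(t-based, alpha={self.alpha})",
            f"  intercept a = {self.intercept:.4g} +/- "
            f"{self.intercept_ci_halfwidth:.3g}"
            + ("  [crosses through the origin]" if self.crosses_origin else ""),
            f"  r = {self.r:.4f}   s_yx = {self.s_yx:.4g}   df = {self.df}",
        ]
        if np.isfinite(self.lack_of_fit_p):
            lines.append(
                f"  lack of fit: F = {self.lack_of_fit_f:.3g}, "
                f"p = {self.lack_of_fit_p:.3g}"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Detection limits
# ---------------------------------------------------------------------------

@dataclass
class DetectionLimits:
    """LOD/LOQ in concentration (ng/mL) and on-column mass (pg)."""

    lod_conc: float
    loq_conc: float
    lod_mass: float
    loq_mass: float
    injection_volume_ul: float
    k_lod: float = 3.0
    k_loq: float = 10.0


def on_column_mass(conc_ng_per_ml: float, volume_ul: float) -> float:
    """Mass injected on column, pg: conc (ng/mL) x volume (uL).

    1 ng/mL = 1 pg/uL, so the product is already in pg.
    """
    if conc_ng_per_ml < 0:
        raise ValueError("concentration must be >= 0")
    if volume_ul <= 0:
        raise ValueError("injection volume must be > 0")
    return conc_ng_per_ml * volume_ul


def detection_limits(
    curve: CalibrationResults, injection_volume_ul: float = 2.0
) -> DetectionLimits:
    """L = k * s_yx / b with k = 3 (LOD) and k = 10 (LOQ)."""
    if curve.slope <= 0:
        raise ValueError("calibration slope must be positive")
    lod = 3.0 * curve.s_yx / curve.slope
    loq = 10.0 * curve.s_yx / curve.slope
    return DetectionLimits(
        lod_conc=lod, loq_conc=loq,
        lod_mass=on_column_mass(lod, injection_volume_ul),
        loq_mass=on_column_mass(loq, injection_volume_ul),
        injection_volume_ul=injection_volume_ul,
    )


# ---------------------------------------------------------------------------
# Precision and accuracy
# ---------------------------------------------------------------------------

@dataclass
class QCBatch:
    """QC measurements at one nominal level: rows = days, cols = replicates."""

    analyte: str
    nominal: float
    measurements: np.ndarray  # (n_days, n_reps)

    def __post_init__(self) -> None:
        self.measurements = np.atleast_2d(np.asarray(self.measurements, float))
        if (self.measurements < 0).any():
            raise ValueError("measured concentrations must be >= 0")


@dataclass
class PrecisionAccuracyResult:
    analyte: str
    nominal: float
    intra_mean: float
    intra_rsd: float
    intra_accuracy: float
    inter_mean: float
    inter_rsd: float
    inter_accuracy: float
    n_intra: int
    n_inter: int


def _rsd(values: np.ndarray) -> float:
    m = values.mean()
    if m == 0:
        raise ValueError("mean is zero: RSD undefined")
    return 100.0 * values.std(ddof=1) / m


def precision_accuracy(batch: QCBatch, intra_day: int = 0) -> PrecisionAccuracyResult:
    """Intra-day (one day's replicates) and inter-day (all days pooled)
    precision (RSD%) and accuracy (% of nominal)."""
    m = batch.measurements
    if m.shape[1] < 2:
        raise ValueError("need >= 2 replicates within a day")
    intra = m[intra_day]
    inter = m.ravel()
    if m.shape[0] < 2:
        inter = intra  # single-day batch: inter == intra
    return PrecisionAccuracyResult(
        analyte=batch.analyte, nominal=batch.nominal,
        intra_mean=float(intra.mean()), intra_rsd=_rsd(intra),
        intra_accuracy=100.0 * intra.mean() / batch.nominal,
        inter_mean=float(inter.mean()), inter_rsd=_rsd(inter),
        inter_accuracy=100.0 * inter.mean() / batch.nominal,
        n_intra=intra.size, n_inter=inter.size,
    )


# ---------------------------------------------------------------------------
# Recovery and matrix effect
# ---------------------------------------------------------------------------

@dataclass
class MatrixEffectLevel:
    """Per-QC-level recovery (R3/R2) and matrix effect (R2/R1), percent."""

    level: float
    r1_mean: float
    r2_mean: float
    r3_mean: float
    r1_rsd: float
    r2_rsd: float
    r3_rsd: float
    recovery_pct: float
    matrix_effect_pct: float
    classification: str
    rsd_acceptable: bool  # all three RSDs <= 15%


@dataclass
class MatrixEffectSummary:
    analyte: str
    levels: list[MatrixEffectLevel]
    recovery_mean: float
    recovery_sd: float
    matrix_effect_mean: float
    matrix_effect_sd: float


def _classify_matrix_effect(pct: float) -> str:
    if pct < 85.0:
        return "suppression"
    if pct > 115.0:
        return "enhancement"
    return "none"


def recovery_matrix_effect(
    sets_by_level: dict[float, tuple],
    analyte: str = "",
) -> MatrixEffectSummary:
    """Recovery and matrix effect from R1/R2/R3 replicate peak areas.

    ``sets_by_level`` maps QC concentration -> (r1, r2, r3) replicate
    arrays: R1 pure standard, R2 spiked post-extraction, R3 spiked before
    extraction.  Recovery = 100*R3/R2 and matrix effect = 100*R2/R1 on the
    means; the overall figures are mean +/- sample sd of the per-level
    percentages.
    """
    levels = []
    for level in sorted(sets_by_level):
        r1, r2, r3 = (np.asarray(a, float) for a in sets_by_level[level])
        for name, arr in (("R1", r1), ("R2", r2), ("R3", r3)):
            if arr.size < 2:
                raise ValueError(f"{name} at level {level}: need >= 2 replicates")
            if arr.mean() <= 0:
                raise ValueError(f"{name} at level {level}: nonpositive mean area")
        me = 100.0 * r2.mean() / r1.mean()
        rsds = (_rsd(r1), _rsd(r2), _rsd(r3))
        levels.append(
            MatrixEffectLevel(
                level=float(level),
                r1_mean=float(r1.mean()), r2_mean=float(r2.mean()),
                r3_mean=float(r3.mean()),
                r1_rsd=rsds[0], r2_rsd=rsds[1], r3_rsd=rsds[2],
                recovery_pct=100.0 * r3.mean() / r2.mean(),
                matrix_effect_pct=me,
                classification=_classify_matrix_effect(me),
                rsd_acceptable=all(v <= 15.0 for v in rsds),
            )
        )
    rec = np.array([lv.recovery_pct for lv in levels])
    me = np.array([lv.matrix_effect_pct for lv in levels])
    sd = (lambda a: float(a.std(ddof=1)) if a.size > 1 else np.nan)
    return MatrixEffectSummary(
        analyte=analyte, levels=levels,
        recovery_mean=float(rec.mean()), recovery_sd=sd(rec),
        matrix_effect_mean=float(me.mean()), matrix_effect_sd=sd(me),
    )
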