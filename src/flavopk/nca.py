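"""Noncompartmental pharmacokinetic analysis of plasma profiles.

Computes the standard model-free PK parameters from a concentration-time
profile after a single oral dose: Cmax/Tmax from the observations, the
terminal elimination rate constant lambda_z by log-linear regression with a
best-adjusted-R2 tail selection, AUC and AUMC by trapezoids on [0, t_end],
MRT = AUMC/AUC, and apparent clearance and volume CL/F = dose/AUC,
V/F = CL/F / lambda_z.  Profiles from sparse destructive sampling designs
(each timepoint a different group of animals) are assembled either as a
single mean profile or as n pseudo-subjects.  Arms are compared with a
two-sided t-test (Welch default, pooled optional) that also accepts
published (mean, sd, n) summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConcTimeProfile",
    "assemble_profiles",
    "NCA",
    "NCAResults",
    "nca_table",
    "GroupComparison",
    "compare_arms",
    "post_tmax_slope",
]

#: The seven parameters of the per-arm summary table, in report order.
TABLE_PARAMETERS = ["t_half", "tmax", "cmax", "auc_0_24", "v_f", "cl_f", "mrt"]


@dataclass
class ConcTimeProfile:
    """A single concentration-time profile with dosing metadata.

    times in hours (strictly increasing, >= 0); concentrations in ng/mL.
    ``conc_sd`` carries per-timepoint dispersion when the profile is a
    mean over animals.  dose_mg = dose_mg_per_kg * body_weight_kg.
    """

    subject_id: str
    analyte: str
    arm: str
    times: np.ndarray
    concentrations: np.ndarray
    dose_mg_per_kg: float
    body_weight_kg: float = 0.225
    conc_sd: np.ndarray | None = None
    blq_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times.size != self.concentrations.size:
            raise ValueError("times and concentrations must have equal length")
        if self.times.size < 3:
            raise ValueError("need at least 3 observations")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if (self.concentrations < 0).any():
            raise ValueError("concentrations must be >= 0")

    @property
    def dose_mg(self) -> float:
        return self.dose_mg_per_kg * self.body_weight_kg


def assemble_profiles(
    records: pd.DataFrame,
    scheme: str = "pseudo-subject",
    dose_mg_per_kg: float = 0.0,
    body_weight_kg: float = 0.225,
) -> list[ConcTimeProfile]:
    """Build profiles from a sparse destructive-sampling table.

    ``records`` needs columns analyte, arm, time_h, conc_ng_per_ml and (for
    pseudo-subject assembly) animal index column 'replicate'.  The
    mean-profile scheme returns one profile of per-timepoint means with the
    per-timepoint sd retained; pseudo-subject returns n profiles, the i-th
    stitched from the i-th animal at every timepoint, and requires the same
    n at every time.
    """
    out = []
    for (analyte, arm), grp in records.groupby(["analyte", "arm"], sort=True):
        if scheme == "mean-profile":
            agg = grp.groupby("time_h")["conc_ng_per_ml"].agg(["mean", "std"])
            agg = agg.sort_index()
            out.append(
                ConcTimeProfile(
                    subject_id=f"{analyte}-{arm}-mean", analyte=analyte, arm=arm,
                    times=agg.index.to_numpy(),
                    concentrations=agg["mean"].to_numpy(),
                    conc_sd=agg["std"].to_numpy(),
                    dose_mg_per_kg=dose_mg_per_kg, body_weight_kg=body_weight_kg,
                )
            )
        elif scheme == "pseudo-subject":
            counts = grp.groupby("time_h").size()
            if counts.nunique() != 1:
                raise ValueError(
                    "pseudo-subject assembly needs equal animals per timepoint; "
                    f"got counts {sorted(counts.unique())}"
                )
            n = int(counts.iloc[0])
            g = grp.sort_values(["time_h", "replicate"])
            times = np.sort(grp["time_h"].unique())
            conc = g["conc_ng_per_ml"].to_numpy().reshape(len(times), n)
            for i in range(n):
                out.append(
                    ConcTimeProfile(
                        subject_id=f"{analyte}-{arm}-ps{i + 1}",
                        analyte=analyte, arm=arm,
                        times=times, concentrations=conc[:, i],
                        dose_mg_per_kg=dose_mg_per_kg,
                        body_weight_kg=body_weight_kg,
                    )
                )
        else:
            raise ValueError(f"unknown scheme {scheme!r}")
    return out


# ---------------------------------------------------------------------------
# Per-profile NCA
# ---------------------------------------------------------------------------

def profile_summary(profile: ConcTimeProfile) -> tuple[float, float]:
    """(cmax, tmax); ties broken by the earliest time."""
    c = profile.concentrations
    if (c == 0).all():
        raise ValueError("all-zero profile: no absorption observed")
    i = int(np.argmax(c))  # argmax returns the first maximum
    return float(c[i]), float(profile.times[i])


def fit_lambda_z(
    profile: ConcTimeProfile,
    selection: str = "best-adjusted-r2",
    indices: list[int] | None = None,
) -> tuple[float, float, list[int], float]:
    """Terminal slope by log-linear OLS: (lambda_z, t_half, points, r2_adj).

    The automatic rule scans every contiguous tail of >= 3 positive
    concentrations strictly after Tmax and keeps the largest adjusted R2,
    preferring more points on ties.
    """
    t, c = profile.times, profile.concentrations
    _, tmax = profile_summary(profile)
    usable = np.where((t > tmax) & (c > 0))[0]
    if selection == "manual":
        if indices is None:
            raise ValueError("manual selection needs indices")
        cand = [list(indices)]
    elif selection == "best-adjusted-r2":
        if usable.size < 3:
            raise ValueError("need >= 3 positive concentrations after Tmax")
        cand = [list(usable[start:]) for start in range(usable.size - 2)]
    else:
        raise ValueError(f"unknown selection {selection!r}")

    best = None
    for idx in cand:
        if len(idx) < 3:
            continue
        x, y = t[idx], np.log(c[idx])
        n = len(idx)
        slope, intercept, r, _, _ = stats.linregress(x, y)
        r2adj = 1.0 - (1.0 - r**2) * (n - 1) / (n - 2)
        # prefer larger adjusted R2; on ties (within 1e-10) prefer more points
        if best is None or r2adj > best[0] + 1e-10 or (
            abs(r2adj - best[0]) <= 1e-10 and n > len(best[1])
        ):
            best = (r2adj, idx, slope)
    if best is None:
        raise ValueError("no usable tail of >= 3 points")
    r2adj, idx, slope = best
    if slope >= 0:
        raise ValueError("terminal phase is not declining (nonnegative slope)")
    lam = -float(slope)
    return lam, math.log(2.0) / lam, idx, float(r2adj)


def auc_aumc(
    profile: ConcTimeProfile, t_end: float = 24.0, method: str = "linear"
) -> tuple[float, float]:
    """AUC and AUMC on [0, t_end] by trapezoids (no extrapolation).

    A (0, 0) anchor is prepended when the first sample is after t=0
    (oral dosing: nothing in plasma at the instant of the dose).  The
    'log-down' method uses the log-trapezoid on strictly declining
    positive segments.
    """
    t = profile.times
    c = profile.concentrations
    if t[0] > 0:
        t = np.r_[0.0, t]
        c = np.r_[0.0, c]
    if t[-1] < t_end - 1e-9:
        raise ValueError(
            f"profile ends at {t[-1]} h; no extrapolation to {t_end} h"
        )
    keep = t <= t_end + 1e-9
    t, c = t[keep], c[keep]
    auc = aumc = 0.0
    for i in range(t.size - 1):
        dt = t[i + 1] - t[i]
        c0, c1 = c[i], c[i + 1]
        if method == "log-down" and c0 > c1 > 0:
            k = math.log(c0 / c1) / dt
            auc += (c0 - c1) / k
            aumc += (t[i] * c0 - t[i + 1] * c1) / k + (c0 - c1) / k**2
        else:
            auc += dt * (c0 + c1) / 2.0
            aumc += dt * (t[i] * c0 + t[i + 1] * c1) / 2.0
    return float(auc), float(aumc)


def clearance_volume(
    auc_0_t: float, lambda_z: float, dose_mg: float
) -> tuple[float, float]:
    """CL/F = dose/AUC in (mg)/(ng/mL)/h and V/F = CL/F / lambda_z."""
    if auc_0_t <= 0:
        raise ValueError("AUC must be positive")
    if lambda_z <= 0:
        raise ValueError("lambda_z must be positive")
    cl_f = dose_mg / auc_0_t
    return cl_f, cl_f / lambda_z


@dataclass
class NCAResults:
    """Noncompartmental parameters of one profile (units as in the report
    tables: h, ng/mL, ng*h/mL, (mg)/(ng/mL) and (mg)/(ng/mL)/h)."""

    subject_id: str
    analyte: str
    arm: str
    tmax: float
    cmax: float
    lambda_z: float
    t_half: float
    auc_0_24: float
    aumc_0_24: float
    mrt: float
    cl_f: float
    v_f: float
    lambda_z_points: list[int]
    lambda_z_r2_adj: float

    def as_dict(self) -> dict[str, float]:
        return {p: getattr(self, p) for p in TABLE_PARAMETERS}

    def summary(self) -> str:
        rows = [
            ("Tmax (h)", self.tmax), ("Cmax (ng/mL)", self.cmax),
            ("lambda_z (1/h)", self.lambda_z), ("T1/2 (h)", self.t_half),
            ("AUC0-24 (ng*h/mL)", self.auc_0_24),
            ("MRT (h)", self.mrt),
            ("CL/F ((mg)/(ng/mL)/h)", self.cl_f),
            ("V/F ((mg)/(ng/mL))", self.v_f),
        ]
        head = f"NCA: {self.subject_id} ({self.analyte}, {self.arm})"
        return "\n".join([head] + [f"  {k:<24s} {v:10.4g}" for k, v in rows])


class NCA:
    """Noncompartmental analysis of a single profile.

    ``blq_loq`` (ng/mL) optionally applies the below-LOQ convention: values
    under the LOQ are set to 0 before Tmax and dropped after Tmax.
    """

    def __init__(
        self,
        profile: ConcTimeProfile,
        t_end: float = 24.0,
        auc_method: str = "linear",
        lambda_z_selection: str = "best-adjusted-r2",
        blq_loq: float | None = None,
    ):
        self.profile = self._apply_blq(profile, blq_loq) if blq_loq else profile
        self.t_end = t_end
        self.auc_method = auc_method
        self.lambda_z_selection = lambda_z_selection

    @staticmethod
    def _apply_blq(profile: ConcTimeProfile, loq: float) -> ConcTimeProfile:
        t, c = profile.times, profile.concentrations.copy()
        i_tmax = int(np.argmax(c))
        below = c < loq
        c[below & (np.arange(c.size) <= i_tmax)] = 0.0
        keep = ~(below & (np.arange(c.size) > i_tmax))
        return ConcTimeProfile(
            profile.subject_id, profile.analyte, profile.arm,
            t[keep], c[keep], profile.dose_mg_per_kg, profile.body_weight_kg,
        )

    def fit(self) -> NCAResults:
        p = self.profile
        cmax, tmax = profile_summary(p)
        lam, t_half, pts, r2adj = fit_lambda_z(p, self.lambda_z_selection)
        auc, aumc = auc_aumc(p, self.t_end, self.auc_method)
        cl_f, v_f = clearance_volume(auc, lam, p.dose_mg)
        return NCAResults(
            subject_id=p.subject_id, analyte=p.analyte, arm=p.arm,
            tmax=tmax, cmax=cmax, lambda_z=lam, t_half=t_half,
            auc_0_24=auc, aumc_0_24=aumc, mrt=aumc / auc,
            cl_f=cl_f, v_f=v_f,
            lambda_z_points=list(pts), lambda_z_r2_adj=r2adj,
        )


def post_tmax_slope(profile: ConcTimeProfile) -> float:
    """OLS slope of concentration vs time (linear scale) from Tmax to the end."""
    _, tmax = profile_summary(profile)
    mask = profile.times >= tmax
    if mask.sum() < 2:
        raise ValueError("need >= 2 points from Tmax to the last time")
    t, c = profile.times[mask], profile.concentrations[mask]
    if np.ptp(t) == 0:
        raise ValueError("degenerate time span after Tmax")
    slope = float(np.polyfit(t, c, 1)[0])
    return slope


def nca_table(results: list[NCAResults]) -> pd.DataFrame:
    """Per-arm mean +/- sample sd of the seven report parameters.

    With a single profile per arm the sd is reported as NaN (absent), not 0.
    """
    rows = []
    df = pd.DataFrame(
        [{"analyte": r.analyte, "arm": r.arm, **r.as_dict()} for r in results]
    )
    for (analyte, arm), grp in df.groupby(["analyte", "arm"], sort=True):
        for param in TABLE_PARAMETERS:
            vals = grp[param].to_numpy()
            rows.append({
                "analyte": analyte, "arm": arm, "parameter": param,
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
                "n": vals.size,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Arm comparison
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    parameter: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t_statistic: float
    df: float
    p_value: float
    variant: str
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def _summarize(values_or_stats) -> tuple[float, float, int]:
    if isinstance(values_or_stats, tuple) and len(values_or_stats) == 3:
        m, s, n = values_or_stats
        return float(m), float(s), int(n)
    arr = np.asarray(values_or_stats, dtype=float)
    if arr.size < 2:
        raise ValueError("need n >= 2 per arm")
    return float(arr.mean()), float(arr.std(ddof=1)), int(arr.size)


def compare_arms(
    a, b, parameter: str = "", variant: str = "welch", alpha: float = 0.05
) -> GroupComparison:
    """Two-sided t-test between arms from raw values or (mean, sd, n).

    variant 'welch' (default) uses the Welch-Satterthwaite df; 'pooled'
    assumes equal variances.  Two identical degenerate groups give t = 0,
    p = 1 rather than 0/0.
    """
    ma, sa, na = _summarize(a)
    mb, sb, nb = _summarize(b)
    va, vb = sa**2, sb**2
    if va == 0 and vb == 0:
        if ma == mb:
            t_stat, df = 0.0, float(na + nb - 2)
        else:
            t_stat, df = math.inf if ma > mb else -math.inf, float(na + nb - 2)
    elif variant == "pooled":
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        t_stat = (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))
        df = float(na + nb - 2)
    elif variant == "welch":
        se2 = va / na + vb / nb
        t_stat = (ma - mb) / math.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    else:
        raise ValueError(f"unknown variant {variant!r}")
    p = float(2.0 * stats.t.sf(abs(t_stat), df)) if math.isfinite(t_stat) else 0.0
    if t_stat == 0.0:
        p = 1.0
    return GroupComparison(
        parameter=parameter, mean_a=ma, sd_a=sa, n_a=na,
        mean_b=mb, sd_b=sb, n_b=nb,
        t_statistic=float(t_stat), df=float(df), p_value=p,
        variant=variant, alpha=alpha,
    )
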