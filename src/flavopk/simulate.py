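"""Synthetic data generators with known ground truth.

Emulates the three data-generating processes of the study so every
estimator in the package can be exercised against a known truth: (a)
quadratic response surfaces with additive Gaussian noise over a coded
design, (b) linear calibration and R1/R2/R3 recovery/matrix-effect peak
areas with constant-sd or proportional-CV noise, and (c) one-compartment
oral-absorption (Bateman) plasma profiles sampled on the sparse
destructive 17-timepoint grid with 3 animals per timepoint and
multiplicative lognormal between-animal error.

All generators are deterministic for a fixed seed and parameter set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .doe import DesignMatrix, _quadratic_model_matrix
from .presets import SAMPLING_GRID_H

__all__ = [
    "SurfaceTruth",
    "AssayTruth",
    "PKSimulationTruth",
    "simulate_surface",
    "simulate_calibration",
    "simulate_recovery_sets",
    "bateman",
    "simulate_pk",
]


@dataclass(frozen=True)
class SurfaceTruth:
    """True quadratic surface: Y = b0 + b.x + x'Bx terms + N(0, noise_sd)."""

    b0: float
    linear: tuple
    quadratic: tuple
    interaction: tuple
    noise_sd: float = 0.0
    seed: int = 0


def simulate_surface(design: DesignMatrix, truth: SurfaceTruth) -> np.ndarray:
    """Responses of the true quadratic at the design's coded points."""
    k = design.n_real_factors
    if not (len(truth.linear) == len(truth.quadratic) == k
            and len(truth.interaction) == k * (k - 1) // 2):
        raise ValueError("truth coefficients do not conform to design dimension")
    params = np.concatenate(
        [[truth.b0], truth.linear, truth.quadratic, truth.interaction]
    )
    X, _ = _quadratic_model_matrix(design.runs[:, :k])
    y = X @ params
    if truth.noise_sd > 0:
        rng = np.random.default_rng(truth.seed)
        y = y + rng.normal(0.0, truth.noise_sd, size=y.shape)
    return y


@dataclass(frozen=True)
class AssayTruth:
    """True calibration line and recovery/matrix-effect factors.

    noise_model 'constant' adds N(0, noise_scale) to each area;
    'proportional' multiplies by (1 + N(0, noise_scale)), i.e. noise_scale
    is a CV.  true_recovery rho in (0, 1]; true_matrix_factor mu > 0, so
    E[R2] = mu*E[R1] and E[R3] = rho*mu*E[R1].
    """

    slope: float
    intercept: float = 0.0
    noise_model: str = "proportional"
    noise_scale: float = 0.05
    true_recovery: float = 1.0
    true_matrix_factor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.true_recovery <= 1):
            raise ValueError("true_recovery must be in (0, 1]")
        if self.true_matrix_factor <= 0:
            raise ValueError("true_matrix_factor must be > 0")
        if self.noise_model not in ("constant", "proportional"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")


def _add_noise(expect: np.ndarray, truth: AssayTruth, rng) -> np.ndarray:
    if truth.noise_scale == 0:
        return expect.copy()
    if truth.noise_model == "constant":
        return expect + rng.normal(0.0, truth.noise_scale, size=expect.shape)
    return expect * (1.0 + rng.normal(0.0, truth.noise_scale, size=expect.shape))


def simulate_calibration(
    truth: AssayTruth, levels, reps: int = 3, analyte: str = "synthetic"
) -> pd.DataFrame:
    """Calibration table (analyte, level_ng_per_ml, area), reps rows per level."""
    levels = np.asarray(levels, dtype=float)
    if (levels <= 0).any():
        raise ValueError("levels must be > 0")
    rng = np.random.default_rng(truth.seed)
    lv = np.repeat(levels, reps)
    areas = _add_noise(truth.intercept + truth.slope * lv, truth, rng)
    return pd.DataFrame(
        {"analyte": analyte, "level_ng_per_ml": lv, "area": areas}
    )


def simulate_recovery_sets(
    truth: AssayTruth, levels, n: int = 6
) -> dict[float, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """R1/R2/R3 replicate areas per QC level (n each).

    R1 is the pure-standard expectation; R2 scales it by the matrix factor
    mu; R3 further by the recovery rho; the chosen noise model applies to
    all three sets independently.
    """
    rng = np.random.default_rng(truth.seed)
    out = {}
    for level in np.asarray(levels, dtype=float):
        e1 = truth.intercept + truth.slope * level
        e2 = truth.true_matrix_factor * e1
        e3 = truth.true_recovery * e2
        out[float(level)] = tuple(
            _add_noise(np.full(n, e), truth, rng) for e in (e1, e2, e3)
        )
    return out


# ---------------------------------------------------------------------------
# One-compartment oral PK
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PKSimulationTruth:
    """One-compartment first-order absorption truth (F absorbed into v_over_f).

    Defaults echo the scale of the flavonoid study: an elimination
    half-life near 3 h (ke = ln2/3), brisk absorption, a ~15.5 mg dose
    (69 mg/kg x 0.225 kg), 17-point sampling over 24 h, 3 animals per
    timepoint and ~10% between-animal CV.
    """

    ka: float = 1.5
    ke: float = np.log(2.0) / 3.0
    v_over_f: float = 0.3          # (mg)/(ng/mL)
    dose_mg: float = 15.525
    residual_cv: float = 0.10
    n_per_timepoint: int = 3
    time_grid: tuple = field(default=SAMPLING_GRID_H)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ka <= 0 or self.ke <= 0:
            raise ValueError("rates must be > 0")
        if abs(self.ka - self.ke) < 1e-12:
            raise ValueError("degenerate Bateman: ka == ke not supported")

    @property
    def tmax_true(self) -> float:
        return float(np.log(self.ka / self.ke) / (self.ka - self.ke))


def bateman(t, ka: float, ke: float, dose_mg: float, v_over_f: float):
    """One-compartment oral concentration: C(t) in ng/mL for t in hours."""
    t = np.asarray(t, dtype=float)
    scale = dose_mg * ka / (v_over_f * (ka - ke))
    return scale * (np.exp(-ke * t) - np.exp(-ka * t))


def simulate_pk(
    truth: PKSimulationTruth, analyte: str = "synthetic", arm: str = "single"
) -> pd.DataFrame:
    """Sparse destructive-sampling table: n animals at each grid time.

    Per-animal concentration is C(t) * exp(eta) with
    eta ~ N(0, log(1 + cv^2)) so the multiplicative error has the stated
    CV; columns match the assembly contract of :func:`nca.assemble_profiles`.
    """
    rng = np.random.default_rng(truth.seed)
    times = np.asarray(truth.time_grid, dtype=float)
    mean_curve = bateman(times, truth.ka, truth.ke, truth.dose_mg, truth.v_over_f)
    rows = []
    sigma = np.sqrt(np.log1p(truth.residual_cv**2))
    for t, c in zip(times, mean_curve):
        for rep in range(truth.n_per_timepoint):
            val = c if truth.residual_cv == 0 else c * np.exp(rng.normal(0.0, sigma))
            rows.append({
                "analyte": analyte, "arm": arm, "time_h": t,
                "replicate": rep + 1, "conc_ng_per_ml": val,
            })
    return pd.DataFrame(rows)
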