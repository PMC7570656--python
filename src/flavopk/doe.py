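"""Screening and response-surface designs for ESI source optimization.

Implements the design-of-experiments chain used to tune an electrospray
source for small-molecule MRM quantification: a 12-run Plackett-Burman
screening design with main-effect estimation and Pareto-style significance
ranking, and a 3-factor Box-Behnken design fitted with a full second-order
polynomial.  The fitted quadratic is analysed the way response-surface
methodology textbooks prescribe: lack-of-fit ANOVA against center-point
pure error, canonical (stationary-point) analysis of the Hessian, and an
exact constrained maximization over the coded design cube
``[-1, 1]^k`` by enumeration of all faces, edges and vertices.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "FactorDef",
    "DesignMatrix",
    "EffectTable",
    "plackett_burman",
    "box_behnken",
    "estimate_main_effects",
    "rank_effects",
    "ResponseSurfaceModel",
    "ResponseSurfaceResults",
    "StationaryPoint",
]


class DegenerateDesignError(ValueError):
    """Design does not support the requested computation."""


# ---------------------------------------------------------------------------
# Factors and coding
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FactorDef:
    """An experimental factor with low / center / high settings.

    Coded levels -1, 0, +1 map exactly to ``low``, ``center``, ``high``.
    The center need not be the arithmetic midpoint, so coding is
    piecewise-affine on [low, center] and [center, high].
    """

    name: str
    units: str
    low: float
    center: float
    high: float

    def __post_init__(self) -> None:
        if not (self.low < self.center < self.high):
            raise ValueError(
                f"factor {self.name!r}: require low < center < high, "
                f"got {self.low}, {self.center}, {self.high}"
            )

    def code(self, actual: float) -> float:
        """Map an actual-unit value into coded units on [-1, 1]."""
        if actual < self.low or actual > self.high:
            raise ValueError(
                f"{self.name}: {actual} {self.units} outside "
                f"[{self.low}, {self.high}]"
            )
        if actual <= self.center:
            return (actual - self.center) / (self.center - self.low)
        return (actual - self.center) / (self.high - self.center)

    def decode(self, coded: float) -> float:
        """Map a coded value on [-1, 1] back to actual units."""
        if coded < -1 - 1e-9 or coded > 1 + 1e-9:
            raise ValueError(f"{self.name}: coded value {coded} outside [-1, 1]")
        if coded <= 0:
            return self.center + coded * (self.center - self.low)
        return self.center + coded * (self.high - self.center)


@dataclass
class DesignMatrix:
    """A coded experimental design: one row per run, entries in {-1, 0, +1}.

    ``n_real_factors`` distinguishes real factors (mapped to
    ``factors``) from trailing dummy columns kept for error estimation in
    saturated screening designs.
    """

    factors: list[FactorDef]
    runs: np.ndarray
    run_ids: list[str]
    center_flags: np.ndarray
    n_real_factors: int = field(default=0)

    def __post_init__(self) -> None:
        self.runs = np.asarray(self.runs, dtype=float)
        self.center_flags = np.asarray(self.center_flags, dtype=bool)
        if self.n_real_factors == 0:
            self.n_real_factors = len(self.factors)
        if not np.isin(self.runs, (-1.0, 0.0, 1.0)).all():
            raise ValueError("design entries must be in {-1, 0, +1}")
        if len(self.run_ids) != self.runs.shape[0]:
            raise ValueError("run_ids length mismatch")

    @property
    def n_runs(self) -> int:
        return self.runs.shape[0]

    @property
    def n_columns(self) -> int:
        return self.runs.shape[1]

    @property
    def non_center(self) -> np.ndarray:
        return self.runs[~self.center_flags]

    def decode_point(self, coded: np.ndarray) -> list[float]:
        """Decode a coded point (real-factor columns only) to actual units."""
        return [f.decode(c) for f, c in zip(self.factors, coded)]

    def to_frame(self):
        import pandas as pd

        cols = [f.name for f in self.factors]
        cols += [f"dummy{i + 1}" for i in range(self.n_columns - self.n_real_factors)]
        df = pd.DataFrame(self.runs, columns=cols)
        df.insert(0, "run_id", self.run_ids)
        df["center"] = self.center_flags
        return df


# 12-run Plackett-Burman first row (cyclic generator); the 12th run is all -1.
_PB12_FIRST_ROW = np.array([1, 1, -1, 1, 1, 1, -1, -1, -1, 1, -1], dtype=float)


def plackett_burman(factors: list[FactorDef], n_center: int = 0) -> DesignMatrix:
    """Build the 12-run Plackett-Burman screening design for up to 11 factors.

    Real factors occupy the first ``len(factors)`` columns; the remaining
    columns of the 11-column base are retained as dummy columns so that
    their (null) effects can estimate experimental error.  ``n_center``
    all-zero rows are appended and flagged.
    """
    k = len(factors)
    if k < 2:
        raise ValueError("need at least 2 factors")
    if k > 11:
        raise DegenerateDesignError("12-run Plackett-Burman supports at most 11 factors")
    rows = [np.roll(_PB12_FIRST_ROW, i) for i in range(11)]
    rows.append(-np.ones(11))
    runs = np.vstack(rows)
    if n_center:
        runs = np.vstack([runs, np.zeros((n_center, 11))])
    flags = np.r_[np.zeros(12, bool), np.ones(n_center, bool)]
    ids = [f"PB{i + 1:02d}" for i in range(12)] + [f"C{i + 1}" for i in range(n_center)]
    return DesignMatrix(list(factors), runs, ids, flags, n_real_factors=k)


def box_behnken(factors: list[FactorDef], n_center: int = 5) -> DesignMatrix:
    """Build the 3-factor Box-Behnken design: 12 edge midpoints + centers.

    Each non-center run sets one factor to its center (coded 0) and the
    other two to +/-1; with the conventional 5 center replicates this is
    the 17-run design used for second-order source optimization.
    """
    if len(factors) != 3:
        raise ValueError("Box-Behnken generator is specified for exactly 3 factors")
    if n_center < 2:
        import warnings

        warnings.warn("fewer than 2 center replicates: pure error is inestimable",
                      stacklevel=2)
    rows = []
    for zero in range(3):
        for a, b in itertools.product((-1.0, 1.0), repeat=2):
            row = np.zeros(3)
            others = [i for i in range(3) if i != zero]
            row[others[0]], row[others[1]] = a, b
            rows.append(row)
    runs = np.vstack(rows + [np.zeros(3)] * n_center)
    flags = np.r_[np.zeros(12, bool), np.ones(n_center, bool)]
    ids = [f"BB{i + 1:02d}" for i in range(12)] + [f"C{i + 1}" for i in range(n_center)]
    return DesignMatrix(list(factors), runs, ids, flags)


# ---------------------------------------------------------------------------
# Screening: main effects and Pareto ranking
# ---------------------------------------------------------------------------

@dataclass
class EffectTable:
    """Main effects of a two-level screening design, optionally standardized.

    ``effects`` holds real-factor effects (response units, high minus low
    on the mean scale); ``dummy_effects`` the same statistic for unused
    design columns.  ``t_values``/``p_values``/``ranks``/``threshold`` are
    filled by :func:`rank_effects`.
    """

    names: list[str]
    effects: np.ndarray
    dummy_effects: np.ndarray
    standard_errors: np.ndarray | None = None
    t_values: np.ndarray | None = None
    p_values: np.ndarray | None = None
    ranks: np.ndarray | None = None
    method: str | None = None
    threshold: float | None = None  # |standardized effect| line at alpha

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame({"factor": self.names, "effect": self.effects})
        if self.t_values is not None:
            df["se"] = self.standard_errors
            df["t"] = self.t_values
            df["p"] = self.p_values
            df["rank"] = self.ranks
        return df


def estimate_main_effects(design: DesignMatrix, response: np.ndarray) -> EffectTable:
    """Two-level main effects: E(Xi) = 2 (sum at +1 - sum at -1) / N.

    N is the number of non-center runs; center rows are excluded.  On a
    balanced column this equals the difference of level means and twice
    the OLS coefficient of the coded column.
    """
    response = np.asarray(response, dtype=float)
    if response.shape[0] != design.n_runs:
        raise ValueError("response length must equal number of design runs")
    X = design.non_center
    y = response[~design.center_flags]
    n = X.shape[0]
    effects = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        col = X[:, j]
        if (col > 0).all() or (col < 0).all():
            raise DegenerateDesignError(f"column {j} has a single level")
        effects[j] = 2.0 * (y[col > 0].sum() - y[col < 0].sum()) / n
    k = design.n_real_factors
    names = [f.name for f in design.factors]
    return EffectTable(names, effects[:k], effects[k:])


def _lenth_pse(all_effects: np.ndarray) -> float:
    """Lenth's pseudo standard error for saturated two-level designs."""
    abs_e = np.abs(all_effects)
    s0 = 1.5 * np.median(abs_e)
    trimmed = abs_e[abs_e < 2.5 * s0]
    if trimmed.size == 0:
        trimmed = abs_e
    return 1.5 * np.median(trimmed)


def rank_effects(
    design: DesignMatrix,
    effects: EffectTable,
    method: str = "lenth",
    response: np.ndarray | None = None,
    alpha: float = 0.05,
) -> EffectTable:
    """Standardize and rank screening effects (Pareto-chart order).

    method 'lenth' uses Lenth's pseudo standard error over all contrast
    columns (df = m/3); 'dummy-variance' pools the squared dummy-column
    effects (df = number of dummies); 'center-replicates' uses center-point
    pure error (needs ``response``; df = n_center - 1).  Effects are always
    ranked by |t|; p-values are two-sided.
    """
    all_eff = np.concatenate([effects.effects, effects.dummy_effects])
    n_noncenter = design.non_center.shape[0]

    if method == "lenth":
        if all_eff.size < 3:
            raise DegenerateDesignError("Lenth method needs at least 3 contrasts")
        se = _lenth_pse(all_eff)
        df = all_eff.size / 3.0
    elif method == "dummy-variance":
        if effects.dummy_effects.size == 0:
            raise DegenerateDesignError("no dummy columns available")
        se = float(np.sqrt(np.mean(effects.dummy_effects**2)))
        df = float(effects.dummy_effects.size)
    elif method == "center-replicates":
        if response is None:
            raise ValueError("center-replicates method needs the response vector")
        yc = np.asarray(response, float)[design.center_flags]
        if yc.size < 2:
            raise DegenerateDesignError("need >= 2 center replicates")
        s2 = float(np.var(yc, ddof=1))
        # Var(effect) = Var(mean_hi - mean_lo) = s^2 * 4 / N on a balanced design
        se = float(np.sqrt(4.0 * s2 / n_noncenter))
        df = float(yc.size - 1)
    else:
        raise ValueError(f"unknown method {method!r}")

    if se == 0.0:
        t = np.where(effects.effects == 0.0, 0.0, np.inf)
        p = np.where(effects.effects == 0.0, 1.0, np.finfo(float).tiny)
        threshold = 0.0
    else:
        t = effects.effects / se
        p = 2.0 * stats.t.sf(np.abs(t), df)
        p = np.maximum(p, np.finfo(float).tiny)
        threshold = float(stats.t.ppf(1.0 - alpha / 2.0, df))

    order = np.argsort(-np.abs(t), kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(1, len(order) + 1)
    return EffectTable(
        effects.names, effects.effects, effects.dummy_effects,
        standard_errors=np.full_like(effects.effects, se),
        t_values=t, p_values=p, ranks=ranks, method=method, threshold=threshold,
    )


# ---------------------------------------------------------------------------
# Second-order response-surface model
# ---------------------------------------------------------------------------

def _quadratic_model_matrix(X: np.ndarray) -> tuple[np.ndarray, list[str]]:
    """Columns [1, x_i, x_i^2, x_i x_j (i<j)] for a k-factor quadratic."""
    n, k = X.shape
    cols = [np.ones(n)]
    names = ["b0"]
    for i in range(k):
        cols.append(X[:, i])
        names.append(f"b{i + 1}")
    for i in range(k):
        cols.append(X[:, i] ** 2)
        names.append(f"b{i + 1}{i + 1}")
    for i, j in itertools.combinations(range(k), 2):
        cols.append(X[:, i] * X[:, j])
        names.append(f"b{i + 1}{j + 1}")
    return np.column_stack(cols), names


@dataclass
class StationaryPoint:
    """Canonical analysis of a fitted quadratic surface.

    The unconstrained stationary point solves the zero-gradient linear
    system; its nature follows from the Hessian eigenvalues.  The
    constrained optimum is the exact global maximum of the quadratic over
    the closed coded cube.
    """

    coded_point: np.ndarray | None
    actual_point: list[float] | None
    classification: str | None  # maximum / minimum / saddle, None if singular
    inside_region: bool | None
    constrained_optimum_coded: np.ndarray
    constrained_optimum_actual: list[float]
    predicted_response_at_optimum: float


class ResponseSurfaceModel:
    """Full second-order polynomial model for a coded design.

    Parameters
    ----------
    design : DesignMatrix
        Coded design (entries in {-1, 0, +1}); center replicates supply
        pure error for the lack-of-fit test.
    response : array-like
        One response value per design run (e.g. peak area).
    """

    def __init__(self, design: DesignMatrix, response: np.ndarray):
        self.design = design
        self.response = np.asarray(response, dtype=float)
        if self.response.shape[0] != design.n_runs:
            raise ValueError("response length must equal number of design runs")
        self.exog, self.param_names = _quadratic_model_matrix(
            design.runs[:, : design.n_real_factors]
        )
        if self.response.shape[0] < self.exog.shape[1] + 1:
            raise DegenerateDesignError(
                f"need >= {self.exog.shape[1] + 1} runs for the "
                f"{self.exog.shape[1]}-parameter quadratic"
            )

    def fit(self) -> "ResponseSurfaceResults":
        X, y = self.exog, self.response
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise DegenerateDesignError("rank-deficient model matrix")
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        return ResponseSurfaceResults(self, beta)


class ResponseSurfaceResults:
    """OLS fit of the quadratic surface with ANOVA and canonical analysis."""

    def __init__(self, model: ResponseSurfaceModel, params: np.ndarray):
        self.model = model
        self.params = params
        design = model.design
        k = design.n_real_factors
        self.k = k
        self.b0 = float(params[0])
        self.linear = params[1 : 1 + k].copy()
        self.quadratic = params[1 + k : 1 + 2 * k].copy()
        self.interaction = params[1 + 2 * k :].copy()

        y = model.response
        self.fitted = model.exog @ params
        self.resid = y - self.fitted
        n, p = model.exog.shape
        self.df_resid = n - p
        sst = float(np.sum((y - y.mean()) ** 2))
        ssr = float(np.sum(self.resid**2))
        self.ss_total = sst
        self.ss_residual = ssr
        self.ss_regression = sst - ssr
        self.r2 = 1.0 - ssr / sst if sst > 0 else 1.0
        self.r2_adj = (
            1.0 - (1.0 - self.r2) * (n - 1) / self.df_resid
            if self.df_resid > 0 else np.nan
        )
        self.residual_sd = (
            float(np.sqrt(ssr / self.df_resid)) if self.df_resid > 0 else np.nan
        )
        self._anova = None
        self._stationary = None

    # -- prediction -------------------------------------------------------

    def predict(self, coded: np.ndarray) -> float | np.ndarray:
        """Evaluate the fitted quadratic at coded point(s)."""
        pts = np.atleast_2d(np.asarray(coded, dtype=float))
        X, _ = _quadratic_model_matrix(pts)
        out = X @ self.params
        return float(out[0]) if np.ndim(coded) == 1 else out

    @property
    def hessian(self) -> np.ndarray:
        """Hessian of the surface: 2*b_ii on the diagonal, b_ij off it."""
        H = np.diag(2.0 * self.quadratic)
        for (i, j), bij in zip(itertools.combinations(range(self.k), 2),
                               self.interaction):
            H[i, j] = H[j, i] = bij
        return H

    # -- ANOVA with lack of fit -------------------------------------------

    def anova(self) -> dict:
        """Lack-of-fit decomposition using center-replicate pure error.

        ss_pure_error pools within-group variation over replicated design
        points (the center replicates here); ss_lack_of_fit is the
        remainder of the residual.  When the replicates are identical the
        F ratio is undefined and flagged rather than divided by zero.
        """
        if self._anova is not None:
            return self._anova
        design = self.model.design
        y = self.model.response
        # group replicated rows by their coded coordinates
        keys = [tuple(row) for row in design.runs[:, : self.k]]
        groups: dict[tuple, list[int]] = {}
        for i, key in enumerate(keys):
            groups.setdefault(key, []).append(i)
        ss_pe = 0.0
        df_pe = 0
        for idx in groups.values():
            if len(idx) > 1:
                vals = y[idx]
                ss_pe += float(np.sum((vals - vals.mean()) ** 2))
                df_pe += len(idx) - 1
        if df_pe == 0:
            raise DegenerateDesignError("no replicated runs: pure error inestimable")
        ss_lof = max(self.ss_residual - ss_pe, 0.0)
        df_lof = self.df_resid - df_pe
        undefined = ss_pe == 0.0 or df_lof <= 0
        if undefined:
            f_lof = np.nan
            p_lof = np.nan
        else:
            f_lof = (ss_lof / df_lof) / (ss_pe / df_pe)
            p_lof = float(stats.f.sf(f_lof, df_lof, df_pe))
        self._anova = {
            "ss_regression": self.ss_regression,
            "ss_residual": self.ss_residual,
            "ss_lack_of_fit": ss_lof,
            "ss_pure_error": ss_pe,
            "df_regression": self.model.exog.shape[1] - 1,
            "df_residual": self.df_resid,
            "df_lack_of_fit": df_lof,
            "df_pure_error": df_pe,
            "f_lack_of_fit": f_lof,
            "p_lack_of_fit": p_lof,
            "f_undefined": bool(undefined),
        }
        return self._anova

    # -- canonical analysis and constrained optimum ------------------------

    def stationary_point(self) -> StationaryPoint:
        """Zero-gradient point, its classification, and the cube-constrained
        maximum of the fitted surface, decoded to actual factor units."""
        if self._stationary is not None:
            return self._stationary
        H = self.hessian
        g = self.linear
        try:
            xs = np.linalg.solve(H, -g)
            eig = np.linalg.eigvalsh(H)
            if (eig < 0).all():
                cls = "maximum"
            elif (eig > 0).all():
                cls = "minimum"
            else:
                cls = "saddle"
            inside = bool(np.all(np.abs(xs) <= 1.0 + 1e-9))
        except np.linalg.LinAlgError:
            xs, cls, inside = None, None, None

        if xs is not None and inside and cls == "maximum":
            xc = np.clip(xs, -1.0, 1.0)
        else:
            xc = self._constrained_maximum()
        design = self.model.design
        self._stationary = StationaryPoint(
            coded_point=xs,
            actual_point=design.decode_point(xs) if (xs is not None and inside) else None,
            classification=cls,
            inside_region=inside,
            constrained_optimum_coded=xc,
            constrained_optimum_actual=design.decode_point(xc),
            predicted_response_at_optimum=self.predict(xc),
        )
        return self._stationary

    def _constrained_maximum(self) -> np.ndarray:
        """Exact maximum of the quadratic over [-1, 1]^k.

        Enumerates every face of the cube (each subset of coordinates
        fixed at +/-1), solves the reduced stationary system on the free
        coordinates, keeps interior solutions, and compares all candidates
        together with the 2^k vertices.
        """
        k = self.k
        H, g = self.hessian, self.linear
        best_x, best_y = None, -np.inf
        for free_mask in itertools.product((False, True), repeat=k):
            free = [i for i in range(k) if free_mask[i]]
            fixed = [i for i in range(k) if not free_mask[i]]
            for signs in itertools.product((-1.0, 1.0), repeat=len(fixed)):
                x = np.zeros(k)
                x[fixed] = signs
                if free:
                    # gradient on free coords: g_f + H_ff x_f + H_fc x_c = 0
                    Hff = H[np.ix_(free, free)]
                    rhs = -(g[free] + H[np.ix_(free, fixed)] @ x[fixed])
                    try:
                        xf = np.linalg.solve(Hff, rhs)
                    except np.linalg.LinAlgError:
                        continue
                    if np.any(np.abs(xf) > 1.0 + 1e-9):
                        continue
                    x[free] = np.clip(xf, -1.0, 1.0)
                yv = self.predict(x)
                if yv > best_y:
                    best_x, best_y = x, yv
        return best_x

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Second-order response-surface fit",
            "=" * 48,
            f"runs: {self.model.design.n_runs}   parameters: {len(self.params)}",
            f"R2 = {self.r2:.4f}   adj R2 = {self.r2_adj:.4f}   "
            f"s = {self.residual_sd:.4g}",
            "",
            "coefficients (coded units):",
        ]
        for name, val in zip(self.model.param_names, self.params):
            lines.append(f"  {name:<6s} {val:12.4f}")
        try:
            an = self.anova()
            if an["f_undefined"]:
                lines += ["", "lack of fit: undefined (zero pure error)"]
            else:
                lines += [
                    "",
                    f"lack of fit: F = {an['f_lack_of_fit']:.4g} "
                    f"(df {an['df_lack_of_fit']}, {an['df_pure_error']}), "
                    f"p = {an['p_lack_of_fit']:.4g}",
                ]
        except DegenerateDesignError:
            pass
        sp = self.stationary_point()
        if sp.coded_point is not None:
            lines += [
                "",
                "stationary point (coded): "
                + np.array2string(sp.coded_point, precision=3),
                f"classification: {sp.classification}, inside region: "
                f"{sp.inside_region}",
            ]
        opt = ", ".join(
            f"{f.name} = {v:g} {f.units}"
            for f, v in zip(self.model.design.factors, sp.constrained_optimum_actual)
        )
        lines += [
            "constrained optimum: " + opt,
            f"predicted response at optimum: {sp.predicted_response_at_optimum:.1f}",
        ]
        return "\n".join(lines)


def results_from_coefficients(
    design: DesignMatrix,
    b0: float,
    linear,
    quadratic,
    interaction,
) -> ResponseSurfaceResults:
    """Build a ResponseSurfaceResults from known coefficients.

    Generates noise-free responses from the coefficients on the design and
    refits; OLS interpolates exactly, so the returned results carry the
    given coefficients and support the full canonical/constrained analysis.
    Useful for analysing a published fitted model without the raw data.
    """
    k = design.n_real_factors
    params = np.concatenate([[b0], linear, quadratic, interaction])
    X, _ = _quadratic_model_matrix(design.runs[:, :k])
    y = X @ params
    return ResponseSurfaceModel(design, y).fit()
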