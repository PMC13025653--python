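"""Box-Behnken response-surface methodology.

Design construction, coded-unit second-order least-squares fitting, ANOVA
with a lack-of-fit split from replicated centre runs, and multi-response
Derringer-Suich desirability optimization over the coded cube.

Conventions
-----------
Factors are coded to x = (actual - center) / ((high - low) / 2), so the
design levels are -1/0/+1 and regression coefficients are comparable
across factors.  The full second-order model in three factors has ten
terms, labelled ``Intercept, A, B, C, AB, AC, BC, A^2, B^2, C^2`` where
A, B, C are the factors in the order given.

Per-term sums of squares are *partial* (drop-one-term refit), which is
what response-surface software prints: on a Box-Behnken design the linear
and interaction columns are orthogonal (for those, partial SS equals the
sequential SS and, for linear terms, ``8 * coefficient**2``), but the
quadratic columns are not mutually orthogonal, so quadratic-term SS do
not sum to the model SS.  That non-additivity is expected.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import DesignError, DomainError, FitError

__all__ = [
    "FactorSpec",
    "DesignTable",
    "QuadraticFit",
    "AnovaReport",
    "DesirabilityGoal",
    "OptimizationResult",
    "TERM_NAMES",
    "generate_bbd",
    "code_point",
    "uncode_point",
    "model_matrix",
    "fit_quadratic",
    "anova",
    "predict",
    "optimize_desirability",
]

TERM_NAMES = ("Intercept", "A", "B", "C", "AB", "AC", "BC", "A^2", "B^2", "C^2")


@dataclass(frozen=True)
class FactorSpec:
    """One continuous factor with its low/centre/high levels in actual units."""

    name: str
    low: float
    center: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.center < self.high:
            raise DesignError(
                f"factor {self.name!r}: levels must satisfy low < center < high, "
                f"got {self.low}, {self.center}, {self.high}"
            )
        midpoint = 0.5 * (self.low + self.high)
        if abs(self.center - midpoint) > 1e-8 * max(1.0, abs(midpoint)):
            warnings.warn(
                f"factor {self.name!r}: center {self.center} is not the midpoint "
                f"{midpoint} of low/high; coded levels will be asymmetric",
                stacklevel=2,
            )

    @property
    def half_range(self) -> float:
        return 0.5 * (self.high - self.low)


def code_point(factors: Sequence[FactorSpec], actual: Sequence[float]) -> tuple[float, ...]:
    """Map a point in actual units to coded units (centre -> all zeros)."""
    return tuple((a - f.center) / f.half_range for f, a in zip(factors, actual, strict=True))


def uncode_point(factors: Sequence[FactorSpec], coded: Sequence[float]) -> tuple[float, ...]:
    """Inverse of :func:`code_point`."""
    return tuple(f.center + x * f.half_range for f, x in zip(factors, coded, strict=True))


@dataclass
class DesignTable:
    """A three-factor design with coded and actual run coordinates and responses.

    ``coded`` and ``actual`` are (n_runs, 3) arrays; ``responses`` maps a
    response name to its n_runs measurements.  Run order carries no
    meaning: all structural checks are multiset comparisons.
    """

    factors: tuple[FactorSpec, FactorSpec, FactorSpec]
    coded: np.ndarray
    actual: np.ndarray
    responses: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coded = np.atleast_2d(np.asarray(self.coded, dtype=float))
        self.actual = np.atleast_2d(np.asarray(self.actual, dtype=float))
        if len(self.factors) != 3:
            raise DesignError(f"exactly 3 factors required, got {len(self.factors)}")
        n = self.coded.shape[0]
        if self.coded.shape != (n, 3) or self.actual.shape != (n, 3):
            raise DesignError("coded and actual must both be (n_runs, 3)")
        recoded = np.array([code_point(self.factors, row) for row in self.actual])
        if not np.allclose(recoded, self.coded, atol=1e-6):
            raise DesignError("coded and actual coordinates disagree under the coding transform")
        self.responses = {k: np.asarray(v, dtype=float) for k, v in self.responses.items()}
        for name, vals in self.responses.items():
            if vals.shape != (n,):
                raise DesignError(f"response {name!r} has {vals.shape} values for {n} runs")

    @property
    def n_runs(self) -> int:
        return self.coded.shape[0]

    @property
    def center_mask(self) -> np.ndarray:
        return np.all(self.coded == 0.0, axis=1)

    def validate_bbd(self) -> None:
        """Check the 12-edge + centre Box-Behnken structure (as a multiset)."""
        centers = int(self.center_mask.sum())
        edges = self.coded[~self.center_mask]
        if centers < 1:
            raise DesignError("Box-Behnken design requires at least one centre run")
        expected = sorted(map(tuple, _bbd_edge_runs()))
        got = sorted(map(tuple, np.round(edges, 6)))
        if got != expected:
            raise DesignError(
                "non-centre runs do not form the standard 3-factor Box-Behnken edge set"
            )

    def to_frame(self) -> pd.DataFrame:
        """Actual-unit run table with one column per factor and response."""
        data = {f.name: self.actual[:, i] for i, f in enumerate(self.factors)}
        data.update(self.responses)
        return pd.DataFrame(data)


def _bbd_edge_runs() -> np.ndarray:
    runs = []
    for i, j in itertools.combinations(range(3), 2):
        for si, sj in itertools.product((-1.0, 1.0), repeat=2):
            row = [0.0, 0.0, 0.0]
            row[i], row[j] = si, sj
            runs.append(row)
    return np.array(runs)


def generate_bbd(factors: Sequence[FactorSpec], n_center: int = 5) -> DesignTable:
    """Construct the standard 3-factor Box-Behnken design.

    Twelve edge-midpoint runs (each with one factor at the centre and the
    other two at +/-1) followed by ``n_center`` replicated centre runs.
    """
    if len(factors) != 3:
        raise DesignError(f"only 3-factor Box-Behnken designs are supported, got {len(factors)}")
    if n_center < 1:
        raise DesignError("n_center must be at least 1")
    coded = np.vstack([_bbd_edge_runs(), np.zeros((n_center, 3))])
    actual = np.array([uncode_point(factors, row) for row in coded])
    return DesignTable(tuple(factors), coded, actual)


def model_matrix(coded: np.ndarray) -> np.ndarray:
    """Design matrix of the full second-order model, columns in ``TERM_NAMES`` order."""
    coded = np.atleast_2d(np.asarray(coded, dtype=float))
    a, b, c = coded[:, 0], coded[:, 1], coded[:, 2]
    return np.column_stack(
        [np.ones_like(a), a, b, c, a * b, a * c, b * c, a * a, b * b, c * c]
    )


@dataclass(frozen=True)
class QuadraticFit:
    """A fitted ten-term second-order model in coded units."""

    response_name: str
    coefficients: np.ndarray  # length 10, TERM_NAMES order
    residual_ss: float
    total_ss: float  # corrected (about the grand mean)
    grand_mean: float
    n_runs: int
    response_min: float
    response_max: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "coefficients", np.asarray(self.coefficients, dtype=float))
        if self.residual_ss < -1e-9:
            raise FitError("residual sum of squares cannot be negative")
        if self.total_ss + 1e-9 < self.residual_ss:
            raise FitError("total SS cannot be smaller than residual SS")

    @property
    def model_ss(self) -> float:
        return self.total_ss - self.residual_ss

    @property
    def df_residual(self) -> int:
        return self.n_runs - 10

    def equation(self, decimals: int = 2) -> str:
        """Human-readable coded-unit equation, coefficients rounded for display."""
        terms = [f"{self.coefficients[0]:.{decimals}f}"]
        for name, coef in zip(TERM_NAMES[1:], self.coefficients[1:]):
            sign = "+" if coef >= 0 else "-"
            terms.append(f"{sign} {abs(coef):.{decimals}f} {name}")
        return f"{self.response_name} = " + " ".join(terms)


def fit_quadratic(design: DesignTable, response_name: str) -> QuadraticFit:
    """Ordinary least squares of the full second-order model on coded factors."""
    if response_name not in design.responses:
        raise FitError(
            f"response {response_name!r} not in design (have {sorted(design.responses)})"
        )
    y = design.responses[response_name]
    if design.n_runs < 10:
        raise FitError(f"need at least 10 runs to fit 10 terms, have {design.n_runs}")
    X = model_matrix(design.coded)
    if np.linalg.matrix_rank(X) < 10:
        raise FitError("design matrix is rank-deficient for the second-order model")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return QuadraticFit(
        response_name=response_name,
        coefficients=beta,
        residual_ss=float(resid @ resid),
        total_ss=float(np.sum((y - y.mean()) ** 2)),
        grand_mean=float(y.mean()),
        n_runs=design.n_runs,
        response_min=float(y.min()),
        response_max=float(y.max()),
    )


def predict(fit: QuadraticFit, point_coded: Sequence[float]) -> float:
    """Evaluate the fitted polynomial at a coded point; the intercept at the centre."""
    x = model_matrix(np.asarray(point_coded, dtype=float).reshape(1, 3))
    return float((x @ fit.coefficients)[0])


def format_p(p: float, threshold: float = 1e-4) -> str:
    """Display convention of response-surface software: tiny p as '<0.0001'."""
    return f"<{threshold:.4f}" if p < threshold else f"{p:.4f}"


@dataclass
class AnovaReport:
    """Per-term ANOVA with lack-of-fit split and fit statistics.

    ``table`` has columns Source, SS, Df, MS, F, p; rows are the model,
    the nine individual terms, residual, lack of fit, pure error and the
    corrected total.  F for each term uses the full-model residual mean
    square; the lack-of-fit F uses the pure-error mean square.
    """

    response_name: str
    table: pd.DataFrame
    r2: float
    r2_adj: float
    cv_percent: float
    has_lof: bool

    def row(self, source: str) -> pd.Series:
        hit = self.table[self.table["Source"] == source]
        if hit.empty:
            raise KeyError(f"no ANOVA row named {source!r}")
        return hit.iloc[0]


def anova(fit: QuadraticFit, design: DesignTable) -> AnovaReport:
    """ANOVA of a second-order fit with partial (drop-one-term) sums of squares.

    Pure error is pooled from all replicated coded points (for a
    Box-Behnken design, the centre runs); lack of fit is the residual
    left over.  Without replicates the report is returned with a warning
    and no lack-of-fit split.
    """
    y = design.responses[fit.response_name]
    X = model_matrix(design.coded)
    n = design.n_runs
    rss = fit.residual_ss
    tss = fit.total_ss
    mss = tss - rss
    df_model, df_resid = 9, n - 10
    if df_resid <= 0:
        raise FitError("no residual degrees of freedom; cannot build an ANOVA table")
    ms_resid = rss / df_resid

    rows = [("Model", mss, df_model, mss / df_model,
             (mss / df_model) / ms_resid,
             stats.f.sf((mss / df_model) / ms_resid, df_model, df_resid))]
    for j, name in enumerate(TERM_NAMES[1:], start=1):
        Xd = np.delete(X, j, axis=1)
        beta_d, _, _, _ = np.linalg.lstsq(Xd, y, rcond=None)
        resid_d = y - Xd @ beta_d
        ss_term = float(resid_d @ resid_d) - rss
        f_term = ss_term / ms_resid
        rows.append((name, ss_term, 1, ss_term, f_term, stats.f.sf(f_term, 1, df_resid)))
    rows.append(("Residual", rss, df_resid, ms_resid, np.nan, np.nan))

    # pure error pooled over replicated coded points
    keys = [tuple(np.round(r, 6)) for r in design.coded]
    groups: dict[tuple, list[int]] = {}
    for i, k in enumerate(keys):
        groups.setdefault(k, []).append(i)
    pe_ss, pe_df = 0.0, 0
    for idx in groups.values():
        if len(idx) > 1:
            vals = y[idx]
            pe_ss += float(np.sum((vals - vals.mean()) ** 2))
            pe_df += len(idx) - 1
    has_lof = pe_df > 0
    if has_lof:
        lof_ss = rss - pe_ss
        lof_df = df_resid - pe_df
        if lof_df > 0:
            lof_ms, pe_ms = lof_ss / lof_df, pe_ss / pe_df
            if pe_ms > 0:
                f_lof = lof_ms / pe_ms
            else:  # exact replicates (e.g. noiseless synthetic data)
                f_lof = np.inf if lof_ms > 0 else np.nan
            rows.append(("Lack of fit", lof_ss, lof_df, lof_ms, f_lof,
                         stats.f.sf(f_lof, lof_df, pe_df) if np.isfinite(f_lof) else np.nan))
            rows.append(("Pure error", pe_ss, pe_df, pe_ms, np.nan, np.nan))
        else:
            has_lof = False
    if not has_lof:
        warnings.warn(
            f"response {fit.response_name!r}: no replicate runs (or no lack-of-fit df); "
            "residual error cannot be split",
            stacklevel=2,
        )
    rows.append(("Cor total", tss, n - 1, np.nan, np.nan, np.nan))

    table = pd.DataFrame(rows, columns=["Source", "SS", "Df", "MS", "F", "p"])
    return AnovaReport(
        response_name=fit.response_name,
        table=table,
        r2=mss / tss,
        r2_adj=1.0 - ms_resid / (tss / (n - 1)),
        cv_percent=100.0 * np.sqrt(ms_resid) / fit.grand_mean,
        has_lof=has_lof,
    )


@dataclass(frozen=True)
class DesirabilityGoal:
    """Per-response Derringer-Suich goal.

    ``direction`` is "maximize" or "minimize"; ``low``/``high`` anchor the
    linear desirability ramp (default: the response's observed range in
    the design, so the best observed value already scores 1).
    """

    direction: str = "maximize"
    low: float | None = None
    high: float | None = None
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.direction not in ("maximize", "minimize"):
            raise DomainError(f"unknown goal direction {self.direction!r}")
        if self.weight <= 0:
            raise DomainError("goal weight must be positive")

    def desirability(self, value: float, observed_min: float, observed_max: float) -> float:
        lo = self.low if self.low is not None else observed_min
        hi = self.high if self.high is not None else observed_max
        if hi <= lo:
            raise DomainError("desirability anchors must satisfy low < high")
        d = (value - lo) / (hi - lo)
        if self.direction == "minimize":
            d = 1.0 - d
        return float(np.clip(d, 0.0, 1.0))


@dataclass(frozen=True)
class OptimizationResult:
    """Argmax of the overall desirability over the coded cube."""

    point_coded: tuple[float, float, float]
    point_actual: tuple[float, float, float]
    predicted_responses: dict[str, float]
    desirability: float


def optimize_desirability(
    fits: Sequence[QuadraticFit],
    factors: Sequence[FactorSpec],
    goals: Mapping[str, DesirabilityGoal] | None = None,
    starts: Sequence[Sequence[float]] | None = None,
) -> OptimizationResult:
    """Maximise the weighted geometric-mean desirability over [-1, 1]^3.

    The overall desirability is D = (prod d_i^w_i)^(1/sum w_i) over the
    fitted responses, each d_i a linear ramp between its anchors.  D is
    multiplied through a common power by rescaling all weights, so the
    argmax is invariant to that.  The search is a deterministic
    multi-start: bounded L-BFGS-B from the 27-point {-1, 0, 1}^3 grid
    (the centre included), keeping the best converged point.
    """
    fits = list(fits)
    if not fits:
        raise DomainError("at least one fitted response is required")
    goals = dict(goals or {})
    for f in fits:
        goals.setdefault(f.response_name, DesirabilityGoal())
    total_w = sum(goals[f.response_name].weight for f in fits)

    def overall(point: np.ndarray) -> float:
        log_d = 0.0
        for f in fits:
            g = goals[f.response_name]
            d = g.desirability(predict(f, point), f.response_min, f.response_max)
            if d <= 0.0:
                return 0.0
            log_d += g.weight * np.log(d)
        return float(np.exp(log_d / total_w))

    if starts is None:
        starts = list(itertools.product((-1.0, 0.0, 1.0), repeat=3))
    best_x, best_d = np.zeros(3), -np.inf
    for x0 in starts:
        res = optimize.minimize(
            lambda x: -overall(x),
            np.asarray(x0, dtype=float),
            method="L-BFGS-B",
            bounds=[(-1.0, 1.0)] * 3,
        )
        d = -res.fun
        if d > best_d:
            best_d, best_x = d, res.x
    point_coded = tuple(float(v) for v in best_x)
    return OptimizationResult(
        point_coded=point_coded,
        point_actual=uncode_point(factors, point_coded),
        predicted_responses={f.response_name: predict(f, best_x) for f in fits},
        desirability=float(best_d),
    )
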