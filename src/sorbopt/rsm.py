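"""Quadratic response-surface fitting, ANOVA and standardized effects.

The full second-order model in coded units for factors ``x1..xN`` is

    y = b0 + sum_i bi xi + sum_i bii xi^2 + sum_{i<j} bij xi xj + e,

fit by ordinary least squares.  For the 15-run three-factor Box-Behnken
design the basis has 10 terms and 5 residual degrees of freedom.  The
ANOVA mirrors the layout common in DoE software: per-term adjusted
(extra) sums of squares, grouped Linear / Square / 2-Way Interaction
rows, and a split of the residual into lack-of-fit (between distinct
design points) and pure error (within replicate groups).  Standardized
effects are the coefficient t-statistics that drive Pareto charts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .design import DesignTable
from .errors import SingularDesignError, ValidationError

__all__ = [
    "QuadraticModel",
    "FitSummary",
    "AnovaRow",
    "AnovaTable",
    "EffectsTable",
    "term_names",
    "quadratic_basis",
    "fit_quadratic",
    "predict",
    "anova",
    "standardized_effects",
    "effects_grid",
]

log = logging.getLogger(__name__)


def term_names(factor_names: Sequence[str]) -> list[str]:
    """Canonical term order: intercept, linear, squares, pairwise interactions."""
    names = list(factor_names)
    terms = ["Intercept"] + names
    terms += [f"{n}*{n}" for n in names]
    n = len(names)
    terms += [f"{names[i]}*{names[j]}" for i in range(n) for j in range(i + 1, n)]
    return terms


def quadratic_basis(coded: np.ndarray) -> np.ndarray:
    """Design matrix of the full quadratic basis at coded points (m, N)."""
    coded = np.atleast_2d(np.asarray(coded, dtype=float))
    m, n = coded.shape
    cols = [np.ones(m)]
    cols += [coded[:, i] for i in range(n)]
    cols += [coded[:, i] ** 2 for i in range(n)]
    cols += [coded[:, i] * coded[:, j] for i in range(n) for j in range(i + 1, n)]
    return np.column_stack(cols)


@dataclass
class QuadraticModel:
    """Fitted coded second-order surface.

    ``coefficients`` follow the canonical term order of
    :func:`term_names`; ``xtx_inv`` is the unscaled coefficient
    covariance ``(X'X)^-1`` needed for standard errors.
    """

    factor_names: tuple[str, ...]
    coefficients: np.ndarray
    residual_df: int | None = None
    residual_ss: float | None = None
    xtx_inv: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.factor_names = tuple(self.factor_names)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        n = len(self.factor_names)
        expected = 1 + 2 * n + n * (n - 1) // 2
        if self.coefficients.shape != (expected,):
            raise ValidationError(
                f"{n} factors require {expected} coefficients, got {self.coefficients.shape}"
            )

    @property
    def terms(self) -> list[str]:
        return term_names(self.factor_names)

    @property
    def coef(self) -> dict[str, float]:
        return dict(zip(self.terms, self.coefficients))

    @property
    def mse(self) -> float | None:
        if self.residual_ss is None or not self.residual_df:
            return None
        return self.residual_ss / self.residual_df

    def predict(self, point) -> np.ndarray | float:
        return predict(self, point)


@dataclass
class FitSummary:
    """Per-run diagnostics of one least-squares fit."""

    fitted: np.ndarray
    residuals: np.ndarray
    r_squared: float
    adj_r_squared: float


def fit_quadratic(design: DesignTable) -> tuple[QuadraticModel, FitSummary]:
    """Ordinary least squares of the full quadratic model on a coded design.

    Requires responses and at least as many runs as basis terms; raises
    :class:`SingularDesignError` naming the collinear columns when the
    basis is rank deficient.
    """
    if design.responses is None:
        raise ValidationError("design has no responses to fit")
    y = design.responses
    X = quadratic_basis(design.coded)
    terms = term_names(design.factor_names)
    n, p = X.shape
    if n < p:
        raise ValidationError(f"need >= {p} runs to fit {p} terms, got {n}")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name the offending columns via the QR diagonal
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = [terms[i] for i in np.nonzero(diag < 1e-9 * diag.max())[0]]
        raise SingularDesignError(
            f"design matrix is rank deficient (rank {rank} < {p}); "
            f"collinear columns: {bad or 'unidentified'}"
        )
    res = sm.OLS(y, X).fit()
    model = QuadraticModel(
        factor_names=design.factor_names,
        coefficients=np.asarray(res.params, dtype=float),
        residual_df=int(res.df_resid),
        residual_ss=float(res.ssr),
        xtx_inv=np.asarray(res.normalized_cov_params, dtype=float),
    )
    # centred R^2; guard the zero-variance corner case
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(res.ssr) / sst if sst > 0 else 1.0
    dfe, dft = int(res.df_resid), n - 1
    adj = 1.0 - (float(res.ssr) / dfe) / (sst / dft) if sst > 0 and dfe > 0 else r2
    summary = FitSummary(
        fitted=np.asarray(res.fittedvalues, dtype=float),
        residuals=np.asarray(res.resid, dtype=float),
        r_squared=r2,
        adj_r_squared=adj,
    )
    return model, summary


def predict(model: QuadraticModel, point) -> np.ndarray | float:
    """Evaluate the quadratic surface at one coded point or an (m, N) array.

    Points outside the [-1, 1] cube are evaluated anyway but logged as
    extrapolation.
    """
    arr = np.asarray(point, dtype=float)
    single = arr.ndim == 1
    pts = np.atleast_2d(arr)
    if np.any(np.abs(pts) > 1.0 + 1e-12):
        log.info("predict: %d point(s) outside the coded [-1,1] cube (extrapolation)",
                 int(np.sum(np.any(np.abs(pts) > 1.0 + 1e-12, axis=1))))
    out = quadratic_basis(pts) @ model.coefficients
    return float(out[0]) if single else out


@dataclass
class AnovaRow:
    source: str
    df: int
    adj_ss: float
    adj_ms: float | None
    f: float | None
    p: float | None


@dataclass
class AnovaTable:
    """Ordered ANOVA rows keyed by source name."""

    rows: dict[str, AnovaRow]

    def __getitem__(self, source: str) -> AnovaRow:
        return self.rows[source]

    def __contains__(self, source: str) -> bool:
        return source in self.rows

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "Source": r.source,
                    "DF": r.df,
                    "AdjSS": r.adj_ss,
                    "AdjMS": r.adj_ms,
                    "F": r.f,
                    "p": r.p,
                }
                for r in self.rows.values()
            ]
        )


def _extra_ss(X: np.ndarray, y: np.ndarray, sse_full: float, drop: Sequence[int]) -> float:
    """Extra sum of squares of the dropped columns (full vs reduced SSE)."""
    Xr = np.delete(X, list(drop), axis=1)
    _, res, _, _ = np.linalg.lstsq(Xr, y, rcond=None)
    sse_r = float(res[0]) if res.size else float(((y - Xr @ np.linalg.lstsq(Xr, y, rcond=None)[0]) ** 2).sum())
    ss = sse_r - sse_full
    if ss < -1e-8 * max(1.0, sse_r):
        raise ArithmeticError(f"negative extra SS ({ss}) for columns {drop}")
    return max(ss, 0.0)


def _f_p(ss: float, df: int, mse: float, df_err: int) -> tuple[float | None, float | None]:
    if df <= 0 or df_err <= 0:
        return None, None
    ms = ss / df
    if mse == 0.0:
        return float("inf"), float("nan")
    f = ms / mse
    return f, float(stats.f.sf(f, df, df_err))


def anova(model: QuadraticModel, design: DesignTable) -> AnovaTable:
    """Minitab-style ANOVA of a fitted quadratic model.

    Adjusted SS is the extra sum of squares of each term (or term group)
    given all others — for grouped rows the whole group is dropped at
    once.  On an orthogonal coded BBD the per-term values coincide with
    sequential SS.  The residual is split into lack-of-fit (tested
    against pure error) and pure error over replicate groups; with no
    replicates those rows are omitted and a note is logged.
    """
    if design.responses is None:
        raise ValidationError("design has no responses")
    y = design.responses
    X = quadratic_basis(design.coded)
    terms = term_names(design.factor_names)
    n, p = X.shape
    nf = len(design.factor_names)
    sse = float(((y - X @ model.coefficients) ** 2).sum())
    sst = float(((y - y.mean()) ** 2).sum())
    if sse < 1e-14 * (1.0 + sst):  # exact interpolation up to round-off
        sse = 0.0
    df_err = n - p
    mse = sse / df_err if df_err > 0 else 0.0
    ssr = sst - sse

    lin_idx = list(range(1, 1 + nf))
    sq_idx = list(range(1 + nf, 1 + 2 * nf))
    int_idx = list(range(1 + 2 * nf, p))

    rows: dict[str, AnovaRow] = {}

    def add(source: str, ss: float, df: int, f: float | None = None, p_: float | None = None,
            with_test: bool = True) -> None:
        ms = ss / df if df > 0 else None
        if with_test and f is None:
            f, p_ = _f_p(ss, df, mse, df_err)
        rows[source] = AnovaRow(source, df, ss, ms, f, p_)

    add("Model", ssr, p - 1)
    add("Linear", _extra_ss(X, y, sse, lin_idx), nf)
    for k in lin_idx:
        add(terms[k], _extra_ss(X, y, sse, [k]), 1)
    add("Square", _extra_ss(X, y, sse, sq_idx), nf)
    for k in sq_idx:
        add(terms[k], _extra_ss(X, y, sse, [k]), 1)
    add("2-Way Interaction", _extra_ss(X, y, sse, int_idx), len(int_idx))
    for k in int_idx:
        add(terms[k], _extra_ss(X, y, sse, [k]), 1)
    add("Error", sse, df_err, with_test=False)

    # pure error over replicate groups (identical coded rows)
    groups: dict[tuple, list[int]] = {}
    for i, row in enumerate(np.round(design.coded, 12)):
        groups.setdefault(tuple(row), []).append(i)
    ss_pe = sum(
        float(((y[idx] - y[idx].mean()) ** 2).sum())
        for idx in (np.asarray(g) for g in groups.values())
        if len(idx) > 1
    )
    df_pe = n - len(groups)
    if df_pe > 0:
        ss_lof = max(sse - ss_pe, 0.0)
        df_lof = df_err - df_pe
        ms_pe = ss_pe / df_pe
        if df_lof > 0:
            if ms_pe == 0.0:
                f_lof, p_lof = float("inf"), float("nan")
            else:
                f_lof = (ss_lof / df_lof) / ms_pe
                p_lof = float(stats.f.sf(f_lof, df_lof, df_pe))
            rows["Lack-of-Fit"] = AnovaRow("Lack-of-Fit", df_lof, ss_lof, ss_lof / df_lof, f_lof, p_lof)
        rows["Pure Error"] = AnovaRow("Pure Error", df_pe, ss_pe, ms_pe, None, None)
    else:
        log.info("anova: no replicate runs; lack-of-fit / pure-error rows omitted")
    rows["Total"] = AnovaRow("Total", n - 1, sst, None, None, None)
    return AnovaTable(rows)


@dataclass
class EffectRow:
    term: str
    coefficient: float
    std_error: float
    t: float
    significant: bool


@dataclass
class EffectsTable:
    """Standardized effects ranked by |t|, with the t critical value."""

    rows: list[EffectRow]
    alpha: float
    threshold: float | None

    def order(self) -> list[str]:
        return [r.term for r in self.rows]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "term": r.term,
                    "coefficient": r.coefficient,
                    "std_error": r.std_error,
                    "t": r.t,
                    "significant": r.significant,
                }
                for r in self.rows
            ]
        )


def standardized_effects(model: QuadraticModel, alpha: float = 0.05) -> EffectsTable:
    """Coefficient t-statistics (Pareto-chart ordinates), sorted by |t|.

    ``t = coefficient / se`` with ``se = sqrt(MS_error * (X'X)^-1_kk)``.
    The significance threshold is the two-sided t critical value at
    ``alpha`` with the residual df; with zero residual variance every t
    is infinite and no threshold is reported.
    """
    if model.xtx_inv is None or model.residual_df is None or model.residual_ss is None:
        raise ValidationError("model lacks fit covariance information (refit required)")
    if model.residual_df < 1:
        raise ValidationError("standardized effects need residual df >= 1")
    residual_ss = model.residual_ss
    if residual_ss < 1e-14 * (1.0 + float(np.sum(model.coefficients**2))):
        residual_ss = 0.0  # exact interpolation up to round-off
    mse = residual_ss / model.residual_df
    terms = model.terms
    rows = []
    for k in range(1, len(terms)):  # intercept excluded from the ranking
        se = float(np.sqrt(mse * model.xtx_inv[k, k])) if mse > 0 else 0.0
        coefk = float(model.coefficients[k])
        t = coefk / se if se > 0 else float("inf") * np.sign(coefk or 1.0)
        rows.append((terms[k], coefk, se, t))
    if mse > 0:
        threshold = float(stats.t.ppf(1 - alpha / 2, model.residual_df))
    else:
        threshold = None
    rows.sort(key=lambda r: abs(r[3]), reverse=True)
    out = [
        EffectRow(term, coefk, se, t,
                  bool(threshold is None or abs(t) > threshold))
        for term, coefk, se, t in rows
    ]
    return EffectsTable(rows=out, alpha=alpha, threshold=threshold)


def effects_grid(
    model: QuadraticModel,
    held_factor: int | str,
    held_value: float = 0.0,
    grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Predictions over a coded grid of the two free factors.

    Rows index the first free factor, columns the second; the held
    factor is fixed at ``held_value``.  The frame serializes to CSV for
    external surface/contour plotting.
    """
    if isinstance(held_factor, str):
        held = model.factor_names.index(held_factor)
    else:
        held = int(held_factor)
    free = [i for i in range(len(model.factor_names)) if i != held]
    if grid is None:
        grid = np.linspace(-1.0, 1.0, 41)
    grid = np.asarray(grid, dtype=float)
    a, b = np.meshgrid(grid, grid, indexing="ij")
    pts = np.zeros((a.size, len(model.factor_names)))
    pts[:, free[0]] = a.ravel()
    pts[:, free[1]] = b.ravel()
    pts[:, held] = held_value
    z = predict(model, pts).reshape(a.shape)
    return pd.DataFrame(
        z,
        index=pd.Index(grid, name=model.factor_names[free[0]]),
        columns=pd.Index(grid, name=model.factor_names[free[1]]),
    )
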