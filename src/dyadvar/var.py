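"""Autocorrelation, AR, and pooled VAR estimation with residual diagnostics.

The estimation target is a VAR(p) over the m monthly behavior series,

    x(t) = c + B(1) x(t-1) + ... + B(p) x(t-p) + eps(t),

fit by per-equation ordinary least squares on a pooled design: lagged
predictors are built WITHIN each dyad (no lag pair spans a dyad
boundary) and stacked, with one common intercept per equation. A model
is admissible when its residuals show no serial correlation
(multivariate Portmanteau), no conditional heteroscedasticity
(multivariate ARCH-LM), and the companion matrix is stable; the lag
order is raised until the residuals meet these requirements.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import (
    ConvergenceError,
    DegenerateSeriesError,
    EstimationError,
)
from .panel import MonthlyPanel


# ---------------------------------------------------------------------------
# autocorrelation and univariate AR
# ---------------------------------------------------------------------------

def acf(series: np.ndarray, max_lag: int | None = None) -> np.ndarray:
    """Lag-indexed autocorrelation weights of a single series.

    The weight at lag j is the sample Pearson correlation between the
    overlapping pairs (x(t), x(t-j)) — i.e. how well values j steps back
    predict current values. A full-length call on a length-N series
    returns exactly N-1 weights (lags 1..N-1); lags whose overlap window
    is degenerate (constant, or a single pair) get NaN.
    """
    x = np.asarray(series, dtype=float).ravel()
    n = x.size
    if n < 2:
        raise ValueError("series must have length >= 2")
    if np.ptp(x) == 0:
        raise DegenerateSeriesError("constant series has undefined autocorrelation")
    if max_lag is None:
        max_lag = n - 1
    if not 1 <= max_lag <= n - 1:
        raise ValueError(f"max_lag must be in 1..{n - 1}")
    out = np.full(max_lag, np.nan)
    for j in range(1, max_lag + 1):
        a, b = x[j:], x[:-j]
        if a.size < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
            continue
        out[j - 1] = np.corrcoef(a, b)[0, 1]
    return out


@dataclasses.dataclass
class ARModel:
    """Least-squares AR(p) fit of a single series."""

    mean: float                 # intercept
    p: int
    coefficients: np.ndarray    # B_1..B_p
    residuals: np.ndarray       # length N - p
    residual_variance: float

    def predict_in_sample(self, series: np.ndarray) -> np.ndarray:
        x = np.asarray(series, dtype=float)
        X = _lag_design(x[:, None], self.p)[0]
        return X @ np.concatenate([[self.mean], self.coefficients])


def fit_ar(series: np.ndarray, p: int) -> ARModel:
    """Fit AR(p) by OLS with intercept; residuals have length N - p."""
    x = np.asarray(series, dtype=float).ravel()
    n = x.size
    if p < 1:
        raise ValueError("p must be >= 1")
    if p >= n:
        raise ValueError(f"p={p} leaves no usable rows for N={n}")
    if n <= p + 2:
        raise ValueError(f"need N > p + 2 (got N={n}, p={p})")
    if np.ptp(x) == 0:
        raise DegenerateSeriesError("constant series cannot be autoregressed")
    X, y = _lag_design(x[:, None], p)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = (y - X @ beta).ravel()
    dof = max(resid.size - (p + 1), 1)
    return ARModel(
        mean=float(beta[0, 0]),
        p=p,
        coefficients=beta[1:, 0].copy(),
        residuals=resid,
        residual_variance=float(resid @ resid / dof),
    )


def _lag_design(values: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Within-series lagged design: rows t = p..T-1, columns [1, x(t-1)..x(t-p)]."""
    t_len, m = values.shape
    y = values[p:]
    cols = [np.ones((t_len - p, 1))]
    for j in range(1, p + 1):
        cols.append(values[p - j : t_len - j])
    return np.hstack(cols), y


# ---------------------------------------------------------------------------
# pooled VAR
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class VARModel:
    """Pooled VAR(p): common intercepts and lag matrices across dyads.

    ``coef_matrices[j-1][i, k]`` is the weight of x_k(t-j) in the
    equation for x_i(t). Residual rows are stacked dyad-by-dyad in time
    order; ``dyad_row_counts`` records how many rows each dyad
    contributed so diagnostics never form lag products across a dyad
    boundary.
    """

    variables: list[str]
    p: int
    intercepts: np.ndarray          # (m,)
    coef_matrices: np.ndarray       # (p, m, m)
    residuals: np.ndarray           # (n_rows, m)
    sigma: np.ndarray               # (m, m), dof-adjusted residual covariance
    dyad_ids: list[str]
    dyad_row_counts: np.ndarray     # rows contributed per dyad

    @property
    def m(self) -> int:
        return len(self.variables)

    @property
    def n_rows(self) -> int:
        return self.residuals.shape[0]

    def companion_matrix(self) -> np.ndarray:
        m, p = self.m, self.p
        comp = np.zeros((m * p, m * p))
        comp[:m] = np.hstack(list(self.coef_matrices))
        if p > 1:
            comp[m:, : m * (p - 1)] = np.eye(m * (p - 1))
        return comp

    def companion_eigenvalues(self) -> np.ndarray:
        return np.linalg.eigvals(self.companion_matrix())

    @property
    def stable(self) -> bool:
        return bool(np.max(np.abs(self.companion_eigenvalues())) < 1.0)

    def residual_blocks(self) -> list[np.ndarray]:
        """Per-dyad residual blocks in stacking order."""
        idx = np.concatenate([[0], np.cumsum(self.dyad_row_counts)])
        return [self.residuals[idx[i] : idx[i + 1]] for i in range(len(self.dyad_row_counts))]

    def reorder(self, order: Sequence[str]) -> "VARModel":
        """Permute the model's variables (coefficients, Sigma, residuals)."""
        if sorted(order) != sorted(self.variables):
            raise ValueError("order must be a permutation of the model variables")
        idx = np.array([self.variables.index(v) for v in order])
        return VARModel(
            variables=list(order),
            p=self.p,
            intercepts=self.intercepts[idx],
            coef_matrices=self.coef_matrices[:, idx][:, :, idx],
            residuals=self.residuals[:, idx],
            sigma=self.sigma[np.ix_(idx, idx)],
            dyad_ids=list(self.dyad_ids),
            dyad_row_counts=self.dyad_row_counts.copy(),
        )

    def to_dict(self) -> dict:
        return {
            "variables": list(self.variables),
            "p": int(self.p),
            "intercepts": self.intercepts.tolist(),
            "coef_matrices": self.coef_matrices.tolist(),
            "sigma": self.sigma.tolist(),
            "dyad_ids": list(self.dyad_ids),
            "dyad_row_counts": self.dyad_row_counts.tolist(),
            "max_eigenvalue_modulus": float(np.max(np.abs(self.companion_eigenvalues()))),
        }


def pooled_design(panel: MonthlyPanel, p: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stacked within-dyad lagged design.

    Returns (X, Y, rows_per_dyad): X has columns [1, lag-1 block, ...,
    lag-p block]; each dyad contributes n_months - p rows.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    if panel.n_months <= p:
        raise EstimationError(
            f"per-dyad series length {panel.n_months} must exceed lag order p={p}"
        )
    xs, ys = [], []
    for d in range(panel.n_dyads):
        X_d, y_d = _lag_design(panel.values[d], p)
        xs.append(X_d)
        ys.append(y_d)
    X = np.vstack(xs)
    Y = np.vstack(ys)
    rows = np.full(panel.n_dyads, panel.n_months - p)
    return X, Y, rows


def fit_var(panel: MonthlyPanel, p: int) -> VARModel:
    """Fit a pooled VAR(p) to a monthly panel by per-equation OLS.

    Lagged predictors are built within each dyad and stacked; a single
    intercept per equation is shared across dyads. The residual
    covariance uses the degrees-of-freedom-adjusted denominator
    rows - m*p - 1.
    """
    m = panel.m
    X, Y, rows = pooled_design(panel, p)
    n = X.shape[0]
    if n <= m * p + 1:
        raise EstimationError(
            f"insufficient pooled rows ({n}) for {m * p + 1} parameters per equation"
        )
    # constant panel columns make the design rank-deficient; name the code
    spans = np.ptp(panel.values.reshape(-1, m), axis=0)
    if (spans == 0).any():
        const = [panel.variables[j] for j in np.flatnonzero(spans == 0)]
        raise EstimationError(f"constant column(s) {const}: rank-deficient design")
    beta, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    if rank < X.shape[1]:
        raise EstimationError(f"rank-deficient design (rank {rank} < {X.shape[1]})")
    E = Y - X @ beta
    dof = n - m * p - 1
    sigma = E.T @ E / dof
    coef = np.stack([beta[1 + j * m : 1 + (j + 1) * m].T for j in range(p)])
    return VARModel(
        variables=list(panel.variables),
        p=p,
        intercepts=beta[0].copy(),
        coef_matrices=coef,
        residuals=E,
        sigma=sigma,
        dyad_ids=list(panel.dyad_ids),
        dyad_row_counts=rows,
    )


# ---------------------------------------------------------------------------
# residual diagnostics
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TestResult:
    name: str
    statistic: float
    df: int
    p_value: float

    def passes(self, alpha: float = 0.05) -> bool:
        return self.p_value > alpha


def _lagged_cross_products(blocks: list[np.ndarray], j: int) -> tuple[np.ndarray, int]:
    """Sum over dyads of sum_t e_t e_{t-j}', never crossing a boundary."""
    m = blocks[0].shape[1]
    acc = np.zeros((m, m))
    pairs = 0
    for e in blocks:
        if e.shape[0] > j:
            acc += e[j:].T @ e[:-j] if j > 0 else e.T @ e
            pairs += e.shape[0] - j
    return acc, pairs


def portmanteau_test(model: VARModel, h: int | None = None) -> TestResult:
    """Multivariate Portmanteau (Ljung-Box-weighted) test for residual
    serial correlation.

    Q = n^2 * sum_{j=1..h} tr(C_j' C_0^{-1} C_j C_0^{-1}) / n_j, where
    C_j are residual lag-j autocovariances pooled within dyads, n the
    total residual rows and n_j the number of lag-j pairs. Under white
    residuals Q ~ chi^2 with m^2 (h - p) degrees of freedom.
    """
    if h is None:
        h = max(model.p + 1, min(8, model.n_rows // 2))
    if h <= model.p:
        raise ValueError(f"h={h} must exceed the lag order p={model.p}")
    blocks = [e - model.residuals.mean(axis=0) for e in model.residual_blocks()]
    n = model.n_rows
    c0, _ = _lagged_cross_products(blocks, 0)
    c0 /= n
    c0_inv = np.linalg.inv(c0)
    q = 0.0
    for j in range(1, h + 1):
        cj, pairs = _lagged_cross_products(blocks, j)
        if pairs == 0:
            raise EstimationError(f"no lag-{j} residual pairs; reduce h")
        cj /= n
        q += np.trace(cj.T @ c0_inv @ cj @ c0_inv) / pairs
    q *= n * n
    df = model.m ** 2 * (h - model.p)
    return TestResult("portmanteau", float(q), df, float(stats.chi2.sf(q, df)))


def arch_lm_test(model: VARModel, q: int = 4) -> TestResult:
    """Multivariate ARCH-LM test for residual heteroscedasticity.

    Regresses vech(e_t e_t') on q within-dyad lags of itself; the LM
    statistic (1/2) n m (m+1) R_m^2 with R_m^2 = 1 - 2 tr(Omega
    Omega_0^{-1}) / (m (m+1)) is chi^2 with q m^2 (m+1)^2 / 4 degrees of
    freedom under homoscedastic residuals.
    """
    if q < 1:
        raise ValueError("q must be >= 1")
    m = model.m
    iu = np.triu_indices(m)
    vech_blocks = []
    for e in model.residual_blocks():
        outer = e[:, :, None] * e[:, None, :]
        vech_blocks.append(outer[:, iu[0], iu[1]])
    d = m * (m + 1) // 2
    xs, ys = [], []
    for v in vech_blocks:
        if v.shape[0] > q:
            X_b, y_b = _lag_design(v, q)
            xs.append(X_b)
            ys.append(y_b)
    if not xs:
        raise EstimationError(f"too few residual rows for {q} ARCH lags")
    X = np.vstack(xs)
    Y = np.vstack(ys)
    n = X.shape[0]
    if n <= X.shape[1] + d:
        raise EstimationError(
            f"too few residual rows ({n}) for the {X.shape[1]}-column ARCH-LM regression"
        )
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    centered = Y - Y.mean(axis=0)
    omega = resid.T @ resid / n
    omega0 = centered.T @ centered / n
    r2m = 1.0 - 2.0 / (m * (m + 1)) * np.trace(omega @ np.linalg.inv(omega0))
    lm = 0.5 * n * m * (m + 1) * r2m
    df = q * m ** 2 * (m + 1) ** 2 // 4
    return TestResult("arch_lm", float(lm), df, float(stats.chi2.sf(lm, df)))


@dataclasses.dataclass
class DiagnosticsReport:
    """Residual-admissibility verdict for one fitted lag order."""

    p: int
    portmanteau: TestResult | None
    arch_lm: TestResult | None
    max_eigenvalue_modulus: float
    alpha: float
    skipped: dict[str, str] = dataclasses.field(default_factory=dict)

    @property
    def stable(self) -> bool:
        return self.max_eigenvalue_modulus < 1.0

    def passes(self) -> bool:
        ok = self.stable
        for t in (self.portmanteau, self.arch_lm):
            if t is not None:
                ok = ok and t.passes(self.alpha)
        return ok

    def to_dict(self) -> dict:
        def _t(t):
            return None if t is None else dataclasses.asdict(t)

        return {
            "p": self.p,
            "portmanteau": _t(self.portmanteau),
            "arch_lm": _t(self.arch_lm),
            "max_eigenvalue_modulus": self.max_eigenvalue_modulus,
            "stable": self.stable,
            "alpha": self.alpha,
            "passes": self.passes(),
            "skipped": self.skipped,
        }


def diagnose(
    model: VARModel,
    alpha: float = 0.05,
    h: int | None = None,
    q: int = 4,
) -> DiagnosticsReport:
    """Run both residual tests plus the stability check on a fitted VAR.

    A test whose regression is infeasible at the panel size (e.g. the
    ARCH-LM vech regression for large m on a short panel) is recorded as
    skipped with the reason rather than failing the model.
    """
    report = DiagnosticsReport(
        p=model.p,
        portmanteau=None,
        arch_lm=None,
        max_eigenvalue_modulus=float(np.max(np.abs(model.companion_eigenvalues()))),
        alpha=alpha,
    )
    try:
        report.portmanteau = portmanteau_test(model, h=h)
    except (EstimationError, np.linalg.LinAlgError) as exc:
        report.skipped["portmanteau"] = str(exc)
    try:
        report.arch_lm = arch_lm_test(model, q=q)
    except (EstimationError, np.linalg.LinAlgError) as exc:
        report.skipped["arch_lm"] = str(exc)
    return report


@dataclasses.dataclass
class LagSelection:
    p: int
    model: VARModel
    audit: list[DiagnosticsReport]


def select_lag(
    panel: MonthlyPanel,
    p_max: int = 4,
    alpha: float = 0.05,
    h: int | None = None,
    q: int = 4,
) -> LagSelection:
    """Smallest lag order whose residuals meet the admissibility
    requirements.

    Fits p = 1, 2, ... and stops at the first model that is
    eigenvalue-stable and passes both residual tests at level alpha;
    the full per-lag audit trail is returned (and attached to the
    non-convergence error if no p <= p_max passes).
    """
    if p_max < 1:
        raise ValueError("p_max must be >= 1")
    audit: list[DiagnosticsReport] = []
    for p in range(1, p_max + 1):
        try:
            model = fit_var(panel, p)
        except EstimationError as exc:
            raise ConvergenceError(
                f"lag {p} cannot be estimated: {exc}", audit=audit
            ) from exc
        report = diagnose(model, alpha=alpha, h=h, q=q)
        audit.append(report)
        if report.passes():
            return LagSelection(p=p, model=model, audit=audit)
    raise ConvergenceError(
        f"no lag order p <= {p_max} produced admissible residuals", audit=audit
    )
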