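"""Orthogonalized impulse-response functions, bootstrap bands, the
conservative last-position ordering sweep, and sign tables.

An impulse-response function projects how a one-time shock of one
orthogonalized-innovation standard error in a single variable
propagates through the fitted VAR over later months. Innovations are
orthogonalized with the Cholesky factor P of the residual covariance
(P P' = Sigma), which makes the result depend on variable order; the
conservative convention reports each variable's impulse effects only
from the ordering in which that variable is entered LAST, so its shock
is credited only with variance unexplained by every other variable.
Confidence bands come from a residual bootstrap: residual rows are
resampled with replacement, pseudo-panels are rebuilt dyad-by-dyad
through the fitted coefficients, and the whole estimation is repeated.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import BootstrapError, EstimationError, StabilityError
from .panel import MonthlyPanel
from .var import VARModel, fit_var

DEFAULT_HORIZON = 10
DEFAULT_REPS = 100
DEFAULT_LEVEL = 95.0
SIGN_WINDOW = (1, 3)  # months-ahead window scored in sign tables
COEF_ORDER_TOL = 1e-10


# ---------------------------------------------------------------------------
# Cholesky orthogonalization
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CholeskyFactor:
    """Lower-triangular P with P P' = Sigma for a given variable order.

    The (1,1) entry is the first-entered variable's residual standard
    deviation; the rest of column 1 holds that variable's residual
    covariances divided by it. Later columns are progressively tempered
    by the variables entered before them.
    """

    matrix: np.ndarray
    order: list[str]


def cholesky_factor(sigma: np.ndarray, order: Sequence[str] | None = None) -> CholeskyFactor:
    """Cholesky-decompose a residual covariance (already in ``order``)."""
    sigma = np.asarray(sigma, dtype=float)
    if not np.allclose(sigma, sigma.T):
        raise EstimationError("residual covariance is not symmetric")
    try:
        p_mat = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:
        raise EstimationError(
            "residual covariance is not positive-definite (degenerate residuals?)"
        ) from exc
    if order is None:
        order = [f"x{i + 1}" for i in range(sigma.shape[0])]
    return CholeskyFactor(matrix=p_mat, order=list(order))


# ---------------------------------------------------------------------------
# point IRFs
# ---------------------------------------------------------------------------

def _theta_curves(coef_matrices: np.ndarray, p_mat: np.ndarray, horizon: int) -> np.ndarray:
    """Moving-average recursion: Theta_h = sum_j B_j Theta_{h-j}, Theta_0 = P."""
    p_lags, m, _ = coef_matrices.shape
    theta = np.empty((horizon + 1, m, m))
    theta[0] = p_mat
    for h in range(1, horizon + 1):
        acc = np.zeros((m, m))
        for j in range(1, min(h, p_lags) + 1):
            acc += coef_matrices[j - 1] @ theta[h - j]
        theta[h] = acc
    return theta


@dataclasses.dataclass
class IRFResult:
    """One impulse/response pair: mean curve and (optional) bootstrap band."""

    impulse: str
    response: str
    horizon: int
    mean: np.ndarray                 # (horizon+1,)
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None
    level: float | None = None
    reps: int | None = None
    ordering: list[str] | None = None

    @property
    def significant_at(self) -> list[int]:
        """Horizons whose band excludes zero (empty without bands)."""
        if self.lower is None:
            return []
        sig = (self.lower > 0) | (self.upper < 0)
        return [int(h) for h in np.flatnonzero(sig)]


@dataclasses.dataclass
class IRFSet:
    """All m x m orthogonalized IRFs under a single variable ordering.

    ``point[h, i, j]`` is the response of variable i at horizon h to a
    one-standard-error orthogonalized shock in variable j; at h = 0 it
    equals P[i, j].
    """

    order: list[str]
    horizon: int
    point: np.ndarray                 # (horizon+1, m, m)
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None
    level: float | None = None
    reps: int | None = None

    def pair(self, impulse: str, response: str) -> IRFResult:
        i = self.order.index(response)
        j = self.order.index(impulse)
        return IRFResult(
            impulse=impulse,
            response=response,
            horizon=self.horizon,
            mean=self.point[:, i, j].copy(),
            lower=None if self.lower is None else self.lower[:, i, j].copy(),
            upper=None if self.upper is None else self.upper[:, i, j].copy(),
            level=self.level,
            reps=self.reps,
            ordering=list(self.order),
        )


def compute_irf(
    model: VARModel, horizon: int = DEFAULT_HORIZON, order: Sequence[str] | None = None
) -> IRFSet:
    """Orthogonalized IRFs of a stable fitted VAR over ``horizon`` steps.

    The shock is one orthogonalized-innovation standard error, i.e.
    exactly a column of the Cholesky factor of Sigma under ``order``.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    if not model.stable:
        raise StabilityError(
            "model has a companion eigenvalue on or outside the unit circle; "
            "impulse responses would not decay"
        )
    ordered = model if order is None else model.reorder(order)
    p_mat = cholesky_factor(ordered.sigma, ordered.variables).matrix
    theta = _theta_curves(ordered.coef_matrices, p_mat, horizon)
    return IRFSet(order=list(ordered.variables), horizon=horizon, point=theta)


# ---------------------------------------------------------------------------
# residual bootstrap
# ---------------------------------------------------------------------------

def _bootstrap_models(
    model: VARModel,
    panel: MonthlyPanel,
    reps: int,
    seed: int | np.random.SeedSequence | None,
    max_drop_frac: float = 0.2,
) -> list[VARModel]:
    """Re-estimated VARs on residual-bootstrap pseudo-panels (panel order).

    Each replicate draws innovation rows with replacement from the
    pooled residual matrix, rebuilds every dyad's series from its own
    first p observed months through the fitted coefficients (no lag pair
    crosses a dyad boundary), and refits. Replicates whose re-estimation
    fails are dropped with a warning; more than ``max_drop_frac`` drops
    aborts the bootstrap.
    """
    rng = np.random.default_rng(seed)
    p = model.p
    n_d, n_t, m = panel.values.shape
    resid = model.residuals
    n_pool = resid.shape[0]
    coefs = model.coef_matrices
    out: list[VARModel] = []
    dropped = 0
    for _ in range(reps):
        draws = rng.integers(0, n_pool, size=(n_t - p, n_d))
        pseudo = np.empty_like(panel.values)
        pseudo[:, :p, :] = panel.values[:, :p, :]
        for t in range(p, n_t):
            acc = np.tile(model.intercepts, (n_d, 1))
            for j in range(1, p + 1):
                acc += pseudo[:, t - j, :] @ coefs[j - 1].T
            pseudo[:, t, :] = acc + resid[draws[t - p]]
        pseudo_panel = MonthlyPanel(
            dyad_ids=list(panel.dyad_ids),
            groups=list(panel.groups),
            months=panel.months.copy(),
            variables=list(panel.variables),
            values=pseudo,
            encoding=panel.encoding,
        )
        try:
            out.append(fit_var(pseudo_panel, p))
        except EstimationError as exc:
            dropped += 1
            warnings.warn(f"bootstrap replicate dropped: {exc}")
    if reps and dropped / reps > max_drop_frac:
        raise BootstrapError(f"{dropped}/{reps} bootstrap replicates failed to re-estimate")
    return out


def _band_from_replicates(
    point: np.ndarray, rep_thetas: np.ndarray, level: float
) -> tuple[np.ndarray, np.ndarray]:
    """Percentile band, widened if needed to include the point curve."""
    tail = (100.0 - level) / 2.0
    lower = np.percentile(rep_thetas, tail, axis=0)
    upper = np.percentile(rep_thetas, 100.0 - tail, axis=0)
    return np.minimum(lower, point), np.maximum(upper, point)


def bootstrap_irf_ci(
    model: VARModel,
    panel: MonthlyPanel,
    reps: int = DEFAULT_REPS,
    level: float = DEFAULT_LEVEL,
    seed: int | None = None,
    horizon: int = DEFAULT_HORIZON,
    order: Sequence[str] | None = None,
) -> IRFSet:
    """Orthogonalized IRFs with percentile bootstrap confidence bands.

    ``reps`` re-estimations (default 100) give a pointwise band at
    ``level`` percent (default 95); a pair is flagged significant at the
    horizons where its band excludes zero.
    """
    if reps < 2:
        raise ValueError("reps must be >= 2")
    if not 0 < level < 100:
        raise ValueError("level must be a percentage in (0, 100)")
    base = compute_irf(model, horizon=horizon, order=order)
    order = base.order
    models = _bootstrap_models(model, panel, reps, seed)
    rep_thetas = np.empty((len(models), horizon + 1, model.m, model.m))
    for r, bm in enumerate(models):
        ordered = bm.reorder(order)
        p_mat = cholesky_factor(ordered.sigma, order).matrix
        rep_thetas[r] = _theta_curves(ordered.coef_matrices, p_mat, horizon)
    lower, upper = _band_from_replicates(base.point, rep_thetas, level)
    return IRFSet(
        order=list(order),
        horizon=horizon,
        point=base.point,
        lower=lower,
        upper=upper,
        level=level,
        reps=len(models),
    )


# ---------------------------------------------------------------------------
# conservative last-position sweep
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ConservativeIRFSet:
    """Per-impulse IRFs, each taken from the ordering where that
    variable was entered last.

    ``point[j, h, i]`` is the response of variable i (panel order) at
    horizon h to an impulse in variable j, estimated under the ordering
    that places j rightmost.
    """

    variables: list[str]
    horizon: int
    point: np.ndarray                 # (m, horizon+1, m)
    lower: np.ndarray
    upper: np.ndarray
    level: float
    reps: int
    orderings: list[list[str]]

    def pair(self, impulse: str, response: str) -> IRFResult:
        j = self.variables.index(impulse)
        i = self.variables.index(response)
        return IRFResult(
            impulse=impulse,
            response=response,
            horizon=self.horizon,
            mean=self.point[j, :, i].copy(),
            lower=self.lower[j, :, i].copy(),
            upper=self.upper[j, :, i].copy(),
            level=self.level,
            reps=self.reps,
            ordering=list(self.orderings[j]),
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format curves: one row per (impulse, response, horizon)."""
        rows = []
        for j, imp in enumerate(self.variables):
            for i, resp in enumerate(self.variables):
                for h in range(self.horizon + 1):
                    rows.append(
                        (imp, resp, h, self.point[j, h, i], self.lower[j, h, i], self.upper[j, h, i])
                    )
        return pd.DataFrame(
            rows, columns=["impulse", "response", "horizon", "mean", "lower", "upper"]
        )


def last_position_ordering(variables: Sequence[str], last: str) -> list[str]:
    """Panel order with ``last`` moved to the rightmost position."""
    return [v for v in variables if v != last] + [last]


def conservative_irf_sweep(
    panel: MonthlyPanel,
    p: int = 1,
    horizon: int = DEFAULT_HORIZON,
    reps: int = DEFAULT_REPS,
    level: float = DEFAULT_LEVEL,
    seed: int | None = None,
) -> ConservativeIRFSet:
    """Run the m-ordering conservative sweep with bootstrap bands.

    For each of the m variables the Cholesky/IRF step is re-run with
    that variable entered last, and only its impulse effects are kept
    from that run. The VAR coefficients themselves are re-estimated
    under every ordering and verified identical (up to permutation) to
    the base fit — ordering affects only the orthogonalization. One
    shared set of bootstrap pseudo-panels serves all orderings, since
    re-estimation commutes with column permutation.
    """
    if panel.m < 2:
        raise ValueError("the ordering sweep needs at least 2 variables")
    base = fit_var(panel, p)
    if not base.stable:
        raise StabilityError("fitted model is unstable; IRFs would diverge")
    variables = list(panel.variables)
    m = panel.m
    boot = _bootstrap_models(base, panel, reps, seed)

    point = np.empty((m, horizon + 1, m))
    lower = np.empty_like(point)
    upper = np.empty_like(point)
    orderings = []
    for j, var in enumerate(variables):
        order = last_position_ordering(variables, var)
        orderings.append(order)
        try:
            refit = fit_var(panel.reorder_variables(order), p).reorder(variables)
        except EstimationError as exc:
            raise EstimationError(f"ordering {order} failed to estimate: {exc}") from exc
        if not np.allclose(refit.coef_matrices, base.coef_matrices, atol=COEF_ORDER_TOL):
            raise EstimationError(
                f"VAR coefficients changed under ordering {order}; "
                "estimation should be ordering-invariant"
            )
        irf_o = compute_irf(base, horizon=horizon, order=order)
        rep_thetas = np.empty((len(boot), horizon + 1, m, m))
        for r, bm in enumerate(boot):
            ordered = bm.reorder(order)
            p_mat = cholesky_factor(ordered.sigma, order).matrix
            rep_thetas[r] = _theta_curves(ordered.coef_matrices, p_mat, horizon)
        lo, up = _band_from_replicates(irf_o.point, rep_thetas, level)
        # impulse var sits in the last column of this ordering; map responses
        # back to panel order
        resp_idx = [order.index(v) for v in variables]
        point[j] = irf_o.point[:, resp_idx, -1]
        lower[j] = lo[:, resp_idx, -1]
        upper[j] = up[:, resp_idx, -1]
    return ConservativeIRFSet(
        variables=variables,
        horizon=horizon,
        point=point,
        lower=lower,
        upper=upper,
        level=level,
        reps=len(boot),
        orderings=orderings,
    )


# ---------------------------------------------------------------------------
# sign tables
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SignTable:
    """Impulse x response matrix of {blank, +, -} verdicts.

    A cell is non-blank only if the bootstrap band excludes zero at some
    horizon inside ``window`` (months ahead); its sign is the mean
    curve's sign at the first such horizon.
    """

    cells: pd.DataFrame               # index = responses, columns = impulses
    window: tuple[int, int]
    group: str | None = None
    encoding: str | None = None

    def cell(self, response: str, impulse: str) -> str:
        return str(self.cells.loc[response, impulse])


def build_sign_table(
    irfs: ConservativeIRFSet,
    impulse_set: Sequence[str] | None = None,
    response_set: Sequence[str] | None = None,
    window: tuple[int, int] = SIGN_WINDOW,
    group: str | None = None,
    encoding: str | None = None,
) -> SignTable:
    """Collapse conservative IRFs into a Tables-2/3-style sign matrix."""
    lo, hi = window
    if not (0 <= lo <= hi <= irfs.horizon):
        raise ValueError(f"window {window} outside computed horizon 0..{irfs.horizon}")
    impulses = list(impulse_set) if impulse_set is not None else list(irfs.variables)
    responses = list(response_set) if response_set is not None else list(irfs.variables)
    for v in impulses + responses:
        if v not in irfs.variables:
            raise ValueError(f"variable {v!r} not covered by the IRF set")
    cells = pd.DataFrame("", index=responses, columns=impulses, dtype=object)
    for imp in impulses:
        for resp in responses:
            r = irfs.pair(imp, resp)
            sig = [h for h in r.significant_at if lo <= h <= hi]
            if not sig:
                continue
            signs = {np.sign(r.mean[h]) for h in sig}
            if len(signs) > 1:
                warnings.warn(
                    f"mixed-sign significant response {resp!r} to {imp!r} in window "
                    f"{window}; reporting the sign at the first significant horizon"
                )
            cells.loc[resp, imp] = "+" if r.mean[sig[0]] > 0 else "-"
    return SignTable(cells=cells, window=(lo, hi), group=group, encoding=encoding)


def render_bracket_table(
    duration_tables: dict[str, SignTable],
    occurrence_tables: dict[str, SignTable],
) -> pd.DataFrame:
    """Combine per-group sign tables into the published bracket dialect.

    Duration verdicts appear outside brackets and occurrence verdicts
    inside, each tagged with the group initial, e.g. ``+B[-G]`` means a
    significant positive duration response for boys and a significant
    negative occurrence response for girls.
    """
    some = next(iter(duration_tables.values() or occurrence_tables.values()))
    out = pd.DataFrame("", index=some.cells.index, columns=some.cells.columns, dtype=object)
    for resp in out.index:
        for imp in out.columns:
            outside = "".join(
                f"{t.cells.loc[resp, imp]}{g[0].upper()}"
                for g, t in sorted(duration_tables.items())
                if t.cells.loc[resp, imp]
            )
            inside = "".join(
                f"{t.cells.loc[resp, imp]}{g[0].upper()}"
                for g, t in sorted(occurrence_tables.items())
                if t.cells.loc[resp, imp]
            )
            out.loc[resp, imp] = outside + (f"[{inside}]" if inside else "")
    return out
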