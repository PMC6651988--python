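"""Constrained weight optimization for synthetic-control matching.

Two nested problems:

* inner — given importance weights V, find donor weights W on the probability
  simplex minimizing (X1 - X0 W)' V (X1 - X0 W), a convex QP;
* outer — choose V (nonnegative, summing to one) so that the synthetic
  control implied by W(V) minimizes the pre-policy outcome MSPE, the
  data-driven V selection standard for this estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .panel import PanelDataset
from .predictors import PredictorMatrices

__all__ = [
    "DonorWeights",
    "ImportanceWeights",
    "SolverError",
    "solve_weights",
    "optimize_importance",
]

_SIMPLEX_TOL = 1e-8


class SolverError(RuntimeError):
    """The constrained optimizer failed to return a feasible solution."""


@dataclass
class DonorWeights:
    """Donor weights w_j >= 0, sum 1, with the achieved matching objective."""

    w: pd.Series
    objective: float

    def __post_init__(self) -> None:
        arr = self.w.to_numpy(dtype=float)
        if (arr < -_SIMPLEX_TOL).any() or abs(arr.sum() - 1.0) > _SIMPLEX_TOL:
            raise SolverError(
                f"infeasible weights: min={arr.min():.3e} sum={arr.sum():.12f}"
            )

    def to_display(self, cutoff: float = 0.001) -> pd.Series:
        """Weights formatted for reporting; entries below cutoff show as '≈ 0'."""
        return pd.Series(
            ["≈ 0" if v < cutoff else f"{v:.3f}" for v in self.w],
            index=self.w.index,
            name="weight",
        )


@dataclass
class ImportanceWeights:
    """Diagonal predictor-importance weights v_m >= 0 normalized to sum 1."""

    v: pd.Series
    achieved_mspe: float | None = None

    def __post_init__(self) -> None:
        arr = self.v.to_numpy(dtype=float)
        if (arr < -1e-10).any():
            raise ValueError("importance weights must be nonnegative")
        if abs(arr.sum() - 1.0) > 1e-10:
            raise ValueError(f"importance weights must sum to 1, got {arr.sum()!r}")

    @classmethod
    def equal(cls, row_names: list[str]) -> "ImportanceWeights":
        k = len(row_names)
        return cls(pd.Series(np.full(k, 1.0 / k), index=row_names, name="v"))


def _qp_objective(A: np.ndarray, b: np.ndarray):
    AtA = A.T @ A
    Atb = A.T @ b
    btb = float(b @ b)

    def fun(w: np.ndarray) -> float:
        return float(w @ AtA @ w - 2.0 * (Atb @ w) + btb)

    def jac(w: np.ndarray) -> np.ndarray:
        return 2.0 * (AtA @ w - Atb)

    return fun, jac


def _solve_simplex_ls(A: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, float]:
    """min ||A w - b||^2 s.t. w >= 0, sum w = 1 via SLSQP with exact gradient."""
    J = A.shape[1]
    fun, jac = _qp_objective(A, b)
    cons = ({"type": "eq", "fun": lambda w: w.sum() - 1.0, "jac": lambda w: np.ones(J)},)
    bounds = [(0.0, 1.0)] * J
    starts = [np.full(J, 1.0 / J)]
    # a vertex start at the closest single donor helps corner solutions
    dists = ((A - b[:, None]) ** 2).sum(axis=0)
    vertex = np.zeros(J)
    vertex[int(np.argmin(dists))] = 1.0
    starts.append(vertex)

    best: tuple[np.ndarray, float] | None = None
    last_status = ""
    for x0 in starts:
        res = optimize.minimize(
            fun,
            x0,
            jac=jac,
            method="SLSQP",
            bounds=bounds,
            constraints=cons,
            options={"maxiter": 1000, "ftol": 1e-14},
        )
        last_status = res.message
        w = np.clip(res.x, 0.0, None)
        s = w.sum()
        if s <= 0:
            continue
        w = w / s
        val = fun(w)
        if res.success and (best is None or val < best[1]):
            best = (w, val)
    if best is None:
        raise SolverError(f"weight optimization failed: {last_status}")
    return _polish(A, b, fun, *best)


def _polish(
    A: np.ndarray, b: np.ndarray, fun, w: np.ndarray, val: float
) -> tuple[np.ndarray, float]:
    """Refine an SLSQP solution to machine precision on its active support.

    Solves the equality-constrained least squares restricted to the positive
    support via the KKT system; accepted only if it stays feasible and
    improves the objective, so the returned point is never worse than the
    SLSQP iterate.
    """
    support = np.flatnonzero(w > 1e-9)
    if support.size == 0:
        return w, val
    As = A[:, support]
    m = support.size
    # KKT for min ||As u - b||^2 s.t. 1'u = 1
    K = np.zeros((m + 1, m + 1))
    K[:m, :m] = 2.0 * As.T @ As
    K[:m, m] = 1.0
    K[m, :m] = 1.0
    rhs = np.concatenate([2.0 * As.T @ b, [1.0]])
    try:
        sol = np.linalg.lstsq(K, rhs, rcond=None)[0]
    except np.linalg.LinAlgError:  # pragma: no cover
        return w, val
    u = sol[:m]
    if (u < -1e-12).any():
        return w, val
    u = np.clip(u, 0.0, None)
    s = u.sum()
    if s <= 0:
        return w, val
    u = u / s
    cand = np.zeros_like(w)
    cand[support] = u
    cand_val = fun(cand)
    if cand_val <= val:
        return cand, cand_val
    return w, val


def solve_weights(pm: PredictorMatrices, v: ImportanceWeights) -> DonorWeights:
    """Solve the simplex-constrained matching QP for fixed importance V.

    Minimizes ``(X1 - X0 W)' V (X1 - X0 W)`` over the probability simplex.
    Raises :class:`SolverError` rather than returning an infeasible W.
    """
    if pm.n_donors < 2:
        raise ValueError("need J >= 2 donors")
    varr = v.v.to_numpy(dtype=float)
    if varr.shape[0] != pm.k:
        raise ValueError(
            f"importance weights have length {varr.shape[0]}, expected k={pm.k}"
        )
    sqrtv = np.sqrt(np.clip(varr, 0.0, None))
    A = sqrtv[:, None] * pm.X0
    b = sqrtv * pm.X1
    w, val = _solve_simplex_ls(A, b)
    return DonorWeights(
        w=pd.Series(w, index=pm.donor_ids, name="weight"), objective=val
    )


def _pre_outcome_arrays(panel: PanelDataset) -> tuple[np.ndarray, np.ndarray]:
    pre = panel.pre_years
    y1 = panel.outcomes.loc[panel.treated_unit, pre].to_numpy(dtype=float)
    Y0 = panel.outcomes.loc[panel.donors, pre].to_numpy(dtype=float)
    return y1, Y0


def optimize_importance(
    pm: PredictorMatrices,
    panel: PanelDataset,
    *,
    n_restarts: int = 3,
    random_state: int | np.random.Generator | None = None,
    maxiter: int = 100,
) -> ImportanceWeights:
    """Pick V to minimize the pre-policy outcome MSPE of the implied synthetic.

    Nested (bilevel) minimization: the outer objective evaluates the inner
    simplex QP at each candidate V and scores the resulting weights by the
    mean squared prediction error of the raw outcome over pre-policy years.
    Multistart: equal weights plus ``n_restarts`` Dirichlet draws.  Falls back
    to equal importance with a warning if every start fails.
    """
    k = pm.k
    if k == 1:
        return ImportanceWeights(
            pd.Series([1.0], index=pm.row_names, name="v"), achieved_mspe=None
        )
    y1, Y0 = _pre_outcome_arrays(panel)
    rng = (
        random_state
        if isinstance(random_state, np.random.Generator)
        else np.random.default_rng(random_state)
    )

    def outer(vraw: np.ndarray) -> float:
        v = np.clip(vraw, 0.0, None)
        s = v.sum()
        if s <= 0:
            return np.inf
        v = v / s
        try:
            dw = solve_weights(
                pm, ImportanceWeights(pd.Series(v, index=pm.row_names))
            )
        except SolverError:
            return np.inf
        resid = y1 - dw.w.to_numpy() @ Y0
        return float(np.mean(resid**2))

    cons = (
        {"type": "eq", "fun": lambda v: v.sum() - 1.0, "jac": lambda v: np.ones(k)},
    )
    bounds = [(0.0, 1.0)] * k
    starts = [np.full(k, 1.0 / k)]
    for _ in range(n_restarts):
        starts.append(rng.dirichlet(np.ones(k)))

    best_v: np.ndarray | None = None
    best_val = np.inf
    for x0 in starts:
        try:
            res = optimize.minimize(
                outer,
                x0,
                method="SLSQP",
                bounds=bounds,
                constraints=cons,
                options={"maxiter": maxiter, "ftol": 1e-10},
            )
        except (ValueError, FloatingPointError):  # pragma: no cover - solver quirk
            continue
        cand = np.clip(res.x, 0.0, None)
        if cand.sum() <= 0:
            continue
        cand = cand / cand.sum()
        val = outer(cand)
        if np.isfinite(val) and val < best_val:
            best_val = val
            best_v = cand
    # the multistart itself guarantees the equal-weights value was evaluated,
    # so the best candidate is never worse than equal importance
    eq = np.full(k, 1.0 / k)
    eq_val = outer(eq)
    if best_v is None or not np.isfinite(best_val):
        warnings.warn(
            "importance-weight optimization failed from every start; "
            "falling back to equal weights",
            RuntimeWarning,
            stacklevel=2,
        )
        best_v, best_val = eq, eq_val
    elif eq_val < best_val:
        best_v, best_val = eq, eq_val
    return ImportanceWeights(
        pd.Series(best_v, index=pm.row_names, name="v"), achieved_mspe=best_val
    )
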