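"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from synthctrl import PanelDataset

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


# ----------------------------------------------------------------------
# independent brute-force oracle for the simplex-constrained QP
# ----------------------------------------------------------------------

def simplex_grid(J: int, step: float) -> np.ndarray:
    """All points of the probability simplex on a regular grid (rows sum 1)."""
    n = round(1.0 / step)
    if J == 2:
        a = np.arange(n + 1)
        pts = np.column_stack([a, n - a])
    elif J == 3:
        a, b = np.meshgrid(np.arange(n + 1), np.arange(n + 1), indexing="ij")
        mask = a + b <= n
        pts = np.column_stack([a[mask], b[mask], n - a[mask] - b[mask]])
    elif J == 4:
        pts_list = []
        for i in range(n + 1):
            a, b = np.meshgrid(np.arange(n - i + 1), np.arange(n - i + 1),
                               indexing="ij")
            mask = a + b <= n - i
            m = int(mask.sum())
            pts_list.append(
                np.column_stack(
                    [np.full(m, i), a[mask], b[mask], n - i - a[mask] - b[mask]]
                )
            )
        pts = np.vstack(pts_list)
    else:
        raise ValueError("oracle supports J in {2, 3, 4}")
    return pts / n


def grid_objective(X1: np.ndarray, X0: np.ndarray, v: np.ndarray,
                   W: np.ndarray) -> np.ndarray:
    """(X1 - X0 w)' diag(v) (X1 - X0 w) for every row w of W, vectorized."""
    resid = X1[:, None] - X0 @ W.T  # k x N
    return (v[:, None] * resid**2).sum(axis=0)


def brute_force_simplex_min(X1, X0, v, step=0.001, coarse_step=None) -> float:
    """Exhaustive simplex-grid minimum of the matching objective.

    For J <= 3 the grid at ``step`` is fully enumerated.  With
    ``coarse_step`` set (used for J = 4, where a full 0.001 grid is ~1.7e8
    points), an exhaustive coarse grid is refined by an exhaustive local
    ``step`` grid in a box around the coarse optimum.
    """
    J = X0.shape[1]
    if coarse_step is None:
        W = simplex_grid(J, step)
        return float(grid_objective(X1, X0, v, W).min())
    Wc = simplex_grid(J, coarse_step)
    vals = grid_objective(X1, X0, v, Wc)
    w0 = Wc[int(np.argmin(vals))]
    best = float(vals.min())
    # local refinement: every step-grid point within coarse_step of w0
    n = round(1.0 / step)
    r = round(coarse_step / step)
    lo = np.maximum(np.round(w0 * n).astype(int) - r, 0)
    hi = np.minimum(np.round(w0 * n).astype(int) + r, n)
    axes = [np.arange(lo[i], hi[i] + 1) for i in range(J - 1)]
    mesh = np.meshgrid(*axes, indexing="ij")
    flat = np.column_stack([m.ravel() for m in mesh])
    last = n - flat.sum(axis=1)
    ok = (last >= lo[J - 1]) & (last <= hi[J - 1])
    W = np.column_stack([flat[ok], last[ok]]) / n
    if len(W):
        best = min(best, float(grid_objective(X1, X0, v, W).min()))
    return best


# ----------------------------------------------------------------------
# panels
# ----------------------------------------------------------------------

def build_panel(outcomes: dict, covariates=None, treated="A", policy_year=2012,
                years=None) -> PanelDataset:
    """Convenience constructor from {unit: [values...]} dicts."""
    units = list(outcomes)
    n_years = len(next(iter(outcomes.values())))
    years = years or list(range(2010, 2010 + n_years))
    out = pd.DataFrame(
        [outcomes[u] for u in units], index=units, columns=years, dtype=float
    )
    covs = {}
    for name, mat in (covariates or {}).items():
        covs[name] = pd.DataFrame(
            [mat[u] for u in units], index=units, columns=years, dtype=float
        )
    return PanelDataset(
        outcomes=out, covariates=covs, treated_unit=treated,
        policy_year=policy_year,
    )


@pytest.fixture
def tiny_panel() -> PanelDataset:
    """3 units x 4 years, policy at 2012 (2 pre, 2 post), one covariate."""
    return build_panel(
        outcomes={
            "A": [50.0, 48.0, 40.0, 38.0],
            "B": [52.0, 50.0, 49.0, 48.0],
            "C": [48.0, 46.0, 45.0, 44.0],
        },
        covariates={
            "gdp": {
                "A": [1.0, 2.0, 3.0, 4.0],
                "B": [2.0, 3.0, 4.0, 5.0],
                "C": [0.0, 1.0, 2.0, 3.0],
            }
        },
    )


@pytest.fixture(scope="session")
def outpatient_panel():
    from synthctrl import make_study_fixture

    panel, truth = make_study_fixture("outpatient-like", seed=11)
    return panel, truth
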