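"""City-year panel generator with known ground truth.

The outcome follows an interactive-fixed-effects (factor) model

    Y_jt = theta_t + mu_j + lambda_t * f_j + tau_t * D_jt + delta*[j = 1] + eps_jt

with common time shocks theta_t, unit effects mu_j, a time-varying factor
lambda_t loading on unit-specific f_j, a treatment indicator D_jt active for
the treated unit from the policy year onward, an optional persistent treated
level offset delta, and iid Gaussian noise.  The factor term is what makes
the setting interesting for synthetic-control estimation: units follow
non-parallel trends driven by unobserved loadings, the premise under which a
two-group pre/post contrast is biased but a loading-matched convex
combination of donors is not.

The six covariates are affine in (f_j, mu_j) plus unit trends and noise, so
they are informative about the latent loadings that drive outcomes; their
levels are calibrated to plausible prefecture-level magnitudes (outcome in
percentage points 20-70, urbanization 50-70%, elderly share 18-28%, GDP per
capita 40k-80k, life expectancy 77-82 years, per-capita medical operation
expenses 150-300, population 3-8 million).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .panel import PanelDataset

__all__ = ["DgpConfig", "GroundTruth", "generate_panel", "make_study_fixture"]

COVARIATE_NAMES = (
    "population",
    "urbanization",
    "elderly",
    "gdp_per_capita",
    "life_expectancy",
    "medical_expenses",
)

# covariate = a + b_f * f_j + b_mu * mu_j + trend*(t - t0) + noise_sd * eps
_COV_PARAMS = {
    "population": dict(a=5.5e6, b_f=1.5e6, b_mu=2.0e5, trend=2.0e4, noise_sd=5.0e4),
    "urbanization": dict(a=60.0, b_f=5.0, b_mu=0.5, trend=0.8, noise_sd=0.5),
    "elderly": dict(a=22.0, b_f=-3.0, b_mu=0.3, trend=0.3, noise_sd=0.3),
    "gdp_per_capita": dict(a=60000.0, b_f=-12000.0, b_mu=1500.0, trend=1500.0,
                           noise_sd=800.0),
    "life_expectancy": dict(a=79.5, b_f=1.2, b_mu=0.1, trend=0.1, noise_sd=0.15),
    "medical_expenses": dict(a=220.0, b_f=30.0, b_mu=5.0, trend=4.0, noise_sd=5.0),
}


@dataclass
class DgpConfig:
    """Data-generating-process configuration.

    Defaults emulate the study scale: 13 units (1 treated + 12 donors),
    annual years 2008-2015 with the policy starting in 2013 (5 pre, 3 post
    years), outcome in percentage points, a constant post-policy effect of
    -7.7 pp on the treated unit, and 1 pp outcome noise.
    """

    n_units: int = 13
    start_year: int = 2008
    end_year: int = 2015
    policy_year: int = 2013
    tau: float = -7.7
    tau_profile: str = "constant"  # or "ramp"
    delta: float = 0.0  # persistent treated-unit level offset, pp
    noise_sd: float = 1.0  # outcome noise sigma, pp
    base_level: float = 48.0  # theta_t intercept, pp
    time_trend: float = -0.5  # common linear trend, pp / year
    theta_shock_sd: float = 0.4  # common year shock sd, pp
    mu_sd: float = 3.0  # unit-effect sd, pp
    lam_trend: float = -0.8  # factor trend, pp / year
    lam_shock_sd: float = 0.5  # factor shock sd, pp
    f_mean: float = 1.0  # loading mean
    f_sd: float = 0.4  # loading sd; 0 => parallel trends
    treated_in_hull: bool = False  # draw treated (f, mu) as a convex
    # combination of donor loadings so an exact synthetic match exists
    treated_f: float | None = None  # explicit treated loading override
    treated_mu: float | None = None  # explicit treated unit-effect override
    covariate_noise: float = 1.0  # multiplier on covariate noise sds
    treated_unit: str = "treated"
    seed: int = 0

    def years(self) -> list[int]:
        return list(range(self.start_year, self.end_year + 1))

    def validate(self) -> None:
        years = self.years()
        pre = [y for y in years if y < self.policy_year]
        post = [y for y in years if y >= self.policy_year]
        if len(pre) < 2 or len(post) < 1:
            raise ValueError(
                f"need >=2 pre and >=1 post years around {self.policy_year}, "
                f"got {len(pre)} pre / {len(post)} post"
            )
        if self.n_units < 3:
            raise ValueError("need >= 3 units (1 treated + >= 2 donors)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.tau_profile not in ("constant", "ramp"):
            raise ValueError(f"unknown tau profile {self.tau_profile!r}")


@dataclass
class GroundTruth:
    """Latent quantities behind a generated panel, for recovery tests."""

    tau: dict[int, float]
    delta: float
    theta: dict[int, float]
    lam: dict[int, float]
    f: dict[str, float]
    mu: dict[str, float]
    hull_weights: dict[str, float] | None
    seed: int
    config: dict = field(default_factory=dict)


def generate_panel(config: DgpConfig) -> tuple[PanelDataset, GroundTruth]:
    """Draw one panel plus its ground-truth record; same seed, same bytes."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    years = config.years()
    n_years = len(years)
    n = config.n_units
    units = [config.treated_unit] + [f"donor{i:02d}" for i in range(1, n)]
    t_idx = np.arange(n_years, dtype=float)

    theta = (
        config.base_level
        + config.time_trend * t_idx
        + rng.normal(0.0, config.theta_shock_sd, n_years)
    )
    lam = config.lam_trend * t_idx + rng.normal(0.0, config.lam_shock_sd, n_years)
    f = rng.normal(config.f_mean, config.f_sd, n)
    mu = rng.normal(0.0, config.mu_sd, n)

    hull_weights = None
    if config.treated_in_hull:
        c = rng.dirichlet(np.ones(n - 1))
        f[0] = float(c @ f[1:])
        mu[0] = float(c @ mu[1:])
        hull_weights = {units[1 + i]: float(c[i]) for i in range(n - 1)}
    if config.treated_f is not None or config.treated_mu is not None:
        hull_weights = None
        if config.treated_f is not None:
            f[0] = float(config.treated_f)
        if config.treated_mu is not None:
            mu[0] = float(config.treated_mu)

    post_years = [y for y in years if y >= config.policy_year]
    if config.tau_profile == "constant":
        tau_t = {y: config.tau for y in post_years}
    else:  # linear ramp up to the full effect in the last post year
        m = len(post_years)
        tau_t = {y: config.tau * (i + 1) / m for i, y in enumerate(post_years)}

    eps = rng.normal(0.0, config.noise_sd, (n, n_years))
    Y = theta[None, :] + mu[:, None] + np.outer(f, lam) + eps
    Y[0, :] += config.delta
    for j, y in enumerate(years):
        if y in tau_t:
            Y[0, j] += tau_t[y]

    if (Y < 0).any() or (Y > 100).any():
        n_bad = int(((Y < 0) | (Y > 100)).sum())
        warnings.warn(
            f"{n_bad} generated outcome values fell outside [0, 100] and were "
            "clipped",
            UserWarning,
            stacklevel=2,
        )
        Y = np.clip(Y, 0.0, 100.0)

    covs: dict[str, pd.DataFrame] = {}
    for name in COVARIATE_NAMES:
        p = _COV_PARAMS[name]
        noise = rng.normal(0.0, p["noise_sd"] * config.covariate_noise, (n, n_years))
        C = (
            p["a"]
            + p["b_f"] * f[:, None]
            + p["b_mu"] * mu[:, None]
            + p["trend"] * t_idx[None, :]
            + noise
        )
        covs[name] = pd.DataFrame(C, index=units, columns=years)

    panel = PanelDataset(
        outcomes=pd.DataFrame(Y, index=units, columns=years),
        covariates=covs,
        treated_unit=config.treated_unit,
        policy_year=config.policy_year,
        meta={"generator": "synthctrl.simulate", "seed": config.seed,
              "outcome_name": "drug_share"},
    )
    truth = GroundTruth(
        tau=tau_t,
        delta=config.delta,
        theta={y: float(theta[i]) for i, y in enumerate(years)},
        lam={y: float(lam[i]) for i, y in enumerate(years)},
        f={u: float(f[i]) for i, u in enumerate(units)},
        mu={u: float(mu[i]) for i, u in enumerate(units)},
        hull_weights=hull_weights,
        seed=config.seed,
        config=asdict(config),
    )
    return panel, truth


_SCENARIOS = {
    # treated level comparable to donors, clear negative reform effect
    "outpatient-like": dict(tau=-7.7, delta=0.0, noise_sd=0.8,
                            treated_in_hull=True),
    # treated unit sits ~10 pp (5 sigma_mu) below the donor pool: no convex
    # combination can match it until the pool is shifted down by that amount
    "inpatient-like": dict(tau=-3.2, delta=-10.0, noise_sd=0.8, mu_sd=2.0,
                           treated_in_hull=True),
    # no effect at all; used for calibration of placebo inference
    "null": dict(tau=0.0, delta=0.0, noise_sd=1.0, treated_in_hull=False),
}


def make_study_fixture(
    scenario: str, seed: int = 0, **overrides
) -> tuple[PanelDataset, GroundTruth]:
    """Canned study-scale scenarios for tests and demonstrations."""
    if scenario not in _SCENARIOS:
        raise KeyError(
            f"unknown scenario {scenario!r}; choose from {sorted(_SCENARIOS)}"
        )
    params = dict(_SCENARIOS[scenario])
    params.update(overrides)
    return generate_panel(DgpConfig(seed=seed, **params))
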