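"""Bayesian hierarchical logistic regression of NOMS improvement.

The model for patient i in aphasia-type group g(i):

    improved_i ~ Bernoulli(sigmoid(x_i' beta + u_{g(i)}))
    beta_j     ~ Normal(0, prior_coef_sd^2)          (fixed effects)
    u_g        ~ Normal(0, sigma_g^2)                (varying intercepts)
    sigma_g    ~ half-Normal(0, prior_group_sd_scale^2)

with x = (1, age, months post onset, education, African American indicator),
covariates entered unstandardized so coefficients are per-year / per-month
log-odds.  Weakly informative priors regularize the quasi-separated groups a
20-patient cohort produces.

Fitting is by Gibbs sampling with Pólya-Gamma data augmentation: each
observation gains a latent omega_i ~ PG(1, psi_i) whose conditional makes the
joint update of (beta, u) an exact multivariate Gaussian; the group-intercept
variance update is a generalized-inverse-Gaussian draw implied by the
half-Normal prior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.special import expit
from scipy.stats import geninvgauss

from .cohort import AphasiaType, Dimension, PatientRecord, derive_improvement
from .polya_gamma import sample_pg1

__all__ = [
    "FIXED_EFFECTS",
    "ModelSpec",
    "DesignMatrices",
    "PosteriorDraws",
    "SeparationWarning",
    "build_design",
    "fit_model",
    "grid_posterior_oracle",
    "odds_ratio",
    "predict_probability",
]

#: Fixed-effect design columns, in order.
FIXED_EFFECTS = ("intercept", "age", "months_post_onset", "education", "african_american")


class SeparationWarning(UserWarning):
    """The outcome vector is all-improved or all-unimproved; priors carry the fit."""


@dataclass(frozen=True)
class ModelSpec:
    """Sampler configuration for one NOMS dimension."""

    dimension: Dimension = Dimension.VERBAL
    fixed_effects: tuple[str, ...] = FIXED_EFFECTS
    prior_coef_sd: float = 5.0
    prior_group_sd_scale: float = 2.5
    n_chains: int = 4
    n_iterations: int = 2000
    n_burnin: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("at least 2 chains are required for convergence diagnostics")
        if not self.n_iterations > self.n_burnin >= 0:
            raise ValueError("need n_iterations > n_burnin >= 0")
        if self.prior_coef_sd <= 0 or self.prior_group_sd_scale <= 0:
            raise ValueError("prior scales must be positive")


class DesignMatrices(NamedTuple):
    """Outcome vector, fixed-effect matrix and group structure for one dimension."""

    y: np.ndarray
    X: np.ndarray
    group_idx: np.ndarray
    group_levels: tuple[AphasiaType, ...]


@dataclass(frozen=True)
class PosteriorDraws:
    """Post-burn-in MCMC draws, shaped (chain, iteration, parameter).

    Parameters are the fixed effects, one varying intercept per aphasia type
    present in the fit, and the group-intercept sd.
    """

    values: np.ndarray
    param_names: tuple[str, ...]
    fixed_effects: tuple[str, ...]
    group_levels: tuple[AphasiaType, ...]
    dimension: Dimension

    @property
    def n_chains(self) -> int:
        return self.values.shape[0]

    @property
    def n_draws(self) -> int:
        return self.values.shape[1]

    def parameter(self, name: str) -> np.ndarray:
        """(chain, draw) slice for one parameter."""
        return self.values[:, :, self.param_names.index(name)]


def build_design(
    records: Sequence[PatientRecord], dimension: Dimension
) -> DesignMatrices:
    """Assemble (y, X, group index) for the improvement regression.

    Columns follow :data:`FIXED_EFFECTS`; group levels are the aphasia types
    present in the cohort, in enum order.  A one-sided outcome vector raises
    :class:`SeparationWarning` but does not abort (the priors regularize).
    """
    if not records:
        raise ValueError("cannot build a design from an empty cohort")
    dimension = Dimension(dimension)
    outcomes = derive_improvement(records, dimension)
    y = np.array([o.improved for o in outcomes], dtype=float)
    X = np.array(
        [
            [1.0, r.age, r.months_post_onset, r.education, float(r.african_american)]
            for r in records
        ]
    )
    levels = tuple(t for t in AphasiaType if any(r.aphasia_type is t for r in records))
    index = {t: i for i, t in enumerate(levels)}
    group_idx = np.array([index[r.aphasia_type] for r in records], dtype=int)
    if y.min() == y.max():
        warnings.warn(
            "outcome vector is completely separated "
            f"(all {'improved' if y[0] else 'unimproved'}); "
            "the posterior is driven by the priors",
            SeparationWarning,
            stacklevel=2,
        )
    return DesignMatrices(y=y, X=X, group_idx=group_idx, group_levels=levels)


def _run_chain(
    design: DesignMatrices,
    spec: ModelSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    y, X, group_idx, levels = design
    n, p = X.shape
    G = len(levels)
    Z = np.zeros((n, G))
    Z[np.arange(n), group_idx] = 1.0
    W = np.hstack([X, Z])
    kappa = y - 0.5

    prior_prec = np.empty(p + G)
    prior_prec[:p] = 1.0 / spec.prior_coef_sd**2
    psi_gig = 1.0 / spec.prior_group_sd_scale**2
    gig_p = 0.5 - G / 2.0  # GIG order for sigma_g^2 under the half-Normal prior

    theta = 0.1 * rng.standard_normal(p + G)
    sigma_g2 = (0.5 + rng.random()) ** 2
    kept = np.empty((spec.n_iterations - spec.n_burnin, p + G + 1))

    for it in range(spec.n_iterations):
        psi = W @ theta
        omega = sample_pg1(psi, rng)

        prior_prec[p:] = 1.0 / sigma_g2
        precision = (W.T * omega) @ W
        precision[np.diag_indices_from(precision)] += prior_prec
        if not np.isfinite(precision).all():
            raise FloatingPointError(
                f"non-finite conditional precision at iteration {it}"
            )
        chol = cho_factor(precision, lower=True)
        mean = cho_solve(chol, W.T @ kappa)
        noise = solve_triangular(
            chol[0], rng.standard_normal(p + G), lower=True, trans="T"
        )
        theta = mean + noise

        u = theta[p:]
        chi = max(float(u @ u), 1e-12)
        sigma_g2 = float(
            geninvgauss.rvs(
                gig_p,
                np.sqrt(chi * psi_gig),
                scale=np.sqrt(chi / psi_gig),
                random_state=rng,
            )
        )

        if it >= spec.n_burnin:
            kept[it - spec.n_burnin, : p + G] = theta
            kept[it - spec.n_burnin, p + G] = np.sqrt(sigma_g2)
    return kept


def fit_model(design: DesignMatrices, spec: ModelSpec) -> PosteriorDraws:
    """Fit the hierarchical logistic model by PG-augmented Gibbs sampling.

    Each Gibbs sweep (1) refreshes the PG latent for every observation given
    the current linear predictor, (2) draws fixed effects and group
    intercepts jointly from their exact conditional Gaussian, and
    (3) updates the group-intercept variance from its GIG conditional.
    Deterministic given ``spec.seed``; chains use independent spawned
    streams.
    """
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_chains)
    chains = [
        _run_chain(design, spec, np.random.default_rng(child)) for child in children
    ]
    names = tuple(spec.fixed_effects) + tuple(
        f"intercept[{t.value}]" for t in design.group_levels
    ) + ("group_sd",)
    return PosteriorDraws(
        values=np.stack(chains),
        param_names=names,
        fixed_effects=tuple(spec.fixed_effects),
        group_levels=design.group_levels,
        dimension=spec.dimension,
    )


def grid_posterior_oracle(
    y: np.ndarray,
    X: np.ndarray,
    prior_coef_sd: float = 5.0,
    n_points: int = 801,
    half_width_sds: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Dense-grid quadrature of the exact logistic posterior (test oracle).

    Supports at most two free coefficients and no grouping: the unnormalized
    posterior (Bernoulli-logit likelihood times independent Normal(0,
    prior_coef_sd^2) priors) is evaluated on a uniform grid spanning
    +/- ``half_width_sds`` prior sds per axis and normalized by summation.
    Returns (posterior means, posterior sds).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    p = X.shape[1]
    if p > 2:
        raise ValueError("grid oracle supports at most 2 coefficients")
    axis = np.linspace(-half_width_sds * prior_coef_sd, half_width_sds * prior_coef_sd, n_points)
    if p == 1:
        grid = axis[:, None]
    else:
        a, b = np.meshgrid(axis, axis, indexing="ij")
        grid = np.column_stack([a.ravel(), b.ravel()])
    psi = grid @ X.T
    loglik = psi @ y - np.logaddexp(0.0, psi).sum(axis=1)
    logprior = -0.5 * (grid**2).sum(axis=1) / prior_coef_sd**2
    logpost = loglik + logprior
    weights = np.exp(logpost - logpost.max())
    weights /= weights.sum()
    mean = weights @ grid
    var = weights @ (grid - mean) ** 2
    return mean, np.sqrt(var)


def odds_ratio(log_odds_estimate: float) -> float:
    """exp of a log-odds coefficient: multiplicative change in improvement odds."""
    if not np.isfinite(log_odds_estimate):
        raise ValueError("log-odds estimate must be finite")
    return float(np.exp(log_odds_estimate))


def predict_probability(draws: PosteriorDraws, record: PatientRecord) -> float:
    """Posterior-mean improvement probability for one patient.

    Averages sigmoid(x' beta + u_g) over every post-burn-in draw.  The
    patient's aphasia type must have been present in the fitted cohort.
    """
    if record.aphasia_type not in draws.group_levels:
        raise KeyError(
            f"aphasia type {record.aphasia_type.value!r} was not in the fitted cohort"
        )
    x = np.array(
        [1.0, record.age, record.months_post_onset, record.education,
         float(record.african_american)]
    )
    p = len(draws.fixed_effects)
    g = draws.group_levels.index(record.aphasia_type)
    flat = draws.values.reshape(-1, draws.values.shape[-1])
    psi = flat[:, :p] @ x + flat[:, p + g]
    return float(expit(psi).mean())
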