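"""Pólya-Gamma random variates for logistic data augmentation.

A Pólya-Gamma variable PG(b, c) has the infinite convolution representation

    X  =  (1 / (2 pi^2)) * sum_{k>=1}  g_k / ((k - 1/2)^2 + c^2 / (4 pi^2)),

with g_k ~ Gamma(b, 1) i.i.d., and mean E[X] = (b / (2c)) * tanh(c / 2)
(limit b/4 at c = 0).  Augmenting each Bernoulli-logit observation with
omega_i ~ PG(1, psi_i) makes the conditional posterior of the regression
coefficients Gaussian, which is what the Gibbs sampler in
:mod:`aphasia_econ.model` exploits.

Two samplers are provided:

* an exact alternating-series rejection sampler for unit shape (the only
  shape the logistic augmentation needs), vectorized over the tilt vector;
* a truncated-sum sampler for arbitrary positive shape, using 200 gamma
  terms plus an analytic mean correction for the discarded tail.
"""

from __future__ import annotations

import numpy as np
from scipy.special import log_ndtr

__all__ = ["sample_polya_gamma", "sample_pg1", "pg_mean"]

# Devroye's threshold between the inverse-Gaussian and exponential proposal
# regions for the Jacobi J*(1, z) density.
_T = 0.64
_SUM_TERMS = 200


def pg_mean(shape: float, tilt: float) -> float:
    """Closed-form mean of PG(shape, tilt): (b/2c)·tanh(c/2), b/4 at c = 0."""
    c = abs(tilt)
    if c < 1e-12:
        return shape / 4.0
    return shape / (2.0 * c) * np.tanh(c / 2.0)


def _series_coef(n: int, x: np.ndarray) -> np.ndarray:
    """n-th coefficient a_n(x) of the alternating series for the J*(1, .) density."""
    half = n + 0.5
    with np.errstate(divide="ignore", over="ignore"):
        left = half * (2.0 / (np.pi * x)) ** 1.5 * np.pi * np.exp(-2.0 * half * half / x)
        right = np.pi * half * np.exp(-half * half * np.pi * np.pi * x / 2.0)
    return np.where(x > _T, right, left)


def _exp_branch_prob(z: np.ndarray) -> np.ndarray:
    """Probability of proposing from the truncated-exponential region (x > t)."""
    fz = np.pi * np.pi / 8.0 + z * z / 2.0
    b = np.sqrt(1.0 / _T) * (_T * z - 1.0)
    a = -np.sqrt(1.0 / _T) * (_T * z + 1.0)
    x0 = np.log(fz) + fz * _T
    with np.errstate(over="ignore"):
        xb = x0 - z + log_ndtr(b)
        xa = x0 + z + log_ndtr(a)
        q_div_p = 4.0 / np.pi * (np.exp(xb) + np.exp(xa))
    return 1.0 / (1.0 + q_div_p)


def _trunc_invgauss(z: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw from inverse-Gaussian(mu = 1/z, lambda = 1) truncated to (0, t].

    Vectorized two-regime rejection: a chi-based proposal when mu > t
    (including z = 0) and plain inverse-Gaussian draws retained when <= t
    otherwise.
    """
    m = z.size
    out = np.empty(m)
    big_mu = z < 1.0 / _T

    idx = np.flatnonzero(big_mu)
    while idx.size:
        zi = z[idx]
        e1 = rng.exponential(size=idx.size)
        e2 = rng.exponential(size=idx.size)
        ok = e1 * e1 <= 2.0 * e2 / _T
        x = _T / (1.0 + _T * e1) ** 2
        accept = ok & (rng.random(idx.size) <= np.exp(-zi * zi * x / 2.0))
        out[idx[accept]] = x[accept]
        idx = idx[~accept]

    idx = np.flatnonzero(~big_mu)
    while idx.size:
        mu = 1.0 / z[idx]
        y = rng.standard_normal(idx.size) ** 2
        muy = mu * y
        x = mu * (1.0 + 0.5 * muy - 0.5 * np.sqrt(muy * (4.0 + muy)))
        swap = rng.random(idx.size) > mu / (mu + x)
        x[swap] = (mu[swap] * mu[swap]) / x[swap]
        accept = x <= _T
        out[idx[accept]] = x[accept]
        idx = idx[~accept]

    return out


def sample_pg1(tilt: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Exact draws from PG(1, tilt_i) for a vector of tilts.

    Implements the alternating-series rejection sampler for the Jacobi
    J*(1, z) density (PG(1, c) = J*(1, c/2)/4): propose from a two-piece
    envelope (truncated inverse-Gaussian below t = 0.64, truncated
    exponential above) and accept by evaluating successive partial sums of
    the alternating series until they bracket the uniform variate.
    """
    tilt = np.atleast_1d(np.asarray(tilt, dtype=float))
    z = np.abs(tilt) / 2.0
    out = np.empty(z.shape)
    idx = np.arange(z.size)
    while idx.size:
        zi = z[idx]
        fz = np.pi * np.pi / 8.0 + zi * zi / 2.0
        use_exp = rng.random(idx.size) < _exp_branch_prob(zi)
        x = np.empty(idx.size)
        n_exp = int(use_exp.sum())
        if n_exp:
            x[use_exp] = _T + rng.exponential(size=n_exp) / fz[use_exp]
        if n_exp < idx.size:
            x[~use_exp] = _trunc_invgauss(zi[~use_exp], rng)

        partial = _series_coef(0, x)
        u = rng.random(idx.size) * partial
        undecided = np.ones(idx.size, dtype=bool)
        accepted = np.zeros(idx.size, dtype=bool)
        n = 0
        while undecided.any():
            n += 1
            coef = _series_coef(n, x)
            if n % 2 == 1:
                partial = partial - coef
                newly = undecided & (u <= partial)
                accepted |= newly
                undecided &= ~newly
            else:
                partial = partial + coef
                undecided &= ~(undecided & (u > partial))
            if n > 1000:  # pragma: no cover - series decides within a few terms
                raise RuntimeError("Polya-Gamma series failed to converge")
        out[idx[accepted]] = x[accepted] / 4.0
        idx = idx[~accepted]
    return out


def _sample_pg_sum(
    shape: float, tilt: float, rng: np.random.Generator, terms: int = _SUM_TERMS
) -> float:
    """Truncated-sum sampler for PG(shape, tilt), any shape > 0.

    Sums the first ``terms`` gamma components of the convolution
    representation and adds the (deterministic) expectation of the discarded
    tail so the sampler is unbiased in the mean; the neglected tail variance
    is O(terms^-3).
    """
    k = np.arange(1, terms + 1)
    denom = (k - 0.5) ** 2 + tilt * tilt / (4.0 * np.pi * np.pi)
    g = rng.standard_gamma(shape, size=terms)
    partial = (g / denom).sum() / (2.0 * np.pi * np.pi)
    tail = pg_mean(shape, tilt) - shape * (1.0 / denom).sum() / (2.0 * np.pi * np.pi)
    return partial + tail


def sample_polya_gamma(
    shape: float,
    tilt: float,
    rng: np.random.Generator,
    size: int | None = None,
):
    """Draw from the Pólya-Gamma PG(shape, tilt) distribution.

    Integer shapes use sums of exact unit-shape draws; non-integer shapes
    fall back to the truncated-sum sampler.  Returns a scalar, or an array
    when ``size`` is given.

    Raises ``ValueError`` for non-positive shape.
    """
    if not shape > 0:
        raise ValueError(f"Polya-Gamma shape must be positive, got {shape}")
    n = 1 if size is None else int(size)
    if float(shape).is_integer():
        b = int(shape)
        draws = sample_pg1(np.full(n * b, float(tilt)), rng).reshape(n, b).sum(axis=1)
    else:
        draws = np.array([_sample_pg_sum(shape, tilt, rng) for _ in range(n)])
    if size is None:
        return float(draws[0])
    return draws
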