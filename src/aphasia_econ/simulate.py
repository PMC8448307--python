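"""Synthetic telepractice-aphasia cohorts with the study's statistical structure.

The generator emulates a 20-patient telerehabilitation cohort: aphasia types
drawn at frequencies 9/8/2/1 (anomic, Broca's, conduction, global), age and
education truncated-normal, time post onset log-normal (the observed TPO is
strongly right-skewed: sd 64.1 months against mean 40.4), a 25% African
American share, and 5-12 attended sessions.  Improvement on each NOMS
dimension is Bernoulli with log-odds beta* . x plus a per-type varying
intercept, so the downstream hierarchical logistic fit can be validated by
parameter recovery against the known beta*.

The default generative coefficients are the fitted log-odds estimates of the
study's own regressions, which reproduce the observed improvement rates
(about 9/20 verbal, 15/20 comprehension) at the default covariate mix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import truncnorm

from .cohort import AphasiaType, Dimension, PatientRecord

__all__ = ["CohortConfig", "ConfigError", "generate_cohort", "lognormal_params"]


class ConfigError(ValueError):
    """Invalid generative configuration, raised before any sampling."""


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(log-mean, log-sd) of the log-normal matching the given moments."""
    if mean <= 0 or sd <= 0:
        raise ConfigError("moment-matching needs positive mean and sd")
    log_var = math.log1p((sd / mean) ** 2)
    return math.log(mean) - log_var / 2.0, math.sqrt(log_var)


_TPO_LOG_MEAN, _TPO_LOG_SD = lognormal_params(40.4, 64.1)

# Study-condition generative log-odds (intercept, age, months post onset,
# education, African American), per NOMS dimension.
_TRUE_COEF_VERBAL = (4.143, -0.055, -0.028, 0.002, 0.738)
_TRUE_COEF_COMP = (-15.113, 0.146, -0.004, 0.505, 0.814)

# Baseline NOMS Likert means per aphasia type (anomic, broca, conduction, global).
_NOMS_INITIAL_MEANS = {
    Dimension.VERBAL: (5.9, 3.5, 3.5, 1.0),
    Dimension.COMPREHENSION: (5.9, 4.8, 4.5, 1.0),
}

_TYPES = tuple(AphasiaType)


@dataclass(frozen=True)
class CohortConfig:
    """Generative law of a synthetic cohort; defaults are the study conditions."""

    n: int = 20
    type_probs: tuple[float, float, float, float] = (0.45, 0.40, 0.10, 0.05)
    age_mean: float = 60.9
    age_sd: float = 15.2
    age_bounds: tuple[float, float] = (18.0, 100.0)
    education_mean: float = 14.6
    education_sd: float = 2.3
    education_bounds: tuple[float, float] = (8.0, 22.0)
    tpo_log_mean: float = _TPO_LOG_MEAN
    tpo_log_sd: float = _TPO_LOG_SD
    p_african_american: float = 0.25
    session_min: int = 5
    session_max: int = 12
    true_coefficients: dict[Dimension, tuple[float, ...]] = field(
        default_factory=lambda: {
            Dimension.VERBAL: _TRUE_COEF_VERBAL,
            Dimension.COMPREHENSION: _TRUE_COEF_COMP,
        }
    )
    group_intercept_sd: float = 1.0
    noms_gain_poisson_mean: float = 0.5
    qcl_initial_mean: float = 3.0
    qcl_initial_sd: float = 0.8
    qcl_gain_mean_improver: float = 0.9
    qcl_gain_sd_improver: float = 0.4
    qcl_gain_mean_nonimprover: float = 0.1
    qcl_gain_sd_nonimprover: float = 0.2
    rate_per_session: float = 108.0

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ConfigError("cohort size must be positive")
        if len(self.type_probs) != len(_TYPES):
            raise ConfigError("type_probs must have one entry per aphasia type")
        if any(not 0 <= p <= 1 for p in self.type_probs):
            raise ConfigError("type probabilities must lie in [0, 1]")
        if abs(sum(self.type_probs) - 1.0) > 1e-12:
            raise ConfigError("type_probs must sum to 1")
        if not 0 <= self.p_african_american <= 1:
            raise ConfigError("p_african_american must lie in [0, 1]")
        if not 0 <= self.session_min <= self.session_max <= 12:
            raise ConfigError("need 0 <= session_min <= session_max <= 12")
        for dim in (Dimension.VERBAL, Dimension.COMPREHENSION):
            if dim not in self.true_coefficients:
                raise ConfigError(f"true_coefficients missing dimension {dim.value!r}")
            if len(self.true_coefficients[dim]) != 5:
                raise ConfigError("true_coefficients must have 5 entries per dimension")
        for name in ("age_sd", "education_sd", "tpo_log_sd", "qcl_initial_sd"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.group_intercept_sd < 0 or self.noms_gain_poisson_mean < 0:
            raise ConfigError("group_intercept_sd and gain mean must be non-negative")
        if self.rate_per_session <= 0:
            raise ConfigError("rate_per_session must be positive")


def _trunc_normal(
    mean: float, sd: float, bounds: tuple[float, float], size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    a, b = (bounds[0] - mean) / sd, (bounds[1] - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(config: CohortConfig, seed: int) -> list[PatientRecord]:
    """Draw one synthetic cohort; byte-identical for identical (config, seed).

    Improvement per dimension is Bernoulli with logit beta* . x + u_type
    where the per-type intercepts u are drawn once per cohort from
    Normal(0, group_intercept_sd^2).  Improvers gain 1 + Poisson(0.5) NOMS
    levels (truncated so the final score stays <= 7); baseline NOMS levels
    are capped at 6 so every patient has headroom to improve.  QCL change is
    Normal with improver/non-improver means, clipped so scores stay in
    [1, 5]; "improver" for QCL means improvement on at least one dimension.
    """
    if not isinstance(config, CohortConfig):
        raise ConfigError("config must be a CohortConfig")
    rng = np.random.default_rng(seed)
    n = config.n

    type_idx = rng.choice(len(_TYPES), size=n, p=np.asarray(config.type_probs, float))
    age = np.round(_trunc_normal(config.age_mean, config.age_sd, config.age_bounds, n, rng), 1)
    education = np.round(
        _trunc_normal(config.education_mean, config.education_sd,
                      config.education_bounds, n, rng), 1
    )
    tpo = np.round(rng.lognormal(config.tpo_log_mean, config.tpo_log_sd, size=n), 1)
    tpo = np.maximum(tpo, 0.1)
    race = (rng.random(n) < config.p_african_american).astype(int)
    sessions = rng.integers(config.session_min, config.session_max + 1, size=n)

    group_u = {
        dim: rng.normal(0.0, config.group_intercept_sd, size=len(_TYPES))
        for dim in (Dimension.VERBAL, Dimension.COMPREHENSION)
    }

    X = np.column_stack([np.ones(n), age, tpo, education, race.astype(float)])
    improved: dict[Dimension, np.ndarray] = {}
    initial: dict[Dimension, np.ndarray] = {}
    final: dict[Dimension, np.ndarray] = {}
    for dim in (Dimension.VERBAL, Dimension.COMPREHENSION):
        beta = np.asarray(config.true_coefficients[dim], float)
        logit = X @ beta + group_u[dim][type_idx]
        prob = 1.0 / (1.0 + np.exp(-logit))
        improved[dim] = (rng.random(n) < prob).astype(int)
        base_means = np.asarray(_NOMS_INITIAL_MEANS[dim])[type_idx]
        init = np.clip(np.rint(rng.normal(base_means, 1.0)), 1, 6).astype(int)
        gain = 1 + rng.poisson(config.noms_gain_poisson_mean, size=n)
        fin = np.where(improved[dim] == 1, np.minimum(init + gain, 7), init)
        initial[dim], final[dim] = init, fin

    any_improver = (improved[Dimension.VERBAL] | improved[Dimension.COMPREHENSION]).astype(bool)
    qcl_init = np.clip(
        rng.normal(config.qcl_initial_mean, config.qcl_initial_sd, size=n), 1.0, 4.9
    )
    gain = np.where(
        any_improver,
        rng.normal(config.qcl_gain_mean_improver, config.qcl_gain_sd_improver, size=n),
        rng.normal(config.qcl_gain_mean_nonimprover, config.qcl_gain_sd_nonimprover, size=n),
    )
    qcl_final = np.clip(qcl_init + gain, 1.0, 5.0)
    qcl_init = np.round(qcl_init, 2)
    qcl_final = np.round(qcl_final, 2)

    records = []
    for i in range(n):
        records.append(
            PatientRecord(
                patient_id=f"sim-{i:04d}",
                age=float(age[i]),
                education=float(education[i]),
                african_american=int(race[i]),
                months_post_onset=float(tpo[i]),
                aphasia_type=_TYPES[type_idx[i]],
                sessions_attended=int(sessions[i]),
                noms_verbal_initial=int(initial[Dimension.VERBAL][i]),
                noms_verbal_final=int(final[Dimension.VERBAL][i]),
                noms_comp_initial=int(initial[Dimension.COMPREHENSION][i]),
                noms_comp_final=int(final[Dimension.COMPREHENSION][i]),
                qcl_initial=float(qcl_init[i]),
                qcl_final=float(qcl_final[i]),
            )
        )
    return records
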