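"""Hierarchically structured synthetic studies with known ground truth.

Subjects are sampled from the generative model read forwards: draw group
effects, add per-subject Gaussian random effects, generate observations
through a *linear* forward model, and add observation noise.  The group
level only ever sees Gaussian posteriors, so a linear first level —
inverted exactly by conjugate Gaussian algebra, with an exact log evidence
— exercises every group-level code path while keeping the strongest oracle
in the suite available: model reduction of an exact linear model is exact.

The default configuration mirrors a 60-subject, four-region, two-condition
connectivity study: eight parameters (condition-specific self-connection
modulations of left/right x dorsal/ventral frontal regions), covariates
for the group mean, laterality index (LI), handedness, gender and age, a
group-mean effect profile matching magnitudes typical of such studies, and
an LI effect of 1.74 on the modulation of right dorsal cortex by words.
Between-subject (RFX) standard deviation defaults to sqrt(prior
variance/16) = 0.125, the same 1/16 convention the default priors assume.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .densities import FirstLevelUnit, GaussianDensity, log_det_stable

__all__ = [
    "DEFAULT_PARAMETER_LABELS",
    "SimulationConfig",
    "LinearProblem",
    "SimulatedStudy",
    "simulate_group",
    "simulate_first_level",
    "simulate_study",
]

_LN2PI = float(np.log(2.0 * np.pi))

#: Four frontal regions x two stimulus conditions, condition-major.
DEFAULT_PARAMETER_LABELS = (
    "lvF.pictures",
    "ldF.pictures",
    "rvF.pictures",
    "rdF.pictures",
    "lvF.words",
    "ldF.words",
    "rvF.words",
    "rdF.words",
)


def _default_effects() -> np.ndarray:
    """Default true effects, (covariates x parameters), covariates ordered
    mean, LI, handedness, gender, age."""
    effects = np.zeros((5, 8))
    # Group-mean modulation profile (log-scaling units).
    effects[0] = [-0.02, 0.40, -0.07, -0.23, 0.02, 0.06, 0.00, 0.38]
    # LI slope expressed on rdF.words only.
    effects[1, 7] = 1.74
    return effects


@dataclass
class SimulationConfig:
    """Generative settings for a synthetic hierarchical study."""

    n_subjects: int = 60
    parameter_labels: tuple[str, ...] = DEFAULT_PARAMETER_LABELS
    covariate_names: tuple[str, ...] = ("LI", "handedness", "gender", "age")
    true_effects: Optional[np.ndarray] = None  # (1+len(covariates), P)
    rfx_sd: float | np.ndarray = 0.125
    n_obs: int = 32
    noise_sd: float = 0.25
    prior_mean: float | np.ndarray = 0.0
    prior_variance: float | np.ndarray = 0.25
    covariates: Optional[pd.DataFrame] = None  # override the generator

    def __post_init__(self) -> None:
        p = len(self.parameter_labels)
        c = 1 + len(self.covariate_names)
        if self.true_effects is None:
            if (
                self.parameter_labels == DEFAULT_PARAMETER_LABELS
                and self.covariate_names == ("LI", "handedness", "gender", "age")
            ):
                self.true_effects = _default_effects()
            else:
                self.true_effects = np.zeros((c, p))
        self.true_effects = np.atleast_2d(
            np.asarray(self.true_effects, dtype=float)
        )
        if self.true_effects.shape != (c, p):
            raise ValueError(
                f"true_effects must have shape ({c}, {p}) "
                "(covariates incl. mean x parameters)"
            )
        self.rfx_sd = np.broadcast_to(
            np.asarray(self.rfx_sd, dtype=float), (p,)
        ).copy()
        if np.any(self.rfx_sd <= 0) or self.noise_sd <= 0:
            raise ValueError("all standard deviations must be positive")
        if self.n_obs < p:
            raise ValueError(
                f"n_obs={self.n_obs} < n_params={p}: the toy forward model "
                "would be under-determined"
            )

    @property
    def n_params(self) -> int:
        return len(self.parameter_labels)

    def first_level_prior(self) -> GaussianDensity:
        p = self.n_params
        mean = np.broadcast_to(
            np.asarray(self.prior_mean, dtype=float), (p,)
        ).copy()
        var = np.broadcast_to(
            np.asarray(self.prior_variance, dtype=float), (p,)
        ).copy()
        return GaussianDensity(self.parameter_labels, mean, np.diag(var))


def _default_covariates(config: SimulationConfig, rng) -> pd.DataFrame:
    n = config.n_subjects
    cols = {}
    for name in config.covariate_names:
        if name == "LI":
            cols[name] = np.clip(rng.normal(0.0, 0.5, n), -1.0, 1.0)
        elif name == "handedness":
            cols[name] = np.where(rng.random(n) < 0.9, 1.0, -1.0)
        elif name == "gender":
            cols[name] = np.where(rng.random(n) < 0.5, 1.0, -1.0)
        elif name == "age":
            cols[name] = rng.uniform(20.0, 60.0, n)
        else:
            cols[name] = rng.normal(0.0, 1.0, n)
    return pd.DataFrame(
        cols, index=pd.Index([f"sub-{i + 1:03d}" for i in range(n)], name="subject_id")
    )


def simulate_group(
    config: SimulationConfig, seed: int | np.random.Generator = 0
) -> tuple[np.ndarray, pd.DataFrame]:
    """Sample per-subject true parameters from the group model.

    Each subject's parameter vector is the design-predicted combination of
    group effects plus a zero-mean random effect with the configured
    per-parameter standard deviation.  Returns ``(theta_true, covariates)``
    with ``theta_true`` of shape (N, P).  Covariates used in the design
    prediction are mean-centred, matching the default design convention.
    """
    rng = np.random.default_rng(seed)
    if config.covariates is not None:
        covariates = config.covariates.copy()
        if covariates.shape[0] != config.n_subjects:
            raise ValueError("covariate table must have n_subjects rows")
    else:
        covariates = _default_covariates(config, rng)
    centred = covariates[list(config.covariate_names)].to_numpy(dtype=float)
    centred = centred - centred.mean(axis=0, keepdims=True)
    xb = np.column_stack([np.ones(config.n_subjects), centred])
    predicted = xb @ config.true_effects  # (N, P)
    rfx = rng.normal(0.0, 1.0, predicted.shape) * config.rfx_sd[None, :]
    return predicted + rfx, covariates


@dataclass
class LinearProblem:
    """One subject's toy linear inverse problem ``y = G theta + noise``."""

    subject_id: str
    y: np.ndarray
    design: np.ndarray  # (T, P)
    noise_sd: float
    labels: tuple[str, ...]

    def invert(self, prior: GaussianDensity) -> FirstLevelUnit:
        """Exact conjugate Bayesian inversion under ``prior``.

        Returns a unit whose posterior and log evidence are exact — not
        variational approximations — so downstream Gaussian identities
        (model reduction in particular) hold to machine precision.
        """
        if prior.labels != self.labels:
            raise ValueError(
                f"subject {self.subject_id}: prior labels do not match"
            )
        g = self.design
        t = g.shape[0]
        s2 = self.noise_sd**2
        prior_prec = prior.precision()
        post_prec = prior_prec + g.T @ g / s2
        post_cov = np.linalg.inv(post_prec)
        post_cov = (post_cov + post_cov.T) / 2.0
        post_mean = post_cov @ (prior_prec @ prior.mean + g.T @ self.y / s2)
        resid_cov = s2 * np.eye(t) + g @ prior.cov @ g.T
        diff = self.y - g @ prior.mean
        log_evidence = -0.5 * (
            t * _LN2PI
            + log_det_stable(resid_cov)
            + diff @ np.linalg.solve(resid_cov, diff)
        )
        return FirstLevelUnit(
            subject_id=self.subject_id,
            posterior=GaussianDensity(self.labels, post_mean, post_cov),
            prior=prior,
            free_energy=float(log_evidence),
        )


def simulate_first_level(
    theta_true: np.ndarray,
    config: SimulationConfig,
    seed: int | np.random.Generator = 0,
    subject_ids: Optional[Sequence[str]] = None,
    designs: Optional[np.ndarray] = None,
) -> tuple[list[FirstLevelUnit], list[LinearProblem]]:
    """Generate observations per subject and invert them exactly.

    Each subject gets a (T x P) standard-normal regressor matrix (their toy
    forward model), noisy observations of ``G theta_true``, and an exact
    conjugate posterior under the configured first-level prior.
    """
    rng = np.random.default_rng(seed)
    theta_true = np.atleast_2d(np.asarray(theta_true, dtype=float))
    n, p = theta_true.shape
    if p != config.n_params:
        raise ValueError("theta_true has the wrong number of parameters")
    if subject_ids is None:
        subject_ids = [f"sub-{i + 1:03d}" for i in range(n)]
    prior = config.first_level_prior()
    units, problems = [], []
    for i in range(n):
        g = (
            designs[i]
            if designs is not None
            else rng.normal(0.0, 1.0, (config.n_obs, p))
        )
        y = g @ theta_true[i] + rng.normal(0.0, config.noise_sd, config.n_obs)
        problem = LinearProblem(
            subject_id=str(subject_ids[i]),
            y=y,
            design=g,
            noise_sd=config.noise_sd,
            labels=config.parameter_labels,
        )
        problems.append(problem)
        units.append(problem.invert(prior))
    return units, problems


@dataclass
class SimulatedStudy:
    """A complete synthetic study: truth, covariates, units, problems."""

    config: SimulationConfig
    theta_true: np.ndarray
    covariates: pd.DataFrame
    units: list[FirstLevelUnit]
    problems: list[LinearProblem]
    seed: int


def simulate_study(
    config: Optional[SimulationConfig] = None, seed: int = 0
) -> SimulatedStudy:
    """Run the full generative model under a single seeded RNG stream."""
    if config is None:
        config = SimulationConfig()
    rng = np.random.default_rng(seed)
    theta_true, covariates = simulate_group(config, rng)
    units, problems = simulate_first_level(
        theta_true, config, rng, subject_ids=list(covariates.index)
    )
    return SimulatedStudy(
        config=config,
        theta_true=theta_true,
        covariates=covariates,
        units=units,
        problems=problems,
        seed=seed,
    )
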