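"""Assembly of the two-level hierarchical generative model.

The model states that each subject's first-level parameters are a linear
combination of group-level effects plus zero-mean Gaussian random effects
(RFX), and that the group effects themselves have a Gaussian prior:

    theta_2 ~ N(eta, Sigma3)
    theta_1 = X theta_2 + eps2,   eps2 ~ N(0, Sigma2)

The between-subject covariance ``Sigma2`` is parameterised through precision
components ``Q_j`` with log scaling hyperparameters ``gamma_j``:

    Pi2(gamma) = sum_j exp(gamma_j) Q_j,   Sigma2 = Pi2^-1

Defaults follow the empirical-Bayes convention for connectivity studies:
the first-level prior variance is reused as the prior variance around the
group mean (ratio ``alpha`` = 1), and the baseline RFX variance is the
first-level prior variance divided by ``beta`` = 16 — i.e. one assumes
between-subject variability has at most a quarter of the prior standard
deviation of the parameters themselves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .densities import GaussianDensity, FirstLevelUnit
from .design import FullDesign

__all__ = ["PEBPriors", "PEBModel", "default_priors", "rfx_precision"]


@dataclass
class PEBPriors:
    """Second-level priors and random-effects specification.

    Attributes
    ----------
    eta
        Prior expectation of the group-level effects (length C*P).
    sigma3
        Prior covariance of the group-level effects (C*P square).
    rfx_components
        Precision components ``Q_j`` (each P square, PSD).  The RFX
        precision is ``sum_j exp(gamma_j) Q_j``.
    gamma_prior
        Gaussian hyperprior over the log scaling parameters ``gamma``.
    alpha
        Ratio of group-effect prior variance to first-level prior variance.
    beta
        Ratio of first-level prior variance to baseline RFX variance.
    """

    eta: np.ndarray
    sigma3: np.ndarray
    rfx_components: list[np.ndarray]
    gamma_prior: GaussianDensity
    alpha: float = 1.0
    beta: float = 16.0
    off_floor: float = 1e-8

    def __post_init__(self) -> None:
        self.eta = np.atleast_1d(np.asarray(self.eta, dtype=float))
        self.sigma3 = np.atleast_2d(np.asarray(self.sigma3, dtype=float))
        k = self.eta.shape[0]
        if self.sigma3.shape != (k, k):
            raise ValueError("sigma3 shape does not match eta length")
        if np.linalg.eigvalsh((self.sigma3 + self.sigma3.T) / 2)[0] < -1e-8:
            raise ValueError("sigma3 must be PSD")
        self.rfx_components = [
            np.atleast_2d(np.asarray(q, dtype=float)) for q in self.rfx_components
        ]
        for j, q in enumerate(self.rfx_components):
            if np.linalg.eigvalsh((q + q.T) / 2)[0] < -1e-8:
                raise ValueError(f"RFX precision component Q_{j} must be PSD")
        if self.gamma_prior.dim != len(self.rfx_components):
            raise ValueError(
                "gamma_prior dimension must equal the number of RFX components"
            )

    @property
    def n_components(self) -> int:
        return len(self.rfx_components)


def rfx_precision(priors: PEBPriors, gamma: np.ndarray) -> np.ndarray:
    """Between-subject (RFX) precision ``sum_j exp(gamma_j) Q_j``."""
    gamma = np.atleast_1d(np.asarray(gamma, dtype=float))
    if gamma.shape[0] != priors.n_components:
        raise ValueError(
            f"gamma has length {gamma.shape[0]}, expected {priors.n_components}"
        )
    p = priors.rfx_components[0].shape[0]
    pi2 = np.zeros((p, p))
    for g, q in zip(gamma, priors.rfx_components):
        pi2 += np.exp(g) * q
    return pi2


def default_priors(
    first_level_prior: GaussianDensity,
    n_covariates: int,
    alpha: float = 1.0,
    beta: float = 16.0,
    gamma_prior_variance: float = 1.0 / 16.0,
    per_parameter_rfx: bool = False,
    covariate_scales: Optional[Sequence[float]] = None,
    off_floor: float = 1e-8,
) -> PEBPriors:
    """Default second-level priors derived from the first-level prior.

    The group-mean block inherits the first-level prior mean and (alpha-
    scaled) variances; other covariate blocks are zero-centred with the same
    variance scale.  A single shared RFX precision component is used by
    default (``Q_1 = diag(beta / v)``, v = first-level prior variances), with
    optional per-parameter components for parameter-wise RFX resolution.

    ``covariate_scales`` optionally rescales the prior variance of each
    covariate block (e.g. by an inverse squared regressor norm); by default
    no rescaling is applied.
    """
    if n_covariates < 1:
        raise ValueError("need at least one covariate (the group mean)")
    v = np.clip(np.diag(first_level_prior.cov), off_floor, None)
    p = v.shape[0]
    if covariate_scales is None:
        covariate_scales = np.ones(n_covariates)
    covariate_scales = np.asarray(covariate_scales, dtype=float)
    if covariate_scales.shape != (n_covariates,):
        raise ValueError("covariate_scales must have one entry per covariate")

    eta = np.concatenate(
        [first_level_prior.mean] + [np.zeros(p)] * (n_covariates - 1)
    )
    sigma3 = np.diag(
        np.concatenate([alpha * s * v for s in covariate_scales])
    )
    if per_parameter_rfx:
        components = [
            np.diag(np.where(np.arange(p) == k, beta / v[k], 0.0))
            for k in range(p)
        ]
    else:
        components = [np.diag(beta / v)]
    j = len(components)
    gamma_prior = GaussianDensity(
        tuple(f"gamma_{i}" for i in range(j)),
        np.zeros(j),
        gamma_prior_variance * np.eye(j),
    )
    return PEBPriors(
        eta=eta,
        sigma3=sigma3,
        rfx_components=components,
        gamma_prior=gamma_prior,
        alpha=alpha,
        beta=beta,
        off_floor=off_floor,
    )


@dataclass
class PEBModel:
    """A fully specified second-level model: design, priors, subject units."""

    design: FullDesign
    priors: PEBPriors
    units: list[FirstLevelUnit]

    def __post_init__(self) -> None:
        labels = self.design.within.parameter_labels
        for unit in self.units:
            if unit.labels != labels:
                raise ValueError(
                    f"subject {unit.subject_id}: parameter labels "
                    f"{unit.labels} do not match the within-design "
                    f"labels {labels}"
                )
        if len(self.units) != self.design.n_subjects:
            raise ValueError(
                f"{len(self.units)} subjects but the design has "
                f"{self.design.n_subjects} rows of subjects"
            )
        k = self.design.n_effects
        if self.priors.eta.shape[0] != k:
            raise ValueError(
                f"priors are over {self.priors.eta.shape[0]} effects but the "
                f"design has {k} columns"
            )

    @property
    def n_subjects(self) -> int:
        return len(self.units)

    @property
    def effect_labels(self) -> tuple[str, ...]:
        return self.design.effect_labels()

    def full_prior(self) -> GaussianDensity:
        """The prior N(eta, Sigma3) over group effects, with design-null
        columns clamped at their prior mean (near-zero variance)."""
        sigma3 = self.priors.sigma3.copy()
        zero_cols = np.where(~self.design.matrix.any(axis=0))[0]
        for j in zero_cols:
            sigma3[j, :] = 0.0
            sigma3[:, j] = 0.0
            sigma3[j, j] = self.priors.off_floor
        out = GaussianDensity(self.effect_labels, self.priors.eta, sigma3)
        # Cells held at a numerical point mass (clamped columns, or a
        # reduced prior passed in as sigma3) get their precision exactly,
        # block by block, so that model-reduction identities stay exact.
        diag = np.diag(sigma3)
        offdiag = sigma3 - np.diag(diag)
        is_point = (diag <= 2.0 * self.priors.off_floor) & (
            np.max(np.abs(offdiag), axis=0) == 0.0
        )
        if is_point.any():
            off = np.where(is_point)[0]
            on = np.where(~is_point)[0]
            prec = np.zeros_like(sigma3)
            prec[off, off] = 1.0 / diag[off]
            if on.size:
                from .densities import ridge

                prec[np.ix_(on, on)] = np.linalg.inv(
                    ridge(sigma3[np.ix_(on, on)])
                )
            out.set_precision(prec)
        return out
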