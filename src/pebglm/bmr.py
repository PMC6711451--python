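"""Bayesian Model Reduction (BMR).

Given a full model's prior and posterior, the posterior and log evidence of
any *reduced* model — one whose prior fixes some parameters at their prior
expectation — follow in closed form, without touching the data again.  In
precision (natural-parameter) form, with full prior ``(P0, m0)``, full
posterior ``(Pq, mq)`` and reduced prior ``(R0, r0)``:

    Rq     = Pq + R0 - P0
    Rq rq  = Pq mq + R0 r0 - P0 m0
    dF     = 1/2 (ln|Pq| + ln|R0| - ln|P0| - ln|Rq|)
           + 1/2 (rq' Rq rq - mq' Pq mq + m0' P0 m0 - r0' R0 r0)

``dF`` is the log-evidence difference of the reduced model relative to the
full one.  For linear-Gaussian models the identity is exact; this module is
therefore oracle-testable against explicit re-inversion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .densities import GaussianDensity, OFF_VARIANCE, log_det_stable, ridge

__all__ = ["ModelSpec", "reduce_prior", "bmr_evidence", "model_probabilities"]


@dataclass
class ModelSpec:
    """A named on/off pattern over a full parameter vector."""

    name: str
    on_mask: np.ndarray

    def __post_init__(self) -> None:
        self.on_mask = np.asarray(self.on_mask, dtype=bool).ravel()

    @property
    def n_on(self) -> int:
        return int(self.on_mask.sum())


def reduce_prior(
    full_prior: GaussianDensity,
    spec: ModelSpec,
    off_floor: float = OFF_VARIANCE,
) -> GaussianDensity:
    """Prior of the reduced model named by ``spec``.

    Switched-off cells keep the full prior mean but get variance
    ``off_floor`` (a numerical point mass); their cross-covariances are
    zeroed.  Switched-on cells are untouched.
    """
    if spec.on_mask.shape[0] != full_prior.dim:
        raise ValueError(
            f"mask length {spec.on_mask.shape[0]} does not match density "
            f"dimension {full_prior.dim}"
        )
    cov = full_prior.cov.copy()
    off = np.where(~spec.on_mask)[0]
    on = np.where(spec.on_mask)[0]
    cov[off, :] = 0.0
    cov[:, off] = 0.0
    cov[off, off] = off_floor
    out = GaussianDensity(full_prior.labels, full_prior.mean.copy(), cov)
    # The block structure makes the precision exact: inverting the on-block
    # alone avoids ridge noise on the (huge) off-cell precisions.
    prec = np.zeros_like(cov)
    prec[off, off] = 1.0 / off_floor
    if on.size:
        prec[np.ix_(on, on)] = np.linalg.inv(ridge(cov[np.ix_(on, on)]))
    return out.set_precision(prec)


def bmr_evidence(
    full_posterior: GaussianDensity,
    full_prior: GaussianDensity,
    reduced_prior: GaussianDensity,
) -> tuple[GaussianDensity, float]:
    """Reduced model's posterior and log-evidence change via BMR.

    Returns ``(reduced_posterior, dF)`` where ``dF`` is the reduced model's
    log evidence minus the full model's.
    """
    for other, name in ((full_prior, "full prior"), (reduced_prior, "reduced prior")):
        if other.labels != full_posterior.labels:
            raise ValueError(
                f"{name} labels do not match the posterior's labels"
            )
    pq = full_posterior.precision()
    p0 = full_prior.precision()
    r0 = reduced_prior.precision()
    rq = pq + r0 - p0
    rq = (rq + rq.T) / 2.0
    eigvals = np.linalg.eigvalsh(rq)
    if eigvals[0] <= 0.0:
        raise ValueError(
            "implied reduced posterior precision is indefinite "
            f"(min eigenvalue {eigvals[0]:.3e}); consider a larger "
            "off-floor variance for switched-off parameters"
        )
    mq = full_posterior.mean
    m0 = full_prior.mean
    rm0 = reduced_prior.mean
    h = pq @ mq + r0 @ rm0 - p0 @ m0
    rmq = np.linalg.solve(rq, h)
    d_f = 0.5 * (
        log_det_stable(pq)
        + log_det_stable(r0)
        - log_det_stable(p0)
        - log_det_stable(rq)
    ) + 0.5 * (
        rmq @ rq @ rmq - mq @ pq @ mq + m0 @ p0 @ m0 - rm0 @ r0 @ rm0
    )
    cov = np.linalg.inv(rq)
    cov = (cov + cov.T) / 2.0
    reduced_posterior = GaussianDensity(
        full_posterior.labels, rmq, cov
    ).set_precision(rq)
    return reduced_posterior, float(d_f)


def model_probabilities(log_evidences: np.ndarray) -> np.ndarray:
    """Posterior model probabilities from log evidences (uniform model prior)."""
    log_evidences = np.asarray(log_evidences, dtype=float)
    return np.exp(log_evidences - logsumexp(log_evidences))
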