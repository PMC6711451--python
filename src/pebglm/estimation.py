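"""Fitting the second-level model.

Each subject's data enter only through their first-level posterior and
prior.  Subtracting prior from posterior precision recovers the Gaussian
*data density* for that subject — the likelihood the data place on the
parameters, up to a constant that is absorbed into the subject's stored
free energy.  Conditional on the RFX hyperparameters ``gamma`` the model is
then an exact linear-Gaussian regression of these pseudo-observations on
the design matrix, so the group posterior and the marginal likelihood are
closed-form.  The hyperparameters are optimised by damped Newton ascent on

    J(gamma) = ln p(pseudo-data | gamma) + ln p(gamma)

and the reported second-level free energy adds a Laplace (Gaussian
entropy) correction for the uncertainty over ``gamma``.

Subjects contribute precision ``X_i' (Sigma2 + SigmaTilde_i)^-1 X_i`` to
the group posterior, where ``SigmaTilde_i`` is the subject's data-density
covariance: imprecise subjects are automatically down-weighted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import norm as _normal

from .densities import (
    FirstLevelUnit,
    GaussianDensity,
    log_det_stable,
    ridge,
)
from .model import PEBModel, rfx_precision

__all__ = [
    "FitSettings",
    "PEBResult",
    "subject_data_density",
    "conditional_group_posterior",
    "peb_objective",
    "fit_peb",
    "refit_with_empirical_priors",
    "summary_table",
]

_LN2PI = float(np.log(2.0 * np.pi))


@dataclass
class FitSettings:
    """Convergence controls for the hyperparameter ascent."""

    tol: float = 1e-4  # nats; stop when the objective gain drops below this
    max_iter: int = 64
    fd_step: float = 1e-3  # finite-difference step for gamma derivatives
    max_halvings: int = 16


@dataclass
class PEBResult:
    """Posterior group effects, hyperparameters, free energy, and the
    per-subject empirical priors implied by the fitted group level."""

    group_posterior: GaussianDensity
    gamma_posterior: GaussianDensity
    rfx_estimate: np.ndarray
    free_energy: float
    empirical_priors: dict[str, GaussianDensity]
    iterations: list[float]
    converged: bool
    full_prior: GaussianDensity
    sigma2: np.ndarray
    model: PEBModel


def subject_data_density(
    unit: FirstLevelUnit, floor_scale: float = 1e-8
) -> tuple[np.ndarray, np.ndarray, float]:
    """Gaussian data density implied by a subject's posterior and prior.

    Returns ``(r, D, c)`` such that ``p(y | theta) = exp(c) N(theta; r, D^-1)``
    with ``D = P_post - P_prior`` (eigenvalue-floored to stay PD: directions
    the data did not inform get a near-zero data precision, i.e. an
    essentially flat likelihood).  ``c`` absorbs the subject's stored free
    energy when available, else the prior-independent normalisation alone.
    """
    pq = unit.posterior.precision()
    p0 = unit.prior.precision()
    d = (pq - p0 + (pq - p0).T) / 2.0
    eigvals, vecs = np.linalg.eigh(d)
    floor = floor_scale * max(float(np.abs(eigvals).max()), 1.0)
    eigvals = np.clip(eigvals, floor, None)
    d = (vecs * eigvals) @ vecs.T
    r = np.linalg.solve(d, pq @ unit.posterior.mean - p0 @ unit.prior.mean)
    p = unit.posterior.dim
    mq, m0 = unit.posterior.mean, unit.prior.mean
    c = (
        (unit.free_energy or 0.0)
        + 0.5 * (log_det_stable(ridge(pq)) - log_det_stable(ridge(p0)) - log_det_stable(d))
        + 0.5 * p * _LN2PI
        + 0.5 * (r @ d @ r - mq @ pq @ mq + m0 @ p0 @ m0)
    )
    return r, d, float(c)


class _Prepared:
    """Per-model quantities that do not depend on gamma."""

    def __init__(self, model: PEBModel):
        design = model.design
        p = design.n_params
        n = design.n_subjects
        self.x = np.stack([design.subject_block(i) for i in range(n)])  # (N,P,K)
        r_list, st_list, c_total = [], [], 0.0
        for unit in model.units:
            r, d, c = subject_data_density(unit)
            r_list.append(r)
            st_list.append(np.linalg.inv(d))
            c_total += c
        self.r = np.stack(r_list)  # (N,P)
        self.sigma_tilde = np.stack(st_list)  # (N,P,P)
        self.c_total = c_total
        full_prior = model.full_prior()
        self.eta = full_prior.mean
        self.p3 = full_prior.precision()
        self.logdet_p3 = log_det_stable(self.p3)
        self.full_prior = full_prior
        self.n, self.p, self.k = n, p, self.x.shape[2]
        self.e = self.r - self.x @ self.eta  # (N,P) residuals about prior mean


def _conditional(prep: _Prepared, sigma2: np.ndarray):
    """Exact conditional posterior and log marginal of the pseudo-data."""
    a = sigma2[None, :, :] + prep.sigma_tilde  # (N,P,P)
    chol = np.linalg.cholesky(a)
    logdet_a = 2.0 * np.log(np.diagonal(chol, axis1=1, axis2=2)).sum()
    a_inv = np.linalg.inv(a)
    h = np.einsum("npc,npq,nqd->cd", prep.x, a_inv, prep.x)
    b = np.einsum("npc,npq,nq->c", prep.x, a_inv, prep.e)
    sp = prep.p3 + h
    sp = (sp + sp.T) / 2.0
    mean = prep.eta + np.linalg.solve(sp, b)
    quad = float(np.einsum("np,npq,nq->", prep.e, a_inv, prep.e)) - float(
        b @ np.linalg.solve(sp, b)
    )
    logdet_sp = log_det_stable(sp)
    log_marginal = -0.5 * (
        prep.n * prep.p * _LN2PI + logdet_a - prep.logdet_p3 + logdet_sp + quad
    )
    cov = np.linalg.inv(sp)
    cov = (cov + cov.T) / 2.0
    return mean, cov, float(log_marginal), sp


def conditional_group_posterior(
    model: PEBModel, gamma: np.ndarray
) -> tuple[GaussianDensity, float]:
    """Exact conditional posterior over group effects at fixed ``gamma``.

    Returns the posterior and the conditional free energy: the log marginal
    likelihood of the subjects' data (up to their stored first-level
    accuracies) under the hierarchical model with the RFX precision pinned
    at ``gamma``.
    """
    prep = _Prepared(model)
    sigma2 = np.linalg.inv(ridge(rfx_precision(model.priors, gamma)))
    mean, cov, log_marginal, sp = _conditional(prep, sigma2)
    posterior = GaussianDensity(model.effect_labels, mean, cov).set_precision(sp)
    return posterior, prep.c_total + log_marginal


def peb_objective(model: PEBModel, gamma: np.ndarray) -> float:
    """The free-energy objective maximised over ``gamma``:
    conditional log marginal plus the log hyperprior density."""
    prep = _Prepared(model)
    return _objective(prep, model, np.asarray(gamma, dtype=float))


def _objective(prep: _Prepared, model: PEBModel, gamma: np.ndarray) -> float:
    sigma2 = np.linalg.inv(ridge(rfx_precision(model.priors, gamma)))
    _, _, log_marginal, _ = _conditional(prep, sigma2)
    return prep.c_total + log_marginal + model.priors.gamma_prior.logpdf(gamma)


def _fd_grad_hess(f, x: np.ndarray, h: float) -> tuple[np.ndarray, np.ndarray]:
    """Central-difference gradient and Hessian (small dimension)."""
    j = x.shape[0]
    grad = np.zeros(j)
    hess = np.zeros((j, j))
    f0 = f(x)
    fp = np.zeros(j)
    fm = np.zeros(j)
    for i in range(j):
        ei = np.eye(j)[i] * h
        fp[i] = f(x + ei)
        fm[i] = f(x - ei)
        grad[i] = (fp[i] - fm[i]) / (2 * h)
        hess[i, i] = (fp[i] - 2 * f0 + fm[i]) / h**2
    for i in range(j):
        for l in range(i + 1, j):
            ei = np.eye(j)[i] * h
            el = np.eye(j)[l] * h
            hess[i, l] = hess[l, i] = (
                f(x + ei + el) - f(x + ei - el) - f(x - ei + el) + f(x - ei - el)
            ) / (4 * h**2)
    return grad, hess


def fit_peb(model: PEBModel, settings: Optional[FitSettings] = None) -> PEBResult:
    """Fit the second-level model.

    Alternates the exact conditional posterior over group effects with
    damped Newton updates of the RFX log-scaling hyperparameters ``gamma``,
    until the free-energy gain per iteration falls below ``settings.tol``.
    """
    if settings is None:
        settings = FitSettings()
    if model.n_subjects < 1:
        raise ValueError("need at least one subject")
    prep = _Prepared(model)
    j = model.priors.n_components
    gamma = model.priors.gamma_prior.mean.copy()

    def obj(g: np.ndarray) -> float:
        val = _objective(prep, model, g)
        if not np.isfinite(val):
            raise FloatingPointError(
                f"free energy is not finite at gamma={g}"
            )
        return val

    f_curr = obj(gamma)
    trace = [f_curr]
    converged = False
    hess = -np.eye(j)
    for _ in range(settings.max_iter):
        grad, hess = _fd_grad_hess(obj, gamma, settings.fd_step)
        # Make the Hessian safely negative definite before the Newton step.
        eigmax = float(np.linalg.eigvalsh(hess)[-1])
        if eigmax > -1e-8:
            hess = hess - (eigmax + 1e-4) * np.eye(j)
        step = -np.linalg.solve(hess, grad)
        scale = 1.0
        improved = False
        for _ in range(settings.max_halvings):
            cand = gamma + scale * step
            f_cand = obj(cand)
            if f_cand >= f_curr:
                gamma, f_curr, improved = cand, f_cand, True
                break
            scale /= 2.0
        trace.append(f_curr)
        if not improved or trace[-1] - trace[-2] < settings.tol:
            converged = trace[-1] - trace[-2] < settings.tol
            break

    # Laplace posterior over gamma from the curvature at the optimum.
    _, hess = _fd_grad_hess(obj, gamma, settings.fd_step)
    neg_hess = -(hess + hess.T) / 2.0
    eigvals, vecs = np.linalg.eigh(neg_hess)
    eigvals = np.clip(eigvals, 1e-8, None)
    gamma_cov = (vecs / eigvals) @ vecs.T
    gamma_posterior = GaussianDensity(
        model.priors.gamma_prior.labels, gamma, gamma_cov
    )
    free_energy = f_curr + 0.5 * (j * _LN2PI + log_det_stable(ridge(gamma_cov)))

    pi2 = rfx_precision(model.priors, gamma)
    sigma2 = np.linalg.inv(ridge(pi2))
    labels = model.effect_labels
    # Reported group posterior marginalises over hyperparameter uncertainty
    # via 3-point Gauss-Hermite quadrature on the Laplace posterior of
    # gamma (mixture moments); with many components, fall back to the
    # conditional posterior at the mode.
    if j <= 2:
        eigvals_g, vecs_g = np.linalg.eigh(gamma_cov)
        nodes = [(gamma, 1.0 - j / 3.0)]
        for axis in range(j):
            step = np.sqrt(3.0 * max(eigvals_g[axis], 0.0)) * vecs_g[:, axis]
            nodes.append((gamma + step, 1.0 / 6.0))
            nodes.append((gamma - step, 1.0 / 6.0))
        mix_mean = np.zeros(prep.k)
        mix_second = np.zeros((prep.k, prep.k))
        for g_node, w in nodes:
            s2 = np.linalg.inv(ridge(rfx_precision(model.priors, g_node)))
            m_node, c_node, _, _ = _conditional(prep, s2)
            mix_mean += w * m_node
            mix_second += w * (c_node + np.outer(m_node, m_node))
        cov = mix_second - np.outer(mix_mean, mix_mean)
        cov = (cov + cov.T) / 2.0
        mean = mix_mean
        group_posterior = GaussianDensity(labels, mean, cov)
    else:
        mean, cov, _, sp = _conditional(prep, sigma2)
        group_posterior = GaussianDensity(labels, mean, cov).set_precision(sp)

    param_labels = model.design.within.parameter_labels
    empirical = {}
    for i, unit in enumerate(model.units):
        xi = prep.x[i]
        emp_cov = sigma2 + xi @ cov @ xi.T
        empirical[unit.subject_id] = GaussianDensity(
            param_labels, xi @ mean, (emp_cov + emp_cov.T) / 2.0
        )

    return PEBResult(
        group_posterior=group_posterior,
        gamma_posterior=gamma_posterior,
        rfx_estimate=np.diag(sigma2).copy(),
        free_energy=float(free_energy),
        empirical_priors=empirical,
        iterations=trace,
        converged=converged,
        full_prior=prep.full_prior,
        sigma2=sigma2,
        model=model,
    )


def refit_with_empirical_priors(
    problems,
    peb: PEBResult,
    n_rounds: int = 1,
    settings: Optional[FitSettings] = None,
) -> tuple[list[FirstLevelUnit], PEBResult, list[float]]:
    """Re-estimate each subject under the group-implied empirical prior.

    ``problems`` are first-level inverse problems exposing ``subject_id``
    and ``invert(prior) -> FirstLevelUnit`` (e.g.
    :class:`pebglm.simulate.LinearProblem`).  Each round replaces every
    subject's prior with their empirical prior from the current group fit,
    re-inverts, and re-fits the group model.  Stops early and returns the
    best round if the total free energy drops.
    """
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    by_id = {p.subject_id: p for p in problems}
    missing = [u.subject_id for u in peb.model.units if u.subject_id not in by_id]
    if missing:
        raise ValueError(f"no first-level problem for subjects: {missing}")
    best_units = list(peb.model.units)
    best_result = peb
    trace = [peb.free_energy]
    current = peb
    for _ in range(n_rounds):
        new_units = [
            by_id[u.subject_id].invert(current.empirical_priors[u.subject_id])
            for u in current.model.units
        ]
        new_model = PEBModel(
            design=current.model.design,
            priors=current.model.priors,
            units=new_units,
        )
        current = fit_peb(new_model, settings)
        trace.append(current.free_energy)
        # Tolerance absorbs hyperparameter-ascent noise between rounds.
        if current.free_energy >= best_result.free_energy - 1e-3:
            best_units, best_result = new_units, current
        else:
            break
    return best_units, best_result, trace


def summary_table(result: PEBResult) -> pd.DataFrame:
    """Covariate x parameter table of posterior means, sds and the posterior
    probability that each effect shares the sign of its mean."""
    design = result.model.design
    rows = []
    sds = result.group_posterior.sd
    for (cov_name, par), m, s in zip(
        design.col_labels, result.group_posterior.mean, sds
    ):
        prob = float(_normal.cdf(abs(m) / s)) if s > 0 else 1.0
        rows.append(
            {
                "covariate": cov_name,
                "parameter": par,
                "mean": m,
                "sd": s,
                "prob_same_sign": prob,
            }
        )
    return pd.DataFrame(rows)
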