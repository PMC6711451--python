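"""Multivariate-normal containers and the Gaussian identities used everywhere else.

Every level of the hierarchy — subject posteriors, subject priors, group
priors, group posteriors — is a :class:`GaussianDensity` over a *named*
parameter vector.  Keeping the names on the density (rather than on the
caller) lets dimension mismatches fail with the offending labels attached,
which matters once Kronecker-structured designs start slicing blocks out of
40-dimensional vectors.

Parameters that a model "switches off" are represented by shrinking their
prior variance to :data:`OFF_VARIANCE`, never by deleting the dimension:
all models in a comparison therefore share one coordinate system.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "OFF_VARIANCE",
    "GaussianDensity",
    "FirstLevelUnit",
    "ridge",
    "log_det_stable",
    "combine_precisions",
]

#: Prior variance used for a parameter that is "switched off" (fixed at its
#: prior expectation).  Small enough to be numerically indistinguishable from
#: a point mass, large enough to keep model-reduction formulas finite.
OFF_VARIANCE = 1e-8


def ridge(m: np.ndarray, eps_scale: float = 1e-8) -> np.ndarray:
    """Return ``m`` plus a small diagonal ridge proportional to its scale.

    Variational posteriors are frequently near-singular; a relative ridge of
    ``eps_scale * mean(diag)`` keeps inversions finite without visibly
    perturbing well-conditioned matrices.
    """
    m = np.asarray(m, dtype=float)
    scale = float(np.mean(np.abs(np.diag(m))))
    if scale == 0.0:
        scale = 1.0
    return m + (eps_scale * scale) * np.eye(m.shape[0])


def log_det_stable(m: np.ndarray, tol: float = 1e-6) -> float:
    """Natural-log determinant of a symmetric PSD matrix.

    Uses a Cholesky factorization when possible and falls back to an
    eigendecomposition, raising if the matrix is indefinite beyond a relative
    tolerance instead of silently returning a complex or NaN result.
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {m.shape}")
    try:
        chol = np.linalg.cholesky(m)
        return float(2.0 * np.sum(np.log(np.diag(chol))))
    except np.linalg.LinAlgError:
        pass
    eigvals = np.linalg.eigvalsh((m + m.T) / 2.0)
    scale = max(float(eigvals[-1]), 1.0)
    if eigvals[0] < -tol * scale:
        raise ValueError(
            "matrix is indefinite: min eigenvalue "
            f"{eigvals[0]:.3e} (scale {scale:.3e})"
        )
    floor = max(tol * scale * 1e-8, 1e-300)
    return float(np.sum(np.log(np.clip(eigvals, floor, None))))


def _as_labels(labels: Sequence[str]) -> tuple[str, ...]:
    out = tuple(str(x) for x in labels)
    if len(set(out)) != len(out):
        raise ValueError("parameter labels must be unique")
    return out


@dataclass
class GaussianDensity:
    """A multivariate normal over a named parameter vector.

    Parameters
    ----------
    labels
        Ordered parameter names; define the coordinate system.
    mean
        Expected values, one per label.  Units are model-specific (for
        connectivity parameters: unitless log-scaling values or Hz).
    cov
        Symmetric positive-semidefinite covariance, same ordering.
    """

    labels: tuple[str, ...]
    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        self.labels = _as_labels(self.labels)
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        n = len(self.labels)
        if self.mean.shape != (n,):
            raise ValueError(
                f"mean has shape {self.mean.shape} but there are {n} labels"
            )
        if self.cov.shape != (n, n):
            raise ValueError(
                f"cov has shape {self.cov.shape} but there are {n} labels"
            )
        asym = float(np.max(np.abs(self.cov - self.cov.T))) if n else 0.0
        scale = max(float(np.max(np.abs(self.cov))) if n else 0.0, 1e-12)
        if asym > 1e-6 * scale:
            raise ValueError(f"covariance is asymmetric (max dev {asym:.3e})")
        self.cov = (self.cov + self.cov.T) / 2.0
        if n and n <= 512:
            min_eig = float(np.linalg.eigvalsh(self.cov)[0])
            if min_eig < -1e-6 * scale:
                raise ValueError(
                    f"covariance is not PSD: min eigenvalue {min_eig:.3e}"
                )
        self._precision: Optional[np.ndarray] = None

    @property
    def dim(self) -> int:
        return len(self.labels)

    @property
    def sd(self) -> np.ndarray:
        """Marginal standard deviations (sqrt of the covariance diagonal)."""
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))

    def precision(self) -> np.ndarray:
        """Inverse covariance (exact when the producer supplied it,
        otherwise computed after ridge regularization)."""
        if self._precision is not None:
            return self._precision
        return np.linalg.inv(ridge(self.cov))

    def set_precision(self, precision: np.ndarray) -> "GaussianDensity":
        """Attach the exact precision matrix matching ``cov`` (used by
        estimators that computed it natively, to avoid inversion noise)."""
        precision = np.asarray(precision, dtype=float)
        if precision.shape != self.cov.shape:
            raise ValueError("precision shape does not match covariance")
        self._precision = precision
        return self

    def index_of(self, labels: Sequence[str]) -> np.ndarray:
        pos = {lab: i for i, lab in enumerate(self.labels)}
        missing = [lab for lab in labels if lab not in pos]
        if missing:
            raise KeyError(f"unknown parameter labels: {missing}")
        return np.array([pos[lab] for lab in labels], dtype=int)

    def marginal(self, labels: Sequence[str]) -> "GaussianDensity":
        idx = self.index_of(labels)
        return GaussianDensity(
            tuple(labels), self.mean[idx], self.cov[np.ix_(idx, idx)]
        )

    def logpdf(self, x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float)
        cov = ridge(self.cov)
        diff = x - self.mean
        return float(
            -0.5
            * (
                self.dim * np.log(2 * np.pi)
                + log_det_stable(cov)
                + diff @ np.linalg.solve(cov, diff)
            )
        )

    def allclose(self, other: "GaussianDensity", atol: float = 1e-8) -> bool:
        return (
            self.labels == other.labels
            and np.allclose(self.mean, other.mean, atol=atol)
            and np.allclose(self.cov, other.cov, atol=atol)
        )


@dataclass
class FirstLevelUnit:
    """One subject's first-level estimate: posterior, prior, log evidence.

    The posterior and prior must live on identical labels so that group-level
    algebra can subtract their precisions to recover the data likelihood.
    The posterior need not dominate the prior in precision — data may be
    uninformative on some directions — but both covariances must be
    invertible after ridge regularization.
    """

    subject_id: str
    posterior: GaussianDensity
    prior: GaussianDensity
    free_energy: Optional[float] = None

    def __post_init__(self) -> None:
        self.subject_id = str(self.subject_id)
        if self.posterior.labels != self.prior.labels:
            raise ValueError(
                f"subject {self.subject_id}: posterior labels "
                f"{self.posterior.labels} != prior labels {self.prior.labels}"
            )
        if self.free_energy is not None:
            self.free_energy = float(self.free_energy)

    @property
    def labels(self) -> tuple[str, ...]:
        return self.posterior.labels


def combine_precisions(
    a: GaussianDensity,
    b_precision_update: np.ndarray,
    b_mean_update: np.ndarray,
) -> GaussianDensity:
    """Combine a Gaussian with an additive precision / precision-mean update.

    This is the conjugate Gaussian product in natural-parameter form: the
    result has precision ``P_a + dP`` and precision-mean ``P_a m_a + dPm``.
    It underlies both Bayesian model reduction and empirical-prior updates.
    """
    d_prec = np.atleast_2d(np.asarray(b_precision_update, dtype=float))
    d_pm = np.atleast_1d(np.asarray(b_mean_update, dtype=float))
    n = a.dim
    if d_prec.shape != (n, n) or d_pm.shape != (n,):
        raise ValueError(
            f"update shapes {d_prec.shape}/{d_pm.shape} do not match density "
            f"over labels {a.labels}"
        )
    prec_a = a.precision()
    prec_new = prec_a + d_prec
    try:
        cov_new = np.linalg.inv(ridge(prec_new))
        # Fail loudly on an indefinite result rather than returning garbage.
        log_det_stable(ridge(prec_new))
    except (np.linalg.LinAlgError, ValueError) as err:
        cond = np.linalg.cond(prec_new)
        raise ValueError(
            f"combined precision is singular or indefinite "
            f"(condition number {cond:.3e})"
        ) from err
    mean_new = cov_new @ (prec_a @ a.mean + d_pm)
    cov_new = (cov_new + cov_new.T) / 2.0
    return GaussianDensity(a.labels, mean_new, cov_new)
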