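"""Leave-one-out cross-validation of the group model's predictive validity.

For each fold the group model is fitted to all but one subject.  The
left-out subject's target covariate is treated as unknown with a Gaussian
prior matched to the training distribution; every candidate value implies
an empirical prior over that subject's parameters, whose evidence against
the subject's first-level data density scores the candidate.  Normalising
over a dense grid of candidates yields a predictive posterior for the
covariate, reported as its mean and central 90% credible interval.  The
out-of-sample Pearson correlation between predicted and actual covariate
values summarises predictive validity across folds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .densities import FirstLevelUnit, log_det_stable, ridge
from .design import WithinDesign, build_between_design, build_full_design
from .estimation import FitSettings, fit_peb, subject_data_density
from .model import PEBModel, default_priors

__all__ = ["LooResult", "loo_cv"]

_LN2PI = float(np.log(2.0 * np.pi))


@dataclass
class LooResult:
    """Per-subject predictions and the cross-fold summary."""

    predictions: pd.DataFrame  # subject_id, actual, predicted, lower90, upper90
    correlation: float
    p_value: float
    coverage_count: int  # subjects whose actual value fell in the 90% interval

    @property
    def n_subjects(self) -> int:
        return len(self.predictions)

    def summary(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "correlation": self.correlation,
            "p_value": self.p_value,
            "coverage_count": self.coverage_count,
        }


def _gaussian_logpdf(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> float:
    diff = x - mean
    cov = ridge(cov)
    return float(
        -0.5
        * (
            x.shape[0] * _LN2PI
            + log_det_stable(cov)
            + diff @ np.linalg.solve(cov, diff)
        )
    )


def loo_cv(
    units: Sequence[FirstLevelUnit],
    covariates: pd.DataFrame,
    target_covariate: str,
    within: Optional[WithinDesign] = None,
    cells: Optional[Sequence[str]] = None,
    grid_points: int = 64,
    grid_span: float = 4.0,
    settings: Optional[FitSettings] = None,
    priors_kwargs: Optional[dict] = None,
) -> LooResult:
    """Leave-one-out prediction of ``target_covariate`` for every subject.

    ``cells`` optionally restricts the first-level parameters carried into
    the group model (default: all parameters of the units).  The target
    covariate is mean-centred over the training subjects in each fold, and
    predictions are reported on that centred scale.
    """
    units = list(units)
    n = len(units)
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 subjects")
    if target_covariate not in covariates.columns:
        raise KeyError(f"unknown covariate {target_covariate!r}")
    if covariates.shape[0] != n:
        raise ValueError("covariate table must have one row per subject")
    if float(np.ptp(covariates[target_covariate].to_numpy(dtype=float))) == 0.0:
        raise ValueError(f"covariate {target_covariate!r} has zero variance")
    cov_tab = covariates.copy()
    if "subject_id" in cov_tab.columns:
        cov_tab = cov_tab.set_index(cov_tab["subject_id"].astype(str)).drop(
            columns="subject_id"
        )
    else:
        cov_tab.index = [u.subject_id for u in units]

    if cells is not None:
        units = [
            FirstLevelUnit(
                u.subject_id,
                u.posterior.marginal(cells),
                u.prior.marginal(cells),
                u.free_energy,
            )
            for u in units
        ]
    if within is None:
        within = WithinDesign.identity(units[0].labels)
    priors_kwargs = dict(priors_kwargs or {})

    rows = []
    for held in range(n):
        train_units = [u for k, u in enumerate(units) if k != held]
        test_unit = units[held]
        train_cov = cov_tab.drop(index=test_unit.subject_id)
        train_target = train_cov[target_covariate].to_numpy(dtype=float)
        centre = float(train_target.mean())
        sd = float(train_target.std(ddof=1))

        xb = build_between_design(train_cov, mean_centre=True)
        design = build_full_design(xb, within)
        priors = default_priors(
            train_units[0].prior, xb.n_covariates, **priors_kwargs
        )
        model = PEBModel(design=design, priors=priors, units=train_units)
        fit = fit_peb(model, settings)

        # Candidate design row for the left-out subject: known nuisance
        # covariates (centred by training means) and a free target value.
        cov_names = list(xb.covariate_names)
        target_pos = cov_names.index(target_covariate)
        xb_row = np.zeros(len(cov_names))
        xb_row[0] = 1.0
        for j, name in enumerate(cov_names[1:], start=1):
            value = float(cov_tab.loc[test_unit.subject_id, name])
            if xb.mean_centred[j]:
                value -= float(train_cov[name].to_numpy(dtype=float).mean())
            xb_row[j] = value

        r_star, d_star, _ = subject_data_density(test_unit)
        sigma_tilde = np.linalg.inv(d_star)
        s_group = fit.group_posterior.cov
        m_group = fit.group_posterior.mean

        grid = np.linspace(-grid_span * sd, grid_span * sd, grid_points)
        log_post = np.empty(grid_points)
        for g, x_star in enumerate(grid):
            row = xb_row.copy()
            row[target_pos] = x_star
            x_i = np.kron(row[None, :], within.matrix).reshape(
                within.n_params, -1
            )
            pred_mean = x_i @ m_group
            pred_cov = fit.sigma2 + x_i @ s_group @ x_i.T + sigma_tilde
            log_post[g] = _gaussian_logpdf(r_star, pred_mean, pred_cov)
            # Prior over the unknown covariate: matched to the training
            # sample distribution (mean-centred, sd of the training values).
            log_post[g] += -0.5 * (x_star / sd) ** 2

        log_post -= log_post.max()
        w = np.exp(log_post)
        w /= np.trapezoid(w, grid)
        cdf = np.concatenate(
            [[0.0], np.cumsum((w[1:] + w[:-1]) / 2 * np.diff(grid))]
        )
        cdf /= cdf[-1]
        pred_mean_x = float(np.trapezoid(w * grid, grid))
        lower = float(np.interp(0.05, cdf, grid))
        upper = float(np.interp(0.95, cdf, grid))
        actual = float(cov_tab.loc[test_unit.subject_id, target_covariate]) - centre
        rows.append(
            {
                "subject_id": test_unit.subject_id,
                "actual": actual,
                "predicted": pred_mean_x,
                "lower90": lower,
                "upper90": upper,
            }
        )

    predictions = pd.DataFrame(rows)
    r, p = pearsonr(predictions["actual"], predictions["predicted"])
    covered = int(
        (
            (predictions["actual"] >= predictions["lower90"])
            & (predictions["actual"] <= predictions["upper90"])
        ).sum()
    )
    return LooResult(
        predictions=predictions,
        correlation=float(r),
        p_value=float(p),
        coverage_count=covered,
    )
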