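"""Second-level design matrices.

The group-level design is specified in two parts: a between-subjects matrix
``XB`` (one row per subject, one column per covariate, first column all
ones) and a within-subjects matrix ``XW`` (binary diagonal selecting which
first-level parameters receive group effects).  The full design is their
Kronecker product ``X = XB kron XW``, with rows ordered subject-major and
columns covariate-major.

Mean-centring the covariates after the constant column gives the first
column the interpretation of the group mean; leaving them uncentred makes
it a baseline/intercept.  Centring is the default here.  Categorical
covariates must be numerically encoded by the caller — no automatic dummy
coding is performed, keeping column order transparent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "BetweenDesign",
    "WithinDesign",
    "FullDesign",
    "build_between_design",
    "build_full_design",
    "read_covariates_csv",
]


@dataclass
class BetweenDesign:
    """Between-subjects design matrix ``XB`` (N x C)."""

    matrix: np.ndarray
    covariate_names: tuple[str, ...]
    subject_ids: tuple[str, ...]
    mean_centred: tuple[bool, ...]
    column_norms: np.ndarray  # Euclidean norm of each regressor

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        n, c = self.matrix.shape
        if len(self.covariate_names) != c:
            raise ValueError("covariate_names length != number of columns")
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids length != number of rows")
        if not np.allclose(self.matrix[:, 0], 1.0):
            raise ValueError("first column of XB must be all ones")
        for j, centred in enumerate(self.mean_centred):
            if j == 0:
                continue
            if centred and abs(self.matrix[:, j].mean()) > 1e-8:
                raise ValueError(
                    f"column {self.covariate_names[j]!r} flagged as "
                    "mean-centred but its mean is not zero"
                )

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.matrix.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix,
            index=pd.Index(self.subject_ids, name="subject_id"),
            columns=list(self.covariate_names),
        )


@dataclass
class WithinDesign:
    """Within-subjects design ``XW``: which parameters receive group effects."""

    matrix: np.ndarray
    parameter_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        p = len(self.parameter_labels)
        if self.matrix.shape != (p, p):
            raise ValueError(
                f"XW has shape {self.matrix.shape}, expected ({p}, {p})"
            )
        if not np.isin(self.matrix, (0.0, 1.0)).all():
            raise ValueError("XW entries must be binary (0 or 1)")

    @classmethod
    def identity(cls, parameter_labels: Sequence[str]) -> "WithinDesign":
        labels = tuple(str(x) for x in parameter_labels)
        return cls(np.eye(len(labels)), labels)

    @classmethod
    def from_switches(
        cls, parameter_labels: Sequence[str], on: Iterable[str]
    ) -> "WithinDesign":
        labels = tuple(str(x) for x in parameter_labels)
        on = set(on)
        diag = np.array([1.0 if lab in on else 0.0 for lab in labels])
        return cls(np.diag(diag), labels)

    @property
    def n_params(self) -> int:
        return len(self.parameter_labels)


@dataclass
class FullDesign:
    """Full second-level design ``X = XB kron XW``.

    Rows are (subject, parameter) pairs subject-major; columns are
    (covariate, parameter) pairs covariate-major.
    """

    matrix: np.ndarray
    row_labels: tuple[tuple[str, str], ...]
    col_labels: tuple[tuple[str, str], ...]
    between: BetweenDesign
    within: WithinDesign

    @property
    def n_subjects(self) -> int:
        return self.between.n_subjects

    @property
    def n_params(self) -> int:
        return self.within.n_params

    @property
    def n_effects(self) -> int:
        """Number of second-level effect cells (columns of X)."""
        return self.matrix.shape[1]

    def subject_block(self, i: int) -> np.ndarray:
        """Rows of X for subject ``i`` (a P x C*P matrix)."""
        p = self.n_params
        return self.matrix[i * p : (i + 1) * p, :]

    def effect_labels(self) -> tuple[str, ...]:
        """Flat ``covariate:parameter`` names for the columns of X."""
        return tuple(f"{c}:{p}" for c, p in self.col_labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix,
            index=pd.MultiIndex.from_tuples(
                self.row_labels, names=("subject_id", "parameter")
            ),
            columns=pd.MultiIndex.from_tuples(
                self.col_labels, names=("covariate", "parameter")
            ),
        )


def build_between_design(
    covariates: pd.DataFrame,
    mean_centre: Union[bool, Iterable[str]] = True,
    constant_name: str = "mean",
) -> BetweenDesign:
    """Build ``XB`` from a covariate table (one row per subject).

    A constant column of ones is prepended; requested covariate columns are
    mean-centred.  ``mean_centre`` may be a bool (all/none of the covariate
    columns) or an iterable of covariate names.
    """
    if not isinstance(covariates, pd.DataFrame):
        covariates = pd.DataFrame(covariates)
    if "subject_id" in covariates.columns:
        covariates = covariates.set_index("subject_id")
    if covariates.shape[0] < 2:
        raise ValueError("need at least 2 subjects to build a design")
    if covariates.isna().any().any():
        bad = covariates.columns[covariates.isna().any()].tolist()
        raise ValueError(f"missing covariate values in columns: {bad}")
    names = [constant_name] + [str(c) for c in covariates.columns]
    if mean_centre is True:
        centre = set(names[1:])
    elif mean_centre is False:
        centre = set()
    else:
        centre = {str(c) for c in mean_centre}
        unknown = centre - set(names[1:])
        if unknown:
            raise KeyError(f"unknown covariates in mean_centre: {sorted(unknown)}")

    n = covariates.shape[0]
    cols = [np.ones(n)]
    flags = [False]
    for name in names[1:]:
        col = covariates[name].to_numpy(dtype=float)
        if name in centre:
            col = col - col.mean()
        cols.append(col)
        flags.append(name in centre)
        if np.ptp(col) == 0.0 and name in centre:
            warnings.warn(
                f"covariate {name!r} is constant after centring; its zero "
                "column carries no information and its effect will stay at "
                "the prior mean",
                stacklevel=2,
            )
    xb = np.column_stack(cols)
    # Zero columns (centred constants) are benign under the Bayesian GLM —
    # their effects are clamped at the prior mean — so the rank check only
    # covers genuinely dependent non-zero columns.
    nonzero = [j for j in range(xb.shape[1]) if np.any(xb[:, j] != 0.0)]
    xb_nz = xb[:, nonzero]
    rank = np.linalg.matrix_rank(xb_nz)
    if rank < xb_nz.shape[1]:
        # identify dependent columns by testing incremental rank
        dependent = []
        for k in range(1, xb_nz.shape[1]):
            if np.linalg.matrix_rank(xb_nz[:, : k + 1]) == np.linalg.matrix_rank(
                xb_nz[:, :k]
            ):
                dependent.append(names[nonzero[k]])
        raise ValueError(
            f"between-subjects design is rank deficient; dependent "
            f"columns: {dependent}"
        )
    return BetweenDesign(
        matrix=xb,
        covariate_names=tuple(names),
        subject_ids=tuple(str(s) for s in covariates.index),
        mean_centred=tuple(flags),
        column_norms=np.linalg.norm(xb, axis=0),
    )


def build_full_design(xb: BetweenDesign, xw: WithinDesign) -> FullDesign:
    """Kronecker-combine the between and within designs: ``X = XB kron XW``."""
    x = np.kron(xb.matrix, xw.matrix)
    rows = tuple(
        (sid, par)
        for sid in xb.subject_ids
        for par in xw.parameter_labels
    )
    cols = tuple(
        (cov, par)
        for cov in xb.covariate_names
        for par in xw.parameter_labels
    )
    return FullDesign(
        matrix=x, row_labels=rows, col_labels=cols, between=xb, within=xw
    )


def read_covariates_csv(path) -> pd.DataFrame:
    """Read a covariate table (header row; a ``subject_id`` column required)."""
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise ValueError(f"{path}: covariate CSV must have a subject_id column")
    return df.set_index(df["subject_id"].astype(str)).drop(columns="subject_id")
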