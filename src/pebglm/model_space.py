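"""Factorial model spaces, comparison grids, families, BMA and greedy search.

Hypotheses about where group effects are expressed are encoded as binary
on/off patterns over the (covariate x parameter) cells of the second-level
GLM.  A *factorial* space crosses several experimental factors — each level
of a factor names the set of cells it allows — and the on-mask of a model
is the intersection of its chosen levels' cell sets, plus an optional null
(all-off) model.  Candidate models are scored in closed form by Bayesian
model reduction against the fitted full model, which makes grids of
hundreds of models essentially free.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .bmr import ModelSpec, bmr_evidence, model_probabilities, reduce_prior
from .densities import GaussianDensity, OFF_VARIANCE
from .estimation import PEBResult

__all__ = [
    "Factor",
    "ModelSpace",
    "ComparisonGrid",
    "BMAResult",
    "SearchResult",
    "factorial_space",
    "exhaustive_model_count",
    "compare_grid",
    "family_pool",
    "family_grid",
    "bma",
    "greedy_search",
]


@dataclass
class Factor:
    """An experimental factor: named levels, each switching on a cell set."""

    name: str
    levels: dict[str, frozenset[int]]

    def __post_init__(self) -> None:
        if not self.levels:
            raise ValueError(f"factor {self.name!r} has no levels")
        self.levels = {
            str(k): frozenset(int(i) for i in v) for k, v in self.levels.items()
        }


@dataclass
class ModelSpace:
    """An ordered collection of candidate on/off patterns.

    ``assignments[m]`` maps factor name to level name for model ``m`` (None
    for the null model), which is what family pooling keys on.
    """

    specs: list[ModelSpec]
    factors: list[Factor]
    includes_null: bool
    n_cells: int
    assignments: list[Optional[dict[str, str]]]

    def __len__(self) -> int:
        return len(self.specs)


def factorial_space(
    factors: Sequence[Factor], n_cells: int, include_null: bool = True
) -> ModelSpace:
    """Enumerate the full factorial space over ``factors``.

    Models are ordered factor-major (the last factor cycles fastest) with
    the null model appended last.  Each model's on-cells are the
    intersection of its levels' cell sets.
    """
    factors = list(factors)
    for f in factors:
        if not f.levels:
            raise ValueError(f"factor {f.name!r} is empty")
    specs: list[ModelSpec] = []
    assignments: list[Optional[dict[str, str]]] = []
    level_items = [list(f.levels.items()) for f in factors]
    for combo in itertools.product(*level_items):
        cells = frozenset(range(n_cells))
        for _, level_cells in combo:
            cells &= level_cells
        mask = np.zeros(n_cells, dtype=bool)
        mask[sorted(cells)] = True
        name = "+".join(f"{f.name}={lvl}" for f, (lvl, _) in zip(factors, combo))
        specs.append(ModelSpec(name, mask))
        assignments.append(
            {f.name: lvl for f, (lvl, _) in zip(factors, combo)}
        )
    if include_null:
        specs.append(ModelSpec("null", np.zeros(n_cells, dtype=bool)))
        assignments.append(None)
    return ModelSpace(
        specs=specs,
        factors=factors,
        includes_null=include_null,
        n_cells=n_cells,
        assignments=assignments,
    )


def exhaustive_model_count(n_cells: int) -> int:
    """Number of distinct on/off patterns over ``n_cells`` binary cells.

    For the 40-cell design of a 5-covariate x 8-parameter GLM this is
    2**40 ~ 1.1e12 — the infeasibility bound that motivates greedy search.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be non-negative")
    return 2**n_cells


@dataclass
class ComparisonGrid:
    """Joint posterior over (common-effect model, difference-effect model).

    ``probability[i, j]`` is the posterior probability of the reduced GLM
    with the common block configured by model ``i`` of ``common_space`` and
    the difference block by model ``j`` of ``diff_space``.
    """

    probability: np.ndarray
    delta_f: np.ndarray
    common_space: ModelSpace
    diff_space: ModelSpace
    common_cells: np.ndarray
    diff_cells: np.ndarray
    posteriors: list[list[GaussianDensity]]
    joint_masks: list[list[np.ndarray]]

    @property
    def n_models(self) -> int:
        return self.probability.size

    def common_marginal(self) -> np.ndarray:
        """Posterior over common-effect models (summed over columns)."""
        marg = self.probability.sum(axis=1)
        return marg / marg.sum()

    def diff_marginal(self) -> np.ndarray:
        """Posterior over difference-effect models (summed over rows)."""
        marg = self.probability.sum(axis=0)
        return marg / marg.sum()

    def flatten(self) -> tuple[np.ndarray, np.ndarray, list[GaussianDensity], list[np.ndarray]]:
        """Row-major flat views: (delta_f, probability, posteriors, masks)."""
        probs = self.probability.ravel()
        dfs = self.delta_f.ravel()
        posts = [p for row in self.posteriors for p in row]
        masks = [m for row in self.joint_masks for m in row]
        return dfs, probs, posts, masks

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.probability,
            index=[s.name for s in self.common_space.specs],
            columns=[s.name for s in self.diff_space.specs],
        )


def _joint_mask(
    n_effects: int,
    common_cells: np.ndarray,
    diff_cells: np.ndarray,
    common_mask: np.ndarray,
    diff_mask: np.ndarray,
) -> np.ndarray:
    mask = np.ones(n_effects, dtype=bool)  # nuisance cells stay on
    mask[common_cells] = common_mask
    mask[diff_cells] = diff_mask
    return mask


def compare_grid(
    peb: PEBResult,
    common_space: ModelSpace,
    diff_space: ModelSpace,
    common_cells: Sequence[int],
    diff_cells: Sequence[int],
    off_floor: float = OFF_VARIANCE,
) -> ComparisonGrid:
    """Score every (common, difference) model pair by BMR.

    ``common_cells`` / ``diff_cells`` index the columns of the full design
    that each space's masks act on (e.g. the group-mean block and the
    covariate-of-interest block); they must not overlap.  Cells outside
    both blocks (nuisance covariates) stay on in every model.
    """
    common_cells = np.asarray(common_cells, dtype=int)
    diff_cells = np.asarray(diff_cells, dtype=int)
    if np.intersect1d(common_cells, diff_cells).size:
        raise ValueError("common and difference cell blocks overlap")
    if common_space.n_cells != common_cells.size:
        raise ValueError("common_space masks do not match common_cells length")
    if diff_space.n_cells != diff_cells.size:
        raise ValueError("diff_space masks do not match diff_cells length")
    posterior = peb.group_posterior
    prior = peb.full_prior
    n_eff = posterior.dim
    delta_f = np.zeros((len(common_space), len(diff_space)))
    posteriors: list[list[GaussianDensity]] = []
    masks: list[list[np.ndarray]] = []
    for i, spec_i in enumerate(common_space.specs):
        row_post, row_mask = [], []
        for j, spec_j in enumerate(diff_space.specs):
            mask = _joint_mask(
                n_eff, common_cells, diff_cells, spec_i.on_mask, spec_j.on_mask
            )
            spec = ModelSpec(f"{spec_i.name}|{spec_j.name}", mask)
            red_prior = reduce_prior(prior, spec, off_floor=off_floor)
            red_post, df = bmr_evidence(posterior, prior, red_prior)
            delta_f[i, j] = df
            row_post.append(red_post)
            row_mask.append(mask)
        posteriors.append(row_post)
        masks.append(row_mask)
    prob = model_probabilities(delta_f.ravel()).reshape(delta_f.shape)
    return ComparisonGrid(
        probability=prob,
        delta_f=delta_f,
        common_space=common_space,
        diff_space=diff_space,
        common_cells=common_cells,
        diff_cells=diff_cells,
        posteriors=posteriors,
        joint_masks=masks,
    )


def family_pool(
    log_evidences: np.ndarray, families: Sequence
) -> pd.Series:
    """Pooled family posteriors under equal prior family probability.

    Model priors are reweighted so each family is a priori equally likely
    regardless of its size; the family posterior is the sum of its member
    models' posteriors.
    """
    log_evidences = np.asarray(log_evidences, dtype=float).ravel()
    families = list(families)
    if len(families) != log_evidences.size:
        raise ValueError("one family id required per model")
    unique = list(dict.fromkeys(families))
    sizes = {f: families.count(f) for f in unique}
    if not sizes or min(sizes.values()) == 0:
        raise ValueError("every family needs at least one member model")
    log_prior = np.array(
        [-np.log(len(unique)) - np.log(sizes[f]) for f in families]
    )
    log_joint = log_evidences + log_prior
    log_norm = logsumexp(log_joint)
    post = pd.Series(0.0, index=unique)
    for f, lj in zip(families, log_joint):
        post[f] += np.exp(lj - log_norm)
    return post


def family_grid(grid: ComparisonGrid, factor_name: str) -> pd.DataFrame:
    """Family-wise posterior matrix for one factor.

    Pools the grid's models into families keyed by the chosen factor's
    level on the common axis and on the difference axis (null models form a
    "none" family), under equal prior family probability.  Element (m, n)
    is the pooled probability of common family m with difference family n.
    """

    def fam(space: ModelSpace, idx: int) -> str:
        a = space.assignments[idx]
        if a is None:
            return "none"
        if factor_name not in a:
            raise KeyError(f"factor {factor_name!r} not in model space")
        return a[factor_name]

    dfs, _, _, _ = grid.flatten()
    families = [
        (fam(grid.common_space, i), fam(grid.diff_space, j))
        for i in range(len(grid.common_space))
        for j in range(len(grid.diff_space))
    ]
    pooled = family_pool(dfs, families)
    rows = list(dict.fromkeys(f[0] for f in families))
    cols = list(dict.fromkeys(f[1] for f in families))
    out = pd.DataFrame(0.0, index=rows, columns=cols)
    for (m, n), p in pooled.items():
        out.loc[m, n] = p
    return out


@dataclass
class BMAResult:
    """Bayesian model average over a set of reduced models."""

    density: GaussianDensity
    prob_on: np.ndarray  # per-cell posterior probability of being switched on
    threshold: Optional[float]
    thresholded_mean: np.ndarray
    n_models: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "effect": list(self.density.labels),
                "mean": self.density.mean,
                "sd": self.density.sd,
                "prob_on": self.prob_on,
                "thresholded_mean": self.thresholded_mean,
            }
        )


def bma(
    posteriors: Sequence[GaussianDensity],
    probabilities: np.ndarray,
    on_masks: Sequence[np.ndarray],
    threshold: Optional[float] = 0.95,
) -> BMAResult:
    """Average model posteriors, weighted by model probability.

    The mixture mean and full mixture covariance (including between-model
    dispersion) are returned, along with each cell's probability of being
    switched on — the summed probability of the models that include it.
    The thresholded view zeroes cells whose on-probability falls below
    ``threshold``.
    """
    probabilities = np.asarray(probabilities, dtype=float).ravel()
    if len(posteriors) != probabilities.size or len(on_masks) != probabilities.size:
        raise ValueError("posteriors, probabilities and masks must align")
    if abs(probabilities.sum() - 1.0) > 1e-6:
        raise ValueError("model probabilities must sum to 1")
    labels = posteriors[0].labels
    k = len(labels)
    mean = np.zeros(k)
    second = np.zeros((k, k))
    prob_on = np.zeros(k)
    for post, p, mask in zip(posteriors, probabilities, on_masks):
        if post.labels != labels:
            raise ValueError("all model posteriors must share labels")
        mean += p * post.mean
        second += p * (post.cov + np.outer(post.mean, post.mean))
        prob_on += p * np.asarray(mask, dtype=float)
    cov = second - np.outer(mean, mean)
    cov = (cov + cov.T) / 2.0
    eigvals, vecs = np.linalg.eigh(cov)
    cov = (vecs * np.clip(eigvals, 0.0, None)) @ vecs.T
    density = GaussianDensity(labels, mean, cov)
    if threshold is None:
        thresholded = mean.copy()
    else:
        thresholded = np.where(prob_on >= threshold, mean, 0.0)
    return BMAResult(
        density=density,
        prob_on=prob_on,
        threshold=threshold,
        thresholded_mean=thresholded,
        n_models=probabilities.size,
    )


@dataclass
class SearchResult:
    """Outcome of the automatic greedy search over reduced models."""

    bma: BMAResult
    trace: list[dict]
    final_mask: np.ndarray
    undecided_cells: np.ndarray
    n_terminal_models: int


def greedy_search(
    peb: PEBResult,
    candidate_cells: Optional[Sequence[int]] = None,
    block_size: int = 8,
    threshold: Optional[float] = 0.95,
    off_floor: float = OFF_VARIANCE,
) -> SearchResult:
    """Automatic search over reduced models by iterative pruning.

    At each iteration every currently-on candidate cell is scored by the
    log-evidence change of switching it off alone; the best single prune is
    accepted while it does not decrease the evidence.  When no prune
    improves, the ``min(block_size, remaining)`` still-on cells with the
    smallest single-prune evidence loss are treated as undecided, all their
    on/off combinations are enumerated (up to 2**8 = 256 models) and the
    Bayesian model average over that terminal set is returned.

    Ties between prunes are broken by discarding the cell with the smaller
    posterior |mean|/sd.
    """
    posterior = peb.group_posterior
    prior = peb.full_prior
    n_eff = posterior.dim
    if candidate_cells is None:
        candidate_cells = np.arange(n_eff)
    candidate_cells = np.asarray(candidate_cells, dtype=int)
    if candidate_cells.size < 1:
        raise ValueError("need at least one candidate cell")

    current = np.ones(n_eff, dtype=bool)

    def df_of(mask: np.ndarray) -> float:
        spec = ModelSpec("m", mask)
        _, df = bmr_evidence(posterior, prior, reduce_prior(prior, spec, off_floor))
        return df

    z = np.abs(posterior.mean) / np.clip(posterior.sd, 1e-12, None)
    current_df = df_of(current)
    trace: list[dict] = []
    while True:
        on_cands = [c for c in candidate_cells if current[c]]
        if not on_cands:
            break
        scores = {}
        for c in on_cands:
            mask = current.copy()
            mask[c] = False
            scores[c] = df_of(mask)
        # Best prune: largest dF; ties -> smallest posterior |mean|/sd.
        best = max(on_cands, key=lambda c: (scores[c], -z[c]))
        if scores[best] >= current_df:
            current[best] = False
            trace.append(
                {"pruned": int(best), "delta_f": scores[best] - current_df}
            )
            current_df = scores[best]
        else:
            break

    remaining = np.array([c for c in candidate_cells if current[c]], dtype=int)
    k = min(block_size, remaining.size)
    if k > 0:
        # Undecided = still-on cells whose removal costs the least evidence.
        losses = {}
        for c in remaining:
            mask = current.copy()
            mask[c] = False
            losses[c] = current_df - df_of(mask)
        undecided = np.array(
            sorted(remaining, key=lambda c: (losses[c], z[c]))[:k], dtype=int
        )
    else:
        undecided = np.array([], dtype=int)

    dfs, posts, masks = [], [], []
    for bits in itertools.product((True, False), repeat=undecided.size):
        mask = current.copy()
        mask[undecided] = bits
        spec = ModelSpec("terminal", mask)
        red_prior = reduce_prior(prior, spec, off_floor)
        red_post, df = bmr_evidence(posterior, prior, red_prior)
        dfs.append(df)
        posts.append(red_post)
        masks.append(mask)
    probs = model_probabilities(np.array(dfs))
    result_bma = bma(posts, probs, masks, threshold=threshold)
    return SearchResult(
        bma=result_bma,
        trace=trace,
        final_mask=current,
        undecided_cells=undecided,
        n_terminal_models=len(dfs),
    )
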