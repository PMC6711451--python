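"""Factorial spaces, comparison grids, family pooling, model averaging and
the greedy search, checked against enumeration oracles."""

import itertools

import numpy as np
import pytest

import pebglm as pg
from pebglm.cli import study_factors


@pytest.fixture
def fitted_study(make_study, make_model):
    """A small study with a clear mean effect and one covariate effect."""
    effects = np.zeros((2, 4))
    effects[0] = [0.5, 0.0, 0.45, 0.0]
    effects[1, 2] = 0.6
    study = make_study(
        n_subjects=40, effects=effects, seed=23, n_obs=24, noise_sd=0.2
    )
    model = make_model(study)
    return study, model, pg.fit_peb(model)


class TestFactorialSpace:
    def test_three_by_three_by_three_plus_null_is_28(self):
        factors = study_factors(pg.DEFAULT_PARAMETER_LABELS)
        space = pg.factorial_space(factors, n_cells=8)
        assert len(space) == 28
        assert space.specs[-1].name == "null"
        assert space.specs[-1].n_on == 0

    def test_two_level_factor_without_null(self):
        f = pg.Factor("f", {"on": frozenset({0, 1}), "off": frozenset()})
        space = pg.factorial_space([f], n_cells=2, include_null=False)
        assert len(space) == 2

    def test_masks_are_level_set_intersections(self):
        """The word/picture x dorsal/ventral x left/right construction
        yields each model's on-cells as the intersection of its levels."""
        labels = pg.DEFAULT_PARAMETER_LABELS
        factors = study_factors(labels)
        space = pg.factorial_space(factors, n_cells=8)
        by_name = {s.name: s for s in space.specs}
        spec = by_name["task=words+region=dorsal+hemisphere=right"]
        expected = {labels.index("rdF.words")}
        assert set(np.where(spec.on_mask)[0]) == expected
        spec = by_name["task=both+region=dorsal+hemisphere=both"]
        expected = {i for i, lab in enumerate(labels) if lab[1] == "d"}
        assert set(np.where(spec.on_mask)[0]) == expected

    def test_empty_factor_rejected(self):
        with pytest.raises(ValueError, match="levels"):
            pg.Factor("f", {})

    def test_exhaustive_count_for_forty_cells(self):
        assert pg.exhaustive_model_count(40) == 2**40
        assert np.isclose(pg.exhaustive_model_count(40) / 1e12, 1.0995, atol=1e-3)


class TestComparisonGrid:
    def test_784_models_from_two_28_spaces(self, fitted_study):
        _, model, fit = fitted_study
        factors = [
            pg.Factor("pair", {
                "both": frozenset({0, 1}), "first": frozenset({0}),
                "second": frozenset({1}),
            }),
            pg.Factor("tail", {
                "both": frozenset({2, 3}), "third": frozenset({2}),
                "fourth": frozenset({3}),
            }),
            pg.Factor("all", {
                "everything": frozenset(range(4)), "front": frozenset({0, 2}),
                "back": frozenset({1, 3}),
            }),
        ]
        space = pg.factorial_space(factors, n_cells=4)
        assert len(space) == 28
        cols = model.design.col_labels
        common = [i for i, (c, _) in enumerate(cols) if c == "mean"]
        diff = [i for i, (c, _) in enumerate(cols) if c == "x"]
        grid = pg.compare_grid(fit, space, space, common, diff)
        assert grid.n_models == 784
        assert np.isclose(grid.probability.sum(), 1.0)
        assert np.all(grid.probability >= 0.0)

    def test_overlapping_blocks_rejected(self, fitted_study):
        _, _, fit = fitted_study
        f = pg.Factor("f", {"on": frozenset({0}), "off": frozenset()})
        space = pg.factorial_space([f], n_cells=1)
        with pytest.raises(ValueError, match="overlap"):
            pg.compare_grid(fit, space, space, [0], [0])

    def test_flat_evidence_gives_uniform_grid(self):
        """If every reduced model has the full prior (identity reductions),
        all cells of the grid are equally probable."""
        post = pg.GaussianDensity(("a", "b"), [0.1, 0.2], np.eye(2) * 0.5)
        prior = pg.GaussianDensity(("a", "b"), [0.0, 0.0], np.eye(2))

        class FlatFit:
            group_posterior = post
            full_prior = prior

        f = pg.Factor("f", {"l1": frozenset({0}), "l2": frozenset({0})})
        space = pg.factorial_space([f], n_cells=1, include_null=False)
        grid = pg.compare_grid(FlatFit(), space, space, [0], [1])
        assert np.allclose(grid.probability, 0.25)

    def test_true_difference_cell_recovered(self, make_study, make_model):
        """With a strong covariate effect on one parameter (3x the RFX sd,
        100 subjects), difference models containing that cell take nearly
        all the marginal probability."""
        effects = np.zeros((2, 4))
        effects[0] = [0.4, 0.0, 0.3, 0.0]
        effects[1, 2] = 3 * 0.125
        study = make_study(n_subjects=100, effects=effects, seed=31)
        model = make_model(study)
        fit = pg.fit_peb(model)
        f = pg.Factor(
            "cell", {
                "all": frozenset(range(4)),
                "c-only": frozenset({2}),
                "d-only": frozenset({3}),
            },
        )
        space = pg.factorial_space([f], n_cells=4)
        cols = model.design.col_labels
        common = [i for i, (c, _) in enumerate(cols) if c == "mean"]
        diff = [i for i, (c, _) in enumerate(cols) if c == "x"]
        grid = pg.compare_grid(fit, space, space, common, diff)
        marg = grid.diff_marginal()
        with_cell = [
            m for m, s in enumerate(space.specs) if s.on_mask[2]
        ]
        assert marg[with_cell].sum() > 0.9


class TestFamilyPool:
    def test_equal_evidence_cancels_family_size(self):
        post = pg.family_pool(np.zeros(4), ["A", "B", "B", "B"])
        assert np.allclose(post, [0.5, 0.5])

    def test_all_mass_on_one_model_gives_its_family_everything(self):
        post = pg.family_pool(np.array([200.0, 0.0, 0.0]), ["A", "B", "B"])
        assert post["A"] > 1 - 1e-12

    def test_matches_enumeration_oracle(self, rng):
        """Direct Bayes over the joint (model, family) structure."""
        dfs = rng.normal(size=6) * 2
        fams = ["A", "A", "B", "B", "B", "C"]
        post = pg.family_pool(dfs, fams)
        sizes = {"A": 2, "B": 3, "C": 1}
        prior = np.array([1 / 3 / sizes[f] for f in fams])
        joint = prior * np.exp(dfs)
        joint /= joint.sum()
        expected = {f: joint[[i for i, g in enumerate(fams) if g == f]].sum()
                    for f in sizes}
        for f in sizes:
            assert np.isclose(post[f], expected[f])

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            pg.family_pool(np.zeros(0), [])

    def test_family_grid_sums_to_one(self, fitted_study):
        _, model, fit = fitted_study
        f = pg.Factor("f", {"full": frozenset(range(4)), "half": frozenset({0, 1})})
        space = pg.factorial_space([f], n_cells=4)
        cols = model.design.col_labels
        common = [i for i, (c, _) in enumerate(cols) if c == "mean"]
        diff = [i for i, (c, _) in enumerate(cols) if c == "x"]
        grid = pg.compare_grid(fit, space, space, common, diff)
        fam = pg.family_grid(grid, "f")
        assert np.isclose(fam.to_numpy().sum(), 1.0)
        assert fam.shape == (3, 3)  # two levels + none


class TestBMA:
    def test_single_model_recovers_its_posterior(self):
        d = pg.GaussianDensity(("a", "b"), [0.5, -0.5], np.eye(2) * 0.3)
        out = pg.bma([d], [1.0], [np.array([True, False])], threshold=None)
        assert out.density.allclose(d, atol=1e-10)
        assert np.allclose(out.prob_on, [1.0, 0.0])

    def test_two_model_mixture_moments(self):
        d1 = pg.GaussianDensity(("a",), [0.0], [[1.0]])
        d2 = pg.GaussianDensity(("a",), [2.0], [[1.0]])
        out = pg.bma(
            [d1, d2], [0.5, 0.5], [np.array([True]), np.array([True])],
            threshold=None,
        )
        assert np.isclose(out.density.mean[0], 1.0)
        assert np.isclose(out.density.cov[0, 0], 2.0)

    def test_threshold_keeps_only_confident_cells(self, fitted_study):
        """Thresholding at 95% retains the strongly supported cells and
        zeroes the rest; per-cell probabilities match the exhaustive
        on/off evidence ratio."""
        _, model, fit = fitted_study
        cols = model.design.col_labels
        cand = [i for i, (c, _) in enumerate(cols) if c in ("mean", "x")]
        dfs, posts, masks = [], [], []
        for bits in itertools.product([True, False], repeat=len(cand)):
            mask = np.ones(fit.group_posterior.dim, dtype=bool)
            mask[cand] = bits
            spec = pg.ModelSpec("m", mask)
            red = pg.reduce_prior(fit.full_prior, spec)
            post, df = pg.bmr_evidence(fit.group_posterior, fit.full_prior, red)
            dfs.append(df)
            posts.append(post)
            masks.append(mask)
        probs = pg.model_probabilities(np.array(dfs))
        out = pg.bma(posts, probs, masks, threshold=0.95)
        strong = [i for i, (c, p) in enumerate(cols) if (c, p) in
                  [("mean", "a"), ("mean", "c"), ("x", "c")]]
        assert np.all(out.prob_on[strong] > 0.95)
        assert np.all(out.thresholded_mean[strong] != 0.0)
        # per-cell probability equals summed probability of models with it on
        for i in cand:
            direct = sum(p for p, m in zip(probs, masks) if m[i])
            assert np.isclose(out.prob_on[i], direct)

    def test_shrinkage_toward_zero_for_uncertain_cells(self, fitted_study):
        """Averaging nested models with uniform probabilities never inflates
        a prunable cell's posterior mean beyond the full model's."""
        _, model, fit = fitted_study
        cols = model.design.col_labels
        cand = [i for i, (c, _) in enumerate(cols) if c == "x"]
        posts, masks = [], []
        for bits in itertools.product([True, False], repeat=len(cand)):
            mask = np.ones(fit.group_posterior.dim, dtype=bool)
            mask[cand] = bits
            spec = pg.ModelSpec("m", mask)
            red = pg.reduce_prior(fit.full_prior, spec)
            post, _ = pg.bmr_evidence(fit.group_posterior, fit.full_prior, red)
            posts.append(post)
            masks.append(mask)
        probs = np.full(len(posts), 1.0 / len(posts))
        out = pg.bma(posts, probs, masks, threshold=None)
        for i in cand:
            assert abs(out.density.mean[i]) <= abs(fit.group_posterior.mean[i]) + 1e-9


class TestGreedySearch:
    def test_terminal_bma_has_256_models_with_8_undecided(self, make_study, make_model):
        """When at least eight cells survive pruning, the terminal
        enumeration covers 2^8 = 256 models."""
        effects = np.zeros((2, 4))
        effects[0] = [0.6, -0.6, 0.5, -0.5]
        effects[1] = [0.6, -0.5, 0.5, -0.6]
        study = make_study(n_subjects=60, effects=effects, seed=41, n_obs=24,
                           noise_sd=0.2)
        fit = pg.fit_peb(make_model(study))
        out = pg.greedy_search(fit)
        assert out.n_terminal_models == 256
        assert out.undecided_cells.size == 8

    def test_strong_support_everywhere_prunes_nothing(self, make_study, make_model):
        effects = np.zeros((2, 4))
        effects[0] = [0.8, -0.8, 0.8, -0.8]
        effects[1] = [0.8, -0.8, 0.8, -0.8]
        study = make_study(n_subjects=80, effects=effects, seed=43, n_obs=24,
                           noise_sd=0.15)
        fit = pg.fit_peb(make_model(study))
        out = pg.greedy_search(fit)
        assert len(out.trace) == 0
        assert out.final_mask.all()

    def test_greedy_matches_exhaustive_oracle_on_small_space(
        self, make_study, make_model
    ):
        """On 6-cell problems the greedy search's best reachable model is
        the exhaustive 2^6 optimum in at least 95% of replicates."""
        hits = 0
        n_rep = 100
        for rep in range(n_rep):
            r = np.random.default_rng(1000 + rep)
            effects = np.zeros((1, 6))
            on = r.random(6) < 0.5
            effects[0, on] = r.normal(0.0, 0.4, int(on.sum()))
            study = make_study(
                n_subjects=12,
                labels=tuple("abcdef"),
                covariate_names=(),
                effects=effects,
                seed=2000 + rep,
            )
            fit = pg.fit_peb(make_model(study))
            out = pg.greedy_search(fit, threshold=None)
            prior = fit.full_prior
            best_df = -np.inf
            for bits in itertools.product([True, False], repeat=6):
                spec = pg.ModelSpec("m", np.array(bits))
                _, df = pg.bmr_evidence(
                    fit.group_posterior, prior,
                    pg.reduce_prior(prior, spec),
                )
                best_df = max(best_df, df)
            # best model reachable in the terminal enumeration
            terminal_best = -np.inf
            for bits in itertools.product(
                [True, False], repeat=out.undecided_cells.size
            ):
                mask = out.final_mask.copy()
                mask[out.undecided_cells] = bits
                spec = pg.ModelSpec("m", mask)
                _, df = pg.bmr_evidence(
                    fit.group_posterior, prior, pg.reduce_prior(prior, spec)
                )
                terminal_best = max(terminal_best, df)
            if terminal_best >= best_df - 1e-6:
                hits += 1
        assert hits >= 95

    def test_grid_probability_permutation_equivariance(self, fitted_study):
        _, model, fit = fitted_study
        f = pg.Factor("f", {"a": frozenset({0}), "b": frozenset({1})})
        space = pg.factorial_space([f], n_cells=2, include_null=True)
        cols = model.design.col_labels
        common = [i for i, (c, _) in enumerate(cols) if c == "mean"][:2]
        diff = [i for i, (c, _) in enumerate(cols) if c == "x"][:2]
        grid = pg.compare_grid(fit, space, space, common, diff)
        # reverse the common-space model order: rows permute identically
        space_r = pg.ModelSpace(
            specs=space.specs[::-1],
            factors=space.factors,
            includes_null=space.includes_null,
            n_cells=space.n_cells,
            assignments=space.assignments[::-1],
        )
        grid_r = pg.compare_grid(fit, space_r, space, common, diff)
        assert np.allclose(grid_r.probability, grid.probability[::-1, :])
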