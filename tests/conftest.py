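import numpy as np
import pandas as pd
import pytest

import pebglm as pg


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def make_study():
    """Factory for small synthetic studies with explicit conditions."""

    def _make(
        n_subjects=12,
        labels=("a", "b", "c", "d"),
        covariate_names=("x",),
        effects=None,
        rfx_sd=0.125,
        n_obs=16,
        noise_sd=0.25,
        seed=0,
        covariates=None,
    ):
        c = 1 + len(covariate_names)
        if effects is None:
            effects = np.zeros((c, len(labels)))
        config = pg.SimulationConfig(
            n_subjects=n_subjects,
            parameter_labels=tuple(labels),
            covariate_names=tuple(covariate_names),
            true_effects=np.asarray(effects, dtype=float),
            rfx_sd=rfx_sd,
            n_obs=n_obs,
            noise_sd=noise_sd,
            covariates=covariates,
        )
        return pg.simulate_study(config, seed=seed)

    return _make


@pytest.fixture
def make_model():
    """Factory building a PEBModel (full within-design) from a study."""

    def _make(study, mean_centre=True, units=None, **prior_kwargs):
        xb = pg.build_between_design(study.covariates, mean_centre=mean_centre)
        xw = pg.WithinDesign.identity(study.config.parameter_labels)
        design = pg.build_full_design(xb, xw)
        priors = pg.default_priors(
            study.units[0].prior, xb.n_covariates, **prior_kwargs
        )
        return pg.PEBModel(
            design=design,
            priors=priors,
            units=list(units) if units is not None else list(study.units),
        )

    return _make


@pytest.fixture
def normal_covariates():
    """Standard-normal covariate generator (for calibration studies)."""

    def _make(n, name="x", seed=0):
        r = np.random.default_rng(seed)
        return pd.DataFrame(
            {name: r.normal(0.0, 1.0, n)},
            index=pd.Index([f"sub-{i + 1:03d}" for i in range(n)], name="subject_id"),
        )

    return _make
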