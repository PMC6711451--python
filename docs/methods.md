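# Methods

## The model

`pebglm` implements group-level (second-level) inference over subject-level
Bayesian parameter estimates using a two-level hierarchical Gaussian model —
the parametric empirical Bayes (PEB) approach used in group effective-
connectivity analysis. Each subject *i* contributes a first-level posterior
density N(μᵢ, Σᵢ) and the shared first-level prior N(μ₀, Σ₀) over P named
parameters (e.g. condition-specific modulations of regional self-
connections). The hierarchy is

    θ⁽²⁾ = η + ε⁽³⁾,             ε⁽³⁾ ~ N(0, Σ⁽³⁾)
    θᵢ⁽¹⁾ = Xᵢ θ⁽²⁾ + ε⁽²⁾,      ε⁽²⁾ ~ N(0, Σ⁽²⁾)

where X = X_B ⊗ X_W is the Kronecker product of an N×C between-subjects
design (first column ones; remaining covariates mean-centred by default, so
the first column reads as the group mean) and a P×P binary within-subject
selector. Rows are subject-major, columns covariate-major: cell (c, p) of
θ⁽²⁾ is the effect of covariate c on parameter p.

Between-subject (random-effects, RFX) covariance is parameterised through
precision components with log scaling hyperparameters,

    Π⁽²⁾(γ) = Σⱼ exp(γⱼ) Qⱼ,     Σ⁽²⁾ = Π⁽²⁾(γ)⁻¹,

with a single shared component Q₁ = diag(β/v) by default (v = first-level
prior variances) and optional per-parameter components.

## Default priors and their rationale

- α = 1: the prior variance around each group-mean effect equals the
  corresponding first-level prior variance — the group level makes no
  stronger a priori claim than the subject level.
- β = 16: the baseline RFX variance is v/16, i.e. between-subject
  variability is assumed a priori to have at most a quarter of the prior
  standard deviation of the parameters themselves. This is the standard
  empirical-Bayes convention for connectivity studies, and is what
  `default_priors` produces at γ = 0.
- η equals the first-level prior mean on the group-mean block and zero on
  covariate blocks, so a data-free group reverts to the first-level prior.
- Hyperprior γⱼ ~ N(0, 1/16): a weakly informative prior on the log scale
  of each precision component; configurable, since no canonical value
  exists.
- Covariate regressor norms are recorded on the design and can optionally
  rescale covariate-block prior variances (`covariate_scales`); by default
  no rescaling is applied.

## Estimation

Each subject's data enter only through the *data density* obtained by
precision subtraction: D = Σᵢ⁻¹ − Σ₀⁻¹, r = D⁻¹(Σᵢ⁻¹μᵢ − Σ₀⁻¹μ₀), so that
p(yᵢ|θᵢ) ∝ N(θᵢ; r, D⁻¹) up to a constant absorbed into the subject's
stored log evidence. D is eigenvalue-floored (relative floor 1e-8) so that
directions the data did not inform receive an essentially flat likelihood;
a subject's posterior is *not* required to dominate its prior.

Conditional on γ the model is an exact linear-Gaussian regression of these
pseudo-observations on X, giving a closed-form conditional posterior over
θ⁽²⁾ (each subject contributes precision Xᵢᵀ(Σ⁽²⁾ + Σ̃ᵢ)⁻¹Xᵢ with
Σ̃ᵢ = D⁻¹ — imprecise subjects are automatically down-weighted) and a
closed-form log marginal. γ is optimised by damped Newton ascent on

    J(γ) = ln p(pseudo-data | γ) + ln p(γ)

with finite-difference derivatives (γ has at most a handful of
dimensions), halving the step until the objective does not decrease;
convergence at ΔJ < 1e-4 nats, at most 64 iterations. The reported free
energy F⁽²⁾ adds the Laplace (Gaussian-entropy) correction for γ
uncertainty; subject first-level free energies enter as additive
constants, so all model comparisons are differences in the second-level
terms.

The *reported* group posterior marginalises over γ uncertainty by 3-point
Gauss–Hermite quadrature on the Laplace posterior of γ (mixture moments;
used when J ≤ 2, conditional-at-the-mode otherwise). This makes credible
intervals honest about hyperparameter uncertainty. Exactness checks (and
the model-reduction oracle below) use `conditional_group_posterior`, the
fixed-γ conditional, where the Gaussian identities hold to machine
precision.

Design columns that are identically zero (a within-design switch-off, or a
covariate that is constant after centring) are clamped at their prior mean
with near-zero variance rather than removed, preserving cell alignment
across models.

## Bayesian model reduction, spaces, families, BMA, search

A reduced model fixes a subset of θ⁽²⁾ cells at their prior expectation by
shrinking their prior variance to 1e-8 (configurable): all models share
one coordinate system. Its posterior and log evidence follow analytically
from the full model (precision-space identity; `bmr_evidence`); for the
linear-Gaussian second level the identity is exact, which the test suite
verifies against explicit re-inversion for every mask of small problems.

Numerical note: the point-mass prior variances make naive
covariance→precision round trips lose ~1e-3 nats; densities produced by
reductions and estimators therefore carry their exact precision matrices,
and log-determinants are taken of the already-positive-definite precision
matrices directly.

Factorial model spaces cross named factors; each level names the set of
cells it permits and a model's on-mask is the intersection of its chosen
levels, with an optional null (all-off) model appended last. Crossing a
"commonalities" space with a "differences" space scores every pair by BMR
(nuisance-covariate cells stay on) and softmax-normalises to a joint
probability grid; marginals are row/column sums renormalised. Families
pool model posteriors under equal prior family probability (model priors
reweighted by 1/family size). The Bayesian model average uses full mixture
moments (between-model dispersion included) and reports each cell's
probability of being switched on — the summed probability of the models
that include it — with an optional display threshold (default 0.95).

The automatic greedy search prunes one cell at a time (the prune with the
largest evidence; ties broken by the smaller posterior |mean|/sd) while
the evidence does not decrease, then enumerates all on/off combinations of
the min(8, remaining) least-decided surviving cells — up to 2⁸ = 256
models — and returns their BMA. Single-cell pruning plus terminal block
enumeration is a design choice; multi-cell pruning per iteration would be
a straightforward extension.

## Leave-one-out cross-validation

For each fold the model is fitted to N−1 subjects (target covariate
mean-centred over the training set). The held-out subject's covariate
value x* gets a Gaussian prior matched to the training distribution
(mean-centred, training sd) and is scored on a 64-point grid spanning
±4 training sd: each candidate implies an empirical prior
N(X*(x*) m, Σ⁽²⁾ + X* S X*ᵀ) over the subject's parameters, whose evidence
against the subject's data density is computed in closed form. The
grid-normalised posterior yields the predictive mean and central 90%
interval; predictions default to all modelled parameter cells (a `cells`
argument restricts them). The cross-fold Pearson correlation carries a
two-sided p-value computed under the usual independence assumption.

Known limitation: because all folds share N−1 training subjects, the
cross-fold correlation statistic is over-dispersed relative to the
independent-pairs null — under a true null effect at N=50 its spread is
roughly sd ≈ 0.2 rather than 1/√(N−1) ≈ 0.14, and its nominal p-values
are correspondingly approximate. A permuted-actuals control inside the
test suite reproduces the independence null exactly, confirming that the
excess dispersion is fold coupling rather than an artefact of the
predictive distributions. Interval coverage is unaffected (90% intervals
cover ≈ 88–91% of held-out subjects in calibrated simulations).

## Synthetic studies

The generator reads the hierarchy forwards: draw covariates, form
per-subject true parameters Xθ⁽²⁾_true plus N(0, diag(rfx_sd²)) random
effects, generate T observations per subject through a *linear* forward
model y = Gθ + noise (G standard normal, T×P), and invert each subject
exactly by conjugate Gaussian algebra with an exact log evidence. The
group level only ever consumes Gaussian posteriors, so the linear toy
exercises every group-level code path exactly — and makes model reduction
of the first level exact, the strongest oracle in the suite. What the toy
does *not* emulate: nonlinear/dynamical forward models, approximate
variational posteriors (with their possible under-dispersion and local
optima), temporally correlated observation noise, and session/site
structure. Passing tests therefore certify the group-level machinery, not
first-level robustness.

Defaults mirror a 60-subject, four-region, two-condition connectivity
study: P = 8 parameters (pictures/words × left/right × dorsal/ventral
self-connection modulations), covariates mean + laterality index (LI) +
handedness + gender + age; group-mean effect profile
(−0.02, 0.40, −0.07, −0.23, 0.02, 0.06, 0.00, 0.38) and an LI effect of
1.74 on the rdF-words cell — magnitudes typical of published group
connectivity estimates; first-level prior variance 0.25, RFX sd
0.125 = √(0.25/16) (matching the default-prior convention), T = 32
observations, observation noise sd 0.25.

Calibration suites use scaled-down versions of these conditions chosen for
tractable run times: parameter-recovery coverage uses 100 replicates of
N=100 subjects with P=4 and a covariate effect of 3× the RFX sd;
leave-one-out calibration uses 20 replicates of N=25 (interval coverage),
one N=50 study at 5× the RFX sd (strong-effect recovery), and 100 pure-null
replicates at N=50. The problem sizes are stated in the test docstrings.

## Degenerate inputs and numerical choices

- Ridge regularisation ε = 1e-8 · mean(diag) before generic inversions.
- Switched-off prior variance 1e-8 (configurable `off_floor`).
- Data-precision eigenvalue floor 1e-8 (relative).
- Rank-deficient between-subject designs: zero (centred-constant) columns
  are warned about and clamped by the prior; genuinely dependent columns
  raise, naming the offenders.
- All internal log quantities are in nats; probabilities appear only at
  reporting time.

## Known limitations

- Gaussian densities only; no sampling-based representations.
- One level of grouping (no third-level, PEB-of-PEBs designs).
- Random-effects model for parameters, not for model identity: comparing
  structurally different first-level forward models per subject is out of
  scope.
- The LOO correlation's null distribution is over-dispersed (above); treat
  its p-value as approximate and prefer the interval-based summaries.
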