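# Methods

This note documents the models, the synthetic-data generator, the training
and inference schemes, and the design choices behind them. Everything
quantitative stated here is computed by the test suite or by
`scripts/acceptance.py`; nothing is quoted from elsewhere.

## Models

**Static RBM.** Binary visible units `v ∈ {0,1}^Nv` (neurons) and binary
hidden units `h ∈ {0,1}^Nh` (assemblies) interact through

    P(v, h) ∝ exp(bv·v + bh·h + hᵀ W v),

with `W` stored hidden-major (`Nh × Nv`), so the interaction term is
`hᵀ W v`; checkpoints record this layout. Both conditionals factorize into
logistic units, `P(h_j=1|v) = σ(bh_j + Σ_i W_ji v_i)` and symmetrically for
`v`, which enables blockwise Gibbs sampling. Hidden units are Bernoulli
throughout; real-valued (dReLU-style) potentials are out of scope.

**RTRBM.** The recurrent temporal RBM chains static RBMs in time: the model
at step `t` is an RBM whose hidden bias is shifted by `U r[t−1]`, where

    r[1] = σ(W v[1] + binit),      r[t] = σ(W v[t] + bh + U r[t−1])

is the mean-field hidden state. Real-valued `r`, never binary hidden
samples, propagates between steps. `U` is directed (`U[i,j]` couples
assembly `j` at `t−1` to assembly `i` at `t`) and need not be symmetric.
The sequence likelihood factorizes as `Π_t P(v[t] | r[t−1])`, each factor a
static-RBM likelihood with conditional partition sum `Z_{r[t−1]}`.

**Exact oracles.** For models with `Nv + Nh ≤ 24`, partition sums, visible
marginals and model moments are computed by summing the hidden layer
analytically (softplus) and enumerating visible states with log-sum-exp.
These oracles back every sampler and gradient test.

## Training

**RBM.** Contrastive divergence CD-K (default `K = 1`): the data-side
hidden terms use conditional means `σ(bh + Wv)`, the model side a K-step
Gibbs chain started at each data column. Mini-batches are contiguous
16-step windows treated as i.i.d. columns; 20 batch gradients are
accumulated per parameter update. Plain SGD with optional momentum
(default 0); initialization `W ~ N(0, 0.01/√Nv)`, zero biases.

**RTRBM.** The gradient of the sequence likelihood has a static part
(per-step CD gradients under the conditional RBM at `t`, teacher-forced on
the data-derived `r[t−1]`) and a temporal part obtained by backpropagation
through time: the adjoint `d[t] = ∂L/∂r[t]` satisfies

    d[T] = 0,
    d[t] = Uᵀ[(r[t+1] − q[t+1]) + d[t+1] ⊙ r[t+1] ⊙ (1 − r[t+1])],

with `q[t]` the model-side hidden expectation, and is chained into the
parameter blocks through the sigmoid recursion. On the data side hidden
"samples" are the mean-field `r[t]`; the model side uses K-step Gibbs
negatives (or exact enumerated moments on tiny models — the configuration
under which the analytic gradient matches central finite differences of
the exact sequence log-likelihood to relative error below 1e-4). Each
16-step batch is treated as a sequence starting at its own `t = 1`, so
`binit` is learned from batch onsets. The L1 subgradient at `W = 0` is
taken as 0.

**Transfer mode.** When a donor `W` is supplied, the learning rate on `W`
is reduced by two orders of magnitude (configurable, including 0 to freeze
`W`) and the L1 penalty `λ` (default 1e-6) applies to `W`. Biases and `U`
train at the full rate.

**Assembly warm start.** `assembly_init_W` partitions neurons by
average-linkage agglomerative clustering of the correlation distance
`1 − corr(v_i, v_j)` and returns the scaled group indicator (scale 3.0,
calibrated so that one active hidden unit raises its neurons' firing
probability into the empirically observed range). This warm start exists
because de novo maximum-likelihood training from small random weights
reliably converges to mixed "difference features" — each hidden unit with
one strongly positive and one strongly negative assembly — which model the
data about as well as the assembly-aligned solution (the two solutions'
reconstruction errors differ by < 3%) but are useless for interpreting `U`.
Warm-started transfer training keeps one dominant weight per neuron while
`U`, trained at the full rate, absorbs the between-assembly dynamics. All
recovery and comparison experiments in the test suite use this workflow;
it is the package's analogue of initializing from an externally trained
sparse model.

**Desk-scale defaults** used by the tests and the acceptance script:
learning rate 0.02, momentum 0.9, 100 epochs, CD-1, batch length 16,
20 batches per update, λ = 1e-6. The real-data workflow documented in the
trainer (10,000 epochs, η = 1e-3) is config-exposed but not exercised at
desk scale.

## Synthetic-data generator

`Nh` latent assemblies carry time-varying rates built from two independent
trains of randomly timed peaks (inter-peak interval ~ Uniform(t1, t2) in
time-steps, first peak at a Uniform(0, t2) offset), each convolved with a
unit-sum Gaussian kernel on the integer grid (width ~ Uniform(σ1, σ2),
truncated at ±⌈4σ⌉ bins; σ < 1 yields near-delta bumps, accepted as such).
The two instances are min–max renormalized (over each instance's own
realized range) to `[0, fmax/10]` and `[0, fmax]` and summed into the
intrinsic rate. Assemblies then interact at delay `ΔtA`:

    λ_i(t) = ϕ(λ_init_i(t) + Σ_j U_ij λ_j(t − ΔtA)),

with ϕ a hard clamp to `[0, 3·fmax]` (a scaled Gaussian-CDF squashing onto
the same interval is available behind `limiter="cdf"` but is not default:
the CDF reading would impose a 1.5·fmax baseline at zero input). Missing
history (`t ≤ ΔtA`) contributes zero. Each assembly drives a distinct block
of `Nv_per_unit` neurons: neuron `k` fires at `t` when a Poisson draw with
mean `c_k · λ_i(t)` is nonzero (`c_k ~ Uniform(c1, c2)`); counts are
binarized as `count ≥ 1` because the visible units are binary. The first
`tsettle` columns are dropped as burn-in.

Defaults (the study conditions): `Nh=10`, `Nv_per_unit=20`, `t1=5`,
`t2=10`, `σ1=0.1`, `σ2=0.5`, `c1=0.6`, `c2=1.4`, `tsettle=25`, `fmax=0.8`;
`ΔtA=1` for model-comparison runs and `ΔtA=4` for the timescale scan. The
default interaction matrix is a ring — assembly `i` excites `i+1` and
inhibits `i−1`, each row and column holding exactly one `+magnitude` and
one `−magnitude` entry (magnitude 1.0, at which the interaction term is
comparable to the intrinsic drive, so dynamics are interaction-dominated).
Sequence length `T = 5000` is the desk-scale default.

`downsample` keeps every `ΔtD`-th column (pure selection, no averaging,
mirroring plane-by-plane acquisition) and multiplies the `dt` metadata.

**What the generator does and does not emulate.** It produces binary
rasters with assembly-level delayed interactions and per-neuron Poisson
noise. It does not emulate calcium-indicator dynamics or deconvolution
artifacts, unequal assembly sizes, overlapping memberships, multiple
interaction timescales, or non-stationarity. Passing tests therefore
demonstrate recovery of latent delayed interactions from clean binarized
population activity — not robustness to the full complexity of
fluorescence-derived recordings.

## Generation and prediction

Generation draws `v[t]` by K-step block Gibbs under the conditional RBM at
`t`. Two chain initializations are provided:

* **prior start** (generative default): the chain opens on the hidden side
  from the temporal prior `σ(bh + U r[t−1])`; with `K = 1` this is an
  ancestral draw through the hidden layer.
* **state start**: the chain opens on the visible side at the previous
  visible state and performs `K` full sweeps, interpolating between
  persistence and the conditional equilibrium.

For prediction benchmarks, only the mean-field hidden state is seeded on
the observed history; the per-step visible chains start fresh (from an
all-zero column, `K = 15` sweeps). All predictive information thus flows
through `r` — no persistence of the observed column leaks into the
estimate, and the static RBM, which has no hidden recursion, predicts from
its stationary statistics under the identical scheme. Predictions are
binary per-chain draws; their squared error equals their absolute error
(1 − accuracy), and averaging over chains estimates the disagreement rate
of the stochastic estimator — the same quantity both error bounds measure.
A mean-probability prediction would undercut the variance floor for a good
model and break the bound ordering, so it is returned for inspection but
not used for the normalized error.

## Evaluation

**Moments.** Time-averaged `⟨v_i⟩`, `⟨v_i v_j⟩` (upper triangle), and lag-1
`⟨v_i[t] v_j[t+1]⟩` (full matrix), with hidden-unit analogues computed from
mean-field traces (`⟨h|v⟩`, not binary samples). Model moments are sampled
with chains initialized at 100 random test time points, 15 Gibbs sweeps
per retained sample, chain length 20; the static RBM additionally burns in
4000 sweeps (config-exposed). Note a caveat measured during development:
with a CD-trained RBM whose equilibrium mode weights are imperfect, long
burn-in redistributes data-seeded chains toward the model's equilibrium
mixture and can *degrade* the sampled first-order moments; the defaults
follow the stated protocol, and the burn-in is a parameter worth reducing
when chains are visibly mode-sticky.

**Comparison.** Spearman rank correlation (average ranks on ties) between
data and model moments; significance on large populations by a
neuron-subset bootstrap (non-overlapping random subsets, default 1000
neurons, mean ± 2 SD intervals, difference called significant when the
intervals do not overlap). Named statistical tests (one-sided
Mann–Whitney U with exact enumeration when tie-free, one-sided Wilcoxon,
per-horizon t-tests with Bonferroni correction by the number of horizons,
two-way ANOVA with horizon and model factors) are dispatched by
`model_comparison_tests`.

**Prediction error.** `MSE(t) = mean_i (v_i(t) − v̂_i(t))²` over units,
start points and chains, normalized as

    nMSE = (MSE − MSEvar) / (MSEnaive − MSEvar),

so 1 is the naive unbiased estimator `P(v̂=1)=⟨v_i⟩` (closed form
`⟨2p(1−p)⟩`) and 0 an ideal estimator limited only by generator
stochasticity. `MSEvar` is estimated empirically: per sampled initial
assembly state, the deterministic interaction term is propagated `ΔtA`
steps, pairs of full states are formed with independent intrinsic-rate
draws, each is Poisson-observed once, and the paired disagreement is
averaged (SEM over per-initial-state means). Documented defaults are
10,000 states × 200 pairs; the tests and the acceptance script use 200–300
states × 20 pairs — the estimator is unbiased in the number of states, so
the reduction only widens the SEM (measured ≲ 0.002).

**Train/test split.** Ten contiguous equal segments (remainder to the
last); 1-based segments {2, 6, 7} form the test set, converted to 0-based
columns internally.

**Timescale scan.** For each downsampling rate the raster is downsampled,
split, and an RTRBM is warm-started and trained with an equal
gradient-update budget across rates (epochs are rescaled as data shrinks);
one-step-ahead nMSE on the held-out segments uses the closed-form naive
bound of that rate's test raster and a single generator-level variance
floor. The scan reports the per-rate mean nMSE, the aligned-Û cosine
similarity with the generator's `U`, and the best rate under each. At the
desk scale used in the tests (T = 5000, 3 seeds × 10 rates), rates that
are multiples of the true delay 4 drop to nMSE ≈ 0.67 (rate 4) and ≈ 0.70
(rate 8) while all other rates sit near 0.9, and the cosine similarity
peaks sharply at rate 4 (≈ 0.88 vs < 0.31 elsewhere).

## Alignment and clustering

Assemblies are matched to hidden units by the largest mean `|W|` over the
assembly's neurons, assigning greedily in order of descending match
strength (ties then by lowest assembly index); contested units are
recorded as conflicts and resolved by the same order, with no repair
attempted when an assembly is split across units. The sign of the mean
signed weight marks inverse matches; aligning `U` permutes rows and
columns and negates an inverted unit's row and column, so two inverted
units' mutual weights are unchanged. Cosine similarity z-scores both
flattened matrices with population (N) normalization for bit
reproducibility.

Clustering of `Û` uses Ward linkage on raw Euclidean distances between
rows (incoming) or columns (outgoing) — both axes are supported, rows by
default — cut at a distance threshold. Receptive fields use proportional
thresholding: `w_thr` is set so that exactly `n_strong` neurons exceed it
in `max_j |W_ji|` (ties admit lower indices first); default 5000 neurons,
reduced to `⌈0.125·Nv⌉` for rasters smaller than 5000 neurons to preserve
the proportional intent.

## Numerical and reproducibility choices

Conditionals use `scipy.special.expit`; partition sums use log-sum-exp.
Every stochastic operation takes an explicit `numpy` Generator; trainers
derive all randomness from `config.seed`, and two runs with identical
config and seed are bit-identical. Degenerate (all-zero or all-one)
neurons are trained as-is and flagged in the training log.

## Known limitations

* De novo training does not recover assembly-aligned weights (see the
  warm-start rationale above); recovery claims are conditional on the
  correlation partition finding the assemblies, which is easy at the
  generator's noise levels but not guaranteed on arbitrary data.
* Multi-step-ahead rollouts accumulate phase error in the sampled hidden
  trajectory; with a delay-1 ring generator the normalized error can
  exceed 1 at intermediate horizons (anti-phase predictions) before
  relaxing toward 1. Horizon-1 error is the robust quantity at desk scale.
* The CD-trained static RBM's equilibrium is imperfectly calibrated
  (measured via its sampled first-order moments); conclusions about the
  RBM baseline concern this training recipe, not the best attainable RBM.
* All assemblies share a single interaction delay; multiple concurrent
  timescales are out of scope.
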