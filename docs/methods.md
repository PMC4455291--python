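# Methods

## Scope

glomnose models the signal-processing question, not the hardware: given a
4-class × 4-replica chemical sensor array whose normalized responses
r ∈ [0, 1] drift, jump and occasionally fail, how much classification
stability does an adaptive glomerular pre-processor add over feeding the raw
channels to PLS-DA? Physical sensor modeling (temperature, flow, humidity),
concentration–response curves and spiking neural dynamics are out of scope.

## Glomerular network

State: excitatory weights c (L × N, nonzero only where the class mask is 1),
PG weights d (L × N, all channels), fixed inhibitory couplings
f (L × N × N) ∈ [0, 0.1]. Forward pass per presentation:

    p_ik = d_ik r_k
    m_ij = c_ij r_j Π_k (1 − f_ijk p_ik)
    m_i  = Σ_j m_ij

Initialization: c, d ~ U(0,1) (c masked), f ~ U(0, 0.1) × Bernoulli(0.5).
The masking probability of f is a free choice (only "randomly weighted with
0 or 1" is specified for this architecture); 0.5 is the symmetric default and
is exposed in the config. f entries pointing at a non-existent MC branch
(masked-out (i, j)) are zeroed at initialization and never adapt.

### Plasticity rule

Per presentation (the data are per-exposure ΔR values; there is no
within-exposure time axis):

    Δc_ij = γ_a m_ij (1 − c_ij) − γ_b c_ij²
    Δd_ik = δ_a r_k (1 − d_ik) − δ_b d_ik²

with γ_a = 5·10⁻⁰·⁷ ≈ 0.998, γ_b = 10⁻⁰·⁷ ≈ 0.200, δ_a = 10⁻⁰·⁶ ≈ 0.251,
δ_b = 5·10⁻⁰·⁶ ≈ 1.256, followed by clipping to [0, 1] and re-applying the
class mask. Outputs are recorded *before* the update, so a classifier always
sees pre-update responses. f does not adapt.

The functional form is a design decision constrained by four requirements:
locality (driven by subcompartment quantities, not cell outputs),
nonlinearity, fast-then-slow decay of a deprived synapse, and slower decay of
small weights than under a linear rule. The quadratic-decay saturating-growth
form satisfies all four. One choice deserves emphasis: the PG growth term is
driven by the subcompartment's afferent signal r_k, not by its own potential
p_ik = d_ik r_k. The self-referential variant
(Δd = δ_a p (1−d) − δ_b d²) is degenerate under the stated rates: d = 0 is
then absorbing (p vanishes with d), and because δ_b > 1 any d ≳ 0.8 is
clipped to zero within a single update — in practice most PG synapses die
permanently within the first few presentations and the inhibitory pathway
silences itself. The r-driven form keeps the same locality and the identical
pure-decay behaviour (under r = 0 both rules reduce to Δd = −δ_b d², the
same closed recurrence as c), equilibrates d at ~0.25–0.35 for typical
drives, and lets d recover after a fault, matching the intended circuit
behaviour. The self-referential form remains available via
`LearningRates(d_drive="potential")` for comparison.

Consequences of the quadratic decay (both tested): under a dropout fault the
deprived weight follows c_{t+1} = c_t − γ_b c_t² exactly — decaying to
< 10% of a healthy value within the 120-sample fault window — with strictly
shrinking decrements; silencing any single channel can only increase the
other branch potentials (each factor (1 − f p) ≤ 1 is removed from a
product), and with renewed drive the weight regrows.

## Synthetic sensor array

The generative model for channel (class c, replica q) at presentation t with
stimulus s:

    value = clip_[0,1]( S[c,s]·g_q + h[c,q,s] + b_c(t) + J_c(t) + ε )

- S: 4 × 5 selectivity matrix (clean mean responses). Stimulus 1 is well
  separated (one compound is clearly distinct); stimuli 2–5 overlap, and
  each class is the decisive tie-breaker for a different stimulus pair, so
  that every sensor class carries unique information. The default matrix is
  an editable config entry.
- g_q = 1 + N(0, 0.10): per-replica gain, drawn once per campaign.
- h: optional per-replica selectivity-shape perturbation
  (replica_selectivity_sd, default 0 — see "calibration" below).
- b_c(t): Gaussian random walk, per-step sd 0.0025, with cross-class step
  correlation (classes 2/4: 0.8, class 3 to 2/4: 0.5, class 1: 0.3 —
  replicas of one class share their class walk exactly).
- J_c(t): at each episode boundary, with probability 0.7, a persistent step
  N(0, 0.035), drawn with the same cross-class correlation and shared by all
  replicas of a class. Jumps model the large between-episode shifts
  (episodes are weeks apart in the emulated campaign).
- ε = N(0, 0.01·exp(N(0,1))): i.i.d. read-out noise with a log-normal
  per-channel scale, drawn once per campaign — real sensors differ markedly
  in how noisy they are, and this heterogeneity is what makes naive
  class-averaging costly (the average is forced to include the noisy
  replica; a trained classifier can down-weight it).

Schedules follow the emulated campaign: a training phase of 150
presentations of the 5 stimuli (40/50/20/20/20) in random interleaved order
(episode id 0), then 706 testing presentations in 26 irregular
single-stimulus episodes with per-stimulus totals 25/60/75/188/358. The two
phases are simulated as one continuous stream (drift does not reset) and
split by sample index. Faults replace a channel in a half-open sample-index
window with 0 (dropout) or U(0, 1) draws (random; mean 0.5, spanning the
response scale — the distribution is a design choice, only the mean is
constrained).

What the simulator does not emulate: concentration dependence, response
kinetics within an exposure, humidity/temperature interference, sensor
aging trends (drift is a martingale here), and any fitting to real recorded
data — no raw dataset of the emulated campaign is publicly available, so
simulator parameters are stated choices, not estimates. Passing benchmarks
on this simulator therefore demonstrates internal consistency of the
mechanism under the stated statistical structure, not performance on any
particular physical array.

### Calibration of the defaults

Drift and jump magnitudes were chosen once so that the direct 16-channel
PLS-DA loses roughly 30–40 CCR points relative to its drift-free ceiling —
a degradation of the same order as reported for long-duration metal-oxide
campaigns — and then frozen. Two structural parameters deserve a note:

- replica_selectivity_sd (per-replica fingerprints) defaults to 0. Nonzero
  values hand the 16-channel classifier stationary, drift-immune,
  channel-specific fingerprints; even sd = 0.01 largely rescues the direct
  PLS-DA from drift, which contradicts the campaign being emulated (where it
  demonstrably was not rescued). The parameter exists for sensitivity
  studies.
- noise heterogeneity (noise_spread = 1.0) is what separates the two
  baselines; with homogeneous noise, class-averaging and the 16-channel
  PLS-DA are statistically indistinguishable on this simulator.

## PLS-DA

From-scratch PLS2 on mean-centered predictors and one-hot class indicators.
Each component's predictor weight vector is the dominant left singular
vector of X_resᵀY_res (the SVD form; deterministic, no NIPALS iteration or
convergence tolerance), with rank-one deflation of X. If the response
residual is exhausted before the requested number of components, the
remaining directions fall back to principal components of the predictor
residual so the score basis spans the predictor column space — this makes
full-component PLS exactly reproduce multivariate least squares (tested to
1e-8), a useful oracle. Signs are fixed (largest-magnitude coordinate
positive). Assignment is argmax of the predicted indicator scores; exact
ties go to the lowest class index. Columns are not variance-scaled by
default (all channels share one response scale after normalization);
autoscaling is a config flag. The default component count is 4 (the number
of glomerular outputs, and the bottleneck of the network branch; both
branches use the same setting for a fair comparison).
Cross-validated selection (stratified k-fold, one-standard-error rule) is
available via `n_components: "auto"`.

## Experiment drivers

Normalization: per-channel affine map fitted on training data (1st/99th
percentiles → [0, 1], clipped); the same fitted map is applied to the test
stream, and faults are injected *after* normalization (r = 0 / mean 0.5 are
statements about the normalized scale). All three pipelines consume
identical normalized inputs.

- Baselines: PLS-DA on the 16 channels; PLS-DA on the 4 per-class means.
- Network pipeline, per trial: new random weights; process the training
  stream with adaptation; fit PLS-DA on the recorded MC outputs; keep
  adapting through the test stream; classify its MC outputs. Adaptation
  never stops — that is the point of the model. PLS-DA is refit per trial
  (each trial has its own representation).
- Fault sweep: for each sensor in turn, inject the fault into the normalized
  test stream and score both pipelines on fault-window samples only; the
  network side is averaged over trials, with the (fault-independent)
  training pass shared across sensors within a trial.
- Fault dynamics: three matched passes (none / dropout / random) from the
  identical post-training state, recording the faulty channel's c and d, the
  affected MC's output, and the surviving branches' mean weight.

### Statistical design of the benchmark comparisons

A single simulated campaign is dominated by a handful of drift/jump
realizations: entire episodes are classified all-or-nothing, giving a
per-campaign sd of the pipeline CCR difference of ≈ 0.14. Comparisons are
therefore averaged over many independently seeded campaigns with a fixed,
documented seed list: 300 campaigns × 1 network trial for the three-pipeline
comparison (observed: network − direct ≈ +2.4 points, z ≈ 3.7;
class-average − direct ≈ −1.2 points), and 24 campaigns × 2 trials for the
16-sensor dropout sweep, scored over a 320-sample fault window
([300, 620); the longer window measures the steady state of the adapted
network rather than the onset transient — the default single-fault window
for the dynamics study remains [400, 520)). Problem sizes were chosen so the
full suite and the acceptance script each run in minutes on one CPU.

## Numerical choices and degenerate inputs

- Weight boxes enforced by clipping after every update; masked c entries are
  re-zeroed each step.
- Network inputs are validated to [0, 1] (tolerance 1e-12) — the
  normalization contract.
- Correlation of a constant channel is reported as NaN, not an error.
- A constant channel in normalization falls back to unit scale with a
  warning.
- Empty fault windows warn and leave data unchanged; an empty-window sweep
  reports NaN rates.
- Trial seeds derive from the master seed via `numpy.random.SeedSequence`
  spawning, truncated below 2³¹.
- The drift correlation matrix is factored by symmetric eigendecomposition
  (tolerating positive-semidefinite inputs where Cholesky fails).

## Known limitations

- The network's drift advantage on this simulator is real but modest
  (~2–3 CCR points seed-averaged); its robust, across-the-board advantage is
  under sensor faults. The multiplicative inhibition with f ≤ 0.1 provides
  only weak common-mode gain control, and the weight equilibria track —
  rather than cancel — slow input drift.
- With only 4 MC outputs for 5 stimuli the network representation is a
  bottleneck; it is near-lossless in the drift-free limit (CCR ≈ 0.99) but
  concentrates fault damage in single features.
- Class labels, not concentrations; one concentration per stimulus.
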