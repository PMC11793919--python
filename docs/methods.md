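# Methods

## Problem and data model

The package imputes missing entries in multivariate time series that are
irregularly sampled: a sequence is a D×T value matrix with a binary mask
(1 = observed), and a strictly increasing timestamp vector anchored at 0.
Missing entries are NaN in memory and empty cells in CSV; the package does
not attempt to distinguish true observed zeros from missing values — the
mask is authoritative. Duplicate timestamps are rejected: a zero gap would
make the decay mechanism meaningless. When no timestamps are supplied, unit
spacing is assumed.

Two time-lag matrices drive the temporal model. Entry (d, i) of the forward
matrix δᶠ is the time elapsed since feature d was last observed (0 at i = 1,
accumulating across runs of missingness); the backward matrix δᵇ is its
mirror image anchored at i = T. The two are exact duals: reversing the
series in time (columns flipped, timestamps reflected through the total
span) swaps their roles, a property the test suite checks exactly on
integer timestamp grids and to float rounding otherwise.

## Recurrent cells

The GRUI cell is a concatenated-weight GRU whose previous hidden state is
first attenuated elementwise by β_t = exp(−max(0, W_β δ_t + b_β)) ∈ (0, 1]^H.
W_β maps the D-dimensional lag vector into hidden space as a full matrix —
the least restrictive reading, since the decay multiplies the hidden state
while the lags are feature-indexed; a diagonal per-feature variant would be
a special case. When every decay pre-activation is ≤ 0 the cell reduces
exactly to a plain GRU, which doubles as a strong equivalence test.
Forward and backward cells have independent parameters; initial hidden
states are fixed at zero, not learned; the bidirectional hidden state is
the arithmetic mean of the two directional trajectories. Hidden components
stay in (−1, 1) by induction: each state is a convex combination of a
decayed previous state and a tanh output.

Numerical guard: the decay pre-activation is clipped at +50 before the
exponential, bounding β away from exact zero (≥ ~2e−22; documented floor
1e−20).

## f-divergence losses

For convex f with f(1) = 0, D_f(P‖Q) = E_Q[f(p/q)] admits the variational
lower bound sup_T E_P[T] − E_Q[f*(T)] over critics T with range in dom f*.
The registry carries the standard construction — generator function f,
conjugate f*, and output activation g_f mapping raw critic scores into
dom f*:

| name       | f(u)                        | f*(t)            | dom f*    | g_f(v) |
|------------|-----------------------------|------------------|-----------|--------|
| forward_kl | u log u                     | exp(t−1)         | ℝ         | v |
| reverse_kl | −log u                      | −1−log(−t)       | t < 0     | −eᵛ |
| js         | u log u − (u+1) log((u+1)/2)| −log(2−eᵗ)       | t < log 2 | log 2 − softplus(−v) |
| pearson    | (u−1)²                      | t²/4 + t         | ℝ         | v |

The reverse-KL activation is −exp(v) so critic outputs are strictly
negative. The JS activation is kept 1e−7 inside its boundary because
softplus underflows to 0 at very large scores, which would otherwise land
the critic exactly on t = log 2 where f* diverges. Exponential arguments
are clamped at ±30 throughout, and the public conjugate evaluator enforces
an ε = 1e−7 interior margin. Conjugates are verified against a dense
grid-search supremum to 1e−6; note the Pearson generator is the quadratic
on all of ℝ (restricting it to u > 0 would change f* below t = −2).

Wasserstein is included for comparison but handled as a special case: an
unconstrained critic with identity activation, kept approximately Lipschitz
by clipping all discriminator weights to ±0.01 after each critic update,
with 5 critic steps per generator step — the original weight-clipped
recipe of the unidirectional antecedent, not gradient penalty. The
unidirectional + Wasserstein configuration therefore reproduces that
antecedent architecture class structurally (no backward cell,
mean-difference critic objective).

## Adversarial imputation

The generator consumes M⊙X + (1−M)⊙Z per timestep (Z i.i.d. N(0, 0.01²),
shaped like X), runs the bidirectional GRUI, and projects each combined
hidden state back to D outputs. The completed matrix X̂ = M⊙X + (1−M)⊙Ĝ
preserves observed entries exactly by construction. The discriminator is a
second bidirectional GRUI stack emitting one raw score per feature per
timestep of X̂; scores at observed positions form the "real" expectation
and scores at imputed positions the "fake" expectation of the f-GAN
objective — reconciling entrywise mask discrimination with the sample-level
variational formulation.

Training: a reconstruction-only pretraining phase, then alternating
discriminator ascent and generator descent. Both optimizers are Adam with
betas (0.5, 0.9) — the conventional low-momentum GAN setting — with global
gradient-norm clipping at 5. Inside the generator objective the
reconstruction term is the squared Frobenius norm over observed entries
(a sum, not a mean): with a mean-normalized term, λ = 0.15 lets the
adversarial gradient dominate at small batch sizes and the imputations
inflate toward marginal samples; the sum form keeps the weighting stable
across scales. The standalone `reconstruction_loss` metric reported in
training history is mean-normalized so values are comparable across
missing rates.

Sequences of different lengths are bucketed (equal T per batch); the
recurrent arithmetic never sees padding, so the decay is always driven by
real gaps.

After training, the noise occupying the missing slots is refined per
sequence with the network weights frozen: plain gradient descent (step
0.5 in standardized units) on L_R + 0.1·(−mean discriminator score at the
imputed positions). A backtracking rule keeps the reconstruction component
nonincreasing up to a tolerance of 1e−6 per accepted step: rejected steps
revert and retry, and the step size halves only after 5 consecutive
rejections. The tolerance matters — near a generator that already
reconstructs the observed context well, L_R is almost flat in Z, and a
hard monotonicity rule freezes the adversarial pull entirely. Equal-length
sequences are refined jointly for shared forward passes, but each keeps
its own step size and acceptance state, so the result equals refining them
one at a time.

Defaults follow the reference configuration: batch 128, hidden size 64,
λ = 0.15, learning rate 1e−3, 5 pretraining + 30 adversarial epochs, 400
refinement iterations, Adam. The `noise_dim` field records the alternative
64-dimensional latent-vector reading of the noise input; the implemented
noise is X-shaped as the compose formula requires, and the latent variant
is not implemented.

### A scale-dependent failure mode worth knowing

The generator's input at time t contains the observed x_t itself, so
driving the observed-entry reconstruction too far teaches the network an
identity shortcut: observed entries are copied perfectly while missing-slot
outputs collapse to the global feature mean plus noise, which is *worse*
than per-sequence mean imputation. On small datasets this happens within a
few hundred Adam steps at learning rate 1e−2; at the default 1e−3 the
5 + 15 epoch schedule stays in the regime where the recurrent context
(not the shortcut) explains the observed entries, and the adversarial
phase then improves the imputations further. Users fitting small corpora
should prefer the default rate and treat a near-zero training
reconstruction loss as a warning sign, not a success metric.

## Synthetic benchmark

The generator emulates the target data class: a latent VAR(1) process
x_t = a·x_{t−1} + ε_t with scalar autoregression a and exchangeable
innovation correlation Σ = σ²[(1−ρ)I + ρJ], initialized from its
stationary marginal; the last feature additionally carries a sinusoid
(period 12 time units, amplitude 1) evaluated at the actual timestamps, so
irregular sampling is visible in the values. Irregular gaps are drawn as
0.1 + Exp(0.9) (mean gap 1), keeping timestamps strictly increasing.
Missingness is MCAR by default — each entry hidden independently — with an
optional two-state Markov mechanism producing geometric runs of
missingness at the same marginal rate, since accumulated time lags only
matter under consecutive gaps. Sequences left with an unobserved feature
are redrawn. Ground truth and the evaluation mask are retained, so a
perfect oracle has masked RMSE exactly 0. Binary sequence labels follow
Bernoulli(sigmoid(wᵀ(feature time means) + N(0, 0.1))).

Study conditions for the shipped benchmark, chosen once: 20 sequences,
D = 5, T = 48, a = 0.8, ρ = 0.3, σ = 1, irregular sampling, 20% MCAR;
training uses batch size 4 (so the 5 + 15 epoch schedule performs a
meaningful number of updates at n = 20), the default learning rate 1e−3,
and 50 refinement iterations (scaled from the reference 400 to desk-scale
runtime). What passing shows: the bidirectional decay-GRU GAN extracts
per-sequence temporal context that per-feature mean imputation cannot
(masked RMSE ≈ 1.2–1.3 versus ≈ 1.6 across seeds). What it does not show:
performance under informative (MAR/MNAR) missingness, non-stationary or
heavy-tailed dynamics, or real clinical measurement processes — the
generator has none of these.

## Evaluation harness

Masked RMSE is computed only over deliberately hidden entries. Baselines:
per-feature observed mean, forward fill (leading gaps back-filled), and
constant zero (meaningful in standardized units, where it equals the
dataset-level feature mean). AUC is the Mann–Whitney probability with ties
counted one half (via scikit-learn, cross-checked against exhaustive
pairwise counting in tests). The downstream classifier is a plain
single-layer GRU with a logistic read-out on the final hidden state —
plain rather than GRUI because completed data has no missingness, so decay
is undefined; its hyperparameters (hidden 16, Adam 0.9/0.999, logistic
loss) are exposed as estimator parameters rather than fixed. The
missing-rate sweep runs simulate → mask → train → impute → evaluate per
(rate, divergence, direction) cell with independent seeds, asserts the
observed-entry preservation invariant on every run, and reports mean ±
standard error over 5 repeats by default.

## Known limitations

- MCAR (and optional bursty) missingness only; no value-dependent
  mechanisms.
- One recurrent layer per direction; no LSTM variant, attention, or
  stacking.
- The identity-shortcut regime described above: prolonged reconstruction
  training on small corpora degrades imputation while improving the
  training loss.
- GAN imputation draws a single realization per gap; it is not a posterior
  mean, so on purely RMSE terms heavy adversarial weighting can be
  counterproductive even when the generative fit improves.
- Numerical exactness of the time-reversal duality holds on exactly
  representable timestamp grids; float gaps agree to rounding error.
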