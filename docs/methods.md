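# Methods

## The model

Population activity is reduced to binary words: each cell's spike train is
binned at 20 ms (configurable), a bin holding one or more spikes becomes 1.
The distribution over words `R = {r_i}` is modelled by the maximum-entropy
family

```
P(R) = exp(-E(R)) / Z
E(R) = Σ_i h_i r_i  +  Σ_{i, j≠i} J_ij r_i r_j  +  λ_K ,   K = Σ_i r_i
```

with three nested classes: *independent* (h only), *pairwise* (h, J), and
*k-pairwise* (h, J, λ).  The classes are exactly the least-structured
distributions matching, respectively, the firing rates `<r_i>`; plus the
pairwise second moments `<r_i r_j>`; plus the spike-count distribution
P(K).  The pair sum runs over ordered pairs, so a coupled pair contributes
`2 J_ij`; the all-silent word has energy `λ_0 = 0`.

Gauge freedoms and their fixing: adding `aK + b` to λ while subtracting
`a` from every `h_i` leaves P unchanged, which `λ_0 = λ_1 = 0` absorbs.
Less obviously, a uniform coupling shift `J_ij → J_ij + c` is equivalent
to `λ_K → λ_K + c·K(K-1)`, so the fitters additionally pin `λ_2 = 0`;
P(K=2) is then implied by normalisation, the rates and the pair moments.
With this gauge the fitted parameters are unique (verified by refitting
from shuffled coordinate orders; spread < 1e-3 in exact mode).

## Inference

Every sufficient statistic is a binary feature, so a single coefficient
has a closed-form coordinate update: if the model expectation of a feature
is `p` and its target `t`, the step `d = log[p(1-t) / (t(1-p))]` matches
it exactly.  An L1 penalty on couplings and λ (weight `1/n_samples` by
default, never on the fields) enters through the standard two-branch
soft-threshold variant of the same update.

*Exact mode* (N ≤ 15 by default, available to 20): sequential coordinate
descent over an incrementally reweighted enumeration of all 2^N state
weights; convergence when every constraint is within 3 target standard
errors (bootstrap errors when attached to the target, binomial otherwise,
floored at `abs_tol = 1e-4`).

*Monte-Carlo mode* (larger N): expectations are re-estimated each epoch
from ~1e5 sweeps of 100 persistent heat-bath chains, and all coordinates
take damped parallel steps.  Three stabilisations matter:

- the λ family is updated jointly (the spike-count indicators partition
  the state space, so reweighting K=k states by `t_k/p_k` matches P(K) in
  one exact step), then re-gauged;
- the h and pair steps are zero-meaned when P(K) is fitted — the global
  activity level and the uniform-coupling mode are owned by the λ/gauge
  pathway; two controllers on one nearly-degenerate mode produce a
  period-2 limit cycle;
- the step size shrinks when successive update directions anti-align and
  recovers when they persist (collective modes at N ≳ 40 otherwise
  oscillate at any fixed usable step).

λ_K is fitted only where P(K) is resolvable at the sampling budget
(expected count ≥ 8).  Beyond that range λ is continued so the mean-field
energy `E(K) = K·h̄ + K(K-1)·J̄ + λ_K` increases with K: with negative
mean couplings a naive tail opens a spurious low-energy high-K phase that
ruins the low-temperature thermodynamics.  Convergence tolerances add the
Monte-Carlo standard error of each estimated moment (chain-to-chain
spread) in quadrature with the target's.  Each parameter block (fields,
pairs, spike-count potential) carries its own adaptive step, so damping
an oscillation-prone collective block never throttles the many
nearly-independent pair coordinates; a short fixed-step polish phase
tail-averages the parameters at the end, which visibly stabilises the
downstream specific-heat curves of near-critical models.

## Thermodynamics

A fictitious temperature enters as `P(R;T) ∝ exp(-E(R)/T)` and the
specific heat is `C(T) = (<E²> - <E>²)/T²`, reported per neuron (`C/N`,
`per_neuron` flag; the unnormalised value is kept alongside).  For N ≤ 20
everything is enumerated with log-sum-exp.  For larger populations an
annealing protocol is used: parallel chains (default 100 × 5000 sweeps
per level, one sweep = one full random-order update of all N cells) are
initialised at the highest temperature of a descending grid (default 40
log-spaced points, 3.0 → 0.5), re-equilibrated for 50 sweeps at each new
level, and carried downward.  C comes from the pooled energy variance;
its standard error from the spread of per-chain estimates.  Incremental
energy and pair-field bookkeeping make a sweep O(N) plus O(N) per actual
flip, so the default protocol runs in seconds up to N ≈ 60 (numba).

The independent-population reference curve is analytic:
`C(T) = Σ_i (h_i/T)² q_i (1-q_i)` with `q_i = σ(-h_i/T)`.

Peak statistics take the grid argmax after optional 3-point smoothing,
flagging flat curves (range < 2 SE) and boundary peaks.  Subsampling
scans fit models to random cell subsets at several sizes (10 groups per
size; when the "subset" is the whole population, 3 independently seeded
fits) and summarise `T_max` and `C(T_max)` per size.

Near the transition a chain started cold at the target temperature can
stay trapped on one side of the free-energy barrier; single-temperature
measurements (e.g. C at the operating point T = 1 in the α scan)
therefore anneal down a short ladder from T = 3 by default rather than
sampling directly — direct estimates differed between protocols by
factors of 2–3 near the peak, annealed ones were reproducible.

## Correlation surgery

All manipulations fix the rates and act on the Pearson correlation
matrix, rebuilding second moments as `q = C σ_i σ_j + m_i m_j` and
clipping to the Fréchet box (error if > 1% of pairs clip).  The shuffled
baseline is one realised grand shuffle (independent circular shift per
cell), retaining sampling noise.  Top-L keeps each cell's L strongest
|C| partners with union symmetrisation.  The α mix is elementwise,
`C(α) = α C_true + (1-α) C_shuff`.  The α* estimator brackets the first
grid interval after which the largest-vs-smallest-N gap in C(T=1)
exceeds 3 pooled SEs and stays there.

## Landscape probes

The effective field `dE_i = h_i + 2 Σ_j J_ij r_j + λ_{K'+1} - λ_{K'}`
(K' excluding cell i) is the energy of spiking given the rest of the
word; the flow vector collects `x_i = σ(-dE_i/T)` — the heat-bath
conditionals, the unique single-site rule stationary for P(R;T).
Zero-temperature descent flips the single most energy-lowering cell
(ties to the lowest index) until none remains.  Dwell times count full
sweeps at T = 1 until ≥ `silent_target` (default 9) of the initially
spiking cells are simultaneously silent, checked after each sweep;
re-activations count as active; runs hitting `max_sweeps` are censored
and excluded from means.  The persistence index is `cos(X(R), R)`,
strictly in (0, 1] for K ≥ 1.  Flow-overlap profiles sort states by
spike count (≥ 5 by default), split them into 100 equal groups, and
average the unit-vector overlap and norm ratio between two models.

## LN comparison network

Filters are spike-triggered averages of the mean-subtracted stimulus
(default 15 lags of 20 ms); the nonlinearity is the empirical
P(spike | q) on 25 equal-occupancy bins of the generator signal —
identically the Bayes-rule ratio.  Simulation shifts each nonlinearity
horizontally (bisection) until the expected rate matches its target
within 1%, then draws Bernoulli spikes.  Stimulus frames are
nearest-bin aligned to the raster when counts differ; color channels
enter the filter dot-product directly (equal weighting).

## Synthetic data

The reference population is a dichotomised Gaussian: a latent Gaussian
with unit variances whose correlation comes from several overlapping
non-negative factors (each loading on ~80% of cells with heterogeneous
weights — the latent analogue of overlapping receptive-field pools),
thresholded per cell at the Gaussian quantile of its target rate.  This
controls rates and correlations without touching the maximum-entropy
machinery, keeping inference validation non-circular.  Defaults: 60
cells, rate 0.03 per 20 ms bin, coupling scale 0.7 — calibrated once so
the mean pairwise correlation is ≈ 0.04 — giving many weak positive
correlations with outliers up to ~0.2 and a long-tailed P(K), and 1e5
time bins (a ~30 min recording).

Two earlier factor geometries were rejected at design time.  A single
global factor makes the population collectively ferromagnetic (one
dominant latent mode), unlike overlapping local common input.  Sparser
factors (loading ~60% of cells) concentrate the correlation into tight
blocks: at matched mean correlation the fitted N = 60 model then sits
*on* its first-order line at T = 1, where phase coexistence makes every
sampling-based estimate (and the fit itself) irreproducible — a regime
incompatible with the smooth, single-peaked specific-heat curves of the
recordings this generator emulates.  The dense-overlap geometry keeps
the peak just above the operating point, where those curves live.

What the generator does *not* emulate: refractoriness and temporal
autocorrelation within cells, stimulus-locked repeat structure in the
main population (a separate trial-raster generator covers that),
negative correlations beyond what dichotomisation induces, and any
adaptation. Passing tests therefore validate the estimators and the
pipeline's internal consistency on populations with realistic low-order
statistics — not the biological claims themselves.

Ground-truth model sampling is exact (enumeration) for N ≤ 20 and
single-chain Gibbs (burn-in 100 sweeps, thinning 1) above.  All
generators are pure functions of their integer seed; pipelines derive
per-operation seeds from one master seed via `SeedSequence` with hashed
text tags.

## Numerical choices and limitations

- All partition sums use log-sum-exp; Monte-Carlo energies are tracked
  incrementally and re-synced at every kernel entry.
- Descent ties break toward the lowest cell index; boundary spikes bin
  half-open `[t·w, (t+1)·w)`.
- Zero-variance cells carry NaN correlations and are excluded from
  z-score summaries.
- The specific-heat peak at N ≈ 60 under the default synthetic regime
  sits within grid resolution of T = 1 (it can land marginally below);
  the finite-size trend (peak growth, T_max → 1) is the robust
  observable, not the exact peak position.
- Fit-sampling noise, not Monte-Carlo error, dominates comparisons of
  fitted-model thermodynamics against analytic references at 1e5
  samples; tests estimate that component by bootstrap refits and include
  it in the tolerance.
- Problem sizes in the test-suite and in `scripts/acceptance.py` (N up
  to 60, 1e5 bins, 30–40 temperature levels, 32–100 chains × 0.8–5k
  sweeps) were chosen as the package's reference configuration; all are
  ordinary keyword arguments.
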