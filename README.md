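# spikemaxent

Maximum-entropy analysis of binary neural population activity: model
inference, fictitious-temperature thermodynamics, correlation-matrix
surgery, and energy-landscape geometry, with seeded synthetic-data
generators so the whole pipeline runs without any external recording.

## The problem

Dense multielectrode recordings deliver the simultaneous spike trains of
tens to hundreds of neurons.  Binned at 20 ms and binarised, the
population emits binary words `R = {r_i}`; the question is whether the
distribution `P(R)` is just a bag of weakly coupled cells or a genuinely
collective, structured state.  The standard tool is the maximum-entropy
model family

```
P(R) = exp(-E(R)) / Z
E(R) = Σ_i h_i r_i + Σ_{i,j≠i} J_ij r_i r_j + λ_K ,   K = Σ_i r_i
```

— the least-structured distribution matching the measured firing rates
`<r_i>`, pairwise moments `<r_i r_j>`, and (for the *k-pairwise* class)
the spike-count distribution P(K).  Introducing a fictitious temperature
`P(R;T) ∝ exp(-E/T)` and tracing the specific heat
`C(T) = Var(E)/T²` diagnoses the collective state: a peak that grows and
sharpens with population size N, approaching the operating point T = 1
from above, signals a phase transition and places the real population in
the structured, "low-temperature" regime.  The package implements that
analysis end to end, plus the probes that connect it to attractor-like
structure in the energy landscape: zero-temperature descent, Monte-Carlo
flow vectors, dwell times, and the persistence index
`PI = cos(X(R), R)`.

Intended users: computational-neuroscience groups analysing population
spike rasters, and anyone who needs a tested k-pairwise/Ising pipeline
on binary data.

## Worked example

```python
import numpy as np
import spikemaxent as sm
from spikemaxent.synthetic import default_study_population
from spikemaxent.thermo import annealed_specific_heat, default_t_grid, peak_statistics

# 60 sparse cells (0.03 spikes/bin), weak heterogeneous correlations
raster = default_study_population(n_cells=60, n_bins=100_000, seed=11)
mom = sm.compute_moments(raster)
iu = np.triu_indices(60, k=1)
print(f"mean rate {mom.rates.mean():.3f}, "
      f"mean correlation {np.nanmean(mom.correlations[iu]):.4f}")

model, report = sm.fit_maxent(mom, model_class="k-pairwise", seed=99)
print(f"converged={report.converged} after {report.n_epochs} epochs")

curve = annealed_specific_heat(model, default_t_grid(30),
                               n_runs=64, samples_per_run=2000, seed=7)
peak_statistics(curve)
print(f"per-neuron C peaks at {curve.c_at_t_max:.2f} for T = {curve.t_max:.2f}")
```

prints

```
mean rate 0.030, mean correlation 0.0399
converged=True after 26 epochs
per-neuron C peaks at 1.41 for T = 1.12
```

meaning: the fitted population's specific heat peaks just above the
operating point — the signature of a structured, "low-temperature"
collective state.  Smaller subgroups of the same raster peak at higher
temperatures with lower peaks, and the peak marches toward T = 1 as N
grows (`spikemaxent.thermo.subsample_scan` quantifies the trend).

A command-line interface covers the common pipeline steps:

```
spikemaxent simulate --kind ground-truth --n-cells 10 --n-bins 30000 --seed 4 --out raster.txt
spikemaxent fit     --raster raster.txt --out model.json --seed 5
spikemaxent thermo  --model model.json --out curve.csv --seed 6
```

Each command writes a `*.manifest.json` with the configuration, seeds
and versions that produced its output.

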