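"""Geometry of the model probability landscape.

Each activity state R sits on an energy landscape E(R); the heat-bath
sampler's single-site transition probabilities define a local 'direction
of motion' there.  For cell i the energy cost of spiking given the rest of
the state is the effective field

    dE_i(R) = h_i + 2 sum_{j != i} J_ij r_j + (lambda_{K'+1} - lambda_{K'}),

with K' the spike count of the other cells, and the conditional spike
probability is x_i = 1 / (1 + exp(dE_i / T)).  The vector
X(R) = {x_i} — the *flow vector* — is probed four ways:

* zero-temperature descent: greedy single-cell flips that strictly
  decrease energy, mapping states to local minima (for sparse populations
  almost all states drain into the all-silent minimum);
* flow-overlap profiles: how the direction and magnitude of X(R) under a
  manipulated model compare to a reference model, state by state;
* dwell times: sweeps of T = 1 sampling until most of a state's initially
  spiking cells have fallen silent — long dwells mark attractor-like
  states;
* the persistence index PI = cos(X(R), R), a cheap proxy for dwell time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _gibbs
from ._seeds import child_seed
from .maxent import MaxEntModel, model_moments

__all__ = [
    "FlowVector",
    "DescentResult",
    "DwellResult",
    "effective_field",
    "effective_fields",
    "flow_vector",
    "flow_vectors",
    "zero_temperature_descent",
    "descent_census",
    "flow_overlap_profile",
    "dwell_time",
    "persistence_index",
    "pi_dwell_correlation",
]


@dataclass
class FlowVector:
    """Conditional spike probabilities x_i(R) at temperature T."""

    x: np.ndarray
    temperature: float = 1.0

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.x))

    @property
    def unit(self) -> np.ndarray:
        return self.x / self.norm


@dataclass
class DescentResult:
    final_state: np.ndarray
    n_flips: int
    energy_trajectory: np.ndarray  # strictly decreasing
    reached_silence: bool


@dataclass
class DwellResult:
    """Per-run dwell times (sweeps) from one initial state."""

    dwell: np.ndarray
    censored: np.ndarray
    silent_target: int
    max_sweeps: int

    @property
    def n_censored(self) -> int:
        return int(self.censored.sum())

    @property
    def mean(self) -> float:
        ok = self.censored == 0
        return float(self.dwell[ok].mean()) if ok.any() else float("nan")

    @property
    def median(self) -> float:
        ok = self.censored == 0
        return float(np.median(self.dwell[ok])) if ok.any() else float("nan")


# ---------------------------------------------------------------------------
# fields and flow
# ---------------------------------------------------------------------------


def effective_field(model: MaxEntModel, state: np.ndarray, i: int) -> float:
    """dE_i = E(r_i = 1) - E(r_i = 0) with the other cells held fixed."""
    r = np.asarray(state, dtype=np.float64)
    kp = int(round(r.sum() - r[i]))
    return float(model.h[i] + 2.0 * (model.J[i] @ r - model.J[i, i] * r[i])
                 + model.lam[kp + 1] - model.lam[kp])


def effective_fields(model: MaxEntModel, states: np.ndarray) -> np.ndarray:
    """dE_i for every cell of every state; states is (n_states, N)."""
    r = np.atleast_2d(np.asarray(states, dtype=np.float64))
    k = r.sum(axis=1).astype(int)
    kp = k[:, None] - r.astype(int)  # spike count excluding each cell
    lam = model.lam
    return model.h[None, :] + 2.0 * (r @ model.J) + lam[kp + 1] - lam[kp]


def flow_vector(model: MaxEntModel, state: np.ndarray, temperature: float = 1.0) -> FlowVector:
    """Heat-bath conditional spike probabilities for one state.

    ``x_i = 1 / (1 + exp(dE_i / T))`` — the unique single-site rule that
    leaves P(R) ∝ exp(-E/T) invariant.  For finite parameters every
    component lies strictly inside (0, 1).
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    de = effective_fields(model, np.atleast_2d(state))[0]
    return FlowVector(1.0 / (1.0 + np.exp(de / temperature)), temperature)


def flow_vectors(model: MaxEntModel, states: np.ndarray, temperature: float = 1.0) -> np.ndarray:
    de = effective_fields(model, states)
    return 1.0 / (1.0 + np.exp(de / temperature))


# ---------------------------------------------------------------------------
# zero-temperature descent
# ---------------------------------------------------------------------------


def zero_temperature_descent(model: MaxEntModel, state: np.ndarray) -> DescentResult:
    """Greedy steepest descent to a local energy minimum.

    Repeatedly flips the single cell whose flip lowers the energy the most
    (ties broken toward the lowest cell index) until no flip decreases the
    energy.  The recorded energy trajectory is strictly decreasing, so the
    walk terminates on the finite state space.
    """
    r = np.asarray(state, dtype=np.uint8).copy()
    energies = [model.energy(r)]
    n_flips = 0
    while True:
        de = effective_fields(model, r[None, :])[0]
        # energy change of flipping each cell: +dE if silent, -dE if active
        delta = np.where(r == 1, -de, de)
        best = int(np.argmin(delta))
        if delta[best] >= 0:
            break
        r[best] ^= 1
        n_flips += 1
        energies.append(energies[-1] + delta[best])
    return DescentResult(
        final_state=r,
        n_flips=n_flips,
        energy_trajectory=np.asarray(energies),
        reached_silence=bool((r == 0).all()),
    )


def descent_census(model: MaxEntModel, states: np.ndarray):
    """Descend every state; tally the local minima reached.

    Returns (fraction_silent, minima) where ``minima`` maps each distinct
    final state (as a tuple) to the number of start states in its basin.
    """
    states = np.atleast_2d(np.asarray(states, dtype=np.uint8))
    if states.shape[0] == 0 or states.size == 0:
        return float("nan"), {}
    minima: dict[tuple, int] = {}
    n_silent = 0
    for s in states:
        res = zero_temperature_descent(model, s)
        key = tuple(int(v) for v in res.final_state)
        minima[key] = minima.get(key, 0) + 1
        n_silent += res.reached_silence
    return n_silent / states.shape[0], minima


# ---------------------------------------------------------------------------
# flow overlap across models
# ---------------------------------------------------------------------------


def flow_overlap_profile(
    model_a: MaxEntModel,
    model_ref: MaxEntModel,
    states: np.ndarray,
    n_groups: int = 100,
    min_spikes: int = 5,
    temperature: float = 1.0,
) -> pd.DataFrame:
    """Direction and magnitude similarity of flow vectors across two models.

    States are filtered to spike count >= ``min_spikes``, sorted by spike
    count and split into ``n_groups`` equally populated groups.  Per group
    the mean direction overlap  unit(X_a) . unit(X_ref)  and the mean
    magnitude ratio  ||X_a|| / ||X_ref||  are reported, with their SEs.
    """
    if model_a.n_cells != model_ref.n_cells:
        raise ValueError("models must have the same population size")
    states = np.atleast_2d(np.asarray(states, dtype=np.uint8))
    k = states.sum(axis=1)
    states = states[k >= min_spikes]
    k = k[k >= min_spikes]
    if states.shape[0] == 0:
        raise ValueError("no states with enough spikes")
    if states.shape[0] < n_groups:
        warnings.warn(
            f"only {states.shape[0]} states; reducing group count", stacklevel=2)
        n_groups = states.shape[0]
    order = np.argsort(k, kind="stable")
    states = states[order]
    k = k[order]
    xa = flow_vectors(model_a, states, temperature)
    xr = flow_vectors(model_ref, states, temperature)
    na = np.linalg.norm(xa, axis=1)
    nr = np.linalg.norm(xr, axis=1)
    direction = (xa * xr).sum(axis=1) / (na * nr)
    magnitude = na / nr
    bounds = np.linspace(0, states.shape[0], n_groups + 1).astype(int)
    rows = []
    for g in range(n_groups):
        sl = slice(bounds[g], bounds[g + 1])
        m = max(bounds[g + 1] - bounds[g], 1)
        rows.append({
            "group": g,
            "mean_k": float(k[sl].mean()),
            "direction_overlap": float(direction[sl].mean()),
            "direction_se": float(direction[sl].std(ddof=1) / np.sqrt(m)) if m > 1 else 0.0,
            "magnitude_ratio": float(magnitude[sl].mean()),
            "magnitude_se": float(magnitude[sl].std(ddof=1) / np.sqrt(m)) if m > 1 else 0.0,
            "n_states": int(m),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dwell times and persistence
# ---------------------------------------------------------------------------


def dwell_time(
    model: MaxEntModel,
    state: np.ndarray,
    silent_target: int = 9,
    max_sweeps: int = 1000,
    n_runs: int = 1000,
    seed: int = 0,
    temperature: float = 1.0,
) -> DwellResult:
    """Sweeps of T = 1 sampling until the state has mostly dissolved.

    A run ends when at least ``silent_target`` of the initially spiking
    cells are simultaneously silent, checked after each full sweep (cells
    that re-activate count as active again).  Runs reaching ``max_sweeps``
    are censored and excluded from the summary statistics.
    """
    r0 = np.asarray(state, dtype=np.uint8)
    k0 = int(r0.sum())
    if silent_target > k0:
        raise ValueError(f"silent_target {silent_target} exceeds the state's spike count {k0}")
    dwell, censored = _gibbs.dwell_times(
        model.h, model.J, model.lam, float(temperature), r0,
        silent_target, max_sweeps, n_runs, child_seed(seed, "dwell"),
    )
    return DwellResult(dwell, censored, silent_target, max_sweeps)


def persistence_index(model: MaxEntModel, state: np.ndarray, temperature: float = 1.0) -> float:
    """PI = cos(X(R), R): how much the average next state resembles R.

    Both vectors are non-negative, so PI lies in (0, 1]; 1 means the flow
    points exactly along the state.  Undefined (raises) for the all-silent
    state.
    """
    r = np.asarray(state, dtype=np.float64)
    if r.sum() < 1:
        raise ValueError("persistence index undefined for the all-silent state")
    x = flow_vector(model, r, temperature).x
    return float((x @ r) / (np.linalg.norm(x) * np.linalg.norm(r)))


def pi_dwell_correlation(
    model: MaxEntModel,
    states: np.ndarray,
    silent_target: int = 9,
    max_sweeps: int = 1000,
    n_runs: int = 1000,
    seed: int = 0,
    independent_model: MaxEntModel | None = None,
    moment_kwargs: dict | None = None,
):
    """Correlate persistence index with log mean dwell time across states.

    Requires >= 10 states with one common spike count.  Dwell times are
    measured under ``model`` and under its rate-matched independent
    counterpart; the Pearson correlation between PI (from ``model``) and
    log10 mean dwell is reported for both.  Correlations are flagged
    unreliable when more than half the runs of any state are censored.

    Returns a dict with keys ``r_full``, ``r_independent``, ``table``
    (a DataFrame keyed by state id) and ``reliable``.
    """
    states = np.atleast_2d(np.asarray(states, dtype=np.uint8))
    if states.shape[0] < 10:
        raise ValueError("need at least 10 states")
    ks = set(int(s.sum()) for s in states)
    if len(ks) != 1:
        raise ValueError("all states must share one spike count K")
    if independent_model is None:
        independent_model = model.rate_matched_independent(
            seed=child_seed(seed, "pi-indep-rates"), **(moment_kwargs or {}))
    pis = np.array([persistence_index(model, s) for s in states])
    rows = []
    reliable = True
    for sid, s in enumerate(states):
        d_full = dwell_time(model, s, silent_target, max_sweeps, n_runs,
                            seed=child_seed(seed, f"dwell-full-{sid}"))
        d_ind = dwell_time(independent_model, s, silent_target, max_sweeps, n_runs,
                           seed=child_seed(seed, f"dwell-ind-{sid}"))
        if d_full.n_censored > n_runs / 2 or d_ind.n_censored > n_runs / 2:
            reliable = False
        rows.append({"state": sid, "pi": pis[sid],
                     "mean_dwell": d_full.mean, "n_censored": d_full.n_censored,
                     "mean_dwell_independent": d_ind.mean,
                     "n_censored_independent": d_ind.n_censored})
    table = pd.DataFrame(rows)
    if not reliable:
        warnings.warn("censoring dominates some dwell distributions; "
                      "correlations unreliable", stacklevel=2)

    def _corr(col):
        y = np.log10(table[col].to_numpy())
        ok = np.isfinite(y)
        if ok.sum() < 3 or pis[ok].std() == 0 or y[ok].std() == 0:
            return float("nan")
        return float(np.corrcoef(pis[ok], y[ok])[0, 1])

    return {
        "r_full": _corr("mean_dwell"),
        "r_independent": _corr("mean_dwell_independent"),
        "table": table,
        "reliable": reliable,
    }
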