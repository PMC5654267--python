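"""Numba heat-bath (Gibbs) sampling kernels.

One Monte-Carlo "sample" throughout the package is one full sweep in which
all N cells are updated once, in a fresh random order per sweep.  Each
single-site update draws cell i spiking with the heat-bath probability

    x_i = 1 / (1 + exp(dE_i / T)),    dE_i = E(r_i = 1) - E(r_i = 0),

which leaves P(R) proportional to exp(-E(R)/T) invariant.  The effective
field dE_i = h_i + 2 sum_j J_ij r_j + (lambda_{K'+1} - lambda_{K'}) (K' the
spike count of the other cells) is read from an incrementally maintained
pair-field cache, so a sweep costs O(N) plus O(N) per actual flip instead
of O(N^2).  Energies are likewise tracked incrementally and re-synced at
every kernel entry.

All kernels seed numba's internal RNG explicitly and are deterministic
given (inputs, seed).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "gibbs_thermo",
    "gibbs_moments",
    "gibbs_state_counts",
    "gibbs_sample_states",
    "dwell_times",
]


@njit(cache=True)
def _init_chain(J, r, s):
    """Fill the pair-field cache s_i = sum_j J_ij r_j; return spike count."""
    n = r.shape[0]
    k = 0
    for i in range(n):
        s[i] = 0.0
    for j in range(n):
        if r[j]:
            k += 1
            for i in range(n):
                s[i] += J[i, j]
    return k


@njit(cache=True)
def _chain_energy(h, lam, r, s, k):
    e = lam[k]
    for i in range(r.shape[0]):
        if r[i]:
            e += h[i] + s[i]
    return e


@njit(cache=True)
def _sweep(h, J, lam, tinv, r, s, k, e):
    """One full random-order heat-bath sweep; returns updated (k, e)."""
    n = r.shape[0]
    order = np.random.permutation(n)
    for t in range(n):
        i = order[t]
        kp = k - r[i]
        de = h[i] + 2.0 * s[i] + lam[kp + 1] - lam[kp]
        p = 1.0 / (1.0 + np.exp(de * tinv))
        new = 1 if np.random.random() < p else 0
        if new != r[i]:
            r[i] = new
            if new == 1:
                e += de
                k += 1
                for j in range(n):
                    s[j] += J[j, i]
            else:
                e -= de
                k -= 1
                for j in range(n):
                    s[j] -= J[j, i]
    return k, e


@njit(cache=True)
def gibbs_thermo(h, J, lam, temperature, states, n_burn, n_keep, seed):
    """Energy statistics from parallel chains at one temperature.

    ``states`` (n_chains, N, uint8) is advanced in place, so successive
    calls at decreasing temperatures implement the annealing protocol of
    carrying chain state across levels.  Returns per-chain sums of E, E^2
    and total spike count over the ``n_keep`` retained sweeps.
    """
    np.random.seed(seed)
    n_chains, n = states.shape
    tinv = 1.0 / temperature
    sum_e = np.zeros(n_chains)
    sum_e2 = np.zeros(n_chains)
    sum_k = np.zeros(n_chains)
    s = np.zeros(n)
    for c in range(n_chains):
        r = states[c]
        k = _init_chain(J, r, s)
        e = _chain_energy(h, lam, r, s, k)
        for _ in range(n_burn):
            k, e = _sweep(h, J, lam, tinv, r, s, k, e)
        for _ in range(n_keep):
            k, e = _sweep(h, J, lam, tinv, r, s, k, e)
            sum_e[c] += e
            sum_e2[c] += e * e
            sum_k[c] += k
    return sum_e, sum_e2, sum_k


@njit(cache=True)
def gibbs_moments(h, J, lam, temperature, states, n_burn, n_keep, seed):
    """Moment accumulation from parallel chains at one temperature.

    Returns per-chain sums of r_i, r_i r_j (full symmetric matrix), the
    spike-count histogram, and energy sums.  Pair sums are accumulated over
    the active cells only, so sparse states cost O(K^2) per sweep.
    """
    np.random.seed(seed)
    n_chains, n = states.shape
    tinv = 1.0 / temperature
    sum_r = np.zeros((n_chains, n))
    sum_rr = np.zeros((n_chains, n, n))
    k_hist = np.zeros((n_chains, n + 1))
    sum_e = np.zeros(n_chains)
    sum_e2 = np.zeros(n_chains)
    s = np.zeros(n)
    active = np.empty(n, dtype=np.int64)
    for c in range(n_chains):
        r = states[c]
        k = _init_chain(J, r, s)
        e = _chain_energy(h, lam, r, s, k)
        for _ in range(n_burn):
            k, e = _sweep(h, J, lam, tinv, r, s, k, e)
        for _ in range(n_keep):
            k, e = _sweep(h, J, lam, tinv, r, s, k, e)
            sum_e[c] += e
            sum_e2[c] += e * e
            k_hist[c, k] += 1.0
            na = 0
            for i in range(n):
                if r[i]:
                    active[na] = i
                    na += 1
            for a in range(na):
                ia = active[a]
                sum_r[c, ia] += 1.0
                sum_rr[c, ia, ia] += 1.0
                for b in range(a + 1, na):
                    ib = active[b]
                    sum_rr[c, ia, ib] += 1.0
                    sum_rr[c, ib, ia] += 1.0
    return sum_r, sum_rr, k_hist, sum_e, sum_e2


@njit(cache=True)
def gibbs_state_counts(h, J, lam, temperature, state, n_burn, n_keep, seed):
    """Visit counts over all 2^N states from a single chain (N <= 20)."""
    np.random.seed(seed)
    n = state.shape[0]
    tinv = 1.0 / temperature
    counts = np.zeros(2**n, dtype=np.int64)
    s = np.zeros(n)
    k = _init_chain(J, state, s)
    e = _chain_energy(h, lam, state, s, k)
    for _ in range(n_burn):
        k, e = _sweep(h, J, lam, tinv, state, s, k, e)
    for _ in range(n_keep):
        k, e = _sweep(h, J, lam, tinv, state, s, k, e)
        idx = 0
        for i in range(n):
            if state[i]:
                idx += 1 << i
        counts[idx] += 1
    return counts


@njit(cache=True)
def gibbs_sample_states(h, J, lam, temperature, state, n_burn, thin, n_samples, seed):
    """Record ``n_samples`` states from one chain, one every ``thin`` sweeps."""
    np.random.seed(seed)
    n = state.shape[0]
    tinv = 1.0 / temperature
    out = np.empty((n_samples, n), dtype=np.uint8)
    s = np.zeros(n)
    k = _init_chain(J, state, s)
    e = _chain_energy(h, lam, state, s, k)
    for _ in range(n_burn):
        k, e = _sweep(h, J, lam, tinv, state, s, k, e)
    for m in range(n_samples):
        for _ in range(thin):
            k, e = _sweep(h, J, lam, tinv, state, s, k, e)
        for i in range(n):
            out[m, i] = state[i]
    return out


@njit(cache=True)
def dwell_times(h, J, lam, temperature, r0, silent_target, max_sweeps, n_runs, seed):
    """Sweeps until >= silent_target of the initially spiking cells are silent.

    The condition is checked on the current state after each full sweep;
    originally spiking cells that re-activate count as active again.  Runs
    that reach ``max_sweeps`` without satisfying the condition are censored
    (flag 1 in the second return array, dwell recorded as max_sweeps).
    """
    np.random.seed(seed)
    n = r0.shape[0]
    tinv = 1.0 / temperature
    n_orig = 0
    orig = np.empty(n, dtype=np.int64)
    for i in range(n):
        if r0[i]:
            orig[n_orig] = i
            n_orig += 1
    dwell = np.empty(n_runs, dtype=np.int64)
    censored = np.zeros(n_runs, dtype=np.uint8)
    r = np.empty(n, dtype=np.uint8)
    s = np.zeros(n)
    for run in range(n_runs):
        for i in range(n):
            r[i] = r0[i]
        k = _init_chain(J, r, s)
        e = _chain_energy(h, lam, r, s, k)
        t = 0
        done = False
        while t < max_sweeps:
            k, e = _sweep(h, J, lam, tinv, r, s, k, e)
            t += 1
            n_silent = 0
            for a in range(n_orig):
                if r[orig[a]] == 0:
                    n_silent += 1
            if n_silent >= silent_target:
                done = True
                break
        dwell[run] = t
        if not done:
            censored[run] = 1
    return dwell, censored
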