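"""Linear-nonlinear (LN) neurons fitted by reverse correlation.

The LN cascade is the classical receptive-field description of a sensory
neuron: a linear spatiotemporal filter applied to the stimulus history
produces a generator signal ``q``, and a static nonlinearity maps ``q`` to
a spike probability per bin.  Here the filter is estimated as the
spike-triggered average (STA) of a binary checkerboard stimulus, and the
nonlinearity by Bayes' rule, ``P(spike | q) = P(q | spike) P(spike) / P(q)``,
evaluated empirically on equal-occupancy bins of ``q``.

A population of such model neurons driven by a *common* stimulus inherits
correlations only through receptive-field overlap.  Simulating the fitted
LN population on a novel stimulus (with each nonlinearity shifted
horizontally so the model's firing rate matches its target) therefore
provides a comparison network: whatever correlation — and downstream
specific-heat structure — the LN network fails to reproduce must come
from processing beyond the classical receptive field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seeds import child_seed
from .raster import SpikeRaster
from .synthetic import Stimulus

__all__ = [
    "LNNonlinearity",
    "LNNeuron",
    "align_frames",
    "compute_sta",
    "estimate_nonlinearity",
    "linear_response",
    "fit_ln_neuron",
    "simulate_ln_population",
    "save_ln_neurons",
    "load_ln_neurons",
]


@dataclass
class LNNonlinearity:
    """Binned lookup q -> spike probability per bin.

    ``edges`` are the n_bins - 1 interior bin edges (strictly increasing,
    from equal-occupancy quantiles of the training q); ``values`` the
    per-bin spike probabilities in [0, 1].
    """

    edges: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.edges.size and (np.diff(self.edges) <= 0).any():
            raise ValueError("bin edges must be strictly increasing")
        if ((self.values < 0) | (self.values > 1)).any():
            raise ValueError("nonlinearity values must be probabilities")

    def __call__(self, q: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.edges, np.asarray(q, dtype=float), side="right")
        return self.values[idx]


@dataclass
class LNNeuron:
    """Spatiotemporal filter + static nonlinearity (+ rate-matching shift)."""

    filter: np.ndarray  # (n_lags, n_y, n_x, n_colors)
    nonlinearity: LNNonlinearity
    rate_offset: float = 0.0

    @property
    def n_lags(self) -> int:
        return self.filter.shape[0]


# ---------------------------------------------------------------------------
# alignment and reverse correlation
# ---------------------------------------------------------------------------


def align_frames(stimulus: Stimulus, raster: SpikeRaster) -> np.ndarray:
    """Stimulus frames resampled to the raster's bins (nearest frame).

    When frame count equals bin count the frames are used as-is; otherwise
    each bin takes the frame nearest its centre given the stimulus frame
    rate and the raster bin width.
    """
    n_bins = raster.n_bins
    if stimulus.n_frames == n_bins:
        return stimulus.frames
    centers_s = (np.arange(n_bins) + 0.5) * raster.bin_width / 1000.0
    idx = np.clip(np.round(centers_s * stimulus.frame_rate - 0.5).astype(int),
                  0, stimulus.n_frames - 1)
    return stimulus.frames[idx]


def compute_sta(
    stimulus: Stimulus, raster: SpikeRaster, cell: int, n_lags: int = 15
) -> np.ndarray:
    """Spike-triggered average of the preceding ``n_lags`` frames.

    Lag 0 is the frame in the spike's own bin.  The stimulus mean is
    subtracted, so a stimulus-independent spike train gives a filter near
    zero.  Cells with no spikes are rejected; fewer than ~100 spikes gives
    a noisy estimate (warning).
    """
    frames = align_frames(stimulus, raster).astype(np.float64)
    frames = frames - frames.mean(axis=0, keepdims=True)
    spikes = np.nonzero(raster.values[cell])[0]
    spikes = spikes[spikes >= n_lags - 1]
    if spikes.size == 0:
        raise ValueError(f"cell {cell} has no usable spikes")
    if spikes.size < 100:
        import warnings

        warnings.warn(f"cell {cell}: only {spikes.size} spikes; STA will be noisy",
                      stacklevel=2)
    sta = np.empty((n_lags,) + frames.shape[1:])
    for lag in range(n_lags):
        sta[lag] = frames[spikes - lag].mean(axis=0)
    return sta


def estimate_nonlinearity(
    q_values: np.ndarray, spikes: np.ndarray, n_bins: int = 25
) -> LNNonlinearity:
    """Empirical P(spike | q) on equal-occupancy bins of q.

    Binning by quantiles guarantees every bin is populated; the per-bin
    spike fraction is identically the Bayes-rule ratio
    P(q|spike) P(spike) / P(q) evaluated on those bins.
    """
    q = np.asarray(q_values, dtype=float)
    s = np.asarray(spikes, dtype=float)
    if q.shape != s.shape:
        raise ValueError("q and spike vectors must align")
    if n_bins < 1:
        raise ValueError("need at least one bin")
    edges = np.quantile(q, np.linspace(0, 1, n_bins + 1)[1:-1])
    edges = np.unique(edges)  # ties (e.g. discrete q) merge bins
    idx = np.searchsorted(edges, q, side="right")
    values = np.array([s[idx == b].mean() if (idx == b).any() else 0.0
                       for b in range(edges.size + 1)])
    return LNNonlinearity(edges, values)


def linear_response(neuron_filter: np.ndarray, frames: np.ndarray) -> np.ndarray:
    """Generator signal q_t = sum_lag filter[lag] . frames[t - lag].

    ``frames`` should be mean-subtracted; early bins use the available
    (truncated) history.
    """
    n_lags = neuron_filter.shape[0]
    n_frames = frames.shape[0]
    flat_frames = frames.reshape(n_frames, -1)
    flat_filter = neuron_filter.reshape(n_lags, -1)
    q = np.zeros(n_frames)
    for lag in range(n_lags):
        q[lag:] += flat_frames[: n_frames - lag] @ flat_filter[lag]
    return q


def fit_ln_neuron(
    stimulus: Stimulus, raster: SpikeRaster, cell: int,
    n_lags: int = 15, n_bins: int = 25,
) -> LNNeuron:
    """Reverse-correlation fit: STA filter + Bayes-rule nonlinearity."""
    sta = compute_sta(stimulus, raster, cell, n_lags)
    frames = align_frames(stimulus, raster).astype(np.float64)
    frames = frames - frames.mean(axis=0, keepdims=True)
    q = linear_response(sta, frames)
    nl = estimate_nonlinearity(q, raster.values[cell], n_bins)
    return LNNeuron(sta, nl)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def _solve_rate_offset(nl: LNNonlinearity, q: np.ndarray, target: float,
                       tol: float = 0.01) -> float:
    """Horizontal shift of the nonlinearity matching the expected rate.

    Solves mean(nl(q - offset)) = target by bisection on the (monotone, up
    to lookup granularity) offset-rate curve; rejects targets outside the
    attainable range.
    """
    span = (q.max() - q.min()) + 2 * (np.abs(nl.edges).max() if nl.edges.size else 1.0) + 1.0

    def realised(offset: float) -> float:
        return float(nl(q - offset).mean())

    lo, hi = -span, span
    r_lo, r_hi = realised(lo), realised(hi)
    r_min, r_max = min(r_lo, r_hi), max(r_lo, r_hi)
    if not (r_min <= target <= r_max):
        raise ValueError(
            f"target rate {target:.4g} unattainable (range [{r_min:.4g}, {r_max:.4g}])")
    increasing = r_hi > r_lo
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        r = realised(mid)
        if abs(r - target) <= tol * max(target, 1e-12):
            return mid
        if (r > target) == increasing:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def simulate_ln_population(
    neurons: list[LNNeuron],
    stimulus: Stimulus,
    rate_targets: np.ndarray,
    seed: int = 0,
    bin_width: float = 20.0,
) -> SpikeRaster:
    """Drive fitted LN neurons with a (novel) stimulus; Bernoulli spikes.

    Each neuron's nonlinearity is shifted horizontally (bisection on the
    offset) so its expected rate matches the target within 1%; the fitted
    ``rate_offset`` is stored back on the neuron.  Correlations in the
    output arise only from receptive-field overlap on the shared
    stimulus.
    """
    frames = stimulus.frames.astype(np.float64)
    frames = frames - frames.mean(axis=0, keepdims=True)
    rate_targets = np.broadcast_to(np.asarray(rate_targets, dtype=float),
                                   (len(neurons),))
    values = np.empty((len(neurons), stimulus.n_frames), dtype=np.uint8)
    for c, neuron in enumerate(neurons):
        q = linear_response(neuron.filter, frames)
        offset = _solve_rate_offset(neuron.nonlinearity, q, rate_targets[c])
        neuron.rate_offset = offset
        p = neuron.nonlinearity(q - offset)
        rng = np.random.default_rng(child_seed(seed, f"ln-sim-{c}"))
        values[c] = (rng.random(q.shape[0]) < p).astype(np.uint8)
    return SpikeRaster(values, bin_width, condition_label="LN simulation")


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------


def save_ln_neurons(neurons: list[LNNeuron], path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        for c, nrn in enumerate(neurons):
            g = f.create_group(f"neuron_{c}")
            g.create_dataset("filter", data=nrn.filter)
            g.create_dataset("edges", data=nrn.nonlinearity.edges)
            g.create_dataset("values", data=nrn.nonlinearity.values)
            g.attrs["rate_offset"] = nrn.rate_offset


def load_ln_neurons(path) -> list[LNNeuron]:
    import h5py

    neurons = []
    with h5py.File(path, "r") as f:
        for name in sorted(f, key=lambda s: int(s.split("_")[1])):
            g = f[name]
            neurons.append(LNNeuron(
                g["filter"][...],
                LNNonlinearity(g["edges"][...], g["values"][...]),
                float(g.attrs["rate_offset"]),
            ))
    return neurons
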