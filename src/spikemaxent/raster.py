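"""Binary spike rasters, population statistics, and shuffle controls.

The analyses in this package start from a binary raster: each cell's spike
train is divided into fixed-width time bins (20 ms by default throughout)
and a bin is 1 if the cell fired at least once in it, 0 otherwise. From the
raster we estimate the statistics that the maximum-entropy models are
constrained to match — per-cell firing probabilities ``m_i = <r_i>``,
pairwise second moments ``<r_i r_j>`` (equivalently Pearson correlation
coefficients ``C_ij`` of the binary variables), and the spike-count
distribution ``P(K)`` where ``K`` is the number of cells active in one bin.

Two controls live here as well.  A *grand shuffle* rotates each cell's
spike train circularly by an independent random offset, destroying
correlations at all orders while preserving every cell's spike count
exactly.  The *shuffled autocorrelation* of a trial-structured recording
(coincidences between different trials of the same stimulus, normalised by
the per-bin spike probability) measures how reproducibly a cell fires at
the same stimulus times, and a cross-condition reproducibility index
summarises how much of that reproducible firing survives a change in
recording condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpikeTimes",
    "SpikeRaster",
    "PopulationMoments",
    "ZScoreReport",
    "CorrelogramCurve",
    "binarize",
    "compute_moments",
    "bootstrap_errors",
    "correlation_zscores",
    "shuffle_raster",
    "shuffled_autocorrelation",
    "cross_trial_correlogram",
    "reproducibility_index",
    "read_spike_times",
    "write_raster_txt",
    "read_raster_txt",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class SpikeTimes:
    """Spike events as ``(cell_id, time)`` pairs.

    Parameters
    ----------
    events
        Array of shape ``(n_events, 2)``; column 0 is the integer cell id,
        column 1 the spike time in seconds.
    n_cells
        Number of cells in the population (ids run ``0 .. n_cells-1``).
    duration
        Recording length in seconds; all times must satisfy
        ``0 <= t < duration``.
    """

    events: np.ndarray
    n_cells: int
    duration: float

    def __post_init__(self) -> None:
        ev = np.asarray(self.events, dtype=float).reshape(-1, 2)
        self.events = ev
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if ev.size:
            if ev[:, 1].min() < 0:
                raise ValueError("negative spike times are not allowed")
            if ev[:, 1].max() >= self.duration:
                raise ValueError("spike times must be < duration")
            cid = ev[:, 0]
            if cid.min() < 0 or cid.max() >= self.n_cells:
                raise ValueError("cell ids must lie in [0, n_cells)")


@dataclass
class SpikeRaster:
    """Binary activity matrix, cells x time bins.

    ``values[i, t]`` is 1 iff cell ``i`` spiked at least once in bin ``t``.
    ``trial_bounds`` optionally marks repeated-trial structure as a list of
    half-open ``(start_bin, end_bin)`` intervals, ordered and
    non-overlapping.
    """

    values: np.ndarray
    bin_width: float  # ms
    trial_bounds: list[tuple[int, int]] | None = None
    condition_label: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError("raster values must be a 2-D matrix")
        if not np.isin(v, (0, 1)).all():
            raise ValueError("raster entries must be 0 or 1")
        self.values = v.astype(np.uint8)
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.trial_bounds is not None:
            tb = [(int(a), int(b)) for a, b in self.trial_bounds]
            prev = 0
            for a, b in tb:
                if a < prev or b <= a or b > self.n_bins:
                    raise ValueError("trial_bounds must be ordered, non-overlapping, in range")
                prev = b
            self.trial_bounds = tb

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def trial_stack(self) -> np.ndarray:
        """Return trials as an array ``(n_trials, n_cells, trial_len)``.

        Requires trial_bounds with equal-length trials.
        """
        if not self.trial_bounds or len(self.trial_bounds) < 2:
            raise ValueError("raster has no (or fewer than 2) trials")
        lengths = {b - a for a, b in self.trial_bounds}
        if len(lengths) != 1:
            raise ValueError("trials must have equal length")
        return np.stack([self.values[:, a:b] for a, b in self.trial_bounds])

    def subset(self, cells: Sequence[int]) -> "SpikeRaster":
        return SpikeRaster(
            self.values[np.asarray(cells, dtype=int)],
            self.bin_width,
            trial_bounds=self.trial_bounds,
            condition_label=self.condition_label,
        )


@dataclass
class PopulationMoments:
    """Empirical statistics of a binary population.

    ``correlations`` holds Pearson coefficients of the binary variables;
    entries involving a zero-variance cell are NaN (undefined).  Error
    arrays (``rate_se`` etc.) are filled by :func:`bootstrap_errors` and are
    ``None`` until then.
    """

    rates: np.ndarray
    second_moments: np.ndarray
    correlations: np.ndarray
    pk: np.ndarray
    n_samples: int
    rate_se: np.ndarray | None = None
    corr_se: np.ndarray | None = None
    pk_se: np.ndarray | None = None
    provenance: str = "data"

    @property
    def n_cells(self) -> int:
        return self.rates.shape[0]

    def validate(self, atol: float = 1e-9) -> None:
        """Check internal consistency (normalisation, moment bounds)."""
        if abs(self.pk.sum() - 1.0) > atol:
            raise ValueError("P(K) does not sum to 1")
        m = self.rates
        q = self.second_moments
        if not np.allclose(np.diag(q), m, atol=1e-12):
            raise ValueError("diagonal of second moments must equal rates")
        upper = np.minimum.outer(m, m) + 1e-12
        if (q > upper).any():
            raise ValueError("second moments exceed min(m_i, m_j)")
        lower = np.maximum(0.0, np.add.outer(m, m) - 1.0) - 1e-12
        if (q < lower).any():
            raise ValueError("second moments below Frechet lower bound")


@dataclass
class ZScoreReport:
    """Per-pair z-scores for a change in correlation between two datasets."""

    z: np.ndarray  # full symmetric matrix, NaN where undefined
    n_infinite: int = 0

    @property
    def values(self) -> np.ndarray:
        """Finite z-scores from the upper triangle, as a flat array."""
        iu = np.triu_indices_from(self.z, k=1)
        v = self.z[iu]
        return v[np.isfinite(v)]

    def histogram(self, bins: int = 41, range_: tuple[float, float] = (-10, 10)):
        return np.histogram(self.values, bins=bins, range=range_, density=True)


@dataclass
class CorrelogramCurve:
    """Normalised coincidence rate vs time lag; 1.0 is the chance level."""

    lags: np.ndarray  # ms, symmetric grid
    values: np.ndarray
    baseline: float = 1.0

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.lags.shape != self.values.shape:
            raise ValueError("lags and values must have the same shape")

    def excess_area(self) -> float:
        """Integral of (value - baseline) over the lag axis (ms units)."""
        return float(np.trapezoid(self.values - self.baseline, self.lags))

    def to_csv(self, path) -> None:
        pd.DataFrame({"lag_ms": self.lags, "value": self.values}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# raster construction and statistics
# ---------------------------------------------------------------------------


def binarize(spikes: SpikeTimes, bin_width: float = 20.0) -> SpikeRaster:
    """Bin spike times into a binary raster.

    A bin is 1 iff at least one spike of that cell falls in the half-open
    window ``[t*w, (t+1)*w)``; multiple spikes in one bin collapse to a
    single 1.  ``bin_width`` is in milliseconds, spike times in seconds.
    Spikes at or beyond the last full bin are dropped.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    w = bin_width / 1000.0  # seconds
    n_bins = int(np.floor(spikes.duration / w))
    if n_bins < 1:
        raise ValueError("duration shorter than one bin")
    values = np.zeros((spikes.n_cells, n_bins), dtype=np.uint8)
    if spikes.events.size:
        cells = spikes.events[:, 0].astype(int)
        bins = np.floor(spikes.events[:, 1] / w).astype(int)
        keep = bins < n_bins
        values[cells[keep], bins[keep]] = 1
    return SpikeRaster(values, bin_width)


def compute_moments(raster: SpikeRaster, provenance: str = "data") -> PopulationMoments:
    """Estimate rates, second moments, correlations and P(K) from a raster.

    Correlations involving a constant (zero-variance) cell are NaN.
    """
    v = raster.values
    n_cells, n_bins = v.shape
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    x = v.astype(np.float64)
    m = x.mean(axis=1)
    q = (x @ x.T) / n_bins
    np.fill_diagonal(q, m)
    var = m * (1.0 - m)
    sd = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = q - np.outer(m, m)
        corr = cov / np.outer(sd, sd)
    corr[~np.isfinite(corr)] = np.nan
    np.fill_diagonal(corr, np.where(var > 0, 1.0, np.nan))
    k = x.sum(axis=0).astype(int)
    pk = np.bincount(k, minlength=n_cells + 1).astype(float) / n_bins
    return PopulationMoments(
        rates=m,
        second_moments=q,
        correlations=corr,
        pk=pk,
        n_samples=n_bins,
        provenance=provenance,
    )


def bootstrap_errors(
    raster: SpikeRaster,
    n_boot: int = 200,
    seed: int = 0,
    resample: str = "bins",
) -> PopulationMoments:
    """Moments with bootstrap standard errors attached.

    Resamples time bins with replacement (``resample="bins"``, the default,
    matching how the model-fitting pipeline treats bins as samples) or
    whole trials (``resample="trials"``, for trial-based statistics), and
    reports the standard deviation of each statistic over the resamples.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives noisy error estimates", stacklevel=2)
    base = compute_moments(raster)
    rng = np.random.default_rng(seed)
    n_bins = raster.n_bins
    rates_b = np.empty((n_boot, raster.n_cells))
    corr_b = np.empty((n_boot, raster.n_cells, raster.n_cells))
    pk_b = np.empty((n_boot, raster.n_cells + 1))
    for b in range(n_boot):
        if resample == "bins":
            idx = rng.integers(0, n_bins, size=n_bins)
        elif resample == "trials":
            if not raster.trial_bounds:
                raise ValueError("trial resampling requires trial_bounds")
            picks = rng.integers(0, len(raster.trial_bounds), size=len(raster.trial_bounds))
            idx = np.concatenate(
                [np.arange(*raster.trial_bounds[p]) for p in picks]
            )
        else:
            raise ValueError(f"unknown resample mode {resample!r}")
        mom = compute_moments(SpikeRaster(raster.values[:, idx], raster.bin_width))
        rates_b[b] = mom.rates
        corr_b[b] = mom.correlations
        pk_b[b] = mom.pk
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        base.rate_se = rates_b.std(axis=0, ddof=1)
        base.corr_se = np.nanstd(corr_b, axis=0, ddof=1)
        base.pk_se = pk_b.std(axis=0, ddof=1)
    return base


def correlation_zscores(a: PopulationMoments, b: PopulationMoments) -> ZScoreReport:
    """z-score of the correlation change between two datasets, per pair.

    ``z_ij = (C_a,ij - C_b,ij) / sqrt(sigma_a,ij^2 + sigma_b,ij^2)``.
    Pairs where both errors are zero get z = 0 if the correlations agree
    and +/-inf (counted in ``n_infinite``) otherwise; pairs involving a
    zero-variance cell are NaN.
    """
    if a.n_cells != b.n_cells:
        raise ValueError("populations must have the same size")
    if a.corr_se is None or b.corr_se is None:
        raise ValueError("both inputs need bootstrap errors (corr_se)")
    diff = a.correlations - b.correlations
    sig = np.sqrt(a.corr_se**2 + b.corr_se**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = diff / sig
    zero_sig = (sig == 0) & np.isfinite(diff)
    z[zero_sig & (diff == 0)] = 0.0
    inf_mask = zero_sig & (diff != 0)
    z[inf_mask] = np.sign(diff[inf_mask]) * np.inf
    iu = np.triu_indices_from(z, k=1)
    return ZScoreReport(z=z, n_infinite=int(np.isinf(z[iu]).sum()))


def shuffle_raster(raster: SpikeRaster, seed: int = 0) -> SpikeRaster:
    """Grand shuffle: circularly rotate each cell's train independently.

    Each row is rotated by a uniform random offset in ``[0, n_bins)`` with
    periodic wrap-around, which preserves every per-cell spike count (and
    hence rate) exactly while destroying correlations between cells at all
    orders.
    """
    if raster.n_bins < 2:
        raise ValueError("need at least 2 bins to shuffle")
    rng = np.random.default_rng(seed)
    shifts = rng.integers(0, raster.n_bins, size=raster.n_cells)
    out = np.empty_like(raster.values)
    for i, s in enumerate(shifts):
        out[i] = np.roll(raster.values[i], int(s))
    return SpikeRaster(out, raster.bin_width, condition_label=raster.condition_label)


# ---------------------------------------------------------------------------
# trial-based reliability
# ---------------------------------------------------------------------------


def cross_trial_correlogram(
    raster_a: SpikeRaster,
    raster_b: SpikeRaster,
    cell: int,
    max_lag: float,
) -> CorrelogramCurve:
    """Coincidence rate between trials of two recordings, vs lag.

    At lag ``l`` (in bins) the raw statistic is the average of
    ``r_a[trial u, t] * r_b[trial v, t+l]`` over all trial pairs with
    ``u != v`` when the two rasters are the same object (the *shuffled*
    autocorrelation, which excludes same-trial coincidences) or all
    ``(u, v)`` pairs otherwise (the cross-condition correlogram).  The
    result is normalised by the product of the two mean spike
    probabilities, so that independent stationary trains give 1 at all
    lags.
    """
    same = raster_a is raster_b
    stack_a = raster_a.trial_stack()[:, cell, :].astype(np.float64)
    stack_b = raster_b.trial_stack()[:, cell, :].astype(np.float64)
    if stack_a.shape[1] != stack_b.shape[1]:
        raise ValueError("trial lengths must match across conditions")
    p_a = stack_a.mean()
    p_b = stack_b.mean()
    if p_a == 0 or p_b == 0:
        raise ValueError(f"cell {cell} is silent; correlogram undefined")
    bw = raster_a.bin_width
    max_lag_bins = int(round(max_lag / bw))
    trial_len = stack_a.shape[1]
    max_lag_bins = min(max_lag_bins, trial_len - 1)
    lags = np.arange(-max_lag_bins, max_lag_bins + 1)
    # sum over trial pairs via totals: sum_{u,v} a_u b_v = (sum a)(sum b);
    # subtract the diagonal for the same-recording case
    tot_a = stack_a.sum(axis=0)
    tot_b = stack_b.sum(axis=0)
    n_a, n_b = stack_a.shape[0], stack_b.shape[0]
    vals = np.empty(lags.shape[0])
    for k, l in enumerate(lags):
        if l >= 0:
            x, y = tot_a[: trial_len - l], tot_b[l:]
            d = (stack_a[:, : trial_len - l] * stack_b[:, l:]).sum() if same else 0.0
        else:
            x, y = tot_a[-l:], tot_b[: trial_len + l]
            d = (stack_a[:, -l:] * stack_b[:, : trial_len + l]).sum() if same else 0.0
        pair_sum = float(x @ y) - d
        n_pairs = n_a * n_b - (n_a if same else 0)
        n_t = trial_len - abs(l)
        vals[k] = pair_sum / (n_pairs * n_t) / (p_a * p_b)
    return CorrelogramCurve(lags * bw, vals)


def shuffled_autocorrelation(
    raster: SpikeRaster, cell: int, max_lag: float
) -> CorrelogramCurve:
    """Autocorrelation across (not within) trials, normalised to 1 at chance.

    Requires at least two equal-length trials and a non-silent cell; the
    lag grid uses the raster's own bin width.
    """
    return cross_trial_correlogram(raster, raster, cell, max_lag)


def reproducibility_index(
    auto_a: CorrelogramCurve,
    auto_b: CorrelogramCurve,
    cross_ab: CorrelogramCurve,
) -> float:
    """Cross-condition spike-timing reproducibility in [0, ~1].

    The area of each correlogram above the chance level 1 measures
    within-condition reproducibility; the cross-condition excess area,
    normalised by the geometric mean of the two within-condition areas,
    measures how much of that reproducible firing is shared between
    conditions.  1 means firing is as reproducible across conditions as
    within each; 0 means no shared structure.  NaN (with a warning) if a
    within-condition area is non-positive.
    """
    if not (np.array_equal(auto_a.lags, auto_b.lags) and np.array_equal(auto_a.lags, cross_ab.lags)):
        raise ValueError("correlograms must share one lag grid")
    area_a = auto_a.excess_area()
    area_b = auto_b.excess_area()
    if area_a <= 0 or area_b <= 0:
        warnings.warn("non-positive within-condition area; index undefined", stacklevel=2)
        return float("nan")
    return max(0.0, cross_ab.excess_area() / np.sqrt(area_a * area_b))


# ---------------------------------------------------------------------------
# plain-text I/O
# ---------------------------------------------------------------------------


def read_spike_times(path, n_cells: int | None = None, duration: float | None = None) -> SpikeTimes:
    """Read spike events from two-column delimited text (cell_id, time_s)."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#", header=None, skip_blank_lines=True)
    if df.shape[1] < 2:
        raise ValueError("expected two columns: cell_id and time in seconds")
    if isinstance(df.iloc[0, 0], str):  # header row
        df = df.iloc[1:]
    ev = df.iloc[:, :2].to_numpy(dtype=float)
    if n_cells is None:
        n_cells = int(ev[:, 0].max()) + 1 if ev.size else 0
    if duration is None:
        duration = float(np.nextafter(ev[:, 1].max(), np.inf)) if ev.size else 1.0
    return SpikeTimes(ev, n_cells=n_cells, duration=duration)


def write_raster_txt(raster: SpikeRaster, path) -> None:
    """Write a raster as a delimited 0/1 matrix (rows = cells).

    The bin width and any trial bounds go into comment lines so the file
    round-trips through :func:`read_raster_txt`.
    """
    with open(path, "w") as fh:
        fh.write(f"# bin_width_ms={raster.bin_width}\n")
        if raster.trial_bounds:
            tb = ";".join(f"{a},{b}" for a, b in raster.trial_bounds)
            fh.write(f"# trial_bounds={tb}\n")
        if raster.condition_label:
            fh.write(f"# condition={raster.condition_label}\n")
        np.savetxt(fh, raster.values, fmt="%d", delimiter="\t")


def read_raster_txt(path) -> SpikeRaster:
    bin_width = 20.0
    trial_bounds = None
    condition = None
    with open(path) as fh:
        lines = fh.readlines()
    rows = []
    for line in lines:
        if line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("bin_width_ms="):
                bin_width = float(body.split("=", 1)[1])
            elif body.startswith("trial_bounds="):
                trial_bounds = [
                    tuple(int(x) for x in part.split(","))
                    for part in body.split("=", 1)[1].split(";")
                ]
            elif body.startswith("condition="):
                condition = body.split("=", 1)[1]
        elif line.strip():
            rows.append([int(x) for x in line.split()])
    return SpikeRaster(np.asarray(rows, dtype=np.uint8), bin_width, trial_bounds, condition)
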