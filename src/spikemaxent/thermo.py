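"""Fictitious-temperature thermodynamics of fitted models.

A fictitious temperature T is introduced into the fitted distribution,
``P(R; T) = exp(-E(R)/T) / Z(T)``, and the specific heat

    C(T) = (<E^2> - <E>^2) / T^2

is traced over a temperature grid.  A peak in C(T) that grows and sharpens
with population size N, at a temperature above the operating point T = 1,
is the phase-transition signature this package is built to measure.  For
N <= 20 all quantities come from exact enumeration; for larger populations
they are estimated by an annealed Monte-Carlo protocol: parallel heat-bath
chains are initialised at the highest temperature and carried down the
grid, re-equilibrated briefly at each level, and the energy variance is
pooled across chains (the chain-to-chain spread gives the standard error).

The specific heat of an *independent* population has a closed form (each
cell is a two-state system), which serves both as the shuffle-control
reference curve and as an oracle for the Monte-Carlo machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _exact, _gibbs
from ._seeds import child_seed
from .maxent import MaxEntModel, fit_maxent
from .raster import SpikeRaster, compute_moments

__all__ = [
    "PartitionSummary",
    "ThermoCurve",
    "SubsampleScanResult",
    "energy",
    "exact_thermo",
    "annealed_specific_heat",
    "exact_specific_heat_curve",
    "independent_heat_analytic",
    "peak_statistics",
    "subsample_scan",
    "default_t_grid",
]


def default_t_grid(n_points: int = 40, t_high: float = 3.0, t_low: float = 0.5) -> np.ndarray:
    """Descending log-spaced temperature grid (annealing order)."""
    return np.geomspace(t_high, t_low, n_points)


@dataclass
class PartitionSummary:
    """Exact partition-function summary at one temperature."""

    temperature: float
    log_z: float
    mean_energy: float
    mean_energy_sq: float
    rates: np.ndarray

    @property
    def heat_capacity(self) -> float:
        return (self.mean_energy_sq - self.mean_energy**2) / self.temperature**2


@dataclass
class ThermoCurve:
    """C(T), <E>(T) and mean rate(T) over a (descending) temperature grid.

    ``c`` is per neuron when ``per_neuron`` is set; ``c_total`` always holds
    the unnormalised value.  ``t_max``/``c_at_t_max`` are filled by
    :func:`peak_statistics`.
    """

    temperatures: np.ndarray
    c: np.ndarray
    c_se: np.ndarray
    mean_energy: np.ndarray
    mean_rate: np.ndarray
    n_cells: int
    per_neuron: bool = True
    c_total: np.ndarray = field(default=None)  # type: ignore[assignment]
    t_max: float | None = None
    c_at_t_max: float | None = None
    peak_flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.c_total is None:
            self.c_total = self.c * self.n_cells if self.per_neuron else self.c.copy()
        if (np.asarray(self.c_se) < 0).any():
            raise ValueError("standard errors must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "T": self.temperatures,
            "C": self.c,
            "C_se": self.c_se,
            "mean_energy": self.mean_energy,
            "mean_rate": self.mean_rate,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class SubsampleScanResult:
    """Per-size, per-group thermodynamic curves from a subsampling scan."""

    sizes: list[int]
    groups: dict  # (size, group) -> list of cell indices
    curves: dict  # (size, group) -> ThermoCurve
    summary: pd.DataFrame  # per size: mean/SE of T_max and C(T_max)

    def to_csv(self, path) -> None:
        rows = []
        for (size, g), curve in self.curves.items():
            for t, c, se in zip(curve.temperatures, curve.c, curve.c_se):
                rows.append({"N": size, "group": g, "T": t, "C": c, "C_se": se})
        pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# energies and exact sums
# ---------------------------------------------------------------------------


def energy(model: MaxEntModel, state: np.ndarray) -> float:
    """E(R) = sum h_i r_i + sum_{i,j != i} J_ij r_i r_j + lambda_K.

    The pair sum runs over ordered pairs, so a symmetric pair contributes
    2 J_ij; the all-silent state has E = lambda_0 = 0 by the gauge choice.
    """
    return model.energy(state)


def exact_thermo(model: MaxEntModel, temperature: float) -> PartitionSummary:
    """Exact enumeration of Z, <E>, <E^2> and rates at one temperature (N <= 20)."""
    _exact.check_exact_size(model.n_cells)
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    logz, me, me2, rates = _exact.exact_thermo_sums(model.h, model.J, model.lam, temperature)
    return PartitionSummary(temperature, logz, me, me2, rates)


def exact_specific_heat_curve(
    model: MaxEntModel, t_grid: np.ndarray | None = None, per_neuron: bool = True
) -> ThermoCurve:
    """Exact C(T) over a grid; the zero-error oracle for the annealed curve."""
    t_grid = default_t_grid() if t_grid is None else np.asarray(t_grid, dtype=float)
    n = model.n_cells
    c = np.empty(t_grid.shape[0])
    me = np.empty_like(c)
    mr = np.empty_like(c)
    for i, t in enumerate(t_grid):
        ps = exact_thermo(model, t)
        c[i] = ps.heat_capacity
        me[i] = ps.mean_energy
        mr[i] = ps.rates.mean()
    scale = n if per_neuron else 1
    return ThermoCurve(t_grid, c / scale, np.zeros_like(c), me, mr, n_cells=n,
                       per_neuron=per_neuron, c_total=c)


# ---------------------------------------------------------------------------
# annealed Monte Carlo
# ---------------------------------------------------------------------------


def annealed_specific_heat(
    model: MaxEntModel,
    t_grid: np.ndarray | None = None,
    n_runs: int = 100,
    samples_per_run: int = 5000,
    n_burn: int = 50,
    seed: int = 0,
    per_neuron: bool = True,
) -> ThermoCurve:
    """Annealed Monte-Carlo estimate of C(T) over a descending grid.

    At each temperature level, ``n_runs`` parallel chains each contribute
    ``samples_per_run`` full sweeps after ``n_burn`` re-equilibration
    sweeps; chain states carry over from the preceding (higher) level.
    C is evaluated from the pooled energy variance; its standard error is
    the spread of per-chain C estimates over sqrt(n_runs).
    """
    t_grid = default_t_grid() if t_grid is None else np.asarray(t_grid, dtype=float)
    if t_grid.size < 1 or (np.diff(t_grid) >= 0).any():
        raise ValueError("t_grid must be strictly decreasing")
    if n_runs < 2:
        raise ValueError("need at least 2 runs for a standard error")
    n = model.n_cells
    rng = np.random.default_rng(child_seed(seed, "anneal-init"))
    states = (rng.random((n_runs, n)) < 0.5).astype(np.uint8)
    c = np.empty(t_grid.shape[0])
    c_se = np.empty_like(c)
    me = np.empty_like(c)
    mr = np.empty_like(c)
    nk = samples_per_run
    for lev, t in enumerate(t_grid):
        sum_e, sum_e2, sum_k = _gibbs.gibbs_thermo(
            model.h, model.J, model.lam, float(t), states, n_burn, nk,
            child_seed(seed, f"anneal-{lev}"),
        )
        mean_e = sum_e.sum() / (n_runs * nk)
        mean_e2 = sum_e2.sum() / (n_runs * nk)
        c[lev] = (mean_e2 - mean_e**2) / t**2
        per_run_c = (sum_e2 / nk - (sum_e / nk) ** 2) / t**2
        c_se[lev] = per_run_c.std(ddof=1) / np.sqrt(n_runs)
        me[lev] = mean_e
        mr[lev] = sum_k.sum() / (n_runs * nk * n)
    scale = n if per_neuron else 1
    return ThermoCurve(t_grid, c / scale, c_se / scale, me, mr, n_cells=n,
                       per_neuron=per_neuron, c_total=c)


def independent_heat_analytic(
    rates: np.ndarray, t_grid: np.ndarray | None = None, per_neuron: bool = True
) -> ThermoCurve:
    """Closed-form C(T) for an independent population with given rates.

    With h_i = ln((1-p_i)/p_i), each cell is a two-level system and

        C(T) = sum_i (h_i / T)^2 q_i (1 - q_i),  q_i = 1 / (1 + exp(h_i/T)).

    Cells with rate exactly 0 or 1 carry no energy fluctuations and are
    skipped with a warning.
    """
    t_grid = default_t_grid() if t_grid is None else np.asarray(t_grid, dtype=float)
    p = np.asarray(rates, dtype=float)
    bad = (p <= 0) | (p >= 1)
    if bad.any():
        warnings.warn(f"skipping {int(bad.sum())} cell(s) with rate 0 or 1", stacklevel=2)
    p_ok = p[~bad]
    h = np.log((1 - p_ok) / p_ok)
    ht = h[None, :] / t_grid[:, None]
    q = 1.0 / (1.0 + np.exp(ht))
    c = (ht**2 * q * (1 - q)).sum(axis=1)
    me = (h[None, :] * q).sum(axis=1)
    mr = q.mean(axis=1) if p_ok.size else np.zeros_like(t_grid)
    n = p.shape[0]
    scale = n if per_neuron else 1
    return ThermoCurve(t_grid, c / scale, np.zeros_like(c), me, mr, n_cells=n,
                       per_neuron=per_neuron, c_total=c)


# ---------------------------------------------------------------------------
# peaks and subsampling scans
# ---------------------------------------------------------------------------


def peak_statistics(curve: ThermoCurve, smooth: bool = True) -> tuple[float | None, float | None]:
    """Locate the specific-heat peak on the grid.

    Optionally smooths C with a 3-point moving average before taking the
    argmax (the reported C value is the unsmoothed one at that grid
    point).  Flags ``peak_at_boundary`` when the argmax is an endpoint and
    ``no_peak`` when the curve's range is within 2 SE of flat; results are
    also written back onto the curve.
    """
    if curve.temperatures.size < 5:
        raise ValueError("need at least 5 grid points")
    c = curve.c.astype(float)
    flags: list[str] = []
    rng_c = c.max() - c.min()
    se_scale = float(np.median(curve.c_se)) if np.any(curve.c_se > 0) else 0.0
    if rng_c < 2 * se_scale or rng_c == 0.0:
        flags.append("no_peak")
        curve.peak_flags = flags
        curve.t_max = None
        curve.c_at_t_max = None
        return None, None
    cs = c
    if smooth and c.size >= 3:
        cs = np.convolve(c, np.ones(3) / 3, mode="same")
        cs[0], cs[-1] = c[0], c[-1]
    idx = int(np.argmax(cs))
    if idx in (0, c.size - 1):
        flags.append("peak_at_boundary")
    curve.t_max = float(curve.temperatures[idx])
    curve.c_at_t_max = float(c[idx])
    curve.peak_flags = flags
    return curve.t_max, curve.c_at_t_max


def subsample_scan(
    raster: SpikeRaster,
    sizes,
    n_groups: int = 10,
    model_class: str = "k-pairwise",
    seed: int = 0,
    t_grid: np.ndarray | None = None,
    n_runs: int = 50,
    samples_per_run: int = 1000,
    n_groups_full: int = 3,
    fit_kwargs: dict | None = None,
) -> SubsampleScanResult:
    """Fit models to random cell subgroups of several sizes and anneal each.

    For each size N, ``n_groups`` random subsets of distinct cells are
    drawn (cells sampled without replacement within a group, independently
    across groups), a model of ``model_class`` is fitted to each subgroup's
    moments, and the per-neuron specific-heat curve is estimated.  The
    summary table reports the mean and SE of T_max and C(T_max) per size —
    the finite-size trend that diagnoses the phase transition.
    """
    sizes = [int(s) for s in sizes]
    if max(sizes) > raster.n_cells:
        raise ValueError("subgroup size exceeds number of cells")
    fit_kwargs = dict(fit_kwargs or {})
    curves: dict = {}
    groups: dict = {}
    rows = []
    for size in sizes:
        tmaxes, cmaxes = [], []
        # when a "subgroup" is the whole population every group holds the
        # same cells; a few independently seeded fits suffice there
        g_count = n_groups if size < raster.n_cells else min(n_groups, n_groups_full)
        for g in range(g_count):
            rng = np.random.default_rng(child_seed(seed, f"scan-{size}-{g}"))
            cells = np.sort(rng.choice(raster.n_cells, size=size, replace=False))
            groups[(size, g)] = cells.tolist()
            mom = compute_moments(raster.subset(cells))
            model, _ = fit_maxent(mom, model_class=model_class,
                                  seed=child_seed(seed, f"scan-fit-{size}-{g}"),
                                  **fit_kwargs)
            curve = annealed_specific_heat(
                model, t_grid=t_grid, n_runs=n_runs, samples_per_run=samples_per_run,
                seed=child_seed(seed, f"scan-anneal-{size}-{g}"),
            )
            peak_statistics(curve)
            curves[(size, g)] = curve
            if curve.t_max is not None:
                tmaxes.append(curve.t_max)
                cmaxes.append(curve.c_at_t_max)
        rows.append({
            "N": size,
            "t_max_mean": float(np.mean(tmaxes)) if tmaxes else np.nan,
            "t_max_se": float(np.std(tmaxes, ddof=1) / np.sqrt(len(tmaxes))) if len(tmaxes) > 1 else np.nan,
            "t_max_median": float(np.median(tmaxes)) if tmaxes else np.nan,
            "c_max_mean": float(np.mean(cmaxes)) if cmaxes else np.nan,
            "c_max_se": float(np.std(cmaxes, ddof=1) / np.sqrt(len(cmaxes))) if len(cmaxes) > 1 else np.nan,
            "c_max_median": float(np.median(cmaxes)) if cmaxes else np.nan,
            "n_groups": g_count,
        })
    return SubsampleScanResult(sizes, groups, curves, pd.DataFrame(rows))
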