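"""Correlation-matrix surgery: shuffled, top-L and alpha-mixed targets.

These manipulations alter the measured pairwise correlation matrix while
keeping every firing rate fixed, refit the (pairwise) maximum-entropy
model to the manipulated targets, and ask what happens to the specific
heat at the operating point T = 1:

* *shuffled* — correlations replaced by those of a grand-shuffled raster
  (retaining sampling noise rather than substituting analytic zeros);
* *top-L* — only each cell's L strongest correlations (by absolute value,
  symmetrised by union) are kept, the rest replaced by shuffled values;
* *alpha-mixed* — every coefficient interpolated,
  ``C_mixed = alpha * C_true + (1 - alpha) * C_shuff``, sweeping the
  population continuously from independent (alpha = 0) to fully
  correlated (alpha = 1).

Scanning C(T=1) against alpha for several population sizes N exposes the
transition: above a threshold alpha* an N-dependent contribution to the
specific heat appears, and :func:`estimate_alpha_star` brackets it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seeds import child_seed
from .maxent import fit_maxent
from .raster import PopulationMoments, SpikeRaster, compute_moments, shuffle_raster
from .thermo import annealed_specific_heat

__all__ = [
    "AlphaScanResult",
    "shuffled_moments",
    "topL_moments",
    "alpha_mixed_moments",
    "heat_vs_alpha",
    "estimate_alpha_star",
    "mc_heat_at_temperature",
]


@dataclass
class AlphaScanResult:
    """C(T = 1) per (alpha, N, group), plus group-averaged summaries."""

    alphas: np.ndarray
    sizes: list[int]
    table: pd.DataFrame  # columns: alpha, N, group, c_t1, c_t1_se, fit_converged

    def summary(self) -> pd.DataFrame:
        g = self.table.groupby(["alpha", "N"])["c_t1"]
        out = g.agg(["mean", "std", "count"]).reset_index()
        out["se"] = out["std"] / np.sqrt(out["count"])
        return out

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# manipulated moment targets
# ---------------------------------------------------------------------------


def shuffled_moments(raster: SpikeRaster, seed: int = 0) -> PopulationMoments:
    """Moments of one realised grand shuffle of the raster.

    Rates are bit-identical to the unshuffled raster's (circular rotation
    preserves counts); correlations retain finite-sample noise around
    zero, as an experimental shuffle control would.
    """
    mom = compute_moments(shuffle_raster(raster, seed), provenance="shuffled")
    return mom


def _rebuild_second_moments(rates: np.ndarray, corr: np.ndarray):
    """Second moments from correlations + rates, clipped to the feasible box.

    Returns (q, n_clipped) where pairs falling outside
    [max(0, m_i + m_j - 1), min(m_i, m_j)] were clipped to the boundary.
    """
    sd = np.sqrt(np.clip(rates * (1 - rates), 0, None))
    q = np.nan_to_num(corr) * np.outer(sd, sd) + np.outer(rates, rates)
    hi = np.minimum.outer(rates, rates)
    lo = np.maximum(0.0, np.add.outer(rates, rates) - 1.0)
    clipped = (q > hi) | (q < lo)
    np.fill_diagonal(clipped, False)
    q = np.clip(q, lo, hi)
    np.fill_diagonal(q, rates)
    iu = np.triu_indices_from(q, k=1)
    return q, int(clipped[iu].sum())


def _check_rates_match(a: PopulationMoments, b: PopulationMoments) -> None:
    if a.n_cells != b.n_cells or not np.array_equal(a.rates, b.rates):
        raise ValueError("manipulated targets require identical rates in both inputs")


def topL_moments(true_m: PopulationMoments, shuff_m: PopulationMoments, L: int) -> PopulationMoments:
    """Keep each cell's L strongest correlations; replace the rest.

    Pair (i, j) keeps its true correlation iff j is among cell i's top L
    partners by |C|, or i among j's (union symmetrisation); every other
    pair takes the shuffled value.  Rates are unchanged.
    """
    _check_rates_match(true_m, shuff_m)
    n = true_m.n_cells
    if not 0 <= L <= n - 1:
        raise ValueError("L must lie in [0, N-1]")
    absc = np.abs(np.nan_to_num(true_m.correlations, nan=-np.inf))
    np.fill_diagonal(absc, -np.inf)
    keep = np.zeros((n, n), dtype=bool)
    if L > 0:
        part = np.argsort(-absc, axis=1)[:, :L]
        rows = np.repeat(np.arange(n), L)
        keep[rows, part.ravel()] = True
        keep |= keep.T  # union rule
    corr = np.where(keep, true_m.correlations, shuff_m.correlations)
    np.fill_diagonal(corr, np.diag(true_m.correlations))
    q, n_clip = _rebuild_second_moments(true_m.rates, corr)
    if n_clip:
        warnings.warn(f"top-L rebuild clipped {n_clip} pair moment(s)", stacklevel=2)
    return PopulationMoments(true_m.rates.copy(), q, corr, true_m.pk.copy(),
                             n_samples=true_m.n_samples, provenance="manipulated")


def alpha_mixed_moments(true_m: PopulationMoments, shuff_m: PopulationMoments,
                        alpha: float) -> PopulationMoments:
    """Interpolate correlations: C = alpha*C_true + (1-alpha)*C_shuff.

    Rates stay fixed; second moments are rebuilt from the mixed
    coefficients.  Pairs pushed outside the feasible (Frechet) box are
    clipped with a warning; more than 1% of pairs clipping raises, since
    that signals an unusable alpha/rate combination.
    """
    _check_rates_match(true_m, shuff_m)
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    corr = alpha * true_m.correlations + (1.0 - alpha) * shuff_m.correlations
    q, n_clip = _rebuild_second_moments(true_m.rates, corr)
    n_pairs = true_m.n_cells * (true_m.n_cells - 1) // 2
    if n_clip:
        if n_clip > 0.01 * n_pairs:
            raise ValueError(f"{n_clip}/{n_pairs} pairs infeasible after mixing")
        warnings.warn(f"alpha mixing clipped {n_clip} pair moment(s)", stacklevel=2)
    return PopulationMoments(true_m.rates.copy(), q, corr, true_m.pk.copy(),
                             n_samples=true_m.n_samples, provenance="manipulated")


# ---------------------------------------------------------------------------
# the alpha scan
# ---------------------------------------------------------------------------


def mc_heat_at_temperature(model, temperature: float = 1.0, n_runs: int = 100,
                           samples_per_run: int = 5000, n_burn: int = 100,
                           seed: int = 0, per_neuron: bool = True,
                           anneal_from: float | None = 3.0, n_levels: int = 10):
    """Specific heat at a single temperature, annealed down from ``anneal_from``.

    Near the transition a chain started cold at the target temperature can
    stay trapped on one side of the free-energy barrier and badly mis-
    estimate the energy variance, so by default the chains are carried
    down a short geometric temperature ladder before measuring (only the
    final level is measured at full length).  Pass ``anneal_from=None``
    for direct sampling at the target temperature.  Returns (C, SE), per
    neuron by default.
    """
    t = float(temperature)
    if anneal_from is None or anneal_from <= t:
        grid = np.array([t])
    else:
        grid = np.geomspace(float(anneal_from), t, n_levels)
    curve = annealed_specific_heat(
        model, t_grid=grid, n_runs=n_runs,
        samples_per_run=samples_per_run, n_burn=n_burn, seed=seed,
        per_neuron=per_neuron,
    )
    return float(curve.c[-1]), float(curve.c_se[-1])


def heat_vs_alpha(
    raster: SpikeRaster,
    alphas,
    sizes,
    n_groups: int = 10,
    seed: int = 0,
    n_runs: int = 60,
    samples_per_run: int = 2000,
    fit_kwargs: dict | None = None,
) -> AlphaScanResult:
    """C(T = 1) of pairwise fits to alpha-mixed targets, per size and group.

    For each (size, group) a random cell subset is drawn and one grand
    shuffle of its raster is realised (the same shuffle serves all
    alphas, so the alpha axis varies only the mixing).  A pairwise model
    is fitted to each mixed target and its per-neuron specific heat at
    T = 1 is measured by direct sampling.  Failed fits are recorded in
    the table (``fit_converged``), not fatal.
    """
    alphas = np.asarray(sorted(alphas), dtype=float)
    sizes = [int(s) for s in sizes]
    fit_kwargs = dict(fit_kwargs or {})
    rows = []
    for size in sizes:
        for g in range(n_groups):
            rng = np.random.default_rng(child_seed(seed, f"alpha-cells-{size}-{g}"))
            cells = np.sort(rng.choice(raster.n_cells, size=size, replace=False))
            sub = raster.subset(cells)
            true_m = compute_moments(sub)
            shuff_m = shuffled_moments(sub, seed=child_seed(seed, f"alpha-shuffle-{size}-{g}"))
            for a in alphas:
                target = alpha_mixed_moments(true_m, shuff_m, a)
                model, rep = fit_maxent(
                    target, model_class="pairwise",
                    seed=child_seed(seed, f"alpha-fit-{size}-{g}-{a}"),
                    **fit_kwargs,
                )
                c, c_se = mc_heat_at_temperature(
                    model, 1.0, n_runs=n_runs, samples_per_run=samples_per_run,
                    seed=child_seed(seed, f"alpha-heat-{size}-{g}-{a}"),
                )
                rows.append({"alpha": a, "N": size, "group": g, "c_t1": c,
                             "c_t1_se": c_se, "fit_converged": rep.converged})
    return AlphaScanResult(alphas, sizes, pd.DataFrame(rows))


def estimate_alpha_star(scan: AlphaScanResult) -> tuple[float, float] | None:
    """Bracket the correlation strength where an N-dependent C(T=1) emerges.

    Compares the largest and smallest population sizes in the scan: the
    returned interval is the pair of adjacent grid points between which
    the gap in group-averaged C(T=1) first exceeds 3 pooled standard
    errors and stays above for every larger alpha.  ``None`` if the gap
    never establishes itself.
    """
    if len(scan.sizes) < 2:
        raise ValueError("need at least two population sizes")
    if scan.alphas.size < 5:
        raise ValueError("need at least 5 alpha grid points")
    summ = scan.summary()
    n_lo, n_hi = min(scan.sizes), max(scan.sizes)
    lo = summ[summ["N"] == n_lo].set_index("alpha").sort_index()
    hi = summ[summ["N"] == n_hi].set_index("alpha").sort_index()
    alphas = np.asarray(lo.index)
    gap = hi["mean"].to_numpy() - lo["mean"].to_numpy()
    pooled = np.sqrt(hi["se"].to_numpy() ** 2 + lo["se"].to_numpy() ** 2)
    exceeds = gap > 3.0 * pooled
    # first index from which the excess persists to the end of the grid
    idx = None
    for j in range(alphas.size):
        if exceeds[j:].all():
            idx = j
            break
    if idx is None:
        return None
    if idx == 0:
        # already separated at the smallest alpha probed; the transition is
        # below the grid resolution
        return (float(alphas[0]), float(alphas[min(1, alphas.size - 1)]))
    return (float(alphas[idx - 1]), float(alphas[idx]))
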