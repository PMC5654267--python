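"""Synthetic populations, stimuli and trial structure.

No public recording accompanies the analyses this package implements, so
every downstream stage is exercised on synthetic data with the same
qualitative statistics as dense retinal ganglion-cell recordings: sparse
binary activity (per-cell spike probability per 20 ms bin of order
0.01-0.1), weak heterogeneous pairwise correlations (many near-zero values
plus a tail of outliers), and a long-tailed spike-count distribution P(K).

Two generators matter most:

* :func:`sample_ground_truth` draws exact or Gibbs samples from a known
  maximum-entropy model — the sampling oracle against which inference and
  thermodynamics are validated.
* :func:`make_correlated_population` draws a dichotomised-Gaussian
  population: a latent Gaussian with a sparse-factor correlation
  structure, thresholded per cell to hit target rates.  It controls rates
  and correlations without using the maximum-entropy machinery at all,
  which keeps validation of the inference pipeline non-circular.

All generators are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from . import _exact, _gibbs
from ._seeds import child_seed
from .maxent import MaxEntModel
from .raster import SpikeRaster

__all__ = [
    "GroundTruthSpec",
    "Stimulus",
    "random_model",
    "sample_ground_truth",
    "make_correlated_population",
    "default_study_population",
    "generate_checkerboard",
    "make_trial_raster",
    "shared_skeletons",
    "save_stimulus",
    "load_stimulus",
    "DEFAULT_COUPLING_SCALE",
]

# Factor-model coupling scale whose dichotomised output has mean pairwise
# correlation ~ 0.04 at the default sparse rates (N = 60, rate 0.03),
# the regime the rest of the pipeline is exercised in.
DEFAULT_COUPLING_SCALE = 0.7


@dataclass
class GroundTruthSpec:
    """Recipe for a random sparse k-pairwise ground-truth model.

    ``mean_rate`` sets the field mean via the independent-cell inverse
    ``mu_h = ln((1-p)/p)``; couplings are zero-mean Gaussian with density
    ``j_density`` of nonzeros; the spike-count potential is a mild convex
    penalty ``lambda_K = curvature * K (K-1) / 2`` (zero at K = 0, 1 by the
    gauge), discouraging large synchronous events.
    """

    n_cells: int = 20
    mean_rate: float = 0.03
    sigma_h: float = 0.3
    sigma_j: float = 0.3
    j_density: float = 0.2
    lambda_curvature: float = 0.02
    seed: int = 0


def random_model(spec: GroundTruthSpec) -> MaxEntModel:
    """Draw a ground-truth k-pairwise model from a :class:`GroundTruthSpec`."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cells
    if not 0 < spec.mean_rate < 1:
        raise ValueError("mean_rate must be in (0, 1)")
    mu_h = np.log((1 - spec.mean_rate) / spec.mean_rate)
    h = rng.normal(mu_h, spec.sigma_h, size=n)
    iu = np.triu_indices(n, k=1)
    vals = rng.normal(0.0, spec.sigma_j, size=iu[0].shape[0])
    mask = rng.random(iu[0].shape[0]) < spec.j_density
    J = np.zeros((n, n))
    J[iu] = vals * mask
    J = J + J.T
    k = np.arange(n + 1)
    lam = spec.lambda_curvature * k * (k - 1) / 2.0
    lam[:2] = 0.0
    return MaxEntModel(h, J, lam, model_class="k-pairwise",
                       provenance="synthetic ground truth", seed=spec.seed)


def sample_ground_truth(
    model: MaxEntModel,
    n_samples: int,
    temperature: float = 1.0,
    seed: int = 0,
    method: str = "exact",
    bin_width: float = 20.0,
    n_burn: int = 100,
    thin: int = 1,
) -> SpikeRaster:
    """Sample states from ``P(R) ∝ exp(-E(R)/T)`` as a raster.

    ``exact`` enumerates all 2^N probabilities (N <= 20) and draws i.i.d.
    states; ``gibbs`` runs a single heat-bath chain with ``n_burn``
    burn-in sweeps and ``thin`` sweeps between retained samples.
    """
    n = model.n_cells
    if method == "exact":
        _exact.check_exact_size(n)
        rng = np.random.default_rng(seed)
        p = np.exp(_exact.log_probs(model.h, model.J, model.lam, temperature))
        idx = rng.choice(p.shape[0], size=n_samples, p=p)
        bits = _exact.state_bits(n)
        values = bits[idx].T.astype(np.uint8)
    elif method == "gibbs":
        rng = np.random.default_rng(child_seed(seed, "gibbs-init"))
        state = (rng.random(n) < 0.5).astype(np.uint8)
        samples = _gibbs.gibbs_sample_states(
            model.h, model.J, model.lam, float(temperature), state,
            n_burn, thin, n_samples, child_seed(seed, "gibbs-run"),
        )
        values = samples.T
    else:
        raise ValueError(f"unknown sampling method {method!r}")
    return SpikeRaster(values, bin_width, condition_label=model.provenance or None)


# ---------------------------------------------------------------------------
# dichotomised-Gaussian populations
# ---------------------------------------------------------------------------


def _factor_correlation(n_cells: int, coupling_scale: float, rng, n_factors: int | None,
                        loading_density: float) -> np.ndarray:
    """Latent correlation from a few overlapping non-negative factors.

    Each factor is a shared input loading on a random ~``loading_density``
    fraction of cells with heterogeneous positive weights — the latent
    analogue of overlapping receptive-field pools.  Pairs sharing strong
    loadings become outliers; pairs linked only through weak or partial
    overlap form the web of many weak positive correlations; no single
    global mode dominates.  The construction is positive semi-definite for
    any coupling_scale >= 0, and correlations grow monotonically with it.
    """
    if n_factors is None:
        n_factors = max(4, n_cells // 8)
    loadings = np.abs(rng.normal(0.0, 1.0, size=(n_cells, n_factors)))
    loadings *= rng.random((n_cells, n_factors)) < loading_density
    cov = np.eye(n_cells) + coupling_scale * (loadings @ loadings.T) / n_factors
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)


def make_correlated_population(
    n_cells: int,
    rate_targets: np.ndarray | float,
    coupling_scale: float,
    n_bins: int,
    seed: int = 0,
    latent_corr: np.ndarray | None = None,
    n_factors: int | None = None,
    loading_density: float = 0.8,
    bin_width: float = 20.0,
) -> SpikeRaster:
    """Dichotomised-Gaussian raster with target rates and tunable correlation.

    A latent Gaussian vector with unit variances and correlation matrix
    either built from sparse factor loadings (scaled by
    ``coupling_scale``) or supplied as ``latent_corr`` is thresholded per
    cell at the Gaussian quantile of its target rate, so realised rates
    track their targets regardless of the correlation strength, and the
    mean binary correlation grows monotonically with ``coupling_scale``.
    """
    if coupling_scale < 0:
        raise ValueError("coupling_scale must be non-negative")
    rates = np.broadcast_to(np.asarray(rate_targets, dtype=float), (n_cells,)).copy()
    if ((rates <= 0) | (rates >= 1)).any():
        raise ValueError("rate targets must be in (0, 1)")
    rng = np.random.default_rng(seed)
    if latent_corr is not None:
        latent_corr = np.asarray(latent_corr, dtype=float)
        w = np.linalg.eigvalsh(latent_corr)
        if w.min() < -1e-8:
            raise ValueError(
                f"latent correlation not positive semi-definite (min eigenvalue {w.min():.3g}); "
                "the requested rate/correlation combination is infeasible"
            )
        corr = latent_corr
    else:
        corr = _factor_correlation(n_cells, coupling_scale, rng, n_factors, loading_density)
    # eigh-based square root tolerates the semi-definite boundary
    w, v = np.linalg.eigh(corr)
    root = v * np.sqrt(np.clip(w, 0.0, None))
    thresh = norm.ppf(1.0 - rates)
    values = np.empty((n_cells, n_bins), dtype=np.uint8)
    chunk = max(1, int(5e6) // max(n_cells, 1))
    for start in range(0, n_bins, chunk):
        stop = min(start + chunk, n_bins)
        z = rng.standard_normal((stop - start, n_cells)) @ root.T
        values[:, start:stop] = (z.T > thresh[:, None]).astype(np.uint8)
    return SpikeRaster(values, bin_width, condition_label="dichotomised gaussian")


def default_study_population(
    n_cells: int = 60,
    n_bins: int = 100_000,
    rate: float = 0.03,
    coupling_scale: float = DEFAULT_COUPLING_SCALE,
    seed: int = 0,
) -> SpikeRaster:
    """The package's reference synthetic population.

    Sixty cells at 0.03 spikes per bin with mean pairwise correlation
    around 0.04 — sparse activity, a web of weak correlations with
    outliers, and a long-tailed P(K), the regime in which the finite-size
    and correlation-strength scans are run.
    """
    return make_correlated_population(n_cells, rate, coupling_scale, n_bins, seed=seed)


# ---------------------------------------------------------------------------
# stimuli
# ---------------------------------------------------------------------------


@dataclass
class Stimulus:
    """Frame sequence for the LN stage: (n_frames, n_y, n_x, n_colors)."""

    frames: np.ndarray
    frame_rate: float = 50.0  # Hz; 50 Hz frames align 1:1 with 20 ms bins
    checker_size: int = 1
    levels: tuple = (0, 1)

    def __post_init__(self) -> None:
        f = np.asarray(self.frames)
        if f.ndim != 4:
            raise ValueError("frames must be (n_frames, n_y, n_x, n_colors)")
        if not np.isin(f, self.levels).all():
            raise ValueError("frame values outside the declared level set")
        self.frames = f

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def generate_checkerboard(
    n_y: int, n_x: int, n_frames: int, n_colors: int = 3, seed: int = 0,
    frame_rate: float = 50.0,
) -> Stimulus:
    """Random binary checkerboard, i.i.d. per checker per color per frame.

    With ``n_colors`` independent binary guns each checker takes one of
    ``2**n_colors`` distinct color values.
    """
    if min(n_y, n_x, n_frames, n_colors) < 1:
        raise ValueError("all dimensions must be >= 1")
    rng = np.random.default_rng(seed)
    frames = rng.integers(0, 2, size=(n_frames, n_y, n_x, n_colors), dtype=np.uint8)
    return Stimulus(frames, frame_rate=frame_rate)


def save_stimulus(stimulus: Stimulus, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("frames", data=stimulus.frames, compression="gzip")
        f.attrs["frame_rate"] = stimulus.frame_rate
        f.attrs["checker_size"] = stimulus.checker_size


def load_stimulus(path) -> Stimulus:
    import h5py

    with h5py.File(path, "r") as f:
        return Stimulus(f["frames"][...], frame_rate=float(f.attrs["frame_rate"]),
                        checker_size=int(f.attrs["checker_size"]))


# ---------------------------------------------------------------------------
# trial structure
# ---------------------------------------------------------------------------


def shared_skeletons(
    n_cells: int, trial_len: int, rate: float, shared_frac: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Two event skeletons sharing a fraction of their events.

    Useful for building two "condition" variants whose cross-condition
    reproducibility sits between the 0 and 1 calibration points.
    """
    rng = np.random.default_rng(seed)
    base = rng.random((n_cells, trial_len)) < rate
    a = base.copy()
    b = base.copy()
    # events unique to each condition replace the non-shared fraction
    swap = rng.random((n_cells, trial_len)) >= shared_frac
    a_extra = rng.random((n_cells, trial_len)) < rate
    b_extra = rng.random((n_cells, trial_len)) < rate
    a[swap] = a_extra[swap]
    b[swap] = b_extra[swap]
    return a.astype(np.uint8), b.astype(np.uint8)


def make_trial_raster(
    base,
    n_trials: int,
    trial_len: int | None = None,
    jitter: float = 0.0,
    drop_prob: float = 0.0,
    seed: int = 0,
    bin_width: float = 20.0,
    condition_label: str | None = None,
) -> SpikeRaster:
    """Repeated-trial raster from a shared event skeleton.

    ``base`` is either an explicit binary skeleton array
    ``(n_cells, trial_len)`` or a dict ``{"n_cells", "rate"}`` from which
    a Bernoulli skeleton is drawn.  Each trial replays the skeleton with
    every event independently dropped with probability ``drop_prob`` and
    jittered by a Gaussian time shift of SD ``jitter`` ms (rounded to
    bins, events jittered off the trial are lost).  ``trial_bounds`` is
    populated with the resulting equal-length trials.
    """
    if n_trials < 2:
        raise ValueError("need at least 2 trials")
    rng = np.random.default_rng(seed)
    if isinstance(base, dict):
        if trial_len is None:
            raise ValueError("trial_len required with a dict base")
        skeleton = (rng.random((base["n_cells"], trial_len)) < base["rate"]).astype(np.uint8)
    else:
        skeleton = np.asarray(base, dtype=np.uint8)
        trial_len = skeleton.shape[1]
    n_cells = skeleton.shape[0]
    jitter_bins_sd = jitter / bin_width
    values = np.zeros((n_cells, n_trials * trial_len), dtype=np.uint8)
    cells, times = np.nonzero(skeleton)
    for tr in range(n_trials):
        keep = rng.random(cells.shape[0]) >= drop_prob
        t = times[keep].astype(float)
        if jitter_bins_sd > 0:
            t = t + np.round(rng.normal(0.0, jitter_bins_sd, size=t.shape[0]))
        ok = (t >= 0) & (t < trial_len)
        values[cells[keep][ok], tr * trial_len + t[ok].astype(int)] = 1
    bounds = [(tr * trial_len, (tr + 1) * trial_len) for tr in range(n_trials)]
    return SpikeRaster(values, bin_width, trial_bounds=bounds, condition_label=condition_label)
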