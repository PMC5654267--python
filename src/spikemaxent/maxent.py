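"""Maximum-entropy model inference for binary neural populations.

The model family is the Boltzmann form ``P(R) = exp(-E(R)) / Z`` with the
unitless energy

    E(R) = sum_i h_i r_i + sum_{i, j != i} J_ij r_i r_j + lambda_K,

where ``K = sum_i r_i`` is the spike count of state ``R``.  Three nested
model classes are supported:

* ``independent`` — fields only (J = 0, lambda = 0); matches the rates.
* ``pairwise``    — fields and symmetric couplings; matches rates and
  pairwise second moments (the classic Ising-type model).
* ``k-pairwise``  — additionally a spike-count potential ``lambda_K``;
  matches the spike-count distribution P(K) as well.

Two gauge freedoms leave all probabilities unchanged:
``lambda_K -> lambda_K + a K + b`` with ``h_i -> h_i - a``, and a
uniform coupling shift ``J_ij -> J_ij + c`` with
``lambda_K -> lambda_K - c K (K-1)``.  The fitters pin
``lambda_0 = lambda_1 = lambda_2 = 0``, which makes the fitted
parameters unique (the model container itself only requires
``lambda_0 = lambda_1 = 0`` so that externally built models, e.g.
ground-truth recipes with a curved spike-count potential, remain valid).

Fitting uses sequential coordinate descent with closed-form single-feature
updates.  Because every sufficient statistic here is a binary feature
``f_g(R)`` (a single r_i, a product r_i r_j, or a spike-count indicator),
changing its coefficient by ``d`` reweights the distribution in a way with
an exactly solvable one-dimensional condition: if ``p`` is the current
model expectation of ``f_g`` and ``t`` the target,

    d = log[ p (1 - t) / (t (1 - p)) ]

matches the expectation exactly.  An L1 penalty on the couplings (and, for
k-pairwise, on lambda) enters through the standard soft-threshold variant
of the same update; the local fields are never penalised.  For N <= 15
expectations are exact (full enumeration, reweighted incrementally); for
larger N they are estimated each epoch by persistent-chain heat-bath
sampling and the updates are damped.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from . import _exact, _gibbs
from ._seeds import child_seed
from .raster import PopulationMoments

__all__ = [
    "MaxEntModel",
    "FitReport",
    "fit_maxent",
    "model_moments",
    "goodness_of_fit",
    "poisson_binomial_pk",
]

MODEL_CLASSES = ("independent", "pairwise", "k-pairwise")
CONVENTION = "P ∝ exp(−E); E = Σ h·r + Σ_{i≠j} J r r + λ_K"


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------


@dataclass
class MaxEntModel:
    """Parameters of an independent / pairwise / k-pairwise model."""

    h: np.ndarray
    J: np.ndarray
    lam: np.ndarray
    model_class: str = "k-pairwise"
    convention: str = CONVENTION
    provenance: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=np.float64).copy()
        n = self.h.shape[0]
        self.J = np.asarray(self.J, dtype=np.float64).copy()
        self.lam = np.asarray(self.lam, dtype=np.float64).copy()
        if self.J.shape != (n, n):
            raise ValueError("J must be (N, N)")
        if self.lam.shape != (n + 1,):
            raise ValueError("lambda must have length N + 1")
        if not np.allclose(self.J, self.J.T, atol=1e-12):
            raise ValueError("J must be symmetric")
        if not np.allclose(np.diag(self.J), 0.0, atol=1e-12):
            raise ValueError("J must have zero diagonal")
        if self.lam[0] != 0.0 or self.lam[1] != 0.0:
            raise ValueError("gauge requires lambda_0 = lambda_1 = 0")
        if not (np.isfinite(self.h).all() and np.isfinite(self.J).all() and np.isfinite(self.lam).all()):
            raise ValueError("parameters must be finite")
        if self.model_class not in MODEL_CLASSES:
            raise ValueError(f"model_class must be one of {MODEL_CLASSES}")

    @property
    def n_cells(self) -> int:
        return self.h.shape[0]

    def energy(self, state: np.ndarray) -> float:
        """E(R) for one binary state (ordered-pair sum: a pair adds 2 J_ij)."""
        r = np.asarray(state, dtype=np.float64)
        k = int(round(r.sum()))
        return float(self.h @ r + r @ self.J @ r + self.lam[k])

    def rate_matched_independent(self, rates: np.ndarray | None = None, **kwargs) -> "MaxEntModel":
        """Independent model with the same firing rates (at T = 1)."""
        if rates is None:
            rates = model_moments(self, **kwargs).rates
        p = np.clip(rates, 1e-12, 1 - 1e-12)
        n = self.n_cells
        return MaxEntModel(
            np.log((1 - p) / p), np.zeros((n, n)), np.zeros(n + 1),
            model_class="independent", provenance="rate-matched independent",
        )

    # -- JSON round trip ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_cells": self.n_cells,
            "model_class": self.model_class,
            "h": self.h.tolist(),
            "J": self.J.tolist(),
            "lambda": self.lam.tolist(),
            "convention": self.convention,
            "provenance": self.provenance,
            "seed": self.seed,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "MaxEntModel":
        return cls(
            np.asarray(d["h"]), np.asarray(d["J"]), np.asarray(d["lambda"]),
            model_class=d.get("model_class", "k-pairwise"),
            convention=d.get("convention", CONVENTION),
            provenance=d.get("provenance", ""),
            seed=d.get("seed"),
        )

    @classmethod
    def from_json(cls, path) -> "MaxEntModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class FitReport:
    """Constraint deviations and diagnostics of a fit (or goodness check).

    Deviations are reported per constraint family both in absolute units
    and in units of the target standard error.
    """

    converged: bool
    n_epochs: int
    max_dev_se: dict = field(default_factory=dict)
    max_dev_abs: dict = field(default_factory=dict)
    frac_within: dict = field(default_factory=dict)
    final_penalty: float = 0.0
    nnz_J: int = 0
    gradient_mode: str = "exact"
    message: str = ""
    triplet_r: float | None = None
    triplet_data: np.ndarray | None = None
    triplet_model: np.ndarray | None = None
    state_logp_model: np.ndarray | None = None
    state_logp_data: np.ndarray | None = None


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def poisson_binomial_pk(p: np.ndarray) -> np.ndarray:
    """P(K) for independent cells with spike probabilities ``p`` (DP)."""
    pk = np.array([1.0])
    for pi in np.asarray(p, dtype=float):
        pk = np.convolve(pk, [1.0 - pi, pi])
    return pk


def _check_feasible(target: PopulationMoments) -> None:
    m = target.rates
    if (m < 0).any() or (m > 1).any():
        raise ValueError("rates must lie in [0, 1]")
    q = target.second_moments
    hi = np.minimum.outer(m, m)
    lo = np.maximum(0.0, np.add.outer(m, m) - 1.0)
    if (q > hi + 1e-9).any() or (q < lo - 1e-9).any():
        raise ValueError("infeasible targets: second moments violate Frechet bounds")
    if abs(target.pk.sum() - 1) > 1e-6:
        raise ValueError("target P(K) must sum to 1")


def _coordinate_shift(theta: float, p: float, t: float, gamma: float) -> float:
    """New coefficient after one exact coordinate step with L1 weight gamma.

    Solves <f>(theta') = t + gamma * sign(theta') on the coordinate, with
    the usual zero-crossing rule; gamma = 0 reduces to exact matching.
    Returns the new theta (caller applies damping if desired).
    """
    eps = 1e-12
    p = min(max(p, eps), 1 - eps)
    if gamma <= 0:
        t = min(max(t, eps), 1 - eps)
        return theta + np.log(p * (1 - t) / (t * (1 - p)))
    # positive branch: expectation pulled down to t + gamma
    tp = min(t + gamma, 1 - eps)
    d = np.log(p * (1 - tp) / (tp * (1 - p)))
    if theta + d > 0:
        return theta + d
    # negative branch
    tm = max(t - gamma, eps)
    d = np.log(p * (1 - tm) / (tm * (1 - p)))
    if theta + d < 0:
        return theta + d
    return 0.0


def _target_ses(target: PopulationMoments, iu, fit_pk: bool, abs_tol: float):
    """Standard errors for rates, pair moments and P(K) used as tolerances.

    Bootstrap errors attached to the target are used when present (pair
    correlation errors are converted to second-moment errors); otherwise a
    binomial SE from n_samples is used.  All SEs are floored so that an
    exactly-zero error never makes convergence unattainable.
    """
    n = target.n_samples
    m = target.rates
    q = target.second_moments[iu]
    if target.rate_se is not None:
        se_r = target.rate_se.copy()
    else:
        se_r = np.sqrt(np.clip(m * (1 - m), 0, None) / n)
    if target.corr_se is not None:
        sd = np.sqrt(np.clip(m * (1 - m), 0, None))
        se_q = (np.nan_to_num(target.corr_se) * np.outer(sd, sd))[iu]
    else:
        se_q = np.sqrt(np.clip(q * (1 - q), 0, None) / n)
    se_pk = None
    if fit_pk:
        if target.pk_se is not None:
            se_pk = target.pk_se.copy()
        else:
            se_pk = np.sqrt(np.clip(target.pk * (1 - target.pk), 0, None) / n)
        se_pk = np.maximum(se_pk, abs_tol)
    return np.maximum(se_r, abs_tol), np.maximum(se_q, abs_tol), se_pk


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def fit_maxent(
    target: PopulationMoments,
    model_class: Literal["independent", "pairwise", "k-pairwise"] = "k-pairwise",
    l1_penalty: float | None = None,
    gradient_mode: Literal["auto", "exact", "mc"] = "auto",
    seed: int = 0,
    max_epochs: int = 200,
    se_tol: float = 3.0,
    abs_tol: float = 1e-4,
    mc_samples: int = 100_000,
    mc_chains: int = 100,
    mc_step: float = 0.3,
) -> tuple[MaxEntModel, FitReport]:
    """Fit a maximum-entropy model to population moments.

    Parameters
    ----------
    target
        Moments to match (rates always; pair moments for pairwise and
        k-pairwise; P(K) additionally for k-pairwise).
    l1_penalty
        L1 weight on couplings (and lambda), in per-sample likelihood
        units.  ``None`` uses ``1 / n_samples``, which vanishes as data
        volume grows; the local fields are never penalised.
    gradient_mode
        ``exact`` enumerates all states (N <= 20); ``mc`` estimates
        expectations by Gibbs sampling (``mc_samples`` sweeps per epoch
        over ``mc_chains`` persistent chains, damped updates of size
        ``mc_step``); ``auto`` picks exact for N <= 15.
    se_tol, abs_tol
        Convergence: every constraint within ``se_tol`` target standard
        errors (SEs floored at ``abs_tol``), or ``max_epochs`` reached.

    Returns
    -------
    (MaxEntModel, FitReport)
    """
    _check_feasible(target)
    n = target.n_cells
    m = np.clip(target.rates, 0.0, 1.0)
    if gradient_mode == "auto":
        gradient_mode = "exact" if n <= 15 else "mc"
    if gradient_mode == "exact":
        _exact.check_exact_size(n)
    gamma = (1.0 / target.n_samples) if l1_penalty is None else float(l1_penalty)

    # independent class: closed form
    p_clip = np.clip(m, 1e-12, 1 - 1e-12)
    h0 = np.log((1 - p_clip) / p_clip)
    if model_class == "independent":
        model = MaxEntModel(h0, np.zeros((n, n)), np.zeros(n + 1),
                            model_class="independent", provenance=target.provenance, seed=seed)
        return model, FitReport(converged=True, n_epochs=0, gradient_mode="closed-form",
                                message="independent model solved in closed form")

    fit_pk = model_class == "k-pairwise"
    iu = np.triu_indices(n, k=1)
    t_pairs = target.second_moments[iu]
    se_r, se_q, se_pk = _target_ses(target, iu, fit_pk, abs_tol)

    h = h0.copy()
    # pair coefficients in "feature" parametrisation: theta_ij = 2 J_ij
    theta = np.zeros(t_pairs.shape[0])
    lam = np.zeros(n + 1)
    # Gauge: lambda_0 = lambda_1 = 0 absorbs the constant and linear-in-K
    # freedom into Z and h.  A further freedom remains in the k-pairwise
    # class — a uniform coupling shift is equivalent to a quadratic
    # lambda_K term — so lambda_2 = 0 is pinned as well, which makes the
    # fitted parameters unique; P(K = 2) is then implied by normalisation,
    # the rates, and the pair moments.
    # Spike counts never observed in the target keep lambda free in exact
    # mode (the L1 penalty equilibrates them at a small positive value,
    # P(K) ~ gamma); Monte-Carlo mode instead continues lambda beyond the
    # resolvable range (see _fit_mc), which is marked here.
    pinned_k = np.zeros(n + 1, dtype=bool)
    if fit_pk and gradient_mode == "mc":
        pinned_k[3:] = target.pk[3:] <= 0

    rng = np.random.default_rng(child_seed(seed, "fit-order"))

    def build_model() -> MaxEntModel:
        J = np.zeros((n, n))
        J[iu] = theta / 2.0
        J = J + J.T
        return MaxEntModel(h, J, lam, model_class=model_class,
                           provenance=target.provenance, seed=seed)

    if gradient_mode == "exact":
        epochs, converged, devs = _fit_exact(
            n, m, t_pairs, target.pk, se_r, se_q, se_pk, h, theta, lam, pinned_k,
            fit_pk, gamma, iu, rng, max_epochs, se_tol,
        )
    else:
        epochs, converged, devs = _fit_mc(
            n, m, t_pairs, target.pk, se_r, se_q, se_pk, h, theta, lam, pinned_k,
            fit_pk, gamma, iu, rng, max_epochs, se_tol,
            mc_samples, mc_chains, mc_step, seed,
        )

    model = build_model()
    report = FitReport(
        converged=converged,
        n_epochs=epochs,
        max_dev_se={k: v[0] for k, v in devs.items()},
        max_dev_abs={k: v[1] for k, v in devs.items()},
        frac_within={k: v[2] for k, v in devs.items()},
        final_penalty=gamma,
        nnz_J=int((np.abs(model.J[iu]) > 1e-10).sum()),
        gradient_mode=gradient_mode,
        message="" if converged else "constraint deviations above tolerance at max_epochs",
    )
    if not converged:
        warnings.warn(f"fit did not converge: {report.max_dev_se}", stacklevel=2)
    return model, report


def _deviation_summary(dev_r, dev_q, dev_pk, se_r, se_q, se_pk, se_tol):
    out = {
        "rates": (float(np.max(dev_r / se_r)), float(np.max(dev_r)),
                  float(np.mean(dev_r <= se_tol * se_r))),
        "pairs": (float(np.max(dev_q / se_q)), float(np.max(dev_q)),
                  float(np.mean(dev_q <= se_tol * se_q))),
    }
    if dev_pk is not None:
        out["pk"] = (float(np.max(dev_pk / se_pk)), float(np.max(dev_pk)),
                     float(np.mean(dev_pk <= se_tol * se_pk)))
    return out


def _fit_exact(n, m, t_pairs, t_pk, se_r, se_q, se_pk, h, theta, lam, pinned_k,
               fit_pk, gamma, iu, rng, max_epochs, se_tol):
    """Sequential coordinate descent with an incrementally reweighted
    enumeration of all 2^N state weights."""
    bits = _exact.state_bits(n).astype(bool)
    kvec = bits.sum(axis=1).astype(int)
    # feature masks
    h_cols = [bits[:, i] for i in range(n)]
    pair_cols = [bits[:, i] & bits[:, j] for i, j in zip(*iu)]
    k_masks = [kvec == k for k in range(n + 1)]
    free_ks = [k for k in range(3, n + 1) if fit_pk and not pinned_k[k]]

    # initial weights from the starting parameters
    J = np.zeros((n, n))
    J[iu] = theta / 2.0
    logw = -(_exact.all_energies(h, J + J.T, lam))
    logw -= logw.max()
    w = np.exp(logw)

    # feature list: (kind, index)
    feats = [("h", i) for i in range(n)] + [("p", g) for g in range(t_pairs.shape[0])]
    feats += [("k", k) for k in free_ks]

    converged = False
    epochs = 0
    for epoch in range(1, max_epochs + 1):
        epochs = epoch
        order = rng.permutation(len(feats))
        for fi in order:
            kind, g = feats[fi]
            if kind == "h":
                col, t, old, gam = h_cols[g], m[g], h[g], 0.0
            elif kind == "p":
                col, t, old, gam = pair_cols[g], t_pairs[g], theta[g], gamma
            else:
                col, t, old, gam = k_masks[g], t_pk[g], lam[g], gamma
            wtot = w.sum()
            p = w[col].sum() / wtot
            new = _coordinate_shift(old, p, t, gam)
            d = np.clip(new - old, -8.0, 8.0)
            new = old + d
            if d != 0.0:
                w[col] *= np.exp(-d)
                if kind == "h":
                    h[g] = new
                elif kind == "p":
                    theta[g] = new
                else:
                    lam[g] = new
            if not np.isfinite(w.sum()) or w.max() > 1e250:
                w /= w.max()
        # convergence check on full moments
        wtot = w.sum()
        p_states = w / wtot
        fb = bits.astype(np.float64)
        rates = p_states @ fb
        q = ((fb * p_states[:, None]).T @ fb)[iu]
        dev_r = np.abs(rates - m)
        dev_q = np.abs(q - t_pairs)
        dev_pk = None
        if fit_pk:
            pk = np.bincount(kvec, weights=p_states, minlength=n + 1)
            dev_pk = np.abs(pk - t_pk)
            dev_pk[pinned_k] = 0.0
            # P(K <= 2) is gauge-implied (normalisation, rates, pair
            # moments) up to accumulated L1 slack, not directly fitted
            dev_pk[:3] = 0.0
        ok = (dev_r <= se_tol * se_r).all() and (dev_q <= se_tol * se_q).all()
        if fit_pk:
            ok = ok and (dev_pk <= se_tol * se_pk).all()
        if ok:
            converged = True
            break
    devs = _deviation_summary(dev_r, dev_q, dev_pk, se_r, se_q, se_pk, se_tol)
    return epochs, converged, devs


def _fit_mc(n, m, t_pairs, t_pk, se_r, se_q, se_pk, h, theta, lam, pinned_k,
            fit_pk, gamma, iu, rng, max_epochs, se_tol,
            mc_samples, mc_chains, mc_step, seed):
    """Damped parallel coordinate updates with persistent-chain sampling.

    After the adaptive phase reaches tolerance (or the epoch budget), a
    short polish phase runs at a fixed small step and tail-averages the
    parameters: near-critical models are exquisitely sensitive to small
    systematic coupling residuals, and averaging removes the sampling
    noise the adaptive phase leaves behind.
    """
    n_keep = max(10, mc_samples // mc_chains)
    states = np.zeros((mc_chains, n), dtype=np.uint8)
    # start chains from independent draws at the target rates
    init_rng = np.random.default_rng(child_seed(seed, "fit-mc-init"))
    states[:] = (init_rng.random((mc_chains, n)) < m).astype(np.uint8)
    n_tot = mc_chains * n_keep
    mc_floor = 1.0 / (2.0 * n_tot)
    # lambda_k is only fitted where P(K = k) is resolvable at this sample
    # size; rarer (but observed) counts get an energy-increasing
    # continuation below.  Fitting unresolvable tail values head-on drives
    # lambda into a runaway that opens a metastable high-K phase.
    resolvable = t_pk * n_tot >= 8.0
    resolvable[:2] = False
    resolvable &= ~pinned_k
    fitted_ks = np.nonzero(resolvable)[0]
    eps = mc_floor
    t_r = np.clip(m, 1e-12, 1 - 1e-12)
    t_k = np.clip(t_pk, 1e-12, None)

    def sample(tag, burn):
        J = np.zeros((n, n))
        J[iu] = theta / 2.0
        J = J + J.T
        sum_r, sum_rr, k_hist, _, _ = _gibbs.gibbs_moments(
            h, J, lam, 1.0, states, burn, n_keep, child_seed(seed, tag))
        rates = sum_r.sum(axis=0) / n_tot
        q = sum_rr.sum(axis=0)[iu] / n_tot
        pk = k_hist.sum(axis=0) / n_tot
        se_mc_r = sum_r.std(axis=0, ddof=1) / n_keep / np.sqrt(mc_chains)
        se_mc_q = sum_rr.std(axis=0, ddof=1)[iu] / n_keep / np.sqrt(mc_chains)
        se_mc_pk = k_hist.std(axis=0, ddof=1) / n_keep / np.sqrt(mc_chains)
        return rates, q, pk, se_mc_r, se_mc_q, se_mc_pk

    def deviations(rates, q, pk, se_mc_r, se_mc_q, se_mc_pk):
        dev_r = np.abs(rates - m)
        dev_q = np.abs(q - t_pairs)
        eff_r = np.sqrt(se_r**2 + se_mc_r**2)
        eff_q = np.sqrt(se_q**2 + se_mc_q**2)
        ok = (dev_r <= se_tol * eff_r).all() and (dev_q <= se_tol * eff_q).all()
        dev_pk = eff_pk = None
        if fit_pk:
            eff_pk = np.sqrt(se_pk**2 + se_mc_pk**2)
            dev_pk = np.abs(pk - t_pk)
            dev_pk[~resolvable] = 0.0
            ok = ok and (dev_pk <= se_tol * eff_pk).all()
        return ok, dev_r, dev_q, dev_pk, eff_r, eff_q, eff_pk

    def signals(rates, q, pk):
        # closed-form coordinate displacements.  The global activity level
        # and the per-cell detail are controlled separately: when P(K) is
        # fitted, the lambda-family update owns the global level (it is
        # re-gauged into a uniform h shift), and the per-cell h and pair
        # steps are zero-meaned — otherwise two controllers fight along
        # the nearly-degenerate gauge directions and the iteration
        # oscillates or creeps.
        p_r = np.clip(rates, eps, 1 - eps)
        h_sig = np.clip(np.log(p_r * (1 - t_r) / (t_r * (1 - p_r))), -2, 2)
        if fit_pk:
            h_sig -= h_sig.mean()
        p_q = np.clip(q, eps, 1 - eps)
        theta_sig = np.empty_like(theta)
        for g in range(theta.shape[0]):
            new = _coordinate_shift(theta[g], p_q[g], t_pairs[g], gamma)
            theta_sig[g] = np.clip(new - theta[g], -2, 2)
        if fit_pk:
            # a uniform coupling shift is gauge-equivalent to a quadratic
            # lambda_K term; zero-meaning the pair step leaves that
            # collective (high-gain) mode to the lambda update below
            theta_sig -= theta_sig.mean()
        lam_sig = np.zeros(n + 1)
        if fit_pk:
            p_k = np.clip(pk, eps, None)
            lam_sig = np.clip(np.log(p_k / t_k), -2, 2)
            lam_sig[2:][~resolvable[2:]] = 0.0
        return h_sig, theta_sig, lam_sig

    def apply(steps, h_sig, theta_sig, lam_sig):
        step_h, step_t, step_l = steps
        h[:] = h + step_h * h_sig
        theta[:] = theta + step_t * theta_sig
        if not fit_pk:
            return
        # The spike-count indicators partition the state space, so the
        # lambda family admits a joint multiplicative update: reweighting
        # K = k states by t_k / p_k matches P(K) exactly in one step.
        # Applied damped over all k, then re-gauged to
        # lambda_0 = lambda_1 = 0 via the (a K + b, h + a) identity and to
        # lambda_2 = 0 via a uniform coupling shift.
        lam[:] = lam + step_l * lam_sig
        a, b = lam[1] - lam[0], lam[0]
        kk_all = np.arange(n + 1)
        lam[:] = lam - (a * kk_all + b)
        lam[:2] = 0.0
        h[:] = h + a
        c = lam[2] / 2.0
        lam[:] = lam - c * kk_all * (kk_all - 1)
        theta[:] = theta + 2.0 * c
        if fitted_ks.size:
            # beyond the resolvable range, continue lambda so that the
            # mean-field energy E(K) = K h_bar + K(K-1) J_bar + lambda_K
            # rises with K: with negative mean couplings a naive tail
            # would open a spurious low-energy high-K phase that ruins
            # the low-temperature thermodynamics
            k1 = int(fitted_ks[-1])
            hbar = h.mean()
            jbar = theta.mean() / 2.0
            kk = np.arange(k1 + 1, n + 1)
            emf = kk * hbar + kk * (kk - 1) * jbar
            emf1 = k1 * hbar + k1 * (k1 - 1) * jbar
            lam[k1 + 1:] = lam[k1] + (emf1 - emf) + 0.5 * (kk - k1)

    def adapt(step, sig, prev):
        # oscillation-adaptive damping, per parameter block: when a
        # block's update direction reverses between epochs (a period-2
        # collective mode), shrink its step; when it clearly persists,
        # let it recover toward the nominal value.  Only the collective
        # blocks (fields, spike-count potential) are oscillation-prone;
        # keeping per-block steps stops their damping from throttling
        # the many nearly-independent pair coordinates.
        if prev is not None:
            denom = np.linalg.norm(sig) * np.linalg.norm(prev)
            cos = float(sig @ prev / denom) if denom > 0 else 0.0
            if cos < -0.2:
                step = max(0.02, step * 0.6)
            elif cos > 0.5:
                step = min(mc_step, step * 1.1)
        return step

    epochs = 0
    steps = [mc_step, mc_step, mc_step]  # h, theta, lambda blocks
    prev_sigs = [None, None, None]
    converged_main = False
    for epoch in range(1, max_epochs + 1):
        epochs = epoch
        rates, q, pk, se_mc_r, se_mc_q, se_mc_pk = sample(
            f"fit-mc-{epoch}", 40 if epoch == 1 else 5)
        ok, *_ = deviations(rates, q, pk, se_mc_r, se_mc_q, se_mc_pk)
        if ok and epoch > 3:
            converged_main = True
            break
        sigs = signals(rates, q, pk)
        steps = [adapt(s, sig, prev) for s, sig, prev in zip(steps, sigs, prev_sigs)]
        prev_sigs = sigs
        apply(steps, *sigs)

    # polish: small fixed-step epochs (no larger than the steps the
    # adaptive phase settled on) with tail averaging
    polish_step = [min(s, 0.1) for s in steps]
    n_polish = 20
    acc_h = np.zeros_like(h)
    acc_theta = np.zeros_like(theta)
    acc_lam = np.zeros_like(lam)
    for pe in range(1, n_polish + 1):
        rates, q, pk, *_ = sample(f"fit-polish-{pe}", 5)
        apply(polish_step, *signals(rates, q, pk))
        acc_h += h
        acc_theta += theta
        acc_lam += lam
    h[:] = acc_h / n_polish
    theta[:] = acc_theta / n_polish
    lam[:] = acc_lam / n_polish

    # final evaluation on the polished parameters
    rates, q, pk, se_mc_r, se_mc_q, se_mc_pk = sample("fit-final", 20)
    ok, dev_r, dev_q, dev_pk, eff_r, eff_q, eff_pk = deviations(
        rates, q, pk, se_mc_r, se_mc_q, se_mc_pk)
    converged = ok or converged_main
    devs = _deviation_summary(dev_r, dev_q, dev_pk if fit_pk else None,
                              eff_r, eff_q, eff_pk, se_tol)
    return epochs, converged, devs


# ---------------------------------------------------------------------------
# forward moments and goodness of fit
# ---------------------------------------------------------------------------


def model_moments(
    model: MaxEntModel,
    temperature: float = 1.0,
    mode: Literal["auto", "exact", "mc"] = "auto",
    n_samples: int = 100_000,
    n_chains: int = 50,
    n_burn: int = 100,
    seed: int = 0,
) -> PopulationMoments:
    """Moments of the model distribution at a fictitious temperature.

    ``exact`` sums over all 2^N states (N <= 20).  ``mc`` pools heat-bath
    chains and attaches standard errors from the chain-to-chain spread
    (pair-moment spread is propagated to the correlation scale).
    """
    n = model.n_cells
    if mode == "auto":
        mode = "exact" if n <= _exact.MAX_EXACT_N else "mc"
    if mode == "exact":
        _exact.check_exact_size(n)
        rates, q, pk = _exact.exact_moments(model.h, model.J, model.lam, temperature)
        mom = _moments_from_rq(rates, q, pk, n_samples=0)
        mom.provenance = "model-exact"
        return mom
    n_keep = max(10, n_samples // n_chains)
    rng = np.random.default_rng(child_seed(seed, "model-moments-init"))
    states = (rng.random((n_chains, n)) < 0.5).astype(np.uint8)
    sum_r, sum_rr, k_hist, _, _ = _gibbs.gibbs_moments(
        model.h, model.J, model.lam, float(temperature), states,
        n_burn, n_keep, child_seed(seed, "model-moments"),
    )
    n_tot = n_chains * n_keep
    rates = sum_r.sum(axis=0) / n_tot
    q = sum_rr.sum(axis=0) / n_tot
    np.fill_diagonal(q, rates)
    pk = k_hist.sum(axis=0) / n_tot
    mom = _moments_from_rq(rates, q, pk, n_samples=n_tot)
    mom.rate_se = sum_r.std(axis=0, ddof=1) / n_keep / np.sqrt(n_chains)
    se_q = sum_rr.std(axis=0, ddof=1) / n_keep / np.sqrt(n_chains)
    sd = np.sqrt(np.clip(rates * (1 - rates), 1e-300, None))
    mom.corr_se = se_q / np.outer(sd, sd)
    mom.pk_se = k_hist.std(axis=0, ddof=1) / n_keep / np.sqrt(n_chains)
    mom.provenance = "model-mc"
    return mom


def _moments_from_rq(rates, q, pk, n_samples: int) -> PopulationMoments:
    sd = np.sqrt(np.clip(rates * (1 - rates), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (q - np.outer(rates, rates)) / np.outer(sd, sd)
    corr[~np.isfinite(corr)] = np.nan
    np.fill_diagonal(corr, np.where(sd > 0, 1.0, np.nan))
    return PopulationMoments(rates, q, corr, pk, n_samples=max(n_samples, 1))


def goodness_of_fit(
    model: MaxEntModel,
    data: PopulationMoments,
    raster=None,
    n_triplets: int = 2000,
    min_state_count: int = 10,
    seed: int = 0,
    se_tol: float = 3.0,
    abs_tol: float = 1e-4,
    **moment_kwargs,
) -> FitReport:
    """Compare model predictions to data beyond the fitted constraints.

    Always reports constraint deviations (rates, pair moments, P(K)).
    Given a raster, additionally checks out-of-sample statistics: average
    triplet moments ``<r_i r_j r_k>`` over random triplets, and (exact mode
    only) model log-probability vs empirical log-frequency for states
    observed at least ``min_state_count`` times.
    """
    if model.n_cells != data.n_cells:
        raise ValueError("model and data sizes differ")
    n = model.n_cells
    mm = model_moments(model, seed=seed, **moment_kwargs)
    iu = np.triu_indices(n, k=1)
    se_r, se_q, se_pk = _target_ses(data, iu, True, abs_tol)
    dev_r = np.abs(mm.rates - data.rates)
    dev_q = np.abs(mm.second_moments[iu] - data.second_moments[iu])
    dev_pk = np.abs(mm.pk - data.pk)
    devs = _deviation_summary(dev_r, dev_q, dev_pk, se_r, se_q, se_pk, se_tol)
    ok = all(v[0] <= se_tol for v in devs.values())
    report = FitReport(
        converged=ok, n_epochs=0,
        max_dev_se={k: v[0] for k, v in devs.items()},
        max_dev_abs={k: v[1] for k, v in devs.items()},
        frac_within={k: v[2] for k, v in devs.items()},
        nnz_J=int((np.abs(model.J[iu]) > 1e-10).sum()),
        gradient_mode="check",
    )
    if raster is None:
        return report

    rng = np.random.default_rng(child_seed(seed, "gof-triplets"))
    x = raster.values.astype(np.float64)
    trips = set()
    while len(trips) < min(n_triplets, n * (n - 1) * (n - 2) // 6):
        i, j, k = sorted(rng.choice(n, size=3, replace=False))
        trips.add((i, j, k))
    trips = sorted(trips)
    t_data = np.array([(x[i] * x[j] * x[k]).mean() for i, j, k in trips])
    if n <= _exact.MAX_EXACT_N:
        bits = _exact.state_bits(n)
        p = np.exp(_exact.log_probs(model.h, model.J, model.lam))
        t_model = np.array([p @ (bits[:, i] * bits[:, j] * bits[:, k]) for i, j, k in trips])
    else:
        samples = _gibbs.gibbs_sample_states(
            model.h, model.J, model.lam, 1.0,
            (rng.random(n) < data.rates).astype(np.uint8),
            200, 1, 50_000, child_seed(seed, "gof-samples"),
        ).astype(np.float64)
        t_model = np.array([(samples[:, i] * samples[:, j] * samples[:, k]).mean()
                            for i, j, k in trips])
    report.triplet_data = t_data
    report.triplet_model = t_model
    if t_data.std() > 0 and t_model.std() > 0:
        report.triplet_r = float(np.corrcoef(t_data, t_model)[0, 1])

    if n <= _exact.MAX_EXACT_N:
        idx = _exact.state_index(raster.values.T)
        counts = np.bincount(idx, minlength=2**n)
        seen = np.nonzero(counts >= min_state_count)[0]
        if seen.size:
            logp = _exact.log_probs(model.h, model.J, model.lam)
            report.state_logp_model = logp[seen]
            report.state_logp_data = np.log(counts[seen] / raster.n_bins)
    return report
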