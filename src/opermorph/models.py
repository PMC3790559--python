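"""Maximum-likelihood BM / OU / EB models of continuous trait evolution.

All three models treat the tip vector as multivariate normal.  Under Brownian
motion (BM) the covariance of two tips is ``sigma2`` times their shared path
length from the root.  The single-optimum, fixed-root Ornstein–Uhlenbeck (OU)
model pulls the trait toward the root state with strength ``alpha``; its tip
covariance is ``sigma2/(2 alpha) * (1 - exp(-2 alpha s)) * exp(-2 alpha (T - s))``
for shared time ``s`` on a tree of depth ``T``.  The early-burst (EB) model is
BM with an exponentially decaying rate ``sigma2 * exp(a t)`` (``a <= 0``),
equivalent to BM on a branch-length-transformed tree.

Likelihoods are evaluated by the linear-time pruning recursion; for OU on an
ultrametric tree the covariance is realized exactly by a node-height transform
so the same recursion applies.  ``z0`` and ``sigma2`` have closed-form MLEs at
fixed ``alpha``/``a``, so fitting reduces to a bounded one-dimensional search.

Model comparison uses AICc and Akaike weights
``w_i = exp(-delta_i/2) / sum_j exp(-delta_j/2)`` with
``delta_i = AICc_i - min AICc``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .phylo import Phylogeny

__all__ = ["ModelParams", "ModelFitResult", "ModelComparison", "bm_loglik",
           "ou_loglik", "eb_transform", "fit_model", "compare_models",
           "akaike_weights"]

MODELS = ("BM", "OU", "EB")
_PARAM_COUNT = {"BM": 2, "OU": 3, "EB": 3}


@dataclass
class ModelParams:
    model: str
    sigma2: float
    z0: float
    alpha: float | None = None   # OU attraction, 1/time
    a: float | None = None       # EB rate-change exponent, 1/time, <= 0


@dataclass
class ModelFitResult:
    params: ModelParams
    logL: float
    k: int
    n: int
    AIC: float
    AICc: float
    converged: bool

    @property
    def model(self) -> str:
        return self.params.model


@dataclass
class ModelComparison:
    fits: list[ModelFitResult]
    delta: np.ndarray
    weights: np.ndarray

    def frame(self) -> pd.DataFrame:
        rows = []
        for fit, d, w in zip(self.fits, self.delta, self.weights):
            rows.append({
                "model": fit.model, "logL": fit.logL, "k": fit.k,
                "AIC": fit.AIC, "AICc": fit.AICc, "dAICc": d, "weight": w,
                "sigma2": fit.params.sigma2, "z0": fit.params.z0,
                "alpha": fit.params.alpha, "a": fit.params.a,
                "converged": fit.converged,
            })
        return pd.DataFrame(rows).set_index("model")


# ------------------------------------------------------------------ pruning

def _prune(tree: Phylogeny, lengths: np.ndarray, x: np.ndarray
           ) -> tuple[float, float, float, float]:
    """One pruning pass with unit rate.

    Returns ``(ss, sum_log_v, x_root, v_root)`` where ``ss`` is the summed
    standardized squared contrast, ``sum_log_v`` the summed log contrast
    variances, and ``x_root``/``v_root`` the root's conditional value and
    variance.  Multifurcations are folded pairwise (equivalent to resolving
    with zero-length branches).
    """
    n = tree.n_tips
    val = np.empty(tree.n_nodes)
    val[:n] = x
    extra = np.zeros(tree.n_nodes)
    ss = 0.0
    slv = 0.0
    for v in tree.postorder:
        if v < n:
            continue
        kids = tree.children[v]
        acc_x = val[kids[0]]
        acc_v = extra[kids[0]] + lengths[kids[0]]
        for c in kids[1:]:
            Vc = extra[c] + lengths[c]
            Vsum = acc_v + Vc
            if Vsum <= 0:
                raise np.linalg.LinAlgError(
                    "singular covariance: sister branches of zero length "
                    "(duplicate tips at identical positions)"
                )
            ss += (acc_x - val[c]) ** 2 / Vsum
            slv += np.log(Vsum)
            acc_x = (acc_x * Vc + val[c] * acc_v) / Vsum
            acc_v = acc_v * Vc / Vsum
        val[v] = acc_x
        extra[v] = acc_v
    v_root = extra[tree.root] + lengths[tree.root]
    if v_root <= 0:
        raise np.linalg.LinAlgError("singular covariance at the root")
    return ss, slv, val[tree.root], v_root


def _loglik_from_prune(ss, slv, x_root, v_root, n, sigma2, z0) -> float:
    ss_total = ss + (x_root - z0) ** 2 / v_root
    return (-0.5 * n * np.log(2 * np.pi * sigma2)
            - 0.5 * (slv + np.log(v_root))
            - ss_total / (2 * sigma2))


def _profile(ss, slv, x_root, v_root, n) -> tuple[float, float, float]:
    """MLEs of ``(z0, sigma2)`` and the maximized log-likelihood."""
    z0 = x_root
    sigma2 = ss / n
    if sigma2 <= 0:
        return z0, sigma2, np.inf   # degenerate (constant trait); caller flags
    logL = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1) - 0.5 * (slv + np.log(v_root))
    return z0, sigma2, logL


def _align_trait(tree: Phylogeny, trait) -> np.ndarray:
    if isinstance(trait, pd.Series):
        missing = [s for s in tree.tip_labels if s not in trait.index]
        if missing:
            raise ValueError(f"missing trait values for species: {missing}")
        return trait.loc[tree.tip_labels].to_numpy(dtype=float)
    arr = np.asarray(trait, dtype=float)
    if arr.shape != (tree.n_tips,):
        raise ValueError("trait must give one value per tip")
    return arr


# -------------------------------------------------------------- likelihoods

def bm_loglik(tree: Phylogeny, trait, sigma2: float, z0: float) -> float:
    """Brownian-motion log-likelihood of the tip vector."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    x = _align_trait(tree, trait)
    ss, slv, xr, vr = _prune(tree, tree.blen, x)
    return float(_loglik_from_prune(ss, slv, xr, vr, tree.n_tips, sigma2, z0))


def _ou_lengths(tree: Phylogeny, alpha: float) -> np.ndarray:
    """Branch lengths realizing the OU covariance as a BM tree (ultrametric)."""
    if alpha <= 1e-12:
        return tree.blen
    T = tree.depth
    t = tree.node_times

    def h(ts):
        return (np.exp(-2 * alpha * (T - ts)) - np.exp(-2 * alpha * T)) / (2 * alpha)

    hp = h(np.where(tree.parent >= 0, t[np.maximum(tree.parent, 0)], 0.0))
    lengths = h(t) - hp
    lengths[tree.root] = 0.0
    return lengths


def ou_loglik(tree: Phylogeny, trait, sigma2: float, alpha: float, z0: float
              ) -> float:
    """Single-optimum fixed-root OU log-likelihood (optimum = root state)."""
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    x = _align_trait(tree, trait)
    if not tree.is_ultrametric():
        warnings.warn("OU covariance transform assumes an ultrametric tree; "
                      "using dense evaluation")
        return _ou_dense_loglik(tree, x, sigma2, alpha, z0)
    ss, slv, xr, vr = _prune(tree, _ou_lengths(tree, alpha), x)
    return float(_loglik_from_prune(ss, slv, xr, vr, tree.n_tips, sigma2, z0))


def _ou_dense_loglik(tree: Phylogeny, x: np.ndarray, sigma2, alpha, z0) -> float:
    from scipy.stats import multivariate_normal

    S = tree.vcv()
    tip_t = tree.node_times[: tree.n_tips]
    if alpha <= 1e-12:
        V = sigma2 * S
    else:
        Tij = 0.5 * (tip_t[:, None] + tip_t[None, :])
        V = (sigma2 / (2 * alpha)) * (1 - np.exp(-2 * alpha * S)) \
            * np.exp(-2 * alpha * (Tij - S))
    return float(multivariate_normal.logpdf(x, mean=np.full(len(x), z0), cov=V))


def eb_transform(tree: Phylogeny, a: float) -> Phylogeny:
    """Early-burst branch-length transform.

    A branch spanning node times ``(t1, t2)`` gets length
    ``(exp(a t2) - exp(a t1)) / a`` (unchanged at ``a = 0``), so BM on the
    transformed tree has rate ``sigma2 * exp(a t)`` on the original.
    """
    if a > 0:
        raise ValueError("EB rate-change parameter a must be <= 0")
    if a == 0:
        return tree
    t = tree.node_times
    tp = np.where(tree.parent >= 0, t[np.maximum(tree.parent, 0)], 0.0)
    lengths = (np.exp(a * t) - np.exp(a * tp)) / a
    lengths[tree.root] = 0.0
    return tree.with_lengths(lengths)


def eb_loglik(tree: Phylogeny, trait, sigma2: float, a: float, z0: float
              ) -> float:
    """Early-burst log-likelihood: BM on the EB-transformed tree."""
    return bm_loglik(eb_transform(tree, a), trait, sigma2, z0)


# ------------------------------------------------------------------ fitting

def _fit_profiled(tree: Phylogeny, x: np.ndarray, lengths_for, grid):
    """Maximize the profiled likelihood over one shape parameter.

    ``grid`` is an ascending array of starting values whose first/last entries
    are the search bounds (log-spaced interior points let the search span
    orders of magnitude); the best grid point is refined by bounded
    minimization in its bracketing interval.
    """
    n = tree.n_tips

    def neg_profile(theta: float) -> float:
        try:
            ss, slv, xr, vr = _prune(tree, lengths_for(theta), x)
        except np.linalg.LinAlgError:
            return np.inf
        _, s2, logL = _profile(ss, slv, xr, vr, n)
        return np.inf if not np.isfinite(logL) else -logL

    grid = np.asarray(grid, dtype=float)
    lo, hi = grid[0], grid[-1]
    vals = np.array([neg_profile(g) for g in grid])
    best = int(np.argmin(vals))
    a_lo = grid[max(best - 1, 0)]
    a_hi = grid[min(best + 1, len(grid) - 1)]
    converged = np.isfinite(vals[best])
    theta = grid[best]
    if a_hi > a_lo:
        res = minimize_scalar(neg_profile, bounds=(a_lo, a_hi),
                              method="bounded",
                              options={"xatol": 1e-8 * max(abs(hi - lo), 1.0)})
        if res.success and res.fun <= vals[best] + 1e-12:
            theta = float(res.x)
            converged = converged and np.isfinite(res.fun)
    ss, slv, xr, vr = _prune(tree, lengths_for(theta), x)
    z0, s2, logL = _profile(ss, slv, xr, vr, n)
    if not np.isfinite(logL):
        converged = False
    return theta, z0, s2, logL, converged


def fit_model(tree: Phylogeny, trait, model: str,
              alpha_max: float | None = None,
              a_min: float | None = None) -> ModelFitResult:
    """ML fit of one evolutionary model to one trait.

    ``z0`` and ``sigma2`` are profiled analytically; OU's ``alpha`` (in
    ``[0, alpha_max]``, default ``alpha_max = 50/T``) and EB's ``a`` (in
    ``[log(1e-5)/T, 0]``) are found by bounded search seeded from a grid, so
    the boundary (BM) is always a candidate and the nesting
    ``logL_OU, logL_EB >= logL_BM`` holds up to optimizer tolerance.
    """
    model = model.upper()
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    if tree.n_tips < 4:
        raise ValueError("need at least 4 tips to fit a model")
    x = _align_trait(tree, trait)
    n = tree.n_tips
    k = _PARAM_COUNT[model]
    if n <= k + 1:
        raise ValueError(f"AICc undefined: need n > k + 1 = {k + 1}")
    T = tree.depth

    if model == "BM":
        ss, slv, xr, vr = _prune(tree, tree.blen, x)
        z0, s2, logL = _profile(ss, slv, xr, vr, n)
        converged = np.isfinite(logL) and s2 > 0
        params = ModelParams("BM", sigma2=s2, z0=z0)
    elif model == "OU":
        hi = alpha_max if alpha_max is not None else 50.0 / T
        grid = np.concatenate([[0.0], np.geomspace(1e-4 * hi, hi, 14)])
        theta, z0, s2, logL, converged = _fit_profiled(
            tree, x, lambda al: _ou_lengths(tree, al), grid)
        params = ModelParams("OU", sigma2=s2, z0=z0, alpha=theta)
    else:  # EB
        lo = a_min if a_min is not None else np.log(1e-5) / T
        grid = np.sort(np.concatenate(
            [[0.0], -np.geomspace(1e-4 * abs(lo), abs(lo), 14)]))
        theta, z0, s2, logL, converged = _fit_profiled(
            tree, x, lambda a: eb_transform(tree, a).blen, grid)
        params = ModelParams("EB", sigma2=s2, z0=z0, a=theta)

    if not np.isfinite(logL):
        logL = -np.inf
        converged = False
    aic = 2 * k - 2 * logL
    aicc = aic + 2 * k * (k + 1) / (n - k - 1)
    return ModelFitResult(params=params, logL=float(logL), k=k, n=n,
                          AIC=float(aic), AICc=float(aicc),
                          converged=bool(converged))


def akaike_weights(aicc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Akaike weights from AICc values: ``(delta, weights)``."""
    aicc = np.asarray(aicc, dtype=float)
    delta = aicc - aicc.min()
    w = np.exp(-delta / 2)
    return delta, w / w.sum()


def compare_models(fits: list[ModelFitResult]) -> ModelComparison:
    """Rank fitted models by AICc and attach Akaike weights."""
    if len(fits) < 2:
        raise ValueError("need at least 2 fits to compare")
    ns = {f.n for f in fits}
    if len(ns) != 1:
        raise ValueError(f"fits are not on the same data (n differs: {sorted(ns)})")
    delta, weights = akaike_weights(np.asarray([f.AICc for f in fits]))
    return ModelComparison(fits=list(fits), delta=delta, weights=weights)


def fit_all_models(tree: Phylogeny, trait, models=MODELS) -> ModelComparison:
    """Fit several models to one trait and compare them by AICc weight."""
    return compare_models([fit_model(tree, trait, m) for m in models])
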