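"""Morphological disparity, disparity through time, and the MDI statistic.

Disparity is the average pairwise Euclidean distance among species in shape
(eigenshape score) space; a mean squared-distance option is also provided.
The disparity-through-time (DTT) curve evaluates, at the time of each internal
node, the mean of subclade disparity over whole-clade disparity across all
lineages present at that instant, and is compared against simulations of
multivariate Brownian motion whose rate matrix is estimated from the tip data
by independent contrasts.  The morphological disparity index (MDI) is the
signed area between the observed curve and the median null curve, omitting
the most recent fraction of relative time (default 20%) where incomplete
taxon sampling over-disperses the tips.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .phylo import Phylogeny

__all__ = ["DTTResult", "pairwise_disparity", "clade_disparity",
           "per_species_standardization", "dtt_curve", "bm_null_envelope",
           "mdi", "disparity_through_time"]


@dataclass
class DTTResult:
    node_times: np.ndarray       # relative time in [0, 1], ascending
    observed: np.ndarray
    null_median: np.ndarray
    null_curves: np.ndarray      # (n_sim, n_times)
    MDI: float
    truncation: float
    n_sim: int
    seed: int

    def frame(self) -> pd.DataFrame:
        lo = np.quantile(self.null_curves, 0.025, axis=0)
        hi = np.quantile(self.null_curves, 0.975, axis=0)
        return pd.DataFrame({
            "rel_time": self.node_times,
            "observed": self.observed,
            "null_median": self.null_median,
            "null_q025": lo,
            "null_q975": hi,
        })


def pairwise_disparity(points: np.ndarray, squared: bool = False) -> float:
    """Mean pairwise Euclidean distance over rows (0 for a single row).

    With ``squared=True`` the mean squared distance is returned instead.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] == 0:
        raise ValueError("points must have at least one dimension")
    if pts.shape[0] < 2:
        return 0.0
    d = pdist(pts)
    return float(np.mean(d**2) if squared else np.mean(d))


def clade_disparity(scores: pd.DataFrame, clade_map: Mapping[str, str]
                    ) -> pd.DataFrame:
    """Summed tip disparity per clade, with a per-species standardization.

    Each tip's contribution is its mean squared distance to all other species
    divided by the sample-wide mean of those values, so contributions average
    1 and clade sums are comparable across data sets.  The standardized value
    divides the clade sum by the number of sampled species in the clade.
    """
    clades = pd.Series(dict(clade_map))
    missing = set(scores.index) - set(clades.index)
    if missing:
        raise ValueError(f"species without clade assignment: {sorted(missing)}")
    clades = clades.loc[scores.index]
    X = scores.to_numpy(dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 species")
    from scipy.spatial.distance import squareform

    D2 = squareform(pdist(X)) ** 2
    tip_msd = D2.sum(axis=1) / (n - 1)
    rel = tip_msd / tip_msd.mean()
    rows = []
    for clade in clades.unique():
        mask = (clades == clade).to_numpy()
        k = int(mask.sum())
        if k == 0:
            raise ValueError(f"clade {clade!r} has no sampled species")
        value = float(rel[mask].sum())
        rows.append({"clade": clade, "disparity": value, "n_species": k,
                     "per_species": per_species_standardization(value, k)})
    return pd.DataFrame(rows).set_index("clade")


def per_species_standardization(clade_value: float, n_species: int) -> float:
    """Standardize a clade disparity by its sampled species count."""
    if n_species < 1:
        raise ValueError("clade must contain at least one species")
    return clade_value / n_species


def _align_scores(tree: Phylogeny, scores: pd.DataFrame) -> np.ndarray:
    extra = set(scores.index) - set(tree.tip_labels)
    missing = set(tree.tip_labels) - set(scores.index)
    if extra or missing:
        raise ValueError(
            "species sets differ between tree and scores; "
            f"missing from scores: {sorted(missing)}; not in tree: {sorted(extra)}"
        )
    return scores.loc[tree.tip_labels].to_numpy(dtype=float)


class _DTTStructure:
    """Cached per-tree geometry for fast repeated DTT evaluation."""

    def __init__(self, tree: Phylogeny):
        if tree.n_tips < 3:
            raise ValueError("DTT needs a tree with at least 3 tips")
        self.tree = tree
        n = tree.n_tips
        times = np.unique(tree.node_times[n:])
        self.abs_times = times
        self.rel_times = times / tree.depth
        desc = tree.descendant_tips()
        # condensed pdist indices for every node's descendant tip set
        self.pair_idx: list[np.ndarray] = []
        for v in range(tree.n_nodes):
            tips = np.sort(desc[v])
            if len(tips) < 2:
                self.pair_idx.append(np.empty(0, dtype=np.intp))
                continue
            ii, jj = np.triu_indices(len(tips), k=1)
            a, b = tips[ii], tips[jj]
            self.pair_idx.append(a * n - a * (a + 1) // 2 + (b - a - 1))
        # lineages present at each node time: branches spanning (t_parent, t]
        parent_t = np.where(tree.parent >= 0,
                            tree.node_times[np.maximum(tree.parent, 0)], 0.0)
        self.crossing: list[np.ndarray] = []
        for t in times:
            if t <= times[0]:
                self.crossing.append(np.asarray([tree.root], dtype=np.intp))
                continue
            mask = (tree.parent >= 0) & (parent_t < t) & (tree.node_times >= t)
            self.crossing.append(np.flatnonzero(mask))

    def curve(self, X: np.ndarray, squared: bool = False) -> np.ndarray:
        d = pdist(X)
        if squared:
            d = d**2
        total = d.mean()
        if total <= 0:
            raise ValueError("total disparity is zero; curve undefined")
        obs = np.empty(len(self.abs_times))
        for k, nodes in enumerate(self.crossing):
            vals = [
                (self.pair_idx[v].size and d[self.pair_idx[v]].mean()) or 0.0
                for v in nodes
            ]
            obs[k] = np.mean(vals) / total
        return obs


def dtt_curve(tree: Phylogeny, scores: pd.DataFrame, squared: bool = False
              ) -> tuple[np.ndarray, np.ndarray]:
    """Observed relative subclade disparity at each internal node time.

    Returns ``(rel_times, observed)`` with the root first; ``observed[0]`` is
    exactly 1 since the whole clade is the only lineage present at the root.
    """
    st = _DTTStructure(tree)
    X = _align_scores(tree, scores)
    return st.rel_times, st.curve(X, squared=squared)


def bm_null_envelope(tree: Phylogeny, scores: pd.DataFrame,
                     n_sim: int = 1000, seed: int = 0, squared: bool = False
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Brownian null DTT curves with rate structure estimated from the data.

    The multivariate evolutionary variance–covariance of the score columns is
    estimated by independent contrasts, ``n_sim`` multivariate BM data sets
    are simulated on the tree, and the DTT curve of each is computed.  Returns
    ``(null_curves, null_median)``.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    st = _DTTStructure(tree)
    X = _align_scores(tree, scores)
    R = tree.pic_rate_matrix(X)
    rng = np.random.default_rng(seed)
    sims = tree.simulate_bm(R, n_sim, rng)
    curves = np.vstack([st.curve(sims[i], squared=squared)
                        for i in range(n_sim)])
    return curves, np.median(curves, axis=0)


def mdi(observed: np.ndarray, null_median: np.ndarray, node_times: np.ndarray,
        truncation: float = 0.2) -> float:
    """Signed area between observed and null-median DTT curves.

    Trapezoid rule over relative time, restricted to node times at or before
    ``1 - truncation``.  Positive values mean observed disparity exceeds the
    Brownian expectation (disparity concentrated within subclades of the
    modern fauna).
    """
    t = np.asarray(node_times, dtype=float)
    obs = np.asarray(observed, dtype=float)
    med = np.asarray(null_median, dtype=float)
    if not (t.shape == obs.shape == med.shape):
        raise ValueError("curves must share node_times")
    mask = t <= (1.0 - truncation) + 1e-12
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid((obs - med)[mask], t[mask]))


def disparity_through_time(tree: Phylogeny, scores: pd.DataFrame,
                           n_sim: int = 1000, truncation: float = 0.2,
                           seed: int = 0, squared: bool = False) -> DTTResult:
    """Full DTT analysis: observed curve, BM envelope, and MDI."""
    rel_times, observed = dtt_curve(tree, scores, squared=squared)
    curves, med = bm_null_envelope(tree, scores, n_sim=n_sim, seed=seed,
                                   squared=squared)
    value = mdi(observed, med, rel_times, truncation=truncation)
    return DTTResult(node_times=rel_times, observed=observed, null_median=med,
                     null_curves=curves, MDI=value, truncation=truncation,
                     n_sim=n_sim, seed=seed)
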