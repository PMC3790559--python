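"""Phylomorphospace projections: ancestral eigenshape scores on the tree.

Ancestral states are maximum-likelihood estimates under Brownian motion,
equivalently branch-length-weighted squared-change parsimony: the internal
node values minimize ``sum over edges (delta value)^2 / branch length``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phylo import Phylogeny

__all__ = ["Phylomorphospace", "ancestral_states", "project"]

_MIN_BLEN = 1e-12


@dataclass
class Phylomorphospace:
    """Tip and internal-node coordinates for one pair of shape axes."""

    axis_pair: tuple[str, str]
    tip_coords: pd.DataFrame        # species x 2
    node_coords: pd.DataFrame       # internal node id x 2
    edges: list[tuple[int, int]]    # parent -> child node ids

    def edges_frame(self, tree: Phylogeny) -> pd.DataFrame:
        rows = []
        coords = {}
        for i, sp in enumerate(self.tip_coords.index):
            coords[i] = self.tip_coords.loc[sp].to_numpy()
        for v, row in self.node_coords.iterrows():
            coords[v] = row.to_numpy()
        for p, c in self.edges:
            label = tree.tip_labels[c] if c < tree.n_tips else ""
            rows.append({
                "parent": p, "child": c, "child_label": label,
                "x0": coords[p][0], "y0": coords[p][1],
                "x1": coords[c][0], "y1": coords[c][1],
            })
        return pd.DataFrame(rows)


def ancestral_states(tree: Phylogeny, tip_values: pd.Series | np.ndarray
                     ) -> np.ndarray:
    """ML Brownian ancestral states for one trait.

    ``tip_values`` is a per-species scalar, either an array ordered like
    ``tree.tip_labels`` or a Series indexed by species.  Returns values for
    all nodes (tips echo the data).  States solve the weighted least-squares
    normal equations of squared-change parsimony, so each internal node is the
    branch-length-weighted mean of its neighbors.
    """
    x = _align(tree, tip_values)
    n_int = tree.n_nodes - tree.n_tips
    idx = {v: i for i, v in enumerate(range(tree.n_tips, tree.n_nodes))}
    A = np.zeros((n_int, n_int))
    b = np.zeros(n_int)
    for v in range(tree.n_nodes):
        p = tree.parent[v]
        if p < 0:
            continue
        w = 1.0 / max(tree.blen[v], _MIN_BLEN)
        vi = idx.get(v)
        pi = idx[int(p)]
        A[pi, pi] += w
        if vi is None:                 # tip child: known value
            b[pi] += w * x[v]
        else:
            A[vi, vi] += w
            A[vi, pi] -= w
            A[pi, vi] -= w
    states = np.empty(tree.n_nodes)
    states[: tree.n_tips] = x[: tree.n_tips]
    states[tree.n_tips:] = np.linalg.solve(A, b)
    return states


def project(tree: Phylogeny, scores: pd.DataFrame,
            axis_pair: tuple[int, int] | tuple[str, str] = (1, 2)
            ) -> Phylomorphospace:
    """Project species-mean scores and BM ancestral states into a plane.

    ``scores`` has one row per species (means over specimens, taken before
    projection) and columns named ``ES1, ES2, ...``.  ``axis_pair`` may give
    1-based axis numbers or column names.
    """
    cols = [a if isinstance(a, str) else f"ES{a}" for a in axis_pair]
    for c in cols:
        if c not in scores.columns:
            raise ValueError(f"axis {c!r} not present in scores")
    missing = set(tree.tip_labels) - set(scores.index)
    if missing:
        raise ValueError(f"species in tree absent from scores: {sorted(missing)}")
    tip_xy = scores.loc[tree.tip_labels, cols]
    node_vals = {c: ancestral_states(tree, scores[c]) for c in cols}
    internal = list(range(tree.n_tips, tree.n_nodes))
    node_coords = pd.DataFrame(
        {c: node_vals[c][internal] for c in cols}, index=internal
    )
    edges = [(int(tree.parent[v]), v) for v in range(tree.n_nodes)
             if tree.parent[v] >= 0]
    return Phylomorphospace(
        axis_pair=(cols[0], cols[1]),
        tip_coords=tip_xy,
        node_coords=node_coords,
        edges=edges,
    )


def _align(tree: Phylogeny, tip_values) -> np.ndarray:
    if isinstance(tip_values, pd.Series):
        missing = [s for s in tree.tip_labels if s not in tip_values.index]
        if missing:
            raise ValueError(f"missing tip values for species: {missing}")
        arr = tip_values.loc[tree.tip_labels].to_numpy(dtype=float)
    else:
        arr = np.asarray(tip_values, dtype=float)
        if arr.shape != (tree.n_tips,):
            raise ValueError("tip_values must give one value per tip")
    if not np.all(np.isfinite(arr)):
        bad = [tree.tip_labels[i] for i in np.flatnonzero(~np.isfinite(arr))]
        raise ValueError(f"non-finite tip values for species: {bad}")
    return arr
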