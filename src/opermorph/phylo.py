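"""Rooted time-calibrated phylogenies as flat arrays.

The :class:`Phylogeny` container stores a rooted tree as parent/branch-length
arrays with tips occupying node ids ``0 .. n_tips-1``.  All comparative
machinery in this package (pruning likelihoods, ancestral states, disparity
through time, Brownian simulation) runs on these arrays; dendropy is used only
to parse and serialize Newick.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = ["Phylogeny", "read_newick"]

_TINY = 1e-12


class Phylogeny:
    """A rooted tree with branch lengths in time units.

    Parameters
    ----------
    parent : array of int
        Parent node id per node; the root has parent ``-1``.  Node ids
        ``0 .. n_tips-1`` must be the tips.
    blen : array of float
        Length of the branch subtending each node (0 for the root).
    tip_labels : sequence of str
        Species names for tips ``0 .. n_tips-1``.
    """

    def __init__(self, parent: Sequence[int], blen: Sequence[float],
                 tip_labels: Sequence[str]):
        self.parent = np.asarray(parent, dtype=np.intp)
        self.blen = np.asarray(blen, dtype=float)
        self.tip_labels = list(tip_labels)
        self.n_nodes = len(self.parent)
        self.n_tips = len(self.tip_labels)
        if self.n_nodes != len(self.blen):
            raise ValueError("parent and blen length mismatch")
        if len(set(self.tip_labels)) != self.n_tips:
            raise ValueError("tip labels are not unique")
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise ValueError("tree must have exactly one root")
        self.root = int(roots[0])
        children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for v in range(self.n_nodes):
            p = self.parent[v]
            if p >= 0:
                children[p].append(v)
        for v in range(self.n_tips):
            if children[v]:
                raise ValueError(f"node {v} is labelled as a tip but has children")
        self.children = children
        # preorder via explicit stack; reversed preorder is a valid postorder
        pre = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            pre.append(v)
            stack.extend(reversed(children[v]))
        self.preorder = np.asarray(pre, dtype=np.intp)
        self.postorder = self.preorder[::-1].copy()
        t = np.zeros(self.n_nodes)
        for v in pre[1:]:
            t[v] = t[self.parent[v]] + self.blen[v]
        self.node_times = t
        self.depth = float(t[: self.n_tips].max())
        self._desc: list[np.ndarray] | None = None

    # ------------------------------------------------------------------ IO

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        nodes = list(tree.preorder_node_iter())
        tips = [nd for nd in nodes if nd.is_leaf()]
        internals = [nd for nd in nodes if not nd.is_leaf()]
        index = {id(nd): i for i, nd in enumerate(tips)}
        for j, nd in enumerate(internals):
            index[id(nd)] = len(tips) + j
        n = len(nodes)
        parent = np.full(n, -1, dtype=np.intp)
        blen = np.zeros(n)
        labels = []
        for nd in tips:
            tax = nd.taxon.label if nd.taxon else (nd.label or "")
            labels.append(str(tax))
        for nd in nodes:
            i = index[id(nd)]
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                if nd.edge.length is None:
                    raise ValueError(
                        f"branch length missing above node {labels[i] if i < len(tips) else i}"
                    )
                blen[i] = float(nd.edge.length)
        return cls(parent, blen, labels)

    @classmethod
    def from_newick(cls, source: str) -> "Phylogeny":
        """Parse a Newick string or file path (branch lengths required)."""
        import os

        if os.path.exists(source):
            tree = dendropy.Tree.get(path=source, schema="newick")
        else:
            tree = dendropy.Tree.get(data=source, schema="newick")
        return cls.from_dendropy(tree)

    def to_newick(self) -> str:
        def fmt(v: int) -> str:
            if v < self.n_tips:
                body = _quote(self.tip_labels[v])
            else:
                body = "(" + ",".join(fmt(c) for c in self.children[v]) + ")"
            if v == self.root:
                return body
            return f"{body}:{self.blen[v]:.10g}"

        return fmt(self.root) + ";"

    def write_newick(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    # ------------------------------------------------------------ structure

    def is_ultrametric(self, rtol: float = 1e-6) -> bool:
        tip_t = self.node_times[: self.n_tips]
        return bool(tip_t.max() - tip_t.min() <= rtol * max(self.depth, _TINY))

    def descendant_tips(self) -> list[np.ndarray]:
        """Tip ids under each node (cached)."""
        if self._desc is None:
            desc: list = [None] * self.n_nodes
            for v in self.postorder:
                if v < self.n_tips:
                    desc[v] = np.asarray([v], dtype=np.intp)
                else:
                    desc[v] = np.concatenate([desc[c] for c in self.children[v]])
            self._desc = desc
        return self._desc

    def tip_index(self, species: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.tip_labels)}
        missing = [s for s in species if s not in lookup]
        if missing:
            raise ValueError(f"species not in tree: {sorted(missing)}")
        return np.asarray([lookup[s] for s in species], dtype=np.intp)

    def vcv(self) -> np.ndarray:
        """Brownian tip covariance structure: shared path length from root."""
        desc = self.descendant_tips()
        C = np.zeros((self.n_tips, self.n_tips))
        for v in self.postorder:
            if v < self.n_tips:
                continue
            kids = self.children[v]
            t = self.node_times[v]
            for i in range(len(kids)):
                for j in range(i + 1, len(kids)):
                    a, b = desc[kids[i]], desc[kids[j]]
                    C[np.ix_(a, b)] = t
                    C[np.ix_(b, a)] = t
        np.fill_diagonal(C, self.node_times[: self.n_tips])
        return C

    def branching_times(self) -> np.ndarray:
        """Times (from the root) of internal nodes, ascending."""
        internal = np.asarray(
            [v for v in range(self.n_nodes) if v >= self.n_tips], dtype=np.intp
        )
        return np.sort(self.node_times[internal])

    def with_lengths(self, blen: np.ndarray) -> "Phylogeny":
        return Phylogeny(self.parent.copy(), np.asarray(blen, dtype=float),
                         list(self.tip_labels))

    def rescaled_to_depth(self, depth: float) -> "Phylogeny":
        if self.depth <= 0:
            raise ValueError("tree has zero depth")
        return self.with_lengths(self.blen * (depth / self.depth))

    def clades(self, k: int) -> dict[str, list[str]]:
        """Partition tips into ``k`` monophyletic groups by the earliest splits.

        The root and successively the oldest remaining internal node are
        replaced by their children until ``k`` subtree roots remain.
        """
        if not (1 <= k <= self.n_tips):
            raise ValueError("need 1 <= k <= n_tips")
        roots = [self.root]
        while len(roots) < k:
            internal = [v for v in roots if v >= self.n_tips]
            if not internal:
                raise ValueError(f"tree cannot be cut into {k} clades")
            v = min(internal, key=lambda u: self.node_times[u])
            roots.remove(v)
            roots.extend(self.children[v])
        desc = self.descendant_tips()
        out = {}
        for i, v in enumerate(sorted(roots, key=lambda u: -len(desc[u]))):
            out[f"clade{chr(ord('A') + i)}"] = [self.tip_labels[t] for t in desc[v]]
        return out

    # ----------------------------------------------------------- simulation

    def simulate_bm(self, rate: np.ndarray | float, n_rep: int,
                    rng: np.random.Generator, root_state: float = 0.0
                    ) -> np.ndarray:
        """Simulate (multivariate) Brownian motion to the tips.

        ``rate`` is either a scalar variance per unit time or a d×d
        evolutionary rate (variance–covariance) matrix.  Returns an array of
        shape ``(n_rep, n_tips, d)``.
        """
        R = np.atleast_2d(np.asarray(rate, dtype=float))
        d = R.shape[0]
        L = np.linalg.cholesky(R + _TINY * np.eye(d))
        z = rng.standard_normal((n_rep, self.n_nodes, d))
        inc = (z @ L.T) * np.sqrt(self.blen)[None, :, None]
        x = np.zeros((n_rep, self.n_nodes, d))
        for v in self.preorder[1:]:
            x[:, v] = x[:, self.parent[v]] + inc[:, v]
        return x[:, : self.n_tips, :] + root_state

    def pic_rate_matrix(self, X: np.ndarray) -> np.ndarray:
        """Evolutionary rate matrix from phylogenetically independent contrasts.

        ``X`` is an ``(n_tips, d)`` matrix of tip values.  Contrasts are
        accumulated by the standard pruning pass; the returned matrix is
        ``sum(u u^T / V) / (n_contrasts)``.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != self.n_tips:
            raise ValueError("one row per tip required")
        d = X.shape[1]
        val = np.zeros((self.n_nodes, d))
        val[: self.n_tips] = X
        extra = np.zeros(self.n_nodes)
        M = np.zeros((d, d))
        n_c = 0
        for v in self.postorder:
            if v < self.n_tips:
                continue
            kids = self.children[v]
            acc_x = val[kids[0]]
            acc_v = extra[kids[0]] + self.blen[kids[0]]
            for c in kids[1:]:
                Vc = extra[c] + self.blen[c]
                Vsum = acc_v + Vc
                if Vsum <= 0:
                    raise np.linalg.LinAlgError(
                        "zero-length sister branches give a singular contrast"
                    )
                u = acc_x - val[c]
                M += np.outer(u, u) / Vsum
                n_c += 1
                acc_x = (acc_x * Vc + val[c] * acc_v) / Vsum
                acc_v = acc_v * Vc / Vsum
            val[v] = acc_x
            extra[v] = acc_v
        return M / n_c


def read_newick(source: str) -> Phylogeny:
    """Convenience wrapper over :meth:`Phylogeny.from_newick`."""
    tree = Phylogeny.from_newick(source)
    if not tree.is_ultrametric():
        warnings.warn("tree is not ultrametric within 1e-6 of its depth")
    return tree


def _quote(label: str) -> str:
    import re

    if re.search(r"[\s,():;\[\]']", label):
        return "'" + label.replace("'", "''") + "'"
    return label
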