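"""Optional matplotlib plots for phylomorphospace and DTT results."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .disparity import DTTResult
from .morphospace import Phylomorphospace
from .phylo import Phylogeny

__all__ = ["plot_phylomorphospace", "plot_dtt"]


def plot_phylomorphospace(pm: Phylomorphospace, tree: Phylogeny, path: str,
                          clade_map: dict[str, str] | None = None) -> None:
    fig, ax = plt.subplots(figsize=(6, 5))
    coords = {}
    for i, sp in enumerate(pm.tip_coords.index):
        coords[i] = pm.tip_coords.loc[sp].to_numpy()
    for v, row in pm.node_coords.iterrows():
        coords[v] = row.to_numpy()
    for p, c in pm.edges:
        xy0, xy1 = coords[p], coords[c]
        ax.plot([xy0[0], xy1[0]], [xy0[1], xy1[1]], color="0.6", lw=0.8,
                zorder=1)
    clades = sorted({(clade_map or {}).get(sp, "") for sp in pm.tip_coords.index})
    palette = {c: f"C{i}" for i, c in enumerate(clades)}
    for sp, row in pm.tip_coords.iterrows():
        color = palette[(clade_map or {}).get(sp, "")]
        ax.scatter(row.iloc[0], row.iloc[1], s=25, color=color, zorder=2)
    root_xy = coords[tree.root]
    ax.scatter(*root_xy, s=70, facecolors="none", edgecolors="k", zorder=3)
    ax.set_xlabel(pm.axis_pair[0])
    ax.set_ylabel(pm.axis_pair[1])
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_dtt(dtt: DTTResult, path: str) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    frame = dtt.frame()
    ax.fill_between(frame["rel_time"], frame["null_q025"], frame["null_q975"],
                    color="0.85", label="BM 95% envelope")
    ax.plot(frame["rel_time"], frame["null_median"], "k--",
            label="BM median")
    ax.plot(frame["rel_time"], frame["observed"], "k-", label="observed")
    ax.axvline(1 - dtt.truncation, color="0.5", lw=0.5)
    ax.set_xlabel("relative time (0 = root, 1 = tips)")
    ax.set_ylabel("mean relative subclade disparity")
    ax.set_title(f"MDI = {dtt.MDI:.3f}")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
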