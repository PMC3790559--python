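"""Synthetic study data with the structure the analysis pipeline assumes.

Real opercle photographs for this kind of study are rarely deposited, so this
module generates an end-to-end testable stand-in: a pure-birth ultrametric
phylogeny, species trait values evolved under BM/OU/EB, per-specimen closed
outlines deformed along one known parametric mode in proportion to a species'
trait value, and per-species stable-isotope tables optionally coupled to the
same trait.  Because the deformation mode is known, downstream eigenshape
axes have a ground truth to recover.

Defaults mirror the sampling structure of the motivating study system:
25 species in 4 clades, 1–12 specimens per species, 100-point outlines, and a
tree depth of 23 time units (My).  Digitizing error is modelled as independent
radial Gaussian noise — an assumption, since real digitizing error is not
distributionally characterized.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import models as _models
from .outlines import Outline, write_tps
from .phylo import Phylogeny

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate_tree",
           "simulate_traits", "generate_outlines", "generate_isotopes",
           "generate_dataset", "write_dataset"]

# Fixed outline template: smooth convex base shape (truncated Fourier series
# on the unit circle) with its curvature maximum at parameter 0, where the
# starting landmark is placed.  The deformation mode is a fixed smooth radial
# field; its amplitude stays in the small-deformation regime so the
# tangent-angle response is linear in the trait value.
_TEMPLATE_COEFS = ((2, 0.18, 0.0), (3, 0.07, 1.2))   # (harmonic, amp, phase)
_MODE_AMPLITUDE = 0.06


def _template_radius(theta: np.ndarray) -> np.ndarray:
    r = np.ones_like(theta)
    for h, amp, ph in _TEMPLATE_COEFS:
        r += amp * np.cos(h * theta + ph)
    return r


def _mode(theta: np.ndarray) -> np.ndarray:
    return np.cos(3 * theta + 0.7)


@dataclass
class SyntheticConfig:
    """Configuration of the synthetic study (defaults = study conditions)."""

    n_species: int = 25
    n_clades: int = 4
    specimens_per_species: tuple[int, int] = (1, 12)
    p_points: int = 100
    outline_noise_sd: float = 0.01        # image units (template radius = 1)
    clade_effect_size: float = 1.0        # multiplier on the deformation mode
    tree_depth: float = 23.0              # time units (My)
    trait_model: str = "BM"
    trait_params: dict = field(default_factory=dict)
    isotope_coupling: float = 0.5         # per-mil per trait unit, for d15N
    isotope_noise_sd: float = 0.4         # per mil
    seed: int = 0

    def __post_init__(self):
        if not (self.n_species >= self.n_clades >= 1):
            raise ValueError("need n_species >= n_clades >= 1")
        if self.p_points < 8:
            raise ValueError("p_points must be >= 8")
        if self.outline_noise_sd < 0:
            raise ValueError("outline_noise_sd must be >= 0")
        lo, hi = self.specimens_per_species
        if not (1 <= lo <= hi):
            raise ValueError("specimens_per_species must be a valid range")
        if not self.trait_params:
            # unit tip variance at the study depth
            self.trait_params = {"sigma2": 1.0 / self.tree_depth, "z0": 0.0}


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    tree: Phylogeny
    traits: pd.DataFrame          # species x trait columns
    outlines: list[Outline]
    specimens: pd.DataFrame       # specimen_id, species, clade, lifestyle
    isotopes: pd.DataFrame        # species, d13C, d15N


def generate_tree(n_taxa: int, depth: float, seed: int, rate: float = 1.0
                  ) -> Phylogeny:
    """Simulate a pure-birth (Yule) tree rescaled to the given depth.

    The tree is rooted, bifurcating and exactly ultrametric by construction;
    tips are labelled ``sp001, sp002, ...`` in order of appearance.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    rng = np.random.default_rng(seed)
    # node records: (parent_slot, birth_time); slots renumbered at the end
    parent_slot = [-1, 0, 0]
    birth = [0.0, 0.0, 0.0]
    active = [1, 2]
    t = 0.0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / (rate * len(active)))
        i = int(rng.integers(len(active)))
        node = active.pop(i)
        for _ in range(2):
            parent_slot.append(node)
            birth.append(t)
            active.append(len(parent_slot) - 1)
    t_end = t + rng.exponential(1.0 / (rate * n_taxa))
    n_nodes = len(parent_slot)
    end_time = np.full(n_nodes, t_end)
    for slot in range(n_nodes):
        kids = [v for v in range(n_nodes) if parent_slot[v] == slot]
        if kids:
            end_time[slot] = birth[kids[0]]
    # renumber: tips (active lineages, in slot order) first, internals after
    tips = sorted(active)
    internals = [v for v in range(n_nodes) if v not in set(tips)]
    new_id = {slot: i for i, slot in enumerate(tips)}
    new_id.update({slot: len(tips) + j for j, slot in enumerate(internals)})
    parent = np.full(n_nodes, -1, dtype=np.intp)
    blen = np.zeros(n_nodes)
    scale = depth / t_end
    for slot in range(n_nodes):
        v = new_id[slot]
        ps = parent_slot[slot]
        if ps >= 0:
            parent[v] = new_id[ps]
            blen[v] = (end_time[slot] - birth[slot]) * scale
    labels = [f"sp{i + 1:03d}" for i in range(n_taxa)]
    return Phylogeny(parent, blen, labels)


def simulate_traits(tree: Phylogeny, model: str, params: dict,
                    n_traits: int = 1, seed: int = 0) -> pd.DataFrame:
    """Simulate independent traits on the tree under BM, OU or EB.

    ``params``: ``sigma2`` (>= 0) and ``z0`` for all models; ``alpha`` (>= 0)
    for OU (fixed-root process whose optimum is the root state); ``a`` (<= 0)
    for EB, simulated as BM on the EB-transformed tree.
    """
    model = model.upper()
    if model not in _models.MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of "
                         f"{_models.MODELS}")
    sigma2 = float(params.get("sigma2", 1.0))
    z0 = float(params.get("z0", 0.0))
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    rng = np.random.default_rng(seed)
    if model == "BM":
        X = _bm_tips(tree, sigma2, n_traits, rng)
    elif model == "EB":
        a = float(params.get("a", 0.0))
        if a > 0:
            raise ValueError("EB parameter a must be <= 0")
        X = _bm_tips(_models.eb_transform(tree, a), sigma2, n_traits, rng)
    else:  # OU
        alpha = float(params.get("alpha", 0.0))
        if alpha < 0:
            raise ValueError("OU alpha must be >= 0")
        X = _ou_tips(tree, sigma2, alpha, n_traits, rng)
    cols = [f"trait{i + 1}" for i in range(n_traits)]
    return pd.DataFrame(X + z0, index=tree.tip_labels, columns=cols)


def _bm_tips(tree: Phylogeny, sigma2, n_traits, rng) -> np.ndarray:
    inc = rng.standard_normal((tree.n_nodes, n_traits)) \
        * np.sqrt(sigma2 * tree.blen)[:, None]
    x = np.zeros((tree.n_nodes, n_traits))
    for v in tree.preorder[1:]:
        x[v] = x[tree.parent[v]] + inc[v]
    return x[: tree.n_tips]


def _ou_tips(tree: Phylogeny, sigma2, alpha, n_traits, rng) -> np.ndarray:
    if alpha == 0:
        return _bm_tips(tree, sigma2, n_traits, rng)
    x = np.zeros((tree.n_nodes, n_traits))
    z = rng.standard_normal((tree.n_nodes, n_traits))
    decay = np.exp(-alpha * tree.blen)
    sd = np.sqrt(sigma2 * (1 - np.exp(-2 * alpha * tree.blen)) / (2 * alpha))
    for v in tree.preorder[1:]:
        x[v] = x[tree.parent[v]] * decay[v] + sd[v] * z[v]
    return x[: tree.n_tips]


def generate_outlines(config: SyntheticConfig, species_axis_values: pd.Series,
                      seed: int, clade_map: dict[str, str] | None = None
                      ) -> tuple[list[Outline], pd.DataFrame]:
    """Per-specimen outlines deformed along one mode by the species value.

    Each outline is a closed counter-clockwise loop: the fixed template radius
    plus ``clade_effect_size * 0.06 * value`` times the deformation mode, plus
    independent radial Gaussian noise per specimen; coordinates are rotated by
    a small random angle and offset to mimic digitizer image coordinates.  The
    starting landmark sits at the template's curvature maximum (parameter 0,
    a fixed template property, not re-estimated per specimen).
    """
    rng = np.random.default_rng(seed)
    p = config.p_points
    theta = 2 * np.pi * np.arange(p) / p
    base = _template_radius(theta)
    mode = _mode(theta)
    lo, hi = config.specimens_per_species
    outlines: list[Outline] = []
    rows = []
    values = species_axis_values
    scale = np.std(values.to_numpy()) or 1.0
    for species in values.index:
        value = float(values.loc[species])
        n_spec = int(rng.integers(lo, hi + 1))
        lifestyle = _lifestyle(value, scale)
        for i in range(n_spec):
            radius = base + config.clade_effect_size * _MODE_AMPLITUDE \
                * value * mode
            radius = radius + rng.normal(0.0, config.outline_noise_sd, p)
            rot = rng.uniform(-0.3, 0.3)
            pts = np.column_stack([radius * np.cos(theta),
                                   radius * np.sin(theta)])
            c, s = np.cos(rot), np.sin(rot)
            pts = pts @ np.array([[c, -s], [s, c]]).T
            pts = pts * 80.0 + np.array([250.0, 250.0])   # image units
            spec_id = f"{species}_{i + 1:02d}"
            outlines.append(Outline(spec_id, pts))
            rows.append({
                "specimen_id": spec_id,
                "species": species,
                "clade": (clade_map or {}).get(species, "cladeA"),
                "lifestyle": lifestyle,
            })
    return outlines, pd.DataFrame(rows)


def _lifestyle(value: float, scale: float) -> str:
    z = value / scale
    if z > 0.43:
        return "pelagic"
    if z < -0.43:
        return "benthic"
    return "semipelagic"


def generate_isotopes(species_axis_values: pd.Series, coupling: float,
                      noise_sd: float, seed: int,
                      coupling_13c: float | None = None,
                      baseline_15n: float = 10.5,
                      baseline_13c: float = -22.5) -> pd.DataFrame:
    """Per-species isotope values linearly coupled to a shape-axis value.

    ``d15N = baseline + coupling * value + noise``; ``d13C`` is generated
    analogously with its own coupling (default ``-coupling``: higher trophic
    level tracking more pelagic, hence lighter, carbon).  Values are per mil.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    v = species_axis_values.to_numpy(dtype=float)
    cc = -coupling if coupling_13c is None else coupling_13c
    d15n = baseline_15n + coupling * v + rng.normal(0, noise_sd, len(v))
    d13c = baseline_13c + cc * v + rng.normal(0, noise_sd, len(v))
    return pd.DataFrame({"d13C": d13c, "d15N": d15n},
                        index=species_axis_values.index)


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate the full synthetic study: tree, traits, outlines, isotopes."""
    master = np.random.default_rng(config.seed)
    sub = master.integers(2**31, size=4)
    tree = generate_tree(config.n_species, config.tree_depth, int(sub[0]))
    traits = simulate_traits(tree, config.trait_model, config.trait_params,
                             n_traits=1, seed=int(sub[1]))
    clade_lists = tree.clades(config.n_clades)
    clade_map = {sp: c for c, sps in clade_lists.items() for sp in sps}
    outlines, specimens = generate_outlines(
        config, traits["trait1"], int(sub[2]), clade_map=clade_map)
    isotopes = generate_isotopes(traits["trait1"], config.isotope_coupling,
                                 config.isotope_noise_sd, int(sub[3]))
    return SyntheticDataset(config=config, tree=tree, traits=traits,
                            outlines=outlines, specimens=specimens,
                            isotopes=isotopes)


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the dataset in the pipeline's input formats.

    TPS outlines, Newick tree, and CSV specimen/isotope tables; byte-identical
    for identical config + seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "tps": outdir / "outlines.tps",
        "tree": outdir / "tree.nwk",
        "specimens": outdir / "specimens.csv",
        "isotopes": outdir / "isotopes.csv",
        "traits": outdir / "true_traits.csv",
    }
    write_tps(ds.outlines, str(paths["tps"]))
    ds.tree.write_newick(str(paths["tree"]))
    ds.specimens.to_csv(paths["specimens"], index=False)
    iso = ds.isotopes.copy()
    iso.insert(0, "species", iso.index)
    iso.to_csv(paths["isotopes"], index=False)
    ds.traits.to_csv(paths["traits"], index_label="species")
    return paths
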