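"""End-to-end orchestration: outlines -> eigenshape -> comparative analyses.

``run_all`` reads the four inputs (TPS outlines, Newick tree, specimen table,
isotope table), computes eigenshape scores, and runs phylomorphospace
projection, disparity through time, evolutionary model selection, PGLS
against isotope values, and the group statistics (ANOVA, CVA, repeatability
when replicates are present).  Every stage writes CSV into the output
directory; the configuration is serialized alongside so a run is reproducible
from its own output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import disparity as _disp
from . import models as _models
from . import stats as _stats
from .eigenshape import broken_stick, eigenshape, zahn_roskies
from .morphospace import project
from .outlines import read_tps, resample_equidistant
from .phylo import read_newick

__all__ = ["PipelineConfig", "run_all"]

log = logging.getLogger("opermorph")


@dataclass
class PipelineConfig:
    tps: str
    tree: str
    specimens: str
    isotopes: str | None
    outdir: str
    p_points: int = 100
    axes_for_stats: int = 8
    dtt_n_sim: int = 1000
    dtt_truncation: float = 0.2
    dtt_seed: int = 0
    dtt_squared: bool = False
    models: tuple[str, ...] = ("BM", "OU", "EB")
    traits_to_fit: tuple[int, ...] = (1, 2)
    pgls_responses: tuple[str, ...] = ("d13C", "d15N")
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("models", "traits_to_fit", "pgls_responses"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        data = dataclasses.asdict(self)
        for key in ("models", "traits_to_fit", "pgls_responses"):
            data[key] = list(data[key])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def _setup_logging(config: PipelineConfig, outdir: Path) -> None:
    log.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    log.handlers = []
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for handler in (logging.StreamHandler(),
                    logging.FileHandler(outdir / "run.log", mode="w")):
        handler.setFormatter(fmt)
        log.addHandler(handler)


def run_all(config: PipelineConfig) -> dict:
    """Run the full analysis; returns a bundle of in-memory results."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(config, outdir)
    config.to_yaml(str(outdir / "config.yaml"))

    outlines = read_tps(config.tps)
    specimens = pd.read_csv(config.specimens).set_index("specimen_id")
    tree = read_newick(config.tree)
    log.info("read %d outlines, %d specimens, tree with %d tips",
             len(outlines), len(specimens), tree.n_tips)

    unknown = [o.specimen_id for o in outlines
               if o.specimen_id not in specimens.index]
    if unknown:
        raise ValueError(f"outlines without specimen-table rows: {unknown}")
    species_of = specimens["species"]
    bad_species = sorted(set(species_of) - set(tree.tip_labels))
    if bad_species:
        raise ValueError(
            f"species present in outlines but absent from tree: {bad_species}")

    # eigenshape stage
    shape_functions = [
        zahn_roskies(resample_equidistant(o, config.p_points)) for o in outlines
    ]
    es = eigenshape(shape_functions)
    scores = es.scores_frame()
    scores.to_csv(outdir / "scores.csv", index_label="specimen_id")
    pd.DataFrame(es.axes,
                 columns=[f"ES{i + 1}" for i in range(es.n_axes)]
                 ).to_csv(outdir / "eigenshape_axes.csv", index_label="point")
    pd.DataFrame({"variance_fraction": es.variance_fraction}
                 ).to_csv(outdir / "variance_fractions.csv", index_label="axis")
    n_sig = broken_stick(es.variance_fraction)
    log.info("ES1 explains %.1f%% of variance; %d axes significant "
             "under the broken-stick model",
             100 * es.variance_fraction[0], n_sig)

    k_axes = min(config.axes_for_stats, es.n_axes)
    axis_cols = [f"ES{i + 1}" for i in range(k_axes)]
    species_means = scores.groupby(species_of).mean()
    species_means.to_csv(outdir / "species_mean_scores.csv",
                         index_label="species")
    missing_means = sorted(set(tree.tip_labels) - set(species_means.index))
    if missing_means:
        raise ValueError(f"tree tips without any specimen: {missing_means}")

    # phylomorphospace
    morpho = {}
    for pair in ((1, 2), (1, 3)):
        if max(pair) > es.n_axes:
            continue
        pm = project(tree, species_means, axis_pair=pair)
        name = f"phylomorphospace_ES{pair[0]}_ES{pair[1]}"
        pm.tip_coords.to_csv(outdir / f"{name}_tips.csv",
                             index_label="species")
        pm.edges_frame(tree).to_csv(outdir / f"{name}_edges.csv", index=False)
        morpho[pair] = pm

    # disparity through time
    dtt = _disp.disparity_through_time(
        tree, species_means[axis_cols], n_sim=config.dtt_n_sim,
        truncation=config.dtt_truncation, seed=config.dtt_seed,
        squared=config.dtt_squared)
    dtt.frame().to_csv(outdir / "dtt.csv", index=False)
    clade_per_species = specimens.groupby("species")["clade"].first()
    clade_disp = _disp.clade_disparity(species_means[axis_cols],
                                       clade_per_species)
    clade_disp.to_csv(outdir / "clade_disparity.csv")
    log.info("MDI = %.3f (truncation %.0f%%, %d simulations)",
             dtt.MDI, 100 * config.dtt_truncation, config.dtt_n_sim)

    # evolutionary model selection
    comparisons = {}
    for axis_no in config.traits_to_fit:
        col = f"ES{axis_no}"
        if col not in species_means.columns:
            continue
        comp = _models.fit_all_models(tree, species_means[col],
                                      models=config.models)
        comp.frame().to_csv(outdir / f"model_comparison_{col}.csv")
        comparisons[col] = comp
        best = comp.frame()["weight"].idxmax()
        log.info("%s: best model %s (weight %.3f)", col, best,
                 comp.frame()["weight"].max())

    # PGLS against isotope ecology
    pgls_results = {}
    if config.isotopes:
        iso = pd.read_csv(config.isotopes).set_index("species")
        keep = sorted(set(species_means.index) & set(iso.index))
        dropped = sorted(set(species_means.index) - set(iso.index))
        for sp in dropped:
            log.info("PGLS: excluding %s (no isotope data)", sp)
        log.info("PGLS runs on %d species (%d excluded)", len(keep),
                 len(dropped))
        for resp in config.pgls_responses:
            if resp not in iso.columns:
                continue
            res = _stats.pgls(tree, iso.loc[keep, resp],
                              species_means.loc[keep, axis_cols])
            res.coefficients.to_csv(outdir / f"pgls_{resp}.csv")
            pgls_results[resp] = res
            log.info("PGLS %s ~ %s: r2_lr=%.3f, F p=%.3g", resp,
                     "+".join(axis_cols), res.r2_lr, res.f_pvalue)

    # group statistics on specimen-level scores
    clade_of = specimens["clade"]
    anova_tab, posthoc = _stats.anova_per_axis(scores[axis_cols],
                                               clade_of)
    anova_tab.to_csv(outdir / "anova.csv")
    posthoc.to_csv(outdir / "anova_posthoc.csv", index=False)
    cva = None
    try:
        cva = _stats.cva_wilks(scores[axis_cols], clade_of)
        cva.coefficients.to_csv(outdir / "cva_coefficients.csv")
        cva.wilks.to_csv(outdir / "cva_wilks.csv")
    except (np.linalg.LinAlgError, ValueError) as exc:
        log.warning("CVA skipped: %s", exc)

    repeat = None
    if "individual" in specimens.columns:
        reps = specimens["individual"].value_counts()
        if (reps > 1).any():
            repeat = _stats.repeatability(scores[axis_cols],
                                          specimens["individual"])
            _stats.repeatability_frame(repeat).to_csv(
                outdir / "repeatability.csv")

    summary = {
        "n_specimens": int(len(scores)),
        "n_species": int(len(species_means)),
        "es1_variance_pct": float(100 * es.variance_fraction[0]),
        "n_significant_axes": int(n_sig),
        "mdi": float(dtt.MDI),
        "model_weights": {
            col: {m: float(w) for m, w in comp.frame()["weight"].items()}
            for col, comp in comparisons.items()
        },
        "pgls": {r: {"r2_lr": res.r2_lr, "f_pvalue": res.f_pvalue}
                 for r, res in pgls_results.items()},
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return {
        "eigenshape": es,
        "scores": scores,
        "species_means": species_means,
        "n_significant_axes": n_sig,
        "phylomorphospace": morpho,
        "dtt": dtt,
        "clade_disparity": clade_disp,
        "model_comparisons": comparisons,
        "pgls": pgls_results,
        "anova": anova_tab,
        "posthoc": posthoc,
        "cva": cva,
        "repeatability": repeat,
        "summary": summary,
        "tree": tree,
    }
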