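# opermorph

Outline-based eigenshape morphometrics coupled to phylogenetic comparative
methods, built for studies of craniofacial bone shape evolution across a
radiation — the motivating case is the opercle (gill-cover bone) of Antarctic
notothenioid fishes, where a 2-D bone outline per specimen, an ultrametric
species tree, and per-species stable-isotope values (δ¹³C, δ¹⁵N) are combined
to ask how morphological disparity accumulated through time and whether shape
tracks trophic ecology.

## What it computes

**Eigenshape analysis.** Each closed outline (TPS format, as written by
outline digitizers) is resampled to *p* equidistant points (default 100) and
converted to the Zahn–Roskies Φ\* shape function: the unwrapped cumulative
tangent direction minus the turning expected of a circle,

&nbsp;&nbsp;Φ\*ⱼ = θⱼ − θ₀ − j·(2π/p),

which is invariant to translation, rotation and scale. SVD of the centered
Φ\* matrix yields mutually orthogonal eigenshape axes ES1, ES2, … ordered by
variance explained, per-specimen scores, and shape models along each axis;
the broken-stick rule selects the significant axes.

**Phylomorphospace.** Species-mean scores plus maximum-likelihood Brownian
ancestral states (weighted squared-change parsimony) projected into axis
pairs, with every branch drawn between parent and child.

**Disparity through time (DTT).** Disparity is the average pairwise Euclidean
distance among species in ES space. At each internal node's (relative) age
the mean ratio of subclade to whole-clade disparity is computed over the
lineages present, compared against simulations of multivariate Brownian
motion (rate matrix estimated by independent contrasts), and summarized by
the MDI statistic — the signed area between the observed curve and the null
median, omitting the most recent 20% of time.

**Evolutionary model selection.** Brownian motion (σ², z₀), single-optimum
Ornstein–Uhlenbeck (+α) and early-burst (+a ≤ 0, rate ∝ e^{at}) models fitted
by maximum likelihood (pruning algorithm; OU via an exact branch-length
transform on ultrametric trees), compared by AICc and Akaike weights
wᵢ = exp(−Δᵢ/2) / Σⱼ exp(−Δⱼ/2).

**Ecology and quality control.** PGLS regression of isotope values on ES
scores under a Brownian correlation structure; per-axis ANOVA across clades
with Bonferroni correction; canonical variates analysis with Wilks' Λ;
measurement-error repeatability *R* (among-individual variance fraction) from
replicated digitizations.

A synthetic-data module generates the whole study design — pure-birth
ultrametric tree, BM/OU/EB trait evolution, outlines deformed along one known
parametric mode, coupled isotope tables — so every stage is testable without
specimen photographs and with known ground truth.

## Worked example

```sh
opermorph simulate --out data --seed 1
```

```python
import opermorph as om

config = om.PipelineConfig(
    tps="data/outlines.tps", tree="data/tree.nwk",
    specimens="data/specimens.csv", isotopes="data/isotopes.csv",
    outdir="results", dtt_n_sim=1000)
bundle = om.run_all(config)

es = bundle["eigenshape"]
print(f"ES1 variance: {100 * es.variance_fraction[0]:.1f}%")
print(f"broken-stick significant axes: {bundle['n_significant_axes']}")
print(f"MDI: {bundle['dtt'].MDI:.3f}")
print(bundle["model_comparisons"]["ES1"].frame()[["logL", "AICc", "dAICc", "weight"]].round(3))
res = bundle["pgls"]["d15N"]
print(f"PGLS d15N ~ ES1..ES8: r2 = {res.r2_lr:.2f}, F p = {res.f_pvalue:.3f}")
```

prints

```
ES1 variance: 61.1%
broken-stick significant axes: 2
MDI: 0.063
         logL     AICc   dAICc  weight
model
BM    -61.528  127.602  25.745     0.0
OU    -47.357  101.857   0.000     1.0
EB    -61.528  130.199  28.342     0.0
PGLS d15N ~ ES1..ES8: r2 = 0.84, F p = 0.000
```

Reading this: the generator put a single deformation mode on the outlines in
proportion to a Brownian trait, so ES1 dominates (61% of Φ\* variance) and
only two axes beat the broken-stick expectation. MDI slightly above zero
means subclades retain a bit more of the total disparity than the Brownian
median. The synthetic trait is near-Brownian on this seed, yet OU wins the
AICc comparison — a reminder that single-optimum OU often absorbs extra tip
variance; the weights table mirrors the standard model-selection report
(logL, AICc, ΔAICc, weight). The PGLS recovers the built-in coupling between
δ¹⁵N and the ES1 trait (here r² = 0.84 on the 21 species with isotope data;
4 species are pruned, and logged, as lacking isotope values).

Every output is also written as CSV under `results/` (scores, species means,
phylomorphospace coordinates and edges, DTT curve + envelope, model
comparison, PGLS/ANOVA/CVA tables, run log, and the serialized config).

The CLI exposes each stage separately:
`opermorph simulate | eigenshape | phylomorphospace | dtt | fit-models |
pgls | qc | run-all`.

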