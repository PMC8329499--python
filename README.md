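# sedom

Stratified sediment DOM molecular composition and microbe–DOM association
networks, from FT-ICR MS peak lists and 16S ASV tables.

## The problem

Porewater dissolved organic matter (DOM) in anoxic sediments becomes more
recalcitrant with depth: molecular weight, double bond equivalents (DBE) and
aromaticity rise while H/C falls, and the microbial community turns over with
it — archaeal groups such as Bathyarchaeia track high-DBE, lignin/CRAM-like
molecules while many bacteria track labile aliphatic material. Testing such
claims requires a reproducible chain from ultrahigh-resolution mass spectra
to statistics: formula assignment, molecular indices, compound classes,
depth-stratification tests, constrained ordination, and a correlation
network. `sedom` implements that chain as a library (plus a thin CLI), with a
ground-truth-labeled synthetic-study generator so every stage can be
validated end to end without any external dataset.

## What it computes

* **Formula assignment** — negative-ion peaks ([M−H]⁻) with s/n > 4 in
  200–800 Da get the neutral formula (C, H, N, O, S, P grid) whose ion m/z is
  within 1 ppm, under DOM plausibility rules (H/C, O/C, integer DBE ≥ 0,
  DBE−O window); near-tied candidates resolve by heteroatom parsimony.
* **Indices** — per formula: DBE = 1 + (2C−H+N+P)/2,
  AI-mod = (1+C−O/2−S−H/2)/(C−O/2−S−N−P) clamped to [0,1],
  NOSC = 4 − (4C+H−3N−2O−2S)/C, O/C, H/C, exact mass. Per sample:
  magnitude-weighted bulk means (MW_wa, DBE_wa, …) and the ten-formula
  degradation index I_DEG.
* **Compound classes** — the seven van Krevelen windows (lipids,
  aliphatic/proteins, lignins/CRAM-like, carbohydrates, unsaturated
  hydrocarbons, aromatic, tannins) with exact open/closed boundary semantics.
* **Stratification** — linear and exponential (`a + b·e^(k·depth)`) depth
  trends; upper (≤100 cm) vs deep (≥110 cm) group split; group-unique
  molecule sets; two-class LEfSe (Kruskal–Wallis screen + bootstrapped LDA
  effect size, threshold LDA > 2).
* **Ordination** — Bray–Curtis; PCoA (classical scaling); NMDS (Kruskal
  stress-1, SMACOF with isotonic disparities, multi-restart); envfit with
  999-permutation tests; CCorA on the first five PCoA axes with Pillai's
  trace; dbRDA with permutation forward selection and variance partitioning
  between environmental and community predictors.
* **Network** — prevalence (> 1/3 of samples) and abundance (> 0.05%)
  filters; Pearson edges (r ≥ 0.65, p < 0.01, positive only); bipartite graph
  with summary (2E/N average neighbors); grouped views; MCODE dense modules
  (score = density × size); Table-1-style weighted-average index summaries of
  bacteria- vs archaea-correlated molecules.
* **Synthetic studies** — 40-depth two-stratum core, 5,000 CHONS formulas,
  1,000 ASVs, planted depth trends, differential molecules, unique sets, and
  guild↔molecule-set couplings at a target Pearson r, all recorded as ground
  truth. See `docs/methods.md` for the generative model.

## Worked example

```python
from sedom import (SimulationConfig, simulate_study, bulk_table, split_groups,
                   bray_curtis, nmds, lefse_two_class)
from sedom.network import (prevalence_filter, abundance_filter, pearson_edges,
                           build_network, mcode, correlated_molecule_summary)

cfg = SimulationConfig(seed=42)
study = simulate_study(cfg)                       # DOM matrix, ASVs, metadata, truth
groups = split_groups(study.metadata["depth_cm"])

bulk = bulk_table(study.dom, study.indices)       # magnitude-weighted parameters
print("H/C_wa upper mean: %.3f   deep mean: %.3f" % (
    bulk.loc[groups == "upper", "hc_wa"].mean(),
    bulk.loc[groups == "deep", "hc_wa"].mean()))

print("NMDS stress: %.4f" % nmds(bray_curtis(study.dom), k=2, seed=0).stress)

lefse = lefse_two_class(study.dom, groups, seed=0)
print("LEfSe: %d molecules with LDA > 2" % lefse.significant.sum())

asv, _ = prevalence_filter(study.asv)
dom, _ = prevalence_filter(study.dom)
dom = abundance_filter(dom)
edges, _ = pearson_edges(asv, dom)
graph, summary = build_network(edges)
print("network: %d nodes, %d edges, average neighbors %.2f" % (
    summary.n_nodes, summary.n_edges, summary.average_neighbors))
modules = mcode(graph)
print("MCODE: %d modules, top score %.2f" % (len(modules), modules[0].score))

table = correlated_molecule_summary(edges, study.indices,
                                    study.dom.mean(axis=1),
                                    study.taxonomy["domain"])
print("weighted-average DBE  archaea: %.2f   bacteria: %.2f" % (
    table.loc[("Archaea", "weighted_average"), "DBE"],
    table.loc[("Bacteria", "weighted_average"), "DBE"]))
```

Output:

```
H/C_wa upper mean: 1.336   deep mean: 1.210
NMDS stress: 0.0733
LEfSe: 819 molecules with LDA > 2
network: 256 nodes, 2107 edges, average neighbors 16.46
MCODE: 3 modules, top score 4.57
weighted-average DBE  archaea: 14.12   bacteria: 10.30
```

Read: hydrogen saturation drops below the 100/110 cm boundary (deep DOM is
more unsaturated); the two-dimensional NMDS represents the Bray–Curtis
structure well (stress ≈ 0.07); 819 molecules differ between strata at
LDA > 2 (the 100 planted 4-fold shifts plus molecules moved by the planted
depth trend); the filtered ASV–molecule correlation network resolves the
planted guild blocks, MCODE extracts the small dense modules, and molecules
correlated with archaea have a markedly higher abundance-weighted DBE than
those correlated with bacteria — the planted recalcitrant-DOM/archaea
association, recovered.

The same steps are available from the shell:

```bash
sedom simulate --seed 42 --peaklists --out study/
sedom assign --peaks study/peaklists --out assignments.tsv
sedom indices --assignments assignments.tsv --out indices.tsv --bulk bulk.tsv
sedom classify --indices indices.tsv --out classes.tsv
sedom lefse --matrix study/dom.tsv --metadata study/metadata.tsv --seed 1 --out lefse.tsv
sedom ordinate --matrix study/dom.tsv --method nmds --seed 7 --out coords.tsv
sedom network --asv study/asv.tsv --dom study/dom.tsv --out edges.tsv --modules-out modules.tsv
```

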