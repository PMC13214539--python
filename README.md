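# ecozone

Ecological zoning of river survey sites from community and environmental
tables: niche statistics, random-forest attribution of species richness to
environmental drivers, and silhouette-optimized hierarchical clustering of
sites into management zones.

The package is aimed at freshwater community ecologists working with the
classic survey layout — a site × taxon abundance matrix (counts or cell
densities) paired with a site × gradient table of physicochemical
measurements (DO, pH, WT, TC, DOC, TN, DTN, TP, DTP, TSi, DSi) — who want
the full analysis chain as tested, scriptable, exactly reproducible code
rather than a spreadsheet pipeline.

## What it computes

**Representative species** by McNaughton dominance
`Y_i = (n_i / N) · f_i`, with `n_i` the taxon's total abundance, `N` the
grand total and `f_i` its occurrence frequency across sites; taxa with
`Y ≥ 0.02` are representative.

**Richness** per site by Margalef's index `D = (S − 1) / ln N_site`.

**Niche breadth and overlap.** Each gradient is split into `R = 5`
percentile resource states; species utilization profiles
`P_ij = n_ij / n_i` feed Levins breadth

    B_i = 1 / Σ_j P_ij²            (1 = specialist … R = generalist)

and Pianka overlap

    O_ik = Σ_j P_ij P_kj / √(Σ_j P_ij² · Σ_j P_kj²)   ∈ [0, 1],

reported as pairwise matrices, per-species totals `Σ_{k≠i} O_ik`,
Mean-S/Mean-R summaries with ranks, and an OLS regression of mean overlap
on mean breadth.

**Richness drivers.** A bootstrap regression forest (out-of-bag %IncMSE
permutation importance, permutation-test p-values, OOB R²) ranks the 11
gradients plus two site-level niche covariates as drivers of `D`; the top 7
positive-importance features are selected.

**Zoning.** Sites are clustered on the z-scored selected features plus
richness (Ward linkage, Euclidean distance); the mean silhouette
coefficient picks the number of zones, Kruskal–Wallis tests validate
per-feature zone differences, and TN:TP ratios are summarized per zone and
per channel type.

A synthetic survey generator with planted zone structure (26 sites in
zones of 5/6/15), known niche parameters and known richness drivers
provides ground truth for every stage; see `docs/methods.md` for the model
and its assumptions.

## Worked example

```python
from ecozone import (SyntheticConfig, generate_dataset, dominance_index,
                     margalef_richness, bin_resource_states,
                     utilization_profile, levins_breadth, pianka_overlap)

ds = generate_dataset(SyntheticConfig(seed=1))
dom = dominance_index(ds.community)
print(int(dom["representative"].sum()))        # 11 representative taxa
print(round(margalef_richness(ds.community)["D"].mean(), 2))   # 8.36

states = bin_resource_states(ds.environment)   # 5 percentile states/gradient
prof = utilization_profile(ds.community, states,
                           taxa=list(dom.index[dom["representative"]]))
print(round(levins_breadth(prof).mean_s.mean(), 2))   # 4.6 — dominants are generalists
```

The same run from the shell, end to end:

```sh
ecozone run --out out/ --seed 1
```

writes `dominance.csv`, `richness.csv`, `breadth.csv`, `overlap.csv`,
`importance.csv`, `zones.csv`, `silhouette.csv`, `kw_report.csv`,
`np_ratio.csv`, `zone_summary.csv`, a Newick dendrogram and a
`manifest.json` whose checksums are byte-identical across reruns with the
same seed. On the default synthetic survey the zoning stage recovers the
three planted zones exactly (k\* = 3, sizes 5/6/15, adjusted Rand index
1.0 against the planted labels). Subcommands `simulate`, `metrics`,
`niche`, `importance` and `zone` run the pipeline up to the named stage;
`ecozone validate` checks input files and reports schema/range violations.

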