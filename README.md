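# protcov

Spatial proteomics by covariation: normalization of multi-mixture
isobaric-label (TMT) quantification, protein covariation network
construction and module detection, and mixed-model differential abundance
between genotypes across subcellular fractions — with a companion
proximity-proteomics (BioID) enrichment analysis and a synthetic-data
generator so the entire pipeline can be exercised without any external data.

It is written for proteomics groups running LOPIT-style designs: several
16-plex TMT mixtures, each carrying subcellular fractions from two genotypes
plus pooled quality-control (SPQC) channels, asking *which protein
communities change* rather than only which single proteins do.

## What it computes

**Normalization stack** (peptides → protein matrix): contaminant removal →
sample-loading normalization within mixture → SPQC outlier-peptide filtering
(5 intensity bins, 4 SD rule on the SPQC log-ratio) → k-nearest-neighbour
imputation → unique-peptide sum summarization → sample-loading across
mixtures → internal reference scaling (IRS, equalizing each protein's SPQC
geometric mean across mixtures) → presence/peptide-count/SPQC filters →
protein-level outlier filter.

**Covariation modules**: Pearson correlation of log2 profiles over the
biological samples, denoised by Network Enhancement (kNN truncation +
closed-form diffusion re-weighting), partitioned by the Leiden algorithm
maximizing asymptotic Surprise,

    S = m · D_KL(q ‖ ⟨q⟩),

with m the total edge weight, q the within-module share of edge weight and
⟨q⟩ the within-module share of node pairs.

**Inference**: per protein, the linear mixed model

    y_mcb = μ + Condition_c + Mixture_m + ε,   Mixture ~ N(0, σ²_M),

fit by REML; contrasts lᵀβ (per-fraction MUT − WT and the equally weighted
overall genotype effect) are tested with t = lᵀβ̂ / √(lᵀV̂l) at Satterthwaite
degrees of freedom, BH-adjusted across proteins within each contrast family.
Per module, protein intensities are sum-normalized (relative intensity),
log2-transformed, and fit jointly with

    log2(relative intensity) = μ + Condition + Protein + ε,   Protein ~ N(0, σ²_P),

one overall genotype contrast per module, Bonferroni-adjusted over modules.

**Enrichment**: upper-tail hypergeometric tests of every module against GMT
gene sets, background = union of clustered proteins and set members,
Bonferroni over the full test grid.

**BioID**: sample-loading + SPQC pool normalization, filters, kNN
imputation, per-protein two-group linear model on log2 intensities; the
interactome is {fold-change > 4 and BH FDR < 0.05}.

## Worked example

```python
from protcov import (SimulationConfig, simulate_dataset, preprocess_pipeline,
                     covariation_matrix, network_enhancement,
                     partition_surprise_leiden, relative_log2,
                     run_module_contrasts)

cfg = SimulationConfig(n_proteins=200, n_modules=8,
                       effect_map={"M1": -0.25}, seed=4)
table, design, truth = simulate_dataset(cfg)
matrix, log = preprocess_pipeline(table, design)
print(f"retained {log['counts']['final_proteins']} of {cfg.n_proteins} proteins")

graph = covariation_matrix(matrix, design)
part = partition_surprise_leiden(network_enhancement(graph), seed=4, n_restarts=20)
print(f"{part.n_modules} modules, Surprise = {part.quality:.1f}")

profiles = relative_log2(matrix, design)
for r in run_module_contrasts(profiles, part, design):
    print(f"{r.target}: n={r.size} log2FC={r.log2fc:+.3f} df={r.df:.0f} "
          f"p_adj={r.p_adjust:.2e}")
```

prints

```
retained 191 of 200 proteins
5 modules, Surprise = 5872.0
M1: n=52 log2FC=+0.066 df=2170 p_adj=3.20e-03
M2: n=47 log2FC=+0.053 df=1914 p_adj=9.50e-02
M3: n=45 log2FC=+0.044 df=1832 p_adj=1.23e-01
M4: n=25 log2FC=+0.056 df=1036 p_adj=6.02e-09
M5: n=22 log2FC=-0.183 df=910 p_adj=1.28e-54
```

The planted down-shifted module is recovered as detected module M5 (22 of
its proteins), with a strongly negative overall genotype effect; the other
modules sit near zero (small residual shifts are the compositional
footprint of total-intensity normalization when a sizeable fraction of the
proteome is perturbed — see `docs/methods.md`). Module ids are ordered by
size, so the planted module's id depends on the partition, not on the
generator.

The same chain is available from the shell:

```sh
protcov run-all --seed 4 --out-dir runs/demo
protcov simulate --seed 1 --n-proteins 100 --out-dir runs/sim
protcov preprocess --peptides runs/sim/peptides.tsv --design runs/sim/design.tsv --out-dir runs/pre
```

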