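# synscreen

Detection of synergistic (non-additive) gene-expression changes in a 2×2
factorial mutant transcriptome design: wild type (WT), two single mutants
(A, B) and the double mutant (AB).

The motivating biology is the *Arabidopsis thaliana* carpel margin meristem:
the *seuss-3 aintegumenta-1* double mutant loses ovule initiation entirely
although each single mutant is mild, and transcripts whose abundance
collapses specifically in the double mutant are candidates for the genes
whose regulation the two factors redundantly share. `synscreen` implements
the complete screening pipeline for this design — array QC and cyclic loess
normalization, per-gene one-way ANOVA with LSmean contrasts, Storey pFDR
control, a two-criterion synergy screen, hypergeometric gene-family
over-representation, and the qRT-PCR verification arm — plus a synthetic-data
module with known ground truth and the published candidate/qPCR tables as
fixed reference surfaces.

## The statistic at the core

Each gene is fitted with a one-way fixed-effect model by genotype on log2
expression; in a balanced design the LSmean μ_g is the genotype mean. Under
additivity of mutant effects the double-mutant expectation is

    E[μ_AB] = μ_A + μ_B − μ_WT,

so the interaction contrast

    δ = μ_AB − μ_A − μ_B + μ_WT        (weights +1, −1, −1, +1)

is zero under the additive null; δ < 0 is a synergistic loss. δ is tested
with t = δ / SE, SE = √(s² Σ w²_g / n_g), on the pooled residual df. The
two-criterion candidate screen keeps genes for which

1. at least one single mutant is significantly *below* wild type, and
2. δ < 0 with p < α (α = 0.05).

Differential screens (genotype vs WT or vs the grand mean) additionally
require |Δlog2| > 0.35 and control the pFDR with Storey q-values.
Candidate sets are tested for gene-family over-representation with the
hypergeometric upper tail P(X ≥ k) given k family hits among n candidates,
K family members and N genes on the array. qPCR verification quantifies
expression as 2^(Ct_ref − Ct_target) per biological replicate and compares
genotypes with a Tukey-Kramer HSD test summarised as a compact letter
display.

## Worked example

```python
from synscreen import (SimulationConfig, simulate_expression, synergy_screen,
                       simulate_annotation, enrich_terms)

cfg = SimulationConfig(n_genes=2000, frac_synergistic=0.05, synergy_shift=-1.5,
                       single_shift_a=-0.6, single_shift_b=-0.6,
                       noise_sd=0.3, seed=1)
matrix, truth = simulate_expression(cfg)
records, candidates = synergy_screen(matrix, criterion1="rawp")
print(len(candidates))          # 64 candidate genes (64/100 planted recovered)
print(records.head(2).round(3))
```

```
             mu_WT    mu_A    mu_B  mu_AB  delta     se  t_stat  p_value  ...  passes
gene_00542   9.283   8.922   8.723  6.854 -1.508  0.112 -13.452      0.0  ...    True
gene_01272  11.319  10.739  11.087  8.514 -1.993  0.169 -11.828      0.0  ...    True
```

`delta` is the gene's departure from its additive expectation (log2 units):
gene_00542 sits 1.5 log2 units (≈2.8-fold) below the level predicted from
its single-mutant effects, with the interaction t-test overwhelmingly
significant, and both single mutants are themselves significantly below
wild type — so it passes both criteria. Feeding the candidates into the
enrichment module against a planted annotation:

```python
ann = simulate_annotation(list(matrix.genes),
                          [("planted_family", 118), ("decoy", 100)],
                          "planted_family", candidates, overlap=30, seed=1)
print(enrich_terms(candidates, ann))
```

```
          term   k    K   n     N      p_value  enriched
planted_family  30  118  64  2000 1.043606e-21      True
         decoy   3  100  64  2000 6.305251e-01     False
```

The planted family is flagged (uncorrected hypergeometric p < 0.001, the
screening convention); the decoy is not.

The same steps are scriptable from a shell via the `synscreen` CLI
(`synscreen simulate expression`, `normalize`, `anova`, `synergy`,
`enrich`, `qpcr`; see `synscreen --help`).

## Layout

- `synscreen.matrix` — expression-matrix container, TSV I/O
- `synscreen.simulate` — factorial expression / annotation / Ct generators
- `synscreen.datasets` — published candidate and qPCR reference tables
- `synscreen.normalization` — QC summaries, cyclic loess, probe summarization
- `synscreen.differential` — ANOVA, contrasts, q-values, DE screens
- `synscreen.synergy` — interaction contrast and the two-criterion screen
- `synscreen.enrichment` — hypergeometric over-representation
- `synscreen.qpcr` — ddCt quantification, reference stability, Tukey letters

See `docs/methods.md` for the statistical model, parameter choices and
known limitations.
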