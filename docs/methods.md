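# Methods

## Model and design

The pipeline targets a balanced 2×2 factorial mutant design measured on
expression arrays: genotypes WT, A, B and AB with r replicate arrays each
(default r = 3; the replicate count is configurable and nothing in the
fixture-based checks depends on it). All analysis is on the log2 scale.
Per gene, the one-way fixed-effect model

    y_gr = mu_g + e_gr,  e_gr ~ N(0, sigma^2)  (homoscedastic across genotypes)

is fitted by least squares; the LSmean mu_g equals the arithmetic genotype
mean in this balanced single-factor setting, and the pooled residual mean
square s² on nu = N − G degrees of freedom feeds every contrast. A contrast
sum(w_g mu_g) has SE = sqrt(s² · sum(w_g²/n_g)) and is tested two-sided
against t(nu). Degenerate fits (nu = 0, or zero residual variance with
separated means) are flagged rather than tested; all-identical values give
F = 0, p = 1.

## Non-additivity

Additivity of mutant effects on log2 expression means the double-mutant
expectation is mu_A + mu_B − mu_WT; the deviation

    delta = mu_AB − mu_A − mu_B + mu_WT

is the classical interaction contrast (weights +1, −1, −1, +1). Note that
additivity is asserted for *effects*, never for absolute levels — adding two
absolute LSmeans near 9 would predict a nonsensical ~18. The two-criterion
candidate screen requires (1) at least one single mutant significantly
below wild type and (2) delta < 0 with two-sided p < alpha (default 0.05).
A two-sided test plus the sign requirement was chosen over a one-sided
test: it reproduces the published "significance cutoff + lower than"
conjunction and is the more conservative option. Exact ties delta = 0 are
not candidates.

Criterion 1 supports two modes: `qvalue` (default) screens the
single-mutant-below-WT contrasts with Storey q-values over all genes,
mirroring a pFDR-screened single-mutant list; `rawp` uses the raw contrast
p-value. The modes differ greatly in stringency — at n = 3 replicates and
sigma = 0.3 a −0.3 single-mutant effect essentially never survives q-value
screening, so `rawp` is the practical choice when single-mutant effects are
weak; both are measured by `scripts/acceptance.py`.

## Differential screens

Directional gene sets for one genotype are built from the contrast against
wild type or against the grand mean (weights 1 − 1/G on the target and
−1/G elsewhere); both baselines are explicit parameters since published
single-mutant and double-mutant lists can use either. Membership requires
q ≤ alpha, |estimate| > 0.35 log2 (strictly; ≈1.27-fold), and the matching
sign. The 0.35 threshold is read as a magnitude on the log2 scale, the
scale the inputs are already on.

## Multiple testing

Storey q-values: pi0 is estimated from pi0_hat(lambda) = #{p > lambda} /
(m(1 − lambda)) on lambda = 0.05, …, 0.95 by a least-squares straight line
evaluated at lambda = 0.95 — a linear, smoothing-free estimate chosen over
the cubic-spline smoother to avoid an opaque dependency (plain
interpolation evaluated at the grid end would collapse to the single
noisiest grid point). pi0 is clipped to [1/m, 1] so q-values remain
well-defined when nearly every p is small. q_i is the running minimum of
pi0·m·p_(j)/j over j ≥ rank(i), clipped at 1, hence monotone in p; with
pi0 = 1 the procedure is exactly Benjamini–Hochberg (available as a flag).

## Normalization

Arrays are first compared by distribution summaries (min, quartiles,
median, max, mean, sd per array); an array is flagged when its median is
more than 1.0 log2 unit (configurable) from the median of medians.
Normalization is pairwise cyclic loess on MA coordinates: for each array
pair, M = x_i − x_j is regressed on A = (x_i + x_j)/2 by tricube-weighted
local linear regression (statsmodels lowess; span = fraction of points,
default 0.3) and half the fitted trend is moved from one array to the
other; two full passes over all pairs by default. The symmetric correction
conserves the grand mean exactly per pair. Log2-scale input is assumed
throughout. Probe sets are summarized to targets by the arithmetic mean of
their probes per sample; probes mapping to multiple targets contribute to
each, and unmapped probes are dropped with a logged count.

## Over-representation

Family enrichment of a candidate set uses the hypergeometric upper tail
P(X ≥ k) for k annotated candidates of n, with K annotated genes in a
universe of N (scipy's survival function, accurate at p ~ 1e-10 for
N ≈ 22,810; verified against exact rational enumeration in the tests).
The universe defaults to the genes of the expression matrix — the array,
not the genome — and is overridable. Following the screening convention
this pipeline reproduces, term p-values are reported *uncorrected* with a
fixed p < 0.001 flag; a Benjamini–Hochberg column is optional and off by
default. Annotations are flat term → gene-set maps; no ontology-graph
propagation is attempted. Note that the transcribed candidate table's B3
counts (7 of 31, family size 118, universe 22,810) give an upper-tail
p = 1.965e-10; the value printed alongside the original table, 2.5e-10, is
not recoverable from those counts under any standard convention (point
mass 1.94e-10, binomial approximation 2.3e-10) — the order of magnitude,
and the conclusion, are unaffected.

## qPCR arm

Technical replicates are averaged on the Ct scale; each biological
replicate then yields relative expression 2^(Ct_ref − Ct_target), i.e.
100% amplification efficiency and no calibrator — the convention that puts
a target amplifying earlier than the reference above 1, matching the
published verification tables. Reference-gene stability is assessed per
candidate pair by a one-way genotype ANOVA on the per-replicate Ct
difference; p ≥ 0.05 is called stable, and a perfectly constant difference
(degenerate fit) is stable by convention. Genotypes are compared with the
Tukey-Kramer studentized-range test on pooled within-group variance
(scipy.stats.tukey_hsd, valid for unequal group sizes) and summarised with
an insert-and-absorb compact letter display in descending-mean order:
two groups share a letter exactly when their adjusted p ≥ alpha.
Reconstructions of the published letter patterns from means + SEMs (raw Ct
values were never published) are consistency checks, not exact
reproductions; borderline overlapping-letter rows may differ.

## Synthetic data

The generator emulates the measured outcome of the design, not the assay
chemistry: per gene a baseline mu0 ~ N(9, 1) (log2 units, matching the
8.4–11.9 range of the published LSmeans), genotype means mu0, mu0+a,
mu0+b, mu0+a+b+d, and i.i.d. N(0, sigma) replicate noise with sigma = 0.3
by default. A configurable fraction of genes (default 5%) is synergistic:
they receive mean single-mutant effects of −0.3 and an interaction
d ~ N(−1, 0.1) (sd = 0.1·|mean|); every other gene has d = 0 exactly,
giving a sharp null for type-I-error measurement. Optional per-array
smooth distortions (e.g. a gentle quadratic in intensity) create the
artefact class that loess normalization targets. Ct tables assume one
cycle per doubling, biological noise (default 0.1 cycles) shared across a
replicate's technical wells and smaller per-well technical noise. Not
emulated: probe-level chip structure, background/saturation effects,
amplification chemistry, heteroscedasticity, and correlated genes —
so passing tests demonstrate correctness of the statistical machinery
under its own model, not robustness to those real-data features.

Problem sizes used by the test suite and acceptance script — 10,000 genes
for null calibration, 2,000 genes for operating-characteristic and
normalization measurements — are the package's chosen desk-scale settings;
they keep Monte-Carlo error small relative to the asserted margins.

## Numerical choices and edge cases

- Contrast p-values are exact t probabilities; no moderation or shrinkage
  of s² (no empirical Bayes), matching the plain-ANOVA screen modelled.
- Ties in the loess abscissa are handled by the fitter's stable ordering;
  lowess runs with zero robustness iterations (the M residuals are
  Gaussian-scale, not heavy-tailed).
- `alpha = 0` yields empty screens for continuous data (q > 0 whenever
  p > 0).
- Gene order never affects screen membership; outputs are sorted (by p or
  by index) for reproducibility.
- All generators take a single integer seed; identical configurations are
  bit-identical.

## Known limitations

- LSmeans reduce to arithmetic means only because the design is balanced
  and single-factor; covariates or unbalanced designs would need a proper
  linear-model backend.
- The criterion-1 + criterion-2 cascade has low sensitivity when
  single-mutant effects are small relative to noise at r = 3 (the
  interaction test alone has ~70% power at |d| = sigma·10/3 but
  criterion 1 then dominates the loss); `scripts/acceptance.py` reports
  the measured values rather than hiding the attrition.
- The published-table letter reconstructions assume normality of the
  per-replicate normalized values with the reported means/SEMs.
- GRF-family over-representation can be checked only with an externally
  supplied family size (the published record does not state it); use
  `hypergeom_upper_tail(k, K_grf, 31, 22810)` directly.
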