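# Methods

This note documents the statistical models implemented in `dconet`,
the defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical decisions that
matter for reproducibility.

## Study design and orientation conventions

The package targets a two-group design with a reference group
("fertile") and a contrast group ("subfertile"), each with at least
three — by default six — samples. Every fold change is
contrast-over-reference (subfertile/fertile) and the "up"/"down"
direction labels refer to the subfertile group. Differential network
statistics are oriented fertile-minus-subfertile (DK = K_fertile −
K_subfertile). These conventions are applied uniformly; swapping the
group labels negates every log2FC, DK, RIF1 and RIF2 value and leaves
all p-values and |z| rankings unchanged (verified by tests).

## Differential expression (transcripts)

1. **Filter:** keep genes with CPM ≥ 10 in at least ⌈0.7·n⌉ samples.
2. **Normalization:** median-of-ratios size factors over the genes
   positive in every sample, rescaled to geometric mean 1; library-size
   ratios are the fallback when no such gene exists.
3. **Test:** per gene, group means μ_A, μ_B of normalized counts and a
   pooled moment estimate of the NB dispersion
   α = max(0, (s̄² − μ̄)/μ̄²). The contrast is
   log2FC = log2((μ_B + ½)/(μ_A + ½)) with delta-method standard error
   SE = (1/ln 2)·√((1/(μ_A+½) + α)/n_A + (1/(μ_B+½) + α)/n_B), and the
   Wald statistic z = log2FC/SE is referred to a **t distribution on
   n_A + n_B − 2 df**. The moment dispersion is itself estimated from
   the same few samples; at n = 6 per group the asymptotic normal
   reference is measurably anti-conservative (empirical type-I error
   ≈ 0.07–0.08 at p ≤ 0.05 in null simulations) while the t reference
   is calibrated (≈ 0.04–0.05). This is a deliberate small-sample
   choice, checked by the calibration acceptance test.
4. **Flags:** DEG iff p ≤ 0.05 and |log2FC| ≥ 0.5. Raw p-values are
   used for the flags (matching the thresholded-contrast convention
   this pipeline reproduces); BH-adjusted q-values are reported as an
   extra column but do not drive any decision.

There is no dispersion shrinkage, dispersion trend, LFC shrinkage or
independent filtering: the scientific content downstream is the
thresholded contrast, and the simplified test is validated by planted
recovery (≥ 95% of planted |log2FC| = 1.5–2 effects at n = 6) and null
calibration rather than by reproducing any particular fitter.

## Differential abundance (proteins)

Abundances are log2-transformed and median-normalized (per-sample
median subtracted, global median of medians added back, preserving the
scale). The test is an empirical-Bayes moderated t: per protein the
pooled two-group variance s²_g on d_g = n_A + n_B − 2 df; a prior
(d₀, s₀²) fitted by matching the first two moments of log s²_g through
digamma/trigamma relations (trigamma inverted by Newton iteration);
posterior variance s̃² = (d₀s₀² + d_g s²_g)/(d₀ + d_g); t on d₀ + d_g
df (standard normal when the variances show no excess spread and
d₀ = ∞). Missing values are handled complete-case per protein;
proteins with fewer than three observed values in either group are
excluded from the table, and proteins with any missing value are
additionally excluded from network construction. DAP iff p ≤ 0.05
(no fold-change threshold on the protein layer).

## PCIT edge selection

Networks are built per phenotype group on log2 normalized values
(log2(count/sf + ½) for transcripts; median-normalized log2 abundance
for proteins). For every trio (x, y, z) the three first-order partial
correlations are computed; the local tolerance is
ε = ⅓(|r_xy·z|/|r_xy| + |r_xz·y|/|r_xz| + |r_yz·x|/|r_yz|), where a
ratio with an exactly zero denominator contributes 0 (such an edge is
trivially eliminable anyway). Edge (x, y) is flagged non-significant
if for some z both |r_xy| ≤ ε|r_xz| and |r_xy| ≤ ε|r_yz|; edges never
eliminated are kept. Comparisons use ≤ with no tolerance fudge; the
guard against implementation drift is exact edge-for-edge equivalence
with an independent brute-force triple-loop oracle on 1,000 random
correlation matrices (an acceptance test). The production
implementation vectorizes the z-conditioned slice of the trio loop
with preallocated buffers; it is O(n³) time, O(n²) memory.

Retained edges then pass three post-hoc filters: a two-sided t-test on
the correlation (t = r√((n−2)/(1−r²)) on n − 2 df, the conventional
test for a Pearson coefficient — the edge-significance test is a
package decision since only "P ≤ 0.05" is conventionally reported for
such networks), a hard threshold |r| ≥ 0.95 within a layer (0.90 for
gene–protein edges), and the anchor rule: a gene edge must touch a DEG
or a RIF-flagged TF; a protein edge must touch a DAP; a cross-layer
edge must touch a DEG or DAP. Both the PCIT-retained and
p-significant pair counts are recorded in the network object because
published "significant connection" counts can refer to either stage.

## RIF and DK

RIF scores candidate regulators (an input TF list restricted to
expressed TFs) against the DE target list on the same normalized
matrices as the networks:

- PIF_j = ½(e1_j + e2_j)(e1_j − e2_j) — expression-weighted DE signal
  of target j, with e the per-group mean normalized (log-scale) value;
- RIF1_i = mean_j PIF_j (r1_ij − r2_ij)² — differential co-expression
  weighted by target importance;
- RIF2_i = mean_j [(e1_j r1_ij)² − (e2_j r2_ij)²] — change in the TF's
  ability to predict target abundance.

Both metrics are z-standardized across scored TFs (sample SD); a TF is
flagged when either |z| ≥ 1.96 (the two-sided normal critical value at
p ≤ 0.05). Scoring requires ≥ 3 TFs (a z-score over fewer is
meaningless); TFs with zero variance in either group are dropped. The
raw-scale choice for e (log-scale group means) is second-order because
the z-standardization is scale-free within a run.

DK uses degree normalized by the maximum degree within each group's
network (k/k_max), dk = k_fertile − k_subfertile, z-standardized over
the union node set, flagged at |dk_z| ≥ 1.96. Nodes absent from one
network count as degree 0; an empty network contributes k = 0
everywhere with a warning.

## Cross-omics integration

Matched pairs come from the protein→gene mapping file; when several
quantified proteins map to one gene the protein with the highest
median abundance is kept (deterministic; favors the better-quantified
isoform). Concordance is reported two ways, because the two framings
answer different questions: sign-based counts (up-up / down-down
concordant, exact zeros excluded) and a 3×3 grid with ±0.5 log2FC
boundaries (zeros fall in the neutral band). The fold-change
correlation is plain Pearson with its t-test p. Cross-layer
co-expression runs PCIT on the stacked gene+protein matrix per group
— so a gene–protein edge must survive conditioning on *both* layers'
features — and reports only heterolayer edges.

## Enrichment

ORA is the hypergeometric upper tail within an explicit background
(all tested features of the layer); layer results are combined per set
by one-sided Stouffer (z_i = Φ⁻¹(1 − p_i), combined z = Σz/√k).
Preranked GSEA ranks features by sign(log2FC)·(−log10 p) (p floored at
1e-300; ties broken by feature ID), computes the weighted running-sum
ES (weight exponent 1), and calibrates against gene-label permutations:
NES = ES / mean(|ES_null| among same-sign nulls), p_perm = same-sign
tail fraction floored at 1/n_perm. Gene-label permutation is the only
scheme available to a preranked method (the sample labels are already
consumed by the ranking). Multi-omics combination is directional
Stouffer, z_i = sign(NES_i)·Φ⁻¹(1 − p_i/2), so agreement requires
consistent direction; significance needs combined p ≤ 0.01 and
|NES| ≥ 1.5 on the layer NES of largest magnitude. The ES extremum is
taken as the larger of the maximal positive and negative running-sum
deviations; list reversal therefore negates ES exactly except on
floating-point ties between the two deviations.

## Synthetic-data generator

The generator emulates the two-group blood multi-omics design the
package targets, with every planted effect recorded as ground truth:

| parameter | default | meaning |
|---|---|---|
| `n_genes` / `n_proteins` | 600 / 300 | feature universe (scaled so the O(n³) network stage runs in seconds; real studies are larger but the statistics are size-free) |
| `n_per_group` | 6 | samples per group |
| `frac_de` | 0.08 | planted DEG and DAP fraction (half up, half down) |
| `lfc_de` | 2.0 | planted |log2FC| |
| `nb_dispersion` | 0.1 | single global NB dispersion α |
| `protein_sd` | 0.5 | log2-scale protein noise SD |
| `frac_missing` | 0.05 | protein missingness (MCAR) |
| `n_tf` / `n_targets` | 50 / 20 | TF list size; regulon size of the planted regulator |
| `hub_degree` | 25 | partners of the planted hub |
| `overlap_frac` | 0.33 | fraction of proteins mapped to a gene |
| `cross_coupling` | 0.2 | gene→protein sample-level coupling |

Counts are NB (gamma–Poisson) around log-normal baseline means
(log2 μ ~ N(5, 2)), with a 20% near-zero-expressed fraction so the CPM
filter has work to do, and per-sample size factors log-uniform in
[0.7, 1.4]. The planted regulator's targets are same-direction
(up-regulated) DEGs — a coherent activated regulon; with mixed-sign
targets the PIF weights in RIF1 cancel across the regulon and the
score loses its meaning. In the coupled group only, targets are
regenerated to track the regulator's size-factor-corrected log signal
with Poisson noise (pairwise r ≈ 0.95 in expectation); in the other
group they keep independent draws. The hub is a planted DEG outside
the regulon (so its edges pass the anchor rule) whose partners track
it the same way in the fertile group only. Proteins are log-normal
with a weak within-group coupling to their mapped gene's signal; the
coupling is group-centered so it transmits sample-level covariation
but not fold changes, keeping the cross-layer fold-change correlation
weak, as observed in real transcriptome–proteome comparisons.

What the generator does **not** emulate: read-level or peptide-level
data, mean–dispersion trends, batch structure, informative
missingness, correlated gene–gene background beyond the planted
structures, or isoform ambiguity in the protein mapping. Passing the
planted-recovery tests therefore demonstrates that the statistics
detect the effects they are designed for at the study's sample size —
not that they are robust to every artifact of real data.

## Numerical choices and degenerate inputs

- Pseudo-count ½ in fold changes and log transforms keeps zero groups
  finite and is standard practice.
- Zero-variance and missing-value features are removed before any
  correlation; reaching the correlation kernel with one is an error.
- Exact-zero denominators in the PCIT tolerance contribute 0.
- The moderated-t prior fit excludes zero variances; if all variances
  are equal the prior df is infinite and the normal reference is used.
- A single scored TF (or two) is refused rather than z-scored.
- p-values are clipped into (0, 1]; the GSEA permutation p is floored
  at 1/n_perm; rank statistics floor p at 1e-300.
- All randomness flows from one master seed through fixed offsets, so
  sub-stages are independently reproducible and two runs with the same
  seed produce byte-identical output files.

## Known limitations

- The simplified NB test has no dispersion shrinkage: it is calibrated
  and well-powered for the planted-effect sizes tested, but will be
  less efficient than shrinkage estimators for subtle effects on real
  data.
- At n = 6 per group the null distribution of a Pearson correlation is
  wide (SD ≈ 0.45); the |r| ≥ 0.95 edge threshold and the RIF/DK
  z-cutoffs inherit that noise, which is why recovery guarantees are
  stated over seeds rather than per run.
- Raw p-values (not FDR) drive the DEG/DAP flags by design; at 600
  features this admits a visible false-positive fringe around the
  planted sets.
- ORA treats features as exchangeable; no set-size or composition bias
  correction is applied.
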