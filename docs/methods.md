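# Methods

This note documents the models, conventions and numerical choices behind
each stage, what the synthetic generator does and does not emulate, and the
known limitations a user should weigh before applying the pipeline to real
data.

## Count model and preprocessing

Counts are modelled as negative binomial, `var = μ + αμ²`, with per-gene
dispersion α. The expression filter keeps a gene when its CPM is at least
`min_cpm` (default 1.0) in at least the smallest group's number of samples
and its total count is at least 15; the rule is deterministic and
deliberately simpler than design-aware library heuristics. Size factors are
median-of-ratios: the median over always-detected genes of the ratio of a
sample's count to the gene's geometric mean. The stabilizing transform is
`log2(count/sf + 1)` — closed-form and monotone. It is *not* a
fitted-dispersion variance stabilization; for the correlation-based stages
downstream (Pearson r is invariant to per-gene location/scale) the
difference is immaterial, and the output carries a provenance tag naming the
transform actually used.

## Differential expression

Per gene, a two-group NB GLM with log link and `log(sf)` offsets. The binary
design is saturated, so the IRLS normal equations decouple into two
independent one-parameter fits; we exploit that both for speed (vectorized
over genes) and for exact mirror symmetry: swapping condition labels negates
log2FC and the Wald statistic bit-for-bit and leaves p unchanged.
Convergence is `|Δβ| < 1e-8`, at most 50 iterations; non-converged genes are
reported with p = 1 and counted in the manifest. A group with all-zero
counts drives its mean parameter to the working lower bound; the fold change
is then capped at ±30 log2 units and flagged.

Dispersion is method-of-moments on size-factor-normalized counts, pooling
the two condition-level means and variances, floored at 1e-8. There is no
dispersion shrinkage, no fold-change shrinkage and no outlier filtering —
declared simplifications relative to full DE frameworks. DEG calls gate on
the **raw** p-value (p ≤ 0.05) together with |log2FC| ≥ 0.5; BH-adjusted
values are reported but not used for the call. Measured on null simulations
(2,000 genes, 6 vs 6) the type-I error is ≈ 0.06–0.08 — mildly liberal, as
expected for a Wald test with plug-in moment dispersions at n = 6.

## Regulatory impact factors

Condition A is the reference (CON), B the treatment (VTM); condition means
`e` are taken on the stabilized scale (a declared choice — raw-scale means
would weight abundant genes more strongly). Correlation conventions: a pair
with zero within-condition variance scores r = 0 (warned); a TF that is
itself a DEG is excluded from its own target average (its self-correlations
are zeroed and its n_de decremented) but remains a target for other TFs.
Significance is the |z| ≥ 1.96 rule on the cross-TF distribution of each raw
metric, not a permutation test. The module logs three bookkeeping counts for
any input: TFs in the list, TFs tested (expressed), TFs removed.

## PCIT

The tolerance ε uses **signed** ratios of first-order partial to direct
correlations; the elimination test compares absolute values. Conventions for
degenerate trios: if any direct correlation of the trio is below 1e-12 the
trio cannot eliminate (the ratio is undefined); a near-zero
partial-correlation denominator skips the trio. Off-diagonal correlations
are clipped to ±0.999999 before the O(n³) pass. The inner loop is a
numba-compiled triple loop with early exit per edge; 2,000 genes take a few
seconds on one CPU, and a warning is raised above 5,000 genes. The unit and
acceptance suites verify the kernel against a literal Python triple-loop
reference on random positive-definite matrices.

The magnitude threshold (default 0.9) is applied to the **direct** Pearson r
of PCIT-surviving edges; restricting the threshold instead to the minimum
absolute partial correlation over all conditioning genes is available via
`r_mode="partial_min"`. Network nodes are the endpoints of retained edges;
genes isolated after filtering are absent.

## Differential connectivity

Degrees are max-normalized per network (`k = K/max K`, k ≡ 0 for an empty
network); DK = k_treatment − k_reference is computed over the union of both
node sets, with genes present in only one network entering at degree 0, and
z-scored across that population (`dk_population="keep"` restricts the
population to the DEG/RIF genes instead). Classes: gained at z ≥ +1.96,
lost at z ≤ −1.96. DK is exactly antisymmetric under swapping the two
networks.

## Enrichment

The GSEA rank statistic is `sign(log2FC) × −log10 p` with p clamped at
1e-300 (clamping is logged); ties are broken lexicographically by gene id so
the ranking is deterministic. The running sum uses weight exponent 1 (hits
step by normalized |rank|, misses by 1/(N − n_set)); the enrichment score is
the running-sum value of largest magnitude, first occurrence on ties. The
null is gene-label permutation: membership positions resampled uniformly,
NES = ES / mean |ES*| over same-sign permutations, nominal
p = (1 + #{|ES*| ≥ |ES|, same sign}) / (1 + #same-sign), so p is
add-one-smoothed and scale-invariant. ORA is the exact hypergeometric upper
tail over the expressed-gene universe with BH control; sets disjoint from
the universe are excluded and logged.

## Synthetic data

The generator emulates a 6-vs-6 bulk RNA-seq contrast at desk scale: 2,000
genes of which 100 are TFs, log-normal baseline abundances
(`ln μ ~ N(5.5, 1.5²)`, ≈10⁶ mean depth), gamma-distributed dispersions
(shape 2, rate 40, mean α = 0.05), and uniform library factors in
[0.7, 1.3]. Ten regulatory modules of 15 targets share a per-sample latent
factor with their TF; a target's latent component is
`coupling·f + √(1−coupling²)·ε`, so the TF–target correlation before count
noise equals the coupling, and the term is mean-centred (−latent_sd²/2,
latent_sd default 0.7) so coupled genes keep the same expected count. At
coupling exactly 0 the latent term is dropped, making decoupled genes
exactly negative binomial — the moment checks in the test suite rely on
this. A module whose coupling differs between conditions is rewired and its
TF is a ground-truth positive.

Planted DEGs (default 10% of genes, |log2FC| uniform in [0.5, 2] applied to
the treatment condition) are drawn module-targets-first with a coherent
direction per module — the modelling stance is that rewired regulation
drives expression change — and any remainder comes from free genes with
random directions. Seeds fan out through named, counter-based child streams,
so a fixed seed gives bit-identical output regardless of call order.

What the generator does **not** emulate: batch effects, GC/length bias,
outlier samples, count overdispersion trends with abundance, overlapping
regulons, and signed (repressive) couplings. Passing recovery tests on this
data therefore demonstrates the machinery is correct and calibrated, not
that real-tissue effect sizes are detectable at n = 6.

## Validation experiments and their designs

- **DE calibration**: null simulation (no DE, no coupling), 2,000 genes;
  fraction of p ≤ 0.05 must lie in [0.02, 0.09].
- **RIF recovery**: strong-signal preset (10 rewired 50-target regulons, all
  targets DE at |log2FC| = 2), ranking TFs by max(|z RIF1|, |z RIF2|).
  A power analysis sets expectations here: at n = 6/group the sampling sd of
  a Pearson correlation is ≈ 0.45, and because the DEG set is clustered into
  coupled modules, a TF's mean squared differential wiring has a noise floor
  (~0.06) that more DEGs cannot average away, while the own-module signal
  share is 1/n_modules (~0.07). Median AUROC over seeds is therefore ≈ 0.6
  with this design and stays below ~0.85 for any generator setting we
  examined; the acceptance suite keeps the aspirational ≥ 0.9 bound and
  currently fails it, honestly. Detecting rewired regulators from six
  replicates per group is, by this analysis, underpowered — a caveat that
  applies to real studies of this design, not only to the simulation.
- **DK module enrichment**: one rewired module next to one stable module in
  a narrow genome (400 genes). The width matters because at n = 6 a
  |r| ≥ 0.9 cut passes ≈1.5% of null pairs, so noise degree grows with gene
  count while the module's signal degree does not. Median Fisher p over 10
  seeds is ≈ 1e-5.
- **GSEA calibration/recovery**: calibration uses 200 uniformly random sets
  on a smooth ranked list (fraction of p ≤ 0.05 lands on 0.05). Recovery
  uses a single coherent 50-gene program over a 3% DEG background: with many
  strong programs the permutation null |ES*| is itself inflated and caps the
  NES at ≈1.25 for every set, so the |NES| ≥ 1.5 flag is only meaningful in
  the one-program regime, where the planted set is recovered in 10/10 seeds.

## Numerical and interface choices

- Thresholds (p ≤ 0.05, |log2FC| ≥ 0.5, |z| ≥ 1.96, |r| ≥ 0.9, FDR ≤ 0.05,
  GSEA p ≤ 0.1 with |NES| ≥ 1.5) are config fields, not constants.
- The condition order (which level is the reference) always comes from the
  caller/config, never from sorting the data.
- Output tables carry a `#` header comment with the config hash and seed;
  the manifest counts every warning (zero-variance genes, clipped
  correlations, non-converged fits).
- All stages are re-runnable from saved intermediates and reproduce the
  full-pipeline outputs exactly.

## Problem sizes

The shipped analyses and tests run at desk scale — 2,000 genes, 12 samples,
1,000 permutations, 10-seed medians — chosen so the whole study re-runs in
minutes on a laptop while preserving every structural feature of the
full-size design (the motivating study had ~13,000 expressed genes and the
same 6 vs 6 layout). PCIT is the only O(n³) stage and handles the ~13,000
gene scale in roughly an hour; all other stages are effectively linear.
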