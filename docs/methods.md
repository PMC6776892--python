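# Methods

## Scope and model

`polyswitch` analyses broad repressive chromatin domains (EZH2 / H3K27me3)
across cellular states and integrates them with inhibitor-response RNA-seq.
It starts from fragment-level intervals (BED3) — alignment, deduplication at
the read level and blacklist filtering are upstream concerns — and from
gene-level counts. Everything downstream of those inputs is implemented
here: island calling, consensus merging, co-occupancy filtering,
differential-binding classification, TSS annotation, differential
expression, the integration cascade, feature-enrichment tests, methylation
summaries and FISH scoring.

## Island calling

The caller is a self-contained re-derivation of the window-clustering
family of broad-peak methods, parameter-compatible with the published
tools' settings (window 200 bp, gaps 400/600 bp, effective genome fraction
0.75, redundancy threshold 1, island FDR 10⁻⁴) but with a documented,
testable statistic:

- Background per-window mean λ = N·w / (G·f). With the default synthetic
  depth (2×10⁵ fragments, 10 Mb genome) λ ≈ 5.3.
- Window eligibility at Poisson upper-tail ≤ 0.2 — the smallest integer
  count c₀ with P(X ≥ c₀ | λ) ≤ 0.2.
- Islands: maximal runs of eligible windows whose internal stretches of
  ineligible sequence are ≤ the gap size.
- Island score: Σ −ln P(X ≥ kᵢ | λ) over eligible windows; island p-value:
  the Poisson upper tail of the island's total count at λ × (windows
  spanned); Benjamini–Hochberg across candidate islands, retained at
  q < FDR.

Equivalence with any specific published tool's score-distribution FDR is
not claimed; on micro-fixtures the caller equals exhaustive enumeration of
eligible runs, and on synthetic genomes it recovers planted domains with
recall and precision ≥ 0.9 at 8× enrichment.

The `fragment_size = 110` setting of the original tools parameterises
single-end read extension; with true fragment intervals it is accepted and
ignored, with a logged notice.

Fragments are assigned to windows by midpoint (floor((start+end)/2)), not
by overlap, so each fragment counts exactly once and window counts conserve
the library size — which keeps the background model analytically checkable.

## Numerical choices

All Poisson tails are computed in natural-log space. For k ≤ λ the tail is
log1p(−Q(k, λ)) with Q the regularized upper incomplete gamma (the
complement is ≤ ½ there, so precision is full even when p is within 1e-300
of 1); for k > λ the tail is log pmf(k) plus the log of the convergent
ratio series 1 + λ/(k+1) + λ²/((k+1)(k+2)) + …, truncated at 1e-18 relative.
This keeps log p exact far below the double-precision floor (the acceptance
grid reaches log₁₀ p ≈ −3000). Verified against arbitrary-precision
summation to 1e-6 relative error in log₁₀ p; in the degenerate p ≈ 1 region
(|log₁₀ p| < 1e-12) an absolute tolerance of 1e-12 applies because the
relative metric on the log is ill-posed there.

Fisher's two-tailed test uses the point-probability rule evaluated in exact
rational arithmetic (integer binomials via `math.comb`, `Fraction` sums),
so knife-edge ties between table probabilities are resolved exactly rather
than to a floating-point epsilon; the hypergeometric overlap test is exact
in the same way. BH and Holm adjustments are vectorised implementations of
the step-up/step-down definitions and are cross-checked against
`statsmodels` in tests.

## Differential binding

The site union fuses islands overlapping by ≥ 1 bp across states into
common sites (spanning interval); unique islands keep their extent.
Normalisation is tags per 10⁷ library fragments with replicates pooled, and
the enrichment test is Poisson with a pseudocount of 1:
fold = (t+1)/(b+1), p = P(X ≥ round(t) | max(b, 1)). The observation is
rounded because normalised counts are non-integer while the test's
semantics are count-like. The test runs in both directions around the
union; classification thresholds (fold ≥ 1.5, p ≤ 10⁻²⁰) are inclusive,
and a site passing both directions (possible only when fc_min = 1) is
classified unchanged. The normalisation depth and pseudocount are exposed
in `DiffParams` since published differential-peak tools do not document a
single convention. Volcano output floors p at 10⁻¹⁰⁰ for display only;
classification always uses the unfloored value.

## Annotation

Site–TSS distance is measured from the site edges (0 inside the interval),
matching the "peak overlapped with … TSS" semantics rather than midpoint
distance. All TSSs inside a site are recorded; otherwise all genes at the
exact minimal distance (bp equality, no tolerance); assignments beyond 5 kb
are dropped. One TSS per gene id is assumed; collapsing multi-isoform
annotations to the most upstream TSS per gene is a documented
pre-processing convention of the caller of this library.

## Differential expression

The NB engine is a deliberate simplification of full DE packages: no
Cox–Reid dispersion adjustment, no fold-change shrinkage, no independent
filtering. Concretely: median-of-ratios size factors over all-nonzero
genes; per-gene method-of-moments dispersion from the pooled within-group
variance, shrunk 50/50 toward a fitted trend α(μ) = a + b/μ and floored at
1e-8; log₂ fold change of normalised group means with a 0.5 pseudocount;
delta-method Wald SE √[(1/μ̂_A + α)/n_A + (1/μ̂_B + α)/n_B]/ln 2; two-sided
normal p; BH over genes with nonzero total count. Its acceptance surface is
calibration and power on simulated data (null p<0.05 fraction within
[0.03, 0.07] at n = 3 vs 3 and dispersion 0.05; power ≥ 0.8 for 4-fold
effects at base mean ≥ 50) rather than equivalence to any package.

`max_tpm` is the maximum over per-condition *mean* TPM, reading "maximal
TPM across conditions" literally; the sensitivity criteria are
FDR ≤ 0.01, log₂FC ≥ 1 and maxTPM ≥ 1, all inclusive. Between-state DE
(vehicle vs vehicle) reuses the same engine and the same thresholds, which
the source analyses did not state separately; they are exposed in
`DEThresholds`.

## Integration cascade

Direction conventions: state A is the reference (untransformed-like), state
B the transformed-like state, configurable rather than hard-coded to any
particular cell system. For the B-direction cascade, candidates are genes
annotated to B-enriched large-magnitude sites; filter 2 intersects with the
EZH2i-upregulated set of B; filter 3 requires between-state log₂FC(B/A)
≤ −1 at FDR ≤ 0.01 (silenced-in-B); the A-direction cascade is symmetric
with ≥ +1 (de-repressed-in-B). A gene annotated to both an A-enriched and
a B-enriched site is ambiguous — a case the filtering logic does not
define — and is excluded from final sets with a logged listing. Tightening
any threshold can only shrink the final sets (monotone filtering).

## Methylation and FISH

Clone matrices (clones × CpGs, 0/1/missing) are summarised as methylated /
non-missing fractions per CpG, per clone and overall, with all-missing
CpGs reported as missing and excluded. Gene-set comparisons use an
unpaired pooled-variance t-test per cell line / sample — the equal-variance
form is a choice, as the source analyses do not state the variance
assumption — with Holm step-down correction across the family; degenerate
identical samples give t = 0, p = 1. FISH scoring uses the mean of
per-image foci/nuclei ratios (not pooled counts). The printed band
intervals ("0–0.5", "0.51–0.75", "0.76–1", ">1") leave gaps such as
(0.50, 0.51) undefined for continuous means, so bands are implemented as
half-open at 0.50 / 0.75 / 1.0, making the function total and monotone.
A field is positive at ratio strictly greater than 0.8.

## Synthetic data generator

The generator emulates the statistical structure of the emulated study
design, not its sequences: two or three cellular states with two ChIP
replicates per state and mark; uniform background fragment coverage with
broad enriched domains (default 10 kb, 8× enrichment) — shared,
state-specific, and switch-gene domains — every EZH2 domain nested in an
H3K27me3 domain extended 2 kb on each side; fixed-length fragments
(200 bp, the sheared-chromatin regime) placed by midpoint from the
piecewise-constant intensity, so window counts are exactly Poisson and the
model is analytically checkable. Replicates share domain positions and
differ only by stream and a ±20 % library-size jitter, mirroring high
replicate concordance. RNA counts are negative binomial (dispersion 0.05)
with base means spanning four orders of magnitude (10⁻¹–10³), ±30 %
sample size factors, a 2²-fold planted EZH2i response in sensitive genes,
and switch genes repressed 2² -fold in every state where their promoter
domain is present (so gain-in-B ⇒ lower in B, loss-in-B ⇒ higher in B,
and EZH2i partially restores expression in the bound state). Planted
sensitive and switch genes draw base means ≥ 50 so that the planted
effects are detectable at the study's replicate numbers; switch-gene
domains are centred on the TSS (distance 0), keeping ground truth free of
annotation edge cases, which are tested separately. Promoter methylation
draws from Beta(2, 8) for sensitive and Beta(8, 2) for insensitive genes —
anti-correlated with inhibitor sensitivity — and clone matrices are
Bernoulli draws at the gene's planted fraction.

Randomness: one root seed; child streams derived per (purpose, state,
mark/treatment, replicate) via CRC32-keyed `numpy.random.SeedSequence`
spawns, so outputs are byte-reproducible and adding a sample never
perturbs existing ones.

Default problem sizes — 2 × 5 Mb chromosomes, 400 genes, 20 common + 10
state-specific domains per state, 3 + 2 switch genes, 2 × 10⁵ fragments
per ChIP sample, 3 RNA replicates per condition — are chosen as the
smallest study at which all planted structure is comfortably detectable
with the same statistical margins as a real broad-mark experiment.

### What passing tests do and do not show

The generator's background is homogeneous and mappability-uniform; it has
no input-control bias, copy-number structure, GC effects, fragment-length
variation or isoform complexity, and domains have hard edges. Recovery
results on this data validate the pipeline's logic, thresholds and
statistics — they do not certify performance on real libraries, where
background structure and soft domain boundaries will erode the margins.

## Known limitations

- The island FDR is BH over candidate islands, an approximation of the
  original callers' score-distribution FDR; absolute island counts at a
  given FDR may differ from those tools on the same data.
- The DE engine's Wald test with n = 2–3 replicates is mildly conservative
  near zero counts and has no outlier handling.
- The cascade treats promoter binding as the only linkage between sites
  and genes; distal regulation is out of scope.
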