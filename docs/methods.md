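# Methods

## The prioritization model

`cilioprior` treats candidate-gene prioritization as a deterministic funnel
over typed tables. Coordinates are 1-based inclusive everywhere inside the
package; the BED convention (0-based half-open) is converted exactly once, at
the I/O boundary, which is the only place an off-by-one can enter.

### Genomic blocks

Risk SNPs are grouped per chromosome by single-linkage under the relation
|pos_i − pos_j| < merge threshold (strict inequality; a gap exactly equal to
the threshold does not merge). On a sorted list this reduces to chaining
adjacent SNPs, which equals the transitive closure of the pairwise relation —
the property the test suite verifies against an all-pairs union-find oracle.
Each group is flanked symmetrically (default ±1 Mb, floored at base 1 with a
warning) and labeled in genome order (`GWAS_EOC_1`, `GWAS_EOC_2`, …).

Two deliberate consequences of taking the grouping rule literally:

- blocks from distinct groups **may overlap** (a flank reaches up to 1 Mb
  past the group boundary while groups only require ≥1 Mb SNP separation);
  overlap never forces a merge. The published block list itself contains
  overlapping retained blocks, which is why overlap-merging was rejected.
- labels are assigned by genome order for determinism; when comparing
  against the published table, that table's own label→locus assignment is
  authoritative, not regenerated.

LD proxies are consumed, never computed: a proxy with r² ≥ 0.5 (default) must
lie inside its index SNP's block; the containment report lists violations.
Proxies below the threshold are ignored.

### Moderated differential expression

The two-group model per probe g on a log2 matrix is

- logFC_g = mean(HGSOC) − mean(FTE),
- s²_g = pooled residual variance, d_g = n₁ + n₂ − 2,
- prior: σ²_g ~ s₀²·d₀/χ²_{d₀} (scaled inverse chi-square),
- posterior variance s̃²_g = (d₀ s₀² + d_g s²_g)/(d₀ + d_g),
- t_g = logFC_g / √(s̃²_g (1/n₁ + 1/n₂)), two-sided p on d₀ + d_g df.

(d₀, s₀²) are moment-matched on z = log s²_g: Var(z) = ψ′(d_g/2) + ψ′(d₀/2)
and E[z] has closed form in digamma, so d₀ comes from a Newton inversion of
the trigamma function and s₀² from the mean equation. When the observed
spread of z does not exceed the chi-square sampling noise (underdispersed
variances), d₀ = ∞: every probe shrinks fully to s₀² and the reference
distribution becomes normal. Zero-variance probes are excluded and logged;
fewer than two probes makes the prior unestimable and raises an error
pointing at plain mode. The fit was cross-checked once against an
independent reference empirical-Bayes implementation on a frozen 30-probe
fixture and agrees to ~1e-9 relative error (tests/data/limma_oracle.tsv).

`shrink=False` (CLI `--method plain`) drops the prior (d₀ = 0), reducing the
statistic to the pooled-variance two-sample t — a sensitivity-analysis mode,
not the default.

Multiplicity is controlled by Benjamini–Hochberg step-up (delegated to
statsmodels behind the module surface and property-tested against the
literal step-up definition). The adjustment method is a package choice: the
source analyses report only "adjusted p", and BH is the default of the
standard toolchain for this kind of data. Thresholds are strict on both
sides: q < 0.05 and |logFC| > 1. Concordance across the two datasets
requires joint significance **and** matching sign — a sign flip is never
concordant.

### Block overlap and gene dedup

A concordant probe hits a block when its gene span shares ≥1 base with the
block (any-overlap of the full annotated span; not TSS-only, not full
containment — the least surprising reading and the one an all-pairs oracle
can check). Probe-level hits collapse to one record per (gene, block); the
representative probe is the smallest q in dataset A, ties broken by larger
|logFC|, then lexicographic probe id. A gene overlapping two blocks keeps
two records, matching the published table where one block hosts two genes
and one gene span touches two blocks.

### Tissue-specificity rank filter

For each candidate, the 25 tissues shared by the two resources are ranked
per resource by expression, and the gene passes iff some target tissue
(cervix, endometrium, fallopian tube, ovary) occupies a top-k position
(k = 2) in *both* resources. "Occupies a top-k position" is made exact as:
strictly fewer than k **non-target** tissues exceed it. The tie rule is
deterministic and favors inclusion (an exact tie cannot demote a target);
another target tissue ranking higher never demotes either. Ranking is
within-resource, so cross-resource unit mismatch (TPM vs FPKM) is irrelevant
by construction; the filter is invariant under any strictly monotone
per-row transform, which is property-tested. An all-zero row fails with an
"unexpressed" note rather than receiving a rank. The identity of the shared
tissues is a required config input (YAML), never hard-coded; only the
default panel of the synthetic generator bakes in a 25-name list.

### Reviewer consensus and summary

Two reviewers each call one localization class per gene from the enum
{ciliated, ciliated_subset, serous, ciliated_and_serous, not_expressed,
ambiguous, not_available}. Agreement stands; disagreement resolves to the
joint adjudication when present, else to `ambiguous` with an "unresolved"
flag. The published table's vocabulary maps onto the enum ("Ciliated cells
(not all)" → ciliated_subset, "Not detected" → not_expressed, "Not
available" → not_available) so the fixture round-trips. Summary counts:
`definite` = not in {ambiguous, not_available, not_expressed};
`ciliated-positive` = {ciliated, ciliated_subset, ciliated_and_serous}
(serous-only genes are definite but not ciliated-positive); the percentage
of blocks containing a ciliated-positive gene is **truncated** to a whole
percent (10/54 → 18%), matching the printed arithmetic.

## The synthetic study

The generator's defaults are the study's conditions, not tuning knobs:

| parameter | default | why |
|---|---|---|
| SNP panel | 76 SNPs (70 substitutions, 6 indels) in 54 planted clusters | the real panel's composition and block count |
| flank / merge | 1 Mb / <1 Mb strict | the published interval rule |
| expression designs | 10v10 and 24v11 | the two source datasets' sample sizes |
| probes | 2000 | enough for stable prior moment-matching, seconds to run |
| variance prior | d₀ = 4, s₀² = 0.05 log₂-units² | typical microarray-scale probe variance heterogeneity |
| planted DE | 5% of probes at ±2 log₂FC | clearly detectable at n = 10v10 without being trivial at the |logFC| > 1 cutoff |
| DE genes in blocks | 50% | funnels a realistic minority of DE genes into candidate regions |
| tissue panel | 25 tissues incl. the 4 targets, k = 2 | the published filter's geometry |
| planted specific genes | 28 (drawn from DE-in-block genes) | the published shortlist size |
| reviewer discordance | 0.3 | roughly the adjudication burden a real dual review produces |

Baseline log2 expression is Normal(7, 1); per-probe variances are drawn from
the scaled inverse chi-square prior, so the moderated model is exactly
correctly specified — deliberate, because the null-calibration test (type-I
error ≈ 0.05) is then a sharp check of the implementation rather than of
model robustness. Cluster placement guarantees intra-cluster gaps < the
merge threshold and inter-cluster gaps ≥ it, so the block partition is
forced, not probable. Planted tissue-specific genes get a target tissue as
their row maximum in both resources; background genes get all target tissues
below every non-target tissue, so recovery is exact by construction. One
master seed drives all generators through fixed per-module substreams
(`default_rng([seed, stream_id])`): regenerating one input never perturbs
another.

What the generator does **not** emulate: probe-level microarray artifacts
(probe effects, batch structure, background correction), realistic LD
structure, correlated expression between neighboring genes, and
tissue-expression correlation between the two resources. Passing tests
therefore demonstrate the pipeline's correctness and calibration under the
stated model, not robustness to real-data messiness; the real headline gene
lists additionally depend on external data the package only consumes.

## Numerical and policy choices

- Trigamma inversion by damped Newton iteration (50 iterations max,
  relative tolerance 1e-10), with asymptotic closed forms outside
  [1e-6, 1e7].
- Probe rows with any missing value are dropped at read time and counted in
  the log (simplest defensible policy; the testing model needs complete
  two-group rows).
- Indel position = first affected base (BED start + 1); a single convention
  is needed for interval arithmetic and none is externally specified.
- The published block list prints spans that exceed an exact 2 Mb by 1 bp
  for apparently single-SNP blocks; its end-coordinate convention is not
  recoverable, so the fixture stores coordinates verbatim and the interval
  builder keeps its own convention (end = max pos + flank) without forcing
  agreement.
- Chromosome ordering is natural (chr1 < chr2 < … < chr10 < chrX), applied
  to block labeling and BED output.
- Every stage is deterministic; the only randomness in the package lives in
  the synthetic generator and is fully seed-derived.

## Problem sizes

Simulation-backed tests use 300–2000 probes, ≤50-SNP panels and 141-gene
tissue tables; the full suite runs in a few seconds, and
`scripts/acceptance.py` (which regenerates the default-scale study and runs
the entire funnel twice over) in under ten. These sizes were chosen so a
reader can rerun everything interactively while keeping Monte-Carlo error
small relative to the tested tolerances (e.g. ±3 s.e. ≈ ±0.015 on the
type-I error at 2000 probes).

## Known limitations

- The real 141-probe and 28-gene lists require the original external
  datasets (two GEO series, GTEx, HPA) and are out of reach offline; the
  package reproduces the *procedure* and the published table's arithmetic,
  and validates the procedure on planted truth.
- Gene assignment is purely positional (span overlap); no eQTL or
  distance-weighted locus-to-gene scoring.
- Only unpaired two-group designs; no batch correction or normalization —
  matrices are consumed already log-scaled.
- Inter-rater agreement is reported only as the adjudicated/unresolved
  flags; no kappa statistic is computed.
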