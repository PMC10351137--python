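# Methods

`snp2enhancer` re-creates, as a tested pipeline, the desk analysis that
nominates a causal regulatory variant at a GWAS locus and corroborates
it with chromatin-contact, single-cell and reporter-assay evidence.
This note records the models, the parameters that matter, and the
design choices made where the procedure was genuinely open.

## The prioritization cascade

The pipeline's core is a monotone evidence cascade over the candidate
SNPs at a locus:

1. **LD expansion.** From a phased haplotype panel, every variant
   within a window (default 1 Mb) of the index SNP with r² strictly
   above 0.8 joins the candidate set. LD is computed from haplotype
   counts: with alt-allele frequencies `pA`, `pB` and joint alt–alt
   frequency `pAB`, `D = pAB − pA·pB`, `r² = D²/(pA(1−pA)pB(1−pB))`,
   and `D′ = |D|/Dmax` with the usual sign-dependent `Dmax`. r² equals
   the squared Pearson correlation of the 0/1 haplotype columns — the
   test suite asserts this equivalence to 1e-12 against an independent
   oracle. X-chromosome panels pool male (one haplotype row) and
   female (two rows) samples. Unphased diploid input is rejected
   rather than phased in-package: the estimator stays exact and
   testable, at the cost of requiring a phased reference panel, which
   is what such analyses use anyway. The strict `>` at the threshold
   follows the published criterion; the index SNP is always reported
   (flagged `is_index`), so at an unattainable threshold of 1.0 the
   proxy set is empty but the index row remains for auditability.
2. **eQTL annotation (tier 2).** Candidates are matched to a
   GTEx-style association table on (chrom, pos, ref, alt); the slope
   is harmonized so it is always per alt-allele copy (an involution:
   flipping the effect allele and slope sign changes nothing).
   Significance is taken from the table (the upstream eQTL catalogs
   ship pre-filtered significant associations); a `pvalue_max` filter
   is exposed for synthetic use and defaults to 1.0. Candidates with
   no record continue with a null annotation — they fail the tier, not
   the pipeline.
3. **Epigenomic overlap (tier 3).** A SNP at 1-based position `p` hits
   a half-open peak `[start, end)` iff `start ≤ p−1 < end`. Hits are
   partitioned into TF ChIP-seq versus regulatory (histone /
   open-chromatin) datasets; tier 3 requires at least one of each.
   Membership is evaluated with vectorized interval tests per dataset
   (desk-scale inputs; no interval-tree dependency) and is checked
   against a quadratic brute-force oracle in the tests.
4. **Allele-dependent motif scoring (tier 4).** For each motif, both
   alleles are substituted into the sequence context and scored at
   every offset that keeps the SNP inside the motif window, on both
   strands; the best placement per allele is kept (ties break at the
   smaller offset, then + strand). The log-odds weight of base `b` at
   position `i` is `log2(f̃(i,b)/background(b))` with pseudocount
   smoothing `f̃ = (f + pc/4)/(1 + pc)`, `pc = 0.1` and a uniform
   background by default (both configurable; the published analysis
   names neither). The ΔΔG energy parameterization is
   `e(i,b) = −(ln f̃(i,b) − mean_b′ ln f̃(i,b′))` in RT units:
   mean-centered rows, preferred bases negative, so an energy logo
   plots height `−e` with preferred bases above the axis. With a
   uniform background the two parameterizations are affinely related
   per window and rank sequences identically (asserted numerically).
   A (candidate, motif) pair is flagged when `|Δ| ≥ 2` bits **and**,
   with the ChIP gate on, the candidate lies inside a TF ChIP-seq peak
   for that factor — a predicted allelic site is only credible where
   the factor is observed bound. The 2-bit default is a package
   choice (no published cutoff exists); it is recorded in every
   output.

Ranking makes the final cross-referencing explicit: a stable sort on
(tier desc, max |Δ| desc, TF-dataset count desc, r² desc, position
asc), which is deterministic and permutation-invariant. A composite
score `tier + 0.5·tanh(max|Δ|/4)` is reported for transparency only —
the sort key, not the score, defines the order.

## Corroborating analyses

**Observed/expected contacts.** The expected count at bin separation
`d` is the mean over all bin pairs at that separation in the supplied
table; distances carrying fewer than `min_pairs = 10` pairs are pooled
greedily with neighboring distances before averaging. A bait-bin
profile reports every bin with O/E at or above 2.00 (the threshold the
published analysis set in its 3D-contact browser) and calls promoter
hits where a gene's TSS ± 2 kb falls in a reported bin. O/E is
scale-invariant in the counts; the estimator matches brute-force pair
enumeration in the tests. The exact expected-value estimator used by
the original web resource is not documented; equivalence with it is
not claimed — this is the standard binned-mean O/E construction.

**Single-cell enrichment.** A cell expresses the gene when its raw
count reaches `min_count = 1`; no normalization (the statistic is
presence/absence, and clustering is an upstream input, not computed
here). Per cluster: expression frequency, enrichment fold over the
all-cell frequency, and an upper-tail hypergeometric p-value
(population = all cells, successes = expressing cells, draws = cluster
size). The published figure does not name its test; the hypergeometric
is the simplest exchangeable null consistent with a
(frequency, fold, p) triple, and is validated against exhaustive
enumeration for populations up to 12 cells.

**Reporter statistics.** Per well, nano/firefly; then division by the
same-condition mean backbone ratio, so the empty backbone normalizes
to 1. The allelic comparison is a two-sided pooled-variance Student's
t-test ("Student's t-test" read literally; Welch is available behind a
flag, and two-sided is the conservative default since sidedness was
not stated). Experiments and replicates are modeled as a flat well
table; no mixed-effects model for experiment-level variance — a known
limitation, acceptable at 3×3 wells per construct.

## The synthetic study

The generators stand in for the external resources the real analysis
downloads, with the ground truth recorded so every stage can be
scored. All generators are pure functions of `SimConfig`; the same
seed reproduces outputs byte-for-byte.

- **Haplotypes** follow a founder-mosaic copying model: each haplotype
  copies one of 12 founders (per-site founder frequencies uniform in
  [0.2, 0.8]), switching founders with probability 0.15 per site and
  flipping the copied allele with probability 0.02. Three parameters
  give tunable LD with no coalescent machinery. Defaults: 2000
  haplotypes (1000 phased female samples), 60 SNPs ~3 kb apart on the
  X chromosome. The causal column is built from the index column by
  flipping each haplotype's allele with probability `q` solved from
  `(1−2q)²·p(1−p)/(pY(1−pY)) = target r²` given the realized index
  frequency `p` (`pY = p + q(1−2p)`); the naive `q = (1−√r²)/2` is
  biased low whenever `p` is away from 0.5. The realized r² is
  stochastic and recorded. A degenerate monomorphic index column is
  flagged (`realized_r2 = None`) rather than silently reported; a
  polymorphic but near-fixed column (MAF < 2%) raises with a
  suggestion to reseed.
- **Annotation layers.** The causal SNP sits in one H3K27ac peak and
  two TF ChIP-seq peaks for the planted factor ("observed bound in
  multiple experiments"); the index SNP gets a histone peak only; one
  decoy gets an open-chromatin peak; all other decoys are clean. SNPs
  in LD with the causal SNP (r² > 0.2) receive eQTL records with slope
  `−r²` per alt copy (risk allele lowers expression) and p-value
  `10^−(1+19r²)`. The planted motif (length 8) matches the reference
  flanking sequence at 0.7 per column, with its most informative
  column on the causal SNP: reference base 0.85, risk base 0.05 — the
  allelic penalty is ≈3.5 bits, comfortably past the 2-bit flag.
- **Contacts.** `C(i,j) = 100·exp(−|i−j|/8)` over 60 bins of 40 kb,
  multiplicative lognormal noise with CV 0.1, and the (enhancer bin,
  promoter bin) entry — 5 bins, 200 kb apart, matching the locus
  geometry — multiplied by `loop_strength = 3`.
- **Single-cell counts.** 23,110 cells in 8 named clusters; the
  planted stromal cluster holds 4% of cells. The target gene is
  expressed with probability 0.052 inside the planted cluster and
  0.0158 elsewhere; expressing cells draw `1 + NB(mean 2,
  dispersion 0.5)` counts (only presence matters downstream), filler
  genes carry Poisson noise. Note an arithmetic consequence of these
  frequencies: because the planted cluster contributes to the all-cell
  frequency, the expected enrichment fold is
  `0.052/(0.0158 + 0.0362·w) ≤ 3.29` for cluster fraction `w`
  (≈3.06 at `w = 0.04`), and the per-seed spread of the estimated
  fold is dominated by the binomial noise on the cluster's expressing
  cells (sd ≈ 0.4 at these sizes). Single-seed folds therefore scatter
  roughly between 2.5 and 3.6 around that expectation.
- **Reporter wells.** firefly ~ lognormal; nano = firefly ×
  construct mean × lognormal(CV 0.15); constructs backbone (1),
  promoter-only (2), T-haplotype (6) and C-haplotype
  (6 × `reporter_effect`, default 0.5); decidualization doubles
  promoter-driven activity. 3 experiments × 3 replicates per
  construct and condition.

**What the generators do not emulate:** recombination-map and
demographic realism (no coalescent), genotyping error and missingness,
peak-strength and footprint structure, eQTL winner's-curse and LD
between decoys and expression, matrix-balancing artifacts in contacts,
library-size variation and doublets in counts, plate-position effects
in reporter wells. Passing tests therefore demonstrate that the
estimators and the cascade are correct and calibrated under a clean
generative model — not that the pipeline is robust to every artifact
of real data.

## Numerical choices and degenerate inputs

- Monomorphic columns make LD undefined: `pairwise_ld` raises naming
  the column; `ld_expand` skips them (they cannot pass any threshold).
- Motif windows containing an ambiguous base (N) are skipped; if every
  placement is skipped the scan errors rather than report a default.
- Placement ties break deterministically (smaller offset, + strand).
- O/E with a zero-marginal bait bin warns and returns an empty
  profile; an empty contact table errors.
- Hypergeometric edge cases (no expressing cells) give p = 1.
- Reporter statistics refuse groups with fewer than 2 wells or zero
  pooled variance.
- File formats: VCF is 1-based, BED half-open 0-based; all internal
  math is half-open 0-based with conversion only at parser boundaries.
  Coordinates are assumed build-consistent across inputs; no liftover.
  eQTL-table float columns round-trip exactly (repr on write,
  round-trip parsing on read).

## Problem sizes in tests and the acceptance script

The statistical checks run at the study scale described above: 100
seeds for end-to-end causal-SNP recovery, 50 for loop recovery and
single-cell enrichment, 100 for reporter effect recovery and 1000 for
null calibration of the t-test. These sizes put Monte-Carlo error
comfortably below the assertion bands while keeping the whole suite in
the low tens of seconds on one CPU.

## Known limitations

- No Bayesian fine-mapping (posterior inclusion probabilities,
  credible sets); the cascade is a transparent filter-and-rank, as in
  the analysis it re-creates.
- No colocalization statistics; eQTL evidence is a lookup.
- Single-locus only; no genome-wide scan mode.
- The reporter model ignores experiment-level random effects.
- The motif scan scores the best placement, not occupancy summed over
  placements — matching the single-site logic of an allelic energy
  logo.
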