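# snp2enhancer

Post-GWAS functional-variant prioritization at an enhancer locus, as a
reusable, tested Python library.

A GWAS association rarely names its causal variant: the lead (index)
SNP tags a linkage-disequilibrium block in which any correlated
variant may be the functional one. For a non-coding locus acting as a
distal enhancer — such as an X-linked block more than 200 kb upstream
of its target gene — the standard desk analysis is a cascade:

1. **LD expansion** — collect every variant with haplotype r² > 0.8
   to the index SNP (`r² = D²/(pA(1−pA)pB(1−pB))`, `D′ = |D|/Dmax`,
   from phased haplotype counts, male X hemizygotes contributing one
   haplotype);
2. **eQTL annotation** — keep candidates whose genotype associates
   with the target gene's expression in the relevant tissue, slopes
   harmonized to the alt allele;
3. **epigenomic overlap** — require the SNP to sit inside regulatory
   peaks (H3K27ac, open chromatin) *and* TF ChIP-seq peaks;
4. **allele-dependent motif scoring** — scan both alleles against TF
   binding models (PWM log-odds in bits, and the equivalent ΔΔG
   energy-logo parameterization in RT units) at every placement and
   strand, flagging SNPs whose risk allele breaks a motif of a factor
   observed bound there.

Candidates are assigned monotone evidence tiers (1–4) and ranked
deterministically. Three corroborating analyses round out the
picture: observed/expected Hi-C contact profiles from the enhancer
bait bin (loops called at O/E ≥ 2.00), single-cell
expression-frequency enrichment per cell cluster (upper-tail
hypergeometric), and dual-luciferase reporter statistics
(nano/firefly, backbone-normalized, pooled-variance t-test between
allelic constructs).

Because the real inputs (reference haplotype panels, peak atlases,
eQTL catalogs, Hi-C maps, cell atlases) are large external downloads,
the package ships a seeded synthetic-data module that generates every
input with a **planted** causal SNP, TF, loop, cluster and allelic
effect — so the whole cascade is testable, end to end, against known
ground truth.

## Worked example

```bash
python examples/01_prioritize_planted_locus.py
```

```
 rank      rsid  tier  r2_with_index  eqtl_slope_alt  n_tf  n_reg  max_abs_delta flagged_motifs
    1 rs1249422     4       0.901764       -1.000000     2      1       3.544321          CEBPB
    2 rs1755960     2       1.000000       -0.901764     0      1       1.008268

planted causal SNP: rs1249422 (realized r² with index = 0.902)
top-ranked candidate: rs1249422
```

The simulated locus has two candidates above r² > 0.8: the index SNP
itself (a tier-2 eQTL with no TF peak) and the planted causal SNP,
which carries the full chain — eQTL with the most negative alt-allele
slope (risk allele lowers expression), two TF ChIP-seq peaks plus an
H3K27ac peak, and a 3.5-bit allelic loss of the planted CEBPB-like
motif — so it alone reaches tier 4 and ranks first.

The other examples each exercise one capability and print what the
numbers mean: `02` the LD worked example and proxy expansion, `03`
allele scoring on the printed probe sequence with an energy logo, `04`
the O/E loop call (promoter hit at O/E ≈ 2.6), `05` per-cluster
enrichment (~5% frequency, ~3-fold, p ~ 1e-8 in the planted stromal
cluster), `06` reporter normalization and the allelic t-test
(C/T ≈ 0.5, p ~ 1e-9).

A thin CLI wraps the same functions for shell use:

```bash
snp2enhancer simulate --seed 7 --out study/
snp2enhancer ld-expand --vcf study/panel.vcf --index rs1755960 --r2 0.8 --out ld.tsv
snp2enhancer annotate --ld ld.tsv --eqtl study/eqtl.tsv --gene AGTR2 \
    --tissue uterus --peaks study/peaks/manifest.tsv --out annotated.tsv
snp2enhancer score-motifs --candidates annotated.tsv --fasta study/sequence.fa \
    --motifs study/CEBPB.pwm.txt --out scores.tsv
snp2enhancer prioritize --in annotated.tsv --motif-scores scores.tsv --out ranked.tsv
snp2enhancer run-all --seed 7 --out out/     # the whole chain + report.json
```

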