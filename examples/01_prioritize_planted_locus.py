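"""End-to-end prioritization of a synthetic enhancer locus.

Simulates a phased X-chromosome haplotype panel with a planted causal
SNP in LD (r² ≈ 0.9) with a GWAS index SNP, plus peak, eQTL and motif
annotation layers, then runs the full evidence cascade and prints the
ranked candidate table.  The planted causal SNP should come out on top
at tier 4 (LD proxy + eQTL + peaks + allele-dependent motif hit).
"""

from snp2enhancer import SimConfig, run_planted_analysis
from snp2enhancer.prioritize import records_to_dataframe

cfg = SimConfig(seed=7)
ranked, truth, report = run_planted_analysis(cfg)

cols = ["rank", "rsid", "tier", "r2_with_index", "eqtl_slope_alt",
        "n_tf", "n_reg", "max_abs_delta", "flagged_motifs"]
print(records_to_dataframe(ranked)[cols].to_string(index=False))
print(f"\nplanted causal SNP: {truth.causal_rsid} "
      f"(realized r² with index = {truth.realized_r2:.3f})")
print(f"top-ranked candidate: {report['top_rsid']}")
print("\nTier 4 means the SNP is an LD proxy, an eQTL for the target gene,")
print("sits in regulatory + TF ChIP-seq peaks, and carries a flagged")
print("allele-dependent motif disruption — the cascade's full evidence chain.")
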