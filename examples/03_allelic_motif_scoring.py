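"""Allele-dependent TF binding prediction on the printed probe context.

Scores the reference (T) and risk (C) alleles of the enhancer SNP
against a site-matching motif whose SNP column strongly prefers T
(C most disfavored), in both the log-odds and the ΔΔG-energy
parameterizations, and prints the per-position energy-logo heights.
A negative delta means the risk allele is predicted to bind more
weakly — the direction the downstream EMSA and reporter data support.
"""

import numpy as np

from snp2enhancer import MotifModel, Variant, pfm_to_energy, score_alleles

PROBE_T = "AACCCAAAAGCAAATGCAATAAAAACAAAGATAAATAGC"
SNP_INDEX = 19

L, snp_col = 7, 3
pfm = np.full((L, 4), 0.1)
for i in range(L):
    pfm[i, "ACGT".index(PROBE_T[SNP_INDEX + i - snp_col])] = 0.65
pfm[snp_col] = [0.05, 0.02, 0.05, 0.88]  # T preferred, C most disfavored
pfm /= pfm.sum(axis=1, keepdims=True)
motif = MotifModel("CEBPB_like", pfm)

snp = Variant("chrX", 1_000_000, "rs_probe", "T", "C")
score = score_alleles(snp, PROBE_T, SNP_INDEX, motif)
print(f"best log-odds, T allele: {score.score_ref:6.2f} bits "
      f"(offset {score.best_offset_ref}, strand {score.best_strand_ref})")
print(f"best log-odds, C allele: {score.score_alt:6.2f} bits")
print(f"delta (C − T):           {score.delta:6.2f} bits  -> risk allele weaker")
print(f"ΔΔG at best placement:   T {score.energy_ref:.2f} RT, "
      f"C {score.energy_alt:.2f} RT (lower = more favorable)\n")

heights = pfm_to_energy(motif).logo_heights()
print("energy-logo heights (−ΔΔG, RT units; positive = preferred base):")
print("pos   " + "      ".join("ACGT"))
for i, row in enumerate(heights, 1):
    print(f"{i:3d} " + " ".join(f"{h:6.2f}" for h in row))
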