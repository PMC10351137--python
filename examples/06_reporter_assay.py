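"""Dual-luciferase normalization and allelic comparison.

Simulates a reporter plate (backbone, promoter-only, T- and C-allele
enhancer constructs; 3 experiments × 3 replicates; risk allele at half
the non-risk activity), normalizes each well by its firefly reading and
the condition's mean backbone ratio, and tests the allelic difference
with a pooled-variance two-sided t-test.
"""

from snp2enhancer import SimConfig, compare_constructs, normalize_wells
from snp2enhancer.synthetic import simulate_reporter

cfg = SimConfig(seed=3)  # planted allelic effect: C = 0.5 x T
wells = simulate_reporter(cfg)
activities = normalize_wells(wells)

print(f"{'construct':>14} {'condition':>17} {'mean':>7} {'sd':>6}")
for a in activities:
    print(f"{a.construct:>14} {a.condition:>17} {a.mean:>7.2f} {a.sd:>6.2f}")

for condition in ("non_decidualized", "decidualized"):
    res = compare_constructs(activities, "C_haplotype", "T_haplotype", condition)
    print(f"\n{condition}: C/T activity ratio = {res['ratio_a_over_b']:.2f}, "
          f"t = {res['t']:.2f}, p = {res['p']:.2e}")
print("\nA ratio near 0.5 with a small p-value recovers the planted loss of")
print("enhancer activity on the risk allele.")
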