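"""Expression-frequency enrichment of the target gene in one cell cluster.

Simulates ~23,000 cells in 8 clusters where the target gene is
expressed in 5.2% of the planted stromal cluster versus 1.58%
elsewhere, then computes per-cluster expression frequency, enrichment
fold over the all-cell frequency, and an upper-tail hypergeometric
p-value.
"""

from snp2enhancer import SimConfig, detect_expressing, enrich_all_clusters
from snp2enhancer.synthetic import simulate_counts

cfg = SimConfig(seed=1)
counts, labels, planted = simulate_counts(cfg)
flags = detect_expressing(counts, cfg.gene)
print(f"{cfg.gene}: {int(flags.sum())} expressing cells of {cfg.n_cells}\n")

print(f"{'cluster':>14} {'cells':>6} {'freq':>7} {'fold':>6} {'p':>10}")
for r in enrich_all_clusters(counts, labels, cfg.gene):
    mark = "  <- planted" if r.cluster == planted else ""
    print(f"{r.cluster:>14} {r.n_cells_cluster:>6} {r.frequency:>7.1%} "
          f"{r.fold:>6.2f} {r.pvalue:>10.1e}{mark}")
print("\nfold is the cluster frequency over the all-cell frequency; the")
print("hypergeometric tail asks how surprising the cluster's expressing-cell")
print("count is when cells are exchangeable.")
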