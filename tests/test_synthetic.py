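import numpy as np
import pandas as pd
import pytest

from snp2enhancer.annotation import annotate_overlaps
from snp2enhancer.enrichment import cluster_enrichment, detect_expressing
from snp2enhancer.hic import bait_query, expected_by_distance
from snp2enhancer.ld import pairwise_ld
from snp2enhancer.motif import pfm_to_energy
from snp2enhancer.synthetic import (
    SimConfig,
    simulate_all,
    simulate_annotations,
    simulate_contacts,
    simulate_counts,
    simulate_locus,
    simulate_panel,
    simulate_reporter,
    write_study,
)

SMALL = dict(n_haplotypes=400, n_snps=20, causal_index=10, index_index=8,
             n_cells=3000)


class TestSimulatePanel:
    def test_same_seed_is_byte_identical(self):
        a, ta = simulate_panel(SimConfig(seed=4, **SMALL))
        b, tb = simulate_panel(SimConfig(seed=4, **SMALL))
        assert np.array_equal(a.alleles, b.alleles)
        assert a.variants == b.variants
        assert ta.realized_r2 == tb.realized_r2

    def test_perfect_target_r2_copies_the_index_column(self):
        panel, truth = simulate_panel(SimConfig(seed=2, target_r2=1.0, **SMALL))
        assert truth.realized_r2 == pytest.approx(1.0)
        assert np.array_equal(panel.alleles[:, truth.index_index],
                              panel.alleles[:, truth.causal_index])

    def test_degenerate_single_founder_flags_undefined_ld(self):
        cfg = SimConfig(seed=0, founder_count=1, switch_rate=0.0,
                        mutation_rate=0.0, **SMALL)
        panel, truth = simulate_panel(cfg)
        assert truth.monomorphic_index
        assert truth.realized_r2 is None
        # every non-causal column is a constant copy of the single founder
        assert (panel.alleles[:, truth.index_index]
                == panel.alleles[0, truth.index_index]).all()

    def test_realized_r2_close_to_target(self):
        _, truth = simulate_panel(SimConfig(seed=1))
        assert truth.realized_r2 == pytest.approx(0.9, abs=0.05)


class TestSimulateAnnotations:
    def test_causal_snp_covered_and_decoys_mostly_clean(self):
        panel, ann, truth = simulate_locus(SimConfig(seed=6, **SMALL))
        overlaps = annotate_overlaps(panel.variants, ann.peaksets)
        causal = overlaps[truth.causal_rsid]
        assert causal.n_tf >= 2 and causal.n_reg >= 1
        decoys = [v.rsid for i, v in enumerate(panel.variants)
                  if i not in (truth.causal_index, truth.index_index)]
        clean = sum(overlaps[r].n_tf + overlaps[r].n_reg == 0 for r in decoys)
        assert clean / len(decoys) >= 0.8

    def test_planted_motif_penalizes_the_risk_base(self):
        panel, ann, truth = simulate_locus(SimConfig(seed=6, **SMALL))
        causal = panel.variants[truth.causal_index]
        e = pfm_to_energy(ann.motif).energies
        j0 = ann.motif.length // 2
        idx = "ACGT".index
        assert e[j0, idx(causal.alt_allele)] > e[j0, idx(causal.ref_allele)]

    def test_causal_slope_is_the_strongest_and_negative(self):
        for seed in range(10):
            panel, ann, truth = simulate_locus(SimConfig(seed=seed, **SMALL))
            by_rsid = {r.variant.rsid: r for r in ann.eqtl_records}
            causal = by_rsid[truth.causal_rsid]
            assert causal.slope == pytest.approx(-1.0)
            assert all(abs(r.slope) <= abs(causal.slope) + 1e-12
                       for r in ann.eqtl_records)

    def test_sequence_carries_reference_alleles(self):
        panel, ann, truth = simulate_locus(SimConfig(seed=3, **SMALL))
        for v in panel.variants[:5]:
            context, snp_index = ann.locus_seq(v)
            assert context[snp_index] == v.ref_allele

    def test_short_motif_rejected(self):
        panel, truth = simulate_panel(SimConfig(seed=0, **SMALL))
        with pytest.raises(ValueError, match="motif_length"):
            simulate_annotations(SimConfig(seed=0, motif_length=1, **SMALL),
                                 panel, truth)


class TestSimulateContacts:
    def test_no_loop_no_noise_has_unit_oe(self):
        cfg = SimConfig(seed=0, loop_strength=1.0, contact_noise_cv=0.0, **SMALL)
        table, tss, (bait, prom) = simulate_contacts(cfg)
        prof = bait_query(table, bait * cfg.bin_size, tss, threshold=2.0, min_pairs=1)
        assert np.allclose(prof.normalized[np.isfinite(prof.normalized)], 1.0, atol=1e-9)
        assert prof.reported_bins.size == 0

    def test_flat_decay_limit_equals_base_everywhere(self):
        cfg = SimConfig(seed=0, decay_tau=1e12, contact_noise_cv=0.0,
                        loop_strength=1.0, **SMALL)
        table, _, _ = simulate_contacts(cfg)
        exp = expected_by_distance(table, min_pairs=1)
        assert np.allclose(exp, cfg.contact_base, rtol=1e-9)

    def test_planted_loop_lands_on_the_promoter_bin(self):
        cfg = SimConfig(seed=5, **SMALL)
        table, tss, (bait, prom) = simulate_contacts(cfg)
        prof = bait_query(table, bait * cfg.bin_size, tss, threshold=2.0)
        assert any(g == cfg.gene and b == prom for g, b, _ in prof.promoter_hits)


class TestSimulateCountsAndReporter:
    def test_equal_frequencies_give_unit_fold(self):
        cfg = SimConfig(seed=2, cluster_freq=0.05, background_freq=0.0499999,
                        n_cells=20_000)
        counts, labels, planted = simulate_counts(cfg)
        flags = detect_expressing(counts, cfg.gene)
        r = cluster_enrichment(flags, labels, planted)
        assert r.fold == pytest.approx(1.0, abs=0.35)

    def test_planted_cluster_is_enriched(self):
        cfg = SimConfig(seed=2)
        counts, labels, planted = simulate_counts(cfg)
        flags = detect_expressing(counts, cfg.gene)
        r = cluster_enrichment(flags, labels, planted, gene=cfg.gene)
        assert r.fold > 2.0 and r.pvalue < 1e-5

    def test_reporter_wells_positive_and_complete(self):
        cfg = SimConfig(seed=9)
        df = simulate_reporter(cfg)
        assert (df["nano"] > 0).all() and (df["firefly"] > 0).all()
        per_group = df.groupby(["construct", "condition"]).size()
        assert (per_group == cfg.n_experiments * cfg.replicates_per_experiment).all()


def test_write_study_roundtrips_panel_and_annotations(tmp_path):
    from snp2enhancer.io_formats import (
        read_bed_manifest, read_eqtl_table, read_motif, read_vcf,
    )
    from snp2enhancer.hic import read_contacts

    cfg = SimConfig(seed=12, **SMALL)
    study = simulate_all(cfg)
    out = write_study(study, tmp_path / "study")
    panel = read_vcf(out / "panel.vcf")
    assert np.array_equal(panel.alleles, study.panel.alleles)
    assert panel.variants == study.panel.variants
    peaksets = read_bed_manifest(out / "peaks" / "manifest.tsv")
    assert [(p.dataset_id, len(p.intervals)) for p in peaksets] == \
        [(p.dataset_id, len(p.intervals)) for p in study.annotations.peaksets]
    assert read_eqtl_table(out / "eqtl.tsv") == study.annotations.eqtl_records
    motif = read_motif(out / f"{cfg.tf_name}.pwm.txt")
    assert np.allclose(motif.pfm, study.annotations.motif.pfm, atol=1e-5)
    contacts = read_contacts(out / "contacts.tsv")
    assert np.allclose(contacts.to_dense(), study.contacts.to_dense(), rtol=1e-8)
    clusters = pd.read_csv(out / "clusters.tsv", sep="\t")
    assert (clusters["cluster"].to_numpy() == study.cluster_labels).all()


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(target_r2=0.0)
    with pytest.raises(ValueError):
        SimConfig(cluster_freq=0.01, background_freq=0.02)
    with pytest.raises(ValueError):
        SimConfig(reporter_effect=0.0)
    with pytest.raises(ValueError):
        SimConfig(causal_index=5, index_index=5)
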