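"""Seeded generators for every pipeline input, with a planted causal SNP.

The generators stand in for the external resources a real post-GWAS
analysis would download (a phased reference panel, ENCODE/Roadmap-style
peak sets, a GTEx-style eQTL table, a Hi-C contact map, a uterus
single-cell atlas, reporter plate readings) and are built so that the
ground truth — which SNP is causal, which TF binds differentially,
where the enhancer loops to, which cell cluster expresses the target
gene — is known and recorded, making the full cascade testable without
any downloads.

Haplotypes follow a founder-mosaic copying model: each haplotype copies
one of ``founder_count`` founder haplotypes, switching founders at each
site with probability ``switch_rate`` and flipping the copied allele
with probability ``mutation_rate``.  Three parameters give tunable LD
without a coalescent simulator.  The causal column is then constructed
from the index column by flipping each haplotype's allele with a
probability q solved (given the realized index allele frequency) so
that the expected r² between the two columns equals ``target_r2``; the
realized r² is stochastic and therefore recorded in the truth record.

Every generator is a pure function of :class:`SimConfig` — the same
seed yields byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .enrichment import CountMatrix
from .hic import ContactTable, write_contacts
from .io_formats import (
    BASES,
    EQTLRecord,
    GenomicInterval,
    HaplotypePanel,
    PeakSet,
    Variant,
    write_bed_manifest,
    write_eqtl_table,
    write_motif_cisbp,
    write_reporter_table,
    write_tss_bed,
    write_vcf,
)
from .ld import MonomorphicVariantError, pairwise_ld
from .motif import MotifModel


class TargetR2UnreachableError(ValueError):
    """The requested index/causal LD cannot be realized on this panel."""


@dataclass
class SimConfig:
    """Knobs of the synthetic study; defaults are the study conditions.

    The defaults mirror the structure of the real analysis: a ~180-kb
    X-linked LD block of 60 SNPs in 2000 phased haplotypes with the
    causal SNP at r² ≈ 0.9 to the GWAS index SNP; a CEBPB-like motif
    whose information-rich column sits on the causal SNP with the
    reference (non-risk) allele preferred; a contact map with
    exponential distance decay plus a 3× loop from the enhancer bin to
    the promoter bin ~200 kb away; ~23,000 cells in 8 clusters with the
    target gene expressed in 5.2% of the planted stromal cluster versus
    1.58% elsewhere; and reporter wells in which the risk-allele
    construct has half the activity of the non-risk construct with
    ~15% multiplicative noise.
    """

    seed: int = 0
    # haplotype panel
    n_haplotypes: int = 2000
    n_snps: int = 60
    founder_count: int = 12
    switch_rate: float = 0.15
    mutation_rate: float = 0.02
    causal_index: int = 30
    index_index: int = 28
    target_r2: float = 0.9
    # locus geometry
    chrom: str = "chrX"
    locus_start: int = 1_000_000
    snp_spacing: int = 3_000
    # annotation layers
    motif_length: int = 8
    tf_name: str = "CEBPB"
    gene: str = "AGTR2"
    tissue: str = "uterus"
    # contact map
    n_bins: int = 60
    bin_size: int = 40_000
    decay_tau: float = 8.0
    contact_base: float = 100.0
    contact_noise_cv: float = 0.1
    loop_strength: float = 3.0
    promoter_offset_bins: int = 5
    # single-cell counts
    n_cells: int = 23_110
    n_genes: int = 30
    n_clusters: int = 8
    planted_cluster_fraction: float = 0.04
    cluster_freq: float = 0.052
    background_freq: float = 0.0158
    nb_dispersion: float = 0.5
    nb_mean: float = 2.0
    # reporter plate
    reporter_effect: float = 0.5
    reporter_cv: float = 0.15
    n_experiments: int = 3
    replicates_per_experiment: int = 3

    def __post_init__(self) -> None:
        if not (0.0 < self.target_r2 <= 1.0):
            raise ValueError("target_r2 must be in (0, 1]")
        if not (0.0 <= self.background_freq < self.cluster_freq <= 1.0):
            raise ValueError("require 0 <= background_freq < cluster_freq <= 1")
        if self.reporter_effect <= 0:
            raise ValueError("reporter_effect must be > 0")
        if self.founder_count < 1:
            raise ValueError("founder_count must be >= 1")
        if not (0 <= self.causal_index < self.n_snps) or not (0 <= self.index_index < self.n_snps):
            raise ValueError("causal_index and index_index must address panel columns")
        if self.causal_index == self.index_index:
            raise ValueError("causal_index and index_index must differ")
        if self.n_clusters < 2:
            raise ValueError("need >= 2 clusters")
        if self.n_experiments * self.replicates_per_experiment < 3:
            raise ValueError("need >= 3 wells per construct")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class TruthRecord:
    """Everything needed to score the pipeline against the simulation."""

    index_rsid: str = ""
    causal_rsid: str = ""
    index_index: int = -1
    causal_index: int = -1
    realized_r2: float | None = None
    monomorphic_index: bool = False
    tf_name: str = ""
    gene: str = ""
    tissue: str = ""
    bait_bin: int = -1
    promoter_bin: int = -1
    loop_strength: float = 1.0
    planted_cluster: str = ""
    cluster_freq: float = 0.0
    background_freq: float = 0.0
    reporter_effect: float = 1.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _rng(cfg: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed), stage])


# ---------------------------------------------------------------------------
# Haplotype panel
# ---------------------------------------------------------------------------

def _flip_probability(p: float, target_r2: float) -> float:
    """Allele-flip probability q giving expected r² = target with index freq p.

    A symmetric flip with probability q turns an index column of alt
    frequency p into a causal column of frequency p_Y = p + q(1 − 2p)
    with

        r²(q) = (1 − 2q)² · p(1 − p) / (p_Y (1 − p_Y)),

    which decreases monotonically from 1 (q = 0) to 0 (q = 1/2); the
    unique root is bracketed and solved numerically.
    """
    from scipy.optimize import brentq

    if target_r2 >= 1.0:
        return 0.0

    def gap(q: float) -> float:
        p_y = p + q * (1.0 - 2.0 * p)
        return (1.0 - 2.0 * q) ** 2 * p * (1.0 - p) / (p_y * (1.0 - p_y)) - target_r2

    return float(brentq(gap, 0.0, 0.5 - 1e-12))


def simulate_panel(cfg: SimConfig) -> tuple[HaplotypePanel, TruthRecord]:
    """Founder-mosaic haplotypes with a planted index/causal SNP pair.

    If the index column comes out monomorphic (possible only in
    degenerate configurations such as a single founder with no
    mutation) the pairwise r² is undefined; the truth record flags this
    (``monomorphic_index=True``, ``realized_r2=None``) instead of
    reporting a number.  A polymorphic but near-fixed index column
    (minor-allele frequency < 2%) cannot support the requested LD
    construction reliably and raises
    :class:`TargetR2UnreachableError` suggesting a different seed.
    """
    rng = _rng(cfg, 1)
    H, S, K = cfg.n_haplotypes, cfg.n_snps, cfg.founder_count

    founder_freq = rng.uniform(0.2, 0.8, size=S)
    founders = (rng.random((K, S)) < founder_freq).astype(np.uint8)

    alleles = np.empty((H, S), dtype=np.uint8)
    fid = rng.integers(0, K, size=H)
    for s in range(S):
        if s > 0:
            switch = rng.random(H) < cfg.switch_rate
            n_sw = int(switch.sum())
            if n_sw:
                fid[switch] = rng.integers(0, K, size=n_sw)
        alleles[:, s] = founders[fid, s]
    flips = rng.random((H, S)) < cfg.mutation_rate
    alleles ^= flips.astype(np.uint8)

    truth = TruthRecord(
        index_index=cfg.index_index, causal_index=cfg.causal_index,
        tf_name=cfg.tf_name, gene=cfg.gene, tissue=cfg.tissue,
        loop_strength=cfg.loop_strength,
        cluster_freq=cfg.cluster_freq, background_freq=cfg.background_freq,
        reporter_effect=cfg.reporter_effect,
    )

    index_col = alleles[:, cfg.index_index]
    p_index = float(index_col.mean())
    q = 0.0
    if p_index in (0.0, 1.0):
        truth.monomorphic_index = True
    elif min(p_index, 1 - p_index) < 0.02:
        raise TargetR2UnreachableError(
            f"index column minor-allele frequency {min(p_index, 1 - p_index):.3f} is too "
            f"low to plant r² = {cfg.target_r2}; try a different seed or founder frequencies"
        )
    else:
        q = _flip_probability(p_index, cfg.target_r2)
    causal_col = index_col ^ (rng.random(H) < q).astype(np.uint8)
    alleles[:, cfg.causal_index] = causal_col

    positions = cfg.locus_start + np.arange(S) * cfg.snp_spacing \
        + rng.integers(0, max(cfg.snp_spacing // 3, 1), size=S)
    rs_numbers = rng.choice(9_000_000, size=S, replace=False) + 1_000_000
    variants = []
    for s in range(S):
        ref, alt = rng.choice(4, size=2, replace=False)
        variants.append(Variant(cfg.chrom, int(positions[s]), f"rs{rs_numbers[s]}",
                                BASES[ref], BASES[alt]))

    n_samples = H // 2
    sample_ids = [f"S{i + 1:04d}" for i in range(n_samples)]
    sexes = ["F"] * n_samples
    if H % 2 == 1:
        sample_ids.append(f"S{n_samples + 1:04d}")
        sexes.append("M")
    panel = HaplotypePanel(variants, sample_ids, alleles, sexes=sexes)

    truth.index_rsid = variants[cfg.index_index].rsid
    truth.causal_rsid = variants[cfg.causal_index].rsid
    if not truth.monomorphic_index:
        try:
            truth.realized_r2 = pairwise_ld(panel, cfg.index_index, cfg.causal_index).r2
        except MonomorphicVariantError:
            truth.monomorphic_index = True
    return panel, truth


# ---------------------------------------------------------------------------
# Sequence, motif, peaks, eQTL
# ---------------------------------------------------------------------------

@dataclass
class LocusSequence:
    """A contiguous reference sequence; callable as a scan sequence source."""

    chrom: str
    start0: int          # 0-based start of seq on the chromosome
    seq: str
    flank: int = 25      # context half-width handed to the motif scan

    def context(self, variant: Variant, flank: int | None = None) -> tuple[str, int]:
        """(context, snp_index) window of ±flank bases around the SNP."""
        flank = self.flank if flank is None else flank
        center = variant.pos0 - self.start0
        if not (0 <= center < len(self.seq)):
            raise ValueError(f"{variant.rsid} at {variant.pos} lies outside the sequence")
        lo, hi = max(0, center - flank), min(len(self.seq), center + flank + 1)
        return self.seq[lo:hi], center - lo

    def __call__(self, variant: Variant) -> tuple[str, int]:
        return self.context(variant)

    def write_fasta(self, path: str | Path) -> None:
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord
        rec = SeqRecord(Seq(self.seq), id=f"{self.chrom}:{self.start0 + 1}",
                        description=f"locus sequence, 1-based start {self.start0 + 1}")
        SeqIO.write([rec], str(path), "fasta")


@dataclass
class AnnotationBundle:
    peaksets: list[PeakSet]
    eqtl_records: list[EQTLRecord]
    motif: MotifModel
    locus_seq: LocusSequence


def simulate_annotations(cfg: SimConfig, panel: HaplotypePanel,
                         truth: TruthRecord) -> AnnotationBundle:
    """Peak sets, eQTL table, planted motif and surrounding sequence.

    The causal SNP sits inside one H3K27ac peak and two TF ChIP-seq
    peaks for the planted factor; the index SNP gets a histone peak
    only, one decoy gets an open-chromatin peak, and all other decoys
    lie in no peak.  Each SNP in LD with the causal SNP (r² > 0.2)
    receives an eQTL record whose slope is proportional to −r² (the
    risk/alt allele lowers expression) with p-value decreasing in r².
    The motif's highest-information column coincides with the causal
    SNP and prefers the reference (non-risk) base, so the risk allele
    scores lower.
    """
    if cfg.motif_length < 2:
        raise ValueError("motif_length must be >= 2")
    rng = _rng(cfg, 2)
    causal = panel.variants[cfg.causal_index]
    index = panel.variants[cfg.index_index]

    start0 = cfg.locus_start - 1000
    end0 = panel.variants[-1].pos0 + 1000
    seq = rng.choice(list("ACGT"), size=end0 - start0).tolist()
    for v in panel.variants:
        seq[v.pos0 - start0] = v.ref_allele
    locus_seq = LocusSequence(cfg.chrom, start0, "".join(seq),
                              flank=max(cfg.motif_length + 10, 25))

    # Planted motif: SNP column prefers the reference base strongly; the
    # other columns prefer the flanking reference sequence moderately.
    L = cfg.motif_length
    j0 = L // 2
    pfm = np.full((L, 4), 0.1)
    for i in range(L):
        base = locus_seq.seq[causal.pos0 - start0 + (i - j0)]
        pfm[i, BASES.index(base)] = 0.7
    pfm[j0] = 0.05
    pfm[j0, BASES.index(causal.ref_allele)] = 0.85
    pfm /= pfm.sum(axis=1, keepdims=True)
    motif = MotifModel(name=cfg.tf_name, pfm=pfm)

    def peak(center: Variant, half: int, name: str) -> GenomicInterval:
        return GenomicInterval(cfg.chrom, center.pos0 - half, center.pos0 + half + 1, name)

    decoy_idx = next(i for i in range(cfg.n_snps)
                     if i not in (cfg.causal_index, cfg.index_index))
    decoy = panel.variants[decoy_idx]
    peaksets = [
        PeakSet([peak(causal, 250, "h3k27ac_pk"), peak(index, 200, "h3k27ac_pk2")],
                dataset_id="H3K27ac_uterus", assay_class="histone",
                cell_type="uterus"),
        PeakSet([peak(causal, 150, f"{cfg.tf_name.lower()}_pk")],
                dataset_id=f"{cfg.tf_name}_chip_rep1", assay_class="tf_chip",
                factor=cfg.tf_name, cell_type="endometrial_fibroblast"),
        PeakSet([peak(causal, 220, f"{cfg.tf_name.lower()}_pk")],
                dataset_id=f"{cfg.tf_name}_chip_rep2", assay_class="tf_chip",
                factor=cfg.tf_name, cell_type="endometrial_fibroblast"),
        PeakSet([peak(decoy, 100, "atac_pk")],
                dataset_id="ATAC_decoy_region", assay_class="open_chromatin",
                cell_type="uterus"),
    ]

    eqtl_records = []
    for i, v in enumerate(panel.variants):
        try:
            r2 = pairwise_ld(panel, cfg.causal_index, i).r2
        except MonomorphicVariantError:
            continue
        if r2 <= 0.2:
            continue
        slope = -1.0 * r2
        pvalue = max(10.0 ** (-(1.0 + 19.0 * r2)), 1e-300)
        eqtl_records.append(EQTLRecord(v, cfg.gene, cfg.tissue,
                                       effect_allele=v.alt_allele,
                                       slope=slope, pvalue=pvalue))
    return AnnotationBundle(peaksets, eqtl_records, motif, locus_seq)


# ---------------------------------------------------------------------------
# Contact map
# ---------------------------------------------------------------------------

def simulate_contacts(
    cfg: SimConfig,
    bait_position_bp: int | None = None,
) -> tuple[ContactTable, list[tuple[str, str, int]], tuple[int, int]]:
    """Exponential-decay contacts with a planted enhancer→promoter loop.

    C(i, j) = base · exp(−|i−j|/τ) · lognormal multiplicative noise,
    with the (bait bin, promoter bin) entry multiplied by
    ``loop_strength``.  Returns the table, a one-gene TSS annotation at
    the promoter bin, and the (bait_bin, promoter_bin) pair.
    """
    rng = _rng(cfg, 3)
    if bait_position_bp is None:
        bait_position_bp = cfg.locus_start + cfg.causal_index * cfg.snp_spacing
    bait_bin = bait_position_bp // cfg.bin_size
    promoter_bin = bait_bin + cfg.promoter_offset_bins
    n = cfg.n_bins
    if promoter_bin >= n:
        raise ValueError("promoter bin falls outside the simulated matrix")

    ii, jj = np.triu_indices(n)
    dist = jj - ii
    counts = cfg.contact_base * np.exp(-dist / cfg.decay_tau)
    if cfg.contact_noise_cv > 0:
        sigma = np.sqrt(np.log1p(cfg.contact_noise_cv ** 2))
        counts = counts * rng.lognormal(-sigma ** 2 / 2.0, sigma, size=counts.size)
    loop_mask = (ii == min(bait_bin, promoter_bin)) & (jj == max(bait_bin, promoter_bin))
    counts[loop_mask] *= cfg.loop_strength

    table = ContactTable(cfg.chrom, cfg.bin_size, ii, jj, counts)
    tss_pos = promoter_bin * cfg.bin_size + cfg.bin_size // 2 + 1
    tss = [(cfg.gene, cfg.chrom, tss_pos)]
    return table, tss, (bait_bin, promoter_bin)


# ---------------------------------------------------------------------------
# Single-cell counts
# ---------------------------------------------------------------------------

def simulate_counts(cfg: SimConfig) -> tuple[CountMatrix, np.ndarray, str]:
    """Cell×gene counts with one cluster of elevated expression frequency.

    The target gene is expressed (count > 0) with probability
    ``cluster_freq`` in the planted cluster and ``background_freq``
    elsewhere; expressing cells draw 1 + NB(mean, dispersion) counts —
    only presence/absence matters to the downstream statistic.  Filler
    genes carry Poisson noise.  Returns (counts, labels, planted
    cluster name).
    """
    rng = _rng(cfg, 4)
    n_cells, n_clusters = cfg.n_cells, cfg.n_clusters
    if n_clusters == 8:
        names = ["Stromal-1", "Stromal-2", "Epithelial", "Endothelial",
                 "Immune-T", "Immune-M", "Smooth-muscle", "Lymphatic"]
    else:
        names = [f"cluster_{i + 1}" for i in range(n_clusters)]
    planted = names[1]
    props = np.full(n_clusters, (1.0 - cfg.planted_cluster_fraction) / (n_clusters - 1))
    props[1] = cfg.planted_cluster_fraction
    labels = np.array(names)[rng.choice(n_clusters, size=n_cells, p=props)]

    freq = np.where(labels == planted, cfg.cluster_freq, cfg.background_freq)
    expressing = rng.random(n_cells) < freq

    genes = [cfg.gene] + [f"GENE{i:03d}" for i in range(1, cfg.n_genes)]
    counts = rng.poisson(1.0, size=(n_cells, cfg.n_genes)).astype(np.int32)
    target = np.zeros(n_cells, dtype=np.int32)
    r = 1.0 / cfg.nb_dispersion
    p = r / (r + cfg.nb_mean)
    target[expressing] = 1 + rng.negative_binomial(r, p, size=int(expressing.sum()))
    counts[:, 0] = target

    cell_ids = [f"cell_{i + 1}" for i in range(n_cells)]
    return CountMatrix(counts, genes, cell_ids), labels, planted


# ---------------------------------------------------------------------------
# Reporter plate
# ---------------------------------------------------------------------------

REPORTER_CONSTRUCTS = ("backbone", "promoter_only", "T_haplotype", "C_haplotype")


def simulate_reporter(cfg: SimConfig) -> pd.DataFrame:
    """Dual-luciferase wells with a multiplicative allelic effect.

    firefly ~ lognormal; nano = firefly · construct mean · lognormal
    noise with coefficient of variation ``reporter_cv``.  The
    risk-allele (C) construct mean is ``reporter_effect`` × the
    non-risk (T) mean; decidualization doubles enhancer/promoter
    activity, as in hormone-treated endometrial stromal cells.
    """
    rng = _rng(cfg, 5)
    base_means = {"backbone": 1.0, "promoter_only": 2.0, "T_haplotype": 6.0}
    base_means["C_haplotype"] = base_means["T_haplotype"] * cfg.reporter_effect
    sigma = np.sqrt(np.log1p(cfg.reporter_cv ** 2))

    rows = []
    for condition, scale in (("non_decidualized", 1.0), ("decidualized", 2.0)):
        for construct in REPORTER_CONSTRUCTS:
            mean = base_means[construct] * (scale if construct != "backbone" else 1.0)
            for e in range(1, cfg.n_experiments + 1):
                for r in range(1, cfg.replicates_per_experiment + 1):
                    firefly = rng.lognormal(np.log(1000.0), 0.2)
                    noise = rng.lognormal(-sigma ** 2 / 2.0, sigma)
                    rows.append((construct, condition, f"exp{e}_rep{r}",
                                 firefly * mean * noise, firefly))
    return pd.DataFrame(rows, columns=["construct", "condition", "replicate_id",
                                       "nano", "firefly"])


# ---------------------------------------------------------------------------
# Whole study
# ---------------------------------------------------------------------------

@dataclass
class SimulatedStudy:
    cfg: SimConfig
    truth: TruthRecord
    panel: HaplotypePanel
    annotations: AnnotationBundle
    contacts: ContactTable
    tss: list[tuple[str, str, int]]
    counts: CountMatrix
    cluster_labels: np.ndarray
    reporter: pd.DataFrame


def simulate_locus(cfg: SimConfig) -> tuple[HaplotypePanel, AnnotationBundle, TruthRecord]:
    """Panel + annotation layers only (the prioritization cascade's inputs)."""
    panel, truth = simulate_panel(cfg)
    annotations = simulate_annotations(cfg, panel, truth)
    return panel, annotations, truth


def simulate_all(cfg: SimConfig) -> SimulatedStudy:
    """Generate every input the end-to-end analysis consumes."""
    panel, annotations, truth = simulate_locus(cfg)
    bait_pos = panel.variants[cfg.causal_index].pos
    contacts, tss, (bait_bin, promoter_bin) = simulate_contacts(cfg, bait_pos)
    truth.bait_bin, truth.promoter_bin = bait_bin, promoter_bin
    counts, labels, planted = simulate_counts(cfg)
    truth.planted_cluster = planted
    reporter = simulate_reporter(cfg)
    return SimulatedStudy(cfg, truth, panel, annotations, contacts, tss,
                          counts, labels, reporter)


def write_study(study: SimulatedStudy, out_dir: str | Path) -> Path:
    """Write every simulated input in its on-disk interchange format."""
    from scipy import io as spio
    from scipy import sparse

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_vcf(study.panel, out / "panel.vcf")
    write_bed_manifest(study.annotations.peaksets, out / "peaks")
    write_eqtl_table(study.annotations.eqtl_records, out / "eqtl.tsv")
    write_motif_cisbp(study.annotations.motif, out / f"{study.annotations.motif.name}.pwm.txt")
    study.annotations.locus_seq.write_fasta(out / "sequence.fa")
    write_contacts(study.contacts, out / "contacts.tsv")
    write_tss_bed(study.tss, out / "tss.bed")
    spio.mmwrite(str(out / "counts.mtx"), sparse.csr_matrix(study.counts.matrix))
    pd.Series(study.counts.gene_names).to_csv(out / "genes.tsv", sep="\t",
                                              index=False, header=False)
    pd.Series(study.counts.cell_ids).to_csv(out / "cells.tsv", sep="\t",
                                            index=False, header=False)
    pd.DataFrame({"cell_id": study.counts.cell_ids,
                  "cluster": study.cluster_labels}).to_csv(
        out / "clusters.tsv", sep="\t", index=False)
    write_reporter_table(study.reporter, out / "reporter.tsv")
    meta = study.truth.to_dict()
    meta["seed"] = study.cfg.seed
    meta["sequence_start0"] = study.annotations.locus_seq.start0
    with open(out / "truth.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    return out
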