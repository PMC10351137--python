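"""eQTL and epigenomic-peak annotation of candidate SNPs.

Candidates are matched against a GTEx-style association table on
(chrom, pos, ref, alt) with allele harmonization — the slope is
re-oriented so it is always expressed per copy of the candidate's
alternate allele — and intersected with peak datasets, partitioned into
TF ChIP-seq hits versus regulatory-region hits (histone marks and open
chromatin).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_formats import (
    EQTLRecord,
    PeakSet,
    Variant,
    normalize_chrom,
)

log = logging.getLogger(__name__)


@dataclass
class EQTLAnnotation:
    """eQTL evidence for one candidate, oriented to the alt allele."""

    variant: Variant
    gene: str
    tissue: str
    slope_alt: float
    pvalue: float
    direction_label: str = field(init=False)

    def __post_init__(self) -> None:
        self.direction_label = "alt_lower" if self.slope_alt < 0 else "alt_higher"


@dataclass
class OverlapSummary:
    """Which peak datasets a candidate SNP falls inside."""

    variant: Variant
    tf_datasets: list[tuple[str, str]]        # (dataset_id, factor)
    regulatory_datasets: list[str]            # histone / open_chromatin dataset ids

    @property
    def n_tf(self) -> int:
        return len(self.tf_datasets)

    @property
    def n_reg(self) -> int:
        return len(self.regulatory_datasets)


def _norm_tissue(label: str) -> str:
    return label.strip().lower().replace(" ", "_").replace("-", "_")


def harmonize_slope(candidate: Variant, record: EQTLRecord) -> float | None:
    """Slope per alt-allele copy of the candidate; None if alleles mismatch.

    Flipping a record's effect allele to the other allele and negating
    its slope describes the same association, so harmonization is an
    involution.
    """
    if record.effect_allele == candidate.alt_allele:
        return record.slope
    if record.effect_allele == candidate.ref_allele:
        return -record.slope
    return None


def annotate_eqtl(
    candidates: list[Variant],
    eqtl_table: list[EQTLRecord],
    gene: str,
    tissue: str,
) -> dict[str, EQTLAnnotation | None]:
    """Match candidates to eQTL records for one gene/tissue.

    Returns rsid → annotation; candidates without a matching record map
    to None (they fail the eQTL tier downstream, not the pipeline).
    Records whose effect allele matches neither candidate allele are
    skipped with a warning (possible strand or allele mismatch).
    """
    tissue_n = _norm_tissue(tissue)
    by_site: dict[tuple[str, int], list[EQTLRecord]] = {}
    for rec in eqtl_table:
        if rec.gene != gene or _norm_tissue(rec.tissue) != tissue_n:
            continue
        key = (normalize_chrom(rec.variant.chrom), rec.variant.pos)
        by_site.setdefault(key, []).append(rec)

    out: dict[str, EQTLAnnotation | None] = {}
    for cand in candidates:
        out[cand.rsid] = None
        for rec in by_site.get((normalize_chrom(cand.chrom), cand.pos), []):
            if {rec.variant.ref_allele, rec.variant.alt_allele} != {
                cand.ref_allele, cand.alt_allele
            }:
                log.warning(
                    "%s: eQTL record alleles %s/%s do not match candidate %s/%s; skipped",
                    cand.rsid, rec.variant.ref_allele, rec.variant.alt_allele,
                    cand.ref_allele, cand.alt_allele,
                )
                continue
            slope_alt = harmonize_slope(cand, rec)
            if slope_alt is None:
                log.warning("%s: effect allele %s matches neither candidate allele; skipped",
                            cand.rsid, rec.effect_allele)
                continue
            out[cand.rsid] = EQTLAnnotation(
                variant=cand, gene=rec.gene, tissue=rec.tissue,
                slope_alt=slope_alt, pvalue=rec.pvalue,
            )
            break
    return out


def annotate_overlaps(
    candidates: list[Variant],
    peaksets: list[PeakSet],
    chrom_aliases: dict[str, str] | None = None,
) -> dict[str, OverlapSummary]:
    """Count, per candidate, the peak datasets containing it.

    A SNP at 1-based position p hits an interval [start, end) iff
    start <= p − 1 < end.  Chromosome names are normalized (chrX == X)
    through a configurable alias map; a dataset on another chromosome
    simply contributes zero hits.
    """
    # Pre-sort interval arrays per (peakset, chrom) for vectorized membership.
    prepared = []
    for ps in peaksets:
        by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for iv in ps.intervals:
            by_chrom.setdefault(normalize_chrom(iv.chrom, chrom_aliases), ([], []))
        for iv in ps.intervals:
            starts, ends = by_chrom[normalize_chrom(iv.chrom, chrom_aliases)]
            starts.append(iv.start)
            ends.append(iv.end)
        prepared.append((ps, {c: (np.asarray(s), np.asarray(e))
                              for c, (s, e) in by_chrom.items()}))

    out: dict[str, OverlapSummary] = {}
    for cand in candidates:
        chrom = normalize_chrom(cand.chrom, chrom_aliases)
        tf_hits: list[tuple[str, str]] = []
        reg_hits: list[str] = []
        for ps, by_chrom in prepared:
            if chrom not in by_chrom:
                continue
            starts, ends = by_chrom[chrom]
            if bool(((starts <= cand.pos0) & (cand.pos0 < ends)).any()):
                if ps.assay_class == "tf_chip":
                    tf_hits.append((ps.dataset_id, ps.factor))
                else:
                    reg_hits.append(ps.dataset_id)
        out[cand.rsid] = OverlapSummary(cand, tf_hits, reg_hits)
    return out
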