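"""Evidence integration: the tiered cascade and final candidate ranking.

Each candidate accumulates evidence layers and is assigned the deepest
tier whose requirements — and those of every shallower tier — it meets:

    tier 1  in the LD proxy set of the index SNP
    tier 2  … and a significant eQTL for the target gene/tissue
    tier 3  … and inside >= 1 regulatory peak AND >= 1 TF ChIP-seq peak
    tier 4  … and >= 1 flagged allele-dependent motif prediction

The cascade is monotone by construction: removing any evidence layer
can only lower a tier.  Ranking makes the cross-referencing explicit
with a fully keyed, stable sort — (tier desc, max |Δ| desc, number of
TF datasets desc, r² desc, position asc) — so the order is
deterministic and permutation-invariant; a composite score
(tier + 0.5·tanh(max|Δ|/4)) is reported for transparency only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import (
    EQTLAnnotation,
    OverlapSummary,
    annotate_eqtl,
    annotate_overlaps,
)
from .io_formats import EQTLRecord, PeakSet, Variant
from .ld import LDResult, ld_expand
from .motif import AllelicBindingScore, MotifModel, differential_binding_scan


@dataclass
class CandidateRecord:
    """Per-SNP evidence ledger feeding the tier assignment and ranking."""

    variant: Variant
    r2_with_index: float
    is_index: bool = False
    eqtl: EQTLAnnotation | None = None
    overlaps: OverlapSummary | None = None
    motif_scores: list[AllelicBindingScore] = field(default_factory=list)
    tier: int = 0
    composite_score: float = 0.0
    rank: int = 0

    @property
    def motif_flags(self) -> list[AllelicBindingScore]:
        return [s for s in self.motif_scores if s.flagged]

    @property
    def max_abs_delta(self) -> float:
        if not self.motif_scores:
            return 0.0
        return max(abs(s.delta) for s in self.motif_scores)

    @property
    def n_tf(self) -> int:
        return self.overlaps.n_tf if self.overlaps else 0

    @property
    def n_reg(self) -> int:
        return self.overlaps.n_reg if self.overlaps else 0


def assign_tiers(records: list[CandidateRecord], pvalue_max: float = 1.0) -> list[CandidateRecord]:
    """Assign each record the deepest tier it qualifies for (monotone cascade)."""
    for rec in records:
        tier = 1  # presence in the LD set is what put it here
        if rec.eqtl is not None and rec.eqtl.pvalue <= pvalue_max:
            tier = 2
            if rec.overlaps is not None and rec.n_reg >= 1 and rec.n_tf >= 1:
                tier = 3
                if rec.motif_flags:
                    tier = 4
        rec.tier = tier
        rec.composite_score = tier + 0.5 * float(np.tanh(rec.max_abs_delta / 4.0))
    return records


def rank_candidates(records: list[CandidateRecord]) -> list[CandidateRecord]:
    """Stable total order: best candidate first, ranks written back."""
    ordered = sorted(
        records,
        key=lambda r: (-r.tier, -r.max_abs_delta, -r.n_tf,
                       -r.r2_with_index, r.variant.pos),
    )
    for i, rec in enumerate(ordered, 1):
        rec.rank = i
    return ordered


def prioritize_locus(
    panel,
    index_rsid: str,
    peaksets: list[PeakSet],
    eqtl_table: list[EQTLRecord],
    sequence_source,
    motif_library: list[MotifModel],
    gene: str,
    tissue: str,
    r2_threshold: float = 0.8,
    window_bp: int = 1_000_000,
    delta_threshold: float = 2.0,
    gate: bool = True,
    pvalue_max: float = 1.0,
) -> tuple[list[CandidateRecord], dict]:
    """Run the full cascade on in-memory inputs; returns (ranked records, report).

    The report captures every threshold so a run is auditable.
    """
    ld_results: list[LDResult] = ld_expand(panel, index_rsid,
                                           r2_threshold=r2_threshold,
                                           window_bp=window_bp)
    candidates = [r.proxy_variant for r in ld_results]
    eqtl_ann = annotate_eqtl(candidates, eqtl_table, gene, tissue)
    overlaps = annotate_overlaps(candidates, peaksets)
    scores = differential_binding_scan(
        candidates, sequence_source, motif_library,
        chip_gate=overlaps if gate else None,
        delta_threshold=delta_threshold,
    )
    scores_by_rsid: dict[str, list[AllelicBindingScore]] = {}
    for s in scores:
        scores_by_rsid.setdefault(s.variant.rsid, []).append(s)

    records = []
    for ld_res in ld_results:
        v = ld_res.proxy_variant
        records.append(CandidateRecord(
            variant=v,
            r2_with_index=ld_res.r2,
            is_index=ld_res.is_index,
            eqtl=eqtl_ann.get(v.rsid),
            overlaps=overlaps.get(v.rsid),
            motif_scores=scores_by_rsid.get(v.rsid, []),
        ))
    assign_tiers(records, pvalue_max=pvalue_max)
    ranked = rank_candidates(records)
    report = {
        "index_rsid": index_rsid,
        "gene": gene,
        "tissue": tissue,
        "r2_threshold": r2_threshold,
        "window_bp": window_bp,
        "delta_threshold": delta_threshold,
        "chip_gate": gate,
        "pvalue_max": pvalue_max,
        "n_candidates": len(records),
        "n_tier4": sum(r.tier == 4 for r in records),
        "top_rsid": ranked[0].variant.rsid if ranked else None,
    }
    return ranked, report


def run_planted_analysis(cfg, **overrides):
    """Simulate a locus and run the cascade against its planted truth.

    Convenience wrapper used by the end-to-end recovery checks; returns
    (ranked records, truth, report).
    """
    from .synthetic import simulate_locus

    panel, ann, truth = simulate_locus(cfg)
    ranked, report = prioritize_locus(
        panel, truth.index_rsid, ann.peaksets, ann.eqtl_records,
        ann.locus_seq, [ann.motif], cfg.gene, cfg.tissue, **overrides,
    )
    return ranked, truth, report


def records_to_dataframe(records: list[CandidateRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "rank": r.rank,
            "rsid": r.variant.rsid,
            "chrom": r.variant.chrom,
            "pos": r.variant.pos,
            "ref": r.variant.ref_allele,
            "alt": r.variant.alt_allele,
            "is_index": r.is_index,
            "r2_with_index": r.r2_with_index,
            "tier": r.tier,
            "composite_score": r.composite_score,
            "eqtl_slope_alt": r.eqtl.slope_alt if r.eqtl else np.nan,
            "eqtl_pvalue": r.eqtl.pvalue if r.eqtl else np.nan,
            "eqtl_direction": r.eqtl.direction_label if r.eqtl else "",
            "n_tf": r.n_tf,
            "n_reg": r.n_reg,
            "max_abs_delta": r.max_abs_delta,
            "flagged_motifs": ";".join(sorted({s.motif_name for s in r.motif_flags})),
        })
    return pd.DataFrame(rows)
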