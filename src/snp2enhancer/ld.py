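"""Linkage-disequilibrium estimation from phased haplotypes.

With ``pA``, ``pB`` the alt-allele frequencies at two sites and ``pAB``
the joint alt-alt haplotype frequency:

    D   = pAB − pA·pB
    r²  = D² / (pA(1−pA) pB(1−pB))
    D′  = |D| / Dmax,   Dmax = min(pA·pB, (1−pA)(1−pB))       if D < 0
                        Dmax = min(pA(1−pB), (1−pA)·pB)       if D ≥ 0

r² equals the squared Pearson correlation of the two 0/1 haplotype
columns and is invariant to ref/alt relabeling at either site; the
classical inequality |r| ≤ D′ (hence r² ≤ D′) holds for all biallelic
pairs.  X-chromosome panels pool male (one row) and female (two rows)
haplotypes, as PLINK does.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import HaplotypePanel, Variant


class MonomorphicVariantError(ValueError):
    """LD is undefined when a column carries only one allele."""


@dataclass(frozen=True)
class LDResult:
    index_variant: Variant
    proxy_variant: Variant
    r2: float
    d_prime: float
    n_haplotypes: int
    is_index: bool = False


def pairwise_ld(panel: HaplotypePanel, a: int, b: int) -> LDResult:
    """Haplotype-based r² and D′ between panel columns ``a`` and ``b``."""
    col_a = panel.alleles[:, a].astype(float)
    col_b = panel.alleles[:, b].astype(float)
    p_a, p_b = col_a.mean(), col_b.mean()
    for idx, p in ((a, p_a), (b, p_b)):
        if p <= 0.0 or p >= 1.0:
            raise MonomorphicVariantError(
                f"undefined LD: column {idx} ({panel.variants[idx].rsid}) is monomorphic"
            )
    p_ab = float((col_a * col_b).mean())
    d = p_ab - p_a * p_b
    r2 = d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))
    if d < 0:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    else:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    d_prime = abs(d) / d_max if d_max > 0 else 1.0
    return LDResult(
        index_variant=panel.variants[a],
        proxy_variant=panel.variants[b],
        r2=float(r2),
        d_prime=float(min(d_prime, 1.0)),
        n_haplotypes=panel.n_haplotypes,
        is_index=(a == b),
    )


def ld_expand(
    panel: HaplotypePanel,
    index_rsid: str,
    r2_threshold: float = 0.8,
    window_bp: int = 1_000_000,
) -> list[LDResult]:
    """All proxies of the index SNP with r² strictly above the threshold.

    Returns the index SNP first (self-r² = 1, ``is_index=True``),
    followed by proxies sorted by descending r².  The comparison is a
    strict ``>`` (the printed criterion is "r² > 0.8"), so a threshold
    of 1.0 returns an empty proxy list — even the index SNP cannot
    exceed it; the index is still reported, flagged, for auditability.
    Monomorphic columns can never pass the threshold and are skipped.
    """
    idx = panel.variant_index(index_rsid)
    index_variant = panel.variants[idx]
    out = [pairwise_ld(panel, idx, idx)]
    proxies = []
    for j, v in enumerate(panel.variants):
        if j == idx or abs(v.pos - index_variant.pos) > window_bp:
            continue
        try:
            res = pairwise_ld(panel, idx, j)
        except MonomorphicVariantError:
            continue
        if res.r2 > r2_threshold:
            proxies.append(res)
    proxies.sort(key=lambda r: (-r.r2, r.proxy_variant.pos))
    return out + proxies
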