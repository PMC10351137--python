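import numpy as np
import pytest

from snp2enhancer.io_formats import HaplotypePanel, Variant

# EMSA probe sequences for the T/C enhancer SNP, as printed (39 nt, SNP at
# 0-based offset 19): the reference allele is T, the risk allele C.
PROBE_T = "AACCCAAAAGCAAATGCAATAAAAACAAAGATAAATAGC"
PROBE_C = "AACCCAAAAGCAAATGCAACAAAAACAAAGATAAATAGC"
PROBE_SNP_INDEX = 19


@pytest.fixture
def probe_variant() -> Variant:
    """The T/C SNP carried by the printed probe sequences."""
    return Variant("chrX", 1_000_000, "rs_probe", "T", "C")


@pytest.fixture
def worked_panel() -> HaplotypePanel:
    """8 haplotypes at two sites: (1,1)x3, (1,0)x1, (0,1)x1, (0,0)x3.

    Direct counting gives pA = pB = 0.5, pAB = 0.375, D = 0.125,
    r² = 0.25, D′ = 0.5.
    """
    alleles = np.array(
        [[1, 1]] * 3 + [[1, 0]] + [[0, 1]] + [[0, 0]] * 3, dtype=np.uint8
    )
    variants = [
        Variant("chrX", 100, "rsA", "A", "G"),
        Variant("chrX", 200, "rsB", "C", "T"),
    ]
    return HaplotypePanel(variants, [f"s{i}" for i in range(4)], alleles)


def random_panel(rng: np.random.Generator, n_hap: int, n_snps: int) -> HaplotypePanel:
    """A random polymorphic panel for oracle-equivalence checks."""
    while True:
        alleles = (rng.random((n_hap, n_snps)) < rng.uniform(0.15, 0.85, n_snps)).astype(np.uint8)
        freqs = alleles.mean(axis=0)
        if ((freqs > 0) & (freqs < 1)).all():
            break
    variants = [
        Variant("chr7", 1000 + 10 * i, f"rs{i}", "A", "C") for i in range(n_snps)
    ]
    n_samples = n_hap // 2
    ids = [f"s{i}" for i in range(n_samples)]
    if n_hap % 2:
        # odd haplotype counts only make sense on X with a male sample
        variants = [Variant("chrX", v.pos, v.rsid, v.ref_allele, v.alt_allele)
                    for v in variants]
        ids.append("sM")
        return HaplotypePanel(variants, ids, alleles, sexes=["F"] * n_samples + ["M"])
    return HaplotypePanel(variants, ids, alleles)
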