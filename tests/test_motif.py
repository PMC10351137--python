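import numpy as np
import pytest

from snp2enhancer.annotation import OverlapSummary
from snp2enhancer.io_formats import Variant
from snp2enhancer.motif import (
    MotifModel,
    differential_binding_scan,
    pfm_to_energy,
    pfm_to_logodds,
    score_alleles,
)

from conftest import PROBE_SNP_INDEX, PROBE_T

_RC = str.maketrans("ACGT", "TGCA")


def brute_force_best(seq: str, snp_index: int, allele: str, motif: MotifModel) -> float:
    """Independent enumeration oracle: try every window containing the SNP,
    score forward and reverse-complement window strings directly."""
    w = pfm_to_logodds(motif)
    seq = seq[:snp_index] + allele + seq[snp_index + 1:]
    L = motif.length
    best = -np.inf
    for start in range(snp_index - L + 1, snp_index + 1):
        if start < 0 or start + L > len(seq):
            continue
        window = seq[start:start + L]
        if any(c not in "ACGT" for c in window):
            continue
        for s in (window, window.translate(_RC)[::-1]):
            score = sum(w[i, "ACGT".index(c)] for i, c in enumerate(s))
            best = max(best, score)
    return best


def random_motif(rng, L=None) -> MotifModel:
    L = L or int(rng.integers(2, 9))
    pfm = rng.dirichlet(np.ones(4) * 0.5, size=L)
    return MotifModel("m", pfm)


def random_case(rng):
    motif = random_motif(rng)
    L = motif.length
    flank = L + int(rng.integers(0, 4))
    seq = "".join(rng.choice(list("ACGT"), size=2 * flank + 1))
    ref = seq[flank]
    alt = rng.choice([b for b in "ACGT" if b != ref])
    v = Variant("chr1", 500, "rs", ref, alt)
    return v, seq, flank, motif


class TestLogOdds:
    def test_uniform_pfm_uniform_background_is_zero(self):
        m = MotifModel("u", np.full((4, 4), 0.25))
        assert np.allclose(pfm_to_logodds(m), 0.0)

    def test_smoothing_arithmetic_on_certain_column(self):
        # f = (1,0,0,0), pc = 0.1: smoothed = (1.025, 0.025, ...) / 1.1
        m = MotifModel("c", np.array([[1.0, 0, 0, 0], [0.25] * 4]))
        w = pfm_to_logodds(m)
        assert w[0, 0] == pytest.approx(np.log2((1.025 / 1.1) / 0.25), abs=1e-12)
        assert np.allclose(w[0, 1:], np.log2((0.025 / 1.1) / 0.25), atol=1e-12)

    def test_doubling_background_costs_one_bit(self):
        pfm = np.array([[0.7, 0.1, 0.1, 0.1], [0.25] * 4])
        a = pfm_to_logodds(MotifModel("a", pfm))
        b = pfm_to_logodds(MotifModel("b", pfm,
                                      background=np.array([0.5, 1 / 6, 1 / 6, 1 / 6])))
        assert np.allclose(a[:, 0] - b[:, 0], 1.0, atol=1e-12)


class TestEnergyMatrix:
    def test_uniform_column_has_zero_energies(self):
        em = pfm_to_energy(MotifModel("u", np.full((3, 4), 0.25)))
        assert np.allclose(em.energies, 0.0)

    def test_preferred_base_has_negative_energy_and_rows_sum_zero(self):
        m = MotifModel("p", np.array([[0.85, 0.05, 0.05, 0.05], [0.25] * 4]))
        e = pfm_to_energy(m).energies
        assert e[0, 0] < 0 < e[0, 1]
        assert np.allclose(e[0, 1:], e[0, 1])
        assert abs(e.sum(axis=1)).max() < 1e-9

    def test_minimum_energy_tracks_maximum_frequency(self):
        rng = np.random.default_rng(2)
        m = random_motif(rng, L=6)
        e = pfm_to_energy(m).energies
        assert (np.argmin(e, axis=1) == np.argmax(m.pfm, axis=1)).all()

    def test_logo_heights_put_preferred_bases_above_axis(self):
        m = MotifModel("p", np.array([[0.85, 0.05, 0.05, 0.05], [0.25] * 4]))
        heights = pfm_to_energy(m).logo_heights()
        assert heights[0, 0] > 0 > heights[0, 1]


class TestScoreAlleles:
    def test_uniform_motif_gives_zero_delta(self):
        m = MotifModel("u", np.full((3, 4), 0.25))
        v = Variant("chr1", 100, "rs", "A", "G")
        s = score_alleles(v, "CCAACC", 2, m)
        assert s.score_ref == s.score_alt == s.delta == 0.0

    def test_best_placement_matches_enumeration_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(200):
            v, seq, snp_index, motif = random_case(rng)
            s = score_alleles(v, seq, snp_index, motif)
            assert s.score_ref == pytest.approx(
                brute_force_best(seq, snp_index, v.ref_allele, motif), abs=1e-10)
            assert s.score_alt == pytest.approx(
                brute_force_best(seq, snp_index, v.alt_allele, motif), abs=1e-10)
            assert s.delta == s.score_alt - s.score_ref

    def test_strand_symmetry(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            v, seq, snp_index, motif = random_case(rng)
            rc_seq = seq.translate(_RC)[::-1]
            rc_index = len(seq) - 1 - snp_index
            rc_v = Variant(v.chrom, v.pos, v.rsid,
                           v.ref_allele.translate(_RC), v.alt_allele.translate(_RC))
            a = score_alleles(v, seq, snp_index, motif)
            b = score_alleles(rc_v, rc_seq, rc_index, motif)
            assert a.score_ref == pytest.approx(b.score_ref, abs=1e-10)
            assert a.score_alt == pytest.approx(b.score_alt, abs=1e-10)

    def test_delta_antisymmetric_under_allele_swap(self):
        rng = np.random.default_rng(29)
        for _ in range(50):
            v, seq, snp_index, motif = random_case(rng)
            swapped_seq = seq[:snp_index] + v.alt_allele + seq[snp_index + 1:]
            vs = Variant(v.chrom, v.pos, v.rsid, v.alt_allele, v.ref_allele)
            a = score_alleles(v, seq, snp_index, motif)
            b = score_alleles(vs, swapped_seq, snp_index, motif)
            assert a.delta == pytest.approx(-b.delta, abs=1e-10)

    def test_energy_and_logodds_agree_affinely_at_fixed_placement(self):
        # uniform background: score = const − energy/ln2 per window, so the
        # two parameterizations rank any set of sequences identically
        rng = np.random.default_rng(5)
        motif = random_motif(rng, L=5)
        w, e = pfm_to_logodds(motif), pfm_to_energy(motif).energies
        g = np.log(motif.smoothed())
        const = (g.mean(axis=1).sum() + motif.length * np.log(4)) / np.log(2)
        seqs = ["".join(rng.choice(list("ACGT"), size=5)) for _ in range(30)]
        scores = [sum(w[i, "ACGT".index(c)] for i, c in enumerate(s)) for s in seqs]
        energies = [sum(e[i, "ACGT".index(c)] for i, c in enumerate(s)) for s in seqs]
        assert np.allclose(scores, const - np.asarray(energies) / np.log(2), atol=1e-10)

    def test_risk_allele_scores_lower_on_printed_probe(self, probe_variant):
        """On the printed probe context, any motif preferring T at the SNP
        column predicts weaker binding of the risk C allele (delta < 0)."""
        rng = np.random.default_rng(1)
        for _ in range(20):
            # site-matching motif, as in an energy logo drawn over the locus
            # sequence: flanking columns prefer the probe bases, the SNP
            # column strongly prefers T with C most disfavored
            L = 7
            snp_col = 3
            pfm = np.full((L, 4), 0.1)
            for i in range(L):
                base = PROBE_T[PROBE_SNP_INDEX + i - snp_col]
                pfm[i, "ACGT".index(base)] = float(rng.uniform(0.5, 0.7))
            pfm[snp_col] = [0.05, 0.02, 0.05, 0.88]
            pfm /= pfm.sum(axis=1, keepdims=True)
            s = score_alleles(probe_variant, PROBE_T, PROBE_SNP_INDEX,
                              MotifModel("t_pref", pfm))
            assert s.delta < 0

    def test_context_base_must_match_reference_allele(self):
        m = MotifModel("u", np.full((2, 4), 0.25))
        v = Variant("chr1", 100, "rs", "G", "T")
        with pytest.raises(ValueError, match="reference allele"):
            score_alleles(v, "AAAAA", 2, m)

    def test_ambiguous_base_skips_placement_or_errors(self):
        m = MotifModel("u", np.full((2, 4), 0.25))
        v = Variant("chr1", 100, "rs", "A", "G")
        # N on the left: only the right-hand placement is scorable
        s = score_alleles(v, "NACC", 1, m)
        assert s.best_offset_ref == 1
        with pytest.raises(ValueError, match="ambiguous"):
            score_alleles(v, "NAN", 1, m)


class TestDifferentialBindingScan:
    def _setup(self):
        # context GC[T/C]AG with a site-matching motif over CTA: the C
        # allele breaks the strongly T-preferring middle column
        v = Variant("chrX", 100, "rs1", "T", "C")
        pfm = np.array([
            [0.1, 0.7, 0.1, 0.1],
            [0.04, 0.02, 0.04, 0.9],
            [0.7, 0.1, 0.1, 0.1],
        ])
        motif = MotifModel("CEBPB", pfm)
        source = {"rs1": ("GCTAG", 2)}
        return v, motif, (lambda var: source[var.rsid])

    def test_gate_blocks_candidates_outside_matching_chip_peaks(self):
        v, motif, source = self._setup()
        no_chip = {"rs1": OverlapSummary(v, [], ["h1"])}
        (s,) = differential_binding_scan([v], source, [motif], chip_gate=no_chip,
                                         delta_threshold=0.0)
        assert abs(s.delta) > 0 and not s.flagged and s.gate_passed is False

    def test_matching_chip_peak_passes_gate(self):
        v, motif, source = self._setup()
        gate = {"rs1": OverlapSummary(v, [("d1", "CEBPB")], [])}
        (s,) = differential_binding_scan([v], source, [motif], chip_gate=gate,
                                         delta_threshold=0.5)
        assert s.flagged and s.gate_passed

    def test_zero_threshold_flags_every_nonzero_delta_without_gate(self):
        v, motif, source = self._setup()
        (s,) = differential_binding_scan([v], source, [motif], delta_threshold=0.0)
        assert s.flagged and s.gate_passed is None

    def test_empty_motif_library_rejected(self):
        v, _, source = self._setup()
        with pytest.raises(ValueError, match="empty"):
            differential_binding_scan([v], source, [])
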