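"""Allele-dependent transcription-factor binding prediction.

A motif is held as a position frequency matrix (PFM) and scored in two
equivalent parameterizations:

* **log-odds (bits)** — the classical PWM: smoothed frequencies divided
  by a background distribution, log2.  Used for the best-placement scan
  and the differential (Δ) score between alleles.
* **ΔΔG energy (RT units)** — per-position, per-base relative binding
  free energies: minus the mean-centered log of the smoothed
  frequencies.  Favorable (preferred) bases get negative energy; a
  "energy logo" plots height = −energy, so preferred bases sit above
  the axis.  With a uniform background the two parameterizations differ
  by an affine transform per column and therefore always agree in rank.

The allele-dependent scan substitutes each allele at the SNP, evaluates
the PWM at every offset that keeps the SNP inside the motif window, on
both strands, and keeps the maximum.  The reported Δ (alt minus ref
best score) is negative when the alternate (risk) allele weakens the
predicted site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_formats import BASE_INDEX, BASES, Variant

log = logging.getLogger(__name__)

COMPLEMENT_INDEX = np.array([3, 2, 1, 0])  # A<->T, C<->G in (A, C, G, T) order


@dataclass
class MotifModel:
    """A TF binding model: L×4 position frequency matrix, rows sum to 1."""

    name: str
    pfm: np.ndarray
    pseudocount: float = 0.1
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.pfm = np.asarray(self.pfm, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.pfm.ndim != 2 or self.pfm.shape[1] != 4 or self.pfm.shape[0] < 2:
            raise ValueError(f"{self.name}: PFM must be L x 4 with L >= 2")
        if (self.pfm < 0).any():
            raise ValueError(f"{self.name}: PFM frequencies must be non-negative")
        if np.abs(self.pfm.sum(axis=1) - 1.0).max() > 1e-6:
            raise ValueError(f"{self.name}: PFM rows must sum to 1 (tolerance 1e-6)")
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError(f"{self.name}: background must sum to 1")

    @property
    def length(self) -> int:
        return self.pfm.shape[0]

    def smoothed(self) -> np.ndarray:
        """Pseudocount-smoothed frequencies: (f + pc/4) / (1 + pc)."""
        pc = self.pseudocount
        return (self.pfm + pc / 4.0) / (1.0 + pc)


@dataclass
class EnergyMatrix:
    """Relative binding free energies (ΔΔG) in RT units, rows mean-centered."""

    name: str
    energies: np.ndarray
    derivation: str = "from_pfm"

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        if self.derivation == "from_pfm":
            centering = np.abs(self.energies.mean(axis=1)).max()
            if centering > 1e-9:
                raise ValueError(
                    f"{self.name}: from_pfm energy rows must be mean-centered "
                    f"(max deviation {centering:g})"
                )

    def logo_heights(self) -> np.ndarray:
        """Heights for an energy logo: preferred bases (negative ΔΔG) plot above the axis."""
        return -self.energies


def pfm_to_logodds(m: MotifModel) -> np.ndarray:
    """L×4 log2-odds weight matrix of smoothed frequencies vs background."""
    return np.log2(m.smoothed() / m.background[None, :])


def pfm_to_energy(m: MotifModel) -> EnergyMatrix:
    """ΔΔG energies: e(i,b) = −(ln f̃(i,b) − mean_b' ln f̃(i,b')).

    The most-preferred base in a column has the minimum (most negative)
    energy; each row sums to zero.
    """
    g = np.log(m.smoothed())
    e = -(g - g.mean(axis=1, keepdims=True))
    return EnergyMatrix(name=m.name, energies=e, derivation="from_pfm")


def logo_table(m: MotifModel):
    """Per-position logo heights (−ΔΔG) as a list of dicts, ready for TSV dumping."""
    heights = pfm_to_energy(m).logo_heights()
    return [
        {"pos": i + 1, **{b: float(heights[i, j]) for j, b in enumerate(BASES)}}
        for i in range(m.length)
    ]


# ---------------------------------------------------------------------------
# Allele-dependent scanning
# ---------------------------------------------------------------------------

@dataclass
class AllelicBindingScore:
    """Best-placement PWM scores of both alleles of one SNP for one motif."""

    variant: Variant
    motif_name: str
    score_ref: float
    score_alt: float
    energy_ref: float
    energy_alt: float
    delta: float
    best_offset_ref: int
    best_strand_ref: str
    best_offset_alt: int
    best_strand_alt: str
    flagged: bool = False
    gate_passed: bool | None = None


def _encode(seq: str) -> np.ndarray:
    """Map a sequence to indices in (A, C, G, T); anything else (N) -> -1."""
    out = np.full(len(seq), -1, dtype=np.int64)
    for i, ch in enumerate(seq.upper()):
        out[i] = BASE_INDEX.get(ch, -1)
    return out


def _best_placement(codes: np.ndarray, snp_index: int, weights: np.ndarray,
                    energies: np.ndarray) -> tuple[float, float, int, str]:
    """Max PWM score over all windows containing the SNP, both strands.

    Ties break deterministically: smaller offset first, '+' strand
    before '-'.  Windows containing an ambiguous base are skipped; if
    every window is skipped a ValueError is raised.
    """
    L = weights.shape[0]
    rc_weights = weights[::-1][:, COMPLEMENT_INDEX]
    rc_energies = energies[::-1][:, COMPLEMENT_INDEX]
    best = None
    for start in range(snp_index - L + 1, snp_index + 1):
        if start < 0 or start + L > codes.size:
            continue
        window = codes[start:start + L]
        if (window < 0).any():
            continue
        idx = np.arange(L)
        for strand, w, e in (("+", weights, energies), ("-", rc_weights, rc_energies)):
            score = float(w[idx, window].sum())
            if best is None or score > best[0]:
                best = (score, float(e[idx, window].sum()), start, strand)
    if best is None:
        raise ValueError("no scorable placement: every window contains an ambiguous base")
    return best


def score_alleles(variant: Variant, sequence_context: str, snp_index: int,
                  motif: MotifModel) -> AllelicBindingScore:
    """Score both alleles of a SNP against one motif.

    ``sequence_context`` must cover at least motif-length − 1 bases on
    each side of the SNP, whose base (at ``snp_index``, 0-based within
    the context) must equal the variant's reference allele.
    """
    L = motif.length
    context = sequence_context.upper()
    if snp_index < L - 1 or len(context) - snp_index - 1 < L - 1:
        raise ValueError(
            f"{variant.rsid}: context must extend >= {L - 1} bases on each side of the SNP"
        )
    if context[snp_index] != variant.ref_allele:
        raise ValueError(
            f"{variant.rsid}: context base {context[snp_index]!r} at the SNP does not "
            f"match the reference allele {variant.ref_allele!r}"
        )
    weights = pfm_to_logodds(motif)
    energies = pfm_to_energy(motif).energies
    codes = _encode(context)

    results = {}
    for label, allele in (("ref", variant.ref_allele), ("alt", variant.alt_allele)):
        allele_codes = codes.copy()
        allele_codes[snp_index] = BASE_INDEX[allele]
        results[label] = _best_placement(allele_codes, snp_index, weights, energies)

    (s_ref, e_ref, off_ref, st_ref) = results["ref"]
    (s_alt, e_alt, off_alt, st_alt) = results["alt"]
    return AllelicBindingScore(
        variant=variant, motif_name=motif.name,
        score_ref=s_ref, score_alt=s_alt,
        energy_ref=e_ref, energy_alt=e_alt,
        delta=s_alt - s_ref,
        best_offset_ref=off_ref, best_strand_ref=st_ref,
        best_offset_alt=off_alt, best_strand_alt=st_alt,
    )


def differential_binding_scan(
    candidates,
    sequence_source,
    motif_library: list[MotifModel],
    chip_gate=None,
    delta_threshold: float = 2.0,
) -> list[AllelicBindingScore]:
    """Scan every (candidate, motif) pair and flag predicted differential binding.

    ``sequence_source`` maps a variant to its ``(context, snp_index)``
    pair (any callable; :class:`~snp2enhancer.synthetic.LocusSequence`
    provides one).  A pair is flagged when ``|delta| >= delta_threshold``
    and — if ``chip_gate`` (variant rsid → OverlapSummary) is given —
    the candidate sits inside a TF ChIP-seq peak whose factor matches
    the motif name.  The ChIP gate encodes the requirement that a
    predicted allelic site is only credible where the factor is
    actually observed bound.
    """
    if not motif_library:
        raise ValueError("motif library is empty")
    scores = []
    for variant in candidates:
        context, snp_index = sequence_source(variant)
        for motif in motif_library:
            s = score_alleles(variant, context, snp_index, motif)
            if chip_gate is not None:
                summary = chip_gate.get(variant.rsid)
                factors = {f.upper() for _, f in summary.tf_datasets} if summary else set()
                s.gate_passed = motif.name.upper() in factors
            else:
                s.gate_passed = None
            s.flagged = abs(s.delta) >= delta_threshold and (s.gate_passed is not False)
            scores.append(s)
    return scores
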