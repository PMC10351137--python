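"""Readers and writers for the external formats the pipeline touches.

Coordinate conventions
----------------------
VCF positions are 1-based; BED intervals are 0-based half-open.  Every
internal interval computation uses the half-open 0-based convention, and
conversion happens only at the parser boundary: a variant at 1-based
position ``p`` overlaps ``[start, end)`` iff ``start <= p - 1 < end``.

The VCF reader covers the subset this pipeline needs (CHROM, POS, ID,
REF, ALT, GT): biallelic SNPs with phased genotypes.  On the X
chromosome a male contributes exactly one haplotype row (hemizygote,
PLINK convention) and a female two.  Unphased diploid records are
rejected on multi-variant panels because the LD estimator requires
haplotype phase.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from difflib import get_close_matches
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
VALID_ASSAY_CLASSES = frozenset({"tf_chip", "histone", "open_chromatin"})


class FormatError(ValueError):
    """A file violates the subset of its format this pipeline accepts."""


def normalize_chrom(name: str, aliases: dict[str, str] | None = None) -> str:
    """Map 'chrX'/'X' style names onto one label ('X').

    ``aliases`` may supply extra mappings (applied after prefix
    stripping); mismatching conventions across inputs are tolerated this
    way rather than erroring.
    """
    stripped = name[3:] if name.lower().startswith("chr") else name
    if aliases and stripped in aliases:
        return aliases[stripped]
    return stripped


def is_x_chromosome(name: str) -> bool:
    return normalize_chrom(name).upper() == "X"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Variant:
    """A biallelic SNP at a 1-based position."""

    chrom: str
    pos: int
    rsid: str
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "ref_allele", self.ref_allele.upper())
        object.__setattr__(self, "alt_allele", self.alt_allele.upper())
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        for allele in (self.ref_allele, self.alt_allele):
            if allele not in BASES:
                raise ValueError(
                    f"{self.rsid}: allele {allele!r} is not a single base "
                    "(indels and ambiguity codes are rejected)"
                )
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.rsid}: ref and alt alleles are identical")

    @property
    def pos0(self) -> int:
        """0-based position (half-open convention)."""
        return self.pos - 1


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval ``[start, end)``."""

    chrom: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): require 0 <= start < end"
            )

    def contains_variant(self, v: Variant) -> bool:
        return (
            normalize_chrom(self.chrom) == normalize_chrom(v.chrom)
            and self.start <= v.pos0 < self.end
        )


@dataclass
class PeakSet:
    """Peaks from one functional-genomics dataset (one BED file)."""

    intervals: list[GenomicInterval]
    dataset_id: str
    assay_class: str
    factor: str = ""
    cell_type: str = ""

    def __post_init__(self) -> None:
        if self.assay_class not in VALID_ASSAY_CLASSES:
            raise FormatError(
                f"{self.dataset_id}: unknown assay_class {self.assay_class!r} "
                f"(expected one of {sorted(VALID_ASSAY_CLASSES)})"
            )
        if (self.assay_class == "tf_chip") != bool(self.factor):
            raise FormatError(
                f"{self.dataset_id}: factor must be set iff assay_class is tf_chip"
            )


@dataclass(frozen=True)
class EQTLRecord:
    """One variant-gene-tissue association with a signed effect."""

    variant: Variant
    gene: str
    tissue: str
    effect_allele: str
    slope: float
    pvalue: float

    def __post_init__(self) -> None:
        if self.effect_allele not in (self.variant.ref_allele, self.variant.alt_allele):
            raise ValueError(
                f"{self.variant.rsid}: effect allele {self.effect_allele} matches "
                "neither ref nor alt"
            )
        if not np.isfinite(self.slope):
            raise ValueError(f"{self.variant.rsid}: slope is not finite")
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError(f"{self.variant.rsid}: p-value {self.pvalue} outside (0, 1]")


@dataclass
class HaplotypePanel:
    """Phased 0/1 allele matrix: one row per haplotype, one column per SNP.

    ``sexes`` carries per-sample 'M'/'F' labels; on the X chromosome a
    male sample owns a single haplotype row, everything else two.
    """

    variants: list[Variant]
    sample_ids: list[str]
    alleles: np.ndarray
    sexes: list[str] | None = None

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        if self.alleles.ndim != 2 or self.alleles.shape[1] != len(self.variants):
            raise ValueError(
                f"allele matrix shape {self.alleles.shape} does not match "
                f"{len(self.variants)} variants"
            )
        if self.alleles.size and self.alleles.max() > 1:
            raise ValueError("allele matrix entries must be 0 or 1")
        if self.sexes is not None and len(self.sexes) != len(self.sample_ids):
            raise ValueError("sexes must have one label per sample")
        expected = sum(self.rows_per_sample)
        if self.alleles.shape[0] != expected:
            raise ValueError(
                f"{self.alleles.shape[0]} haplotype rows but sample sexes imply {expected}"
            )

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def on_x(self) -> bool:
        return bool(self.variants) and is_x_chromosome(self.variants[0].chrom)

    @property
    def rows_per_sample(self) -> list[int]:
        if self.sexes is None or not self.on_x:
            return [2] * len(self.sample_ids)
        return [1 if s.upper() == "M" else 2 for s in self.sexes]

    def variant_index(self, rsid: str) -> int:
        for i, v in enumerate(self.variants):
            if v.rsid == rsid:
                return i
        near = get_close_matches(rsid, [v.rsid for v in self.variants], n=3)
        raise KeyError(
            f"rsid {rsid!r} not in panel" + (f"; nearest: {', '.join(near)}" if near else "")
        )

    def alt_frequency(self, col: int) -> float:
        return float(self.alleles[:, col].mean())


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_REGION_RE = re.compile(r"^([^:]+)(?::(\d+)-(\d+))?$")


def _parse_region(region: str) -> tuple[str, int | None, int | None]:
    m = _REGION_RE.match(region)
    if not m:
        raise ValueError(f"cannot parse region {region!r} (expected chrom[:start-end])")
    chrom, lo, hi = m.groups()
    return chrom, (int(lo) if lo else None), (int(hi) if hi else None)


def read_vcf(
    path: str | Path,
    region: str | None = None,
    sexes: dict[str, str] | None = None,
) -> HaplotypePanel:
    """Read phased genotypes from a text VCF into a :class:`HaplotypePanel`.

    Multiallelic and non-SNP records are skipped with a warning.  A male
    X genotype written haploid ("0"/"1") or as a homozygous diploid
    ("0|0", when ``sexes`` marks the sample 'M') contributes one
    haplotype row.  Unphased ('/') diploid genotypes raise on panels of
    more than one variant, naming the first offending record.
    """
    path = Path(path)
    want_chrom = want_lo = want_hi = None
    if region is not None:
        want_chrom, want_lo, want_hi = _parse_region(region)

    sample_ids: list[str] = []
    records: list[Variant] = []
    gt_rows: list[list[str]] = []
    first_unphased: str | None = None

    with open(path) as fh:
        header_seen = False
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                if "FORMAT" not in cols:
                    raise FormatError(f"{path}: no FORMAT column, GT fields unavailable")
                sample_ids = cols[cols.index("FORMAT") + 1:]
                header_seen = True
                continue
            if not header_seen:
                raise FormatError(f"{path}: data before #CHROM header (line {lineno})")
            fields = line.split("\t")
            chrom, pos_s, rsid, ref, alt = fields[0], fields[1], fields[2], fields[3], fields[4]
            fmt = fields[8].split(":")
            if "GT" not in fmt:
                raise FormatError(f"{path} line {lineno}: record has no GT field")
            if "," in alt:
                log.warning("%s line %d: skipping multiallelic record %s", path, lineno, rsid)
                continue
            if len(ref) != 1 or len(alt) != 1 or ref.upper() not in BASES or alt.upper() not in BASES:
                log.warning("%s line %d: skipping non-SNP record %s (%s/%s)",
                            path, lineno, rsid, ref, alt)
                continue
            pos = int(pos_s)
            if want_chrom is not None:
                if normalize_chrom(chrom) != normalize_chrom(want_chrom):
                    continue
                if want_lo is not None and not (want_lo <= pos <= want_hi):
                    continue
            gti = fmt.index("GT")
            gts = [f.split(":")[gti] for f in fields[9:]]
            if len(gts) != len(sample_ids):
                raise FormatError(f"{path} line {lineno}: {len(gts)} genotypes "
                                  f"for {len(sample_ids)} samples")
            if first_unphased is None and any("/" in g for g in gts):
                first_unphased = f"{chrom}:{pos} ({rsid})"
            records.append(Variant(chrom, pos, rsid, ref, alt))
            gt_rows.append(gts)

    if first_unphased is not None and len(records) > 1:
        raise FormatError(
            f"{path}: unphased genotype at {first_unphased}; phased haplotypes "
            "are required for LD on multi-variant panels"
        )

    on_x = bool(records) and is_x_chromosome(records[0].chrom)
    sex_list = [(sexes or {}).get(s, "F") for s in sample_ids]

    # Determine ploidy per sample: haploid GT anywhere marks a hemizygote.
    haploid = [False] * len(sample_ids)
    for gts in gt_rows:
        for si, g in enumerate(gts):
            if "|" not in g and "/" not in g:
                haploid[si] = True
    for si in range(len(sample_ids)):
        if on_x and sex_list[si].upper() == "M":
            haploid[si] = True
        if haploid[si]:
            sex_list[si] = "M"
    if any(haploid) and not on_x:
        raise FormatError(f"{path}: haploid genotypes outside the X chromosome")

    n_rows = sum(1 if h else 2 for h in haploid)
    alleles = np.zeros((n_rows, len(records)), dtype=np.uint8)
    for vi, gts in enumerate(gt_rows):
        row = 0
        for si, g in enumerate(gts):
            parts = g.replace("/", "|").split("|")
            if haploid[si]:
                if len(parts) == 2:
                    if parts[0] != parts[1]:
                        raise FormatError(
                            f"{path}: heterozygous diploid genotype {g!r} for "
                            f"hemizygous male sample {sample_ids[si]}"
                        )
                    parts = parts[:1]
                alleles[row, vi] = int(parts[0])
                row += 1
            else:
                if len(parts) != 2:
                    raise FormatError(
                        f"{path}: sample {sample_ids[si]} mixes haploid and "
                        "diploid genotypes"
                    )
                alleles[row, vi] = int(parts[0])
                alleles[row + 1, vi] = int(parts[1])
                row += 2

    return HaplotypePanel(records, sample_ids, alleles, sexes=sex_list)


def write_vcf(panel: HaplotypePanel, path: str | Path) -> None:
    """Write a panel back to a minimal phased VCF (GT only)."""
    path = Path(path)
    rows = panel.rows_per_sample
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.sample_ids) + "\n")
        for vi, v in enumerate(panel.variants):
            col = panel.alleles[:, vi]
            gts, row = [], 0
            for nr in rows:
                if nr == 1:
                    gts.append(str(col[row]))
                else:
                    gts.append(f"{col[row]}|{col[row + 1]}")
                row += nr
            fh.write(f"{v.chrom}\t{v.pos}\t{v.rsid}\t{v.ref_allele}\t{v.alt_allele}"
                     f"\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n")


# ---------------------------------------------------------------------------
# BED + manifest
# ---------------------------------------------------------------------------

def read_bed(path: str | Path, dataset_id: str = "") -> list[GenomicInterval]:
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else ""
            if start >= end:
                raise FormatError(
                    f"{path} line {lineno}: start {start} >= end {end}"
                )
            intervals.append(GenomicInterval(chrom, start, end, name))
    return intervals


def write_bed(intervals: list[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")


MANIFEST_COLUMNS = ["dataset_id", "bed_path", "assay_class", "factor", "cell_type"]


def read_bed_manifest(manifest_path: str | Path) -> list[PeakSet]:
    """Read a TSV manifest of BED datasets into one PeakSet per row.

    ``bed_path`` entries are resolved relative to the manifest's
    directory.
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, sep="\t", dtype=str).fillna("")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{manifest_path}: manifest missing columns {missing}")
    peaksets = []
    for row in df.itertuples(index=False):
        bed = Path(row.bed_path)
        if not bed.is_absolute():
            bed = manifest_path.parent / bed
        peaksets.append(PeakSet(
            intervals=read_bed(bed, row.dataset_id),
            dataset_id=row.dataset_id,
            assay_class=row.assay_class,
            factor=row.factor,
            cell_type=row.cell_type,
        ))
    return peaksets


def write_bed_manifest(peaksets: list[PeakSet], out_dir: str | Path,
                       manifest_name: str = "manifest.tsv") -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for ps in peaksets:
        bed_name = f"{ps.dataset_id}.bed"
        write_bed(ps.intervals, out_dir / bed_name)
        rows.append((ps.dataset_id, bed_name, ps.assay_class, ps.factor, ps.cell_type))
    manifest = out_dir / manifest_name
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, sep="\t", index=False)
    return manifest


# ---------------------------------------------------------------------------
# Motif files (Cis-BP PWM text and MEME minimal)
# ---------------------------------------------------------------------------

def read_motif(path: str | Path, format: str = "cisbp_pwm"):
    """Read a motif file into a :class:`~snp2enhancer.motif.MotifModel`.

    Rows must already be base probabilities: any row summing outside
    [0.9, 1.1] is rejected (it is probably a count matrix), otherwise
    rows are renormalized to sum exactly to 1.
    """
    from .motif import MotifModel  # deferred: motif module owns the type

    path = Path(path)
    stem = path.stem
    if stem.endswith(".pwm"):
        stem = stem[: -len(".pwm")]
    if format == "cisbp_pwm":
        name = stem
        rows = []
        with open(path) as fh:
            header = fh.readline().split()
            if [h.upper() for h in header[:5]] != ["POS", "A", "C", "G", "T"]:
                raise FormatError(f"{path}: expected 'Pos A C G T' header")
            for line in fh:
                if not line.strip():
                    continue
                vals = line.split()
                rows.append([float(x) for x in vals[1:5]])
    elif format == "meme_minimal":
        name, rows, in_matrix = stem, [], False
        with open(path) as fh:
            for line in fh:
                s = line.strip()
                if s.startswith("MOTIF"):
                    name = s.split()[1]
                elif s.startswith("letter-probability matrix"):
                    in_matrix = True
                elif in_matrix:
                    if not s or not s[0].isdigit() and s[0] != "0" and s[0] != ".":
                        in_matrix = False
                        continue
                    rows.append([float(x) for x in s.split()[:4]])
    else:
        raise ValueError(f"unknown motif format {format!r}")

    pfm = np.asarray(rows, dtype=float)
    if pfm.ndim != 2 or pfm.shape[0] < 2:
        raise FormatError(f"{path}: motif must have length >= 2")
    sums = pfm.sum(axis=1)
    bad = np.where((sums < 0.9) | (sums > 1.1))[0]
    if bad.size:
        raise FormatError(
            f"{path}: row {bad[0] + 1} sums to {sums[bad[0]]:.3g}; looks like "
            "counts, not frequencies — convert before loading"
        )
    pfm = pfm / sums[:, None]
    return MotifModel(name=name, pfm=pfm)


def write_motif_cisbp(motif, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("Pos\tA\tC\tG\tT\n")
        for i, row in enumerate(motif.pfm, 1):
            fh.write(f"{i}\t" + "\t".join(f"{x:.6f}" for x in row) + "\n")


# ---------------------------------------------------------------------------
# eQTL tables (GTEx-style TSV)
# ---------------------------------------------------------------------------

EQTL_COLUMNS = ["variant_id", "gene_id", "tissue", "effect_allele", "slope", "pval"]


def _variant_from_id(variant_id: str, rsid: str = "") -> Variant:
    """Parse a GTEx-style variant_id 'chrX_1000_T_C[_b38]'."""
    parts = variant_id.split("_")
    if len(parts) < 4:
        raise FormatError(f"cannot parse variant_id {variant_id!r}")
    chrom, pos, ref, alt = parts[0], int(parts[1]), parts[2], parts[3]
    return Variant(chrom, pos, rsid or variant_id, ref, alt)


def read_eqtl_table(path: str | Path) -> list[EQTLRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str},
                     float_precision="round_trip")
    missing = [c for c in EQTL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: eQTL table missing columns {missing}")
    has_rsid = "rsid" in df.columns
    records = []
    for row in df.itertuples(index=False):
        v = _variant_from_id(row.variant_id, str(row.rsid) if has_rsid else "")
        records.append(EQTLRecord(v, row.gene_id, row.tissue,
                                  str(row.effect_allele).upper(),
                                  float(row.slope), float(row.pval)))
    return records


def write_eqtl_table(records: list[EQTLRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        v = r.variant
        vid = f"{v.chrom}_{v.pos}_{v.ref_allele}_{v.alt_allele}"
        rows.append((vid, v.rsid, r.gene, r.tissue, r.effect_allele,
                     repr(float(r.slope)), repr(float(r.pvalue))))
    pd.DataFrame(rows, columns=EQTL_COLUMNS[:1] + ["rsid"] + EQTL_COLUMNS[1:]).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# TSS annotation
# ---------------------------------------------------------------------------

def read_tss_bed(path: str | Path) -> list[tuple[str, str, int]]:
    """Read gene TSS positions from a BED file; returns (gene, chrom, 1-based TSS)."""
    out = []
    for iv in read_bed(path):
        out.append((iv.name, iv.chrom, iv.start + 1))
    return out


def write_tss_bed(tss: list[tuple[str, str, int]], path: str | Path) -> None:
    write_bed([GenomicInterval(c, p - 1, p, name=g) for g, c, p in tss], path)


# ---------------------------------------------------------------------------
# Reporter plate tables
# ---------------------------------------------------------------------------

REPORTER_COLUMNS = ["construct", "condition", "replicate_id", "nano", "firefly"]


def read_reporter_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REPORTER_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: reporter table missing columns {missing}")
    if (df["nano"] <= 0).any() or (df["firefly"] <= 0).any():
        raise FormatError(f"{path}: luciferase readings must be strictly positive")
    return df


def write_reporter_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=REPORTER_COLUMNS)
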