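"""Distance-normalized (observed/expected) chromatin-contact analysis.

The expected contact count at genomic separation ``d`` is the mean
count over all bin pairs at that separation in the supplied table —
the standard O/E construction used for calling looping interactions
from a bait bin ("virtual 4C").  Distances supported by fewer than
``min_pairs`` bin pairs are pooled with neighboring distances
(greedy geometric pooling) before the mean is taken, so the expected
curve is never estimated from a handful of pairs.  O/E values are
scale-invariant: multiplying every count by k > 0 changes nothing.

Interactions with O/E at or above a threshold (default 2.00) are
reported, and promoter hits are called when a gene's TSS bin (TSS ± a
promoter window) is among the reported bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class ContactTable:
    """Upper-triangle binned contact counts for one chromosome."""

    chrom: str
    bin_size: int
    bin_i: np.ndarray
    bin_j: np.ndarray
    count: np.ndarray

    def __post_init__(self) -> None:
        self.bin_i = np.asarray(self.bin_i, dtype=np.int64)
        self.bin_j = np.asarray(self.bin_j, dtype=np.int64)
        self.count = np.asarray(self.count, dtype=float)
        if (self.bin_i < 0).any() or (self.bin_j < 0).any():
            raise ValueError("bin indices must be >= 0")
        if (self.count < 0).any():
            raise ValueError("contact counts must be >= 0")
        # canonicalize to upper triangle i <= j
        swap = self.bin_i > self.bin_j
        self.bin_i[swap], self.bin_j[swap] = self.bin_j[swap], self.bin_i[swap]

    @property
    def n_bins(self) -> int:
        if self.bin_j.size == 0:
            return 0
        return int(self.bin_j.max()) + 1

    def to_dense(self) -> np.ndarray:
        n = self.n_bins
        m = np.zeros((n, n))
        m[self.bin_i, self.bin_j] = self.count
        upper = np.triu(m, 1)
        return m + upper.T


@dataclass
class BaitProfile:
    """O/E profile of one bait bin against every other bin."""

    bait_bin: int
    bins: np.ndarray
    observed: np.ndarray
    expected: np.ndarray
    normalized: np.ndarray
    reported_bins: np.ndarray
    promoter_hits: list[tuple[str, int, float]] = field(default_factory=list)


def read_contacts(path, bin_size: int | None = None) -> ContactTable:
    """Read a contacts TSV (chrom, bin_i, bin_j, count).

    A ``# bin_size=N`` comment line, when present, supplies the bin
    size; otherwise it must be passed explicitly.
    """
    header_bin = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "bin_size=" in line:
                header_bin = int(line.split("bin_size=")[1].strip())
            if not line.startswith("#"):
                break
    df = pd.read_csv(path, sep="\t", comment="#")
    bs = bin_size if bin_size is not None else header_bin
    if bs is None:
        raise ValueError(f"{path}: bin size not given and no '# bin_size=' header")
    if df.empty:
        raise ValueError(f"{path}: empty contact table")
    chrom = str(df["chrom"].iloc[0])
    return ContactTable(chrom, bs, df["bin_i"].to_numpy(),
                        df["bin_j"].to_numpy(), df["count"].to_numpy())


def write_contacts(table: ContactTable, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# bin_size={table.bin_size}\n")
        fh.write("chrom\tbin_i\tbin_j\tcount\n")
        for i, j, c in zip(table.bin_i, table.bin_j, table.count):
            fh.write(f"{table.chrom}\t{i}\t{j}\t{c:.10g}\n")


def expected_by_distance(table: ContactTable, min_pairs: int = 10) -> np.ndarray:
    """Expected contact count at each separation d = 0 .. n_bins − 1.

    expected(d) is the mean count over the n_bins − d bin pairs at
    separation d (absent entries count as zero).  Consecutive distances
    are pooled, starting from each distance whose pair count falls
    below ``min_pairs``, until the pooled group reaches ``min_pairs``
    pairs; every distance in a pooled group shares the group mean.
    """
    n = table.n_bins
    if n == 0:
        raise ValueError("empty contact table")
    dense = table.to_dense()
    sums = np.array([np.trace(dense, offset=d) for d in range(n)])
    npairs = np.arange(n, 0, -1)

    expected = np.empty(n)
    d = 0
    while d < n:
        group_sum, group_pairs, end = float(sums[d]), int(npairs[d]), d + 1
        while group_pairs < min_pairs and end < n:
            group_sum += sums[end]
            group_pairs += npairs[end]
            end += 1
        expected[d:end] = group_sum / group_pairs
        d = end
    return expected


def bait_query(
    table: ContactTable,
    bait_position_bp: int,
    tss_annotation: list[tuple[str, str, int]] | None = None,
    threshold: float = 2.00,
    promoter_window: int = 2000,
    min_pairs: int = 10,
) -> BaitProfile:
    """O/E profile from the bin containing ``bait_position_bp``.

    Bins whose distance-normalized frequency reaches ``threshold`` are
    reported; ``promoter_hits`` lists genes whose TSS bin (TSS ±
    ``promoter_window``) is among them.  A bait bin with zero marginal
    contacts yields an empty profile with a warning.
    """
    bait_bin = bait_position_bp // table.bin_size
    n = table.n_bins
    if bait_bin >= n:
        raise ValueError(f"bait position {bait_position_bp} maps to bin {bait_bin}, "
                         f"outside the table ({n} bins)")
    dense = table.to_dense()
    observed = dense[bait_bin]
    bins = np.arange(n)
    if observed.sum() == 0:
        log.warning("bait bin %d has zero marginal contacts; empty profile", bait_bin)
        empty = np.array([], dtype=np.int64)
        return BaitProfile(bait_bin, bins, observed, np.full(n, np.nan),
                           np.full(n, np.nan), empty, [])
    expected = expected_by_distance(table, min_pairs=min_pairs)
    dist = np.abs(bins - bait_bin)
    exp_at = expected[dist]
    with np.errstate(divide="ignore", invalid="ignore"):
        normalized = np.where(exp_at > 0, observed / exp_at, np.nan)
    reported = bins[np.nan_to_num(normalized, nan=-np.inf) >= threshold]

    hits: list[tuple[str, int, float]] = []
    for gene, _chrom, tss_pos in (tss_annotation or []):
        lo = max(0, (tss_pos - 1 - promoter_window)) // table.bin_size
        hi = (tss_pos - 1 + promoter_window) // table.bin_size
        for b in range(lo, hi + 1):
            if b in reported:
                hits.append((gene, b, float(normalized[b])))
    return BaitProfile(bait_bin, bins, observed, exp_at, normalized, reported, hits)
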