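"""ChIP-seq tag-density tracks, normalization and occupancy extraction.

Density is the count of tags (full read extents) overlapping a sliding
150 bp window advanced in 20 bp steps.  Tracks are normalized per sample by
one global linear scale fixing the median of informative bins (count > 15
reads) to 25.  Site occupancy is the maximum normalized density over the
14 bp motif.  A read-simulation mappability filter flags sites whose
simulated 36-mers (per allele at each SNP) map ambiguously.

Coordinates are 0-based half-open throughout.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._util import revcomp_str

DEFAULT_WINDOW = 150
DEFAULT_STEP = 20
DEFAULT_TARGET = 25.0
DEFAULT_MIN_READS = 15


class NormalizationError(RuntimeError):
    """No bins qualify for the global scaling."""


@dataclass
class DensityTrack:
    """Sliding-window tag density over one contiguous region."""

    origin: int                  # genomic start of the first bin
    step: int
    window: int
    counts: np.ndarray           # raw tag counts per bin
    scale: float = 1.0
    normalized: bool = False

    @property
    def values(self) -> np.ndarray:
        return self.counts * self.scale

    @property
    def bin_starts(self) -> np.ndarray:
        return self.origin + self.step * np.arange(len(self.counts))

    @property
    def extent(self) -> tuple:
        return self.origin, self.origin + self.step * (len(self.counts) - 1) + self.window


def sliding_density(tags, extent: Optional[tuple] = None,
                    window: int = DEFAULT_WINDOW, step: int = DEFAULT_STEP) -> DensityTrack:
    """Count tags overlapping each [bin_start, bin_start + window) bin.

    ``tags`` is an (n, 2) array-like of read (start, end) intervals; a tag
    overlaps a bin when start < bin_end and end > bin_start.
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    t = np.asarray(tags, dtype=np.int64).reshape(-1, 2)
    if extent is None:
        if len(t) == 0:
            return DensityTrack(origin=0, step=step, window=window,
                                counts=np.zeros(1))
        lo = int(t[:, 0].min()) - window + 1
        hi = int(t[:, 1].max())
    else:
        lo, hi = extent
    lo = (lo // step) * step
    n_bins = max(1, int(np.ceil((hi - lo) / step)))
    starts = lo + step * np.arange(n_bins)
    if len(t) == 0:
        return DensityTrack(origin=lo, step=step, window=window,
                            counts=np.zeros(n_bins))
    s = np.sort(t[:, 0])
    e = np.sort(t[:, 1])
    # overlap count = #(tag_start < bin_end) - #(tag_end <= bin_start)
    counts = (np.searchsorted(s, starts + window, side="left")
              - np.searchsorted(e, starts, side="right")).astype(float)
    return DensityTrack(origin=lo, step=step, window=window, counts=counts)


def normalize_global(tracks: Sequence[DensityTrack], target: float = DEFAULT_TARGET,
                     min_reads: float = DEFAULT_MIN_READS) -> float:
    """Apply one global linear scale across all of a sample's tracks.

    scale = target / median(counts of bins with count > min_reads), pooled
    over every track given.  Mutates the tracks in place and returns the
    scale.  Raises ``NormalizationError`` when no bin qualifies.
    """
    pooled = np.concatenate([t.counts[t.counts > min_reads] for t in tracks]) \
        if tracks else np.array([])
    if pooled.size == 0:
        raise NormalizationError(
            f"no bins with more than {min_reads} reads; cannot normalize")
    scale = target / float(np.median(pooled))
    for t in tracks:
        t.scale = scale
        t.normalized = True
    return scale


def site_occupancy(track: DensityTrack, motif_interval: tuple) -> float:
    """Maximum normalized density among bins overlapping the motif interval."""
    lo, hi = motif_interval
    t_lo, t_hi = track.extent
    if hi <= t_lo or lo >= t_hi:
        raise IndexError(f"motif interval {motif_interval} outside track extent "
                         f"{track.extent}")
    starts = track.bin_starts
    mask = (starts < hi) & (starts + track.window > lo)
    return float(track.values[mask].max())


# -- read-simulation mappability filter ------------------------------------

class KmerIndex:
    """Exact-match k-mer occurrence index of a (synthetic) genome.

    Counts occurrences of each k-mer on either strand; a read is ambiguous
    when its sequence occurs at more than one genomic locus.
    """

    def __init__(self, genome: str, k: int):
        self.k = k
        self.genome = genome.upper()
        counts: dict = {}
        g = self.genome
        for i in range(len(g) - k + 1):
            km = g[i:i + k]
            counts[km] = counts.get(km, 0) + 1
        self._counts = counts

    def occurrences(self, kmer: str) -> int:
        """Occurrences of ``kmer`` in the genome, both orientations."""
        n = self._counts.get(kmer, 0)
        rc = revcomp_str(kmer)
        if rc != kmer:
            n += self._counts.get(rc, 0)
        return n


@dataclass
class MappabilityReport:
    site_id: str
    ambiguous_fraction: dict          # allele (str) -> fraction in [0,1]
    allele_differential: bool
    passed: bool
    n_reads: int = 0


def mappability_filter(
    site_id: str,
    center: int,
    index: KmerIndex,
    snps: Sequence[tuple] = (),     # (genome_pos, allele_a, allele_b)
    read_len: int = 36,
    flank: int = 147,
    max_ambiguous: float = 0.1,
    allele_margin: float = 0.05,
) -> MappabilityReport:
    """Simulate every read over +/-flank of the site centre, per allele.

    Each ``read_len``-mer starting in [center - flank, center + flank] is
    looked up in the genome index once per allele at each SNP.  A reference-
    allele read is ambiguous when its sequence occurs at >1 locus; an
    alternate-allele read (absent from the reference) is ambiguous when its
    sequence occurs anywhere else.  The site passes when the worst per-allele
    ambiguous fraction is <= ``max_ambiguous`` and no SNP shows an
    allele-differential fraction gap > ``allele_margin``.
    """
    g = index.genome
    k = read_len
    lo = center - flank
    hi = center + flank
    if lo < 0 or hi + k > len(g):
        warnings.warn(f"{site_id}: +/-{flank} bp window truncated at contig bounds")
        lo = max(lo, 0)
        hi = min(hi, len(g) - k)
    starts = range(lo, hi + 1)
    n_reads = len(starts)
    ref_ambig = sum(1 for s in starts if index.occurrences(g[s:s + k]) > 1)
    fractions = {"ref": ref_ambig / n_reads}
    differential = False
    for pos, a_ref, a_alt in snps:
        for allele, base in (("A", a_ref), ("B", a_alt)):
            amb = 0
            for s in starts:
                if not s <= pos < s + k:
                    read = g[s:s + k]
                    amb += index.occurrences(read) > 1
                    continue
                read = g[s:pos] + base + g[pos + 1:s + k]
                if read == g[s:s + k]:
                    amb += index.occurrences(read) > 1
                else:
                    amb += index.occurrences(read) > 0
            fractions[f"{pos}:{allele}"] = amb / n_reads
        if abs(fractions[f"{pos}:A"] - fractions[f"{pos}:B"]) > allele_margin:
            differential = True
    worst = max(fractions.values())
    return MappabilityReport(
        site_id=site_id, ambiguous_fraction=fractions,
        allele_differential=differential,
        passed=(worst <= max_ambiguous) and not differential,
        n_reads=n_reads,
    )
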