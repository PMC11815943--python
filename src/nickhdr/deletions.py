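"""Large on-target deletion profiling from long-amplicon alignments.

Short-amplicon genotyping is blind to deletions that remove one of its
primer sites; sequencing a long amplicon that symmetrically spans the
target recovers them.  This module turns long-read alignments into unique
deletion alleles (clustered by breakpoint), a read-weighted size spectrum,
and the *evasion fraction* — the fraction of retained long reads whose
deletion would abolish a short-amplicon primer site and therefore be
invisible to standard genotyping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from statistics import median
from typing import Sequence

from .align import AlignmentResult
from .errors import InputError
from .locus import AmpliconDef

DEFAULT_MIN_DELETION = 50  # separates kilobase events from nick-site indels
DEFAULT_BREAKPOINT_TOL = 20
DEFAULT_MIN_SUPPORT = 3
DEFAULT_BIN_EDGES = (50, 200, 500, 1_000, 2_000, 5_000)


@dataclass
class DeletionAllele:
    del_start: int
    del_end: int
    support: int
    frequency: float

    @property
    def size(self) -> int:
        return self.del_end - self.del_start

    @property
    def interval(self) -> tuple[int, int]:
        return (self.del_start, self.del_end)


@dataclass
class DeletionSpectrum:
    alleles: list[DeletionAllele]
    n_retained_reads: int
    size_bins: list[tuple[float, float, float]]
    evasion_fraction: float


class _Cluster:
    __slots__ = ("starts", "ends")

    def __init__(self, start: int, end: int) -> None:
        self.starts = [start]
        self.ends = [end]

    @property
    def start(self) -> int:
        return int(median(self.starts))

    @property
    def end(self) -> int:
        return int(median(self.ends))

    def accepts(self, start: int, end: int, tol: int) -> bool:
        return abs(start - self.start) <= tol and abs(end - self.end) <= tol

    def add(self, start: int, end: int) -> None:
        self.starts.append(start)
        self.ends.append(end)


def _read_deletions(alns: Sequence[AlignmentResult], min_size: int):
    """Per retained read, its deletion events of at least ``min_size``."""
    out = []
    for aln in alns:
        if not aln.retained:
            continue
        out.append(aln.deletions(min_len=min_size))
    return out


def extract_deletion_alleles(
    alns: Sequence[AlignmentResult],
    min_deletion_size: int = DEFAULT_MIN_DELETION,
    breakpoint_tol: int = DEFAULT_BREAKPOINT_TOL,
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> list[DeletionAllele]:
    """Cluster per-read deletions into unique alleles.

    Deletions whose start and end each lie within ``breakpoint_tol`` of a
    cluster's running (median) breakpoints join that cluster; cluster
    breakpoints are the medians of their members.  Alleles supported by
    fewer than ``min_support`` reads are dropped.  Sorted by frequency
    descending (ties by size descending, then start).
    """
    retained = _read_deletions(alns, min_deletion_size)
    n_retained = len(retained)
    clusters: list[_Cluster] = []
    for events in retained:
        for start, end in events:
            for cluster in clusters:
                if cluster.accepts(start, end, breakpoint_tol):
                    cluster.add(start, end)
                    break
            else:
                clusters.append(_Cluster(start, end))
    alleles = [
        DeletionAllele(
            del_start=c.start,
            del_end=c.end,
            support=len(c.starts),
            frequency=len(c.starts) / n_retained,
        )
        for c in clusters
        if len(c.starts) >= min_support
    ]
    alleles.sort(key=lambda a: (-a.frequency, -a.size, a.del_start))
    return alleles


def bin_by_size(
    sizes: Sequence[int],
    bin_edges: Sequence[int] = DEFAULT_BIN_EDGES,
) -> list[tuple[float, float, float]]:
    """Read-weighted size spectrum: proportion of deletion-carrying reads
    per size bin; the final bin is open-ended (>= last edge).

    ``sizes`` carries one entry per deletion-carrying read (its largest
    deletion, so read-level categories stay exclusive).
    """
    edges = list(bin_edges)
    if any(b >= c for b, c in zip(edges, edges[1:])):
        raise InputError("bin edges must be strictly increasing")
    bounds = list(zip(edges, edges[1:])) + [(edges[-1], float("inf"))]
    if not sizes:
        return [(lo, hi, 0.0) for lo, hi in bounds]
    counts = [0] * len(bounds)
    for size in sizes:
        for i, (lo, hi) in enumerate(bounds):
            if lo <= size < hi:
                counts[i] += 1
                break
        else:  # below the first edge: clamp into the first bin
            counts[0] += 1
    total = len(sizes)
    return [(lo, hi, k / total) for (lo, hi), k in zip(bounds, counts)]


def evasion_fraction(
    alleles: Sequence[DeletionAllele],
    short_amplicon: AmpliconDef,
    n_retained: int,
) -> float:
    """Fraction of retained long reads whose deletion intersects a primer
    site of the short genotyping amplicon (and is therefore invisible to
    short-amplicon genotyping).

    A deletion strictly interior to the short amplicon leaves both primers
    intact: that event *is* captured and contributes nothing here.
    """
    if n_retained <= 0:
        return 0.0
    evading = 0
    for allele in alleles:
        s, e = allele.interval
        for p_lo, p_hi in (short_amplicon.fwd_primer, short_amplicon.rev_primer):
            if max(s, p_lo) < min(e, p_hi):
                evading += allele.support
                break
    return evading / n_retained


def profile_deletions(
    alns: Sequence[AlignmentResult],
    short_amplicon: AmpliconDef,
    min_deletion_size: int = DEFAULT_MIN_DELETION,
    breakpoint_tol: int = DEFAULT_BREAKPOINT_TOL,
    min_support: int = DEFAULT_MIN_SUPPORT,
    bin_edges: Sequence[int] = DEFAULT_BIN_EDGES,
) -> DeletionSpectrum:
    """End-to-end deletion spectrum for a set of long-amplicon alignments."""
    alleles = extract_deletion_alleles(
        alns, min_deletion_size, breakpoint_tol, min_support
    )
    per_read = _read_deletions(alns, min_deletion_size)
    n_retained = len(per_read)
    largest = [max(e - s for s, e in events) for events in per_read if events]
    return DeletionSpectrum(
        alleles=alleles,
        n_retained_reads=n_retained,
        size_bins=bin_by_size(largest, bin_edges),
        evasion_fraction=evasion_fraction(alleles, short_amplicon, n_retained),
    )


def write_allele_tsv(alleles: Sequence[DeletionAllele], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("del_start\tdel_end\tsize\tsupport\tfrequency\n")
        for a in alleles:
            fh.write(f"{a.del_start}\t{a.del_end}\t{a.size}\t{a.support}\t{a.frequency:.6f}\n")


def write_spectrum(spectrum: DeletionSpectrum, bins_path: str | Path,
                   evasion_path: str | Path) -> None:
    with open(bins_path, "w") as fh:
        fh.write("size_lo\tsize_hi\tproportion\n")
        for lo, hi, p in spectrum.size_bins:
            hi_s = "inf" if hi == float("inf") else str(int(hi))
            fh.write(f"{int(lo)}\t{hi_s}\t{p:.6f}\n")
    Path(evasion_path).write_text(
        json.dumps(
            {
                "n_retained_reads": spectrum.n_retained_reads,
                "evasion_fraction": spectrum.evasion_fraction,
                "n_alleles": len(spectrum.alleles),
            },
            indent=2,
        )
    )
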