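"""Transcript-level quantification and expression normalisation.

Covers three layers of the expression story:

* **exon inclusion** — assign each cDNA read to the exon-including or
  exon-skipping isoform by alignment score and estimate the inclusion
  fraction (alternative splicing of the target exon);
* **transcript SNV incorporation** — among exon-including transcripts, the
  per-SNV frequency of repair-template bases, whose mean is the
  transcript-level incorporation rate to compare with the genomic one;
* **ddPCR-style relative expression** — target concentration normalised by
  the geometric mean of two housekeeper concentrations, plus the
  monoallelic conversion: correcting a heterozygous variant in a fraction
  *f* of genomic reads can restore expression from at most
  *f x (target alleles / total alleles)* of all alleles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import edlib
from statsmodels.stats.proportion import proportion_confint

from .align import _parse_cigar, genotype_column
from .design import RepairTemplate
from .errors import InputError
from .locus import ReferenceLocus, revcomp


@dataclass(frozen=True)
class IsoformModel:
    """Full and target-exon-skipping isoforms of a locus.

    The skipped isoform is the full exon chain minus exactly the target
    exon, which must be internal (flanked on both sides) so that reads can
    span the alternative junction.
    """

    locus: ReferenceLocus
    target_exon: int

    def __post_init__(self) -> None:
        if not 0 < self.target_exon < len(self.locus.exons) - 1:
            raise InputError("target exon must be internal to the exon chain")

    @property
    def exons(self) -> tuple[tuple[int, int], ...]:
        return self.locus.exons

    def transcript(self, included: bool = True) -> str:
        chain = [
            e
            for i, e in enumerate(self.exons)
            if included or i != self.target_exon
        ]
        return "".join(self.locus.sequence[s:e] for s, e in chain)

    def to_transcript(self, position: int) -> int | None:
        """Full-isoform transcript coordinate of a genomic position."""
        offset = 0
        for s, e in self.exons:
            if s <= position < e:
                return offset + position - s
            offset += e - s
        return None

    @property
    def target_interval(self) -> tuple[int, int]:
        """Target-exon interval in full-isoform transcript coordinates."""
        offset = sum(
            e - s for s, e in self.exons[: self.target_exon]
        )
        s, e = self.exons[self.target_exon]
        return (offset, offset + e - s)

    @property
    def junction(self) -> int:
        """Splice-junction coordinate in the skipped transcript."""
        return self.target_interval[0]


@dataclass
class IsoformAssignment:
    read_id: str
    call: str  # included / skipped / ambiguous / discarded
    strand: str
    distance: int
    reason: str | None = None


@dataclass
class InclusionResult:
    fraction: float | None
    confidence_interval: tuple[float, float] | None
    n_included: int
    n_skipped: int
    n_ambiguous: int
    n_discarded: int
    assignments: list[IsoformAssignment]


def _best_alignment(read: str, transcript: str):
    """(distance, strand, locations) of the better-strand infix alignment."""
    fwd = edlib.align(read, transcript, mode="HW", task="locations")
    rev = edlib.align(revcomp(read), transcript, mode="HW", task="locations")
    if fwd["editDistance"] <= rev["editDistance"]:
        return fwd["editDistance"], "+", fwd["locations"]
    return rev["editDistance"], "-", rev["locations"]


def assign_isoform(
    read_id: str,
    read: str,
    isoforms: IsoformModel,
    min_margin: int = 10,
    flank: int = 20,
) -> IsoformAssignment:
    """Assign one cDNA read to the including or skipping isoform.

    The read must span both exons flanking the target exon (alignment
    coverage of the exon +/- ``flank`` in the full isoform, or of the
    alternative junction +/- ``flank`` in the skipped isoform); the winning
    isoform must beat the other by at least ``min_margin`` edit-distance
    units, otherwise the read is ambiguous.
    """
    full = isoforms.transcript(included=True)
    skipped = isoforms.transcript(included=False)
    d_full, strand_full, loc_full = _best_alignment(read, full)
    d_skip, strand_skip, loc_skip = _best_alignment(read, skipped)
    if abs(d_full - d_skip) < min_margin:
        return IsoformAssignment(read_id, "ambiguous", strand_full, min(d_full, d_skip))
    if d_full < d_skip:
        t0, t1 = isoforms.target_interval
        span = loc_full[0]
        if span[0] > t0 - flank or span[1] + 1 < t1 + flank:
            return IsoformAssignment(read_id, "discarded", strand_full, d_full,
                                     reason="flanking_exons_not_spanned")
        return IsoformAssignment(read_id, "included", strand_full, d_full)
    j = isoforms.junction
    span = loc_skip[0]
    if span[0] > j - flank or span[1] + 1 < j + flank:
        return IsoformAssignment(read_id, "discarded", strand_skip, d_skip,
                                 reason="flanking_exons_not_spanned")
    return IsoformAssignment(read_id, "skipped", strand_skip, d_skip)


def exon_inclusion(
    reads: Iterable[tuple[str, str]],
    isoforms: IsoformModel,
    min_margin: int = 10,
    flank: int = 20,
) -> InclusionResult:
    """Exon-inclusion fraction over assignable cDNA reads, with Wilson CI.

    With zero assignable reads the fraction is undefined (None), not 0.
    """
    assignments = [
        assign_isoform(rid, seq, isoforms, min_margin, flank) for rid, seq in reads
    ]
    n_inc = sum(1 for a in assignments if a.call == "included")
    n_skip = sum(1 for a in assignments if a.call == "skipped")
    n_amb = sum(1 for a in assignments if a.call == "ambiguous")
    n_disc = sum(1 for a in assignments if a.call == "discarded")
    if n_inc + n_skip == 0:
        return InclusionResult(None, None, n_inc, n_skip, n_amb, n_disc, assignments)
    frac = n_inc / (n_inc + n_skip)
    lo, hi = proportion_confint(n_inc, n_inc + n_skip, alpha=0.05, method="wilson")
    return InclusionResult(
        frac, (float(lo), float(hi)), n_inc, n_skip, n_amb, n_disc, assignments
    )


@dataclass
class TranscriptIncorporation:
    per_snv: dict[int, float | None]  # keyed by genomic SNV position
    mean_silent: float | None
    n_reads: int


def transcript_snv_incorporation(
    reads: Iterable[tuple[str, str]],
    template: RepairTemplate,
    isoforms: IsoformModel,
    min_margin: int = 10,
    flank: int = 20,
) -> TranscriptIncorporation:
    """Template-SNV incorporation among exon-including transcripts.

    Per SNV, the fraction of covering exon-including reads carrying the
    template base (uncovered / third-base columns excluded); the reported
    mean is over the silent SNVs — the transcript-level analogue of the
    genomic incorporation rate.
    """
    full = isoforms.transcript(included=True)
    positions = {}
    for snv in template.snvs:
        t_pos = isoforms.to_transcript(snv.position)
        if t_pos is not None:
            positions[snv.position] = (t_pos, snv.alt_base)
    counts = {pos: [0, 0] for pos in positions}  # template, informative
    n_used = 0
    for rid, seq in reads:
        assignment = assign_isoform(rid, seq, isoforms, min_margin, flank)
        if assignment.call != "included":
            continue
        n_used += 1
        query = seq if assignment.strand == "+" else revcomp(seq)
        res = edlib.align(query, full, mode="HW", task="path")
        span = (res["locations"][0][0], res["locations"][0][1] + 1)
        ops = _parse_cigar(res["cigar"], span[0], 0)
        for pos, (t_pos, alt) in positions.items():
            verdict = genotype_column(ops, query, span, full, 0, t_pos, alt)
            if verdict == "alt":
                counts[pos][0] += 1
                counts[pos][1] += 1
            elif verdict == "ref":
                counts[pos][1] += 1
    per_snv: dict[int, float | None] = {
        pos: (c[0] / c[1] if c[1] else None) for pos, c in counts.items()
    }
    silent_vals = [
        per_snv[s.position]
        for s in template.silent_snvs
        if s.position in per_snv and per_snv[s.position] is not None
    ]
    mean_silent = sum(silent_vals) / len(silent_vals) if silent_vals else None
    return TranscriptIncorporation(per_snv=per_snv, mean_silent=mean_silent,
                                   n_reads=n_used)


# ---------------------------------------------------------------------------
# ddPCR normalisation and the monoallelic expectation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionInput:
    """ddPCR concentrations (copies/ul): one target, exactly two housekeepers."""

    target_concentration: float
    housekeeper_concentrations: tuple[float, float]

    def __post_init__(self) -> None:
        values = (self.target_concentration, *self.housekeeper_concentrations)
        if len(self.housekeeper_concentrations) != 2:
            raise InputError("exactly two housekeeper concentrations required")
        if any(v <= 0 for v in values):
            raise InputError("concentrations must be positive")


def relative_expression(sample: ExpressionInput) -> float:
    """Target expression normalised by the geometric mean of the two
    housekeeper concentrations."""
    hk1, hk2 = sample.housekeeper_concentrations
    return sample.target_concentration / math.sqrt(hk1 * hk2)


def expected_allelic_expression(
    genomic_correction_fraction: float,
    n_target_alleles: int,
    total_alleles: int,
) -> float:
    """Expected fraction of all alleles re-expressing after correction.

    Correcting a variant present on ``n_target_alleles`` of
    ``total_alleles`` in ``genomic_correction_fraction`` of target-allele
    copies can restore expression from at most that product of all alleles
    (monoallelic ceiling for a heterozygous variant).
    """
    if not 0 <= genomic_correction_fraction <= 1:
        raise InputError("correction fraction must lie in [0, 1]")
    if total_alleles <= 0:
        raise InputError("total_alleles must be positive")
    if not 0 <= n_target_alleles <= total_alleles:
        raise InputError("n_target_alleles must lie in [0, total_alleles]")
    return genomic_correction_fraction * n_target_alleles / total_alleles
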