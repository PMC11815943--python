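"""Per-read editing-outcome classification and aggregation.

Each retained short-amplicon read is placed in exactly one category:

``perfect_hdr``
    evidence of template incorporation (at least one silent template base
    and at least two template bases overall), no reference base left at any
    planned SNV, and no indel in the quantification window;
``imperfect_hdr``
    template evidence, but a reference base remains at some planned SNV or
    an indel accompanies the incorporation (partial template integration);
``indel``
    insertion/deletion ops totalling at least ``min_indel_len`` bp
    overlapping the quantification window, with no template evidence —
    end-joining;
``unedited``
    none of the above;
``discarded``
    failed the full-length filter, or the window / correction site is not
    covered (a reason code is always recorded).

Two long-read realities shape the rules.  First, in a compound-het locus
the corrective base alone cannot distinguish a corrected allele from the
sibling allele that is wild type at that position, so reads whose only
template base is the correction count as unedited — this is exactly why
silent blocking/bridging SNVs make perfect HDR countable.  Second, at
Nanopore-scale error rates single-column artefacts are common, so a third
base at a planned SNV ('other') is treated as sequencing noise rather than
counted against perfect HDR, and sub-threshold 1-2 bp indels in the window
are ignored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from statsmodels.stats.proportion import proportion_confint

from .align import AlignmentResult, genotype_column
from .design import RepairTemplate
from .errors import InputError
from .locus import GuidePair

CATEGORIES = ("perfect_hdr", "imperfect_hdr", "indel", "unedited")

SNV_TEMPLATE = "template_base"
SNV_REF = "ref_base"
SNV_OTHER = "other"
SNV_UNCOVERED = "uncovered"

_STATUS_FROM_VERDICT = {
    "alt": SNV_TEMPLATE,
    "ref": SNV_REF,
    "ambiguous": SNV_OTHER,
    "uncovered": SNV_UNCOVERED,
}


def _reference_context(template: RepairTemplate) -> str:
    """The unedited locus subsequence over the template interval (all
    planned SNVs reverted)."""
    lo, _ = template.locus_interval
    seq = list(template.sequence)
    for snv in template.snvs:
        seq[snv.position - lo] = snv.ref_base
    return "".join(seq)


@dataclass(frozen=True)
class QuantWindow:
    """Locus interval over which indels are counted as editing events."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise InputError("window start must precede end")

    @classmethod
    def from_pair(cls, pair: GuidePair, flank: int = 10) -> "QuantWindow":
        """Default window: both nick sites plus ``flank`` bp on each side."""
        return cls(pair.left.nick_position - flank, pair.right.nick_position + flank)

    def contains(self, position: int) -> bool:
        return self.start <= position < self.end


@dataclass
class ReadCall:
    read_id: str
    category: str
    snv_status: dict[int, str]
    indels_in_window: list[tuple[int, str, int]]
    identity: float
    reason: str | None = None


def classify_read(
    aln: AlignmentResult,
    template: RepairTemplate,
    window: QuantWindow,
    min_indel_len: int = 5,
) -> ReadCall:
    """Classify one aligned read against the repair template."""
    if not aln.retained:
        return ReadCall(aln.read_id, "discarded", {}, [], aln.identity,
                        reason=aln.reject_reason or "filtered")
    if aln.ref_span[0] > window.start or aln.ref_span[1] < window.end:
        return ReadCall(aln.read_id, "discarded", {}, [], aln.identity,
                        reason="window_uncovered")

    # SNV columns are genotyped by local haplotype re-alignment (ref-window
    # vs template-window edit distance) rather than single-column readout,
    # which is unreliable on noisy long reads
    ref_local = _reference_context(template)
    lo = template.locus_interval[0]
    status: dict[int, str] = {}
    for snv in template.snvs:
        verdict = genotype_column(
            aln.ops, aln.query, aln.ref_span, ref_local, lo,
            snv.position, snv.alt_base,
        )
        status[snv.position] = _STATUS_FROM_VERDICT[verdict]

    correction = template.correction
    if status[correction.position] == SNV_UNCOVERED:
        return ReadCall(aln.read_id, "discarded", status, [], aln.identity,
                        reason="correction_uncovered")

    # qualify on the *net* indel length in the window: aligners split one
    # real event into pieces when the inserted/deleted sequence partially
    # matches the reference (summing restores it), and dense substitution
    # noise admits co-optimal balanced ins/del pairs (netting cancels them)
    window_indels = aln.indels_overlapping(window.start, window.end, min_len=1)
    ins_total = sum(l for _, kind, l in window_indels if kind == "insertion")
    del_total = sum(l for _, kind, l in window_indels if kind == "deletion")
    indel_event = abs(ins_total - del_total) >= min_indel_len

    silent_template = sum(
        1 for s in template.silent_snvs if status[s.position] == SNV_TEMPLATE
    )
    total_template = sum(1 for v in status.values() if v == SNV_TEMPLATE)
    any_ref = any(v == SNV_REF for v in status.values())
    hdr_evidence = silent_template >= 1 and total_template >= 2

    if hdr_evidence:
        if not any_ref and not indel_event:
            category = "perfect_hdr"
        else:
            category = "imperfect_hdr"
    elif indel_event:
        category = "indel"
    else:
        category = "unedited"
    return ReadCall(aln.read_id, category, status, window_indels, aln.identity)


def classify_reads(
    alns: Iterable[AlignmentResult],
    template: RepairTemplate,
    window: QuantWindow,
    min_indel_len: int = 5,
) -> list[ReadCall]:
    return [classify_read(a, template, window, min_indel_len) for a in alns]


@dataclass
class OutcomeSummary:
    n_total: int
    n_retained: int
    fractions: dict[str, float]
    confidence_intervals: dict[str, tuple[float, float]]
    total_editing: float
    low_coverage: bool
    snv_incorporation_rates: dict[int, float | None] | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_total": self.n_total,
            "n_retained": self.n_retained,
            "fractions": self.fractions,
            "confidence_intervals": {
                k: list(v) for k, v in self.confidence_intervals.items()
            },
            "total_editing": self.total_editing,
            "low_coverage": self.low_coverage,
        }
        if self.snv_incorporation_rates is not None:
            payload["snv_incorporation_rates"] = {
                str(k): v for k, v in self.snv_incorporation_rates.items()
            }
        Path(path).write_text(json.dumps(payload, indent=2))


def summarize(
    calls: Sequence[ReadCall],
    min_reads: int = 10_000,
    template: RepairTemplate | None = None,
) -> OutcomeSummary:
    """Aggregate read calls into outcome frequencies with Wilson 95% CIs.

    Fractions are over retained (non-discarded) reads.  When fewer than
    ``min_reads`` reads are retained the summary is flagged low-coverage
    rather than refused.
    """
    if not calls:
        raise InputError("no read calls to summarize")
    retained = [c for c in calls if c.category != "discarded"]
    n = len(retained)
    fractions, cis = {}, {}
    for cat in CATEGORIES:
        k = sum(1 for c in retained if c.category == cat)
        fractions[cat] = k / n if n else 0.0
        if n:
            lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
            cis[cat] = (float(lo), float(hi))
        else:
            cis[cat] = (0.0, 0.0)
    total_editing = (
        fractions["perfect_hdr"] + fractions["imperfect_hdr"] + fractions["indel"]
    )
    incorporation = snv_incorporation(calls, template) if template else None
    return OutcomeSummary(
        n_total=len(calls),
        n_retained=n,
        fractions=fractions,
        confidence_intervals=cis,
        total_editing=total_editing,
        low_coverage=n < min_reads,
        snv_incorporation_rates=incorporation,
    )


def snv_incorporation(
    calls: Sequence[ReadCall], template: RepairTemplate
) -> dict[int, float | None]:
    """Per planned SNV, the fraction of informative covering reads carrying
    the template base.

    The denominator counts retained reads whose column is unambiguously the
    template or the reference base; uncovered and third-base columns are
    uninformative.  An SNV with zero informative reads is reported as None
    (undefined), never as 0.
    """
    out: dict[int, float | None] = {}
    for snv in template.snvs:
        num = den = 0
        for call in calls:
            if call.category == "discarded":
                continue
            st = call.snv_status.get(snv.position)
            if st == SNV_TEMPLATE:
                num += 1
                den += 1
            elif st == SNV_REF:
                den += 1
        out[snv.position] = num / den if den else None
    return out


def write_calls_tsv(calls: Sequence[ReadCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tcategory\treason\tidentity\tn_window_indels\tsnv_status\n")
        for c in calls:
            status = ",".join(f"{p}:{s}" for p, s in sorted(c.snv_status.items()))
            fh.write(
                f"{c.read_id}\t{c.category}\t{c.reason or ''}\t{c.identity:.4f}\t"
                f"{len(c.indels_in_window)}\t{status}\n"
            )
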