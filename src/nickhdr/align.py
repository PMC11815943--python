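"""Pairwise read-to-locus alignment producing edit-operation lists.

Alignment is semi-global (read fully aligned, free end gaps on the
reference), computed with edlib under unit edit costs.  Large structural
deletions — the kilobase events dual-nickase editing produces — cannot be
recovered by any plain pairwise DP (a multi-kb gap always costs more than
letting the read tail run on as mismatches), so reads are first anchored
with exact locus k-mers, anchors are chained, and each colinear segment is
aligned separately; the breakpoint between segments is then refined to base
precision by scanning the split point that minimises the summed edit
distance of the two flanks.

All output coordinates are locus-forward; reverse-strand reads are
canonicalised (reverse complemented) before alignment and reported with
``strand == '-'``.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import edlib

from .errors import InputError
from .locus import READ_ALPHABET, ReferenceLocus, revcomp

# ops are condensed runs: (kind, length, ref_start, read_start)
OP_MATCH = "match"
OP_MISMATCH = "mismatch"
OP_INS = "insertion"  # consumes read only
OP_DEL = "deletion"  # consumes reference only

_CIGAR_KIND = {"=": OP_MATCH, "X": OP_MISMATCH, "I": OP_INS, "D": OP_DEL}
_KIND_CIGAR = {v: k for k, v in _CIGAR_KIND.items()}

ANCHOR_K = 17
ANCHOR_STRIDE = 10
DIAG_TOL = 30  # within-segment diagonal drift absorbed by edlib
END_PAD = 24  # slack for locating free read ends on the reference


@dataclass
class AlignmentResult:
    """A canonicalised semi-global alignment of one read against the locus."""

    read_id: str
    strand: str
    query: str  # canonicalised (locus-forward) read sequence
    ops: list[tuple[str, int, int, int]]
    identity: float
    ref_span: tuple[int, int]
    read_span: tuple[int, int]
    retained: bool
    reject_reason: str | None = None

    @property
    def cigar(self) -> str:
        return "".join(f"{length}{_KIND_CIGAR[kind]}" for kind, length, _, _ in self.ops)

    def base_at(self, ref_position: int) -> str | None:
        """Read base aligned to a reference position.

        Returns '-' when the position falls in a deletion, None when the
        position is outside the aligned reference span (uncovered).
        """
        if not self.ops or not self.ref_span[0] <= ref_position < self.ref_span[1]:
            return None
        for kind, length, ref_start, read_start in self.ops:
            if kind == OP_INS:
                continue
            if ref_start <= ref_position < ref_start + length:
                if kind == OP_DEL:
                    return "-"
                return self.query[read_start + (ref_position - ref_start)]
        return None

    def indels_overlapping(
        self, start: int, end: int, min_len: int = 1
    ) -> list[tuple[int, str, int]]:
        """Indel ops of at least ``min_len`` touching [start, end].

        Overlap is boundary-inclusive: an event at either window edge counts.
        """
        hits = []
        for kind, length, ref_start, _ in self.ops:
            if kind == OP_INS and length >= min_len and start <= ref_start <= end:
                hits.append((ref_start, "insertion", length))
            elif kind == OP_DEL and length >= min_len:
                if ref_start <= end and ref_start + length >= start:
                    hits.append((ref_start, "deletion", length))
        return hits

    def deletions(self, min_len: int = 1) -> list[tuple[int, int]]:
        """(start, end) reference intervals of deletion ops >= min_len."""
        return [
            (ref_start, ref_start + length)
            for kind, length, ref_start, _ in self.ops
            if kind == OP_DEL and length >= min_len
        ]


# ---------------------------------------------------------------------------
# cigar helpers
# ---------------------------------------------------------------------------


def _parse_cigar(cigar: str, ref_start: int, read_start: int) -> list[tuple[str, int, int, int]]:
    ops: list[tuple[str, int, int, int]] = []
    rpos, qpos = ref_start, read_start
    num = 0
    for ch in cigar:
        if ch.isdigit():
            num = num * 10 + ord(ch) - 48
            continue
        kind = _CIGAR_KIND[ch]
        ops.append((kind, num, rpos, qpos))
        if kind != OP_INS:
            rpos += num
        if kind != OP_DEL:
            qpos += num
        num = 0
    return ops


def _merge_ops(ops: Iterable[tuple[str, int, int, int]]) -> list[tuple[str, int, int, int]]:
    merged: list[tuple[str, int, int, int]] = []
    for op in ops:
        if merged and merged[-1][0] == op[0]:
            kind, length, rs, qs = merged[-1]
            merged[-1] = (kind, length + op[1], rs, qs)
        else:
            merged.append(op)
    return merged


# ---------------------------------------------------------------------------
# anchoring
# ---------------------------------------------------------------------------


def _kmer_index(locus: ReferenceLocus) -> dict[str, int]:
    """Positions of k-mers unique in the locus (cached on the locus)."""
    cache = locus._kmer_index_cache
    if "index" not in cache:
        seq = locus.sequence
        index: dict[str, int] = {}
        dup = set()
        for i in range(len(seq) - ANCHOR_K + 1):
            kmer = seq[i : i + ANCHOR_K]
            if kmer in dup:
                continue
            if kmer in index:
                del index[kmer]
                dup.add(kmer)
            else:
                index[kmer] = i
        cache["index"] = index
    return cache["index"]


def _anchors(read: str, index: dict[str, int]) -> list[tuple[int, int]]:
    out = []
    for i in range(0, len(read) - ANCHOR_K + 1, ANCHOR_STRIDE):
        pos = index.get(read[i : i + ANCHOR_K])
        if pos is not None:
            out.append((i, pos))
    return out


def _chain(anchors: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Longest chain with strictly increasing ref positions (anchors are
    already sorted by read position)."""
    if not anchors:
        return []
    refs = [a[1] for a in anchors]
    tails: list[int] = []  # ref values of best chain tails
    tail_idx: list[int] = []
    parent = [-1] * len(anchors)
    for i, r in enumerate(refs):
        j = bisect_left(tails, r)
        if j == len(tails):
            tails.append(r)
            tail_idx.append(i)
        else:
            tails[j] = r
            tail_idx[j] = i
        parent[i] = tail_idx[j - 1] if j > 0 else -1
    chain = []
    i = tail_idx[-1]
    while i != -1:
        chain.append(anchors[i])
        i = parent[i]
    chain.reverse()
    return chain


def _segments(chain: list[tuple[int, int]], sv_min_gap: int) -> list[list[tuple[int, int]]]:
    """Split a chain where the diagonal jumps by at least ``sv_min_gap``."""
    segments = [[chain[0]]]
    for prev, cur in zip(chain, chain[1:]):
        if abs((cur[1] - cur[0]) - (prev[1] - prev[0])) >= sv_min_gap:
            segments.append([cur])
        else:
            segments[-1].append(cur)
    # spurious single-anchor segments between consistent neighbours are noise
    return [s for s in segments if len(s) >= 2 or len(segments) == 1]


def _edit_distance(a: str, b: str) -> int:
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def _refine_junction(
    read: str, ref: str, a: tuple[int, int], b: tuple[int, int]
) -> tuple[int, int, int]:
    """Best split between two colinear segments.

    ``a`` is the last anchor of the upstream segment, ``b`` the first anchor
    of the downstream one.  Returns (read_split, ins_len, del_len): the read
    is aligned to the reference up to ``read_split`` on the upstream
    diagonal, then ``ins_len`` read bases are skipped (structural insertion)
    and ``del_len`` reference bases are skipped (structural deletion), and
    the remainder continues on the downstream diagonal.
    """
    (ra, pa), (rb, pb) = a, b
    d_a, d_b = pa - ra, pb - rb
    ins = max(0, d_a - d_b)
    dele = max(0, d_b - d_a)
    lo, hi = ra + ANCHOR_K, max(ra + ANCHOR_K, rb - ins)
    best = (None, None)
    for j in range(lo, hi + 1):
        left = _edit_distance(read[ra:j], ref[ra + d_a : j + d_a])
        right = _edit_distance(
            read[j + ins : rb + ANCHOR_K], ref[j + d_a + dele : rb + ANCHOR_K + d_b]
        )
        cost = left + right
        if best[0] is None or cost < best[0]:
            best = (cost, j)
    return best[1], ins, dele


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------


def _align_piece(read_piece: str, ref: str, ref_lo: int, ref_hi: int, free: str,
                 read_offset: int) -> list[tuple[str, int, int, int]]:
    """Align one read piece against ref[ref_lo:ref_hi].

    ``free`` says which reference end is unpinned: 'left', 'right' or 'none'.
    """
    target = ref[ref_lo:ref_hi]
    if not read_piece:
        return []
    if not target:
        return [(OP_INS, len(read_piece), ref_lo, read_offset)]
    if free == "none":
        res = edlib.align(read_piece, target, mode="NW", task="path")
        return _parse_cigar(res["cigar"], ref_lo, read_offset)
    if free == "right":
        res = edlib.align(read_piece, target, mode="SHW", task="path")
        return _parse_cigar(res["cigar"], ref_lo, read_offset)
    # free == 'left': reverse both so SHW's free target suffix becomes our
    # free target prefix, then mirror coordinates back
    res = edlib.align(read_piece[::-1], target[::-1], mode="SHW", task="path")
    end = res["locations"][0][1] + 1  # columns consumed on reversed target
    ops_rev = _parse_cigar(res["cigar"], 0, 0)
    ops = []
    for kind, length, rs, qs in reversed(ops_rev):
        ref_start = ref_hi - (rs + (length if kind != OP_INS else 0))
        read_start = read_offset + len(read_piece) - (qs + (length if kind != OP_DEL else 0))
        ops.append((kind, length, ref_start, read_start))
    return ops


def read_segment(
    ops: Sequence[tuple[str, int, int, int]],
    query: str,
    ref_lo: int,
    ref_hi: int,
) -> str | None:
    """Read substring aligned to the reference interval [ref_lo, ref_hi).

    Includes insertions falling strictly inside the interval.  Returns an
    empty string when the interval is covered but fully deleted, and None
    when the alignment does not touch the interval at all.
    """
    q_lo = q_hi = None
    touched = False
    for kind, length, rs, qs in ops:
        if kind == OP_INS:
            if ref_lo < rs < ref_hi:
                q_lo = qs if q_lo is None else min(q_lo, qs)
                q_hi = qs + length if q_hi is None else max(q_hi, qs + length)
            continue
        o_lo, o_hi = max(rs, ref_lo), min(rs + length, ref_hi)
        if o_lo >= o_hi:
            continue
        touched = True
        if kind == OP_DEL:
            continue
        a = qs + (o_lo - rs)
        b = qs + (o_hi - rs)
        q_lo = a if q_lo is None else min(q_lo, a)
        q_hi = b if q_hi is None else max(q_hi, b)
    if q_lo is None:
        return "" if touched else None
    return query[q_lo:q_hi]


def genotype_column(
    ops: Sequence[tuple[str, int, int, int]],
    query: str,
    ref_span: tuple[int, int],
    ref_context: str,
    context_lo: int,
    pos: int,
    alt_base: str,
    w: int = 8,
) -> str:
    """Genotype one substitution column by local haplotype re-alignment.

    Single-column readout is unreliable on noisy long reads: under unit
    edit costs, an error adjacent to the column often admits a co-optimal
    alignment that pairs the error base into the column.  Instead, the read
    segment aligned to pos +/- ``w`` is compared by edit distance against
    the reference window and against the same window with ``alt_base`` at
    the column; whichever haplotype explains the segment strictly better
    wins.  Returns 'alt', 'ref', 'ambiguous' or 'uncovered'.  Neighbouring
    planned SNVs inside the window mismatch both haplotypes equally and
    cancel out of the comparison.
    """
    if not ref_span[0] <= pos < ref_span[1]:
        return "uncovered"
    lo = max(context_lo, pos - w, ref_span[0])
    hi = min(context_lo + len(ref_context), pos + w + 1, ref_span[1])
    seg = read_segment(ops, query, lo, hi)
    if seg is None:
        return "uncovered"
    ref_win = ref_context[lo - context_lo : hi - context_lo]
    i = pos - lo
    alt_win = ref_win[:i] + alt_base + ref_win[i + 1 :]
    d_ref = _edit_distance(seg, ref_win)
    d_alt = _edit_distance(seg, alt_win)
    if d_alt < d_ref:
        return "alt"
    if d_ref < d_alt:
        return "ref"
    return "ambiguous"


def align_read(
    read: str,
    locus: ReferenceLocus,
    min_identity: float = 0.80,
    min_span: float = 0.90,
    amplicon=None,
    read_id: str = "read",
    sv_min_gap: int = 50,
) -> AlignmentResult:
    """Align one read (either strand) to the locus and apply the
    full-length filter.

    Reads failing the identity or span thresholds are returned flagged
    ``retained=False`` with a reject reason, never dropped.  ``amplicon``
    (an :class:`~nickhdr.locus.AmpliconDef`) defines the interval the
    aligned span must cover by at least ``min_span``; without it the span
    criterion is the aligned fraction of the read itself.
    """
    if not read:
        raise InputError("empty read")
    read = read.upper()
    if set(read) - READ_ALPHABET:
        raise InputError("read contains non-ACGTN symbols")
    if not 0 < min_identity <= 1 or not 0 < min_span <= 1:
        raise InputError("thresholds must lie in (0, 1]")

    index = _kmer_index(locus)
    fwd_chain = _chain(_anchors(read, index))
    rc = revcomp(read)
    rev_chain = _chain(_anchors(rc, index))

    if max(len(fwd_chain), len(rev_chain)) >= 2:
        if len(fwd_chain) >= len(rev_chain):
            strand, query, chain = "+", read, fwd_chain
        else:
            strand, query, chain = "-", rc, rev_chain
        ops = _align_chained(query, locus.sequence, chain, sv_min_gap)
    else:
        # too few anchors (tiny or very noisy read): plain edlib both strands
        fwd = edlib.align(read, locus.sequence, mode="HW", task="path")
        rev = edlib.align(rc, locus.sequence, mode="HW", task="path")
        if fwd["editDistance"] <= rev["editDistance"]:
            strand, query, res = "+", read, fwd
        else:
            strand, query, res = "-", rc, rev
        ops = _parse_cigar(res["cigar"], res["locations"][0][0], 0)

    ops = _merge_ops(ops)
    return _finalise(read_id, strand, query, ops, min_identity, min_span,
                     amplicon, sv_min_gap)


def _align_chained(query: str, ref: str, chain: list[tuple[int, int]],
                   sv_min_gap: int) -> list[tuple[str, int, int, int]]:
    segments = _segments(chain, sv_min_gap)
    if len(segments) == 1:
        res = edlib.align(query, ref, mode="HW", task="path")
        return _parse_cigar(res["cigar"], res["locations"][0][0], 0)

    # breakpoints between consecutive segments
    junctions = []
    for seg_a, seg_b in zip(segments, segments[1:]):
        junctions.append(_refine_junction(query, ref, seg_a[-1], seg_b[0]))

    ops: list[tuple[str, int, int, int]] = []
    read_cursor = 0
    first_diag = segments[0][0][1] - segments[0][0][0]
    ref_cursor = max(0, first_diag - END_PAD)
    for i, seg in enumerate(segments):
        diag = seg[0][1] - seg[0][0]
        if i < len(junctions):
            j, ins, dele = junctions[i]
            piece = query[read_cursor:j]
            free = "left" if i == 0 else "none"
            ops.extend(_align_piece(piece, ref, ref_cursor, j + diag, free, read_cursor))
            if ins:
                ops.append((OP_INS, ins, j + diag, j))
            if dele:
                ops.append((OP_DEL, dele, j + diag, j + ins))
            read_cursor = j + ins
            ref_cursor = j + diag + dele
        else:
            piece = query[read_cursor:]
            diag_end = seg[-1][1] - seg[-1][0]
            ref_hi = min(len(ref), len(query) + diag_end + END_PAD)
            free = "right" if i > 0 else "left"  # i>0 always true here
            ops.extend(_align_piece(piece, ref, ref_cursor, ref_hi, free, read_cursor))
    return ops


def _finalise(read_id, strand, query, ops, min_identity, min_span, amplicon,
              sv_min_gap) -> AlignmentResult:
    matches = sum(n for k, n, _, _ in ops if k == OP_MATCH)
    # structural deletions are real biology, not alignment noise: exclude
    # them from the identity denominator so deletion reads survive filtering
    columns = sum(
        n for k, n, _, _ in ops if not (k == OP_DEL and n >= sv_min_gap)
    )
    identity = matches / columns if columns else 0.0
    ref_cons = [(rs, rs + n) for k, n, rs, _ in ops if k != OP_INS]
    read_cons = [(qs, qs + n) for k, n, _, qs in ops if k != OP_DEL]
    ref_span = (ref_cons[0][0], ref_cons[-1][1]) if ref_cons else (0, 0)
    read_span = (read_cons[0][0], read_cons[-1][1]) if read_cons else (0, 0)

    if amplicon is not None:
        lo, hi = amplicon.interval
        overlap = max(0, min(ref_span[1], hi) - max(ref_span[0], lo))
        span_frac = overlap / (hi - lo)
    else:
        span_frac = (read_span[1] - read_span[0]) / len(query)

    retained, reason = True, None
    if span_frac < min_span:
        retained, reason = False, "low_span"
    elif identity < min_identity:
        retained, reason = False, "low_identity"
    return AlignmentResult(
        read_id=read_id,
        strand=strand,
        query=query,
        ops=ops,
        identity=identity,
        ref_span=ref_span,
        read_span=read_span,
        retained=retained,
        reject_reason=reason,
    )


def align_reads(
    reads: Iterable[tuple[str, str]],
    locus: ReferenceLocus,
    amplicon=None,
    min_identity: float = 0.80,
    min_span: float = 0.90,
    sv_min_gap: int = 50,
) -> list[AlignmentResult]:
    """Align (read_id, sequence) pairs; convenience wrapper."""
    return [
        align_read(
            seq,
            locus,
            min_identity=min_identity,
            min_span=min_span,
            amplicon=amplicon,
            read_id=read_id,
            sv_min_gap=sv_min_gap,
        )
        for read_id, seq in reads
    ]


def write_alignment_tsv(alns: Sequence[AlignmentResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tstrand\tretained\tidentity\tref_start\tref_end\tcigar\n")
        for a in alns:
            fh.write(
                f"{a.read_id}\t{a.strand}\t{int(a.retained)}\t{a.identity:.4f}\t"
                f"{a.ref_span[0]}\t{a.ref_span[1]}\t{a.cigar}\n"
            )
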