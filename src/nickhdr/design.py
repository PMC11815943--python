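"""ssODN repair-template and PAM-out nickase guide-pair design.

The design logic reproduces a dual-nickase HDR strategy: enumerate paired
guides whose PAMs face away from the inter-nick segment ("PAM-out"), then
build single-stranded oligo templates that carry the corrective edit plus
silent *blocking* SNVs (one per guide, inside the seed or PAM, preventing
re-nicking of repaired DNA) and optional silent *bridging* SNVs between the
proximal nick and the corrective edit (graded series: blocking / low /
medium / full).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from .errors import DesignInfeasibleError, InputError
from .locus import Guide, GuidePair, ReferenceLocus, revcomp, write_fasta

SNV_ROLES = ("correction", "blocking", "bridging")

# transitions first, then transversions alphabetically: deterministic
# preference order for alternative bases at a candidate site
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass(frozen=True)
class PlannedSNV:
    """One intended single-base substitution on the repair template."""

    position: int
    ref_base: str
    alt_base: str
    role: str
    guide_association: str | None = None
    silent: bool = False

    def __post_init__(self) -> None:
        if self.role not in SNV_ROLES:
            raise InputError(f"unknown SNV role {self.role!r}")
        if self.alt_base == self.ref_base:
            raise InputError("alt base must differ from ref base")


@dataclass(frozen=True)
class RepairTemplate:
    """An ssODN repair template over a locus interval.

    ``sequence`` is locus-forward; ``oligo_strand`` records the strand the
    physical oligo is synthesised on (complementary to the non-target strand
    of the bridging-associated guide).
    """

    name: str
    sequence: str
    locus_interval: tuple[int, int]
    snvs: tuple[PlannedSNV, ...]
    arm_lengths: tuple[int, int]
    oligo_strand: str = "+"

    def __post_init__(self) -> None:
        if sum(1 for s in self.snvs if s.role == "correction") != 1:
            raise InputError("template must carry exactly one correction SNV")
        lo, hi = self.locus_interval
        if len(self.sequence) != hi - lo:
            raise InputError("template sequence length disagrees with interval")
        for s in self.snvs:
            if not lo <= s.position < hi:
                raise InputError(f"SNV at {s.position} outside template interval")

    @property
    def correction(self) -> PlannedSNV:
        return next(s for s in self.snvs if s.role == "correction")

    @property
    def silent_snvs(self) -> tuple[PlannedSNV, ...]:
        return tuple(s for s in self.snvs if s.role != "correction")

    @property
    def oligo_sequence(self) -> str:
        return self.sequence if self.oligo_strand == "+" else revcomp(self.sequence)

    def base_at(self, position: int) -> str:
        return self.sequence[position - self.locus_interval[0]]


# ---------------------------------------------------------------------------
# silent verification
# ---------------------------------------------------------------------------


def verify_silent(locus: ReferenceLocus, snv: PlannedSNV) -> bool:
    """True iff the substitution leaves the translated CDS unchanged.

    Raises :class:`InputError` for positions outside the annotated CDS
    (intronic changes are vacuously protein-neutral but must be flagged by
    the caller rather than silently passed).
    """
    if locus.cds_index(snv.position) is None:
        raise InputError(
            f"position {snv.position} is outside the annotated CDS; silent "
            "verification is not applicable"
        )
    if locus.sequence[snv.position] != snv.ref_base:
        raise InputError("SNV ref base disagrees with locus sequence")
    edited = (
        locus.sequence[: snv.position]
        + snv.alt_base
        + locus.sequence[snv.position + 1 :]
    )
    return locus.translate() == locus.translate(edited)


def silent_alternatives(locus: ReferenceLocus, position: int) -> list[str]:
    """Silent alternative bases at an exonic position, preference-ordered
    (transition first, then transversions alphabetically)."""
    if locus.cds_index(position) is None:
        return []
    ref = locus.sequence[position]
    candidates = [_TRANSITION[ref]] + sorted(b for b in "ACGT" if b not in (ref, _TRANSITION[ref]))
    out = []
    for alt in candidates:
        snv = PlannedSNV(position, ref, alt, "bridging", silent=True)
        if verify_silent(locus, snv):
            out.append(alt)
    return out


def _ngg_sites(seq: str, lo: int, hi: int) -> set[tuple[int, str]]:
    """NGG occurrences (either strand) whose PAM interval overlaps [lo, hi)."""
    sites = set()
    for i in range(max(0, lo - 2), min(len(seq) - 2, hi)):
        if seq[i + 1 : i + 3] == "GG":
            sites.add((i, "+"))
        if seq[i : i + 2] == "CC":
            sites.add((i, "-"))
    return sites


def _creates_new_ngg(locus: ReferenceLocus, chosen: dict[int, str],
                     position: int, alt: str, pair: GuidePair) -> bool:
    seq = locus.sequence
    edited = list(seq)
    for p, b in chosen.items():
        edited[p] = b
    before = "".join(edited)
    edited[position] = alt
    after = "".join(edited)
    for guide in pair.guides:
        lo, hi = guide.footprint
        if _ngg_sites(after, lo, hi) - _ngg_sites(before, lo, hi):
            return True
    return False


# ---------------------------------------------------------------------------
# guide-pair enumeration
# ---------------------------------------------------------------------------


def _minus_guide(locus: ReferenceLocus, pam_start: int, name: str) -> Guide:
    s = pam_start + 3
    return Guide(
        name=name,
        protospacer=revcomp(locus.sequence[s : s + 20]),
        pam_interval=(pam_start, pam_start + 3),
        strand="-",
        nick_position=s + 3,
    )


def _plus_guide(locus: ReferenceLocus, pam_start: int, name: str) -> Guide:
    s = pam_start - 20
    return Guide(
        name=name,
        protospacer=locus.sequence[s : s + 20],
        pam_interval=(pam_start, pam_start + 3),
        strand="+",
        nick_position=s + 17,
    )


def find_pam_out_pairs(
    locus: ReferenceLocus,
    window: tuple[int, int],
    offset_range: tuple[int, int],
) -> list[GuidePair]:
    """All PAM-out dual-nickase guide pairs in ``window`` whose nick offset
    lies in ``offset_range`` (inclusive) and that straddle the pathogenic
    variant.

    The left guide sits on the minus strand (PAM 5', pointing away) and the
    right guide on the plus strand (PAM 3', pointing away).  Pairs are
    sorted by |offset - midpoint(offset_range)|, ties by left nick position.
    """
    lo, hi = window
    if not (0 <= lo < hi <= len(locus.sequence)):
        raise InputError(f"window {window} outside locus")
    if offset_range[0] < 0 or offset_range[0] > offset_range[1]:
        raise InputError(f"invalid offset range {offset_range}")
    variant_pos = locus.pathogenic_variant[0]
    if not lo <= variant_pos < hi:
        raise InputError("window must contain the pathogenic variant")

    seq = locus.sequence
    lefts, rights = [], []
    for p in range(lo, hi - 2):
        # minus-strand guide: CCN PAM on the forward strand, protospacer 3'
        if seq[p : p + 2] == "CC" and p + 23 <= hi:
            lefts.append(_minus_guide(locus, p, f"sg{p}-"))
        # plus-strand guide: NGG PAM, protospacer 5'
        if seq[p + 1 : p + 3] == "GG" and p - 20 >= lo:
            rights.append(_plus_guide(locus, p, f"sg{p}+"))

    pairs = []
    for left in lefts:
        for right in rights:
            if left.nick_position >= right.nick_position:
                continue
            offset = right.nick_position - left.nick_position
            if not offset_range[0] <= offset <= offset_range[1]:
                continue
            if not left.nick_position < variant_pos < right.nick_position:
                continue
            pairs.append(GuidePair(left=left, right=right))
    mid = (offset_range[0] + offset_range[1]) / 2
    pairs.sort(key=lambda pr: (abs(pr.offset - mid), pr.left.nick_position))
    return pairs


# ---------------------------------------------------------------------------
# template construction
# ---------------------------------------------------------------------------


def _seed_positions(guide: Guide) -> list[int]:
    """Locus positions of the 10 protospacer bases nearest the PAM
    (the seed region), ordered PAM-proximal first."""
    ps, pe = guide.protospacer_interval
    if guide.strand == "+":
        return list(range(pe - 1, pe - 11, -1))
    return list(range(ps, ps + 10))


def _pam_gg_positions(guide: Guide, locus: ReferenceLocus) -> list[int]:
    lo, hi = guide.pam_interval
    if guide.strand == "+":
        return [lo + 1, lo + 2]
    return [lo, lo + 1]  # CC on the forward strand


def _pick_blocking(locus: ReferenceLocus, guide: Guide, pair: GuidePair,
                   chosen: dict[int, str], forbidden: set[int]) -> PlannedSNV:
    for pool in (_seed_positions(guide), _pam_gg_positions(guide, locus)):
        for pos in pool:
            if pos in forbidden:
                continue
            for alt in silent_alternatives(locus, pos):
                if _creates_new_ngg(locus, chosen, pos, alt, pair):
                    continue
                return PlannedSNV(
                    pos, locus.sequence[pos], alt, "blocking",
                    guide_association=guide.name, silent=True,
                )
    raise DesignInfeasibleError(
        f"no silent blocking substitution available for guide {guide.name}"
    )


def _bridging_candidates(locus: ReferenceLocus, nick: int, correction_pos: int,
                         pair: GuidePair, chosen: dict[int, str],
                         forbidden: set[int]) -> list[PlannedSNV]:
    lo, hi = sorted((correction_pos, nick))
    out = []
    for pos in range(lo + 1, hi):
        if pos in forbidden:
            continue
        for alt in silent_alternatives(locus, pos):
            if _creates_new_ngg(locus, chosen, pos, alt, pair):
                continue
            out.append(
                PlannedSNV(pos, locus.sequence[pos], alt, "bridging", silent=True)
            )
            break
    # proximal (nick-nearest) first
    out.sort(key=lambda s: abs(s.position - nick))
    return out


BRIDGING_LEVELS = {"blocking": 0, "low": 1, "medium": 2, "full": None}


def design_template(
    locus: ReferenceLocus,
    pair: GuidePair,
    bridging_level: str = "blocking",
    total_length: int | None = None,
    arm_length: int = 40,
    bridging_guide: str = "right",
) -> RepairTemplate:
    """Design an ssODN repair template for a PAM-out nickase pair.

    The template carries the corrective SNV, one silent blocking SNV per
    guide (seed preferred over PAM) and, for levels low/medium/full,
    1/2/all-available silent bridging SNVs between the bridging guide's nick
    and the corrective edit, taken proximal-to-distal from the nick.  The
    oligo is centred on the corrective edit with homology arms measured from
    the outermost planned SNV outward.
    """
    if bridging_level not in BRIDGING_LEVELS:
        raise InputError(f"unknown bridging level {bridging_level!r}")
    if pair.orientation != "PAM-out":
        raise InputError("template design requires a PAM-out guide pair")
    pos, ref, alt = locus.pathogenic_variant
    if not pair.left.nick_position < pos < pair.right.nick_position:
        raise InputError("pathogenic variant must lie between the two nicks")
    if total_length is not None and arm_length * 2 > total_length:
        raise InputError("total_length must be at least twice arm_length")

    correction = PlannedSNV(pos, ref, alt, "correction", silent=False)
    chosen: dict[int, str] = {pos: alt}
    forbidden = {pos}

    snvs = [correction]
    for guide in pair.guides:
        blk = _pick_blocking(locus, guide, pair, chosen, forbidden)
        snvs.append(blk)
        chosen[blk.position] = blk.alt_base
        forbidden.add(blk.position)

    proximal = pair.right if bridging_guide == "right" else pair.left
    n_bridge = BRIDGING_LEVELS[bridging_level]
    if n_bridge is None or n_bridge > 0:
        candidates = _bridging_candidates(
            locus, proximal.nick_position, pos, pair, chosen, forbidden
        )
        take = candidates if n_bridge is None else candidates[:n_bridge]
        for snv in take:
            snv = PlannedSNV(
                snv.position, snv.ref_base, snv.alt_base, "bridging",
                guide_association=proximal.name, silent=True,
            )
            snvs.append(snv)
            chosen[snv.position] = snv.alt_base

    snvs.sort(key=lambda s: s.position)
    leftmost, rightmost = snvs[0].position, snvs[-1].position
    natural = (rightmost + arm_length + 1) - (leftmost - arm_length)
    if total_length is None:
        total_length = natural
    if total_length < natural:
        raise DesignInfeasibleError(
            f"total_length {total_length} cannot hold the planned SNVs with "
            f"{arm_length} bp arms (needs {natural})"
        )
    start = pos - total_length // 2
    # keep the requested arms even if centring would clip them
    start = min(start, leftmost - arm_length)
    start = max(start, rightmost + arm_length + 1 - total_length)
    end = start + total_length
    if start < 0 or end > len(locus.sequence):
        raise DesignInfeasibleError("template interval extends beyond the locus")

    template_seq = list(locus.sequence[start:end])
    for snv in snvs:
        template_seq[snv.position - start] = snv.alt_base
    # the oligo is synthesised complementary to the bridging guide's
    # non-target (protospacer) strand
    oligo_strand = "-" if proximal.strand == "+" else "+"
    template = RepairTemplate(
        name=f"ssODN-{bridging_level}",
        sequence="".join(template_seq),
        locus_interval=(start, end),
        snvs=tuple(snvs),
        arm_lengths=(leftmost - start, end - 1 - rightmost),
        oligo_strand=oligo_strand,
    )

    # combined-silence invariant: all silent SNVs together must leave the
    # corrected protein unchanged
    full = list(locus.sequence)
    for snv in template.snvs:
        full[snv.position] = snv.alt_base
    corrected_only = list(locus.sequence)
    corrected_only[pos] = alt
    if locus.translate("".join(full)) != locus.translate("".join(corrected_only)):
        raise DesignInfeasibleError("combined silent SNVs alter the protein")
    ok = renick_check(template, pair)
    if not all(ok.values()):
        raise DesignInfeasibleError("designed template fails the renick check")
    return template


def renick_check(template: RepairTemplate, pair: GuidePair) -> dict[str, bool]:
    """Per guide, True iff the corrected sequence can no longer be nicked
    (at least one mismatch in the protospacer, or the PAM is no longer NGG)."""
    lo, hi = template.locus_interval
    out = {}
    for guide in pair.guides:
        f_lo, f_hi = guide.footprint
        if f_lo < lo or f_hi > hi:
            raise InputError(
                f"template does not span the footprint of guide {guide.name}"
            )
        region = template.sequence[f_lo - lo : f_hi - lo]
        if guide.strand == "-":
            region = revcomp(region)
        # region is protospacer+PAM in guide orientation
        if guide.strand == "+":
            spacer, pam = region[:20], region[20:]
        else:
            spacer, pam = region[:20], region[20:]
        matches = spacer == guide.protospacer and pam[1:] == "GG"
        out[guide.name] = not matches
    return out


def load_design_report(locus: ReferenceLocus, report_path: str | Path) -> RepairTemplate:
    """Rebuild a RepairTemplate from a JSON design report and its locus."""
    report = json.loads(Path(report_path).read_text())
    snvs = tuple(
        PlannedSNV(
            position=row["position"],
            ref_base=row["ref"],
            alt_base=row["alt"],
            role=row["role"],
            guide_association=row.get("guide"),
            silent=row.get("silent", False),
        )
        for row in report["snvs"]
    )
    lo, hi = report["locus_interval"]
    seq = list(locus.sequence[lo:hi])
    for snv in snvs:
        if locus.sequence[snv.position] != snv.ref_base:
            raise InputError(
                f"report SNV at {snv.position} disagrees with locus sequence"
            )
        seq[snv.position - lo] = snv.alt_base
    return RepairTemplate(
        name=report["name"],
        sequence="".join(seq),
        locus_interval=(lo, hi),
        snvs=snvs,
        arm_lengths=tuple(report["arm_lengths"]),
        oligo_strand=report.get("oligo_strand", "+"),
    )


def write_design_report(template: RepairTemplate, locus: ReferenceLocus,
                        fasta_path: str | Path, report_path: str | Path) -> None:
    """Emit the oligo FASTA plus a JSON SNV table (positions, roles, codons)."""
    write_fasta(fasta_path, [(template.name, template.oligo_sequence)])
    rows = []
    for snv in template.snvs:
        cds_idx = locus.cds_index(snv.position)
        rows.append(
            {
                "position": snv.position,
                "genomic_position": locus.to_genomic(snv.position),
                "ref": snv.ref_base,
                "alt": snv.alt_base,
                "role": snv.role,
                "guide": snv.guide_association,
                "silent": snv.silent,
                "codon_position": None if cds_idx is None else cds_idx % 3 + 1,
            }
        )
    report = {
        "name": template.name,
        "locus_interval": list(template.locus_interval),
        "length": len(template.sequence),
        "arm_lengths": list(template.arm_lengths),
        "oligo_strand": template.oligo_strand,
        "snvs": rows,
    }
    Path(report_path).write_text(json.dumps(report, indent=2))
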