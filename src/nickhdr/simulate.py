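"""Seedable generator of editing-outcome allele mixtures and Nanopore-like
amplicon / cDNA reads, with ground-truth tables.

PCR capture is modelled physically: an allele whose deletion removes a
primer site of the requested amplicon cannot template that PCR and
contributes zero reads; its mixture weight is renormalised over the
capturable alleles (keeping the read count exact) and the bias is reported,
so "evasion" of short-amplicon genotyping by large deletions is emulated
rather than asserted.

Sequencing errors are i.i.d. per base with geometric indel lengths — a
deliberately simple stand-in for context-dependent Nanopore error that is
sufficient to stress the downstream classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .design import PlannedSNV, RepairTemplate
from .errors import InputError, SimulationError
from .locus import AmpliconDef, ReferenceLocus, revcomp

if TYPE_CHECKING:
    from .expression import IsoformModel

# quality strings are placeholders: downstream analysis is alignment-based
_PLACEHOLDER_QUAL = chr(12 + 33)  # Q12

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


@dataclass(frozen=True)
class ErrorModel:
    """Per-base i.i.d. error model (Nanopore-like defaults).

    ``indel_len_p`` is the geometric success parameter for indel lengths
    (mean length 1/p), capped at ``max_indel_len``.
    """

    sub_rate: float = 0.02
    ins_rate: float = 0.0025
    del_rate: float = 0.0025
    max_indel_len: int = 10
    seed: int = 0
    indel_len_p: float = 0.85

    def __post_init__(self) -> None:
        for r in (self.sub_rate, self.ins_rate, self.del_rate):
            if not 0 <= r <= 0.3:
                raise InputError("error rates must lie in [0, 0.3]")
        if not 0 < self.indel_len_p <= 1:
            raise InputError("indel_len_p must lie in (0, 1]")


@dataclass(frozen=True)
class AlleleSpec:
    """Ground-truth description of one allele in a cell population.

    ``indels`` holds small events as ``(position, edit)`` where a string
    edit is an insertion placed at that boundary and a negative integer is
    a deletion of that many bases starting there.  ``deletion`` is the
    optional large (kilobase-scale) span.
    """

    name: str
    snvs: tuple[PlannedSNV, ...] = ()
    indels: tuple[tuple[int, object], ...] = ()
    deletion: tuple[int, int] | None = None
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise InputError("allele weight must be non-negative")

    def edit_intervals(self) -> list[tuple[int, int]]:
        """Locus intervals consumed by the allele's edits."""
        ivs = [(s.position, s.position + 1) for s in self.snvs]
        for pos, edit in self.indels:
            if isinstance(edit, str):
                ivs.append((pos, pos))
            elif isinstance(edit, int) and edit < 0:
                ivs.append((pos, pos - edit))
            else:
                raise InputError(
                    f"indel edit must be an inserted string or a negative "
                    f"deletion length, got {edit!r}"
                )
        if self.deletion is not None:
            ivs.append(tuple(self.deletion))
        return ivs


@dataclass(frozen=True)
class MixtureSpec:
    """A weighted set of alleles; weights must sum to one."""

    alleles: tuple[AlleleSpec, ...]

    def __post_init__(self) -> None:
        total = sum(a.weight for a in self.alleles)
        if abs(total - 1.0) > 1e-9:
            raise InputError(f"mixture weights sum to {total}, expected 1")
        if len({a.name for a in self.alleles}) != len(self.alleles):
            raise InputError("allele names must be unique")

    @property
    def weights(self) -> dict[str, float]:
        return {a.name: a.weight for a in self.alleles}


def load_mixture(path, locus: ReferenceLocus) -> MixtureSpec:
    """Load a mixture spec from YAML/JSON, validating SNVs against the locus."""
    import yaml

    cfg = yaml.safe_load(open(path))
    alleles = []
    for row in cfg["alleles"]:
        snvs = tuple(
            PlannedSNV(
                position=s["position"],
                ref_base=s.get("ref", locus.sequence[s["position"]]),
                alt_base=s["alt"],
                role=s.get("role", "bridging"),
                guide_association=s.get("guide"),
                silent=s.get("silent", False),
            )
            for s in row.get("snvs", [])
        )
        for snv in snvs:
            if locus.sequence[snv.position] != snv.ref_base:
                raise InputError(
                    f"mixture SNV at {snv.position} disagrees with locus"
                )
        indels = tuple((int(p), e) for p, e in row.get("indels", []))
        deletion = tuple(row["deletion"]) if row.get("deletion") else None
        alleles.append(
            AlleleSpec(
                name=row["name"],
                snvs=snvs,
                indels=indels,
                deletion=deletion,
                weight=float(row["weight"]),
            )
        )
    return MixtureSpec(alleles=tuple(alleles))


def save_mixture(mixture: MixtureSpec, path) -> None:
    import yaml

    rows = []
    for a in mixture.alleles:
        row: dict = {"name": a.name, "weight": a.weight}
        if a.snvs:
            row["snvs"] = [
                {
                    "position": s.position,
                    "ref": s.ref_base,
                    "alt": s.alt_base,
                    "role": s.role,
                    "guide": s.guide_association,
                    "silent": s.silent,
                }
                for s in a.snvs
            ]
        if a.indels:
            row["indels"] = [[p, e] for p, e in a.indels]
        if a.deletion:
            row["deletion"] = list(a.deletion)
        rows.append(row)
    with open(path, "w") as fh:
        yaml.safe_dump({"alleles": rows}, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# allele construction
# ---------------------------------------------------------------------------


def _sorted_edits(spec: AlleleSpec) -> list[tuple[int, int, object]]:
    """Edits as (start, end, payload), validated non-overlapping."""
    edits: list[tuple[int, int, object]] = []
    for snv in spec.snvs:
        edits.append((snv.position, snv.position + 1, snv.alt_base))
    for pos, edit in spec.indels:
        if isinstance(edit, str):
            edits.append((pos, pos, edit))
        else:
            edits.append((pos, pos - int(edit), None))
    if spec.deletion is not None:
        edits.append((spec.deletion[0], spec.deletion[1], None))
    edits.sort(key=lambda e: (e[0], e[1]))
    for (s1, e1, _), (s2, e2, _) in zip(edits, edits[1:]):
        if max(s1, s2) < min(e1, e2):
            raise InputError(f"overlapping edits at [{s1},{e1}) and [{s2},{e2})")
    return edits


def build_allele(locus: ReferenceLocus, spec: AlleleSpec) -> str:
    """Locus sequence with the allele's edits applied (coordinate shifts
    handled by applying right-to-left)."""
    seq = list(locus.sequence)
    for start, end, payload in reversed(_sorted_edits(spec)):
        if payload is None:  # deletion
            del seq[start:end]
        elif start == end:  # insertion at boundary
            seq[start:start] = list(payload)
        else:  # SNV
            seq[start] = payload
    return "".join(seq)


def allele_position(spec: AlleleSpec, position: int) -> int:
    """Allele-coordinate of a locus position not consumed by a deletion."""
    shift = 0
    for start, end, payload in _sorted_edits(spec):
        if payload is None:
            if start <= position < end:
                raise InputError(f"locus position {position} is deleted in allele")
            if end <= position:
                shift -= end - start
        elif start == end and start <= position:
            shift += len(payload)
    return position + shift


def amplicon_capturable(spec: AlleleSpec, amplicon: AmpliconDef) -> bool:
    """True iff both primer sites survive intact (PCR can amplify)."""
    for p_lo, p_hi in (amplicon.fwd_primer, amplicon.rev_primer):
        for start, end, payload in _sorted_edits(spec):
            if payload is None and max(start, p_lo) < min(end, p_hi):
                return False  # primer bases deleted
            if start == end and isinstance(payload, str) and p_lo < start < p_hi:
                return False  # insertion disrupts the primer site
    return True


def allele_amplicon(locus: ReferenceLocus, spec: AlleleSpec,
                    amplicon: AmpliconDef) -> str:
    """The PCR product sequence of an amplicon on this allele."""
    seq = build_allele(locus, spec)
    a = allele_position(spec, amplicon.fwd_primer[0])
    b = allele_position(spec, amplicon.rev_primer[1] - 1) + 1
    return seq[a:b]


# ---------------------------------------------------------------------------
# error injection
# ---------------------------------------------------------------------------


def _geometric_lengths(rng: np.random.Generator, n: int, error: ErrorModel) -> np.ndarray:
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    return np.minimum(rng.geometric(error.indel_len_p, n), error.max_indel_len)


def mutate(seq: str, error: ErrorModel, rng: np.random.Generator) -> tuple[str, int, int, int]:
    """Inject i.i.d. substitution/indel errors; returns (seq, n_sub, n_ins, n_del)."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    n = len(arr)

    sub_idx = np.nonzero(rng.random(n) < error.sub_rate)[0]
    if len(sub_idx):
        offsets = rng.integers(1, 4, len(sub_idx))
        arr[sub_idx] = _BASES[(_BASE_INDEX[arr[sub_idx]] + offsets) % 4]

    del_starts = np.nonzero(rng.random(n) < error.del_rate)[0]
    del_lens = _geometric_lengths(rng, len(del_starts), error)
    keep = np.ones(n, dtype=bool)
    for s, l in zip(del_starts, del_lens):
        keep[s : s + l] = False
    n_del = int(n - keep.sum())

    ins_pos = np.nonzero(rng.random(n + 1) < error.ins_rate)[0]
    ins_lens = _geometric_lengths(rng, len(ins_pos), error)
    inserts = [
        (p, _BASES[rng.integers(0, 4, l)].tobytes().decode())
        for p, l in zip(ins_pos, ins_lens)
    ]
    n_ins = int(ins_lens.sum())

    prefix = np.concatenate([[0], np.cumsum(keep)])
    out = arr[keep].tobytes().decode()
    for p, ins_seq in reversed(inserts):
        cut = int(prefix[p])
        out = out[:cut] + ins_seq + out[cut:]
    return out, len(sub_idx), n_ins, n_del


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


def simulate_amplicon_reads(
    locus: ReferenceLocus,
    mixture: MixtureSpec,
    amplicon: AmpliconDef,
    n_reads: int,
    error: ErrorModel,
    read_prefix: str = "read",
) -> tuple[list[tuple[str, str, str]], pd.DataFrame, dict]:
    """Simulate amplicon sequencing of a mixture.

    Returns FASTQ-ready ``(read_id, sequence, quality)`` records, a truth
    table (read_id, allele, strand, error counts) and a capture report
    giving, per allele, its nominal weight, whether the amplicon could
    capture it, and the renormalised effective weight actually sampled.
    """
    if n_reads <= 0:
        raise InputError("n_reads must be positive")
    capturable = [amplicon_capturable(a, amplicon) for a in mixture.alleles]
    eff = np.array(
        [a.weight if c else 0.0 for a, c in zip(mixture.alleles, capturable)]
    )
    if eff.sum() == 0:
        raise SimulationError("no allele in the mixture is capturable")
    eff = eff / eff.sum()
    capture = {
        a.name: {
            "weight": a.weight,
            "capturable": c,
            "effective_weight": float(w),
        }
        for a, c, w in zip(mixture.alleles, capturable, eff)
    }

    products = [
        allele_amplicon(locus, a, amplicon) if c else None
        for a, c in zip(mixture.alleles, capturable)
    ]
    rng = np.random.default_rng(error.seed)
    choices = rng.choice(len(mixture.alleles), size=n_reads, p=eff)
    strands = rng.random(n_reads) < 0.5

    records, rows = [], []
    for i in range(n_reads):
        allele = mixture.alleles[choices[i]]
        seq, n_sub, n_ins, n_del = mutate(products[choices[i]], error, rng)
        strand = "-" if strands[i] else "+"
        if strand == "-":
            seq = revcomp(seq)
        read_id = f"{read_prefix}{i:06d}"
        records.append((read_id, seq, _PLACEHOLDER_QUAL * len(seq)))
        rows.append((read_id, allele.name, strand, n_sub, n_ins, n_del))
    truth = pd.DataFrame(
        rows, columns=["read_id", "allele", "strand", "n_sub", "n_ins", "n_del"]
    )
    return records, truth, capture


def simulate_cdna_reads(
    locus: ReferenceLocus,
    isoforms: "IsoformModel",
    n_reads: int,
    isoform_inclusion: float,
    snv_carrier_fraction: float,
    error: ErrorModel,
    template: RepairTemplate | None = None,
    read_prefix: str = "cdna",
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Simulate cDNA amplicon reads across the target exon.

    Each read independently includes the target exon with probability
    ``isoform_inclusion`` and carries the repair-template SNVs with
    probability ``snv_carrier_fraction`` (SNVs only materialise on
    exon-including reads, since they live in the target exon; carrier
    status is still recorded for every read).
    """
    if n_reads <= 0:
        raise InputError("n_reads must be positive")
    for f in (isoform_inclusion, snv_carrier_fraction):
        if not 0 <= f <= 1:
            raise InputError("fractions must lie in [0, 1]")

    full = isoforms.transcript(included=True)
    skipped = isoforms.transcript(included=False)
    full_carrier = full
    if template is not None:
        seq = list(full)
        for snv in template.snvs:
            t_pos = isoforms.to_transcript(snv.position)
            if t_pos is not None:
                seq[t_pos] = snv.alt_base
        full_carrier = "".join(seq)

    rng = np.random.default_rng(error.seed)
    included = rng.random(n_reads) < isoform_inclusion
    carrier = rng.random(n_reads) < snv_carrier_fraction
    strands = rng.random(n_reads) < 0.5

    records, rows = [], []
    for i in range(n_reads):
        base = (full_carrier if carrier[i] else full) if included[i] else skipped
        seq, n_sub, n_ins, n_del = mutate(base, error, rng)
        strand = "-" if strands[i] else "+"
        if strand == "-":
            seq = revcomp(seq)
        read_id = f"{read_prefix}{i:06d}"
        records.append((read_id, seq, _PLACEHOLDER_QUAL * len(seq)))
        rows.append(
            (read_id, bool(included[i]), bool(carrier[i]), strand, n_sub + n_ins + n_del)
        )
    truth = pd.DataFrame(
        rows, columns=["read_id", "includes_exon", "carrier", "strand", "n_errors"]
    )
    return records, truth
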