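"""Reference-locus model: domain types, validation and config/FASTA/FASTQ I/O.

Coordinates are 0-based, half-open and locus-forward everywhere inside the
package; genomic coordinates exist only at I/O boundaries through
``ReferenceLocus.coordinate_origin``.

The locus sequence models the *patient's target allele*: the base present at
``pathogenic_variant.position`` is the pathogenic one and the stored alt base
is the corrective (wild-type) base.  Reads are aligned against this sequence,
so an unedited target-allele read is an exact match and the corrective edit
shows up as a template SNV like every other planned substitution.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConfigError, ConsistencyError, InputError

DNA_ALPHABET = frozenset("ACGT")
READ_ALPHABET = frozenset("ACGTN")

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement (N-safe)."""
    return seq.translate(_COMP)[::-1]


def _check_interval(iv: tuple[int, int], limit: int, what: str) -> None:
    s, e = iv
    if not (0 <= s < e <= limit):
        raise ConfigError(f"{what}: interval {iv} outside [0, {limit})")


@dataclass(frozen=True)
class AmpliconDef:
    """A PCR amplicon given by its two primer intervals on the locus."""

    fwd_primer: tuple[int, int]
    rev_primer: tuple[int, int]
    expected_length: int

    def __post_init__(self) -> None:
        if self.fwd_primer[1] >= self.rev_primer[0]:
            raise ConfigError(
                f"fwd primer {self.fwd_primer} must end before rev primer "
                f"{self.rev_primer} starts"
            )
        want = self.rev_primer[1] - self.fwd_primer[0]
        if self.expected_length != want:
            raise ConfigError(
                f"expected_length {self.expected_length} != rev_primer.end - "
                f"fwd_primer.start = {want}"
            )

    @property
    def interval(self) -> tuple[int, int]:
        """Full amplicon footprint (fwd primer start to rev primer end)."""
        return (self.fwd_primer[0], self.rev_primer[1])

    @classmethod
    def from_primers(cls, fwd: tuple[int, int], rev: tuple[int, int]) -> "AmpliconDef":
        return cls(tuple(fwd), tuple(rev), rev[1] - fwd[0])


@dataclass(frozen=True)
class Guide:
    """A single Cas9(n) guide placed on the locus.

    ``nick_position`` is the inter-base boundary index of the D10A nick:
    the nick falls between locus positions ``nick_position - 1`` and
    ``nick_position``, three nucleotides 5' of the PAM on the protospacer
    strand (between protospacer positions 17 and 18).
    """

    name: str
    protospacer: str
    pam_interval: tuple[int, int]
    strand: str
    nick_position: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ConfigError(f"guide {self.name}: strand must be + or -")
        if len(self.protospacer) != 20:
            raise ConfigError(f"guide {self.name}: protospacer must be 20 nt")

    @property
    def protospacer_interval(self) -> tuple[int, int]:
        """Locus interval occupied by the protospacer."""
        if self.strand == "+":
            return (self.pam_interval[0] - 20, self.pam_interval[0])
        return (self.pam_interval[1], self.pam_interval[1] + 20)

    @property
    def footprint(self) -> tuple[int, int]:
        """Protospacer plus PAM, as one locus interval."""
        ps, pe = self.protospacer_interval
        return (min(ps, self.pam_interval[0]), max(pe, self.pam_interval[1]))

    def validate_against(self, sequence: str) -> None:
        ps, pe = self.protospacer_interval
        _check_interval((ps, pe), len(sequence), f"guide {self.name} protospacer")
        _check_interval(self.pam_interval, len(sequence), f"guide {self.name} PAM")
        genomic = sequence[ps:pe]
        spacer = genomic if self.strand == "+" else revcomp(genomic)
        if spacer != self.protospacer:
            raise ConsistencyError(
                f"guide {self.name}: protospacer does not match locus on "
                f"strand {self.strand}"
            )
        pam = sequence[self.pam_interval[0] : self.pam_interval[1]]
        pam = pam if self.strand == "+" else revcomp(pam)
        if not (len(pam) == 3 and pam[1:] == "GG"):
            raise ConsistencyError(f"guide {self.name}: PAM {pam!r} is not NGG")
        if not ps <= self.nick_position < pe:
            raise ConsistencyError(
                f"guide {self.name}: nick {self.nick_position} outside "
                f"protospacer footprint [{ps}, {pe})"
            )


@dataclass(frozen=True)
class GuidePair:
    """Two nickase guides forming a paired (staggered) break."""

    left: Guide
    right: Guide

    def __post_init__(self) -> None:
        if self.left.nick_position >= self.right.nick_position:
            raise ConfigError("left guide nick must be 5' of right guide nick")

    @property
    def offset(self) -> int:
        """Nick-to-nick distance in bp."""
        return self.right.nick_position - self.left.nick_position

    @property
    def orientation(self) -> str:
        """PAM-out / PAM-in / tandem, derived from the two strands."""
        if self.left.strand == "-" and self.right.strand == "+":
            return "PAM-out"
        if self.left.strand == "+" and self.right.strand == "-":
            return "PAM-in"
        return "tandem"

    @property
    def guides(self) -> tuple[Guide, Guide]:
        return (self.left, self.right)


@dataclass(frozen=True)
class ReferenceLocus:
    """The genomic target: sequence, exon model, variant and amplicons."""

    name: str
    sequence: str
    coordinate_origin: int
    exons: tuple[tuple[int, int], ...]
    cds_frame: int
    pathogenic_variant: tuple[int, str, str]
    short_amplicon: AmpliconDef
    long_amplicon: AmpliconDef
    _kmer_index_cache: dict = field(
        default_factory=dict, repr=False, compare=False, hash=False
    )

    def __post_init__(self) -> None:
        seq = self.sequence
        if not seq or set(seq) - DNA_ALPHABET:
            raise ConfigError("locus sequence must be non-empty uppercase ACGT")
        last = 0
        for iv in self.exons:
            _check_interval(iv, len(seq), "exon")
            if iv[0] < last:
                raise ConfigError("exons must be sorted and non-overlapping")
            last = iv[1]
        pos, ref, alt = self.pathogenic_variant
        if not any(s <= pos < e for s, e in self.exons):
            raise ConfigError(f"pathogenic variant position {pos} not inside an exon")
        if seq[pos] != ref:
            raise ConsistencyError(
                f"pathogenic variant ref base {ref!r} disagrees with locus "
                f"base {seq[pos]!r} at position {pos}"
            )
        if alt == ref or alt not in DNA_ALPHABET:
            raise ConfigError("pathogenic variant alt base invalid")
        for amp, label in ((self.short_amplicon, "short"), (self.long_amplicon, "long")):
            _check_interval(amp.interval, len(seq), f"{label} amplicon")
        ss, se = self.short_amplicon.interval
        ls, le = self.long_amplicon.interval
        if not (ls <= ss and se <= le):
            raise ConfigError("short amplicon must lie within the long amplicon")

    def __hash__(self) -> int:  # frozen dataclass with a mutable cache field
        return hash((self.name, self.sequence))

    # -- exon / CDS helpers -------------------------------------------------

    def cds_sequence(self, sequence: str | None = None) -> str:
        """Concatenated exonic sequence from the reading-frame offset on.

        ``sequence`` may substitute an edited copy of the locus of identical
        length (SNVs only), e.g. to translate a repair-template haplotype.
        """
        seq = self.sequence if sequence is None else sequence
        if len(seq) != len(self.sequence):
            raise InputError("substitute sequence must have identical length")
        joined = "".join(seq[s:e] for s, e in self.exons)
        return joined[self.cds_frame :]

    def cds_index(self, position: int) -> int | None:
        """CDS index of an exonic locus position, or None if intronic."""
        offset = 0
        for s, e in self.exons:
            if s <= position < e:
                idx = offset + (position - s) - self.cds_frame
                return idx if idx >= 0 else None
            offset += e - s
        return None

    def translate(self, sequence: str | None = None) -> str:
        cds = self.cds_sequence(sequence)
        cds = cds[: len(cds) - len(cds) % 3]
        return str(Seq(cds).translate())

    def to_genomic(self, position: int) -> int:
        return position + self.coordinate_origin


# ---------------------------------------------------------------------------
# Config I/O
# ---------------------------------------------------------------------------


def _require(cfg: dict, key: str, where: str):
    if key not in cfg:
        raise ConfigError(f"{where}: missing required field {key!r}")
    return cfg[key]


def _amplicon_from_cfg(cfg: dict, where: str) -> AmpliconDef:
    fwd = tuple(_require(cfg, "fwd_primer", where))
    rev = tuple(_require(cfg, "rev_primer", where))
    return AmpliconDef(fwd, rev, cfg.get("expected_length", rev[1] - fwd[0]))


def load_locus_config(path: str | Path) -> ReferenceLocus:
    """Load and eagerly validate a YAML/JSON locus config.

    The config references the reference FASTA via ``sequence_file`` (resolved
    relative to the config file) and carries keys ``origin``, ``exons``,
    ``cds_frame``, ``variant`` and ``amplicons`` (``short`` / ``long``, each
    with primer intervals).  Guide definitions under ``guides`` are read by
    :func:`load_guide_pair`.
    """
    path = Path(path)
    try:
        cfg = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: cannot parse config: {exc}") from exc
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: config root must be a mapping")

    fasta = path.parent / _require(cfg, "sequence_file", str(path))
    try:
        record = next(SeqIO.parse(str(fasta), "fasta"))
    except (FileNotFoundError, StopIteration) as exc:
        raise ConfigError(f"{path}: cannot read sequence_file {fasta}: {exc}") from exc
    sequence = str(record.seq).upper()

    variant = _require(cfg, "variant", str(path))
    amplicons = _require(cfg, "amplicons", str(path))
    return ReferenceLocus(
        name=cfg.get("name", record.id),
        sequence=sequence,
        coordinate_origin=int(cfg.get("origin", 0)),
        exons=tuple(tuple(iv) for iv in _require(cfg, "exons", str(path))),
        cds_frame=int(_require(cfg, "cds_frame", str(path))),
        pathogenic_variant=(
            int(_require(variant, "position", "variant")),
            _require(variant, "ref", "variant"),
            _require(variant, "alt", "variant"),
        ),
        short_amplicon=_amplicon_from_cfg(
            _require(amplicons, "short", "amplicons"), "amplicons.short"
        ),
        long_amplicon=_amplicon_from_cfg(
            _require(amplicons, "long", "amplicons"), "amplicons.long"
        ),
    )


def load_guide_pair(path: str | Path, locus: ReferenceLocus) -> GuidePair:
    """Load the ``guides`` section of a locus config and validate it."""
    cfg = yaml.safe_load(Path(path).read_text())
    guides_cfg = _require(cfg, "guides", str(path))
    guides = []
    for g in guides_cfg:
        guide = Guide(
            name=_require(g, "name", "guide"),
            protospacer=_require(g, "protospacer", "guide").upper(),
            pam_interval=tuple(_require(g, "pam_interval", "guide")),
            strand=_require(g, "strand", "guide"),
            nick_position=int(_require(g, "nick_position", "guide")),
        )
        guide.validate_against(locus.sequence)
        guides.append(guide)
    if len(guides) != 2:
        raise ConfigError(f"{path}: expected exactly 2 guides, got {len(guides)}")
    guides.sort(key=lambda g: g.nick_position)
    return GuidePair(left=guides[0], right=guides[1])


def save_locus_config(
    locus: ReferenceLocus,
    config_path: str | Path,
    pair: GuidePair | None = None,
) -> None:
    """Write a locus (and optional guide pair) back to FASTA + YAML."""
    config_path = Path(config_path)
    fasta_name = config_path.stem + ".fasta"
    write_fasta(config_path.parent / fasta_name, [(locus.name, locus.sequence)])
    pos, ref, alt = locus.pathogenic_variant
    cfg: dict = {
        "name": locus.name,
        "sequence_file": fasta_name,
        "origin": locus.coordinate_origin,
        "exons": [list(iv) for iv in locus.exons],
        "cds_frame": locus.cds_frame,
        "variant": {"position": pos, "ref": ref, "alt": alt},
        "amplicons": {
            label: {
                "fwd_primer": list(amp.fwd_primer),
                "rev_primer": list(amp.rev_primer),
                "expected_length": amp.expected_length,
            }
            for label, amp in (
                ("short", locus.short_amplicon),
                ("long", locus.long_amplicon),
            )
        },
    }
    if pair is not None:
        cfg["guides"] = [
            {
                "name": g.name,
                "protospacer": g.protospacer,
                "pam_interval": list(g.pam_interval),
                "strand": g.strand,
                "nick_position": g.nick_position,
            }
            for g in pair.guides
        ]
    config_path.write_text(yaml.safe_dump(cfg, sort_keys=False))


# ---------------------------------------------------------------------------
# FASTA / FASTQ I/O
# ---------------------------------------------------------------------------


def _open_maybe_gzip(path: Path, mode: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def write_fasta(path: str | Path, records: Sequence[tuple[str, str]]) -> None:
    path = Path(path)
    with _open_maybe_gzip(path, "w") as fh:
        SeqIO.write(
            (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
            fh,
            "fasta",
        )


def write_fastq(path: str | Path, records: Sequence[tuple[str, str, str]]) -> None:
    """Write (read_id, sequence, quality-string) triples as FASTQ."""
    path = Path(path)
    with _open_maybe_gzip(path, "w") as fh:
        for read_id, seq, qual in records:
            fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")


def read_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) from a FASTQ file (gzip accepted)."""
    path = Path(path)
    with _open_maybe_gzip(path, "r") as fh:
        for record in SeqIO.parse(fh, "fastq"):
            yield record.id, str(record.seq).upper()
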