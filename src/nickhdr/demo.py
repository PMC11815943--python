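"""Bundled synthetic study system: a compound-heterozygous locus analog.

The demo locus emulates the situation the package analyses: a ~12 kb
genomic region whose central exon carries a heterozygous pathogenic point
variant, flanked by a PAM-out dual-nickase guide pair, with a ~700 bp
genotyping amplicon nested inside a ~10.5 kb long amplicon.  The exon is
built codon-by-codon so that

* each guide's seed region contains exactly one synonymous substitution
  site (the blocking-SNV site),
* the two blocking sites sit 26 bp left / 25 bp right of the variant, so a
  132 nt oligo centred on the variant has exactly 40 bp homology arms
  outside the outermost SNVs, and
* the segment between the variant and the right (bridging) nick offers
  several further synonymous sites for the graded bridging series.

The locus sequence represents the patient's *target allele* (pathogenic
base present); the sibling allele of the compound heterozygote is modelled
as the allele carrying only the corrective base at the variant position.

Everything here is deterministic: the filler sequence comes from a fixed
internal seed, because the locus is a reference object, not a random draw.
"""

from __future__ import annotations

import numpy as np

from .design import PlannedSNV, RepairTemplate, design_template
from .locus import AmpliconDef, Guide, GuidePair, ReferenceLocus, revcomp
from .simulate import AlleleSpec, MixtureSpec

_FILLER_SEED = 987654321  # fixed: the demo locus is a constant reference

LOCUS_LENGTH = 12_000
VARIANT_POS = 6_000
EXONS = ((5_200, 5_350), (5_900, 6_150), (6_700, 6_850))
TARGET_EXON = 1
SHORT_AMPLICON = AmpliconDef.from_primers((5_650, 5_670), (6_330, 6_350))
LONG_AMPLICON = AmpliconDef.from_primers((700, 730), (11_170, 11_200))

# engineered codons of the central exon (codon c covers 5900+3c .. +3)
_ENGINEERED_CODONS = {
    21: "CCA",  # CCN = left guide PAM (NGG on the minus strand)
    22: "ATG",  # Met: no synonym — keeps the left seed single-sited
    23: "TGG",  # Trp: no synonym
    24: "GCA",  # Ala: third position 5974 is the left blocking site
    25: "TAC",  # keeps the blocking column clear of homopolymer runs
    33: "ATA",  # variant codon: pathogenic T at 6000, corrected allele ACA
    34: "GTT",  # bridging sites: third positions 6004..6022
    35: "GCT",
    36: "ACT",
    37: "CCT",
    38: "GGT",
    39: "GTA",
    40: "GCA",
    41: "GTT",  # Val: third position 6025 is the right blocking site
    42: "ATG",
    43: "TGG",
    44: "GAT",
    45: "GGT",  # supplies the GG of the right guide PAM at 6035/6036
}

# stop-free filler codons with mixed degeneracy
_FILLER_CODONS = (
    "GCT", "GTC", "ACC", "TCA", "CTG", "GAA", "AAC", "TGC",
    "GGA", "CAT", "ATC", "TTC", "CAG", "AGA", "GAC", "TAC",
)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def demo_sequence() -> str:
    rng = np.random.default_rng(_FILLER_SEED)
    seq = list(_random_dna(rng, LOCUS_LENGTH))
    for start, end in EXONS:
        codons = rng.integers(0, len(_FILLER_CODONS), (end - start) // 3 + 1)
        exon = "".join(_FILLER_CODONS[i] for i in codons)[: end - start]
        seq[start:end] = exon
    start = EXONS[TARGET_EXON][0]
    for c, codon in _ENGINEERED_CODONS.items():
        seq[start + 3 * c : start + 3 * c + 3] = codon
    return "".join(seq)


def demo_locus() -> ReferenceLocus:
    """The bundled reference locus (patient target allele)."""
    return ReferenceLocus(
        name="demo_locus",
        sequence=demo_sequence(),
        coordinate_origin=209_700_000,  # arbitrary genomic-scale offset
        exons=EXONS,
        cds_frame=0,
        pathogenic_variant=(VARIANT_POS, "T", "C"),
        short_amplicon=SHORT_AMPLICON,
        long_amplicon=LONG_AMPLICON,
    )


def demo_guide_pair(locus: ReferenceLocus | None = None) -> GuidePair:
    """The planted PAM-out nickase pair (nick offset 62 bp)."""
    locus = locus or demo_locus()
    seq = locus.sequence
    left = Guide(
        name="sgRNA1",
        protospacer=revcomp(seq[5_966:5_986]),
        pam_interval=(5_963, 5_966),
        strand="-",
        nick_position=5_969,
    )
    right = Guide(
        name="sgRNA2",
        protospacer=seq[6_014:6_034],
        pam_interval=(6_034, 6_037),
        strand="+",
        nick_position=6_031,
    )
    for g in (left, right):
        g.validate_against(seq)
    return GuidePair(left=left, right=right)


def demo_template(locus: ReferenceLocus | None = None,
                  bridging_level: str = "blocking") -> RepairTemplate:
    """The 132 nt / 40 bp-arm ssODN for the demo locus."""
    locus = locus or demo_locus()
    return design_template(
        locus,
        demo_guide_pair(locus),
        bridging_level=bridging_level,
        total_length=132,
        arm_length=40,
    )


# ---------------------------------------------------------------------------
# study-condition mixtures
# ---------------------------------------------------------------------------


def _correction_snv(locus: ReferenceLocus) -> PlannedSNV:
    pos, ref, alt = locus.pathogenic_variant
    return PlannedSNV(pos, ref, alt, "correction")


def het_baseline_mixture(locus: ReferenceLocus) -> MixtureSpec:
    """Unedited compound-het baseline: 50% pathogenic-T / 50% sibling-C."""
    return MixtureSpec(
        alleles=(
            AlleleSpec(name="target_T", weight=0.5),
            AlleleSpec(name="non_target_C", snvs=(_correction_snv(locus),), weight=0.5),
        )
    )


def editing_outcome_mixture(
    locus: ReferenceLocus, template: RepairTemplate
) -> tuple[MixtureSpec, dict[str, str]]:
    """Post-editing mixture emulating a dual-nickase HDR experiment.

    Fractions: perfect HDR 0.48, imperfect HDR 0.12, nick-site indels 0.18
    (split over a deletion and an insertion allele), unedited target allele
    0.11, non-target sibling allele 0.11.  Returns the mixture plus the
    read-level truth category of each allele.
    """
    correction = _correction_snv(locus)
    silent = template.silent_snvs
    right_blocking = next(
        s for s in silent if s.role == "blocking" and s.position > correction.position
    )
    alleles = (
        AlleleSpec(name="perfect_hdr", snvs=template.snvs, weight=0.48),
        AlleleSpec(name="imperfect_hdr", snvs=(correction, right_blocking), weight=0.12),
        AlleleSpec(name="nick_del20", indels=((6_020, -20),), weight=0.09),
        AlleleSpec(name="nick_ins9", indels=((5_969, "ACGTACGTA"),), weight=0.09),
        AlleleSpec(name="target_T", weight=0.11),
        AlleleSpec(name="non_target_C", snvs=(correction,), weight=0.11),
    )
    categories = {
        "perfect_hdr": "perfect_hdr",
        "imperfect_hdr": "imperfect_hdr",
        "nick_del20": "indel",
        "nick_ins9": "indel",
        "target_T": "unedited",
        "non_target_C": "unedited",
    }
    return MixtureSpec(alleles=alleles), categories


def deletion_mixture(locus: ReferenceLocus) -> MixtureSpec:
    """Long-amplicon mixture with three planted kilobase-scale deletions.

    The 6 kb allele removes both primers of the short genotyping amplicon
    (it evades standard genotyping); the 1.5 kb allele lies outside the
    short amplicon entirely; the 300 bp allele sits inside it.
    """
    return MixtureSpec(
        alleles=(
            AlleleSpec(name="unedited", weight=0.80),
            AlleleSpec(name="del_1p5k", deletion=(7_000, 8_500), weight=0.10),
            AlleleSpec(name="del_6k", deletion=(3_000, 9_000), weight=0.05),
            AlleleSpec(name="del_300", deletion=(5_850, 6_150), weight=0.05),
        )
    )


def toy_pam_out_locus() -> tuple[ReferenceLocus, int]:
    """A 200 bp toy locus with exactly one planted PAM-out pair, 66 bp apart.

    Returns the locus and the expected nick offset (66).  Background is an
    AT repeat, so the only minus-strand PAM is the planted CC and the only
    plus-strand PAM the planted GG.
    """
    seq = list("AT" * 100)
    seq[61] = seq[62] = "C"  # left PAM (CCN): guide at 64..84, nick 67
    seq[137] = seq[138] = "G"  # right PAM (NGG at 136): guide 116..136, nick 133
    sequence = "".join(seq)
    locus = ReferenceLocus(
        name="toy_pam_out",
        sequence=sequence,
        coordinate_origin=0,
        exons=((50, 150),),
        cds_frame=0,
        pathogenic_variant=(100, sequence[100], "G"),
        short_amplicon=AmpliconDef.from_primers((20, 40), (160, 180)),
        long_amplicon=AmpliconDef.from_primers((0, 20), (180, 200)),
    )
    return locus, 66
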