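# Methods

This note records the models, rules and numerical choices behind
`nickhdr`, the assumptions they rest on, and what the bundled synthetic
data can and cannot demonstrate.

## The experimental situation being modelled

A compound-heterozygous patient locus carries a pathogenic point variant on
one allele (the *target* allele) while the sibling allele is wild type at
that position.  Two Cas9 D10A nickase guides in PAM-out orientation nick
opposite strands on either side of the variant, and a short single-stranded
oligodeoxynucleotide (ssODN) templates homology-directed repair.  Readouts
are PCR amplicons sequenced on a long-read platform: a ~700 bp genotyping
amplicon, a ~10.5 kb amplicon for deletion surveillance, and a cDNA
amplicon across the exon carrying the variant.

Throughout the package, coordinates are 0-based, half-open and
locus-forward; genomic coordinates appear only at I/O boundaries through a
configured origin offset.  The reference sequence is the *patient target
allele* (pathogenic base present).  This choice makes every planned edit —
corrective, blocking, bridging — a forward substitution relative to the
reference, so one invariant (`ref_base` equals the locus base) covers all
planned SNVs, and it makes the unedited target allele align error-free.
The sibling allele is represented as the allele carrying only the
corrective base.

## Alignment

Reads are aligned semi-globally (read fully aligned, free end gaps on the
reference) with edlib under unit edit costs.  Two long-read realities shape
the layer above it:

* **Kilobase deletions are invisible to pairwise DP.**  Under any affine
  or unit gap cost that tolerates sequencing indels, a multi-kilobase gap
  costs more than letting the read tail run on as a ~75%-mismatch
  alignment, so no single DP pass recovers a 6 kb deletion.  Reads are
  therefore first anchored by exact, locus-unique 17-mers (sampled every
  10 bp), anchors are chained (longest increasing subsequence on reference
  position), and the chain is split wherever the alignment diagonal jumps
  by at least 50 bp (`sv_min_gap`).  Each colinear segment is aligned
  separately, and the breakpoint between segments is refined to base
  precision by scanning the read split point that minimises the summed
  edit distance of both flanks.  Single-segment chains fall through to a
  plain edlib call.
* **Identity must not punish real deletions.**  Identity is
  matches / aligned columns with deletion runs at or above `sv_min_gap`
  excluded from the denominator; otherwise every large-deletion read would
  fail the identity filter and the deletion spectrum would be empty by
  construction.

The full-length filter retains a read iff its aligned reference span
covers at least 90% of the amplicon interval *and* identity is at least
0.80 — both configurable and deliberately permissive for ~5–10% long-read
error.  Rejected reads are flagged with a reason code, never dropped
silently.  Reads may arrive on either strand; the reverse complement is
aligned when it anchors better, and all downstream coordinates are
locus-forward.  `N` bases mismatch everything and are never evidence.

### Column genotyping

Deciding whether a read carries a planned SNV by reading the single
aligned column is unreliable at long-read error rates: under unit costs,
an error *adjacent* to the column frequently admits a co-optimal alignment
that pairs the error base into the column (measured on the bundled
simulations, this tripled the apparent reversion rate at planned SNV
columns).  Each planned SNV is therefore genotyped by **local haplotype
re-alignment**: the read segment aligned to the column ±8 bp is compared by
edit distance against the reference window and against the same window
with the template base substituted; whichever haplotype explains the
segment strictly better wins, and ties are reported as ambiguous
(`other`).  Neighbouring planned SNVs inside the window mismatch both
haplotypes equally and cancel out of the comparison.  The same routine
genotypes template SNVs in cDNA reads against the transcript.

A related consequence of sequence-dependent alignment ambiguity: a planned
SNV whose reference or template base extends an adjacent homopolymer can
be silently converted to the other haplotype by a single indel error.  The
bundled demo locus deliberately keeps its engineered SNV columns clear of
homopolymer runs, as a real designer choosing among synonymous sites
would.

## Outcome classification

Per retained read, with the quantification window defaulting to
[left nick − 10, right nick + 10] (dual-nick processing affects the
inter-nick segment; indels touching the window boundary count):

1. *Template evidence*: at least one **silent** SNV at the template base
   and at least two template bases overall (corrective SNV included).
   Requiring two columns means a single error-mimicked column can never
   create a false HDR call; requiring a silent one encodes the fact that
   in a compound heterozygote the corrective base alone cannot distinguish
   a corrected allele from the sibling allele — reads whose only template
   base is the corrective one classify as `unedited`.  This is precisely
   why blocking/bridging SNVs make perfect HDR countable.
2. `perfect_hdr`: template evidence, no reference base remaining at any
   planned SNV (ambiguous columns are uninformative, not disqualifying),
   and no indel event in the window.
3. `imperfect_hdr`: template evidence with a remaining reference base or a
   window indel — partial template integration.
4. `indel`: a window indel event without template evidence (end-joining).
5. `unedited`: none of the above.

An *indel event* is a **net** indel length (|insertions − deletions| over
window ops) of at least `min_indel_len` = 5 bp.  Netting and summing are
both deliberate: aligners split one real event into pieces when the
inserted/deleted sequence partially matches the reference (summing
restores it), while dense substitution noise admits co-optimal balanced
ins/del pairs (netting cancels them).  The 5 bp floor means true 1–4 bp
end-joining indels are not countable — at 0.5% per-base indel error over
an ~86 bp window they are indistinguishable from noise on single reads,
and the dual-nickase events of interest (offset-scale deletions,
templated insertions) are larger.

Fractions are reported over retained reads with Wilson 95% intervals;
summaries under 10,000 retained reads are flagged low-coverage.  Per-SNV
incorporation is the template-base fraction among reads whose column is
unambiguously template or reference; ambiguous and uncovered columns are
excluded from the denominator, and an SNV with no informative coverage is
undefined (`None`), never 0.

## Template design

* **Pair enumeration** scans a window for CCN (left guide, minus strand)
  and NGG (right guide, plus strand) PAMs, keeps pairs whose nick-to-nick
  offset lies in the requested range with the variant strictly between the
  nicks, and sorts by distance from the offset-range midpoint.  Nicks sit
  between protospacer positions 17 and 18 (3 nt from the PAM).
* **Blocking SNVs** go to the first synonymous site in the guide's seed
  (the 10 protospacer bases nearest the PAM, most disruptive to Cas9
  recognition), falling back to the PAM GG; one per guide.
* **Bridging SNVs** are synonymous sites strictly between the corrective
  edit and the bridging guide's nick (the right guide by default), taken
  nearest-the-nick first: `low` = 1, `medium` = 2, `full` = all available.
* **Base choice** at any site prefers transitions, then transversions
  alphabetically, skipping any base that would create a new NGG
  overlapping either guide footprint (which would arm a new nick site).
  This makes the design a pure function of its inputs.
* **Geometry**: the oligo is centred on the corrective edit, with homology
  arms measured from the outermost planned SNV outward (default 40 bp).
  A requested total length must accommodate the arms or the design fails
  loudly.  The physical oligo strand is the complement of the bridging
  guide's non-target (protospacer) strand.
* Designs are verified end-to-end: each silent SNV individually, the
  combined haplotype against the corrected protein, and a re-nick check
  that the corrected sequence no longer matches either guide
  (protospacer+PAM exact match).

On the bundled demo locus the geometry yields a 132 nt oligo with exactly
40 bp arms at every bridging level.

## Synthetic data

The generator draws each read's source allele from the mixture weights
*renormalised over capturable alleles*: an allele is uncapturable for an
amplicon when a deletion removes primer-site bases or an insertion
interrupts a primer, which is the physical mechanism by which large
deletions evade genotyping.  Renormalising (rather than dropping draws)
keeps the read count exact; the capture report makes the bias explicit so
evasion arithmetic stays testable.

Errors are i.i.d. per base — substitutions 2%, insertions 0.25%, deletions
0.25% by default, geometric indel lengths (mean 1/0.85 ≈ 1.2, capped at
10 bp) — a deliberately simple stand-in for context-dependent,
homopolymer-biased Nanopore error.  Quality strings are constant
placeholders (Q12); the analysis is alignment-based and never reads them.
Identical seeds give byte-identical FASTQ output.

The canonical mixtures encode the study conditions: a 50:50 pathogenic-T /
sibling-C baseline; an editing-outcome mixture of 48% perfect HDR, 12%
imperfect HDR (corrective + proximal blocking SNV only), 18% nick-site
indels (a 20 bp deletion and a 9 bp insertion allele) and 11% + 11%
unedited/sibling; and a long-amplicon deletion mixture of 10% 1.5 kb, 5%
6 kb (removes both short-amplicon primers) and 5% 300 bp interior
deletion over an 80% unedited background.  cDNA simulations default to
40% exon inclusion with an independent per-read template-carrier flag.

What passing tests on this generator do **not** show: robustness to
context-dependent error, chimeric reads, PCR duplicates or jackpotting,
alignment to a full genome rather than a locus, or recovery of editing
outcomes the simulator does not emit (e.g. long templated insertions).

## Deletion profiling

Per-read deletions of at least 50 bp (separating kilobase events from
nick-site indels) are clustered greedily: an event joins a cluster when
its start and end each lie within 20 bp of the cluster's running median
breakpoints; clusters below 3 supporting reads are dropped.  All defaults
are exposed.  Clustering this way is idempotent and cannot merge alleles
more than the tolerance apart.  The size spectrum is read-weighted (a read
with several deletions counts once, by its largest, so categories sum to
one; all events still appear in the allele table), with an open-ended
final bin and default edges 50/200/500/1000/2000/5000 bp.  The evasion
fraction counts retained long reads whose deletion intersects either
primer of the short amplicon — a deletion strictly interior to the
amplicon is captured and contributes nothing.

## Statistics

Off-target screening tests, per candidate site, the 2×2 table
(edited-call vs clean) × (control vs edited) with a two-sided Fisher exact
test (exact at the near-zero counts expected), Bonferroni-corrected over
the number of sites; an "edited call" is any window indel (±10 bp around
the predicted nick, same net-length rule as on-target).  Editing is
declared only when the corrected p clears alpha *and* the edited rate
exceeds the control rate.  Group contrasts use the independent two-sample
*t*-test (Welch degrees of freedom on request); two zero-variance groups
with equal means give p = 1 by convention.

## Transcript stage

Isoform assignment compares each cDNA read's edit distance to the
exon-including and exon-skipping transcripts (better strand of each); the
winner must lead by at least 10 edit-distance units, else the read is
ambiguous, and must span the target exon (or the alternative junction)
±20 bp, else it is discarded as uninformative.  Inclusion is
included / (included + skipped) with a Wilson interval, undefined (not 0)
when nothing is assignable.  Template-SNV incorporation in mRNA is
restricted to exon-including reads and uses the same local-haplotype
genotyping as the DNA side, so the genomic and transcript estimates are
methodologically comparable.  ddPCR quantification enters as pre-computed
concentrations (droplet Poisson calling is instrument-side);
normalisation is target / √(hk1 × hk2), and the monoallelic expectation
is the analytic product `f_genomic × n_target / n_total` — for a
heterozygous variant corrected in 54% of reads, re-expression from 27% of
all alleles.

## Problem sizes and determinism

The bundled simulations use 10,000 short-amplicon reads, 5,000
long-amplicon reads and 10,000 cDNA reads — sizes at which binomial
3-sigma bands are a few tenths of a percentage point, matching the
granularity of the questions asked of them.  All stochastic stages take
explicit integer seeds; the demo locus itself is a fixed reference object
built from an internal constant seed and is identical in every session.

## Known limitations

* The error model is i.i.d.; real Nanopore error is strongly
  context-dependent, and homopolymer-adjacent planned SNVs (avoided in the
  demo locus, flagged nowhere else) remain a genotyping hazard on real
  data.
* Sub-5 bp end-joining indels are not counted as editing events on single
  reads; experiments where 1–2 bp indels dominate need a
  consensus-polishing step upstream of this package.
* Breakpoint clustering is greedy in read order; pathological mixtures of
  closely spaced deletion alleles (< 20 bp apart) can split or merge
  depending on arrival order.
* Off-target analysis assumes per-site mini-loci and indel-based events
  only; it does not model SNV-level off-target edits, translocations or
  other rearrangements.
* Isoform assignment knows exactly two isoforms; novel junctions are
  forced into ambiguous/discarded rather than discovered.
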