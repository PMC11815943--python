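"""Independent reference implementations used only as test oracles.

Each oracle is deliberately written from first principles (tables, naive
loops, exhaustive enumeration, full dynamic programming) and shares no code
with the package paths it checks.
"""

from __future__ import annotations

import math

import numpy as np

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def translate(cds: str) -> str:
    return "".join(
        CODON_TABLE[cds[i : i + 3]] for i in range(0, len(cds) - len(cds) % 3, 3)
    )


def is_silent(locus, position: int, alt: str) -> bool:
    """Translate-both-and-compare, by table lookup, over the exon chain."""
    seq = locus.sequence
    edited = seq[:position] + alt + seq[position + 1 :]
    def cds(s):
        joined = "".join(s[a:b] for a, b in locus.exons)
        return joined[locus.cds_frame:]
    return translate(cds(seq)) == translate(cds(edited))


def semiglobal_distance(query: str, target: str) -> int:
    """Unit-cost edit distance of query aligned as an infix of target
    (free gaps at both target ends), by full dynamic programming."""
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    t = np.frombuffer(target.encode(), dtype=np.uint8)
    m = len(t)
    idx = np.arange(m + 1)
    prev = np.zeros(m + 1, dtype=np.int64)  # free start on target
    for qi in q:
        sub = prev[:-1] + (t != qi)
        up = prev[1:] + 1
        cur = np.empty(m + 1, dtype=np.int64)
        cur[0] = prev[0] + 1
        cur[1:] = np.minimum(sub, up)
        # left-to-right horizontal relaxation as a prefix scan
        cur = np.minimum.accumulate(cur - idx) + idx
        prev = cur
    return int(prev.min())


def naive_apply_edits(sequence: str, snvs, indels, deletion) -> str:
    """Apply edits one at a time, recomputing the shift for each edit."""
    events = []
    for snv in snvs:
        events.append(("snv", snv.position, snv.alt_base))
    for pos, edit in indels:
        if isinstance(edit, str):
            events.append(("ins", pos, edit))
        else:
            events.append(("del", pos, -edit))
    if deletion is not None:
        events.append(("del", deletion[0], deletion[1] - deletion[0]))
    out = sequence
    shift = 0
    for kind, pos, payload in sorted(events, key=lambda e: e[1]):
        p = pos + shift
        if kind == "snv":
            out = out[:p] + payload + out[p + 1 :]
        elif kind == "ins":
            out = out[:p] + payload + out[p:]
            shift += len(payload)
        else:
            out = out[:p] + out[p + payload :]
            shift -= payload
    return out


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by hypergeometric enumeration (math.comb)."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = math.comb(n, c1)
    lo = max(0, c1 - r2)
    hi = min(c1, r1)
    probs = {
        k: math.comb(r1, k) * math.comb(r2, c1 - k) / denom for k in range(lo, hi + 1)
    }
    p_obs = probs[a]
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12)))


def pam_out_pairs_bruteforce(sequence: str, variant: int, window, offset_range):
    """All PAM-out nick pairs straddling the variant, by direct scanning.

    Returns a set of (left_nick, right_nick) boundary coordinates, with the
    left guide on the minus strand (CCN on the forward strand, protospacer
    3' of it) and the right guide on the plus strand (NGG, protospacer 5').
    """
    lo, hi = window
    left_nicks = []
    right_nicks = []
    for p in range(lo, hi - 2):
        triplet = sequence[p : p + 3]
        if triplet.startswith("CC") and p + 23 <= hi:
            # minus-strand guide: protospacer occupies p+3 .. p+23; nick
            # falls 3 nt from the PAM on the protospacer -> boundary p+6
            left_nicks.append(p + 6)
        if triplet[1:] == "GG" and p - 20 >= lo:
            # plus-strand guide: protospacer p-20 .. p; nick boundary p-3
            right_nicks.append(p - 3)
    out = set()
    for ln in left_nicks:
        for rn in right_nicks:
            if ln < variant < rn and offset_range[0] <= rn - ln <= offset_range[1]:
                out.add((ln, rn))
    return out
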