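"""Off-target comparison statistics and the group-contrast t-test.

The off-target screen compares, per candidate site, the rate of reads
carrying an in-window indel between a control (unedited) and an edited
sample, with a two-sided Fisher exact test and Bonferroni correction over
the number of sites.  Editing is declared only when the corrected p-value
clears alpha *and* the edited sample's rate exceeds the control's.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from scipy import stats as sp_stats

from .align import AlignmentResult
from .errors import InputError


@dataclass(frozen=True)
class SiteCounts:
    """Retained reads and edited-call counts at one amplicon site."""

    n: int
    edited: int

    def __post_init__(self) -> None:
        if not 0 <= self.edited <= self.n:
            raise InputError("edited calls must lie in [0, n]")


@dataclass
class SiteComparison:
    site_id: str
    n_control: int
    n_edited: int
    edited_calls_control: int
    edited_calls_edited: int
    raw_p: float
    corrected_p: float
    verdict: str


def count_window_edits(
    alns: Sequence[AlignmentResult],
    nick_position: int,
    flank: int = 10,
    min_indel_len: int = 5,
) -> SiteCounts:
    """Edited-read count at an off-target site: any indel of at least
    ``min_indel_len`` overlapping nick_position +/- flank."""
    retained = [a for a in alns if a.retained]
    edited = sum(
        1
        for a in retained
        if a.indels_overlapping(nick_position - flank, nick_position + flank,
                                min_indel_len)
    )
    return SiteCounts(n=len(retained), edited=edited)


def compare_off_targets(
    control: Mapping[str, SiteCounts],
    edited: Mapping[str, SiteCounts],
    alpha: float = 0.05,
) -> list[SiteComparison]:
    """Per-site Fisher exact control-vs-edited comparison, Bonferroni
    corrected over the number of sites."""
    if set(control) != set(edited):
        raise InputError(
            "control and edited conditions must cover the same site set"
        )
    if not control:
        raise InputError("no sites to compare")
    m = len(control)
    out = []
    for site_id in sorted(control):
        c, e = control[site_id], edited[site_id]
        table = [[c.edited, c.n - c.edited], [e.edited, e.n - e.edited]]
        raw_p = float(sp_stats.fisher_exact(table, alternative="two-sided")[1])
        corrected = min(1.0, m * raw_p)
        rate_c = c.edited / c.n if c.n else 0.0
        rate_e = e.edited / e.n if e.n else 0.0
        verdict = (
            "editing_detected"
            if corrected < alpha and rate_e > rate_c
            else "no_editing_detected"
        )
        out.append(
            SiteComparison(
                site_id=site_id,
                n_control=c.n,
                n_edited=e.n,
                edited_calls_control=c.edited,
                edited_calls_edited=e.edited,
                raw_p=raw_p,
                corrected_p=corrected,
                verdict=verdict,
            )
        )
    return out


def two_sample_t(
    group_a: Sequence[float],
    group_b: Sequence[float],
    equal_var: bool = True,
) -> tuple[float, float, float]:
    """Independent two-sample t-test; returns (t, df, two-sided p).

    Welch degrees of freedom when ``equal_var`` is False.  Two groups with
    zero variance and equal means give p = 1 by convention.
    """
    a, b = list(group_a), list(group_b)
    if len(a) < 2 or len(b) < 2:
        raise InputError("each group needs at least 2 replicates")
    var_a = sp_stats.tvar(a) if len(set(a)) > 1 else 0.0
    var_b = sp_stats.tvar(b) if len(set(b)) > 1 else 0.0
    if var_a == 0.0 and var_b == 0.0:
        df = len(a) + len(b) - 2
        if math.isclose(sum(a) / len(a), sum(b) / len(b)):
            return 0.0, float(df), 1.0
        sign = 1.0 if sum(a) / len(a) > sum(b) / len(b) else -1.0
        return sign * math.inf, float(df), 0.0
    res = sp_stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.df), float(res.pvalue)


def write_comparison_tsv(comparisons: Sequence[SiteComparison], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "site_id\tn_control\tedited_control\tn_edited\tedited_edited\t"
            "raw_p\tcorrected_p\tverdict\n"
        )
        for c in comparisons:
            fh.write(
                f"{c.site_id}\t{c.n_control}\t{c.edited_calls_control}\t"
                f"{c.n_edited}\t{c.edited_calls_edited}\t{c.raw_p:.6g}\t"
                f"{c.corrected_p:.6g}\t{c.verdict}\n"
            )
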