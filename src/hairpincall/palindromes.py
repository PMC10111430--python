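"""Genome-wide DNA palindrome (inverted repeat) detection and site overlap.

A DNA palindrome here is an interval whose left arm is the exact reverse
complement of its right arm, with an optional unpaired loop between them. As
single-stranded DNA such a region can self-anneal into a hairpin: arm
positions form the double-stranded stem (shielded from bisulfite, which
deaminates only ssDNA) while loop positions stay single-stranded and convert
normally. Methylation calls landing in stems are therefore candidate
false positives.

Detection is by center-and-extend: for every loop window of length
0..max_loop the arms are extended outward while bases pair, so every
reported palindrome is maximal (its arms cannot be extended). Structures
nested inside longer ones are then removed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from hairpincall.intersection import SiteKey, stringency_sweep, _as_key_sets
from hairpincall.sites_io import GenomeSequence

__all__ = [
    "Palindrome",
    "PalindromeAnnotation",
    "find_palindromes",
    "remove_nested",
    "length_quantiles",
    "annotate_sites",
    "overlap_stringency_table",
]

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True, order=True, slots=True)
class Palindrome:
    """An inverted-repeat interval, 1-based inclusive outer bounds."""

    chrom: str
    start: int
    end: int
    arm_len: int
    loop_len: int

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != 2 * self.arm_len + self.loop_len:
            raise ValueError("inconsistent palindrome geometry")

    @property
    def total_len(self) -> int:
        return self.end - self.start + 1

    @property
    def left_arm(self) -> tuple[int, int]:
        return (self.start, self.start + self.arm_len - 1)

    @property
    def right_arm(self) -> tuple[int, int]:
        return (self.end - self.arm_len + 1, self.end)

    def classify(self, pos: int) -> str:
        """'stem', 'loop' or 'outside' for a 1-based position."""
        if not self.start <= pos <= self.end:
            return "outside"
        if pos <= self.start + self.arm_len - 1 or pos >= self.end - self.arm_len + 1:
            return "stem"
        return "loop"


@dataclass(frozen=True, slots=True)
class PalindromeAnnotation:
    site: SiteKey
    status: str  # stem | loop | outside
    palindrome: Palindrome | None


def _pairs(a: str, b: str) -> bool:
    return _COMP.get(a) == b


def _scan_sequence(
    seq: str,
    chrom: str,
    min_length: int,
    min_arm: int,
    max_loop: int,
    mismatches: int,
) -> list[Palindrome]:
    n = len(seq)
    best: dict[tuple[int, int], int] = {}  # (start0, end0) -> max arm_len
    for loop in range(0, max_loop + 1):
        # loop window is seq[c : c+loop]; arms extend outward from its edges
        for c in range(1, n - loop):
            left = c - 1
            right = c + loop
            arm = 0
            budget = mismatches
            while left >= 0 and right < n:
                if _pairs(seq[left], seq[right]):
                    arm += 1
                elif budget > 0 and arm > 0:
                    budget -= 1
                    arm += 1
                else:
                    break
                left -= 1
                right += 1
            if arm < min_arm or 2 * arm + loop < min_length:
                continue
            key = (c - arm, c + loop + arm - 1)
            if best.get(key, -1) < arm:
                best[key] = arm
    out = []
    for (s0, e0), arm in best.items():
        total = e0 - s0 + 1
        out.append(Palindrome(chrom=chrom, start=s0 + 1, end=e0 + 1,
                              arm_len=arm, loop_len=total - 2 * arm))
    out.sort(key=lambda p: (p.start, p.end))
    return out


def find_palindromes(
    genome: GenomeSequence,
    min_length: int = 19,
    min_arm: int = 8,
    max_loop: int = 10,
    mismatches: int = 0,
    remove_nested_palindromes: bool = True,
) -> list[Palindrome]:
    """All maximal inverted repeats meeting the length constraints.

    With ``mismatches = 0`` (the default) arms are exact reverse
    complements; a positive budget allows that many mismatched pairs per
    arm during greedy extension (the outermost pair must always match).
    Nested palindromes are removed unless disabled. Sorted by (chrom, start).
    """
    if min_arm < 2:
        raise ValueError("min_arm must be >= 2")
    if min_length < 2 * min_arm:
        raise ValueError(
            f"min_length ({min_length}) must be >= 2 * min_arm ({2 * min_arm})"
        )
    result: list[Palindrome] = []
    for chrom in genome.names:
        pals = _scan_sequence(genome[chrom], chrom, min_length, min_arm,
                              max_loop, mismatches)
        if remove_nested_palindromes:
            pals = remove_nested(pals)
        result.extend(pals)
    return result


def remove_nested(palindromes: Sequence[Palindrome]) -> list[Palindrome]:
    """Drop every palindrome strictly contained in another on the same chromosome.

    Identical intervals are deduplicated (the one with the longer arms, i.e.
    smaller loop, is kept).
    """
    by_chrom: dict[str, list[Palindrome]] = {}
    for p in palindromes:
        by_chrom.setdefault(p.chrom, []).append(p)
    kept: list[Palindrome] = []
    for chrom in sorted(by_chrom):
        pals = sorted(by_chrom[chrom], key=lambda p: (p.start, -p.end, -p.arm_len))
        max_end = -1
        seen_interval = None
        for p in pals:
            if (p.start, p.end) == seen_interval:
                continue  # duplicate interval; the larger-arm one came first
            if p.end > max_end:
                kept.append(p)
                max_end = p.end
            seen_interval = (p.start, p.end)
    kept.sort(key=lambda p: (p.chrom, p.start, p.end))
    return kept


def length_quantiles(palindromes: Sequence[Palindrome]) -> pd.DataFrame:
    """Min/quartile/max summary of total lengths, per chromosome and overall."""
    if not palindromes:
        return pd.DataFrame(
            columns=["chrom", "n", "min", "q25", "median", "q75", "max"]
        )
    df = pd.DataFrame(
        {"chrom": [p.chrom for p in palindromes],
         "length": [p.total_len for p in palindromes]}
    )
    rows = []
    groups = [("all", df["length"])] + [
        (c, g["length"]) for c, g in df.groupby("chrom", sort=True)
    ]
    for name, lengths in groups:
        q = np.percentile(lengths, [0, 25, 50, 75, 100])
        rows.append({"chrom": name, "n": len(lengths), "min": q[0],
                     "q25": q[1], "median": q[2], "q75": q[3], "max": q[4]})
    return pd.DataFrame(rows)


def annotate_sites(
    sites: Iterable[SiteKey], palindromes: Sequence[Palindrome]
) -> list[PalindromeAnnotation]:
    """Label each site stem/loop/outside against nested-removed palindromes.

    A site overlapping several retained palindromes is assigned to the
    longest (ties broken by leftmost start).
    """
    by_chrom: dict[str, list[Palindrome]] = {}
    for p in palindromes:
        by_chrom.setdefault(p.chrom, []).append(p)
    out = []
    for site in sites:
        hits = [
            p for p in by_chrom.get(site.chrom, ())
            if p.start <= site.pos <= p.end
        ]
        if not hits:
            out.append(PalindromeAnnotation(site, "outside", None))
            continue
        best = max(hits, key=lambda p: (p.total_len, -p.start))
        out.append(PalindromeAnnotation(site, best.classify(site.pos), best))
    return out


def overlap_stringency_table(
    call_sets: Sequence,
    palindromes: Sequence[Palindrome],
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Palindrome overlap of shared mCs per replicate subset (size 2..k).

    For every subset of the replicates: the number of shared significant
    sites, how many lie inside a palindrome (stem or loop), and the percent.
    Percent is NaN for subsets with no shared sites.
    """
    sets = _as_key_sets(call_sets)
    sweep = stringency_sweep(sets, labels=labels)
    from itertools import combinations

    rows = []
    i = 0
    for size in range(2, len(sets) + 1):
        for idx in combinations(range(len(sets)), size):
            shared = sorted(set.intersection(*(sets[j] for j in idx)))
            ann = annotate_sites(shared, palindromes)
            in_pal = sum(1 for a in ann if a.status != "outside")
            pct = 100.0 * in_pal / len(shared) if shared else float("nan")
            rows.append({
                "subset": sweep.loc[i, "subset"],
                "size": size,
                "common_mC_count": len(shared),
                "in_palindrome_count": in_pal,
                "percent": pct,
            })
            i += 1
    return pd.DataFrame(rows)


def write_palindromes_bed(palindromes: Sequence[Palindrome], path) -> None:
    """BED6+2 export: 0-based half-open interval plus arm and loop lengths."""
    with open(path, "w") as fh:
        for p in palindromes:
            fh.write(
                f"{p.chrom}\t{p.start - 1}\t{p.end}\tpalindrome\t0\t+"
                f"\t{p.arm_len}\t{p.loop_len}\n"
            )
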