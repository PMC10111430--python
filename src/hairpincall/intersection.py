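"""Cross-replicate intersection of significantly methylated sites.

A "robust" site is one called significant in every replicate methylome
considered. Sites absent from a replicate's mapping output count as
not-significant there: absence of evidence cannot support a robust call.
Strand is part of the site key; equality is exact, with no positional
tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import pandas as pd

from hairpincall.calling import MethylationCall

__all__ = [
    "SiteKey",
    "significant_sites",
    "intersect_significant",
    "stringency_sweep",
    "per_chromosome_counts",
]


@dataclass(frozen=True, order=True, slots=True)
class SiteKey:
    chrom: str
    pos: int
    strand: str


def significant_sites(calls: Iterable[MethylationCall]) -> set[SiteKey]:
    return {
        SiteKey(c.record.chrom, c.record.pos, c.record.strand)
        for c in calls
        if c.significant
    }


def _as_key_sets(call_sets: Sequence) -> list[set[SiteKey]]:
    out = []
    for cs in call_sets:
        items = list(cs)
        if items and isinstance(items[0], SiteKey):
            out.append(set(items))
        else:
            out.append(significant_sites(items))
    return out


def intersect_significant(call_sets: Sequence) -> list[SiteKey]:
    """Sites significant in every input set, sorted by (chrom, pos, strand).

    Each element of ``call_sets`` may be a collection of MethylationCall or
    of SiteKey.
    """
    if len(call_sets) < 2:
        raise ValueError("need at least two call sets to intersect")
    sets = _as_key_sets(call_sets)
    shared = set.intersection(*sets)
    return sorted(shared)


def stringency_sweep(call_sets: Sequence, labels: Sequence[str] | None = None) -> pd.DataFrame:
    """Shared significant-site count for every subset of replicates, size 2..k.

    Subsets are enumerated in deterministic order (by size, then by index
    combination). Returns a DataFrame with columns subset, size, shared_count.
    """
    if len(call_sets) < 2:
        raise ValueError("need at least two call sets")
    sets = _as_key_sets(call_sets)
    if labels is None:
        labels = [f"set{i + 1}" for i in range(len(sets))]
    rows = []
    for size in range(2, len(sets) + 1):
        for idx in combinations(range(len(sets)), size):
            shared = set.intersection(*(sets[i] for i in idx))
            rows.append({
                "subset": "+".join(labels[i] for i in idx),
                "size": size,
                "shared_count": len(shared),
            })
    return pd.DataFrame(rows)


def per_chromosome_counts(
    calls, chromosomes: Sequence[str] | None = None
) -> dict[str, int]:
    """Significant-site count keyed by chromosome (plus a 'total' entry)."""
    items = list(calls)
    if items and isinstance(items[0], SiteKey):
        keys = items
    else:
        keys = sorted(significant_sites(items))
    counts: dict[str, int] = {}
    if chromosomes is not None:
        for c in chromosomes:
            counts[c] = 0
    for k in keys:
        counts[k.chrom] = counts.get(k.chrom, 0) + 1
    counts["total"] = len(keys)
    return counts
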