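"""I/O and genome-derived annotation for per-cytosine bisulfite count data.

Coordinates are 1-based inclusive everywhere inside the package; BED export
converts to 0-based half-open. Minus-strand cytosines carry the position of
the C on the minus strand expressed in plus-strand coordinates, so printed
genomic positions can be used verbatim as keys.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

CONTEXTS = ("CG", "CHG", "CHH", "unknown")

#: methratio.py native column order (BSMAP's extraction script).
METHRATIO_COLUMNS = [
    "chr", "pos", "strand", "context", "ratio", "eff_CT_count",
    "C_count", "CT_count", "rev_G_count", "rev_GA_count",
    "CI_lower", "CI_upper",
]

MINIMAL_COLUMNS = ["chrom", "pos", "strand", "context", "meth_reads", "total_reads"]


class CountTableError(ValueError):
    """Malformed or inconsistent count-table input."""


@dataclass(frozen=True, order=True, slots=True)
class CytosineRecord:
    """One strand-aware cytosine with its bisulfite read counts.

    ``meth_reads`` is the number of unconverted (C) reads supporting
    methylation; ``unmeth_reads`` the number of converted (T) reads.
    """

    chrom: str
    pos: int
    strand: str
    context: str = "unknown"
    meth_reads: int = 0
    unmeth_reads: int = 0

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.meth_reads < 0 or self.unmeth_reads < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def coverage(self) -> int:
        return self.meth_reads + self.unmeth_reads

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.strand)


class GenomeSequence:
    """Per-chromosome nucleotide strings with 1-based inclusive lookup."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {name: str(seq).upper() for name, seq in sequences.items()}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeSequence":
        return cls({rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")})

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, seq in self._seqs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i:i + 70] + "\n")

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def __getitem__(self, name: str) -> str:
        return self._seqs[name]

    @property
    def names(self) -> list[str]:
        return list(self._seqs)

    def length(self, name: str) -> int:
        return len(self._seqs[name])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Subsequence for the 1-based inclusive interval [start, end]."""
        if start < 1 or end > len(self._seqs[chrom]) or start > end:
            raise IndexError(f"interval {chrom}:{start}-{end} out of bounds")
        return self._seqs[chrom][start - 1:end]


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def assign_context(genome: GenomeSequence, chrom: str, pos: int, strand: str) -> str:
    """Sequence context (CG / CHG / CHH) of a cytosine, read 5'->3' on its strand.

    H is any non-G base. Returns ``unknown`` when the two downstream bases are
    unavailable (contig end) or any base involved is N.
    """
    seq = genome[chrom]
    n = len(seq)
    if strand == "+":
        base = seq[pos - 1]
        if base != "C":
            raise ValueError(f"{chrom}:{pos}(+) is {base}, not C")
        if pos + 2 > n:
            return "unknown"
        nxt, nxt2 = seq[pos], seq[pos + 1]
    else:
        base = seq[pos - 1]
        if base != "G":  # C on the minus strand appears as G on the plus strand
            raise ValueError(f"{chrom}:{pos}(-) is {reverse_complement(base)}, not C")
        if pos - 2 < 1:
            return "unknown"
        nxt = reverse_complement(seq[pos - 2])
        nxt2 = reverse_complement(seq[pos - 3])
    if "N" in (nxt, nxt2):
        return "unknown"
    if nxt == "G":
        return "CG"
    if nxt2 == "G":
        return "CHG"
    return "CHH"


def gc_window(genome: GenomeSequence, chrom: str, pos: int, flank: int = 100) -> float:
    """Percent G+C in the window of ``flank`` bp either side of ``pos``.

    The site base is included, so the full window is ``2*flank + 1`` bp
    (201 bp at the default). Windows running off a contig end are truncated.
    """
    n = genome.length(chrom)
    start = max(1, pos - flank)
    end = min(n, pos + flank)
    window = genome.fetch(chrom, start, end)
    return 100.0 * (window.count("G") + window.count("C")) / len(window)


def _records_from_frame(df: pd.DataFrame, path: str) -> list[CytosineRecord]:
    records = []
    for row in df.itertuples(index=True):
        line_no = row.Index + 2  # 1-based, after header
        try:
            pos = int(row.pos)
            meth = int(row.meth_reads)
            total = int(row.total_reads)
        except (TypeError, ValueError) as exc:
            raise CountTableError(f"{path}: malformed row at line {line_no}: {exc}") from None
        if total < meth:
            raise CountTableError(
                f"{path}: line {line_no}: total_reads {total} < meth_reads {meth}"
            )
        context = str(row.context)
        if context not in CONTEXTS:
            context = "unknown"
        try:
            rec = CytosineRecord(
                chrom=str(row.chrom), pos=pos, strand=str(row.strand),
                context=context, meth_reads=meth, unmeth_reads=total - meth,
            )
        except ValueError as exc:
            raise CountTableError(f"{path}: line {line_no}: {exc}") from None
        records.append(rec)
    records.sort(key=lambda r: r.key)
    seen: set[tuple[str, int, str]] = set()
    for rec in records:
        if rec.key in seen:
            raise CountTableError(f"{path}: duplicate site {rec.key}")
        seen.add(rec.key)
    return records


def read_count_table(
    path: str | Path,
    dialect: str = "minimal",
    use_eff_ct: bool = False,
) -> list[CytosineRecord]:
    """Read a per-cytosine count table.

    ``minimal`` dialect: columns chrom, pos, strand, context, meth_reads,
    total_reads. ``methratio`` (BSMAP methratio.py output): methylated count
    = C_count, denominator = CT_count; set ``use_eff_ct`` to use the
    effective-CT-corrected denominator instead (rounded to nearest read).
    """
    path = str(path)
    if dialect in ("minimal",):
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        missing = [c for c in MINIMAL_COLUMNS if c not in df.columns]
        if missing:
            raise CountTableError(f"{path}: missing columns {missing}")
        return _records_from_frame(df[MINIMAL_COLUMNS], path)
    if dialect in ("methratio", "bsmap-methratio"):
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        missing = [c for c in ("chr", "pos", "strand", "context", "C_count", "CT_count") if c not in df.columns]
        if missing:
            raise CountTableError(f"{path}: missing methratio columns {missing}")
        denom = "eff_CT_count" if use_eff_ct else "CT_count"
        out = pd.DataFrame({
            "chrom": df["chr"],
            "pos": df["pos"],
            "strand": df["strand"],
            "context": df["context"],
            "meth_reads": df["C_count"],
            "total_reads": df[denom].astype(float).round().astype(int) if use_eff_ct else df[denom],
        })
        return _records_from_frame(out, path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_count_table(records: Iterable[CytosineRecord], path: str | Path) -> None:
    """Write records in the minimal dialect (round-trips read_count_table)."""
    df = pd.DataFrame(
        [
            (r.chrom, r.pos, r.strand, r.context, r.meth_reads, r.coverage)
            for r in records
        ],
        columns=MINIMAL_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def annotate_contexts(
    records: Sequence[CytosineRecord], genome: GenomeSequence
) -> list[CytosineRecord]:
    """Replace each record's context with the genome-derived one."""
    return [
        replace(r, context=assign_context(genome, r.chrom, r.pos, r.strand))
        for r in records
    ]


def write_calls(calls, path: str | Path, format: str = "TSV") -> None:
    """Write methylation calls as TSV (round-trippable) or BED.

    BED intervals are 0-based half-open; the score column carries the
    methylation ratio scaled to 0-1000, the name column the context.
    """
    rows = []
    if format.upper() == "TSV":
        for c in calls:
            r = c.record
            rows.append((r.chrom, r.pos, r.strand, r.context, r.meth_reads,
                         r.coverage, c.ratio, c.ci_lower, c.ci_upper,
                         c.p_raw, c.q_adj, int(c.significant)))
        df = pd.DataFrame(rows, columns=MINIMAL_COLUMNS + [
            "ratio", "ci_lower", "ci_upper", "p_raw", "q_adj", "significant"])
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    elif format.upper() == "BED":
        with open(path, "w") as fh:
            for c in calls:
                r = c.record
                score = int(round(1000 * c.ratio)) if r.coverage else 0
                fh.write(f"{r.chrom}\t{r.pos - 1}\t{r.pos}\t{r.context}\t{score}\t{r.strand}\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_calls(path: str | Path):
    """Read calls written by :func:`write_calls` in TSV format."""
    from hairpincall.calling import MethylationCall

    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    calls = []
    for row in df.itertuples():
        rec = CytosineRecord(
            chrom=str(row.chrom), pos=int(row.pos), strand=str(row.strand),
            context=str(row.context), meth_reads=int(row.meth_reads),
            unmeth_reads=int(row.total_reads) - int(row.meth_reads),
        )
        calls.append(MethylationCall(
            record=rec, ratio=float(row.ratio),
            ci_lower=float(row.ci_lower), ci_upper=float(row.ci_upper),
            p_raw=float(row.p_raw), q_adj=float(row.q_adj),
            significant=bool(row.significant),
        ))
    return calls
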