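"""Synthetic WGBS count-data generator with hairpin-stem protection.

The generator emulates the statistical structure of a deep-coverage
bisulfite experiment on a very AT-rich genome with essentially no true
methylation:

* background bases i.i.d. with AT fraction 0.77 (genome-wide GC ~ 23%),
* planted non-overlapping palindromes 19-80 bp with exact
  reverse-complement arms,
* per-cytosine depth from a negative binomial (near-Poisson by default)
  around 30x,
* a per-read conversion-failure probability epsilon ~ 0.005 (conversion
  rates of 99.3-99.5%),
* per-read escape from conversion with probability rho ~ 0.30 at
  palindrome *stem* cytosines (hairpin protection), never at loop
  cytosines,
* an unmethylated ~48-kb spike-in sequence observed with pi = epsilon.

Per cytosine the unconverted-read count is Binomial(depth, pi) with

    pi = mu + (1 - mu) * (epsilon + (1 - epsilon) * rho * [stem])

where mu is the true methylation level (zero by default). Protection acts
per read: each read's molecule independently escapes conversion, which
yields the partial methylation ratios (~0.14-0.5) seen at hairpin stems
rather than all-or-nothing protection.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from hairpincall import calling, intersection, palindromes as pal_mod
from hairpincall.sites_io import (
    CytosineRecord,
    GenomeSequence,
    reverse_complement,
    write_count_table,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimResult",
    "generate_genome",
    "generate_counts",
    "simulate_dataset",
    "end_to_end_recovery",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulator (defaults mirror the experiment)."""

    n_chromosomes: int = 6
    chrom_length: int = 100_000
    at_fraction: float = 0.77
    n_palindromes_per_chrom: int = 10
    palindrome_length_range: tuple[int, int] = (19, 80)
    loop_length_range: tuple[int, int] = (3, 9)
    mean_depth: float = 30.0
    depth_dispersion: float = 100.0  # NB size parameter; large = near-Poisson
    conversion_failure: float = 0.005
    stem_protection: float = 0.30
    true_methylation: Mapping[tuple[str, int, str], float] = field(default_factory=dict)
    n_replicates: int = 4
    spikein_length: int = 48_000
    spikein_gc: float = 0.50
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.conversion_failure <= 1.0
                and 0.0 <= self.stem_protection <= 1.0):
            raise ValueError("epsilon and rho must lie in [0, 1]")
        if self.palindrome_length_range[0] < 19:
            raise ValueError("palindrome lengths must be >= 19")


@dataclass
class SimTruth:
    """Ground-truth ledger: planted structures and per-position flags."""

    palindromes: list  # list[Palindrome]
    stem_positions: dict[str, set]  # chrom -> set of 1-based positions in arms
    loop_positions: dict[str, set]
    true_methylation: Mapping[tuple[str, int, str], float]

    def status(self, chrom: str, pos: int) -> str:
        if pos in self.stem_positions.get(chrom, ()):
            return "stem"
        if pos in self.loop_positions.get(chrom, ()):
            return "loop"
        return "outside"


@dataclass
class SimResult:
    genome: GenomeSequence
    spikein: GenomeSequence
    truth: SimTruth
    replicates: list  # list of list[CytosineRecord]
    spikein_counts: list  # list of list[CytosineRecord]
    config: SimConfig


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.array(["A", "C", "G", "T"]), size=n, p=probs)


def generate_genome(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[GenomeSequence, SimTruth]:
    """AT-rich background with planted exact-arm palindromes.

    Palindromes are placed at uniformly chosen non-overlapping loci (with a
    5-bp clearance so planted arms do not merge with neighbours).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    gc = 1.0 - config.at_fraction
    seqs: dict[str, str] = {}
    planted: list = []
    stem_pos: dict[str, set] = {}
    loop_pos: dict[str, set] = {}
    lo, hi = config.palindrome_length_range
    if config.n_palindromes_per_chrom * (hi + 10) > config.chrom_length:
        raise ValueError("requested palindrome mass exceeds chromosome length")
    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        bases = _random_bases(rng, config.chrom_length, gc)
        occupied: list[tuple[int, int]] = []
        stems: set[int] = set()
        loops: set[int] = set()
        for _ in range(config.n_palindromes_per_chrom):
            for _attempt in range(1000):
                total = int(rng.integers(lo, hi + 1))
                loop = int(rng.integers(config.loop_length_range[0],
                                        config.loop_length_range[1] + 1))
                if (total - loop) % 2:
                    loop += 1
                arm = (total - loop) // 2
                if arm < 8:
                    continue
                start0 = int(rng.integers(0, config.chrom_length - total))
                if any(s - 5 <= start0 <= e + 5 or s - 5 <= start0 + total - 1 <= e + 5
                       or (start0 <= s and start0 + total - 1 >= e)
                       for s, e in occupied):
                    continue
                left = _random_bases(rng, arm, gc)
                loop_seq = _random_bases(rng, loop, gc)
                right = np.array(list(reverse_complement("".join(left))))
                bases[start0:start0 + arm] = left
                bases[start0 + arm:start0 + arm + loop] = loop_seq
                bases[start0 + arm + loop:start0 + total] = right
                start1 = start0 + 1  # 1-based
                end1 = start0 + total
                planted.append(pal_mod.Palindrome(
                    chrom=chrom, start=start1, end=end1,
                    arm_len=arm, loop_len=loop,
                ))
                stems.update(range(start1, start1 + arm))
                stems.update(range(end1 - arm + 1, end1 + 1))
                loops.update(range(start1 + arm, end1 - arm + 1))
                occupied.append((start0, start0 + total - 1))
                break
        seqs[chrom] = "".join(bases)
        stem_pos[chrom] = stems
        loop_pos[chrom] = loops
    genome = GenomeSequence(seqs)
    truth = SimTruth(
        palindromes=sorted(planted),
        stem_positions=stem_pos,
        loop_positions=loop_pos,
        true_methylation=dict(config.true_methylation),
    )
    return genome, truth


_BASE_ORD = {"A": 0, "C": 1, "G": 2, "T": 3}


def _cytosine_sites(seq: str) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """1-based positions, strands and contexts of every cytosine on both strands."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_c = arr == ord("C")
    is_g = arr == ord("G")
    n = arr.size

    def ctx_plus(p0: np.ndarray) -> list[str]:
        out = []
        for p in p0:
            if p + 2 >= n:
                out.append("unknown")
            elif arr[p + 1] == ord("G"):
                out.append("CG")
            elif arr[p + 2] == ord("G"):
                out.append("CHG")
            else:
                out.append("CHH")
        return out

    def ctx_minus(p0: np.ndarray) -> list[str]:
        out = []
        for p in p0:
            if p - 2 < 0:
                out.append("unknown")
            elif arr[p - 1] == ord("C"):
                out.append("CG")
            elif arr[p - 2] == ord("C"):
                out.append("CHG")
            else:
                out.append("CHH")
        return out

    plus0 = np.flatnonzero(is_c)
    minus0 = np.flatnonzero(is_g)
    pos = np.concatenate([plus0, minus0]) + 1
    strands = np.array(["+"] * plus0.size + ["-"] * minus0.size)
    contexts = ctx_plus(plus0) + ctx_minus(minus0)
    order = np.lexsort((strands, pos))
    return pos[order], strands[order], [contexts[i] for i in order]


def _draw_depths(rng: np.random.Generator, n: int, config: SimConfig) -> np.ndarray:
    size = config.depth_dispersion
    p = size / (size + config.mean_depth)
    return rng.negative_binomial(size, p, size=n)


def generate_counts(
    genome: GenomeSequence,
    truth: SimTruth,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    spikein: GenomeSequence | None = None,
) -> tuple[list, list]:
    """Per-replicate count tables plus matched spike-in tables.

    Returns (replicates, spikein_counts): each a list of length
    ``config.n_replicates`` holding lists of CytosineRecord.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    eps = config.conversion_failure
    rho = config.stem_protection

    site_info = []
    for chrom in genome.names:
        pos, strands, contexts = _cytosine_sites(genome[chrom])
        stems = truth.stem_positions.get(chrom, set())
        stem_flag = np.array([p in stems for p in pos])
        mu = np.array([
            truth.true_methylation.get((chrom, int(p), s), 0.0)
            for p, s in zip(pos, strands)
        ])
        pi = mu + (1 - mu) * (eps + (1 - eps) * rho * stem_flag)
        site_info.append((chrom, pos, strands, contexts, pi))

    if spikein is None:
        spikein_sites = []
    else:
        spikein_sites = [
            (chrom, *_cytosine_sites(spikein[chrom]))
            for chrom in spikein.names
        ]

    replicates = []
    spike_tables = []
    for _ in range(config.n_replicates):
        records: list[CytosineRecord] = []
        for chrom, pos, strands, contexts, pi in site_info:
            depth = _draw_depths(rng, pos.size, config)
            meth = rng.binomial(depth, pi)
            records.extend(
                CytosineRecord(chrom=chrom, pos=int(p), strand=str(s),
                               context=c, meth_reads=int(m),
                               unmeth_reads=int(d - m))
                for p, s, c, m, d in zip(pos, strands, contexts, meth, depth)
            )
        replicates.append(records)

        spike_records: list[CytosineRecord] = []
        for chrom, pos, strands, contexts in spikein_sites:
            depth = _draw_depths(rng, pos.size, config)
            meth = rng.binomial(depth, eps)
            spike_records.extend(
                CytosineRecord(chrom=chrom, pos=int(p), strand=str(s),
                               context=c, meth_reads=int(m),
                               unmeth_reads=int(d - m))
                for p, s, c, m, d in zip(pos, strands, contexts, meth, depth)
            )
        spike_tables.append(spike_records)
    return replicates, spike_tables


def simulate_dataset(config: SimConfig) -> SimResult:
    """Full deterministic simulation: genome, spike-in, truth and counts."""
    rng = np.random.default_rng(config.seed)
    genome, truth = generate_genome(config, rng)
    spike_seq = "".join(_random_bases(rng, config.spikein_length, config.spikein_gc))
    spikein = GenomeSequence({"spikein": spike_seq})
    replicates, spike_tables = generate_counts(genome, truth, config, rng, spikein)
    return SimResult(genome=genome, spikein=spikein, truth=truth,
                     replicates=replicates, spikein_counts=spike_tables,
                     config=config)


def write_dataset(result: SimResult, outdir: str | Path) -> None:
    """Write FASTA + per-replicate count TSVs + spike-in TSVs + truth ledger."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.genome.to_fasta(outdir / "genome.fa")
    result.spikein.to_fasta(outdir / "spikein.fa")
    for i, (rep, spike) in enumerate(zip(result.replicates, result.spikein_counts), 1):
        write_count_table(rep, outdir / f"rep{i}.counts.tsv")
        write_count_table(spike, outdir / f"rep{i}.spikein.tsv")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("chrom\tstart\tend\tarm_len\tloop_len\n")
        for p in result.truth.palindromes:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.arm_len}\t{p.loop_len}\n")


def end_to_end_recovery(
    config: SimConfig,
    alpha: float = 0.05,
    min_coverage: int = 4,
    min_ci_lower: float = 0.05,
) -> dict:
    """Run calling -> intersection -> palindromes -> overlap on simulated data.

    Compares results against the ground-truth ledger and reports:

    * ``stem_precision`` / ``stem_recall`` of the full-stringency shared
      calls against the planted stem-cytosine set,
    * the overlap-stringency table (fraction of shared calls in detected
      palindromes per subset size),
    * per-replicate conversion-rate estimates and their true value.
    """
    result = simulate_dataset(config)
    call_sets = []
    conv_rates = []
    for rep, spike in zip(result.replicates, result.spikein_counts):
        conv = calling.estimate_conversion_rate(spike)
        conv_rates.append(conv.rate)
        call_sets.append(calling.call_methylation(
            rep, conv, min_coverage=min_coverage,
            min_ci_lower=min_ci_lower, alpha=alpha,
        ))
    shared = intersection.intersect_significant(call_sets)
    found = pal_mod.find_palindromes(result.genome)
    overlap = pal_mod.overlap_stringency_table(call_sets, found)

    truth = result.truth
    n_stem_shared = sum(
        1 for k in shared if truth.status(k.chrom, k.pos) == "stem"
    )
    stem_cytosines = 0
    for chrom in result.genome.names:
        seq = result.genome[chrom]
        stem_cytosines += sum(
            1 for p in truth.stem_positions.get(chrom, ())
            if seq[p - 1] in "CG"
        )
    report = {
        "n_shared_full_stringency": len(shared),
        "stem_precision": (n_stem_shared / len(shared)) if shared else float("nan"),
        "stem_recall": (n_stem_shared / stem_cytosines) if stem_cytosines else float("nan"),
        "overlap_table": overlap,
        "conversion_rate_estimates": conv_rates,
        "true_conversion_rate": 100.0 * (1.0 - config.conversion_failure),
        "per_replicate_significant": [
            len(intersection.significant_sites(cs)) for cs in call_sets
        ],
    }
    return report
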