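"""Per-cytosine methylation calling against a conversion-failure null.

The model: at a truly unmethylated cytosine every read is an independent
Bernoulli trial that fails to convert with probability ``1 - conversion_rate``
(estimated from an unmethylated spike-in genome). A site is called methylated
only if

* it is covered by at least ``min_coverage`` reads (default 4),
* the lower bound of the Wilson 95% score interval of its methylation
  ratio is at least ``min_ci_lower`` (default 0.05), and
* the one-sided binomial tail probability of its unconverted-read count
  under the conversion-failure null, adjusted for multiple testing across
  all tested sites, falls below ``alpha``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from hairpincall.sites_io import CytosineRecord

__all__ = [
    "ConversionEstimate",
    "MethylationCall",
    "methylation_ratio",
    "wilson_interval",
    "estimate_conversion_rate",
    "binomial_nonconversion_pvalue",
    "adjust_pvalues",
    "call_methylation",
    "genome_average_methylation",
    "methylation_level_histogram",
]


@dataclass(frozen=True, slots=True)
class ConversionEstimate:
    """Pooled bisulfite conversion-rate estimate from a spike-in control.

    ``rate`` is the percent of spike-in cytosine reads that converted
    (T / (C + T) x 100); ``failure_prob`` = 1 - rate/100 is the per-read
    nonconversion probability used as the null success probability.
    """

    t_count: int
    ct_count: int

    @property
    def rate(self) -> float:
        return 100.0 * self.t_count / self.ct_count

    @property
    def failure_prob(self) -> float:
        return 1.0 - self.t_count / self.ct_count


@dataclass(frozen=True, slots=True)
class MethylationCall:
    record: CytosineRecord
    ratio: float
    ci_lower: float
    ci_upper: float
    p_raw: float
    q_adj: float
    significant: bool


def methylation_ratio(meth_reads: int, unmeth_reads: int) -> float:
    """Fraction of reads supporting methylation, N_m / (N_m + N_nm)."""
    total = meth_reads + unmeth_reads
    if total <= 0:
        raise ValueError("zero coverage: ratio undefined")
    return meth_reads / total


def wilson_interval(
    meth_reads: int, total_reads: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion.

    Closed-form inversion of the score test; z is the two-sided normal
    quantile (1.959964 at 95%). Bounds are clamped to [0, 1].
    """
    if total_reads < 1:
        raise ValueError("total_reads must be >= 1")
    if not 0 <= meth_reads <= total_reads:
        raise ValueError("meth_reads must be in [0, total_reads]")
    z = stats.norm.ppf(1.0 - (1.0 - confidence) / 2.0)
    n = total_reads
    p = meth_reads / n
    denom = 1.0 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    lower = 0.0 if meth_reads == 0 else max(0.0, center - half)  # exact at k=0
    upper = 1.0 if meth_reads == total_reads else min(1.0, center + half)
    return lower, upper


def estimate_conversion_rate(
    spikein_records: Iterable[CytosineRecord],
) -> ConversionEstimate:
    """Pool converted/total reads over all spike-in cytosines."""
    t = ct = 0
    for rec in spikein_records:
        t += rec.unmeth_reads
        ct += rec.coverage
    if ct == 0:
        raise ValueError("spike-in has zero coverage: cannot estimate conversion rate")
    return ConversionEstimate(t_count=t, ct_count=ct)


def binomial_nonconversion_pvalue(
    meth_reads: int, total_reads: int, failure_prob: float
) -> float:
    """One-sided upper tail P(X >= meth | n=total, p=failure_prob), exact."""
    if not 0.0 <= failure_prob <= 1.0:
        raise ValueError("failure_prob must be in [0, 1]")
    if meth_reads > total_reads:
        raise ValueError("meth_reads exceeds total_reads")
    if meth_reads <= 0:
        return 1.0
    return float(stats.binom.sf(meth_reads - 1, total_reads, failure_prob))


def adjust_pvalues(p_values: Sequence[float], method: str = "BH") -> np.ndarray:
    """Multiple-testing adjustment: Benjamini-Hochberg step-up or Bonferroni."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    key = {"BH": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if key is None:
        raise ValueError(f"unknown method {method!r}")
    return multipletests(p, method=key)[1]


def call_methylation(
    records: Sequence[CytosineRecord],
    conversion: ConversionEstimate,
    min_coverage: int = 4,
    min_ci_lower: float = 0.05,
    alpha: float = 0.05,
    method: str = "BH",
    confidence: float = 0.95,
) -> list[MethylationCall]:
    """Call methylation at every input cytosine.

    Every record receives a call; ``significant`` requires coverage >=
    ``min_coverage``, Wilson lower bound >= ``min_ci_lower`` and adjusted
    binomial p < ``alpha``. The adjustment is computed over all sites
    meeting the coverage rule (the tested set).
    """
    eps = conversion.failure_prob
    meth = np.array([r.meth_reads for r in records], dtype=np.int64)
    cov = np.array([r.coverage for r in records], dtype=np.int64)
    covered = cov > 0

    ratio = np.zeros(len(records))
    np.divide(meth, cov, out=ratio, where=covered)

    # vectorized Wilson score interval (matches wilson_interval elementwise)
    z = stats.norm.ppf(1.0 - (1.0 - confidence) / 2.0)
    lo = np.zeros(len(records))
    up = np.zeros(len(records))
    n = np.where(covered, cov, 1)
    p = ratio
    denom = 1.0 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    lo[covered] = np.clip(center - half, 0.0, 1.0)[covered]
    up[covered] = np.clip(center + half, 0.0, 1.0)[covered]

    # one-sided upper binomial tail; P(X >= 0) = 1 by convention
    p_raw = np.ones(len(records))
    pos = meth > 0
    p_raw[pos] = stats.binom.sf(meth[pos] - 1, cov[pos], eps)

    tested = cov >= min_coverage
    q = np.ones(len(records))
    if tested.any():
        q[tested] = adjust_pvalues(p_raw[tested], method=method)
    sig = tested & (lo >= min_ci_lower) & (q < alpha)

    return [
        MethylationCall(
            record=rec, ratio=float(ratio[i]), ci_lower=float(lo[i]),
            ci_upper=float(up[i]), p_raw=float(p_raw[i]), q_adj=float(q[i]),
            significant=bool(sig[i]),
        )
        for i, rec in enumerate(records)
    ]


def genome_average_methylation(
    records: Iterable[CytosineRecord], by_chromosome: bool = False
):
    """Genome-average methylation percent, 100 * sum(N_m) / sum(N_m + N_nm).

    Pooled over reads, not averaged over sites. With ``by_chromosome`` a dict
    chrom -> percent is returned alongside requiring per-chromosome coverage.
    """
    if by_chromosome:
        num: dict[str, int] = {}
        den: dict[str, int] = {}
        for rec in records:
            num[rec.chrom] = num.get(rec.chrom, 0) + rec.meth_reads
            den[rec.chrom] = den.get(rec.chrom, 0) + rec.coverage
        return {c: 100.0 * num[c] / den[c] for c in num if den[c] > 0}
    meth = total = 0
    for rec in records:
        meth += rec.meth_reads
        total += rec.coverage
    if total == 0:
        raise ValueError("zero total coverage")
    return 100.0 * meth / total


def methylation_level_histogram(
    calls: Sequence[MethylationCall],
    bin_width: float = 10.0,
    min_cov: int = 4,
    max_cov: int = 1000,
) -> dict[str, np.ndarray]:
    """Counts of significant mCs per ratio bin (percent) per context.

    Sites outside the [min_cov, max_cov] coverage band are excluded. Bins are
    (0,10], (10,20], ..., with ratio-0 sites (none among significant calls)
    falling in the first bin.
    """
    n_bins = int(math.ceil(100.0 / bin_width))
    hist = {ctx: np.zeros(n_bins, dtype=int) for ctx in ("CG", "CHG", "CHH")}
    for call in calls:
        rec = call.record
        if not call.significant or rec.context not in hist:
            continue
        if not min_cov <= rec.coverage <= max_cov:
            continue
        b = min(n_bins - 1, int(math.ceil(100.0 * call.ratio / bin_width)) - 1)
        hist[rec.context][max(b, 0)] += 1
    return hist
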