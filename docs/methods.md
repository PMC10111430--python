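# Methods

## Observation model

Each cytosine site on each strand is summarized by $(N_m, N_{nm})$:
unconverted (C) and converted (T) read counts. Reads are modeled as
independent Bernoulli trials; at a site with true methylation level
$\mu$, conversion-failure probability $\varepsilon$ and hairpin-stem
protection probability $\rho$, a read stays unconverted with probability

$$\pi = \mu + (1-\mu)\left(\varepsilon + (1-\varepsilon)\,\rho\,
\mathbf{1}[\text{stem}]\right).$$

Protection acts per read: each molecule independently re-anneals (or not)
during the bisulfite reaction, which is the simplest mechanism consistent
with the *partial* methylation ratios (roughly 0.14–0.5) observed at
hairpin stems; all-or-nothing protection would produce ratios of 0 or 1.
The per-molecule kinetics of re-annealing are not modeled; $\rho$ is a free
parameter, not an estimate of reaction chemistry.

## Calling rule

A site is significant iff all three hold:

1. **Coverage**: $N_m + N_{nm} \ge 4$ (per strand, per cytosine; the
   per-strand convention matches how strand-resolved count tables report
   sites).
2. **Effect floor**: the lower bound of the Wilson 95% score interval of
   $R_m = N_m/(N_m+N_{nm})$ is $\ge 0.05$. The Wilson interval is computed
   closed-form with $z = \Phi^{-1}(0.975) = 1.959964$; the $k=0$ lower and
   $k=n$ upper bounds are pinned to exactly 0 and 1 (they are exact
   algebraically; pinning removes floating-point residue).
3. **Test**: the exact one-sided binomial tail
   $P(X \ge N_m \mid n, \varepsilon)$, adjusted over all coverage-eligible
   sites of the replicate, is $< \alpha = 0.05$. Benjamini–Hochberg is the
   default adjustment; Bonferroni is available. The test is one-sided
   because the null is pure conversion failure and only an excess of
   unconverted reads is evidence of anything.

$\varepsilon$ is estimated per replicate by pooling all spike-in cytosines
($1 - \mathrm{T}/\mathrm{CT}$); per-site estimates at realistic spike-in
depths are far too noisy.

The genome-average methylation level is read-pooled,
$100\cdot\sum N_m / \sum(N_m+N_{nm})$, not a mean of per-site ratios, so
deeply covered sites carry proportionally more weight.

## Robust-site intersection

Replicate call sets are intersected on the exact (chromosome, position,
strand) triple; strand is part of the key because opposite-strand cytosines
at nearby coordinates are distinct molecules. A site absent from one
replicate's mapping output is treated as not significant there — absence of
evidence cannot support a robust call. The stringency sweep enumerates
every subset of replicates of size 2..k; intersection is monotone
non-increasing in subset size by construction.

## Palindrome detection

A palindrome is an interval whose left arm is the exact reverse complement
of its right arm, separated by a loop of $\ge 0$ unpaired bases. Detection
is center-and-extend: for every loop window of length $0..\texttt{max\_loop}$
arms are extended outward while bases pair, so every reported structure is
maximal (arms cannot be extended outward); identical intervals reachable
from several loop widths are collapsed keeping the longest arms. Structures
strictly contained in another on the same chromosome are then removed.

Defaults: `min_length=19`, `min_arm=8`, `max_loop=10`, exact arms
(`mismatches=0`). The 19-bp floor is the conventional minimum for a stable
hairpin-forming repeat; an unbounded loop would make every sequence
trivially palindromic, so a finite loop cap is required for a sane
definition and 10 bp keeps the loop shorter than the shortest admissible
arm pair. The genome-wide census is sensitive to these parameters, which is
why they are all exposed (see `scripts/ax4_palindrome_scan.py`); no census
count is asserted by the tests. A mismatch budget per arm is accepted but
off by default; with mismatches the extension is greedy and arms are no
longer guaranteed minimal-energy structures.

Site classification: arm positions are *stem*, positions strictly between
the arms are *loop*, everything else *outside*. A site covered by several
retained palindromes is assigned to the longest one. Even-length perfect
palindromes have an empty loop.

The implementation is verified against an independent anti-diagonal
enumeration oracle (all arm pairs of an interval lie on one anti-diagonal;
the maximal arm is a run length of complementary pairs) — a different
decomposition of the same definition — with exact agreement required on
randomized AT-rich sequences.

## BSP statistics

Per-site clone frequency is $100\cdot k/n$ over clones. Conditions are
compared with a chi-square goodness-of-fit test: expected methylated clones
$= n_{obs}\cdot p_{ref}$, two cells (methylated / converted), 1 df, no
continuity correction. This construction — observed condition against the
reference condition's frequency — is the one that treats one condition as
the baseline; a 2×2 independence test answers a different question and
gives different statistics. The reference proportion must lie strictly in
(0,1) or the expected counts degenerate.

For the cross-dataset comparison, each site's methylation ratios across the
available datasets (WGBS replicates and both BSP assays) are treated as
independent observations in a one-way ANOVA with sites as groups, followed
by Tukey HSD at family level 0.05. Treating datasets as independent
replicates is a modeling simplification: the datasets share biology but not
sampling, and the ANOVA is used as a screening contrast, not a generative
model.

## Depth-based knockout verification

Per-base depth tracks (zero-coverage positions included) summarize a gene
interval by median and mean; the verdict is *absent* iff the gene median is
less than 10% of the chromosome median. The observed separation between a
deleted gene (ratio below 0.01) and an intact one (ratio near 0.9) is two
orders of magnitude, so the threshold's exact placement is uncritical; it
is configurable.

## Synthetic-data generator

The generator emulates the study conditions: 6 chromosomes × 100 kb of
i.i.d. bases at AT fraction 0.77; 10 planted, non-overlapping palindromes
per chromosome with total lengths uniform on 19–80 bp and loops 3–9 bp;
per-cytosine depth negative binomial with mean 30 (dispersion parameter 100,
i.e. near-Poisson, configurable); $\varepsilon = 0.005$ (conversion rate
99.5%, within the 99.29–99.53% replicate range); $\rho = 0.30$ (within the
0.138–0.5 ratio range at hairpin stems); zero true methylation; 4
replicates; a separate 48-kb, 50% GC unmethylated spike-in. All outputs are
byte-deterministic given the seed.

What it does **not** emulate: read-level artifacts (PCR duplicates,
sequencing errors, mapping bias), strand-specific conversion chemistry,
overdispersion of nonconversion beyond binomial, genomic composition
structure (repeats, coding/non-coding GC gradients), or imperfect/bulged
hairpins. Passing tests therefore demonstrate the statistical machinery and
the structural-false-positive mechanism, not robustness to alignment or
library artifacts in real data.

Test and acceptance problem sizes are scaled to the desk: typically 1–2
chromosomes of 15–25 kb (≈ 9–12 k cytosine sites), 218 kb (≈ 50 k sites)
for the false-positive-rate checks, and 100 seeded repetitions of a small
spike-in for interval-coverage checks. The genome-scale replicate counts of
a real experiment require the original sequencing data and an upstream
aligner, and are out of scope here.

## Numerical and design notes

* Coordinates are 1-based inclusive throughout; BED export converts to
  0-based half-open. Minus-strand cytosines carry plus-strand coordinates,
  so published positions are usable verbatim as keys.
* The methratio dialect takes methylated count = C_count and denominator =
  CT_count, matching the $T/(C+T)$ conversion formula; the
  effective-CT-corrected denominator is available behind a flag (rounded to
  the nearest read).
* Ratios and bounds are compared to printed values after rounding
  half-away-from-zero to the printed precision.
* GC windows include the site base (201 bp for flank 100) and truncate at
  contig ends (percent of the truncated length).
* Binomial tails are exact (`scipy.stats.binom.sf`), never a normal
  approximation, and are cross-checked against term-by-term summation.
* Degenerate inputs: zero-coverage sites receive a non-significant call
  with ratio 0 and $p = 1$; an all-identical-ratio ANOVA reports $F = 0$
  with no significant pairs; empty palindrome sets yield empty summaries.
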