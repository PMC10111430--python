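"""Genome-wide palindrome census for a locally available reference assembly.

The genome-wide palindrome count is sensitive to the scan parameters
(minimum total length, minimum arm, loop cap), which are therefore exposed
here. Given a local copy of a reference FASTA (e.g. the six main AX4
chromosomes), this reports the census, the length quantiles and, optionally,
the GC window at sites of interest:

    python scripts/ax4_palindrome_scan.py genome.fa --min-length 19 \
        --min-arm 8 --max-loop 10 --gc-site chr4:2524803
"""

from __future__ import annotations

import argparse

from hairpincall.palindromes import find_palindromes, length_quantiles
from hairpincall.sites_io import GenomeSequence, gc_window


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("fasta", help="reference genome FASTA (local file)")
    parser.add_argument("--min-length", type=int, default=19)
    parser.add_argument("--min-arm", type=int, default=8)
    parser.add_argument("--max-loop", type=int, default=10)
    parser.add_argument("--gc-site", action="append", default=[],
                        help="chrom:pos to report the 201-bp GC window for")
    args = parser.parse_args()

    genome = GenomeSequence.from_fasta(args.fasta)
    pals = find_palindromes(
        genome, min_length=args.min_length, min_arm=args.min_arm,
        max_loop=args.max_loop,
    )
    print(f"palindromes: {len(pals)} "
          f"(min_length={args.min_length}, min_arm={args.min_arm}, "
          f"max_loop={args.max_loop})")
    print(length_quantiles(pals).to_string(index=False))
    for spec in args.gc_site:
        chrom, pos = spec.split(":")
        pct = gc_window(genome, chrom, int(pos), flank=100)
        print(f"GC window {spec}: {pct:.2f}%")


if __name__ == "__main__":
    main()
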