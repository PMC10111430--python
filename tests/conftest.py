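"""Shared fixtures: printed-count fixtures and small simulated datasets."""

import pytest

from hairpincall.intersection import SiteKey
from hairpincall.simulate import SimConfig, simulate_dataset

# The 11 robust sites (chromosome, position, strand) recovered in all four
# replicate methylomes, used as an intersection fixture.
ROBUST_SITES = [
    SiteKey("chr2", 2831383, "-"),
    SiteKey("chr2", 3200390, "-"),
    SiteKey("chr2", 3200403, "+"),
    SiteKey("chr2", 8101959, "+"),
    SiteKey("chr2", 8101986, "-"),
    SiteKey("chr2", 8102002, "-"),
    SiteKey("chr3", 5720793, "+"),
    SiteKey("chr4", 76958, "-"),
    SiteKey("chr4", 2524803, "+"),
    SiteKey("chr4", 2524824, "-"),
    SiteKey("chr5", 1898399, "+"),
]

# Extra site shared by the three WT replicates but not the KO.
WT_ONLY_EXTRA = SiteKey("chr6", 2767592, "+")

# Published per-replicate (meth, unmeth) read counts at the plus-strand
# target site, with the Wilson 95% lower bounds they reproduce.
PLUS_SITE_COUNTS = {
    "WT1": (4, 9),
    "WT2": (19, 43),
    "WT3": (14, 18),
    "KO": (12, 13),
}


@pytest.fixture(scope="session")
def robust_sites():
    return list(ROBUST_SITES)


@pytest.fixture(scope="session")
def small_sim():
    """A small but fully featured simulated dataset (2 chromosomes, 4 reps)."""
    config = SimConfig(
        n_chromosomes=2, chrom_length=20_000, n_palindromes_per_chrom=8,
        n_replicates=4, spikein_length=10_000, seed=11,
    )
    return simulate_dataset(config)
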