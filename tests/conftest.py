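import numpy as np
import pytest

from colocscreen.simulate import ScenarioConfig, generate_scenario
from colocscreen.types import GenomicInterval, Peak

# A deliberately small scenario for fast unit tests; the full-size default
# configuration is exercised by the acceptance tests.
SMALL_CONFIG = ScenarioConfig(
    n_chroms=1,
    chrom_length=1_000_000,
    n_genes=60,
    gene_len_range=(3000, 6000),
    n_structure=150,
    n_proteins=5,
    n_peaks_per_protein=60,
)


@pytest.fixture(scope="session")
def small_scenario():
    return generate_scenario(11, SMALL_CONFIG)


@pytest.fixture(scope="session")
def full_scenario():
    """Default study conditions: 50 proteins x 500 peaks, 1000 structure
    peaks each (70% promoter-planted), relation slope 0.8 / intercept 0.05 /
    noise sd 0.05."""
    return generate_scenario(7)


def make_peak(chrom, start, end, name=".", score=0.0, summit=-1):
    return Peak(GenomicInterval(chrom, start, end), name=name, score=score,
                summit_offset=summit)


def random_peaks(rng, n, chroms=("chrA", "chrB"), span=100_000, max_len=500):
    peaks = []
    for i in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, span - max_len))
        length = int(rng.integers(1, max_len))
        peaks.append(make_peak(chrom, start, start + length, name=f"p{i}"))
    return peaks


def brute_force_overlapping(A, B):
    """All-pairs O(n*m) oracle for record-level intersection reporting."""
    return [
        a
        for a in A
        if any(
            a.chrom == b.chrom and a.start < b.end and b.start < a.end for b in B
        )
    ]
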