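import numpy as np
import pytest

from msatpop.loci import pcos10_example_locus, synthetic_panel
from msatpop.matrix import GenotypeMatrix
from msatpop.simulate import random_ancestral_freqs


@pytest.fixture(scope="session")
def panel():
    return synthetic_panel()


@pytest.fixture(scope="session")
def pcos10():
    return pcos10_example_locus()


@pytest.fixture(scope="session")
def ancestral(panel):
    return random_ancestral_freqs(panel, seed=11)


def make_gm(calls_by_pop, loci=None):
    """Build a GenotypeMatrix from {pop: [call_dict, ...]} shorthand."""
    calls = {}
    site = {}
    for pop, rows in calls_by_pop.items():
        for i, row in enumerate(rows):
            indiv = f"{pop}_{i}"
            calls[indiv] = row
            site[indiv] = pop
    return GenotypeMatrix.from_calls(calls, site=site, loci=loci)


def draw_pop_calls(rng, n, freqs_by_locus):
    """Random HW genotype rows: freqs_by_locus = {locus: (alleles, probs)}."""
    rows = []
    for _ in range(n):
        row = {}
        for locus, (alleles, probs) in freqs_by_locus.items():
            row[locus] = tuple(sorted(rng.choice(alleles, 2, p=probs).tolist()))
        rows.append(row)
    return rows
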