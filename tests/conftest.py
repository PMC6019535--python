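import numpy as np
import pytest

from ldprune import simgen
from ldprune.panel import GenotypePanel, LocusMeta


def make_count_panel(columns, individual_ids=None, with_positions=False):
    """Build a GenotypePanel from a list of per-locus count columns."""
    counts = np.array(columns, dtype=np.int8).T
    n, m = counts.shape
    loci = [
        LocusMeta(
            f"L{j + 1}",
            j,
            chromosome="1" if with_positions else None,
            position=(j + 1) * 100 if with_positions else None,
        )
        for j in range(m)
    ]
    ids = individual_ids or [f"ind{i + 1}" for i in range(n)]
    return GenotypePanel(counts=counts, loci=loci, individual_ids=ids)


@pytest.fixture
def worked_panel():
    """Five-locus allele-count panel with one complete-LD pair (L1 = 2 - L2)."""
    return make_count_panel(
        [
            [0, 0, 1, 2],  # L1, mac 3, minor allele coded 1
            [2, 2, 1, 0],  # L2 = 2 - L1, mac 3, minor allele coded 0
            [0, 1, 1, 2],  # L3, mac 4 (= n: MAF 0.5)
            [0, 1, 2, 1],  # L4, mac 4
            [0, 0, 0, 1],  # L5, mac 1
        ]
    )


@pytest.fixture(scope="session")
def planted_fixture():
    """Standard planted panel: n=100, m=1000, 20 each of duplicates,
    flipped duplicates, and perturbed copies."""
    return simgen.planted_panel(seed=42)
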