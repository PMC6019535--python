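"""In-memory containers for bi-allelic genotype and haplotype panels.

A *haplotype panel* stores phased 0/1 alleles, two per individual per locus;
a *genotype panel* stores per-individual allele counts in {0, 1, 2}.  Missing
data is not representable: every entry must be a valid code, which is checked
at construction time.  Locus order always equals input-file order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "LocusMeta",
    "GenotypePanel",
    "HaplotypePanel",
    "Removal",
    "ScreenCounters",
    "PruneResult",
]


@dataclass(frozen=True)
class LocusMeta:
    """Identity and (optional) map position of one locus.

    ``chromosome`` and ``position`` are either both present or both absent;
    ``input_index`` is the 0-based rank of the locus in the input file.
    """

    locus_id: str
    input_index: int
    chromosome: Optional[str] = None
    position: Optional[int] = None

    def __post_init__(self) -> None:
        if (self.chromosome is None) != (self.position is None):
            raise ValueError(
                f"locus {self.locus_id!r}: chromosome and position must be "
                "both present or both absent"
            )


def _check_loci(loci: Sequence[LocusMeta], n_loci: int) -> None:
    if len(loci) != n_loci:
        raise ValueError(f"expected {n_loci} locus records, got {len(loci)}")
    if [lm.input_index for lm in loci] != list(range(n_loci)):
        raise ValueError("locus input_index values must be 0..m-1 in order")
    ids = [lm.locus_id for lm in loci]
    if len(set(ids)) != len(ids):
        raise ValueError("locus identifiers must be unique")


def default_loci(m: int, prefix: str = "snp") -> list[LocusMeta]:
    """Generate placeholder locus metadata ``snp1..snp<m>`` (no positions)."""
    return [LocusMeta(f"{prefix}{k + 1}", k) for k in range(m)]


@dataclass
class GenotypePanel:
    """Allele-count panel: ``counts[i, j]`` in {0, 1, 2} for individual i, locus j."""

    counts: np.ndarray
    loci: list[LocusMeta]
    individual_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D individuals x loci matrix")
        if self.counts.size and not np.isin(self.counts, (0, 1, 2)).all():
            raise ValueError("allele counts must all be 0, 1, or 2 (no missing data)")
        self.counts = self.counts.astype(np.int8, copy=False)
        if self.n_individuals < 2:
            raise ValueError("a panel needs at least 2 individuals")
        if len(self.individual_ids) != self.n_individuals:
            raise ValueError("individual_ids length mismatch")
        _check_loci(self.loci, self.n_loci)

    @property
    def n_individuals(self) -> int:
        return self.counts.shape[0]

    @property
    def n_loci(self) -> int:
        return self.counts.shape[1]

    def locus_ids(self) -> list[str]:
        return [lm.locus_id for lm in self.loci]


@dataclass
class HaplotypePanel:
    """Phased panel: ``alleles[i, j, l]`` in {0, 1}, haplotype l in {0, 1}."""

    alleles: np.ndarray
    loci: list[LocusMeta]
    individual_ids: list[str]

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles)
        if self.alleles.ndim != 3 or self.alleles.shape[2] != 2:
            raise ValueError("alleles must have shape (n_individuals, n_loci, 2)")
        if self.alleles.size and not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("phased alleles must all be 0 or 1 (no missing data)")
        self.alleles = self.alleles.astype(np.int8, copy=False)
        if self.n_individuals < 2:
            raise ValueError("a panel needs at least 2 individuals")
        if len(self.individual_ids) != self.n_individuals:
            raise ValueError("individual_ids length mismatch")
        _check_loci(self.loci, self.n_loci)

    @property
    def n_individuals(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[1]

    def locus_ids(self) -> list[str]:
        return [lm.locus_id for lm in self.loci]

    def to_genotype_panel(self) -> GenotypePanel:
        """Collapse haplotypes by summation into an allele-count panel."""
        return GenotypePanel(
            counts=self.alleles.sum(axis=2, dtype=np.int8),
            loci=list(self.loci),
            individual_ids=list(self.individual_ids),
        )


@dataclass(frozen=True)
class Removal:
    """One pruned locus: why it was removed and against which partner."""

    removed_index: int
    partner_index: int
    reason: str  # "complete" | "high"
    r2: float
    orientation: Optional[str] = None  # "same" | "opposite" (complete stage)


@dataclass
class ScreenCounters:
    """Tallies of the high-LD candidate funnel.

    ``candidate_pairs`` counts pairs inside the MAC candidate interval,
    ``screened_out`` those rejected by partial sums, and ``r2_computed`` the
    exact r2 evaluations; the first is always the sum of the other two.
    """

    candidate_pairs: int = 0
    screened_out: int = 0
    r2_computed: int = 0

    def merge(self, other: "ScreenCounters") -> None:
        self.candidate_pairs += other.candidate_pairs
        self.screened_out += other.screened_out
        self.r2_computed += other.r2_computed


@dataclass
class PruneResult:
    """Outcome of a pruning run over one panel."""

    loci: list[LocusMeta]
    kept_indices: list[int]  # input order
    removals: list[Removal]
    excluded_indices: list[int] = field(default_factory=list)  # zero-variance loci
    counters: ScreenCounters = field(default_factory=ScreenCounters)

    @property
    def removed_indices(self) -> list[int]:
        return sorted(r.removed_index for r in self.removals)

    @property
    def n_removed_complete(self) -> int:
        return sum(1 for r in self.removals if r.reason == "complete")

    @property
    def n_removed_high(self) -> int:
        return sum(1 for r in self.removals if r.reason == "high")
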