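"""Per-locus summaries: minor allele counts, orientation, moments, partial sums.

All downstream stages work on a *minor orientation* of each locus: the less
frequent allele is treated as coded 1 (counts: 2 minus the stored code when
the major allele is the coded one).  The stored panel codes are never
rewritten; orientation is carried as a flag, and oriented quantities are
derived on the fly.

The per-locus *partial sums* are minor-oriented allele sums over nested
prefixes of the individuals (first ceil(p*n/S) individuals for subset
p = 1..S, S = 10 by default).  They power the high-LD partial-sum screen and
are computed once per locus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .panel import GenotypePanel, HaplotypePanel

__all__ = [
    "LocusSummary",
    "MacOrder",
    "minor_allele_count",
    "summarize_locus",
    "summarize_panel",
    "sort_loci_by_mac",
    "filter_monomorphic",
    "oriented_matrix",
]

Panel = Union[GenotypePanel, HaplotypePanel]


@dataclass
class LocusSummary:
    locus_index: int  # input index
    allele_sum: int  # raw sum of coded alleles (2n haplotypes / n individuals)
    mac: int  # minor allele count, in [0, n]
    minor_is_one: bool  # True when the allele coded 1 is the minor allele
    sum_x: int  # sum of minor-oriented values (equals mac in both modes)
    sum_x2: int  # sum of squared minor-oriented values (= mac in phased mode)
    variance_term: float  # mac - mac^2/(2n), the phased variance numerator
    partial_sums: np.ndarray  # int64, len = subset_count, non-decreasing


@dataclass
class MacOrder:
    """Stable ordering of loci by (mac, input index), with equal-MAC runs."""

    permutation: np.ndarray  # positions into the summary list, mac-ascending
    group_boundaries: np.ndarray  # start offsets of equal-MAC runs (+ final len)


def minor_allele_count(allele_sum: int, n: int) -> tuple[int, bool]:
    """Translate a raw allele sum over 2n haplotypes into a minor allele count.

    Returns ``(mac, minor_is_one)``.  When the sum is exactly n (minor allele
    frequency 0.5) the allele coded 1 is declared minor; downstream code
    treats such loci as orientation-ambiguous where required.
    """
    if not 0 <= allele_sum <= 2 * n:
        raise ValueError(f"allele_sum {allele_sum} outside [0, {2 * n}]")
    if allele_sum < n + 1:
        return allele_sum, True
    return 2 * n - allele_sum, False


def _prefix_bounds(n: int, subset_count: int) -> np.ndarray:
    # ceil(p*n/subset_count) for p = 1..subset_count
    p = np.arange(1, subset_count + 1)
    return -(-p * n // subset_count)


def summarize_locus(panel: Panel, locus_index: int, subset_count: int = 10) -> LocusSummary:
    """Compute the stored per-locus quantities for one locus."""
    if subset_count < 1:
        raise ValueError("subset_count must be >= 1")
    n = panel.n_individuals
    phased = isinstance(panel, HaplotypePanel)
    if phased:
        per_ind = panel.alleles[:, locus_index, :].sum(axis=1, dtype=np.int64)
    else:
        per_ind = panel.counts[:, locus_index].astype(np.int64)
    allele_sum = int(per_ind.sum())
    mac, minor_is_one = minor_allele_count(allele_sum, n)
    oriented = per_ind if minor_is_one else 2 - per_ind
    cum = np.cumsum(oriented)
    bounds = _prefix_bounds(n, subset_count)
    partial = np.where(bounds > 0, cum[bounds - 1], 0).astype(np.int64)
    if phased:
        sum_x2 = mac  # 0/1 alleles: sum of squares equals the sum
    else:
        sum_x2 = int((oriented * oriented).sum())
    return LocusSummary(
        locus_index=locus_index,
        allele_sum=allele_sum,
        mac=mac,
        minor_is_one=minor_is_one,
        sum_x=int(oriented.sum()),
        sum_x2=sum_x2,
        variance_term=mac - mac * mac / (2 * n),
        partial_sums=partial,
    )


def summarize_panel(panel: Panel, subset_count: int = 10) -> list[LocusSummary]:
    return [summarize_locus(panel, j, subset_count) for j in range(panel.n_loci)]


def sort_loci_by_mac(summaries: list[LocusSummary]) -> MacOrder:
    """Stable ascending sort by (mac, input index), recording equal-MAC runs."""
    if not summaries:
        raise ValueError("summaries must be nonempty")
    keys = np.array([(s.mac, s.locus_index) for s in summaries], dtype=np.int64)
    perm = np.lexsort((keys[:, 1], keys[:, 0]))
    macs = keys[perm, 0]
    starts = np.flatnonzero(np.r_[True, macs[1:] != macs[:-1]])
    return MacOrder(
        permutation=perm.astype(np.int64),
        group_boundaries=np.r_[starts, len(perm)].astype(np.int64),
    )


def filter_monomorphic(
    summaries: list[LocusSummary], n: int, phased: bool = False
) -> tuple[list[int], list[int]]:
    """Split summary positions into (analyzable, excluded).

    Excluded are loci on which r2 is undefined: monomorphic loci (mac 0), and
    in count mode also constant-genotype columns (e.g. all heterozygotes,
    which have mac = n but zero variance among allele counts; for phased
    alleles zero variance is equivalent to mac 0).  Excluded loci never take
    part in pairing and are never pruned.
    """
    N = 2 * n if phased else n
    analyzable, excluded = [], []
    for pos, s in enumerate(summaries):
        if s.mac == 0 or N * s.sum_x2 == s.sum_x * s.sum_x:
            excluded.append(pos)
        else:
            analyzable.append(pos)
    return analyzable, excluded


def oriented_matrix(panel: Panel, summaries: list[LocusSummary]) -> np.ndarray:
    """Materialize minor-oriented data columns (pure optimization; the stored
    panel is untouched).

    Phased mode: (2n, m) 0/1 matrix of haplotype rows; count mode: (n, m)
    matrix of oriented allele counts.  int64 so dot products accumulate
    exactly.
    """
    phased = isinstance(panel, HaplotypePanel)
    if phased:
        X = panel.alleles.transpose(0, 2, 1).reshape(-1, panel.n_loci)
    else:
        X = panel.counts
    X = X.astype(np.int64)
    # summaries may cover a subset of columns; unmentioned columns stay as-is
    flip = np.zeros(panel.n_loci, dtype=bool)
    for s in summaries:
        flip[s.locus_index] = not s.minor_is_one
    top = 1 if phased else 2
    X = np.where(flip[None, :], top - X, X)
    return X
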