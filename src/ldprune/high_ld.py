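"""Detection of loci in high LD (r2 above a threshold t < 1).

The stage avoids computing almost all pairwise r2 values through three
nested filters, all expressed in minor allele counts (MACs) over the
MAC-sorted panel:

1. *Bound table*: for each MAC value c the largest partner MAC that can
   still produce r2 > t, assuming the most favourable allele configuration
   (every minor allele of the rarer locus co-occurring with a minor allele
   of the commoner one).  Pairs outside the interval [c, max_mac(c)] are
   never looked at.
2. *Partial-sum screen*: for pairs inside the interval, minor-oriented
   allele sums over nested subsets of the individuals are compared; if on
   any subset the commoner locus exceeds the rarer one by more than the
   full-data slack max_mac(c) - c, the pair cannot reach r2 > t and is
   dropped without computing r2.  The screen is skipped when either locus
   has minor allele frequency exactly 0.5, where the orientation of the
   coding is ambiguous.
3. Exact r2 on the survivors, computing only the between-locus
   cross-product fresh (all marginal terms come from the stored summaries).

The removal rule is the same "leftmost" rule as the complete-LD stage:
within a pair the locus with the lower MAC (earlier input position on ties)
is removed, i.e. the one earlier in the MAC-sorted order.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from math import sqrt
from typing import Iterator, Optional, Sequence, Union

import numpy as np

from .locus_stats import LocusSummary, MacOrder, oriented_matrix
from .panel import GenotypePanel, HaplotypePanel, ScreenCounters

__all__ = [
    "BoundTable",
    "HighLdRemoval",
    "max_r2_same_overlap",
    "build_bound_table",
    "candidate_pairs",
    "partial_sum_screen",
    "r2_phased",
    "r2_allele_counts",
    "prune_high_ld",
]

Panel = Union[GenotypePanel, HaplotypePanel]


@dataclass
class BoundTable:
    """Largest partner MAC per MAC value that can still exceed the threshold."""

    threshold: float
    n: int
    max_mac: np.ndarray  # index c in [1, n] -> max partner mac; index 0 unused


@dataclass(frozen=True)
class HighLdRemoval:
    removed_index: int  # input index (the lower-MAC / earlier locus)
    partner_index: int  # input index of the partner that triggered removal
    r2: float


def max_r2_same_overlap(c_j: int, c_k: int, n: int) -> float:
    """Maximum achievable phased r2 for MACs c_j <= c_k over 2n haplotypes.

    Attained when the c_j minor alleles of the rarer locus are nested within
    the c_k minor alleles of the commoner one (cross-product = c_j), giving
    r2_max = c_j (2n - c_k) / (c_k (2n - c_j)); equal to 1 iff c_j = c_k.
    """
    if not 1 <= c_j <= c_k <= n:
        raise ValueError(f"require 1 <= c_j <= c_k <= n, got ({c_j}, {c_k}, {n})")
    return c_j * (2 * n - c_k) / (c_k * (2 * n - c_j))


def _can_exceed(c_j: int, c_k: int, n: int, t: float) -> bool:
    # Threshold test in additive form: with minor-oriented 0/1
    # codes the sum of squares equals the sum, so the best cross-product c_j
    # must exceed sqrt(t * v_j * v_k) + c_j*c_k/(2n), v_c = c - c^2/(2n).
    n2 = 2 * n
    v_j = c_j - c_j * c_j / n2
    v_k = c_k - c_k * c_k / n2
    return c_j > sqrt(t * v_j * v_k) + c_j * c_k / n2


def build_bound_table(n: int, t: float) -> BoundTable:
    """Iteratively grow the partner MAC per MAC value while r2 > t is possible.

    For each c_j the partner sum starts at c_j (where r2 = 1 is achievable)
    and is increased while the threshold can still be exceeded; the last
    passing value is stored.  The table is non-decreasing in c_j.
    """
    if not 0.0 < t < 1.0:
        raise ValueError(
            f"threshold must be in (0, 1), got {t} (r2 = 1 pairs belong to the "
            "complete-LD stage)"
        )
    if n < 2:
        raise ValueError("need n >= 2 individuals")
    max_mac = np.zeros(n + 1, dtype=np.int64)
    c_k = 1
    for c_j in range(1, n + 1):
        c_k = max(c_k, c_j)
        while c_k < n and _can_exceed(c_j, c_k + 1, n, t):
            c_k += 1
        max_mac[c_j] = c_k
    return BoundTable(threshold=t, n=n, max_mac=max_mac)


def candidate_pairs(
    order: MacOrder,
    bounds: BoundTable,
    macs: Sequence[int],
    excluded: frozenset[int] = frozenset(),
) -> Iterator[tuple[int, int]]:
    """Yield sorted-position pairs (j, k), j < k, with mac_k <= max_mac(mac_j).

    ``macs`` gives the MAC at each sorted position; ``excluded`` holds sorted
    positions removed by the complete-LD stage, which appear on neither side.
    Pairs stream in deterministic (j ascending, k ascending) order.
    """
    m = len(order.permutation)
    for j in range(m):
        if j in excluded:
            continue
        bound = bounds.max_mac[macs[j]]
        k = j + 1
        while k < m and macs[k] <= bound:
            if k not in excluded:
                yield j, k
            k += 1


def partial_sum_screen(
    s_j: LocusSummary, s_k: LocusSummary, bounds: BoundTable
) -> bool:
    """True when the pair survives the partial-sum screen (r2 > t still possible).

    ``s_j`` must be the lower-MAC locus.  Rejects when on any nested subset
    the commoner locus's minor-allele sum exceeds the rarer one's by more
    than max_mac(mac_j) - mac_j.  Pairs involving a locus with minor allele
    frequency exactly 0.5 pass unconditionally.
    """
    n = bounds.n
    if s_j.mac == n or s_k.mac == n:
        return True
    slack = int(bounds.max_mac[s_j.mac]) - s_j.mac
    return not bool(np.any(s_k.partial_sums - s_j.partial_sums > slack))


def _r2_from_sums(cross: int, sum_j: int, sum_k: int, sq_j: int, sq_k: int, N: int) -> tuple[int, int]:
    """Integer numerator^2 and denominator of r2 scaled by N (= 2n or n)."""
    num = N * cross - sum_j * sum_k
    den = (N * sq_j - sum_j * sum_j) * (N * sq_k - sum_k * sum_k)
    return num * num, den


def r2_phased(
    panel: HaplotypePanel, j: int, k: int, s_j: LocusSummary, s_k: LocusSummary
) -> float:
    """Squared correlation between phased alleles of loci j and k (input indices).

    Only the cross-product is computed fresh; marginal sums come from the
    summaries.  Invariant to the allele orientation at either locus, so raw
    allele sums are used directly (for 0/1 codes the sum of squares equals
    the sum).
    """
    n2 = 2 * panel.n_individuals
    a = panel.alleles[:, j, :].reshape(-1).astype(np.int64)
    b = panel.alleles[:, k, :].reshape(-1).astype(np.int64)
    cross = int(a @ b)
    num2, den = _r2_from_sums(
        cross, s_j.allele_sum, s_k.allele_sum, s_j.allele_sum, s_k.allele_sum, n2
    )
    if den == 0:
        raise ValueError("r2 undefined for a monomorphic locus")
    return num2 / den


def r2_allele_counts(
    panel: GenotypePanel, j: int, k: int, s_j: LocusSummary, s_k: LocusSummary
) -> float:
    """Squared correlation between allele counts of loci j and k (input indices)."""
    n = panel.n_individuals
    x = panel.counts[:, j].astype(np.int64)
    y = panel.counts[:, k].astype(np.int64)
    sq_j = int(x @ x)
    sq_k = int(y @ y)
    cross = int(x @ y)
    num2, den = _r2_from_sums(cross, s_j.allele_sum, s_k.allele_sum, sq_j, sq_k, n)
    if den == 0:
        raise ValueError("r2 undefined for a zero-variance locus")
    return num2 / den


def _scan_chunk(
    j_lo: int,
    j_hi: int,
    macs: np.ndarray,
    partials: np.ndarray,
    dens: np.ndarray,
    X: np.ndarray,
    perm: np.ndarray,
    input_idx: np.ndarray,
    excluded_mask: np.ndarray,
    bounds: BoundTable,
    t: float,
    N: int,
    n: int,
) -> tuple[list[HighLdRemoval], ScreenCounters]:
    removals: list[HighLdRemoval] = []
    counters = ScreenCounters()
    m = len(perm)
    max_mac = bounds.max_mac
    for j in range(j_lo, j_hi):
        if excluded_mask[j]:
            continue
        mac_j = macs[j]
        bound = max_mac[mac_j]
        slack = int(bound) - int(mac_j)
        exempt_j = mac_j == n
        k = j + 1
        while k < m and macs[k] <= bound:
            if excluded_mask[k]:
                k += 1
                continue
            counters.candidate_pairs += 1
            if not (exempt_j or macs[k] == n) and np.any(
                partials[k] - partials[j] > slack
            ):
                counters.screened_out += 1
                k += 1
                continue
            counters.r2_computed += 1
            cross = int(X[:, perm[j]] @ X[:, perm[k]])
            num = N * cross - int(macs[j]) * int(macs[k])
            num2 = num * num
            den = int(dens[j]) * int(dens[k])
            if num2 > t * den:
                removals.append(
                    HighLdRemoval(
                        removed_index=int(input_idx[j]),
                        partner_index=int(input_idx[k]),
                        r2=num2 / den,
                    )
                )
                break
            k += 1
    return removals, counters


def prune_high_ld(
    panel: Panel,
    t: float,
    summaries: list[LocusSummary],
    order: MacOrder,
    excluded_positions: frozenset[int] = frozenset(),
    workers: int = 1,
    oriented: Optional[np.ndarray] = None,
) -> tuple[list[HighLdRemoval], ScreenCounters]:
    """Run the high-LD stage after complete-LD removals.

    ``order`` is the MAC order over analyzable summary positions;
    ``excluded_positions`` are sorted positions already pruned for complete
    LD.  For each sorted position j (ascending) candidates k > j inside the
    MAC interval are screened and, on the first pair with r2 > t, locus j is
    removed with k as partner and scanning for j stops.  Each j's decision
    depends only on complete-LD-surviving data, so partitioning the j range
    over workers is deterministic.
    """
    if not 0.0 < t < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {t}")
    n = panel.n_individuals
    phased = isinstance(panel, HaplotypePanel)
    N = 2 * n if phased else n
    bounds = build_bound_table(n, t)
    if oriented is None:
        oriented = oriented_matrix(panel, summaries)

    perm = order.permutation
    m = len(perm)
    macs = np.array([summaries[p].mac for p in perm], dtype=np.int64)
    partials = np.stack([summaries[p].partial_sums for p in perm])
    # Bound/screen arithmetic uses phased-equivalent sums (sum of squares =
    # sum = mac); the exact r2 below uses the true per-mode moments.
    sum_x = np.array([summaries[p].sum_x for p in perm], dtype=np.int64)
    sum_x2 = np.array([summaries[p].sum_x2 for p in perm], dtype=np.int64)
    dens = N * sum_x2 - sum_x * sum_x
    input_idx = np.array([summaries[p].locus_index for p in perm], dtype=np.int64)
    excluded_mask = np.zeros(m, dtype=bool)
    for pos in excluded_positions:
        excluded_mask[pos] = True

    # map summary positions to panel columns for the oriented matrix
    col_of = np.array([summaries[p].locus_index for p in perm], dtype=np.int64)

    args = (macs, partials, dens, oriented, col_of, input_idx, excluded_mask, bounds, t, N, n)
    if workers <= 1 or m == 0:
        chunks = [(0, m)]
    else:
        edges = np.linspace(0, m, num=min(workers, max(m, 1)) + 1, dtype=int)
        chunks = [(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]

    results: list[tuple[list[HighLdRemoval], ScreenCounters]] = []
    if len(chunks) == 1:
        results.append(_scan_chunk(*chunks[0], *args))
    else:
        with ThreadPoolExecutor(max_workers=len(chunks)) as pool:
            futures = [pool.submit(_scan_chunk, lo, hi, *args) for lo, hi in chunks]
            results = [f.result() for f in futures]

    removals: list[HighLdRemoval] = []
    counters = ScreenCounters()
    for rem, cnt in results:
        removals.extend(rem)
        counters.merge(cnt)
    return removals, counters
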