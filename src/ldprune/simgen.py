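"""Synthetic haplotype panels with planted LD structure, and the brute-force
all-pairs oracle used as ground truth in tests.

The generator draws loci independently (no recombination map): the pruning
algorithm is position-agnostic, so linkage is planted explicitly — exact
duplicate columns, complemented duplicates, and perturbed copies with a
chosen number of flipped haplotypes.  Chromosome/position metadata is
assigned round-robin so distance reporting is exercised.

The oracle computes every pairwise r2 directly from integer Gram matrices
(quadratic in the number of loci, hence the guard) and applies the same
leftmost-removal rule with the same complete-then-high stage sequencing as
the fast path, so removal sets are comparable element for element.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from . import locus_stats
from .panel import (
    GenotypePanel,
    HaplotypePanel,
    LocusMeta,
    PruneResult,
    Removal,
    ScreenCounters,
)

__all__ = [
    "PlantedPair",
    "generate_base_panel",
    "plant_duplicate",
    "planted_panel",
    "brute_force_prune",
]

Panel = Union[GenotypePanel, HaplotypePanel]

BRUTE_FORCE_MAX_LOCI = 5000

# Study conditions for the standard planted fixture: 100 individuals, 1000
# loci of which 20 are exact duplicates, 20 complemented duplicates and 20
# perturbed copies (6 of the 200 haplotypes flipped, i.e. 3% discordance,
# giving true r2 well below a 0.99 threshold).
DEFAULT_N = 100
DEFAULT_M = 1000
DEFAULT_PLANT = 20
DEFAULT_PERTURB_HAPLOTYPES = 6
DEFAULT_MAF_RANGE = (0.05, 0.5)
_N_CHROMOSOMES = 5
_LOCUS_SPACING_BP = 1000


@dataclass(frozen=True)
class PlantedPair:
    source_index: int
    copy_index: int
    planted_relation: str  # "duplicate" | "flipped-duplicate" | "perturbed"
    true_r2: float  # oracle-computed after construction (nan if degenerate)


def _round_robin_loci(m: int) -> list[LocusMeta]:
    return [
        LocusMeta(
            f"snp{k + 1}",
            k,
            chromosome=str(k % _N_CHROMOSOMES + 1),
            position=(k // _N_CHROMOSOMES + 1) * _LOCUS_SPACING_BP,
        )
        for k in range(m)
    ]


def _r2_cols_phased(a: np.ndarray, b: np.ndarray) -> float:
    """Direct evaluation of the phased-allele r2 for two haplotype columns."""
    a = a.reshape(-1).astype(np.int64)
    b = b.reshape(-1).astype(np.int64)
    n2 = a.size
    sa, sb = int(a.sum()), int(b.sum())
    da = n2 * sa - sa * sa
    db = n2 * sb - sb * sb
    if da == 0 or db == 0:
        return float("nan")
    num = n2 * int(a @ b) - sa * sb
    return num * num / (da * db)


def generate_base_panel(
    n: int,
    m: int,
    maf_low: float = DEFAULT_MAF_RANGE[0],
    maf_high: float = DEFAULT_MAF_RANGE[1],
    seed: int = 0,
    max_redraws: int = 10,
) -> HaplotypePanel:
    """Draw a panel of independent loci with per-locus MAF ~ U[maf_low, maf_high].

    All 2n alleles at a locus are independent Bernoulli draws.  Monomorphic
    columns are redrawn up to ``max_redraws`` times and then kept, so the
    monomorphic filter stays exercised on extreme frequency ranges.
    """
    if not 0.0 < maf_low <= maf_high <= 0.5:
        raise ValueError(f"need 0 < maf_low <= maf_high <= 0.5, got ({maf_low}, {maf_high})")
    if n < 2:
        raise ValueError("need n >= 2")
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(maf_low, maf_high, size=m)
    alleles = (rng.random((n, m, 2)) < freqs[None, :, None]).astype(np.int8)
    for _ in range(max_redraws):
        sums = alleles.sum(axis=(0, 2))
        mono = np.flatnonzero((sums == 0) | (sums == 2 * n))
        if mono.size == 0:
            break
        alleles[:, mono, :] = (
            rng.random((n, mono.size, 2)) < freqs[None, mono, None]
        ).astype(np.int8)
    return HaplotypePanel(
        alleles=alleles,
        loci=_round_robin_loci(m),
        individual_ids=[f"ind{i + 1}" for i in range(n)],
    )


def plant_duplicate(
    panel: HaplotypePanel,
    source: int,
    flip: bool = False,
    perturb_haplotypes: int = 0,
    seed: Optional[int] = None,
) -> tuple[HaplotypePanel, PlantedPair]:
    """Append a (possibly complemented, possibly perturbed) copy of a column.

    ``perturb_haplotypes`` haplotype entries chosen at random are inverted.
    The true r2 between source and copy is recomputed directly and returned
    with the planted-pair record.
    """
    n = panel.n_individuals
    if perturb_haplotypes >= 2 * n:
        raise ValueError("cannot perturb all haplotypes")
    col = panel.alleles[:, source, :].copy()
    if flip:
        col = 1 - col
    if perturb_haplotypes:
        rng = np.random.default_rng(seed)
        flat = col.reshape(-1)
        pos = rng.choice(2 * n, size=perturb_haplotypes, replace=False)
        flat[pos] = 1 - flat[pos]
        col = flat.reshape(n, 2)
    alleles = np.concatenate([panel.alleles, col[:, None, :]], axis=1)
    m = alleles.shape[1]
    new_panel = HaplotypePanel(
        alleles=alleles,
        loci=_round_robin_loci(m),
        individual_ids=list(panel.individual_ids),
    )
    relation = (
        "perturbed"
        if perturb_haplotypes
        else ("flipped-duplicate" if flip else "duplicate")
    )
    pair = PlantedPair(
        source_index=source,
        copy_index=m - 1,
        planted_relation=relation,
        true_r2=_r2_cols_phased(panel.alleles[:, source, :], col),
    )
    return new_panel, pair


def planted_panel(
    n: int = DEFAULT_N,
    m: int = DEFAULT_M,
    n_duplicates: int = DEFAULT_PLANT,
    n_flipped: int = DEFAULT_PLANT,
    n_perturbed: int = DEFAULT_PLANT,
    perturb_haplotypes: int = DEFAULT_PERTURB_HAPLOTYPES,
    maf_low: float = DEFAULT_MAF_RANGE[0],
    maf_high: float = DEFAULT_MAF_RANGE[1],
    seed: int = 0,
) -> tuple[HaplotypePanel, list[PlantedPair]]:
    """Standard test fixture: base panel plus planted duplicate structure."""
    n_planted = n_duplicates + n_flipped + n_perturbed
    if n_planted >= m:
        raise ValueError("more planted loci than total loci")
    rng = np.random.default_rng(seed)
    panel = generate_base_panel(
        n, m - n_planted, maf_low, maf_high, seed=int(rng.integers(2**31))
    )
    sums = panel.alleles.sum(axis=(0, 2))
    polymorphic = np.flatnonzero((sums > 0) & (sums < 2 * n))
    kinds = (
        ["duplicate"] * n_duplicates
        + ["flipped-duplicate"] * n_flipped
        + ["perturbed"] * n_perturbed
    )
    pairs: list[PlantedPair] = []
    for kind in kinds:
        source = int(rng.choice(polymorphic))
        panel, pair = plant_duplicate(
            panel,
            source,
            flip=(kind == "flipped-duplicate"),
            perturb_haplotypes=perturb_haplotypes if kind == "perturbed" else 0,
            seed=int(rng.integers(2**31)),
        )
        pairs.append(pair)
    return panel, pairs


def _gram_r2_terms(panel: Panel, mode: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs integer r2 ingredients: num matrix, den vector, mac array."""
    if mode == "phased":
        if not isinstance(panel, HaplotypePanel):
            raise ValueError("phased mode requires a haplotype panel")
        X = panel.alleles.transpose(0, 2, 1).reshape(-1, panel.n_loci).astype(np.int64)
        N = X.shape[0]
    elif mode == "counts":
        gp = panel.to_genotype_panel() if isinstance(panel, HaplotypePanel) else panel
        X = gp.counts.astype(np.int64)
        N = X.shape[0]
    else:
        raise ValueError(f"mode must be 'phased' or 'counts', got {mode!r}")
    s = X.sum(axis=0)
    sq = (X * X).sum(axis=0)
    G = X.T @ X
    num = N * G - np.outer(s, s)
    den = N * sq - s * s
    return num, den, s


def brute_force_prune(panel: Panel, t: float, mode: str = "counts") -> PruneResult:
    """All-pairs reference pruner (testing ground truth).

    Computes every pairwise r2 directly, then applies the identical
    leftmost-removal rule with the identical stage sequencing as the fast
    path: exact r2 = 1 removals first (earlier-in-data locus of each pair
    removed), then first-hit r2 > t removals scanning the MAC-sorted order.
    Quadratic in loci; refuses panels above ``BRUTE_FORCE_MAX_LOCI``.
    """
    if not 0.0 < t < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {t}")
    m = panel.n_loci
    if m > BRUTE_FORCE_MAX_LOCI:
        raise ValueError(f"brute force guard: {m} loci > {BRUTE_FORCE_MAX_LOCI}")
    n = panel.n_individuals
    num, den, _ = _gram_r2_terms(panel, mode)

    stat_panel = (
        panel.to_genotype_panel()
        if (mode == "counts" and isinstance(panel, HaplotypePanel))
        else panel
    )
    summaries = locus_stats.summarize_panel(stat_panel)
    analyzable = [s.locus_index for s in summaries if den[s.locus_index] > 0]
    order = sorted(analyzable, key=lambda j: (summaries[j].mac, j))

    removals: list[Removal] = []
    # stage 1: complete LD (exact integer test num^2 == den_j * den_k)
    survivors: list[int] = []
    removed_complete: set[int] = set()
    for j in order:
        if survivors:
            sv = np.array(survivors)
            hits = np.flatnonzero(num[j, sv] * num[j, sv] == den[j] * den[sv])
            if hits.size:
                sj = survivors.pop(int(hits[0]))
                removed_complete.add(sj)
                removals.append(Removal(sj, j, "complete", 1.0))
        survivors.append(j)

    # stage 2: high LD, first hit per sorted position
    alive = np.array([j for j in order if j not in removed_complete], dtype=np.int64)
    removed_high: set[int] = set()
    for pos in range(len(alive)):
        j = int(alive[pos])
        ks = alive[pos + 1:]
        if ks.size == 0:
            continue
        nm = num[j, ks]
        hits = np.flatnonzero(nm * nm > t * (den[j] * den[ks]))
        if hits.size:
            k = int(ks[hits[0]])
            n2_ = int(num[j, k]) ** 2
            d = int(den[j]) * int(den[k])
            removed_high.add(j)
            removals.append(Removal(j, k, "high", n2_ / d))

    removed = removed_complete | removed_high
    removals.sort(key=lambda r: r.removed_index)
    kept = [j for j in analyzable if j not in removed]
    excluded = [j for j in range(m) if j not in set(analyzable)]
    return PruneResult(
        loci=list(panel.loci),
        kept_indices=kept,
        removals=removals,
        excluded_indices=excluded,
        counters=ScreenCounters(),
    )
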