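"""Detection of loci in complete LD (r2 exactly 1).

Two bi-allelic loci can only have squared correlation 1 between phased
alleles when their minor allele counts are equal, and then only when their
minor-oriented allele vectors are identical.  So the whole stage reduces to
comparing allele vectors within equal-MAC groups of the MAC-sorted panel,
with early exit on the first mismatching individual.

Within a group the loci are processed in input order against the current
survivors; on a match the earlier-appearing locus is removed and the later
one recorded as its partner.  Consequently, in a clique of g mutually
identical loci the *last* one in the data survives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .locus_stats import LocusSummary, MacOrder
from .panel import GenotypePanel, HaplotypePanel

__all__ = ["CompleteLdRemoval", "vectors_identical", "find_complete_ld"]

Panel = Union[GenotypePanel, HaplotypePanel]


@dataclass(frozen=True)
class CompleteLdRemoval:
    removed_index: int  # input index of the pruned locus
    partner_index: int  # input index of the surviving, identical locus
    orientation: str  # "same" | "opposite" minor-allele coding


def _raw_column(panel: Panel, j: int) -> np.ndarray:
    if isinstance(panel, HaplotypePanel):
        return panel.alleles[:, j, :].reshape(-1)
    return panel.counts[:, j]


def vectors_identical(panel: Panel, j: int, k: int, orientation: str) -> bool:
    """True when loci j and k carry identical alleles under ``orientation``.

    ``"same"`` compares raw codes directly; ``"opposite"`` compares against
    the complemented codes (1 - a for phased alleles, 2 - x for counts).
    Both loci must have equal minor allele counts (caller's contract).
    """
    a = _raw_column(panel, j)
    b = _raw_column(panel, k)
    if orientation == "opposite":
        top = 1 if isinstance(panel, HaplotypePanel) else 2
        b = top - b
    elif orientation != "same":
        raise ValueError(f"orientation must be 'same' or 'opposite', got {orientation!r}")
    return bool(np.array_equal(a, b))


def find_complete_ld(
    panel: Panel,
    order: MacOrder,
    summaries: list[LocusSummary],
) -> list[CompleteLdRemoval]:
    """Scan equal-MAC groups for identical loci and prune the earlier of each pair.

    ``order`` must be built on the analyzable (polymorphic) summaries only;
    ``summaries`` is the full per-locus list indexed by the positions stored
    in ``order.permutation``.  At minor allele frequency exactly 0.5 the
    orientation of the coding is ambiguous, so both orientations are tested.
    """
    n = panel.n_individuals
    removals: list[CompleteLdRemoval] = []
    perm = order.permutation
    gb = order.group_boundaries
    for g in range(len(gb) - 1):
        group = perm[gb[g]: gb[g + 1]]
        if len(group) < 2:
            continue
        survivors: list[int] = []
        for pos in group:
            s = summaries[pos]
            matched_with: int | None = None
            matched_orient = ""
            for si, spos in enumerate(survivors):
                ss = summaries[spos]
                if s.mac == n:  # MAF exactly 0.5: coding is ambiguous
                    orients = ("same", "opposite")
                elif ss.minor_is_one == s.minor_is_one:
                    orients = ("same",)
                else:
                    orients = ("opposite",)
                for orient in orients:
                    if vectors_identical(panel, ss.locus_index, s.locus_index, orient):
                        matched_with = si
                        matched_orient = orient
                        break
                if matched_with is not None:
                    break
            if matched_with is not None:
                spos = survivors.pop(matched_with)
                removals.append(
                    CompleteLdRemoval(
                        removed_index=summaries[spos].locus_index,
                        partner_index=s.locus_index,
                        orientation=matched_orient,
                    )
                )
            survivors.append(pos)
    removals.sort(key=lambda r: r.removed_index)
    return removals
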