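"""High-LD stage: MAC bound table, candidate interval, partial-sum screen,
exact r2, and the full screening funnel."""

import itertools

import numpy as np
import pytest

from ldprune import high_ld, locus_stats, prune_panel, simgen
from ldprune.high_ld import (
    build_bound_table,
    candidate_pairs,
    max_r2_same_overlap,
    partial_sum_screen,
    r2_allele_counts,
    r2_phased,
)
from ldprune.locus_stats import sort_loci_by_mac, summarize_panel
from ldprune.panel import HaplotypePanel

from conftest import make_count_panel


def nested_haplotype_columns(c_j, c_k, n):
    """Construct the extremal configuration: the c_j minor alleles of the
    rarer locus nested inside the c_k minor alleles of the commoner one."""
    a = np.zeros(2 * n, dtype=np.int8)
    b = np.zeros(2 * n, dtype=np.int8)
    a[:c_j] = 1
    b[:c_k] = 1
    alleles = np.stack([a.reshape(n, 2), b.reshape(n, 2)], axis=1)
    return HaplotypePanel(
        alleles=alleles,
        loci=simgen._round_robin_loci(2),
        individual_ids=[f"i{i}" for i in range(n)],
    )


class TestMaxR2:
    @pytest.mark.parametrize(
        "c_j,c_k,n,expected",
        [
            (5, 5, 10, 1.0),
            (5, 6, 10, 5 * 14 / (6 * 15)),
            (1, 10, 10, 1 * 10 / (10 * 19)),
        ],
    )
    def test_closed_form(self, c_j, c_k, n, expected):
        assert max_r2_same_overlap(c_j, c_k, n) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("c_j,c_k,n", [(2, 5, 8), (3, 3, 6), (1, 7, 12), (4, 9, 10)])
    def test_matches_direct_evaluation_of_nested_configuration(self, c_j, c_k, n):
        panel = nested_haplotype_columns(c_j, c_k, n)
        s = summarize_panel(panel)
        assert max_r2_same_overlap(c_j, c_k, n) == pytest.approx(
            r2_phased(panel, 0, 1, s[0], s[1]), rel=1e-12
        )

    def test_contract_violation(self):
        with pytest.raises(ValueError):
            max_r2_same_overlap(6, 5, 10)


class TestBoundTable:
    def test_strict_threshold_gives_equal_mac_only(self):
        bounds = build_bound_table(10, 0.99)
        assert bounds.max_mac[5] == 5  # partner mac 6 gives r2max ~ 0.778

    def test_small_panel(self):
        assert build_bound_table(2, 0.5).max_mac[1] == 1

    def test_tiny_threshold_admits_everything(self):
        bounds = build_bound_table(10, 1e-6)
        assert bounds.max_mac[1] == 10

    def test_threshold_validation(self):
        for t in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                build_bound_table(10, t)

    @pytest.mark.parametrize("t", [0.8, 0.95, 0.99])
    @pytest.mark.parametrize("n", [2, 7, 25, 50])
    def test_bound_is_tight_and_monotone(self, n, t):
        bounds = build_bound_table(n, t)
        mm = bounds.max_mac
        assert (mm[1:] >= np.arange(1, n + 1)).all()
        assert (np.diff(mm[1:]) >= 0).all()
        for c in range(1, n + 1):
            if mm[c] < n:  # first value outside the interval cannot exceed t
                assert max_r2_same_overlap(c, int(mm[c]) + 1, n) <= t
            assert max_r2_same_overlap(c, int(mm[c]), n) > t or mm[c] == c


class TestCandidatePairs:
    def test_equal_mac_only_at_strict_threshold(self):
        panel = make_count_panel([[0, 0, 0, 1], [1, 0, 0, 0], [0, 1, 1, 1], [1, 1, 2, 0]])
        # macs 1, 1, 3, 4
        summaries = summarize_panel(panel)
        order = sort_loci_by_mac(summaries)
        bounds = build_bound_table(4, 0.99)
        macs = [summaries[p].mac for p in order.permutation]
        assert list(candidate_pairs(order, bounds, macs)) == [(0, 1)]

    def test_wide_bound_emits_all_pairs_for_rarest_locus(self):
        panel = make_count_panel([[0, 0, 0, 1], [1, 0, 1, 0], [0, 1, 1, 1]])
        summaries = summarize_panel(panel)
        order = sort_loci_by_mac(summaries)
        bounds = build_bound_table(4, 1e-9)
        macs = [summaries[p].mac for p in order.permutation]
        pairs = list(candidate_pairs(order, bounds, macs))
        assert [(j, k) for j, k in pairs if j == 0] == [(0, 1), (0, 2)]

    def test_excluded_locus_on_neither_side(self):
        panel = make_count_panel([[0, 0, 0, 1], [0, 0, 1, 0], [0, 1, 0, 0]])
        summaries = summarize_panel(panel)
        order = sort_loci_by_mac(summaries)
        bounds = build_bound_table(4, 0.5)
        macs = [summaries[p].mac for p in order.permutation]
        pairs = list(candidate_pairs(order, bounds, macs, excluded=frozenset({1})))
        assert pairs == [(0, 2)]


class TestPartialSumScreen:
    def _summaries(self, cols):
        panel = make_count_panel(cols)
        return summarize_panel(panel), panel.n_individuals

    def test_rejects_on_violating_subset(self):
        # equal MAC but disjoint carriers: zero slack at t=0.8 forces any
        # positive subset gap to reject
        (s_j, s_k), n = self._summaries(
            [[0, 0, 0, 0, 0, 0, 0, 0, 1, 1], [1, 1, 0, 0, 0, 0, 0, 0, 0, 0]]
        )
        bounds = build_bound_table(n, 0.8)
        assert bounds.max_mac[s_j.mac] == s_j.mac  # slack 0
        assert not partial_sum_screen(s_j, s_k, bounds)
        # with a looser threshold the slack covers the gap
        assert partial_sum_screen(s_j, s_k, build_bound_table(n, 1e-6))

    def test_identical_loci_pass(self):
        (s_j, s_k), n = self._summaries([[0, 1, 0, 2], [0, 1, 0, 2]])
        assert partial_sum_screen(s_j, s_k, build_bound_table(n, 0.99))

    def test_maf_half_exemption(self):
        # second locus has mac = n (MAF 0.5); its subset gap (4 > slack 3)
        # would reject, but the ambiguous-coding exemption passes it
        (s_j, s_k), n = self._summaries([[0, 0, 0, 1], [2, 2, 0, 0]])
        bounds = build_bound_table(n, 1e-6)
        assert s_k.mac == n
        assert int(bounds.max_mac[s_j.mac]) - s_j.mac == 3
        assert np.any(s_k.partial_sums - s_j.partial_sums > 3)
        assert partial_sum_screen(s_j, s_k, bounds)


class TestExactR2:
    def test_phased_hand_example(self):
        alleles = np.array([[[1, 0], [0, 1]], [[0, 0], [0, 0]]], dtype=np.int8)
        panel = HaplotypePanel(
            alleles=alleles,
            loci=simgen._round_robin_loci(2),
            individual_ids=["a", "b"],
        )
        s = summarize_panel(panel)
        assert r2_phased(panel, 0, 1, s[0], s[1]) == pytest.approx(1 / 9, rel=1e-15)

    def test_phased_complement_has_r2_one(self):
        hap = simgen.generate_base_panel(20, 1, seed=5)
        hap2, _ = simgen.plant_duplicate(hap, 0, flip=True)
        s = summarize_panel(hap2)
        assert r2_phased(hap2, 0, 1, s[0], s[1]) == pytest.approx(1.0, abs=0)

    def test_counts_hand_example(self):
        panel = make_count_panel([[0, 1, 1, 2], [0, 1, 2, 1]])
        s = summarize_panel(panel)
        assert r2_allele_counts(panel, 0, 1, s[0], s[1]) == pytest.approx(0.25, rel=1e-15)

    def test_counts_mirrored_pair(self):
        panel = make_count_panel([[0, 0, 1, 2], [2, 2, 1, 0]])
        s = summarize_panel(panel)
        assert r2_allele_counts(panel, 0, 1, s[0], s[1]) == pytest.approx(1.0, abs=0)

    def test_identical_loci(self):
        panel = make_count_panel([[0, 1, 0, 2], [0, 1, 0, 2]])
        s = summarize_panel(panel)
        assert r2_allele_counts(panel, 0, 1, s[0], s[1]) == 1.0

    def test_zero_variance_rejected(self):
        panel = make_count_panel([[1, 1, 1, 1], [0, 1, 0, 2]])
        s = summarize_panel(panel)
        with pytest.raises(ValueError):
            r2_allele_counts(panel, 0, 1, s[0], s[1])


class TestPruneHighLd:
    def test_worked_panel_keeps_everything_after_complete_ld(self, worked_panel):
        result, report = prune_panel(worked_panel, 0.99)
        assert result.n_removed_complete == 1
        assert result.n_removed_high == 0
        assert result.kept_indices == [1, 2, 3, 4]
        # the L3-L4 pair (both MAF 0.5) reaches the exact-r2 step
        assert report.counters.r2_computed == 1

    def test_counter_conservation(self, planted_fixture):
        panel, _ = planted_fixture
        result, _ = prune_panel(panel, 0.99)
        c = result.counters
        assert c.candidate_pairs == c.screened_out + c.r2_computed

    def test_near_duplicate_above_threshold_removed_large_n(self):
        pan = simgen.generate_base_panel(1000, 30, seed=7)
        pan, pair = simgen.plant_duplicate(pan, 3, perturb_haplotypes=1, seed=11)
        assert pair.true_r2 > 0.99
        for mode in ("phased", "counts"):
            result, _ = prune_panel(pan, 0.99, mode=mode)
            high = [r for r in result.removals if r.reason == "high"]
            assert len(high) == 1
            assert {high[0].removed_index, high[0].partner_index} == {3, 30}
            assert high[0].r2 > 0.99

    def test_threshold_validation(self, worked_panel):
        with pytest.raises(ValueError):
            prune_panel(worked_panel, 1.0)

    @pytest.mark.parametrize("n", [3, 4])
    @pytest.mark.parametrize("t", [0.8, 0.95, 0.99])
    def test_screen_never_rejects_a_high_ld_pair_phased(self, n, t):
        """Exhaustive soundness on phased alleles: across every pair of
        length-2n haplotype columns, no pair with r2 > t is eliminated by
        the candidate interval or the partial-sum screen."""
        n2 = 2 * n
        cols = np.array(list(itertools.product((0, 1), repeat=n2)), dtype=np.int64)
        s = cols.sum(axis=1)
        keep = (s > 0) & (s < n2)
        cols, s = cols[keep], s[keep]
        mac = np.minimum(s, n2 - s)
        oriented = np.where((s < n + 1)[:, None], cols, 1 - cols)
        per_ind = oriented.reshape(len(cols), n, 2).sum(axis=2)
        prefix = -(-np.arange(1, 11) * n // 10)
        partial = np.cumsum(per_ind, axis=1)[:, prefix - 1]
        num = n2 * (cols @ cols.T) - np.outer(s, s)
        den = n2 * s - s * s
        bounds = build_bound_table(n, t)
        viol = 0
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                r2 = num[i, j] ** 2 / (den[i] * den[j])
                if not r2 > t:
                    continue
                a, b = (i, j) if (mac[i], i) <= (mac[j], j) else (j, i)
                if mac[b] > bounds.max_mac[mac[a]]:
                    viol += 1
                    continue
                if mac[a] == n or mac[b] == n:
                    continue
                if np.any(partial[b] - partial[a] > bounds.max_mac[mac[a]] - mac[a]):
                    viol += 1
        assert viol == 0
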