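from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from coreniche.occupancy import (
    bc_contribution_curve,
    core_phylum_composition,
    group_occupancy,
    rank_taxa,
    ranking_index,
    select_core,
    select_core_elbow,
    select_core_last2pct,
)
from coreniche.table import AbundanceTable
from conftest import random_table


class TestGroupOccupancy:
    def test_ubiquitous_taxon(self, grouped_table, grouped_metadata):
        occ = group_occupancy(grouped_table, grouped_metadata, "site")
        assert occ.loc["t1"].tolist() == [1.0, 1.0]
        assert occ.loc["t4"].tolist() == [1.0, 1.0]

    def test_absent_taxon_zero(self):
        t = AbundanceTable(np.array([[1, 0], [2, 0]]), ["a", "b"], ["x", "y"])
        occ = group_occupancy(t)
        assert occ.loc["y", "all"] == 0.0

    def test_partial_occupancy_by_direct_count(self, grouped_table,
                                               grouped_metadata):
        # t2 present in 2 of 4 group-A samples, 0 of 4 group-B samples
        occ = group_occupancy(grouped_table, grouped_metadata, "site")
        assert occ.loc["t2", "A"] == 0.5
        assert occ.loc["t2", "B"] == 0.0

    def test_grouping_none_pools_everything(self, grouped_table):
        occ = group_occupancy(grouped_table, grouping="none")
        assert list(occ.columns) == ["all"]
        assert occ.loc["t3", "all"] == 4 / 8


class TestRankingIndex:
    def test_full_occupancy_gives_one(self):
        occ = pd.DataFrame({"A": [1.0], "B": [1.0]}, index=["t"])
        out = ranking_index(occ)
        assert out.loc["t", "index"] == 1.0

    def test_half_occupancy_no_full_groups(self):
        occ = pd.DataFrame({"A": [0.5], "B": [0.5]}, index=["t"])
        out = ranking_index(occ)
        assert out.loc["t", "index"] == pytest.approx((1.0 + 0.0) / 4.0)

    def test_absent_taxon_ranked_last(self):
        occ = pd.DataFrame({"A": [1.0, 0.0, 0.4]}, index=["u", "v", "w"])
        out = ranking_index(occ)
        assert out.loc["v", "index"] == 0.0
        assert out.loc["v", "rank"] == 3

    def test_index_bounds(self, rng):
        occ = pd.DataFrame(rng.random((20, 3)), index=[f"t{i}" for i in range(20)])
        out = ranking_index(occ)
        assert ((out["index"] >= 0) & (out["index"] <= 1)).all()

    def test_index_one_iff_everywhere(self, rng):
        occ = pd.DataFrame(rng.random((10, 3)), index=[f"t{i}" for i in range(10)])
        occ.iloc[4] = 1.0
        out = ranking_index(occ)
        assert (out["index"] == 1.0).sum() == 1
        assert out.index[out["rank"] == 1][0] == "t4"

    def test_ranking_is_permutation(self, rng):
        occ = pd.DataFrame(rng.random((15, 2)), index=[f"t{i}" for i in range(15)])
        out = ranking_index(occ)
        assert sorted(out["rank"]) == list(range(1, 16))

    def test_tie_break_by_abundance_then_id(self):
        occ = pd.DataFrame({"A": [0.5, 0.5, 0.5]}, index=["c", "a", "b"])
        mra = pd.Series([0.1, 0.1, 0.9], index=["c", "a", "b"])
        out = ranking_index(occ, mra)
        assert list(out.index) == ["b", "a", "c"]

    def test_invariant_to_taxon_and_sample_order(self, grouped_table,
                                                 grouped_metadata):
        base = rank_taxa(grouped_table, grouped_metadata, "site")
        shuffled = grouped_table.select_taxa(["t3", "t1", "t4", "t2"])
        shuffled = shuffled.select_samples(list(reversed(shuffled.sample_ids)))
        other = rank_taxa(shuffled, grouped_metadata, "site")
        for t in grouped_table.taxon_ids:
            assert base.loc[t, "index"] == other.loc[t, "index"]
            assert base.loc[t, "rank"] == other.loc[t, "rank"]

    def test_single_group_degenerates_to_occupancy_sort(self, rng):
        table = random_table(rng, n_samples=10, n_taxa=12)
        ranked = rank_taxa(table, grouping="none")
        occ = ranked["overall_occupancy"]
        # index order must equal a plain occupancy sort (full-occupancy taxa
        # get the +1 consistency bonus, which preserves the occupancy order)
        assert (occ.diff().dropna() <= 1e-12).all()


def brute_force_contribution(table, ranked_taxa, k, relative=True):
    """Independent oracle: explicit loop over sample pairs with the top-k
    taxa zeroed out of the numerator and full-table denominators."""
    x = table.relative_abundance() if relative else table.counts.astype(float)
    core = set(ranked_taxa[:k])
    core_cols = [j for j, t in enumerate(table.taxon_ids) if t in core]
    ratios = []
    for i, j in combinations(range(table.n_samples), 2):
        num_all = sum(abs(x[i, c] - x[j, c]) for c in range(table.n_taxa))
        den = sum(x[i, c] + x[j, c] for c in range(table.n_taxa))
        if den == 0 or num_all == 0:
            continue  # identical pair: excluded
        bc_all = num_all / den
        num_core = sum(abs(x[i, c] - x[j, c]) for c in core_cols)
        ratios.append((num_core / den) / bc_all)
    return float(np.mean(ratios))


class TestContributionCurve:
    def test_full_core_contributes_everything(self, grouped_table):
        ranked = rank_taxa(grouped_table, grouping="none")
        curve = bc_contribution_curve(grouped_table, ranked.index)
        assert curve[-1] == pytest.approx(1.0)

    def test_toy_table_matches_brute_force_at_k2(self, rng):
        table = random_table(rng, n_samples=3, n_taxa=4)
        ranked = rank_taxa(table, grouping="none")
        curve = bc_contribution_curve(table, ranked.index)
        oracle = brute_force_contribution(table, list(ranked.index), 2)
        assert curve[1] == pytest.approx(oracle, abs=1e-12)

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(25):
            table = random_table(rng, n_samples=5, n_taxa=8)
            ranked = rank_taxa(table, grouping="none")
            curve = bc_contribution_curve(table, ranked.index)
            for k in (1, 3, 8):
                oracle = brute_force_contribution(table, list(ranked.index), k)
                assert curve[k - 1] == pytest.approx(oracle, abs=1e-9)

    def test_counts_mode_matches_brute_force(self, rng):
        table = random_table(rng, n_samples=4, n_taxa=6)
        ranked = rank_taxa(table, grouping="none")
        curve = bc_contribution_curve(table, ranked.index, relative=False)
        oracle = brute_force_contribution(table, list(ranked.index), 3,
                                          relative=False)
        assert curve[2] == pytest.approx(oracle, abs=1e-12)

    def test_non_decreasing(self, rng):
        table = random_table(rng, n_samples=6, n_taxa=10)
        ranked = rank_taxa(table, grouping="none")
        curve = bc_contribution_curve(table, ranked.index)
        assert (np.diff(curve) >= -1e-9).all()

    def test_identical_samples_pair_excluded(self):
        counts = np.array([[5, 5], [5, 5], [1, 9]])
        t = AbundanceTable(counts, ["a", "b", "c"], ["x", "y"])
        ranked = rank_taxa(t, grouping="none")
        curve = bc_contribution_curve(t, ranked.index)
        assert curve[-1] == pytest.approx(1.0)

    def test_all_identical_is_error(self):
        counts = np.array([[5, 5], [5, 5]])
        t = AbundanceTable(counts, ["a", "b"], ["x", "y"])
        ranked = rank_taxa(t, grouping="none")
        with pytest.raises(ValueError, match="identical"):
            bc_contribution_curve(t, ranked.index)

    def test_needs_two_samples(self, rng):
        t = AbundanceTable(np.array([[1, 2]]), ["a"], ["x", "y"])
        with pytest.raises(ValueError):
            bc_contribution_curve(t, ["x", "y"])


class TestLast2pct:
    def test_spec_curve(self):
        # ratios: 0.60/0.50 = 1.20, 0.63/0.60 = 1.05, 0.635/0.63 ~ 1.0079
        assert select_core_last2pct([0.50, 0.60, 0.63, 0.635]) == 3

    def test_flat_curve_keeps_only_first(self):
        assert select_core_last2pct([0.5, 0.5, 0.5, 0.5]) == 1

    def test_growing_curve_keeps_everything(self):
        curve = [0.1 * 1.05 ** i for i in range(8)]
        assert select_core_last2pct(curve) == 8

    def test_last_not_first_qualifying_rank(self):
        # dip below 2% then a later >=2% jump: the later rank wins
        assert select_core_last2pct([0.50, 0.60, 0.605, 0.70, 0.703]) == 4

    def test_leading_zeros_always_included(self):
        assert select_core_last2pct([0.0, 0.0, 0.3, 0.301]) == 3

    def test_empty_curve_is_error(self):
        with pytest.raises(ValueError):
            select_core_last2pct([])


class TestElbow:
    def test_spec_curve(self):
        # fo_diff(4) = (0.9-0.1)/4 - (0.92-0.9)/2 = 0.19
        # fo_diff(5) = (0.91-0.1)/5 - (0.92-0.91)/1 = 0.152
        assert select_core_elbow([0.1, 0.2, 0.3, 0.9, 0.91, 0.92]) == 4

    def test_single_step_at_rank_two(self):
        assert select_core_elbow([0.0, 1.0, 1.0, 1.0]) == 2

    def test_exhaustive_oracle_on_random_curves(self, rng):
        def oracle(curve):
            n = len(curve)
            best_i, best_v = None, -np.inf
            for i in range(1, n):
                v = (curve[i - 1] - curve[0]) / i \
                    - (curve[-1] - curve[i - 1]) / (n - i)
                if v > best_v + 1e-15:
                    best_i, best_v = i, v
            return best_i

        for _ in range(50):
            curve = np.sort(rng.random(rng.integers(3, 12)))
            assert select_core_elbow(curve) == oracle(list(curve))

    def test_short_curve_is_error(self):
        with pytest.raises(ValueError):
            select_core_elbow([0.1, 0.2])


class TestPhylumComposition:
    def test_partition(self, taxonomy4):
        comp = core_phylum_composition(["t1", "t2", "t3"], taxonomy4)
        assert comp == {"Firmicutes": 1, "Proteobacteria": 1, "Cyanobacteria": 1}

    def test_empty_core(self, taxonomy4):
        assert core_phylum_composition([], taxonomy4) == {}

    def test_unknown_bucket(self, taxonomy4):
        comp = core_phylum_composition(["t4"], taxonomy4)
        assert comp == {"Unknown": 1}


class TestSelectCore:
    def test_cores_are_ranking_prefixes(self, rng):
        table = random_table(rng, n_samples=8, n_taxa=12)
        cs = select_core(table)
        assert cs.core_last2pct == cs.ranked_taxa[: cs.k_last2pct]
        assert cs.core_elbow == cs.ranked_taxa[: cs.k_elbow]

    def test_to_frame_flags(self, rng):
        table = random_table(rng, n_samples=8, n_taxa=12)
        cs = select_core(table)
        frame = cs.to_frame()
        assert int(frame["in_core_last2pct"].sum()) == cs.k_last2pct
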