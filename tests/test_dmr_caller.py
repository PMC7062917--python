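import math

import numpy as np
import pandas as pd
import pytest

from methylome.dmr_caller import test_window as window_test  # noqa: N813
from methylome.dmr_caller import (
    CONTEXTS,
    DmrParams,
    annotate_dmrs,
    call_dmrs,
    cluster_dmgs,
    collect_dmgs,
    fisher_exact_p,
    shared_sites,
    venn_overlap,
    window_scan,
)
from methylome.functional_profiles import derive_elements

from conftest import make_methylome


def fisher_oracle(a, b, c, d):
    """Full enumeration of 2x2 tables with fixed margins; point-probability ordering."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def point_prob(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    p_obs = point_prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = point_prob(x)
        if px <= p_obs * (1 + 1e-12):
            total += px
    return min(total, 1.0)


class TestFisher:
    def test_enumeration_example(self):
        # margins (3,3)x(3,3): only the two extreme tables are as improbable
        assert fisher_exact_p(3, 0, 0, 3) == pytest.approx(0.1, abs=1e-12)

    def test_mode_table_gives_one(self):
        assert fisher_exact_p(5, 5, 5, 5) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("table", [(2, 7, 8, 2), (0, 5, 5, 0), (4, 4, 3, 6), (1, 0, 0, 1)])
    def test_matches_enumeration_oracle(self, table):
        assert fisher_exact_p(*table) == pytest.approx(fisher_oracle(*table), abs=1e-12)

    def test_row_swap_symmetry(self):
        assert fisher_exact_p(3, 9, 7, 2) == pytest.approx(fisher_exact_p(7, 2, 3, 9), abs=1e-12)


def _pair(rows_t, rows_c):
    return make_methylome(rows_t, "T"), make_methylome(rows_c, "C")


class TestWindowScan:
    def test_no_shared_covered_sites_gives_empty(self):
        t, c = _pair(
            [("Chr1", 10, "+", 5, 5, "CG", "CGA")],
            [("Chr1", 99, "+", 5, 5, "CG", "CGA")],
        )
        sh = shared_sites(t, c, DmrParams(), "CG")
        assert sh.empty
        assert window_scan(sh, DmrParams(), "CG").empty

    def test_shared_cytosine_count(self):
        rows = [("Chr1", 10 * i + 1, "+", 5, 5, "CG", "CGA") for i in range(12)]
        t, c = _pair(rows, rows)
        sh = shared_sites(t, c, DmrParams(), "CG")
        win = window_scan(sh, DmrParams(), "CG")
        full = win[win["start"] == 1].iloc[0]
        assert full.n_cytosines == 12

    def test_coverage_floor_applies_in_both_samples(self):
        t, c = _pair(
            [("Chr1", 10, "+", 5, 5, "CG", "CGA"), ("Chr1", 20, "+", 2, 2, "CG", "CGA")],
            [("Chr1", 10, "+", 2, 3, "CG", "CGA"), ("Chr1", 20, "+", 5, 5, "CG", "CGA")],
        )
        sh = shared_sites(t, c, DmrParams(), "CG")
        assert len(sh) == 1 and sh.iloc[0]["pos"] == 10

    def test_step_arithmetic_1100bp(self):
        rows = [("Chr1", 50, "+", 5, 5, "CG", "CGA"), ("Chr1", 1090, "+", 5, 5, "CG", "CGA")]
        t, c = _pair(rows, rows)
        sh = shared_sites(t, c, DmrParams(), "CG")
        win = window_scan(sh, DmrParams(), "CG", chrom_lengths={"Chr1": 1100})
        spans = set(zip(win["start"], win["end"]))
        assert (1, 1000) in spans and (101, 1100) in spans
        assert (win["end"] <= 1100).all()


class TestTestWindow:
    def test_equal_mls_have_zero_diff(self):
        s = window_test(10, 10, 20, 20)
        assert s["diff"] == 0.0
        assert abs(s["diff"]) <= DmrParams().min_diff

    def test_fold_change_epsilon_floor(self):
        s = window_test(5, 5, 0, 100)  # ml_ctrl = 0 -> floored at 0.01
        assert s["fold_change"] == pytest.approx(0.5 / 0.01)

    def test_fold_change_symmetric_in_direction(self):
        a = window_test(30, 10, 10, 30)
        b = window_test(10, 30, 30, 10)
        assert a["fold_change"] == pytest.approx(b["fold_change"])
        assert a["diff"] == pytest.approx(-b["diff"])
        assert a["p"] == pytest.approx(b["p"], abs=1e-12)

    def test_zero_coverage_rejected(self):
        with pytest.raises(ValueError):
            window_test(0, 0, 5, 5)


def _windows_frame(rows):
    cols = ["chrom", "start", "end", "context", "n_cytosines",
            "meth_t", "unmeth_t", "meth_c", "unmeth_c",
            "ml_treat", "ml_ctrl", "diff", "fold_change"]
    return pd.DataFrame(rows, columns=cols)


def _shared_from_sites(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "meth_t", "unmeth_t", "meth_c", "unmeth_c"])


class TestCallDmrs:
    def test_nothing_passing_prefilter_gives_no_dmrs(self):
        win = _windows_frame([
            ("Chr1", 1, 1000, "CG", 20, 100, 100, 100, 100, 0.5, 0.5, 0.0, 1.0),
        ])
        assert call_dmrs(win, _shared_from_sites([]), DmrParams()).empty

    def test_overlapping_hyper_windows_merge(self):
        # two strongly differential windows sharing 900 bp merge into one DMR
        shared = _shared_from_sites([
            ("Chr1", 1001 + 50 * i, "+", 28, 2, 6, 24) for i in range(22)
        ])
        params = DmrParams()
        win = window_scan(shared, params, "CG", chrom_lengths={"Chr1": 2500})
        dmrs = call_dmrs(win, shared, params)
        assert len(dmrs) == 1
        d = dmrs.iloc[0]
        assert d.status == "hyper"
        assert d.start <= 1001 and d.end >= 2051
        assert d.n_cytosines == 22  # distinct union, not double-counted
        assert d.q <= d.p * 1.000001 or d.q < 0.05

    def test_merged_runs_split_by_sign(self):
        hyper = [("Chr1", 101 + 40 * i, "+", 28, 2, 6, 24) for i in range(25)]
        hypo = [("Chr1", 5101 + 40 * i, "+", 6, 24, 28, 2) for i in range(25)]
        shared = _shared_from_sites(hyper + hypo)
        params = DmrParams()
        win = window_scan(shared, params, "CG", chrom_lengths={"Chr1": 7000})
        dmrs = call_dmrs(win, shared, params)
        assert set(dmrs["status"]) == {"hyper", "hypo"}
        assert len(dmrs) == 2

    def test_empty_input(self):
        assert call_dmrs(_windows_frame([]), _shared_from_sites([]), DmrParams()).empty

    def test_params_validation(self):
        with pytest.raises(ValueError):
            DmrParams(window_bp=100, step_bp=200)
        with pytest.raises(ValueError):
            DmrParams(min_diff=0)


class TestAnnotation:
    @pytest.fixture()
    def elements(self, small_genome):
        from methylome.functional_profiles import GeneModel

        genes = [
            GeneModel("gA", "Chr1", "+", 5001, 8000, [(5001, 6000), (7001, 8000)]),
            GeneModel("gB", "Chr1", "+", 20_001, 22_000, [(20_001, 22_000)]),
        ]
        return derive_elements(genes, small_genome)

    def _dmr(self, start, end, **kw):
        base = {"chrom": "Chr1", "start": start, "end": end, "context": "CG", "status": "hyper",
                "ml_treat": 0.6, "ml_ctrl": 0.2, "diff": 0.4, "fold_change": 3.0,
                "n_cytosines": 20, "p": 1e-8, "q": 1e-7}
        base.update(kw)
        return base

    def test_promoter_only(self, elements):
        dmrs = annotate_dmrs(pd.DataFrame([self._dmr(3500, 4000)]), elements)
        assert dmrs.iloc[0]["element_hits"] == "promoter"
        assert dmrs.iloc[0]["gene_ids"] == "gA"

    def test_exon_intron_boundary(self, elements):
        dmrs = annotate_dmrs(pd.DataFrame([self._dmr(5900, 6300)]), elements)
        assert dmrs.iloc[0]["element_hits"] == "exon,intron"

    def test_intergenic_dmr_excluded_from_dmgs(self, elements):
        dmrs = annotate_dmrs(pd.DataFrame([self._dmr(50_000, 51_000)]), elements)
        assert dmrs.iloc[0]["gene_ids"] == ""
        dmgs = collect_dmgs(dmrs, {"CG": _shared_from_sites([])})
        assert dmgs.empty


class TestDmgs:
    def _annotated(self, rows):
        cols = ["chrom", "start", "end", "context", "status", "ml_treat", "ml_ctrl", "diff",
                "fold_change", "n_cytosines", "p", "q", "element_hits", "gene_ids"]
        return pd.DataFrame(rows, columns=cols)

    @pytest.mark.parametrize(
        "meth_t, unmeth_t, meth_c, unmeth_c, expected_ratio, expected_status",
        [
            (1504, 8496, 1000, 9000, 1.5040, "hyper"),
            (13, 19987, 2000, 18000, 0.0065, "hypo"),
            (3000, 7000, 3000, 7000, 1.0, "unchanged"),
        ],
    )
    def test_methylation_ratio_statuses(self, meth_t, unmeth_t, meth_c, unmeth_c,
                                        expected_ratio, expected_status):
        dmrs = self._annotated([
            ("Chr1", 1001, 2000, "CG", "hyper", 0.5, 0.3, 0.2, 2.0, 20, 1e-8, 1e-7,
             "promoter", "g1"),
        ])
        shared = {"CG": _shared_from_sites([("Chr1", 1500, "+", meth_t, unmeth_t, meth_c, unmeth_c)])}
        dmgs = collect_dmgs(dmrs, shared)
        assert len(dmgs) == 1
        assert dmgs.iloc[0]["methylation_ratio"] == pytest.approx(expected_ratio, abs=5e-4)
        assert dmgs.iloc[0]["ratio_status"] == expected_status

    def test_union_of_intervals_deduplicates_sites(self):
        dmrs = self._annotated([
            ("Chr1", 1001, 2000, "CG", "hyper", 0.5, 0.3, 0.2, 2.0, 20, 1e-8, 1e-7, "exon", "g1"),
            ("Chr1", 1500, 2500, "CG", "hyper", 0.5, 0.3, 0.2, 2.0, 20, 1e-8, 1e-7, "exon", "g1"),
        ])
        shared = {"CG": _shared_from_sites([
            ("Chr1", 1600, "+", 10, 10, 5, 15),  # inside both intervals: counted once
            ("Chr1", 2400, "+", 10, 10, 5, 15),
        ])}
        dmgs = collect_dmgs(dmrs, shared)
        assert dmgs.iloc[0]["ml_treat"] == pytest.approx(0.5)
        assert dmgs.iloc[0]["n_dmrs"] == 2


class TestVenn:
    def test_identical_sets(self):
        counts = venn_overlap({"A": {"g1", "g2"}, "B": {"g1", "g2"}, "C": {"g1", "g2"}})
        assert counts["A&B&C"] == 2
        assert sum(v for k, v in counts.items() if k != "A&B&C") == 0

    def test_disjoint_sets(self):
        counts = venn_overlap({"A": {"g1"}, "B": {"g2"}})
        assert counts == {"A": 1, "B": 1, "A&B": 0}

    def test_partial_overlap_with_empty_set(self):
        counts = venn_overlap({"A": {"g1", "g2"}, "B": {"g2", "g3"}, "C": set()})
        assert counts["A&B"] == 1 and counts["A&B&C"] == 0
        assert counts["A"] == 1 and counts["B"] == 1 and counts["C"] == 0

    def test_totals_match_cardinalities(self):
        sets = {"A": {"g1", "g2", "g3"}, "B": {"g2", "g4"}, "C": {"g3", "g4", "g5"}}
        counts = venn_overlap(sets)
        for name, members in sets.items():
            total = sum(v for k, v in counts.items() if name in k.split("&"))
            assert total == len(members)

    def test_set_count_bounds(self):
        with pytest.raises(ValueError):
            venn_overlap({"A": set()})
        with pytest.raises(ValueError):
            venn_overlap({k: set() for k in "ABCD"})


class TestClustering:
    def test_identical_rows_merge_at_zero(self):
        mat = pd.DataFrame(
            [[0.1, 0.5, 0.9], [0.1, 0.5, 0.9], [0.9, 0.1, 0.4]],
            index=["g1", "g2", "g3"], columns=["s1", "s2", "s3"],
        )
        res = cluster_dmgs(mat)
        assert res.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_rows_at_distance_two(self):
        mat = pd.DataFrame([[0.0, 1.0], [1.0, 0.0]], index=["g1", "g2"], columns=["s1", "s2"])
        res = cluster_dmgs(mat)
        assert res.linkage[0, 2] == pytest.approx(2.0)

    def test_correlated_pairs_cluster_first(self):
        # hand-computed: d(g1,g2)=d(g3,g4)=0, all cross distances ~1
        mat = pd.DataFrame(
            [[0.1, 0.2, 0.3], [0.2, 0.4, 0.6], [0.3, 0.3, 0.1], [0.6, 0.6, 0.2]],
            index=["g1", "g2", "g3", "g4"], columns=["s1", "s2", "s3"],
        )
        res = cluster_dmgs(mat)
        first_two_merges = {frozenset(res.linkage[i, :2].astype(int)) for i in range(2)}
        assert first_two_merges == {frozenset({0, 1}), frozenset({2, 3})}
        order = res.leaf_order
        assert abs(order.index("g1") - order.index("g2")) == 1
        assert abs(order.index("g3") - order.index("g4")) == 1

    def test_constant_rows_dropped_with_warning(self):
        mat = pd.DataFrame(
            [[0.5, 0.5, 0.5], [0.1, 0.2, 0.3], [0.3, 0.2, 0.1]],
            index=["flat", "g1", "g2"], columns=["s1", "s2", "s3"],
        )
        with pytest.warns(UserWarning, match="constant"):
            res = cluster_dmgs(mat)
        assert "flat" not in res.gene_ids

    def test_missing_values_rejected(self):
        mat = pd.DataFrame([[0.1, np.nan], [0.2, 0.3]], index=["g1", "g2"], columns=["s1", "s2"])
        with pytest.raises(ValueError, match="impute or drop"):
            cluster_dmgs(mat)

    def test_newick_parses_and_covers_all_leaves(self):
        import io

        from Bio import Phylo

        mat = pd.DataFrame(
            np.random.default_rng(0).random((5, 3)), index=[f"g{i}" for i in range(5)],
            columns=["s1", "s2", "s3"],
        )
        res = cluster_dmgs(mat)
        tree = Phylo.read(io.StringIO(res.newick), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == sorted(res.gene_ids)
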