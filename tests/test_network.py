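"""Network assembly, gain/loss extraction, topology and enrichment."""
import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest

import cerna_sponge as cs
from cerna_sponge.inference import SpongeTriple
from conftest import random_network


def _triple(l, m, g, d, p, cond="cancer"):
    return SpongeTriple(l, m, g, d, p, cond, 100)


class TestAssembleNetwork:
    def test_shared_pair_grouped_into_one_edge(self):
        triples = [
            _triple("L1", "M1", "G1", 0.5, 0.002),
            _triple("L1", "M2", "G1", 0.8, 0.005),
            _triple("L1", "M3", "G1", 0.2, 0.001),
        ]
        net = cs.assemble_network(triples, "cancer")
        assert len(net) == 1
        edge = net.edges[("L1", "G1")]
        assert edge.mirnas == {"M1", "M2", "M3"}
        assert edge.best_delta_i == 0.8 and edge.best_p == 0.001

    def test_empty_input_gives_empty_network(self):
        net = cs.assemble_network([], "normal")
        assert len(net) == 0 and net.nodes == frozenset()

    def test_wrong_condition_rejected(self):
        with pytest.raises(cs.ValidationError):
            cs.assemble_network([_triple("L", "M", "G", 0.1, 0.01, "normal")], "cancer")

    def test_edge_count_matches_independent_grouping(self):
        rng = np.random.default_rng(0)
        triples = [
            _triple(f"L{rng.integers(30)}", f"M{rng.integers(40)}",
                    f"G{rng.integers(100)}", float(rng.normal()),
                    float(rng.uniform(1e-4, 0.01)))
            for _ in range(5000)
        ]
        net = cs.assemble_network(triples, "cancer")
        df = pd.DataFrame([(t.lncrna, t.mrna, t.mirna, t.delta_i, t.p_value)
                           for t in triples],
                          columns=["l", "g", "m", "d", "p"])
        grouped = df.groupby(["l", "g"])
        assert len(net) == grouped.ngroups
        agg = grouped.agg(d=("d", "max"), p=("p", "min"), m=("m", lambda s: frozenset(s)))
        for (l, g), row in agg.iterrows():
            edge = net.edges[(l, g)]
            assert edge.mirnas == row["m"]
            assert edge.best_delta_i == row["d"] and edge.best_p == row["p"]


def _two_condition_exprs(deltas: dict[str, tuple[float, float]], seed=0):
    """Expression with per-feature (cancer_mean, normal_mean) around tiny noise."""
    rng = np.random.default_rng(seed)
    cancer = [f"c{i}" for i in range(10)]
    normal = [f"n{i}" for i in range(10)]
    conditions = cs.ConditionTable(
        {**{s: "cancer" for s in cancer}, **{s: "normal" for s in normal}}
    )
    lnc_rows, mrna_rows, lnc_ids, mrna_ids = [], [], [], []
    for fid, (mc, mn) in deltas.items():
        row = np.concatenate([np.full(10, mc), np.full(10, mn)])
        row = row + rng.normal(0, 1e-6, 20)
        if fid.startswith("L"):
            lnc_ids.append(fid); lnc_rows.append(row)
        else:
            mrna_ids.append(fid); mrna_rows.append(row)
    lnc = cs.ExpressionMatrix(
        pd.DataFrame(lnc_rows, index=lnc_ids, columns=cancer + normal), "lncRNA")
    mrna = cs.ExpressionMatrix(
        pd.DataFrame(mrna_rows, index=mrna_ids, columns=cancer + normal), "mRNA")
    return lnc, mrna, conditions


class TestLinkScore:
    def test_sum_of_endpoint_deltas(self):
        lnc, mrna, cond = _two_condition_exprs({"L1": (7, 5), "G1": (6.5, 5)})
        rec = cs.link_score(("L1", "G1"), lnc, mrna, cond)
        assert rec.delta_lnc == pytest.approx(2.0, abs=1e-4)
        assert rec.delta_mrna == pytest.approx(1.5, abs=1e-4)
        assert rec.link_score == pytest.approx(3.5, abs=1e-4)

    def test_identical_condition_means_score_zero(self):
        lnc, mrna, cond = _two_condition_exprs({"L1": (5, 5), "G1": (5, 5)})
        assert cs.link_score(("L1", "G1"), lnc, mrna, cond).link_score == pytest.approx(
            0.0, abs=1e-4
        )

    def test_matches_independent_recomputation(self):
        rng = np.random.default_rng(1)
        deltas = {f"L{i}": tuple(rng.uniform(3, 8, 2)) for i in range(5)}
        deltas |= {f"G{i}": tuple(rng.uniform(3, 8, 2)) for i in range(5)}
        lnc, mrna, cond = _two_condition_exprs(deltas, seed=1)
        for i in range(5):
            rec = cs.link_score((f"L{i}", f"G{i}"), lnc, mrna, cond)
            exp_l = lnc.data.loc[f"L{i}"]
            exp_g = mrna.data.loc[f"G{i}"]
            cancer = cond.samples("cancer")
            normal = cond.samples("normal")
            want = (exp_l[cancer].mean() - exp_l[normal].mean()
                    + exp_g[cancer].mean() - exp_g[normal].mean())
            assert rec.link_score == pytest.approx(want, abs=1e-12)


class TestExtractGainLoss:
    def _nets_and_exprs(self, n_null=90, n_planted=10, seed=2):
        deltas = {}
        edges = {}
        for i in range(n_planted):
            deltas[f"Lp{i}"] = (7.0, 5.0)
            deltas[f"Gp{i}"] = (7.0, 5.0)
            edges[(f"Lp{i}", f"Gp{i}")] = cs.EdgeData(frozenset({"M1"}), 0.5, 0.001)
        rng = np.random.default_rng(seed)
        for i in range(n_null):
            base_l, base_g = rng.uniform(4, 6, 2)
            eps = rng.uniform(-0.01, 0.01, 2)
            deltas[f"Ln{i}"] = (base_l + eps[0], base_l)
            deltas[f"Gn{i}"] = (base_g + eps[1], base_g)
            edges[(f"Ln{i}", f"Gn{i}")] = cs.EdgeData(frozenset({"M2"}), 0.3, 0.005)
        lnc, mrna, cond = _two_condition_exprs(deltas, seed=seed)
        return cs.CeRNANetwork("cancer", edges), lnc, mrna, cond

    def test_planted_gain_edges_recovered_exactly(self):
        cancer_net, lnc, mrna, cond = self._nets_and_exprs()
        # matching top_frac: the planted edges are exactly the top 10 of
        # the sign-passing (eligible) edges by link score
        n_eligible = 0
        for edge in cancer_net.edges:
            rec = cs.link_score(edge, lnc, mrna, cond)
            n_eligible += rec.delta_lnc > 0 and rec.delta_mrna > 0
        gain, loss = cs.extract_gain_loss(
            cancer_net, cs.CeRNANetwork("normal", {}), lnc, mrna, cond,
            top_frac=10 / n_eligible,
        )
        assert set(gain.edges) == {(f"Lp{i}", f"Gp{i}") for i in range(10)}
        assert len(loss) == 0

    def test_sign_rule_excludes_mixed_direction_edges(self):
        deltas = {"L1": (9, 5), "G1": (3, 5)}  # lnc up, mrna down
        lnc, mrna, cond = _two_condition_exprs(deltas)
        net = cs.CeRNANetwork(
            "cancer", {("L1", "G1"): cs.EdgeData(frozenset({"M"}), 1.0, 1e-4)}
        )
        gain, _ = cs.extract_gain_loss(
            net, cs.CeRNANetwork("normal", {}), lnc, mrna, cond, top_frac=1.0
        )
        assert len(gain) == 0

    def test_common_pairs_removed_before_ranking(self):
        deltas = {"L1": (9, 5), "G1": (9, 5)}
        lnc, mrna, cond = _two_condition_exprs(deltas)
        edge = {("L1", "G1"): cs.EdgeData(frozenset({"M"}), 1.0, 1e-4)}
        gain, loss = cs.extract_gain_loss(
            cs.CeRNANetwork("cancer", dict(edge)),
            cs.CeRNANetwork("normal", dict(edge)),
            lnc, mrna, cond, top_frac=1.0,
        )
        assert len(gain) == 0 and len(loss) == 0

    def test_gain_and_loss_disjoint_with_consistent_signs(self):
        rng = np.random.default_rng(5)
        deltas, c_edges, n_edges = {}, {}, {}
        for i in range(40):
            deltas[f"L{i}"] = tuple(rng.uniform(4, 8, 2))
            deltas[f"G{i}"] = tuple(rng.uniform(4, 8, 2))
        for i in range(30):
            c_edges[(f"L{i}", f"G{i}")] = cs.EdgeData(frozenset({"M"}), 0.1, 0.01)
        for i in range(10, 40):
            n_edges[(f"L{i}", f"G{i}")] = cs.EdgeData(frozenset({"M"}), 0.1, 0.01)
        lnc, mrna, cond = _two_condition_exprs(deltas, seed=5)
        gain, loss = cs.extract_gain_loss(
            cs.CeRNANetwork("cancer", c_edges), cs.CeRNANetwork("normal", n_edges),
            lnc, mrna, cond, top_frac=0.5,
        )
        assert not set(gain.edges) & set(loss.edges)
        for edge in gain.edges:
            rec = cs.link_score(edge, lnc, mrna, cond)
            assert rec.delta_lnc > 0 and rec.delta_mrna > 0
        for edge in loss.edges:
            rec = cs.link_score(edge, lnc, mrna, cond)
            assert rec.delta_lnc < 0 and rec.delta_mrna < 0


class TestDegreesAndHubs:
    def test_star_center_above_threshold_is_only_hub(self):
        edges = {("Lc", f"G{i}"): cs.EdgeData(frozenset({"M"}), 0.1, 0.01)
                 for i in range(16)}
        net = cs.CeRNANetwork("cancer", edges)
        assert cs.find_hubs(net, min_degree=15) == ["Lc"]

    def test_degree_exactly_at_threshold_is_not_hub(self):
        edges = {("Lc", f"G{i}"): cs.EdgeData(frozenset({"M"}), 0.1, 0.01)
                 for i in range(15)}
        net = cs.CeRNANetwork("cancer", edges)
        assert cs.find_hubs(net, min_degree=15) == []

    def test_degrees_match_independent_adjacency_count(self):
        net = random_network(21, n_edges=80)
        degrees = cs.node_degrees(net)
        manual: dict[str, set] = {}
        for l, g in net.edges:
            manual.setdefault(l, set()).add(g)
            manual.setdefault(g, set()).add(l)
        assert degrees == {n: len(nb) for n, nb in manual.items()}

    def test_mirna_counting_convention(self):
        edges = {
            ("L1", "G1"): cs.EdgeData(frozenset({"M1", "M2"}), 0.1, 0.01),
            ("L1", "G2"): cs.EdgeData(frozenset({"M2", "M3"}), 0.1, 0.01),
        }
        net = cs.CeRNANetwork("cancer", edges)
        deg = cs.node_degrees(net, count_mirnas=True)
        assert deg["L1"] == 2 + 3  # 2 mRNA partners + 3 distinct mediators


class TestCompareLncrnaProperties:
    def test_identical_distributions_null(self):
        values = list(range(1, 21)) * 2
        ann = cs.GeneAnnotation(pd.DataFrame(
            {"length": [v * 100 for v in values], "exons": [v % 5 + 1 for v in values]},
            index=pd.Index([f"L{i:02d}" for i in range(40)], name="feature_id")))
        in_ids = [f"L{i:02d}" for i in range(20)]  # same multiset as the rest
        res = cs.compare_lncrna_properties(in_ids, ann.table.index, ann)
        assert res["length"].u_statistic == pytest.approx(20 * 20 / 2)
        assert res["length"].p_value > 0.9

    def test_complete_separation_extreme_p(self):
        ann = cs.GeneAnnotation(pd.DataFrame(
            {"length": list(range(100, 110)) + list(range(10, 20)),
             "exons": [5] * 10 + [2] * 10},
            index=pd.Index([f"L{i:02d}" for i in range(20)], name="feature_id")))
        in_ids = [f"L{i:02d}" for i in range(10)]  # all longer than the rest
        res = cs.compare_lncrna_properties(in_ids, ann.table.index, ann)
        assert res["length"].u_statistic == 100.0
        assert res["length"].p_value < 1e-3

    def test_planted_sponges_longer_by_construction(self, default_dataset):
        ds = default_dataset
        planted_lnc = {t[0] for t in ds.truth.planted_triples}
        res = cs.compare_lncrna_properties(
            planted_lnc, ds.expr_lnc.feature_ids, ds.annotation
        )
        assert res["length"].fold_change == pytest.approx(1.8, abs=0.25)
        assert res["length"].p_value < 0.01

    def test_empty_group_rejected(self, default_dataset):
        ds = default_dataset
        with pytest.raises(cs.ValidationError):
            cs.compare_lncrna_properties(
                set(ds.expr_lnc.feature_ids), ds.expr_lnc.feature_ids, ds.annotation
            )


class TestSetEnrichment:
    def test_zero_overlap_gives_p_one(self):
        res = cs.set_enrichment({"a", "b"}, {"c", "d"}, universe_size=100)
        assert res.overlap == 0 and res.p_value == 1.0

    def test_full_overlap_matches_exhaustive_enumeration(self):
        universe = [f"x{i}" for i in range(20)]
        reference = set(universe[:5])
        hits = set(universe[:5])
        res = cs.set_enrichment(hits, reference, 20)
        # enumerate all C(20,5) draws; count those containing >= 5 reference ids
        count = sum(
            1 for draw in itertools.combinations(universe, 5)
            if len(set(draw) & reference) >= 5
        )
        assert count == 1
        assert res.p_value == pytest.approx(1 / comb(20, 5), rel=1e-12)

    def test_degenerate_universe_gives_p_one(self):
        ids = {f"x{i}" for i in range(10)}
        assert cs.set_enrichment(ids, ids, 10).p_value == pytest.approx(1.0)

    def test_impossible_counts_rejected(self):
        with pytest.raises(cs.ValidationError):
            cs.set_enrichment({"a"}, {f"x{i}" for i in range(30)}, universe_size=20)
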