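import numpy as np
import pandas as pd
import pytest
from scipy import stats

import _oracles
from conftest import make_escore_matrix
from esgamap import networks, synthgen
from esgamap.calibrate import AnnotationMap
from esgamap.networks import (call_interactions, crosstalk_matrix,
                              group_compare, topology_stats)


def pair_frame(e_values, p=1e-4):
    rows = []
    k = 0
    n = len(e_values)
    for a in range(100):
        for b in range(a + 1, 100):
            if k >= n:
                break
            rows.append({"gene_a": f"g{a:03d}", "gene_b": f"g{b:03d}",
                         "E": e_values[k], "p": p, "sign_conflict": False})
            k += 1
    return pd.DataFrame(rows)


class TestCallInteractions:
    def test_all_below_cutoff_gives_empty_network(self):
        pairs = pair_frame(np.linspace(-1.9, 1.9, 50))
        assert len(call_interactions(pairs)) == 0

    def test_boundary_value_is_inclusive(self):
        pairs = pair_frame([-2.0, 2.0, -1.999, 1.999])
        edges = call_interactions(pairs)
        assert set(edges["E"]) == {-2.0, 2.0}
        assert list(edges.sort_values("E")["sign"]) == ["aggravating", "alleviating"]

    def test_count_matches_brute_force_scan(self):
        rng = np.random.default_rng(0)
        e = rng.normal(0, 1.5, 1200)
        pairs = pair_frame(e)
        edges = call_interactions(pairs, apply_fdr=False)
        brute = sum(1 for v in e if v <= -2 or v >= 2)
        assert len(edges) == brute

    def test_single_cell_boundary_perturbation_changes_one_call(self):
        e = np.array([-2.5, -1.0, 0.5, 2.4, 1.2])
        base = call_interactions(pair_frame(e), apply_fdr=False)
        e2 = e.copy()
        e2[1] = -2.1  # crosses the negative cutoff
        after = call_interactions(pair_frame(e2), apply_fdr=False)
        assert len(after) == len(base) + 1
        diff = set(map(tuple, after[["gene_a", "gene_b"]].values)) \
            - set(map(tuple, base[["gene_a", "gene_b"]].values))
        assert len(diff) == 1

    def test_fdr_requires_pvalues(self):
        pairs = pair_frame([3.0]).assign(p=np.nan)
        with pytest.raises(ValueError):
            call_interactions(pairs, apply_fdr=True)


class TestTopologyStats:
    def test_star_graph_closed_form(self):
        edges = pd.DataFrame({"gene_a": ["hub"] * 5,
                              "gene_b": [f"leaf{i}" for i in range(5)]})
        stats_df = topology_stats(edges).set_index("gene")
        assert stats_df.loc["hub", "degree"] == 5
        assert stats_df.loc["hub", "betweenness"] == pytest.approx(1.0)
        assert np.allclose(stats_df.drop("hub")["betweenness"], 0.0)

    def test_empty_graph(self):
        assert len(topology_stats(pd.DataFrame(columns=["gene_a", "gene_b"]))) == 0

    def test_random_graph_matches_bfs_oracle(self):
        rng = np.random.default_rng(1)
        nodes = [f"n{i}" for i in range(30)]
        edge_set = [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1:]
                    if rng.random() < 0.12]
        edges = pd.DataFrame(edge_set, columns=["gene_a", "gene_b"])
        stats_df = topology_stats(edges).set_index("gene")
        oracle = _oracles.betweenness_bfs(sorted({g for e in edge_set for g in e}),
                                          edge_set)
        for gene, expected in oracle.items():
            assert stats_df.loc[gene, "betweenness"] == pytest.approx(expected,
                                                                      abs=1e-9)


class TestGroupCompare:
    def test_fisher_ratio_matches_enumeration(self):
        edges = pd.DataFrame({
            "gene_a": ["e1", "e1", "e2", "n1", "n2", "n3", "n4", "n5"],
            "gene_b": ["e2", "e3", "e3", "n2", "n3", "n4", "n5", "n6"],
            "sign": ["alleviating"] * 3 + ["aggravating"] * 1 + ["alleviating"] * 1
                    + ["aggravating"] * 3,
        })
        groups = {g: g.startswith("e") for g in
                  set(edges["gene_a"]) | set(edges["gene_b"])}
        res = group_compare(edges, groups, test="fisher_ratio")
        table = res.detail["table"]
        assert res.pvalue == pytest.approx(_oracles.fisher_two_sided(table),
                                           rel=1e-6)

    def test_fisher_small_table_equals_oracle(self):
        p_scipy = stats.fisher_exact([[3, 1], [1, 3]], alternative="two-sided")[1]
        assert p_scipy == pytest.approx(_oracles.fisher_two_sided([[3, 1], [1, 3]]),
                                        rel=1e-9)

    def test_identical_samples_give_p_one(self):
        data = pd.DataFrame({"gene": [f"g{i}" for i in range(8)],
                             "degree": [1, 2, 3, 4, 1, 2, 3, 4]})
        groups = {f"g{i}": i < 4 for i in range(8)}
        for test in ("wilcoxon", "ks"):
            res = group_compare(data, groups, test=test)
            assert res.pvalue == pytest.approx(1.0)

    def test_ks_disjoint_supports(self):
        data = pd.DataFrame({"gene": [f"g{i}" for i in range(6)],
                             "degree": [1, 2, 3, 14, 15, 16]})
        groups = {f"g{i}": i < 3 for i in range(6)}
        res = group_compare(data, groups, test="ks")
        assert res.statistic == pytest.approx(1.0)

    def test_empty_group_raises(self):
        data = pd.DataFrame({"gene": ["a", "b"], "degree": [1, 2]})
        with pytest.raises(ValueError):
            group_compare(data, {"a": True, "b": True}, test="wilcoxon")

    def test_essential_hubs_detected_by_rank_sum(self):
        """When essential genes carry higher interaction rates, their degree
        distribution shifts detectably upward."""
        truth = synthgen.generate_ground_truth(
            n_genes=120, n_modules=4, within_rate=0.06, between_rate=0.02,
            essential_fraction=0.3, essential_rate_boost=4.0, seed=21,
            conditions=("rich",))
        es = synthgen.simulate_escore_matrices(truth, noise_sd=0.4, seed=22)["rich"]
        from esgamap.scoring import pair_table
        pairs = pair_table(es)
        edges = call_interactions(pairs, apply_fdr=False)
        stats_df = topology_stats(edges)
        res = group_compare(stats_df, dict(truth.essential_flag), test="wilcoxon")
        assert res.pvalue < 0.01
        assert res.detail["median_x"] > res.detail["median_y"]


class TestCrosstalk:
    def test_planted_bridge_detected(self):
        """An aggravating bridge between two modules is the significant cell
        in >= 18 of 20 simulations."""
        hits = 0
        for k in range(20):
            truth = synthgen.generate_ground_truth(
                n_genes=60, n_modules=4, within_rate=0.0, between_rate=0.0,
                crosstalk={(0, 1): 0.4},
                effect_dist=synthgen.EffectModel(aggravating_frac=1.0),
                seed=100 + k, conditions=("rich",))
            es = synthgen.simulate_escore_matrices(truth, noise_sd=0.4,
                                                   seed=200 + k)["rich"]
            from esgamap.scoring import pair_table
            pairs = pair_table(es)
            edges = call_interactions(pairs, apply_fdr=False)
            ann = AnnotationMap(dict(truth.module_label))
            uni = pairs[np.isfinite(pairs["E"])]
            res = crosstalk_matrix(edges, uni, ann)["aggravating"]
            sig = res[res["enriched"].fillna(False)]
            target = tuple(sorted({truth.module_label[g] for g, m in
                                   truth.module_label.items()
                                   if m in ("bioprocess01", "bioprocess02")}))
            got = set(map(tuple, sig[["label_a", "label_b"]].values))
            if got == {("bioprocess01", "bioprocess02")}:
                hits += 1
        assert hits >= 18

    def test_empty_edges_give_no_significance(self):
        genes = [f"g{i}" for i in range(20)]
        ann = AnnotationMap({g: f"m{i % 2}" for i, g in enumerate(genes)})
        uni = pd.DataFrame([{"gene_a": a, "gene_b": b}
                            for i, a in enumerate(genes) for b in genes[i + 1:]])
        edges = pd.DataFrame(columns=["gene_a", "gene_b", "sign"])
        out = crosstalk_matrix(edges, uni, ann)
        for frame in out.values():
            assert not frame["enriched"].fillna(False).any()
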