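"""Network construction, degree comparison, exact ERGM MLE, membership."""

import numpy as np
import pytest

from srnakit.errors import ValidationError
from srnakit.io_formats import GeneFeature, GenomeAnnotation
from srnakit.network import (
    build_network,
    build_network_from_edges,
    degree_summary,
    fit_edge_model,
    fit_edge_model_mcmc,
    membership_proportions,
)
from srnakit.synthetic import simulate_network_nodes


class TestBuildNetwork:
    def test_three_node_cycle(self):
        net = build_network_from_edges([("A", "B"), ("B", "C"), ("C", "A")], {"A"})
        assert len(net.nodes) == 3 and net.n_edges == 3
        assert net.is_target("A") and not net.is_target("B")

    def test_duplicates_collapse_and_self_loops_drop(self, caplog):
        with caplog.at_level("WARNING"):
            net = build_network_from_edges(
                [("A", "B"), ("A", "B"), ("C", "C")], set()
            )
        assert net.n_edges == 1
        assert "duplicate" in caplog.text and "self-loop" in caplog.text

    def test_tsv_reader(self, tmp_path):
        p = tmp_path / "edges.tsv"
        p.write_text("source\ttarget\nA\tB\nB\tC\n")
        assert build_network(str(p), {"B"}).n_edges == 2

    def test_disjoint_target_set_errors_cleanly_downstream(self):
        net = build_network_from_edges([("A", "B")], {"Z"})
        assert net.target_nodes() == []
        with pytest.raises(ValidationError):
            degree_summary(net)
        with pytest.raises(ValidationError):
            fit_edge_model(net)


class TestDegreeSummary:
    def test_identical_degrees_give_zero_relative_difference(self):
        net = build_network_from_edges(
            [("A", "B"), ("B", "C"), ("C", "A")], {"A"}
        )
        s = degree_summary(net)
        assert s["relative_difference"] == 0.0

    def test_star_graph_hand_count(self):
        """Hub H -> leaves L1..L4; target leaf degree 1, others (4+1+1+1)/4."""
        edges = [("H", f"L{i}") for i in range(1, 5)]
        net = build_network_from_edges(edges, {"L1"})
        s = degree_summary(net)
        assert s["mean_degree_targets"] == 1.0
        assert s["mean_degree_nontargets"] == pytest.approx(7 / 4)
        assert s["relative_difference"] == pytest.approx(1 - 4 / 7)

    def test_simulated_deficit_recovered(self):
        nodes = [f"n{i}" for i in range(1000)]
        targets = set(nodes[:100])
        net = simulate_network_nodes(nodes, targets, 0.02, 0.2,
                                     np.random.default_rng(0))
        s = degree_summary(net)
        assert 0.1 <= s["relative_difference"] <= 0.3


def _dyad_logistic_oracle(net):
    """Independent oracle: statsmodels logistic regression over the full
    enumerated ordered-dyad list."""
    sm = pytest.importorskip("statsmodels.api")
    nodes = net.nodes
    x = {n: net.is_target(n) for n in nodes}
    rows, ys = [], []
    for i in nodes:
        for j in nodes:
            if i == j:
                continue
            rows.append([1.0, float(x[i]) + float(x[j])])
            ys.append(1.0 if net.graph.has_edge(i, j) else 0.0)
    fit = sm.Logit(np.array(ys), np.array(rows)).fit(disp=0, tol=1e-12)
    return fit.params, fit.bse


class TestErgmFit:
    def test_null_covariate_recovered_near_zero(self):
        rng = np.random.default_rng(1)
        nodes = [f"n{i}" for i in range(120)]
        net = simulate_network_nodes(nodes, set(nodes[:12]), 0.05, 0.0, rng)
        fit = fit_edge_model(net)
        assert abs(fit.theta_target) <= 2 * fit.se_target

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_enumerated_dyad_logistic_oracle(self, seed):
        """Exact MLE equals statsmodels logistic over all dyads, <= 50 nodes."""
        rng = np.random.default_rng(seed)
        nodes = [f"n{i}" for i in range(40)]
        net = simulate_network_nodes(nodes, set(nodes[:8]), 0.08, 0.3, rng)
        fit = fit_edge_model(net)
        params, bse = _dyad_logistic_oracle(net)
        assert fit.theta_edges == pytest.approx(params[0], abs=1e-6)
        assert fit.theta_target == pytest.approx(params[1], abs=1e-6)
        assert fit.se_edges == pytest.approx(bse[0], rel=1e-4)
        assert fit.se_target == pytest.approx(bse[1], rel=1e-4)

    def test_four_node_toy_against_grid_search(self):
        """Brute-force likelihood maximization over a parameter grid agrees."""
        net = build_network_from_edges(
            [("A", "B"), ("B", "A"), ("A", "C"), ("C", "D")], {"D"},
            nodes=["A", "B", "C", "D"],
        )
        fit = fit_edge_model(net)

        def loglik(te, tt):
            ll = 0.0
            for i in "ABCD":
                for j in "ABCD":
                    if i == j:
                        continue
                    eta = te + tt * ((i == "D") + (j == "D"))
                    y = 1.0 if net.graph.has_edge(i, j) else 0.0
                    ll += y * eta - np.log1p(np.exp(eta))
            return ll

        tes = np.linspace(fit.theta_edges - 0.01, fit.theta_edges + 0.01, 41)
        tts = np.linspace(fit.theta_target - 0.01, fit.theta_target + 0.01, 41)
        grid = np.array([[loglik(a, b) for b in tts] for a in tes])
        i, j = np.unravel_index(grid.argmax(), grid.shape)
        # the MLE is the grid interior maximum
        assert abs(tes[i] - fit.theta_edges) <= (tes[1] - tes[0])
        assert abs(tts[j] - fit.theta_target) <= (tts[1] - tts[0])
        assert fit.loglik == pytest.approx(loglik(fit.theta_edges, fit.theta_target))

    def test_planted_theta_recovered_within_2se(self):
        """theta_target = log(0.8) recovered within 2 SE in >= 90% of seeded
        300-node graphs (run at 30 graphs here; the full 100 runs in the
        acceptance suite)."""
        nodes = [f"n{i}" for i in range(300)]
        targets = set(nodes[:30])
        truth = np.log(0.8)
        ok = sum(
            abs(
                fit_edge_model(
                    simulate_network_nodes(nodes, targets, 0.02, 0.2,
                                           np.random.default_rng(seed))
                ).theta_target
                - truth
            )
            <= 2 * fit_edge_model(
                simulate_network_nodes(nodes, targets, 0.02, 0.2,
                                       np.random.default_rng(seed))
            ).se_target
            for seed in range(30)
        )
        assert ok >= 27

    def test_tie_prob_ratio_interpretation(self):
        rng = np.random.default_rng(3)
        nodes = [f"n{i}" for i in range(200)]
        net = simulate_network_nodes(nodes, set(nodes[:40]), 0.03, 0.2, rng)
        fit = fit_edge_model(net)
        from scipy.special import expit

        assert fit.tie_prob_ratio == pytest.approx(
            expit(fit.theta_edges + fit.theta_target) / expit(fit.theta_edges)
        )
        assert fit.tie_prob_ratio > 0

    def test_label_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        nodes = [f"n{i}" for i in range(60)]
        net = simulate_network_nodes(nodes, set(nodes[:10]), 0.05, 0.2, rng)
        relabel = {n: f"x{i}" for i, n in enumerate(reversed(nodes))}
        net2 = build_network_from_edges(
            [(relabel[u], relabel[v]) for u, v in net.graph.edges],
            {relabel[n] for n in net.target_nodes()},
            nodes=[relabel[n] for n in nodes],
        )
        a, b = fit_edge_model(net), fit_edge_model(net2)
        assert a.theta_edges == pytest.approx(b.theta_edges, abs=1e-12)
        assert a.theta_target == pytest.approx(b.theta_target, abs=1e-12)

    def test_complete_separation_raises(self):
        # targets have zero incident ties
        net = build_network_from_edges(
            [("A", "B"), ("B", "A")], {"C"}, nodes=["A", "B", "C"]
        )
        with pytest.raises(ValidationError, match="separation"):
            fit_edge_model(net)

    def test_mcmc_cross_validates_mle(self):
        rng = np.random.default_rng(6)
        nodes = [f"n{i}" for i in range(150)]
        net = simulate_network_nodes(nodes, set(nodes[:30]), 0.04, 0.2, rng)
        mle = fit_edge_model(net)
        te, tt = fit_edge_model_mcmc(net, n_iter=8000, seed=1)
        assert te == pytest.approx(mle.theta_edges, abs=3 * mle.se_edges)
        assert tt == pytest.approx(mle.theta_target, abs=3 * mle.se_target)


class TestMembership:
    def _ann(self, n=10):
        return GenomeAnnotation(
            replicons={"chr": 10_000},
            genes=[GeneFeature(f"G{i}", "chr", i * 500, i * 500 + 300, "+")
                   for i in range(n)],
        )

    def test_full_network_gives_unit_proportions(self):
        ann = self._ann(4)
        net = build_network_from_edges(
            [("G0", "G1"), ("G2", "G3")], {"G0"}, nodes=[f"G{i}" for i in range(4)]
        )
        m = membership_proportions(ann, {"G0"}, net)
        assert m["prop_targets_in_network"] == 1.0
        assert m["prop_genes_in_network"] == 1.0
        assert m["z"] == 0.0

    def test_hand_built_example(self):
        """10 genes, 4 in the network, 2 targets of which 1 in the network:
        proportions 0.5 and 0.4; z from the pooled formula."""
        ann = self._ann(10)
        net = build_network_from_edges(
            [("G0", "G1"), ("G2", "G3")], {"G0", "G9"},
            nodes=["G0", "G1", "G2", "G3"],
        )
        m = membership_proportions(ann, {"G0", "G9"}, net)
        assert m["prop_targets_in_network"] == 0.5
        assert m["prop_genes_in_network"] == 0.4
        pool = (1 + 4) / (2 + 10)
        se = np.sqrt(pool * (1 - pool) * (1 / 2 + 1 / 10))
        assert m["z"] == pytest.approx((0.5 - 0.4) / se)

    def test_proportions_bounded(self, default_dataset):
        ds = default_dataset
        m = membership_proportions(
            ds.annotation, set(ds.truth.cis_target_map().values()), ds.network
        )
        assert 0 <= m["prop_targets_in_network"] <= 1
        assert 0 <= m["prop_genes_in_network"] <= 1

    def test_empty_annotation_rejected(self):
        net = build_network_from_edges([("A", "B")], set())
        with pytest.raises(ValidationError):
            membership_proportions(GenomeAnnotation(replicons={"chr": 10}), set(), net)
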