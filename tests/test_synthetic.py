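"""Generator geometry, moments, conservation laws and determinism."""

import numpy as np
import pytest

from srnakit.errors import ConfigurationError
from srnakit.stats import calibrate_ladder
from srnakit.synthetic import (
    SimulationConfig,
    generate_genome,
    sample_names,
    simulate_all,
    simulate_counts,
    simulate_coverage,
    simulate_ladder,
    simulate_network_nodes,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"n_genes": 0},
            {"de_fraction": 1.5},
            {"srna_size_range": (10, 400)},
            {"srna_size_range": (400, 1200)},
            {"network_degree_deficit": 1.0},
            {"ladder_shape": 0.0},
            {"ladder_sizes": ()},
        ],
    )
    def test_bad_values_rejected(self, kw):
        with pytest.raises(ConfigurationError):
            SimulationConfig(**kw)

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_genome(
                SimulationConfig(replicon_lengths={"chr": 5000}, n_genes=50)
            )


class TestGenomeGeometry:
    def test_no_srnas_requested_gives_genes_only(self):
        cfg = SimulationConfig(n_cis_srnas=0, n_trans_srnas=0)
        ann, truth = generate_genome(cfg)
        assert len(ann.genes) == cfg.n_genes and truth.srnas == []

    def test_cis_srnas_strictly_inside_one_antisense_gene(self, default_dataset):
        """Every planted cis sRNA intersects exactly one opposite-strand gene
        (exhaustive interval check) and lies strictly within its body."""
        truth = default_dataset.truth
        for s in truth.srnas:
            if s.mode != "cis":
                continue
            hits = [
                g
                for g in truth.annotation.genes
                if g.replicon == s.replicon
                and g.strand != s.strand
                and g.start < s.end
                and s.start < g.end
            ]
            assert [g.locus_tag for g in hits] == [s.antisense_locus]
            host = hits[0]
            assert host.start < s.start and s.end < host.end

    def test_trans_srnas_overlap_no_gene_and_keep_margin(self, default_dataset):
        truth = default_dataset.truth
        cfg = default_dataset.config
        for s in truth.srnas:
            if s.mode != "trans":
                continue
            for g in truth.annotation.genes:
                if g.replicon != s.replicon:
                    continue
                assert g.end <= s.start - cfg.trans_margin or g.start >= s.end + cfg.trans_margin

    def test_sizes_within_configured_range(self, default_dataset):
        lo, hi = default_dataset.config.srna_size_range
        assert all(lo <= s.size <= hi for s in default_dataset.truth.srnas)

    def test_gene_packing_non_overlapping(self, default_dataset):
        by_rep = {}
        for g in default_dataset.annotation.genes:
            by_rep.setdefault(g.replicon, []).append((g.start, g.end))
        for spans in by_rep.values():
            spans.sort()
            assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))


class TestCounts:
    def test_poisson_limit_moment_match(self):
        """With dispersion -> 0, sample variance ~ mean over many draws."""
        cfg = SimulationConfig(seed=5, n_replicates_per_condition=5000)
        ann, truth = generate_genome(SimulationConfig(seed=5))
        for k in truth.feature_means:
            truth.feature_means[k] = 200.0
            truth.log2fc[k] = 0.0
            truth.dispersions[k] = 0.0
        truth.lib_factors = {s: 1.0 for s in sample_names(cfg)[0]}
        cm = simulate_counts(truth, cfg)
        y = cm.counts.to_numpy()[:20]
        ratio = y.var(axis=1, ddof=1) / y.mean(axis=1)
        assert np.abs(ratio - 1).max() < 0.1

    def test_no_planted_effect_gives_equal_condition_means(self, default_dataset):
        truth = default_dataset.truth
        cm = default_dataset.counts
        null_feats = [f for f, l in truth.log2fc.items() if l == 0.0]
        c_cols = cm.samples_in("C")
        n_cols = cm.samples_in("N")
        fc = {s: f for s, f in truth.lib_factors.items()}
        zc = cm.counts.loc[null_feats, c_cols] / [fc[s] for s in c_cols]
        zn = cm.counts.loc[null_feats, n_cols] / [fc[s] for s in n_cols]
        # pooled over ~170 null features the mean log-ratio is near zero
        lr = np.log2(zc.mean(axis=1).sum() / zn.mean(axis=1).sum())
        assert abs(lr) < 0.05

    def test_fixed_seed_reproducible(self):
        cfg = SimulationConfig(seed=3)
        a = simulate_counts(generate_genome(cfg)[1], cfg)
        b = simulate_counts(generate_genome(cfg)[1], cfg)
        assert a.counts.equals(b.counts)


class TestCoverage:
    def test_zero_counts_and_background_give_zero_coverage(self):
        cfg = SimulationConfig(seed=2, background_rate=0.0)
        ann, truth = generate_genome(cfg)
        for k in truth.feature_means:
            truth.feature_means[k] = 0.0
        cm = simulate_counts(truth, cfg)
        cov = simulate_coverage(truth, cm, cfg)
        assert all(not cov.get(r, s).any() for r in ann.replicons for s in "+-")

    def test_depth_mass_conservation(self):
        """count n, feature length 200, read length 50 -> total mass 50n."""
        cfg = SimulationConfig(seed=2, background_rate=0.0)
        ann, truth = generate_genome(cfg)
        gene = truth.annotation.genes[0]
        for k in truth.feature_means:
            truth.feature_means[k] = 0.0
        cm = simulate_counts(truth, cfg)
        cm.counts.loc[gene.locus_tag, :] = 100
        cov = simulate_coverage(truth, cm, cfg)
        total = sum(cov.get(r, s).sum() for r in ann.replicons for s in "+-")
        assert total == 100 * cfg.read_length
        # and all of it inside the feature
        assert cov.get(gene.replicon, gene.strand)[gene.start:gene.end].sum() == total

    def test_background_bounded_outside_features(self, default_dataset):
        """Depth outside all features stays near the Poisson background rate."""
        ds = default_dataset
        mask = {
            (r, s): np.ones(length, dtype=bool)
            for r, length in ds.annotation.replicons.items()
            for s in "+-"
        }
        for g in ds.annotation.genes:
            mask[(g.replicon, g.strand)][g.start:g.end] = False
        for s in ds.truth.srnas:
            mask[(s.replicon, s.strand)][s.start:s.end] = False
        rates = [
            ds.coverage.get(r, s)[mask[(r, s)]].mean()
            for r, s in mask
        ]
        assert max(rates) < 3 * ds.config.background_rate


class TestNetwork:
    def test_zero_deficit_equalizes_expected_degree(self):
        nodes = [f"n{i}" for i in range(400)]
        targets = set(nodes[:40])
        degs = {True: [], False: []}
        net = simulate_network_nodes(nodes, targets, 0.02, 0.0, np.random.default_rng(0))
        for n in nodes:
            degs[n in targets].append(net.graph.degree(n))
        assert abs(np.mean(degs[True]) / np.mean(degs[False]) - 1) < 0.1

    def test_planted_deficit_recovered_in_degree_ratio(self):
        """deficit 0.2 -> target/non-target mean degree ratio ~ 0.8 over
        Monte-Carlo repetition."""
        nodes = [f"n{i}" for i in range(300)]
        targets = set(nodes[:30])
        ratios = []
        for seed in range(100):
            net = simulate_network_nodes(
                nodes, targets, 0.02, 0.2, np.random.default_rng(seed)
            )
            dt = np.mean([net.graph.degree(n) for n in targets])
            dn = np.mean([net.graph.degree(n) for n in nodes if n not in targets])
            ratios.append(dt / dn)
        assert np.mean(ratios) == pytest.approx(0.8, abs=0.03)

    def test_no_self_loops(self, default_dataset):
        assert all(u != v for u, v in default_dataset.network.graph.edges)

    def test_deficit_one_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_network_nodes(["a", "b"], set(), 0.1, 1.0, np.random.default_rng(0))


class TestLadder:
    def test_infinite_shape_gives_exact_curve(self):
        cfg = SimulationConfig(ladder_shape=np.inf)
        df = simulate_ladder(cfg)
        mu = 1.0 / (cfg.ladder_b0 + cfg.ladder_b1 * df["distance"])
        np.testing.assert_allclose(df["size"], mu, rtol=1e-12)

    def test_coefficient_recovery_within_3se(self):
        """Fitted coefficients sit within 3 SE of truth at n=8 standards."""
        cfg = SimulationConfig(seed=9)
        df = simulate_ladder(cfg)
        cal = calibrate_ladder(df["size"], df["distance"])
        assert abs(cal.b0 - cfg.ladder_b0) < 3 * np.sqrt(cal.cov[0, 0])
        assert abs(cal.b1 - cfg.ladder_b1) < 3 * np.sqrt(cal.cov[1, 1])

    def test_fixed_seed_reproducible(self):
        cfg = SimulationConfig(seed=4)
        assert simulate_ladder(cfg).equals(simulate_ladder(cfg))

    def test_infeasible_coefficients_rejected(self):
        with pytest.raises(ConfigurationError):
            # intercept above 1/size for the largest standards -> negative distance
            simulate_ladder(SimulationConfig(ladder_b0=0.02))


def test_end_to_end_fdr_control():
    """Features called at q <= 0.05 on default simulations have empirical
    FDR <= 0.10 pooled over 20 seeds."""
    from srnakit.diffexp import run_de

    false_pos = n_called = 0
    for seed in range(20):
        ds = simulate_all(SimulationConfig(seed=seed))
        truly_de = {f for f, l in ds.truth.log2fc.items() if l != 0}
        called = [
            r.feature for r in run_de(ds.counts) if r.q is not None and r.q <= 0.05
        ]
        false_pos += sum(f not in truly_de for f in called)
        n_called += len(called)
    assert n_called > 100
    assert false_pos / n_called <= 0.10


def test_full_dataset_determinism():
    a = simulate_all(SimulationConfig(seed=21))
    b = simulate_all(SimulationConfig(seed=21))
    assert a.counts.counts.equals(b.counts.counts)
    assert a.truth.log2fc == b.truth.log2fc
    assert sorted(a.network.graph.edges) == sorted(b.network.graph.edges)
    for rep in a.annotation.replicons:
        for s in "+-":
            np.testing.assert_array_equal(a.coverage.get(rep, s), b.coverage.get(rep, s))
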