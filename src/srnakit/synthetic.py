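"""Seeded generators for every input the pipeline consumes.

The generator plants ground truth with the statistical structure the
analyses assume, so each stage can be tested for parameter recovery without
any external data:

* a two-replicon genome with non-overlapping genes on both strands, cis
  sRNAs strictly antisense within gene bodies and trans sRNAs in intergenic
  gaps kept clear of same-strand gene starts (so they are not UTR-like);
* negative-binomial counts for a replicated two-condition design with a
  planted differentially-expressed fraction;
* read-level strand-specific coverage realizing those counts as uniformly
  placed fixed-length reads plus Poisson background;
* a directed metabolic-style network in which target genes carry a planted
  tie-probability deficit on the log-odds scale (the exact generative twin
  of the node-covariate edge model fitted downstream);
* a ladder of (size, migration distance) standards with gamma noise around
  an inverse-link calibration curve.

Every generator is deterministic under the configured seed; independent
stages use independent seed-sequence spawns so adding one stage never
perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logit

from .detection import SrnaCall
from .diffexp import CountMatrix
from .errors import ConfigurationError, ValidationError
from .io_formats import GeneFeature, GenomeAnnotation, StrandCoverage
from .network import MetabolicNetwork, build_network_from_edges

_STAGE_GENOME, _STAGE_COUNTS, _STAGE_COVERAGE, _STAGE_NETWORK, _STAGE_LADDER = range(5)


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with defaults matching the design
    the analyses were built for (scaled to desk size).

    Notable defaults: sRNA sizes uniform over 101-562 nt, triplicate C vs N
    limitation, a differentially-expressed sRNA fraction of 14/99, planted
    |log2FC| of 1-2.5, 50 nt reads, a 20% connectivity deficit for target
    genes, and eight ladder standards with gamma shape 50.
    """

    seed: int = 0
    replicon_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr": 200_000, "plasmid": 40_000}
    )
    n_genes: int = 160
    gene_length_range: tuple[int, int] = (300, 1500)
    min_intergenic_gap: int = 120
    n_cis_srnas: int = 20
    n_trans_srnas: int = 10
    srna_size_range: tuple[int, int] = (101, 562)
    trans_margin: int = 60
    n_replicates_per_condition: int = 3
    de_fraction: float = 14 / 99
    gene_de_fraction: float = 0.10
    planted_log2fc_range: tuple[float, float] = (1.0, 2.5)
    dispersion_mean: float = 0.15
    dispersion_sigma: float = 0.3
    gene_mean_range: tuple[float, float] = (50.0, 5000.0)
    srna_mean_range: tuple[float, float] = (20.0, 2000.0)
    lib_factor_range: tuple[float, float] = (0.8, 1.25)
    read_length: int = 50
    background_rate: float = 0.05
    network_base_tie_prob: float = 0.02
    network_degree_deficit: float = 0.20
    ladder_sizes: tuple[float, ...] = (100, 200, 300, 400, 500, 600, 700, 800)
    ladder_b0: float = 3.0e-4
    ladder_b1: float = 1.0e-4
    ladder_shape: float = 50.0

    def __post_init__(self):
        for name in ("n_genes", "n_replicates_per_condition", "read_length"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.n_cis_srnas < 0 or self.n_trans_srnas < 0:
            raise ConfigurationError("sRNA counts must be >= 0")
        if not (0 <= self.de_fraction <= 1):
            raise ConfigurationError("de_fraction must be in [0, 1]")
        lo, hi = self.srna_size_range
        if not (50 <= lo < hi <= 1000):
            raise ConfigurationError("srna_size_range must lie within [50, 1000]")
        if not (0 <= self.network_degree_deficit < 1):
            raise ConfigurationError("network_degree_deficit must be in [0, 1)")
        if not (0 < self.network_base_tie_prob < 1):
            raise ConfigurationError("network_base_tie_prob must be in (0, 1)")
        if self.ladder_shape <= 0:
            raise ConfigurationError("ladder_shape must be > 0")
        if not self.ladder_sizes or any(s <= 0 for s in self.ladder_sizes):
            raise ConfigurationError("ladder_sizes must be non-empty and positive")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stage,))
        )

    def true_network_theta(self) -> tuple[float, float]:
        """(theta_edges, theta_target) of the generative edge model."""
        return float(logit(self.network_base_tie_prob)), float(
            np.log1p(-self.network_degree_deficit)
        )


@dataclass
class TruthSet:
    """Planted ground truth for parameter-recovery tests."""

    annotation: GenomeAnnotation
    srnas: list[SrnaCall]
    feature_means: dict[str, float]
    log2fc: dict[str, float]
    dispersions: dict[str, float]
    lib_factors: dict[str, float] = field(default_factory=dict)
    network_theta: tuple[float, float] | None = None
    ladder_coefficients: tuple[float, float] | None = None

    @property
    def feature_ids(self) -> list[str]:
        return [g.locus_tag for g in self.annotation.genes] + [s.id for s in self.srnas]

    def cis_target_map(self) -> dict[str, str]:
        return {s.id: s.antisense_locus for s in self.srnas if s.mode == "cis"}


# ---------------------------------------------------------------------------
# Genome and planted sRNAs


def _allocate(total: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of `total` across `weights`."""
    shares = total * weights / weights.sum()
    base = np.floor(shares).astype(int)
    rem = total - base.sum()
    order = np.argsort(shares - base)[::-1]
    base[order[:rem]] += 1
    return base


def generate_genome(config: SimulationConfig) -> tuple[GenomeAnnotation, TruthSet]:
    """Place genes and plant cis/trans sRNAs; also draws per-feature
    expression means, dispersions and the planted log2 fold-changes."""
    rng = config.rng(_STAGE_GENOME)
    reps = list(config.replicon_lengths)
    lengths = np.array([config.replicon_lengths[r] for r in reps], dtype=float)
    per_rep = _allocate(config.n_genes, lengths)

    genes: list[GeneFeature] = []
    gidx = 0
    for rep, n_rep in zip(reps, per_rep):
        L = config.replicon_lengths[rep]
        glen = rng.integers(*config.gene_length_range, size=n_rep, endpoint=True)
        slack = L - int(glen.sum()) - (n_rep + 1) * config.min_intergenic_gap
        if slack < 0:
            raise ConfigurationError(
                f"replicon {rep} (length {L}) cannot hold {n_rep} genes with the "
                f"configured lengths and minimum gap"
            )
        # heavy-tailed slack split so some gaps are wide enough for trans sRNAs
        shares = rng.dirichlet(np.full(n_rep + 1, 0.5)) * slack
        extra = np.floor(shares).astype(int)
        gaps = config.min_intergenic_gap + extra
        pos = 0
        for i in range(n_rep):
            pos += int(gaps[i])
            start, end = pos, pos + int(glen[i])
            gidx += 1
            genes.append(
                GeneFeature(
                    locus_tag=f"G{gidx:04d}",
                    replicon=rep,
                    start=start,
                    end=end,
                    strand=rng.choice(["+", "-"]),
                    product=f"synthetic protein {gidx}",
                )
            )
            pos = end
    annotation = GenomeAnnotation(replicons=dict(config.replicon_lengths), genes=genes)

    srnas: list[SrnaCall] = []
    # cis: strictly antisense within a host gene body
    sizes = rng.integers(*config.srna_size_range, size=config.n_cis_srnas, endpoint=True)
    host_pool = list(rng.permutation(len(genes)))
    for i, size in enumerate(sorted(sizes.tolist(), reverse=True)):
        host = None
        for j in list(host_pool):
            if genes[j].length >= size + 2:
                host = genes[j]
                host_pool.remove(j)
                break
        if host is None:
            raise ConfigurationError(
                "not enough genes long enough to host the requested cis sRNAs"
            )
        start = int(rng.integers(host.start + 1, host.end - size))
        srnas.append(
            SrnaCall(
                id=f"cis{i + 1}",
                replicon=host.replicon,
                start=start,
                end=start + size,
                strand="-" if host.strand == "+" else "+",
                mode="cis",
                antisense_locus=host.locus_tag,
                mean_depth=0.0,
            )
        )

    # trans: in intergenic gaps, clear of neighbours by the margin
    gap_list: list[tuple[str, int, int]] = []
    for rep in reps:
        L = config.replicon_lengths[rep]
        bounds = sorted((g.start, g.end) for g in annotation.genes_on(rep))
        prev = 0
        for s, e in bounds + [(L, L)]:
            if s > prev:
                gap_list.append((rep, prev, s))
            prev = max(prev, e)
    sizes = rng.integers(*config.srna_size_range, size=config.n_trans_srnas, endpoint=True)
    gap_order = list(rng.permutation(len(gap_list)))
    for i, size in enumerate(sorted(sizes.tolist(), reverse=True)):
        placed = False
        for j in list(gap_order):
            rep, gs, ge = gap_list[j]
            lo = gs + config.trans_margin
            hi = ge - config.trans_margin - size
            if hi >= lo:
                start = int(rng.integers(lo, hi + 1))
                srnas.append(
                    SrnaCall(
                        id=f"trans{i + 1}",
                        replicon=rep,
                        start=start,
                        end=start + size,
                        strand=rng.choice(["+", "-"]),
                        mode="trans",
                        antisense_locus=None,
                        mean_depth=0.0,
                    )
                )
                gap_order.remove(j)
                placed = True
                break
        if not placed:
            raise ConfigurationError(
                "not enough intergenic gaps wide enough for the requested trans sRNAs"
            )

    # expression truth
    means: dict[str, float] = {}
    lfcs: dict[str, float] = {}
    disps: dict[str, float] = {}

    def _draw_means(ids, lo, hi):
        u = rng.uniform(np.log(lo), np.log(hi), size=len(ids))
        for fid, m in zip(ids, np.exp(u)):
            means[fid] = float(m)

    gene_ids = [g.locus_tag for g in genes]
    srna_ids = [s.id for s in srnas]
    _draw_means(gene_ids, *config.gene_mean_range)
    _draw_means(srna_ids, *config.srna_mean_range)

    def _plant(ids, fraction):
        n_de = int(round(fraction * len(ids)))
        chosen = rng.choice(len(ids), size=n_de, replace=False) if n_de else []
        for fid in ids:
            lfcs[fid] = 0.0
        for j in chosen:
            mag = rng.uniform(*config.planted_log2fc_range)
            lfcs[ids[j]] = float(mag * rng.choice([-1, 1]))

    _plant(gene_ids, config.gene_de_fraction)
    _plant(srna_ids, config.de_fraction)

    sigma = config.dispersion_sigma
    all_ids = gene_ids + srna_ids
    draws = config.dispersion_mean * np.exp(
        rng.normal(-(sigma**2) / 2, sigma, size=len(all_ids))
    )
    for fid, d in zip(all_ids, draws):
        disps[fid] = float(d)

    truth = TruthSet(
        annotation=annotation,
        srnas=srnas,
        feature_means=means,
        log2fc=lfcs,
        dispersions=disps,
        network_theta=config.true_network_theta(),
        ladder_coefficients=(config.ladder_b0, config.ladder_b1),
    )
    return annotation, truth


# ---------------------------------------------------------------------------
# Counts


def sample_names(config: SimulationConfig) -> tuple[list[str], dict[str, str]]:
    n = config.n_replicates_per_condition
    names = [f"C{i + 1}" for i in range(n)] + [f"N{i + 1}" for i in range(n)]
    conditions = {s: s[0] for s in names}
    return names, conditions


def simulate_counts(truth: TruthSet, config: SimulationConfig) -> CountMatrix:
    """Negative-binomial counts per feature x sample.

    Feature mean is split symmetrically across conditions
    (mu * 2^(+lfc/2) under C, mu * 2^(-lfc/2) under N) and scaled by a
    per-sample library factor drawn once and recorded in the truth set.
    """
    rng = config.rng(_STAGE_COUNTS)
    names, conditions = sample_names(config)
    if not truth.lib_factors:
        f = rng.uniform(*config.lib_factor_range, size=len(names))
        truth.lib_factors = {s: float(v) for s, v in zip(names, f)}
    fids = truth.feature_ids
    mu = np.array([truth.feature_means[f] for f in fids])
    lfc = np.array([truth.log2fc[f] for f in fids])
    phi = np.array([truth.dispersions[f] for f in fids])
    if not (np.isfinite(mu).all() and np.isfinite(lfc).all() and np.isfinite(phi).all()):
        raise ValidationError("non-finite mean, fold-change or dispersion in truth")
    mat = np.empty((len(fids), len(names)), dtype=np.int64)
    for j, s in enumerate(names):
        shift = lfc / 2 if conditions[s] == "C" else -lfc / 2
        m = mu * (2.0**shift) * truth.lib_factors[s]
        poisson = phi <= 1e-12
        col = np.empty(len(fids), dtype=np.int64)
        if poisson.any():
            col[poisson] = rng.poisson(m[poisson])
        if (~poisson).any():
            size = 1.0 / phi[~poisson]
            p = size / (size + m[~poisson])
            col[~poisson] = rng.negative_binomial(size, p)
        mat[:, j] = col
    counts = pd.DataFrame(mat, index=fids, columns=names)
    return CountMatrix(counts=counts, conditions=conditions)


# ---------------------------------------------------------------------------
# Coverage


def simulate_coverage(
    truth: TruthSet, counts: CountMatrix, config: SimulationConfig
) -> StrandCoverage:
    """Realize counts as stranded fixed-length reads plus Poisson background.

    Each feature's read number is the rounded mean of its counts across
    samples; reads start uniformly within the feature and are truncated at
    feature boundaries (features shorter than the read length are covered
    end to end by every read).
    """
    rng = config.rng(_STAGE_COVERAGE)
    ann = truth.annotation
    L = config.read_length
    diff: dict[tuple[str, str], np.ndarray] = {
        (rep, strand): np.zeros(length + 1)
        for rep, length in ann.replicons.items()
        for strand in ("+", "-")
    }
    features: list[tuple[str, str, int, int, str]] = [
        (g.locus_tag, g.replicon, g.start, g.end, g.strand) for g in ann.genes
    ] + [(s.id, s.replicon, s.start, s.end, s.strand) for s in truth.srnas]
    count_of = counts.counts.mean(axis=1).round().astype(int)
    for fid, rep, start, end, strand in features:
        if fid not in count_of.index:
            raise ValidationError(f"no counts row for feature {fid}")
        n = int(count_of[fid])
        if n <= 0:
            continue
        d = diff[(rep, strand)]
        flen = end - start
        if flen <= L:
            d[start] += n
            d[end] -= n
        else:
            starts = rng.integers(start, end - L + 1, size=n)
            np.add.at(d, starts, 1)
            np.add.at(d, starts + L, -1)
    depth = {}
    for key, d in diff.items():
        base = np.cumsum(d[:-1])
        if config.background_rate > 0:
            base = base + rng.poisson(config.background_rate, size=base.size)
        depth[key] = base
    return StrandCoverage(replicon_lengths=dict(ann.replicons), depth=depth)


# ---------------------------------------------------------------------------
# Network


def simulate_network_nodes(
    node_ids: list[str],
    target_ids: set[str],
    base_tie_prob: float,
    deficit: float,
    rng: np.random.Generator,
) -> MetabolicNetwork:
    """Directed simple graph: each ordered dyad (i, j), i != j, is a tie
    independently with log-odds theta_edges + theta_target * (x_i + x_j),
    where theta_target = log(1 - deficit)."""
    if not (0 <= deficit < 1):
        raise ConfigurationError("deficit must be in [0, 1)")
    theta_e = logit(base_tie_prob)
    theta_t = np.log1p(-deficit)
    x = np.array([1.0 if n in target_ids else 0.0 for n in node_ids])
    eta = theta_e + theta_t * (x[:, None] + x[None, :])
    prob = 1.0 / (1.0 + np.exp(-eta))
    np.fill_diagonal(prob, 0.0)
    ties = rng.random(prob.shape) < prob
    src, dst = np.nonzero(ties)
    edges = [(node_ids[i], node_ids[j]) for i, j in zip(src, dst)]
    return build_network_from_edges(edges, set(target_ids) & set(node_ids), nodes=node_ids)


def simulate_network(
    annotation: GenomeAnnotation,
    target_set: set[str],
    config: SimulationConfig,
) -> MetabolicNetwork:
    """Generative twin of the node-covariate edge model over all genes."""
    loci = {g.locus_tag for g in annotation.genes}
    unknown = set(target_set) - loci
    if unknown:
        raise ValidationError(f"target ids not in annotation: {sorted(unknown)[:5]}")
    return simulate_network_nodes(
        [g.locus_tag for g in annotation.genes],
        set(target_set),
        config.network_base_tie_prob,
        config.network_degree_deficit,
        config.rng(_STAGE_NETWORK),
    )


# ---------------------------------------------------------------------------
# Ladder


def simulate_ladder(config: SimulationConfig, truth: TruthSet | None = None) -> pd.DataFrame:
    """(size, distance) standards: distance set by the true inverse-link
    curve, observed size gamma-distributed around the curve mean."""
    rng = config.rng(_STAGE_LADDER)
    b0, b1 = config.ladder_b0, config.ladder_b1
    sizes = np.asarray(config.ladder_sizes, dtype=float)
    eta = 1.0 / sizes
    dist = (eta - b0) / b1
    if (dist <= 0).any() or (b0 + b1 * dist <= 0).any():
        raise ConfigurationError(
            "ladder coefficients imply non-positive mean or distance over the range"
        )
    mu = 1.0 / (b0 + b1 * dist)
    if np.isfinite(config.ladder_shape):
        obs = rng.gamma(shape=config.ladder_shape, scale=mu / config.ladder_shape)
    else:
        obs = mu
    if truth is not None:
        truth.ladder_coefficients = (b0, b1)
    return pd.DataFrame({"size": obs, "distance": dist})


# ---------------------------------------------------------------------------
# Bundle


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    annotation: GenomeAnnotation
    truth: TruthSet
    counts: CountMatrix
    coverage: StrandCoverage
    network: MetabolicNetwork
    ladder: pd.DataFrame


def simulate_all(config: SimulationConfig) -> SimulatedDataset:
    """Generate every pipeline input from one seeded configuration."""
    annotation, truth = generate_genome(config)
    counts = simulate_counts(truth, config)
    coverage = simulate_coverage(truth, counts, config)
    network = simulate_network(annotation, set(truth.cis_target_map().values()), config)
    ladder = simulate_ladder(config, truth)
    return SimulatedDataset(config, annotation, truth, counts, coverage, network, ladder)
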