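"""Connectedness of sRNA target genes in a directed metabolic network.

Three readouts of the same question — are genes regulated by antisense sRNAs
less embedded in metabolism than the average gene?

* :func:`degree_summary` — plain total-degree comparison between target and
  non-target nodes.
* :func:`fit_edge_model` — a dyadic-independent exponential random graph
  model with an edges term and a node-covariate (target status) term.  With
  only these terms every ordered dyad is an independent Bernoulli draw with
  log-odds ``theta_edges + theta_target * (x_i + x_j)``, so the maximum
  likelihood estimate is exact (Newton iterations on the aggregated dyad
  likelihood; no MCMC needed).  A random-walk Metropolis sampler over the
  same likelihood is provided purely to cross-validate the fitter.
* :func:`membership_proportions` — the fraction of target genes vs all
  annotated genes that appear in the network at all, with a two-proportion
  Z-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ValidationError
from .io_formats import GenomeAnnotation

log = logging.getLogger(__name__)


@dataclass
class MetabolicNetwork:
    """Simple directed gene network with a boolean is_target node attribute."""

    graph: nx.DiGraph

    def __post_init__(self):
        for n in self.graph.nodes:
            if "is_target" not in self.graph.nodes[n]:
                raise ValidationError(f"node {n} lacks is_target attribute")
        if any(u == v for u, v in self.graph.edges):
            raise ValidationError("self-loops are not allowed")

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def is_target(self, node: str) -> bool:
        return bool(self.graph.nodes[node]["is_target"])

    def target_nodes(self) -> list[str]:
        return [n for n in self.graph.nodes if self.is_target(n)]


@dataclass(frozen=True)
class ErgmFit:
    """Exact MLE of the edges + node-covariate model.

    ``tie_prob_ratio`` is the fitted tie probability of a dyad with exactly
    one target endpoint over a baseline dyad — the model's twin of "targets
    are X% less connected".
    """

    theta_edges: float
    theta_target: float
    se_edges: float
    se_target: float
    tie_prob_ratio: float
    loglik: float
    n_nodes: int
    n_dyads: int


def build_network_from_edges(
    edges, target_set: set[str], nodes: list[str] | None = None
) -> MetabolicNetwork:
    """Assemble a simple directed network from (source, target) pairs.

    Self-loop rows are dropped with a warning; duplicate edges collapse with
    a logged count.  ``nodes`` may add isolated nodes (e.g. the full gene
    universe of a simulation).
    """
    g = nx.DiGraph()
    if nodes is not None:
        g.add_nodes_from(nodes)
    n_self = n_dup = 0
    for u, v in edges:
        if u == v:
            n_self += 1
            continue
        if g.has_edge(u, v):
            n_dup += 1
            continue
        g.add_edge(u, v)
    if n_self:
        log.warning("dropped %d self-loop edge row(s)", n_self)
    if n_dup:
        log.warning("collapsed %d duplicate edge row(s)", n_dup)
    for n in g.nodes:
        g.nodes[n]["is_target"] = n in target_set
    return MetabolicNetwork(graph=g)


def build_network(edge_list_path: str, target_set: set[str]) -> MetabolicNetwork:
    """Read a TSV edge list (columns: source, target) into a network."""
    df = pd.read_csv(edge_list_path, sep="\t", dtype=str)
    for col in ("source", "target"):
        if col not in df.columns:
            raise ValidationError(f"edge list lacks column {col!r}")
    return build_network_from_edges(
        df[["source", "target"]].itertuples(index=False, name=None), target_set
    )


def degree_summary(network: MetabolicNetwork) -> dict[str, float]:
    """Mean total degree (in + out) of target vs non-target nodes.

    relative_difference = 1 - mean_target / mean_nontarget, the "X% less
    connected" readout.
    """
    g = network.graph
    targets = network.target_nodes()
    others = [n for n in g.nodes if n not in set(targets)]
    if not targets or not others:
        raise ValidationError("need at least one target and one non-target node")
    deg = dict(g.degree())  # total degree on a DiGraph
    mt = float(np.mean([deg[n] for n in targets]))
    mn = float(np.mean([deg[n] for n in others]))
    rel = 1.0 - mt / mn if mn > 0 else np.nan
    return {
        "mean_degree_targets": mt,
        "mean_degree_nontargets": mn,
        "relative_difference": rel,
        "n_targets": len(targets),
        "n_nontargets": len(others),
    }


def _dyad_strata(network: MetabolicNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate ordered dyads by covariate sum s = x_i + x_j in {0, 1, 2}.

    Returns (n_dyads, n_ties) per stratum.
    """
    nodes = network.nodes
    x = np.array([1 if network.is_target(n) else 0 for n in nodes])
    n1 = int(x.sum())
    n0 = len(nodes) - n1
    n_dyads = np.array(
        [n0 * (n0 - 1), 2 * n0 * n1, n1 * (n1 - 1)], dtype=float
    )
    ties = np.zeros(3)
    for u, v in network.graph.edges:
        s = int(network.is_target(u)) + int(network.is_target(v))
        ties[s] += 1
    return n_dyads, ties


def fit_edge_model(network: MetabolicNetwork, tol: float = 1e-12, max_iter: int = 100) -> ErgmFit:
    """Exact MLE of the edges + node-covariate ERGM by Newton iteration.

    Because the model is dyadic-independent, the likelihood factorizes over
    ordered dyads and aggregates into three binomial strata (0, 1 or 2
    target endpoints); Newton's method on that 2-parameter logistic
    likelihood gives the exact MLE with observed-information standard
    errors.
    """
    n_dyads, ties = _dyad_strata(network)
    occupied = n_dyads > 0
    target_ties = ties[1] + ties[2]
    target_dyads = n_dyads[1] + n_dyads[2]
    if ties.sum() == 0 or ties.sum() == n_dyads.sum():
        raise ValidationError("degenerate network: all dyads tied or none")
    if occupied.sum() < 2:
        raise ValidationError(
            "degenerate covariate: need both target and non-target nodes"
        )
    if target_dyads > 0 and (target_ties == 0 or target_ties == target_dyads):
        raise ValidationError(
            "complete separation in the target-incident dyad stratum "
            "(target nodes have no ties or all ties)"
        )
    s = np.array([0.0, 1.0, 2.0])
    X = np.column_stack([np.ones(3), s])[occupied]
    nd, k = n_dyads[occupied], ties[occupied]

    beta = np.array([np.log((ties.sum() + 0.5) / (n_dyads.sum() - ties.sum() + 0.5)), 0.0])
    for _ in range(max_iter):
        eta = X @ beta
        p = expit(eta)
        grad = X.T @ (k - nd * p)
        W = nd * p * (1 - p)
        info = X.T @ (X * W[:, None])
        step = np.linalg.solve(info, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = X @ beta
    p = expit(eta)
    W = nd * p * (1 - p)
    info = X.T @ (X * W[:, None])
    cov = np.linalg.inv(info)
    ll = float(np.sum(k * eta - nd * np.log1p(np.exp(eta))))
    theta_e, theta_t = float(beta[0]), float(beta[1])
    ratio = float(expit(theta_e + theta_t) / expit(theta_e))
    return ErgmFit(
        theta_edges=theta_e,
        theta_target=theta_t,
        se_edges=float(np.sqrt(cov[0, 0])),
        se_target=float(np.sqrt(cov[1, 1])),
        tie_prob_ratio=ratio,
        loglik=ll,
        n_nodes=len(network.nodes),
        n_dyads=int(n_dyads.sum()),
    )


def fit_edge_model_mcmc(
    network: MetabolicNetwork,
    n_iter: int = 20000,
    burn_in: int = 2000,
    step: float = 0.05,
    seed: int = 0,
) -> tuple[float, float]:
    """Random-walk Metropolis over the exact dyad likelihood (flat prior).

    Exists only to cross-validate :func:`fit_edge_model`; returns posterior
    means of (theta_edges, theta_target), which should sit near the MLE.
    """
    n_dyads, ties = _dyad_strata(network)
    occupied = n_dyads > 0
    s = np.array([0.0, 1.0, 2.0])[occupied]
    nd, k = n_dyads[occupied], ties[occupied]

    def loglik(beta):
        eta = beta[0] + beta[1] * s
        return np.sum(k * eta - nd * np.log1p(np.exp(eta)))

    rng = np.random.default_rng(seed)
    mle = fit_edge_model(network)
    beta = np.array([mle.theta_edges, mle.theta_target])
    ll = loglik(beta)
    draws = []
    for t in range(n_iter):
        prop = beta + rng.normal(0, step, size=2)
        llp = loglik(prop)
        if np.log(rng.random()) < llp - ll:
            beta, ll = prop, llp
        if t >= burn_in:
            draws.append(beta.copy())
    mean = np.mean(draws, axis=0)
    return float(mean[0]), float(mean[1])


def membership_proportions(
    annotation: GenomeAnnotation,
    target_set: set[str],
    network: MetabolicNetwork,
) -> dict[str, float]:
    """Fraction of target genes vs all annotated genes present in the network,
    with a pooled two-proportion Z-test on the difference."""
    from .stats import two_proportion_ztest

    loci = {g.locus_tag for g in annotation.genes}
    if not loci:
        raise ValidationError("empty annotation")
    unknown = set(target_set) - loci
    if unknown:
        raise ValidationError(f"target ids not in annotation: {sorted(unknown)[:5]}")
    nodes = set(network.nodes)
    k_t = len(set(target_set) & nodes)
    n_t = len(target_set)
    k_all = len(loci & nodes)
    n_all = len(loci)
    if n_t == 0:
        raise ValidationError("empty target set")
    z, p = two_proportion_ztest(k_t, n_t, k_all, n_all)
    return {
        "prop_targets_in_network": k_t / n_t,
        "prop_genes_in_network": k_all / n_all,
        "n_targets_in_network": k_t,
        "n_targets": n_t,
        "z": z,
        "p": p,
    }
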