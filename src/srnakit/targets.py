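"""Target assignment for called sRNAs.

Cis-encoded sRNAs get a deterministic target: the gene on the antisense
strand.  Trans-encoded sRNAs are screened against start-codon-anchored mRNA
windows with a seed-complementarity score — the longest contiguous antisense
duplex (Watson-Crick pairs weight 1, G:U wobble weight 0.5) between any
sRNA subsequence and the window — and scored for significance against an
empirical null of dinucleotide-preserving shuffles of the sRNA.  This is a
transparent stand-in for a full thermodynamic hybridization predictor: it
reproduces the interface (ranked targets with an empirical p-value cutoff)
without duplex energies or accessibility modelling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .io_formats import GenomeAnnotation

_ALPHABET = "ACGT"
_IDX = {c: i for i, c in enumerate(_ALPHABET)}
_COMP = str.maketrans("ACGTU", "TGCAA")

# pair weights: rows = sRNA base, cols = window (sense mRNA) base.
# Watson-Crick = 1.0, G:U wobble (sRNA G vs mRNA U, or sRNA U vs mRNA G) = 0.5
_WC = np.zeros((4, 4))
for a, b in [("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")]:
    _WC[_IDX[a], _IDX[b]] = 1.0
_WOBBLE = np.zeros((4, 4))
for a, b in [("G", "T"), ("T", "G")]:
    _WOBBLE[_IDX[a], _IDX[b]] = 1.0


def _weight_matrix(wobble_weight: float) -> np.ndarray:
    return _WC + wobble_weight * _WOBBLE


@dataclass(frozen=True)
class TargetPrediction:
    srna_id: str
    target_locus: str
    score: float
    p: float | None  # None for deterministic cis assignments
    window: tuple[str, int, int]  # replicon, start, end (0-based half-open)


def assign_cis_targets(calls, annotation: GenomeAnnotation) -> dict[str, str]:
    """Map each cis call to its antisense locus (one target per cis sRNA)."""
    loci = {g.locus_tag for g in annotation.genes}
    out: dict[str, str] = {}
    for call in calls:
        if call.mode != "cis":
            continue
        if call.antisense_locus is None:
            raise ValidationError(f"cis call {call.id} lacks an antisense locus")
        if call.antisense_locus not in loci:
            raise ValidationError(
                f"cis call {call.id}: antisense locus {call.antisense_locus} "
                "not in annotation"
            )
        out[call.id] = call.antisense_locus
    return out


def _encode(seq: str) -> np.ndarray:
    s = seq.upper().replace("U", "T")
    bad = set(s) - set(_ALPHABET)
    if bad:
        raise ValidationError(f"non-ACGTU characters in sequence: {sorted(bad)}")
    return np.array([_IDX[c] for c in s], dtype=np.intp)


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMP)[::-1]


def max_seed_score(
    srna: str, window: str, seed_min: int = 7, wobble_weight: float = 0.5
) -> float:
    """Maximum weight of a contiguous antisense duplex run of length >=
    ``seed_min`` between any sRNA subsequence and the window (sense strand).

    The duplex is antiparallel, so sRNA position i+1 pairs one step leftward
    in the window; equivalently the sRNA is scanned against the reversed
    window along diagonals.  Watson-Crick pairs weigh 1, G:U wobble pairs
    ``wobble_weight`` (a mismatch breaks the run).  With ``wobble_weight=0``
    the score is exactly reverse-complement symmetric:
    score(s, w) = score(revcomp(w), revcomp(s)); wobble scoring is
    inherently direction-specific (complementing both strands turns G:U
    into the non-pairing A:C), so with wobble the symmetry is approximate.
    """
    if len(srna) < seed_min or len(window) < seed_min:
        return 0.0
    a = _encode(srna)
    b = _encode(window)[::-1]  # antiparallel pairing -> align with reversed window
    W = _weight_matrix(wobble_weight)[a[:, None], b[None, :]]
    run_score = np.zeros(len(b))
    run_len = np.zeros(len(b), dtype=np.intp)
    best = 0.0
    for i in range(len(a)):
        w = W[i]
        prev_score = np.concatenate(([0.0], run_score[:-1]))
        prev_len = np.concatenate(([0], run_len[:-1]))
        hit = w > 0
        run_score = np.where(hit, prev_score + w, 0.0)
        run_len = np.where(hit, prev_len + 1, 0)
        eligible = run_len >= seed_min
        if eligible.any():
            m = float(run_score[eligible].max())
            if m > best:
                best = m
    return best


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Altschul–Erickson shuffle preserving dinucleotide composition."""
    s = seq.upper().replace("U", "T")
    if len(s) < 3:
        return s
    # adjacency lists of the dinucleotide transition multigraph
    succ: dict[str, list[str]] = {}
    for x, y in zip(s[:-1], s[1:]):
        succ.setdefault(x, []).append(y)
    last = s[-1]
    # pick a random final edge into `last`-terminating tree (Wilson-style):
    # shuffle each adjacency list, then fix one edge per non-terminal vertex
    # so the result has an Eulerian path ending at `last`.
    for _ in range(100):
        trial = {k: list(rng.permutation(v)) for k, v in succ.items()}
        # the last listed successor of each vertex (except `last`) must lead
        # to `last` through last-successors; verify connectivity
        ok = True
        for v in trial:
            if v == last:
                continue
            node, seen = v, set()
            while node != last:
                if node not in trial or not trial[node] or node in seen:
                    ok = False
                    break
                seen.add(node)
                node = trial[node][-1]
            if not ok:
                break
        if ok:
            out = [s[0]]
            ptr = {k: 0 for k in trial}
            node = s[0]
            while True:
                lst = trial.get(node)
                if lst is None or ptr[node] >= len(lst):
                    break
                # consume non-final edges first, the reserved final edge last
                nxt = lst[ptr[node]]
                ptr[node] += 1
                out.append(nxt)
                node = nxt
            if len(out) == len(s):
                return "".join(out)
    # fallback (degenerate composition): plain shuffle of the interior
    interior = list(s[1:-1])
    rng.shuffle(interior)
    return s[0] + "".join(interior) + s[-1]


def empirical_p(observed: float, null_scores) -> float:
    """+1-smoothed empirical exceedance probability of a score."""
    null_scores = np.asarray(null_scores, dtype=float)
    return (1 + int(np.sum(null_scores >= observed))) / (null_scores.size + 1)


def gene_window(gene, genome_seq: dict[str, str], window_up: int, window_down: int):
    """Start-codon-anchored window on the mRNA sense strand.

    Returns (sequence, (replicon, start, end)); coordinates are genomic,
    clipped to the replicon.
    """
    if gene.replicon not in genome_seq:
        raise ValidationError(f"no sequence for replicon of locus {gene.locus_tag}")
    seq = genome_seq[gene.replicon]
    if gene.strand == "+":
        lo = max(0, gene.start - window_up)
        hi = min(len(seq), gene.start + window_down)
        return seq[lo:hi].upper().replace("U", "T"), (gene.replicon, lo, hi)
    lo = max(0, gene.end - window_down)
    hi = min(len(seq), gene.end + window_up)
    return revcomp(seq[lo:hi]), (gene.replicon, lo, hi)


def predict_trans_targets(
    srna_id: str,
    srna_seq: str,
    annotation: GenomeAnnotation,
    genome_seq: dict[str, str],
    window_up: int = 80,
    window_down: int = 20,
    seed_min: int = 7,
    wobble_weight: float = 0.5,
    n_shuffles: int = 200,
    p_threshold: float = 0.01,
    seed: int = 0,
) -> list[TargetPrediction]:
    """Rank candidate targets of a trans sRNA by seed-complementarity score.

    For each annotated gene the start-codon window [-window_up, +window_down]
    is scored against the sRNA; significance is the +1-smoothed empirical
    exceedance probability of the observed score among ``n_shuffles``
    dinucleotide-preserving shuffles of the sRNA.  Predictions with
    p < ``p_threshold`` are returned sorted by (p, locus_tag).
    """
    if len(srna_seq) < seed_min:
        return []
    rng = np.random.default_rng(seed)
    windows = [
        (g.locus_tag, *gene_window(g, genome_seq, window_up, window_down))
        for g in annotation.genes
    ]
    obs = {loc: max_seed_score(srna_seq, w, seed_min, wobble_weight)
           for loc, w, _span in windows}
    null = np.zeros((n_shuffles, len(windows)))
    for k in range(n_shuffles):
        shuf = dinucleotide_shuffle(srna_seq, rng)
        for j, (_loc, w, _span) in enumerate(windows):
            null[k, j] = max_seed_score(shuf, w, seed_min, wobble_weight)
    preds = []
    for j, (loc, _w, span) in enumerate(windows):
        p = empirical_p(obs[loc], null[:, j])
        if p < p_threshold:
            preds.append(
                TargetPrediction(srna_id=srna_id, target_locus=loc,
                                 score=obs[loc], p=p, window=span)
            )
    preds.sort(key=lambda t: (t.p, t.target_locus))
    return preds
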