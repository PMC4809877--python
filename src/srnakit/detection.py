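"""Coverage-based sRNA calling.

Turns the study's manual screen — scanning strand-specific read pile-ups for
expression in intergenic regions or antisense to genes — into an explicit
algorithm:

1. :func:`call_candidate_intervals` finds maximal runs of per-base depth at or
   above a threshold, merging runs separated by short zero gaps and keeping
   those within the expected sRNA size band.
2. :func:`remove_utr_like` drops candidates that sit just upstream of a
   same-strand gene start, the geometry of a 5' untranslated region rather
   than an independent transcript.
3. :func:`classify_calls` trims read-through tails that overlap same-strand
   gene bodies, then labels each surviving candidate *cis* (antisense to a
   gene, with the maximally overlapping gene as its presumed target) or
   *trans* (intergenic on both strands); anything overlapping a same-strand
   gene body is not an sRNA and is discarded.

All thresholds live in :class:`DetectionParams`; the defaults are explicit
assumptions standing in for unrecorded manual curation criteria.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from intervaltree import IntervalTree

from .errors import ValidationError
from .io_formats import STRANDS, GenomeAnnotation, StrandCoverage


@dataclass(frozen=True)
class DetectionParams:
    """Tunable thresholds for sRNA calling.

    min_depth : reads/base required for a position to count as expressed.
    min_length, max_length : size band for calls, bracketing the 101-562 nt
        range observed for bacterial sRNAs of this kind.
    merge_gap : maximal below-threshold gap (nt) bridged between runs.
    utr_max_distance : window (nt) upstream of a same-strand gene start
        within which a candidate is considered 5'-UTR-like and removed.
    min_antisense_overlap : fraction of a call's own length that must overlap
        an opposite-strand gene for a *cis* classification.
    """

    min_depth: float = 5.0
    min_length: int = 50
    max_length: int = 700
    merge_gap: int = 25
    utr_max_distance: int = 50
    min_antisense_overlap: float = 0.5

    def __post_init__(self):
        if not (0 < self.min_length < self.max_length):
            raise ValidationError("need 0 < min_length < max_length")
        if self.min_depth < 0 or self.merge_gap < 0 or self.utr_max_distance < 0:
            raise ValidationError("thresholds must be >= 0")
        if not (0 < self.min_antisense_overlap <= 1):
            raise ValidationError("min_antisense_overlap must be in (0, 1]")


@dataclass(frozen=True)
class Candidate:
    """An expressed interval before classification (0-based half-open)."""

    replicon: str
    start: int
    end: int
    strand: str
    mean_depth: float

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SrnaCall:
    """A classified sRNA call."""

    id: str
    replicon: str
    start: int
    end: int
    strand: str
    mode: str  # "cis" | "trans"
    antisense_locus: str | None
    mean_depth: float

    def __post_init__(self):
        if self.mode not in ("cis", "trans"):
            raise ValidationError(f"mode must be cis or trans, got {self.mode!r}")
        if (self.mode == "cis") != (self.antisense_locus is not None):
            raise ValidationError("mode cis iff antisense_locus present")

    @property
    def size(self) -> int:
        return self.end - self.start


def _runs_above(depth: np.ndarray, min_depth: float) -> list[tuple[int, int]]:
    mask = depth >= min_depth
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2].tolist(), edges[1::2].tolist()))


def call_candidate_intervals(
    coverage: StrandCoverage, params: DetectionParams
) -> list[Candidate]:
    """Maximal depth-above-threshold runs, gap-merged and size-filtered."""
    out: list[Candidate] = []
    for rep in coverage.replicon_lengths:
        for strand in STRANDS:
            depth = coverage.get(rep, strand)
            runs = _runs_above(depth, params.min_depth)
            merged: list[list[int]] = []
            for s, e in runs:
                if merged and s - merged[-1][1] <= params.merge_gap:
                    merged[-1][1] = e
                else:
                    merged.append([s, e])
            for s, e in merged:
                if params.min_length <= e - s <= params.max_length:
                    out.append(
                        Candidate(rep, s, e, strand, float(depth[s:e].mean()))
                    )
    return out


def remove_utr_like(
    candidates: list[Candidate],
    annotation: GenomeAnnotation,
    params: DetectionParams,
) -> list[Candidate]:
    """Drop candidates whose 3' end lies just upstream of a same-strand gene.

    For a + strand gene the suspect window is [start - utr_max_distance,
    start]; for a - strand gene (read right-to-left) it is [end,
    end + utr_max_distance].  Antisense or gene-desert candidates pass
    through untouched.
    """
    kept = []
    for cand in candidates:
        utr_like = False
        for g in annotation.genes_on(cand.replicon, cand.strand):
            if cand.strand == "+":
                dist = g.start - cand.end
            else:
                dist = cand.start - g.end
            if 0 <= dist <= params.utr_max_distance:
                utr_like = True
                break
        if not utr_like:
            kept.append(cand)
    return kept


def _gene_trees(annotation: GenomeAnnotation) -> dict[tuple[str, str], IntervalTree]:
    trees: dict[tuple[str, str], IntervalTree] = {}
    for g in annotation.genes:
        trees.setdefault((g.replicon, g.strand), IntervalTree()).addi(g.start, g.end, g)
    return trees


def _trim_same_strand(
    cand: Candidate, tree: IntervalTree, params: DetectionParams
) -> list[Candidate]:
    """Subtract same-strand gene bodies; keep sub-intervals in the size band.

    Handles read-through past a gene 3' end: the portion beyond the gene
    survives as its own candidate.  A candidate entirely inside a gene body
    vanishes.
    """
    hits = sorted(tree.overlap(cand.start, cand.end), key=lambda iv: iv.begin)
    if not hits:
        return [cand]
    pieces: list[tuple[int, int]] = []
    pos = cand.start
    for iv in hits:
        if iv.begin > pos:
            pieces.append((pos, iv.begin))
        pos = max(pos, iv.end)
    if pos < cand.end:
        pieces.append((pos, cand.end))
    return [
        replace(cand, start=s, end=e)
        for s, e in pieces
        if params.min_length <= e - s <= params.max_length
    ]


def classify_calls(
    candidates: list[Candidate],
    annotation: GenomeAnnotation,
    params: DetectionParams,
) -> list[SrnaCall]:
    """Classify candidates as cis (antisense) or trans (intergenic) sRNAs.

    A candidate overlapping an opposite-strand gene by at least
    ``min_antisense_overlap`` of its own length becomes a cis call whose
    presumed target is the maximally overlapping gene (ties broken by the
    lexicographically smaller locus_tag).  A candidate overlapping no gene on
    either strand becomes a trans call.  Everything else — same-strand gene
    overlap, or sub-threshold antisense overlap — is discarded.
    """
    trees = _gene_trees(annotation)
    empty = IntervalTree()

    trimmed: list[Candidate] = []
    for cand in candidates:
        same = trees.get((cand.replicon, cand.strand), empty)
        trimmed.extend(_trim_same_strand(cand, same, params))

    calls: list[tuple[Candidate, str, str | None]] = []
    for cand in trimmed:
        opp_strand = "-" if cand.strand == "+" else "+"
        opp = trees.get((cand.replicon, opp_strand), empty)
        hits = opp.overlap(cand.start, cand.end)
        best_locus, best_olap = None, 0
        for iv in hits:
            olap = min(cand.end, iv.end) - max(cand.start, iv.begin)
            g = iv.data
            if olap > best_olap or (olap == best_olap and best_locus is not None
                                    and g.locus_tag < best_locus):
                best_locus, best_olap = g.locus_tag, olap
        if best_olap >= params.min_antisense_overlap * cand.length and best_locus:
            calls.append((cand, "cis", best_locus))
        elif not hits:
            calls.append((cand, "trans", None))
        # else: partial antisense overlap below threshold -> not an sRNA call

    calls.sort(key=lambda t: (t[0].replicon, t[0].start, t[0].strand))
    out: list[SrnaCall] = []
    counters = {"cis": 0, "trans": 0}
    for cand, mode, locus in calls:
        counters[mode] += 1
        out.append(
            SrnaCall(
                id=f"{mode}{counters[mode]}",
                replicon=cand.replicon,
                start=cand.start,
                end=cand.end,
                strand=cand.strand,
                mode=mode,
                antisense_locus=locus,
                mean_depth=cand.mean_depth,
            )
        )
    return out


def detect_srnas(
    coverage: StrandCoverage,
    annotation: GenomeAnnotation,
    params: DetectionParams | None = None,
) -> list[SrnaCall]:
    """Full detection pipeline: call, UTR-filter, classify."""
    params = params or DetectionParams()
    cands = call_candidate_intervals(coverage, params)
    cands = remove_utr_like(cands, annotation, params)
    return classify_calls(cands, annotation, params)
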