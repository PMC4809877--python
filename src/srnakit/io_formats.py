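"""Readers and writers for the external formats the pipeline touches.

Internally every interval is 0-based, half-open, on a named replicon and
strand.  Conversion to and from the 1-based inclusive convention of GFF3
happens only here, at the I/O boundary.  bedGraph is already half-open and
passes through unchanged.

The sRNA report writer emits a table shaped like the study's summary table:
one row per called sRNA with its size, antisense target, signed
fold-difference and FDR q-value.
"""

from __future__ import annotations

import math
import re
import urllib.parse
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

STRANDS = ("+", "-")

# characters that must be percent-encoded in GFF3 attribute values
_GFF3_UNSAFE = re.compile(r"[;=&,%\t\n]")


@dataclass(frozen=True)
class GeneFeature:
    """A protein-coding gene (or other annotated feature) on a replicon.

    Coordinates are 0-based, half-open.  ``strand`` is '+' or '-'.
    """

    locus_tag: str
    replicon: str
    start: int
    end: int
    strand: str
    product: str = ""
    category: str | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"gene {self.locus_tag}: need 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"gene {self.locus_tag}: strand must be + or -, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeAnnotation:
    """Replicon lengths plus a collection of gene features."""

    replicons: dict[str, int]
    genes: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self):
        for name, length in self.replicons.items():
            if length <= 0:
                raise ValidationError(f"replicon {name}: length must be > 0, got {length}")
        seen: set[str] = set()
        for g in self.genes:
            if g.locus_tag in seen:
                raise ValidationError(f"duplicate locus_tag {g.locus_tag}")
            seen.add(g.locus_tag)
            if g.replicon not in self.replicons:
                raise ValidationError(f"gene {g.locus_tag}: unknown replicon {g.replicon}")
            if g.end > self.replicons[g.replicon]:
                raise ValidationError(
                    f"gene {g.locus_tag}: end {g.end} exceeds replicon length "
                    f"{self.replicons[g.replicon]}"
                )

    def genes_on(self, replicon: str, strand: str | None = None) -> list[GeneFeature]:
        return [
            g
            for g in self.genes
            if g.replicon == replicon and (strand is None or g.strand == strand)
        ]

    def by_locus(self) -> dict[str, GeneFeature]:
        return {g.locus_tag: g for g in self.genes}


@dataclass
class StrandCoverage:
    """Per-base read depth, one vector per (replicon, strand)."""

    replicon_lengths: dict[str, int]
    depth: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        for rep, length in self.replicon_lengths.items():
            for strand in STRANDS:
                key = (rep, strand)
                if key not in self.depth:
                    self.depth[key] = np.zeros(length)
                arr = np.asarray(self.depth[key], dtype=float)
                if arr.shape != (length,):
                    raise ValidationError(
                        f"coverage vector for {rep}{strand} has length {arr.shape}, "
                        f"replicon length is {length}"
                    )
                if np.any(arr < 0):
                    raise ValidationError(f"negative depth on {rep}{strand}")
                self.depth[key] = arr

    def get(self, replicon: str, strand: str) -> np.ndarray:
        return self.depth[(replicon, strand)]


# ---------------------------------------------------------------------------
# GFF3


def _escape_attr(value: str) -> str:
    return _GFF3_UNSAFE.sub(lambda m: urllib.parse.quote(m.group(0)), value)


def _unescape_attr(value: str) -> str:
    return urllib.parse.unquote(value)


def read_gff3(path: str) -> GenomeAnnotation:
    """Read a GFF3 file into a :class:`GenomeAnnotation`.

    Requires the ``##gff-version 3`` directive and ``##sequence-region``
    directives declaring each replicon.  Gene coordinates are converted from
    the 1-based inclusive GFF3 convention to 0-based half-open.
    """
    replicons: dict[str, int] = {}
    genes: list[GeneFeature] = []
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if not first.startswith("##gff-version 3"):
            raise ParseError("missing '##gff-version 3' directive", path, 1)
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                if line.startswith("##sequence-region"):
                    parts = line.split()
                    if len(parts) != 4:
                        raise ParseError("malformed ##sequence-region directive", path, lineno)
                    try:
                        start, end = int(parts[2]), int(parts[3])
                    except ValueError:
                        raise ParseError("non-integer sequence-region bounds", path, lineno)
                    if start != 1 or end < 1:
                        raise ParseError("sequence-region must span 1..length", path, lineno)
                    replicons[parts[1]] = end
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"expected 9 tab-separated columns, got {len(cols)}", path, lineno)
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = cols
            if ftype != "gene":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise ParseError("non-integer coordinates", path, lineno)
            if strand not in STRANDS:
                raise ParseError(f"invalid strand {strand!r}", path, lineno)
            if seqid not in replicons:
                raise ValidationError(f"{path}:{lineno}: feature on undeclared replicon {seqid!r}")
            if not (1 <= start1 <= end1 <= replicons[seqid]):
                raise ValidationError(
                    f"{path}:{lineno}: coordinates {start1}..{end1} outside replicon "
                    f"{seqid} (length {replicons[seqid]})"
                )
            attr_map: dict[str, str] = {}
            for item in attrs.split(";"):
                if not item:
                    continue
                if "=" not in item:
                    raise ParseError(f"malformed attribute {item!r}", path, lineno)
                k, v = item.split("=", 1)
                attr_map[k] = _unescape_attr(v)
            if "locus_tag" not in attr_map:
                raise ParseError("gene feature lacks locus_tag attribute", path, lineno)
            genes.append(
                GeneFeature(
                    locus_tag=attr_map["locus_tag"],
                    replicon=seqid,
                    start=start1 - 1,  # GFF3 1-based inclusive -> 0-based half-open
                    end=end1,
                    strand=strand,
                    product=attr_map.get("product", ""),
                    category=attr_map.get("category"),
                )
            )
    return GenomeAnnotation(replicons=replicons, genes=genes)


def write_gff3(annotation: GenomeAnnotation, path: str) -> None:
    """Write an annotation as GFF3 (inverse of :func:`read_gff3`)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for rep, length in annotation.replicons.items():
            fh.write(f"##sequence-region {rep} 1 {length}\n")
        for g in annotation.genes:
            attrs = f"ID={_escape_attr(g.locus_tag)};locus_tag={_escape_attr(g.locus_tag)}"
            if g.product:
                attrs += f";product={_escape_attr(g.product)}"
            if g.category is not None:
                attrs += f";category={_escape_attr(g.category)}"
            fh.write(
                "\t".join(
                    [
                        g.replicon,
                        "srnakit",
                        "gene",
                        str(g.start + 1),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# bedGraph


def _read_bedgraph_one(path: str, annotation: GenomeAnnotation) -> dict[str, np.ndarray]:
    intervals: dict[str, list[tuple[int, int, float]]] = {r: [] for r in annotation.replicons}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            cols = line.split()
            if len(cols) != 4:
                raise ParseError(f"expected 4 columns, got {len(cols)}", path, lineno)
            rep, start_s, end_s, val_s = cols
            if rep not in annotation.replicons:
                raise ValidationError(f"{path}:{lineno}: unknown replicon {rep!r}")
            try:
                start, end, val = int(start_s), int(end_s), float(val_s)
            except ValueError:
                raise ParseError("malformed interval record", path, lineno)
            if not (0 <= start < end <= annotation.replicons[rep]):
                raise ValidationError(
                    f"{path}:{lineno}: interval [{start}, {end}) outside replicon {rep}"
                )
            if val < 0:
                raise ValidationError(f"{path}:{lineno}: negative coverage value {val}")
            intervals[rep].append((start, end, val))
    out = {r: np.zeros(length) for r, length in annotation.replicons.items()}
    for rep, ivs in intervals.items():
        ivs.sort()
        prev_end = 0
        for start, end, val in ivs:
            if start < prev_end:
                raise ValidationError(
                    f"{path}: overlapping bedGraph intervals on {rep} at {start}"
                )
            out[rep][start:end] = val
            prev_end = end
    return out


def read_bedgraph_pair(
    plus_path: str, minus_path: str, annotation: GenomeAnnotation
) -> StrandCoverage:
    """Read a (+ strand, − strand) bedGraph pair into per-base depth vectors.

    Positions absent from the file have depth 0; overlapping records are
    rejected (the non-overlapping dialect is required).
    """
    plus = _read_bedgraph_one(plus_path, annotation)
    minus = _read_bedgraph_one(minus_path, annotation)
    depth = {}
    for rep in annotation.replicons:
        depth[(rep, "+")] = plus[rep]
        depth[(rep, "-")] = minus[rep]
    return StrandCoverage(replicon_lengths=dict(annotation.replicons), depth=depth)


def write_bedgraph(coverage: StrandCoverage, plus_path: str, minus_path: str) -> None:
    """Write strand coverage as a bedGraph pair (zero runs omitted)."""
    for strand, path in (("+", plus_path), ("-", minus_path)):
        with open(path, "w", encoding="utf-8") as fh:
            for rep in coverage.replicon_lengths:
                vec = coverage.get(rep, strand)
                if vec.size == 0:
                    continue
                # run-length encode constant stretches
                change = np.flatnonzero(np.diff(vec)) + 1
                starts = np.concatenate(([0], change))
                ends = np.concatenate((change, [vec.size]))
                for s, e in zip(starts, ends):
                    v = vec[s]
                    if v != 0:
                        v_repr = int(v) if float(v).is_integer() else v
                        fh.write(f"{rep}\t{s}\t{e}\t{v_repr}\n")


# ---------------------------------------------------------------------------
# sRNA report table


def signed_fold(log2fc: float) -> float:
    """Convert a log2 fold-change to the signed-ratio report convention.

    Positive values mean higher in the numerator condition (C limitation);
    the magnitude is the ratio of normalized means, always >= 1.
    """
    if not math.isfinite(log2fc):
        raise ValidationError(f"non-finite log2 fold-change {log2fc}")
    return 2.0 ** log2fc if log2fc >= 0 else -(2.0 ** (-log2fc))


SRNA_TABLE_COLUMNS = [
    "id",
    "size_nt",
    "replicon",
    "start",
    "end",
    "strand",
    "mode",
    "target_locus",
    "target_annotation",
    "fold_difference",
    "fdr_q",
]


def write_srna_table(calls, de_results, targets, path, annotation=None) -> None:
    """Write the per-sRNA summary report.

    Parameters
    ----------
    calls : sequence of SrnaCall
    de_results : mapping id -> DEResult or None
        Every call id must be present; ``None`` marks an sRNA that was not
        testable and renders as NA.
    targets : mapping id -> target locus_tag (cis assignments)
    annotation : GenomeAnnotation, optional
        Supplies target product descriptions when available.
    """
    missing = [c.id for c in calls if c.id not in de_results]
    if missing:
        raise ValidationError(f"calls without a DE record or missing marker: {missing}")
    by_locus = annotation.by_locus() if annotation is not None else {}
    rows = []
    for c in calls:
        de = de_results[c.id]
        locus = targets.get(c.id, "")
        product = by_locus[locus].product if locus in by_locus else ""
        rows.append(
            {
                "id": c.id,
                "size_nt": c.size,
                "replicon": c.replicon,
                "start": c.start,
                "end": c.end,
                "strand": c.strand,
                "mode": c.mode,
                "target_locus": locus or "NA",
                "target_annotation": product or "NA",
                "fold_difference": "NA" if de is None else f"{signed_fold(de.log2fc):.2f}",
                "fdr_q": "NA" if de is None or de.q is None or not math.isfinite(de.q)
                else f"{de.q:.3f}",
            }
        )
    df = pd.DataFrame(rows, columns=SRNA_TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_srna_table(path: str) -> pd.DataFrame:
    """Re-parse a report written by :func:`write_srna_table`."""
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


# ---------------------------------------------------------------------------
# sRNA call interchange (TSV + BED6)

CALLS_COLUMNS = ["id", "replicon", "start", "end", "strand", "size", "mode",
                 "antisense_locus", "mean_depth"]


def write_calls_tsv(calls, path: str) -> None:
    rows = [
        {
            "id": c.id, "replicon": c.replicon, "start": c.start, "end": c.end,
            "strand": c.strand, "size": c.size, "mode": c.mode,
            "antisense_locus": c.antisense_locus or "NA",
            "mean_depth": f"{c.mean_depth:.3f}",
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=CALLS_COLUMNS).to_csv(path, sep="\t", index=False)


def read_calls_tsv(path: str):
    from .detection import SrnaCall  # deferred: avoid import cycle

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    calls = []
    for _, r in df.iterrows():
        calls.append(
            SrnaCall(
                id=r["id"], replicon=r["replicon"], start=int(r["start"]),
                end=int(r["end"]), strand=r["strand"], mode=r["mode"],
                antisense_locus=None if r["antisense_locus"] == "NA" else r["antisense_locus"],
                mean_depth=float(r["mean_depth"]),
            )
        )
    return calls


def write_calls_bed6(calls, path: str) -> None:
    """BED6: name = call id, score = mean_depth x 10 capped at 1000."""
    with open(path, "w", encoding="utf-8") as fh:
        for c in calls:
            score = min(1000, int(round(c.mean_depth * 10)))
            fh.write(f"{c.replicon}\t{c.start}\t{c.end}\t{c.id}\t{score}\t{c.strand}\n")
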