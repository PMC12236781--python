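"""Readers and writers for the plain-text genomic formats the pipeline consumes.

Supported dialects: BED3/BED6, narrowPeak (10 columns, signalValue kept as the
interval score), bedGraph, BEDPE (6+ columns), and headered TSV tables for
genes, expression and variants. Coordinates are 0-based half-open internally;
a ``one_based`` flag on the interval readers converts 1-based inclusive inputs
at the boundary. Chromosome names are normalized to the "chr"-prefixed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .intervals import Element, GenomicInterval, sort_intervals

__all__ = [
    "ParseError",
    "SignalTrack",
    "ContactSet",
    "GeneRecord",
    "normalize_chrom",
    "read_intervals",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_bedpe",
    "write_bedpe",
    "read_genes",
    "read_expression",
]


class ParseError(ValueError):
    """A malformed line in an input file; carries the 1-based line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


def normalize_chrom(name) -> str:
    """Normalize chromosome naming to the "chr"-prefixed convention."""
    name = str(name).strip()
    return name if name.startswith("chr") else f"chr{name}"


def _iter_data_lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t") if "\t" in line else line.split()


def read_intervals(path, format: str = "BED", one_based: bool = False) -> list:
    """Read an interval file; returns sorted GenomicIntervals (BED) or scored
    Elements (narrowPeak, signalValue column 7 as score)."""
    fmt = format.upper()
    if fmt not in {"BED", "NARROWPEAK"}:
        raise ValueError(f"unsupported interval format: {format}")
    shift = 1 if one_based else 0
    out = []
    for lineno, fields in _iter_data_lines(path):
        if len(fields) < 3:
            raise ParseError(path, lineno, f"expected >=3 columns, got {len(fields)}")
        try:
            chrom = normalize_chrom(fields[0])
            start, end = int(fields[1]) - shift, int(fields[2])
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc)) from None
        if end <= start:
            raise ParseError(path, lineno, f"empty interval [{start}, {end})")
        strand = fields[5] if len(fields) > 5 and fields[5] in "+-." else "."
        iv = GenomicInterval(chrom, start, end, strand)
        if fmt == "NARROWPEAK":
            if len(fields) < 7:
                raise ParseError(path, lineno, "narrowPeak requires >=7 columns")
            try:
                score = float(fields[6])
            except ValueError:
                raise ParseError(path, lineno, f"bad signalValue {fields[6]!r}") from None
            name = fields[3] if len(fields) > 3 else ""
            out.append(Element(iv, score=score, name=name))
        else:
            out.append(iv)
    return sort_intervals(out)


def write_bed(path, items: Iterable, scores: bool | None = None) -> None:
    """Write intervals or elements as BED3/BED6 (BED6 when scores present)."""
    items = list(items)
    if scores is None:
        scores = any(isinstance(i, Element) for i in items)
    with open(path, "w") as fh:
        for obj in sort_intervals(items):
            if isinstance(obj, Element):
                iv, name, score = obj.interval, obj.name or ".", obj.score
            else:
                iv, name, score = obj, ".", 0.0
            if scores:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# signal tracks (bedGraph semantics)


class SignalTrack:
    """Sorted non-overlapping intervals with float values per chromosome.

    Stored as numpy arrays ``(starts, ends, values)`` keyed by chromosome;
    area/mean summaries are computed by clipping covered segments to the query.
    """

    def __init__(self, segments: Iterable[tuple[str, int, int, float]] = ()):
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in segments:
            if end <= start:
                raise ValueError(f"empty track segment [{start}, {end})")
            if not math.isfinite(value):
                raise ValueError("track values must be finite")
            by_chrom.setdefault(normalize_chrom(chrom), []).append((start, end, value))
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, segs in by_chrom.items():
            segs.sort()
            starts = np.array([s for s, _, _ in segs], dtype=np.int64)
            ends = np.array([e for _, e, _ in segs], dtype=np.int64)
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping track segments on {chrom}")
            values = np.array([v for _, _, v in segs], dtype=float)
            self._data[chrom] = (starts, ends, values)

    def chroms(self) -> list[str]:
        return sorted(self._data)

    def segments(self) -> Iterable[tuple[str, int, int, float]]:
        for chrom in self.chroms():
            starts, ends, values = self._data[chrom]
            for s, e, v in zip(starts, ends, values):
                yield chrom, int(s), int(e), float(v)

    def summarize(self, interval: GenomicInterval, stat: str = "area") -> float:
        """Area (value x covered bp) or mean (area / interval length) within
        an interval; uncovered intervals summarize to 0."""
        if stat not in {"area", "mean"}:
            raise ValueError(f"unknown stat: {stat}")
        entry = self._data.get(interval.chrom)
        area = 0.0
        if entry is not None:
            starts, ends, values = entry
            lo = int(np.searchsorted(ends, interval.start, side="right"))
            hi = int(np.searchsorted(starts, interval.end, side="left"))
            if hi > lo:
                cov = (np.minimum(ends[lo:hi], interval.end)
                       - np.maximum(starts[lo:hi], interval.start))
                area = float(np.sum(cov * values[lo:hi]))
        return area / len(interval) if stat == "mean" else area


def read_bedgraph(path) -> SignalTrack:
    segs = []
    for lineno, fields in _iter_data_lines(path):
        if len(fields) < 4:
            raise ParseError(path, lineno, f"expected 4 columns, got {len(fields)}")
        try:
            segs.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc)) from None
    return SignalTrack(segs)


def write_bedgraph(path, track: SignalTrack) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in track.segments():
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


# ---------------------------------------------------------------------------
# chromatin contacts


@dataclass(frozen=True)
class Contact:
    """One binned contact; anchors ordered in genome order."""

    chrom1: str
    start1: int
    end1: int
    chrom2: str
    start2: int
    end2: int
    confidence: float = 1.0


class ContactSet:
    """Binned anchor pairs with a fixed bin size and a minimum genomic span.

    Anchors are stored in genome order (anchor1 <= anchor2); intra-chromosomal
    pairs below ``min_span`` are rejected at construction.
    """

    def __init__(self, contacts: Iterable[Contact] = (), bin_size: int = 10_000,
                 min_span: int = 80_000):
        self.bin_size = int(bin_size)
        self.min_span = int(min_span)
        self._contacts: list[Contact] = []
        for c in contacts:
            self.add(c)

    def add(self, c: Contact) -> None:
        if (c.chrom1, c.start1) > (c.chrom2, c.start2):
            c = Contact(c.chrom2, c.start2, c.end2, c.chrom1, c.start1, c.end1, c.confidence)
        if c.chrom1 == c.chrom2 and c.start2 - c.start1 < self.min_span:
            raise ValueError(
                f"contact span {c.start2 - c.start1} below minimum {self.min_span}")
        self._contacts.append(c)

    def __len__(self) -> int:
        return len(self._contacts)

    def __iter__(self):
        return iter(self._contacts)

    def bin_of(self, position: int) -> int:
        return (position // self.bin_size) * self.bin_size

    def bin_pairs(self) -> set[tuple[str, int, str, int]]:
        """Identity of every contact at bin resolution."""
        return {(c.chrom1, self.bin_of(c.start1), c.chrom2, self.bin_of(c.start2))
                for c in self._contacts}


def read_bedpe(path, bin_size: int = 10_000, min_span: int = 80_000) -> ContactSet:
    cs = ContactSet(bin_size=bin_size, min_span=min_span)
    for lineno, fields in _iter_data_lines(path):
        if len(fields) < 6:
            raise ParseError(path, lineno, f"expected >=6 columns, got {len(fields)}")
        try:
            conf = float(fields[7]) if len(fields) > 7 and fields[7] != "." else 1.0
            c = Contact(normalize_chrom(fields[0]), int(fields[1]), int(fields[2]),
                        normalize_chrom(fields[3]), int(fields[4]), int(fields[5]), conf)
            cs.add(c)
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc)) from None
    return cs


def write_bedpe(path, contacts: ContactSet) -> None:
    with open(path, "w") as fh:
        for c in contacts:
            fh.write(f"{c.chrom1}\t{c.start1}\t{c.end1}\t{c.chrom2}\t{c.start2}\t{c.end2}"
                     f"\t.\t{c.confidence:g}\n")


# ---------------------------------------------------------------------------
# genes and expression


@dataclass(frozen=True)
class GeneRecord:
    """A gene with its TSS, body interval and per-cell-type expression."""

    gene_id: str
    body: GenomicInterval
    tss: int
    strand: str = "+"
    expression: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (self.body.start <= self.tss <= self.body.end):
            raise ValueError(f"TSS {self.tss} outside gene body of {self.gene_id}")

    @property
    def chrom(self) -> str:
        return self.body.chrom


def read_genes(path, expression_path=None) -> list[GeneRecord]:
    """Read a gene annotation TSV (gene_id, chrom, start, end, strand, tss),
    optionally joining a gene_id x cell-type expression TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    required = {"gene_id", "chrom", "start", "end", "strand", "tss"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(path, 1, f"missing columns: {sorted(missing)}")
    expr = read_expression(expression_path) if expression_path else {}
    genes = []
    for row in df.itertuples(index=False):
        body = GenomicInterval(normalize_chrom(row.chrom), int(row.start), int(row.end), row.strand)
        genes.append(GeneRecord(str(row.gene_id), body, int(row.tss), row.strand,
                                expr.get(str(row.gene_id), {})))
    return sorted(genes, key=lambda g: (g.chrom, g.body.start, g.gene_id))


def read_expression(path) -> dict[str, dict[str, float]]:
    """Read a gene_id x cell-type expression TSV to nested dicts."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str}).set_index("gene_id")
    return {gid: {ct: float(v) for ct, v in row.items()} for gid, row in df.iterrows()}
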