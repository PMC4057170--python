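"""Domain types, coordinate arithmetic, interval indexing and file I/O.

All coordinates are 0-based half-open throughout the package, matching the
BED convention: an interval ``[start, end)`` covers ``end - start`` bases and
two intervals overlap iff they share at least one base. Chromosome names are
compared by exact string equality (no ``chr`` aliasing).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

#: Strand value used when a record carries no strand information.
STRAND_UNKNOWN = "."


class ParseError(ValueError):
    """Raised when an input file violates its dialect; names the line."""

    def __init__(self, path: str, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = path
        self.lineno = lineno


@dataclass(frozen=True)
class GenomicInterval:
    """A located genomic region: peak, CpG island or random region.

    ``start`` is 0-based inclusive, ``end`` exclusive; ``end > start`` is
    enforced so zero-length intervals cannot exist.
    """

    chrom: str
    start: int
    end: int
    strand: str = STRAND_UNKNOWN
    name: str = ""
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval: [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", STRAND_UNKNOWN):
            raise ValueError(f"invalid strand: {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """Gene with transcript span and exon structure.

    The TSS is the transcript start on the plus strand and ``tx_end - 1`` on
    the minus strand; the TES is the opposite end. Exons must be sorted,
    non-overlapping and contained in the transcript span.
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.tx_end <= self.tx_start:
            raise ValueError(f"gene {self.gene_id}: empty transcript span")
        prev_end = self.tx_start - 1
        for ex in self.exons:
            if ex.chrom != self.chrom:
                raise ValueError(f"gene {self.gene_id}: exon on wrong chromosome")
            if ex.start < self.tx_start or ex.end > self.tx_end:
                raise ValueError(f"gene {self.gene_id}: exon outside span")
            if ex.start <= prev_end:
                raise ValueError(f"gene {self.gene_id}: exons unsorted/overlapping")
            prev_end = ex.end - 1

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def tes(self) -> int:
        return self.tx_end - 1 if self.strand == "+" else self.tx_start

    @property
    def length(self) -> int:
        return self.tx_end - self.tx_start

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.tx_start, self.tx_end, self.strand, self.gene_id
        )


@dataclass(frozen=True)
class CpGRecord:
    """Methylation call for one CpG dinucleotide (plus-strand C position)."""

    chrom: str
    pos: int
    meth_fraction: float
    coverage: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.meth_fraction <= 1.0:
            raise ValueError(f"meth_fraction outside [0,1]: {self.meth_fraction}")
        if self.coverage < 0:
            raise ValueError(f"negative coverage: {self.coverage}")


class CpGTable:
    """Base-resolution methylome indexed for per-chromosome range queries.

    Records are sorted by (chrom, pos) and stored as parallel numpy arrays
    per chromosome; :meth:`fetch` returns slices in O(log n).
    """

    def __init__(self, records: Iterable[CpGRecord]):
        by_chrom: dict[str, list[tuple[int, float, int]]] = {}
        for r in records:
            by_chrom.setdefault(r.chrom, []).append(
                (r.pos, r.meth_fraction, r.coverage)
            )
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, rows in by_chrom.items():
            rows.sort()
            pos = np.array([r[0] for r in rows], dtype=np.int64)
            if len(pos) > 1 and np.any(np.diff(pos) == 0):
                dup = int(pos[np.flatnonzero(np.diff(pos) == 0)[0]])
                raise ValueError(f"duplicate CpG position {chrom}:{dup}")
            meth = np.array([r[1] for r in rows], dtype=np.float64)
            cov = np.array([r[2] for r in rows], dtype=np.int64)
            self._data[chrom] = (pos, meth, cov)

    @classmethod
    def from_arrays(
        cls, data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]
    ) -> "CpGTable":
        table = cls([])
        for chrom, (pos, meth, cov) in data.items():
            order = np.argsort(pos, kind="stable")
            table._data[chrom] = (
                np.asarray(pos, dtype=np.int64)[order],
                np.asarray(meth, dtype=np.float64)[order],
                np.asarray(cov, dtype=np.int64)[order],
            )
        return table

    @property
    def chroms(self) -> list[str]:
        return sorted(self._data)

    def __len__(self) -> int:
        return sum(len(v[0]) for v in self._data.values())

    def fetch(
        self, chrom: str, start: int, end: int
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Positions, methylation fractions and coverages in [start, end)."""
        if chrom not in self._data:
            empty_i = np.empty(0, dtype=np.int64)
            return empty_i, np.empty(0, dtype=np.float64), empty_i.copy()
        pos, meth, cov = self._data[chrom]
        lo = int(np.searchsorted(pos, start, side="left"))
        hi = int(np.searchsorted(pos, end, side="left"))
        return pos[lo:hi], meth[lo:hi], cov[lo:hi]

    def records(self) -> Iterator[CpGRecord]:
        for chrom in self.chroms:
            pos, meth, cov = self._data[chrom]
            for p, m, c in zip(pos, meth, cov):
                yield CpGRecord(chrom, int(p), float(m), int(c))


class TagTrack:
    """Aligned-read 5' positions for one ChIP or input track.

    Positions are kept sorted per chromosome; ``total_mapped`` is the
    normalization constant (total uniquely mapped reads), which may exceed
    the number of stored tags.
    """

    def __init__(
        self,
        track_name: str,
        tags: Iterable[tuple[str, int, str]] | None = None,
        total_mapped: int | None = None,
    ):
        self.track_name = track_name
        by_chrom: dict[str, list[tuple[int, str]]] = {}
        for chrom, pos, strand in tags or ():
            if pos < 0:
                raise ValueError(f"negative tag position {chrom}:{pos}")
            by_chrom.setdefault(chrom, []).append((pos, strand))
        self._pos: dict[str, np.ndarray] = {}
        self._strand: dict[str, np.ndarray] = {}
        for chrom, rows in by_chrom.items():
            rows.sort()
            self._pos[chrom] = np.array([r[0] for r in rows], dtype=np.int64)
            self._strand[chrom] = np.array([r[1] for r in rows], dtype="U1")
        n = sum(len(v) for v in self._pos.values())
        self.total_mapped = total_mapped if total_mapped is not None else n
        if self.total_mapped < n:
            raise ValueError("total_mapped smaller than number of tags")

    @classmethod
    def from_arrays(
        cls,
        track_name: str,
        positions: dict[str, np.ndarray],
        strands: dict[str, np.ndarray] | None = None,
        total_mapped: int | None = None,
    ) -> "TagTrack":
        track = cls(track_name)
        for chrom, pos in positions.items():
            pos = np.asarray(pos, dtype=np.int64)
            order = np.argsort(pos, kind="stable")
            track._pos[chrom] = pos[order]
            if strands is not None and chrom in strands:
                track._strand[chrom] = np.asarray(strands[chrom], dtype="U1")[order]
            else:
                track._strand[chrom] = np.full(len(pos), "+", dtype="U1")
        n = track.n_tags
        track.total_mapped = total_mapped if total_mapped is not None else n
        if track.total_mapped < n:
            raise ValueError("total_mapped smaller than number of tags")
        return track

    @property
    def n_tags(self) -> int:
        return sum(len(v) for v in self._pos.values())

    @property
    def chroms(self) -> list[str]:
        return sorted(self._pos)

    def positions(self, chrom: str) -> np.ndarray:
        return self._pos.get(chrom, np.empty(0, dtype=np.int64))

    def strands(self, chrom: str) -> np.ndarray:
        return self._strand.get(chrom, np.empty(0, dtype="U1"))

    def count_in(self, chrom: str, start: int, end: int) -> int:
        """Number of tag 5' positions falling in [start, end)."""
        pos = self.positions(chrom)
        return int(
            np.searchsorted(pos, end, side="left")
            - np.searchsorted(pos, start, side="left")
        )


@dataclass
class GenomeAnnotation:
    """Container for the reference structure: chromosomes, genes and CGIs.

    ``cgi_hyper`` is an optional boolean flag per CGI (aligned with ``cgis``)
    marking islands that are hypermethylated; it is populated by the
    synthetic generator and ignored by readers of real annotations.
    """

    chrom_sizes: dict[str, int]
    genes: list[GeneModel]
    cgis: list[GenomicInterval]
    cgi_hyper: list[bool] | None = None

    def __post_init__(self) -> None:
        for g in self.genes:
            size = self.chrom_sizes.get(g.chrom)
            if size is None or g.tx_end > size:
                raise ValueError(f"gene {g.gene_id} outside chromosome bounds")
        for c in self.cgis:
            size = self.chrom_sizes.get(c.chrom)
            if size is None or c.end > size:
                raise ValueError(f"CGI {c.chrom}:{c.start}-{c.end} outside bounds")
        if self.cgi_hyper is not None and len(self.cgi_hyper) != len(self.cgis):
            raise ValueError("cgi_hyper length must match cgis")


# ---------------------------------------------------------------------------
# Interval indexing
# ---------------------------------------------------------------------------


def build_interval_index(
    intervals: Iterable[GenomicInterval],
) -> dict[str, IntervalTree]:
    """Per-chromosome interval trees for overlap queries."""
    index: dict[str, IntervalTree] = {}
    for iv in intervals:
        index.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return index


def query_overlaps(
    index: dict[str, IntervalTree], probe: GenomicInterval
) -> list[GenomicInterval]:
    """Every indexed interval sharing >= 1 base with ``probe``.

    Half-open semantics: an interval ending exactly where the probe starts
    does not overlap. Results are returned sorted by (start, end).
    """
    tree = index.get(probe.chrom)
    if tree is None:
        return []
    hits = [h.data for h in tree.overlap(probe.start, probe.end)]
    hits.sort(key=lambda iv: (iv.start, iv.end))
    return hits


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _open_text(path: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _iter_data_lines(path: str) -> Iterator[tuple[int, list[str]]]:
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def _parse_int(path: str, lineno: int, text: str, what: str) -> int:
    try:
        return int(text)
    except ValueError:
        raise ParseError(path, lineno, f"non-integer {what}: {text!r}") from None


def read_bed(path: str) -> list[GenomicInterval]:
    """Read BED3/BED6 intervals, preserving file order.

    Track/browser/comment lines are skipped. Records missing a strand
    column get strand ``"."`` (unknown).
    """
    intervals: list[GenomicInterval] = []
    for lineno, fields in _iter_data_lines(path):
        if len(fields) < 3:
            raise ParseError(path, lineno, "fewer than 3 columns")
        start = _parse_int(path, lineno, fields[1], "start")
        end = _parse_int(path, lineno, fields[2], "end")
        if end <= start:
            raise ParseError(path, lineno, f"end <= start ({start}, {end})")
        name = fields[3] if len(fields) > 3 else ""
        score = 0.0
        if len(fields) > 4 and fields[4] not in (".", ""):
            try:
                score = float(fields[4])
            except ValueError:
                raise ParseError(path, lineno, f"non-numeric score: {fields[4]!r}")
        strand = fields[5] if len(fields) > 5 else STRAND_UNKNOWN
        if strand not in ("+", "-"):
            strand = STRAND_UNKNOWN
        try:
            intervals.append(
                GenomicInterval(fields[0], start, end, strand, name, score)
            )
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc)) from None
    return intervals


def write_bed(path: str, intervals: Sequence[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                f"{iv.score:g}\t{iv.strand}\n"
            )


def read_methcounts(path: str) -> CpGTable:
    """Read a methcounts-style TSV of base-resolution methylation calls.

    Columns: chrom, pos (0-based), strand, context, meth_fraction, coverage.
    Only rows whose context column equals ``CpG`` (case-insensitive) are
    retained; skipped non-CpG rows are counted and logged. Gzip input is
    handled transparently.
    """
    records: list[CpGRecord] = []
    skipped = 0
    for lineno, fields in _iter_data_lines(path):
        if len(fields) < 6:
            raise ParseError(path, lineno, "fewer than 6 columns")
        if fields[3].upper() != "CPG":
            skipped += 1
            continue
        pos = _parse_int(path, lineno, fields[1], "position")
        try:
            meth = float(fields[4])
        except ValueError:
            raise ParseError(
                path, lineno, f"non-numeric meth_fraction: {fields[4]!r}"
            ) from None
        if not 0.0 <= meth <= 1.0:
            raise ParseError(path, lineno, f"meth_fraction outside [0,1]: {meth}")
        cov = _parse_int(path, lineno, fields[5], "coverage")
        try:
            records.append(CpGRecord(fields[0], pos, meth, cov))
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc)) from None
    if skipped:
        logger.info("read_methcounts(%s): skipped %d non-CpG rows", path, skipped)
    return CpGTable(records)


def write_methcounts(path: str, table: CpGTable) -> None:
    opener: Callable = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for r in table.records():
            fh.write(f"{r.chrom}\t{r.pos}\t+\tCpG\t{r.meth_fraction:g}\t{r.coverage}\n")


def read_gene_table(path: str) -> list[GeneModel]:
    """Read gene models from BED12; exons are rebuilt from the block columns."""
    genes: list[GeneModel] = []
    for lineno, fields in _iter_data_lines(path):
        if len(fields) < 12:
            raise ParseError(path, lineno, "BED12 requires 12 columns")
        chrom = fields[0]
        start = _parse_int(path, lineno, fields[1], "start")
        end = _parse_int(path, lineno, fields[2], "end")
        name = fields[3]
        strand = fields[5]
        if strand not in ("+", "-"):
            raise ParseError(
                path, lineno, f"gene strand required (got {strand!r}); TSS undefined"
            )
        n_blocks = _parse_int(path, lineno, fields[9], "blockCount")
        sizes = [
            _parse_int(path, lineno, s, "blockSize")
            for s in fields[10].rstrip(",").split(",")
        ]
        starts = [
            _parse_int(path, lineno, s, "blockStart")
            for s in fields[11].rstrip(",").split(",")
        ]
        if len(sizes) != n_blocks or len(starts) != n_blocks:
            raise ParseError(path, lineno, "blockCount inconsistent with blocks")
        exons = []
        for bs, sz in zip(starts, sizes):
            ex_start = start + bs
            exons.append(GenomicInterval(chrom, ex_start, ex_start + sz, strand))
        try:
            genes.append(GeneModel(name, chrom, strand, start, end, tuple(exons)))
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc)) from None
    return genes


def write_gene_table(path: str, genes: Sequence[GeneModel]) -> None:
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(ex.length) for ex in g.exons)
            starts = ",".join(str(ex.start - g.tx_start) for ex in g.exons)
            fh.write(
                f"{g.chrom}\t{g.tx_start}\t{g.tx_end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{g.tx_start}\t{g.tx_end}\t0\t{len(g.exons)}\t{sizes}\t{starts}\n"
            )


def read_tags(path: str, track_name: str, total_mapped: int | None = None) -> TagTrack:
    """Read a BED6 tag file: one aligned read per record.

    The stored tag position is the read 5' end: ``start`` for plus-strand
    reads and ``end - 1`` for minus-strand reads.
    """
    tags: list[tuple[str, int, str]] = []
    for lineno, fields in _iter_data_lines(path):
        if len(fields) < 6:
            raise ParseError(path, lineno, "tag BED requires 6 columns")
        start = _parse_int(path, lineno, fields[1], "start")
        end = _parse_int(path, lineno, fields[2], "end")
        strand = fields[5]
        if strand not in ("+", "-"):
            raise ParseError(path, lineno, f"tag strand required (got {strand!r})")
        five_prime = start if strand == "+" else end - 1
        tags.append((fields[0], five_prime, strand))
    return TagTrack(track_name, tags, total_mapped)


def write_tags(path: str, track: TagTrack, read_length: int = 36) -> None:
    """Write a TagTrack as BED6, one fixed-length read per tag."""
    with open(path, "w") as fh:
        for chrom in track.chroms:
            pos = track.positions(chrom)
            strands = track.strands(chrom)
            for p, s in zip(pos, strands):
                if s == "-":
                    start, end = int(p) - read_length + 1, int(p) + 1
                    start = max(start, 0)
                else:
                    start, end = int(p), int(p) + read_length
                fh.write(f"{chrom}\t{start}\t{end}\t.\t0\t{s}\n")
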