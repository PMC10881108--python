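"""Readers/writers for the file formats used throughout the stack.

Formats handled here: qbed (tab-separated insertion records, 5 or 6
columns), BED6 peak output, 4-column bedGraph coverage, gene tables
(BED6 or GTF gene features) and the TTAA tetranucleotide index built
from a genome FASTA or raw sequence strings.

Coordinates are 0-based, half-open everywhere.  An insertion's position
for all downstream statistics is its ``start``; ``end`` is carried but
unused in the math.
"""

from __future__ import annotations

import gzip
import io
import logging
import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

_VALID_STRANDS = {"+", "-", "."}

# bases allowed in input sequences (case-insensitive)
_ALLOWED_BASES = frozenset("ACGTN")


class QbedParseError(ValueError):
    """Raised for malformed qbed/BED/bedGraph lines; carries the line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


@dataclass(frozen=True)
class InsertionRecord:
    """A single transposon insertion event."""

    chrom: str
    start: int
    end: int
    reads: int = 1
    strand: str = "."
    barcode: str | None = None

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if self.start >= self.end:
            raise ValueError(
                f"start must be < end, got [{self.start}, {self.end})"
            )
        if self.reads < 1:
            raise ValueError(f"reads must be >= 1, got {self.reads}")
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"strand must be one of +, -, . (got {self.strand!r})")


class InsertionSet:
    """Insertion records grouped by chromosome and sorted by start.

    Provides fast per-chromosome position arrays (numpy) for the peak
    callers plus cached totals.
    """

    def __init__(self, records: Iterable[InsertionRecord] = ()):
        by_chrom: dict[str, list[InsertionRecord]] = {}
        for rec in records:
            by_chrom.setdefault(rec.chrom, []).append(rec)
        for chrom in by_chrom:
            by_chrom[chrom].sort(key=lambda r: (r.start, r.end, r.strand, r.barcode or ""))
        self._by_chrom = {c: by_chrom[c] for c in sorted(by_chrom)}
        self._positions = {
            c: np.array([r.start for r in recs], dtype=np.int64)
            for c, recs in self._by_chrom.items()
        }
        self._totals = {c: len(recs) for c, recs in self._by_chrom.items()}

    # -- container protocol ------------------------------------------------
    def __len__(self) -> int:
        return sum(self._totals.values())

    def __iter__(self) -> Iterator[InsertionRecord]:
        for chrom in self._by_chrom:
            yield from self._by_chrom[chrom]

    def __eq__(self, other) -> bool:
        if not isinstance(other, InsertionSet):
            return NotImplemented
        return self._by_chrom == other._by_chrom

    # -- accessors ---------------------------------------------------------
    @property
    def chromosomes(self) -> list[str]:
        return list(self._by_chrom)

    def records(self, chrom: str) -> list[InsertionRecord]:
        return self._by_chrom.get(chrom, [])

    def positions(self, chrom: str) -> np.ndarray:
        """Sorted insertion start positions on ``chrom`` (int64 array)."""
        return self._positions.get(chrom, np.empty(0, dtype=np.int64))

    def total(self, chrom: str | None = None) -> int:
        if chrom is None:
            return len(self)
        return self._totals.get(chrom, 0)

    def count_in(self, chrom: str, start: int, end: int) -> int:
        """Insertions with start in the half-open interval [start, end)."""
        pos = self.positions(chrom)
        return int(np.searchsorted(pos, end, "left") - np.searchsorted(pos, start, "left"))

    @property
    def has_barcodes(self) -> bool:
        return any(r.barcode is not None for r in self)

    def barcodes(self) -> list[str]:
        """Distinct barcodes in first-seen order."""
        seen: dict[str, None] = {}
        for rec in self:
            if rec.barcode is not None:
                seen.setdefault(rec.barcode, None)
        return list(seen)

    # -- manipulation ------------------------------------------------------
    def deduplicate(self) -> "InsertionSet":
        """Collapse records sharing (chrom, start, barcode); keeps the first."""
        seen = set()
        kept = []
        for rec in self:
            key = (rec.chrom, rec.start, rec.barcode)
            if key not in seen:
                seen.add(key)
                kept.append(rec)
        return InsertionSet(kept)

    @staticmethod
    def concat(sets: Sequence["InsertionSet"]) -> "InsertionSet":
        out: list[InsertionRecord] = []
        for s in sets:
            out.extend(s)
        return InsertionSet(out)


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _is_header(line: str) -> bool:
    return line.startswith("#") or line.startswith("track") or line.startswith("browser")


def read_qbed(path, has_barcode: bool | None = None, deduplicate: bool = False) -> InsertionSet:
    """Read a qbed file into an :class:`InsertionSet`.

    Parameters
    ----------
    path
        Tab-separated file with 5 columns (chrom, start, end, reads,
        strand) or 6 (plus cell barcode).  ``.gz`` handled transparently.
    has_barcode
        If None (default), inferred from the column count of the first
        data line.  If given, a mismatching column count is an error.
    deduplicate
        Collapse duplicate (chrom, start, barcode) records.  Off by
        default: each line is an independent insertion event.
    """
    records: list[InsertionRecord] = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or _is_header(line):
                continue
            fields = line.split("\t")
            if has_barcode is None:
                has_barcode = len(fields) >= 6
            want = 6 if has_barcode else 5
            if len(fields) < want:
                raise QbedParseError(
                    f"expected {want} tab-separated columns, got {len(fields)}", lineno
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
                reads = int(fields[3])
            except ValueError as exc:
                raise QbedParseError(f"non-integer field: {exc}", lineno) from None
            strand = fields[4]
            barcode = fields[5] if has_barcode else None
            try:
                records.append(
                    InsertionRecord(chrom, start, end, reads, strand, barcode)
                )
            except ValueError as exc:
                raise QbedParseError(str(exc), lineno) from None
    out = InsertionSet(records)
    return out.deduplicate() if deduplicate else out


def write_qbed(insertions: InsertionSet, path) -> None:
    """Write an InsertionSet back to qbed (6 columns if barcodes present)."""
    with_bc = insertions.has_barcodes
    with _open_text(path, "wt") as fh:
        for rec in insertions:
            fields = [rec.chrom, str(rec.start), str(rec.end), str(rec.reads), rec.strand]
            if with_bc:
                fields.append(rec.barcode or "-")
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# TTAA index
# ---------------------------------------------------------------------------

class TTAAIndex:
    """Sorted per-chromosome start positions of TTAA tetranucleotides."""

    def __init__(self, positions: dict[str, Sequence[int]]):
        self._pos: dict[str, np.ndarray] = {}
        for chrom, pos in positions.items():
            arr = np.asarray(sorted(set(int(p) for p in pos)), dtype=np.int64)
            self._pos[chrom] = arr
        self._warned: set[str] = set()

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._pos)

    def positions(self, chrom: str) -> np.ndarray:
        return self._pos.get(chrom, np.empty(0, dtype=np.int64))

    @property
    def total(self) -> int:
        return sum(len(p) for p in self._pos.values())

    def count(self, chrom: str, start: int, end: int) -> int:
        """TTAA starts p with start <= p < end (binary search)."""
        if start > end:
            raise ValueError(f"start > end: [{start}, {end})")
        if chrom not in self._pos:
            if chrom not in self._warned:
                logger.warning("chromosome %r not in TTAA index; count is 0", chrom)
                self._warned.add(chrom)
            return 0
        pos = self._pos[chrom]
        return int(np.searchsorted(pos, end, "left") - np.searchsorted(pos, start, "left"))

    def nearest(self, chrom: str, position: int) -> int | None:
        """TTAA start closest to ``position`` (ties -> leftmost), or None."""
        pos = self._pos.get(chrom)
        if pos is None or len(pos) == 0:
            return None
        i = bisect_left(pos.tolist(), position)
        candidates = []
        if i > 0:
            candidates.append(int(pos[i - 1]))
        if i < len(pos):
            candidates.append(int(pos[i]))
        return min(candidates, key=lambda p: (abs(p - position), p))


def scan_ttaa(sequence: str) -> list[int]:
    """All 0-based starts of the substring TTAA (sliding window, step 1)."""
    seq = sequence.upper()
    bad = set(seq) - _ALLOWED_BASES
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    out = []
    i = seq.find("TTAA")
    while i != -1:
        out.append(i)
        i = seq.find("TTAA", i + 1)
    return out


def build_ttaa_index(source) -> TTAAIndex:
    """Build a :class:`TTAAIndex` from sequences.

    ``source`` may be a dict {chrom: sequence string} or a path to a
    (possibly gzipped) FASTA file.
    """
    if isinstance(source, dict):
        seqs = source.items()
        return TTAAIndex({c: scan_ttaa(s) for c, s in seqs})
    from Bio import SeqIO

    positions: dict[str, list[int]] = {}
    with _open_text(source) as fh:
        for record in SeqIO.parse(fh, "fasta"):
            positions[record.id] = scan_ttaa(str(record.seq))
    return TTAAIndex(positions)


def count_ttaa(index: TTAAIndex, chrom: str, start: int, end: int) -> int:
    """Number of TTAA starts within [start, end); see :meth:`TTAAIndex.count`."""
    return index.count(chrom, start, end)


def read_ttaa_bed(path) -> TTAAIndex:
    """Read precomputed TTAA positions from a BED-like file (chrom, start, ...)."""
    positions: dict[str, list[int]] = {}
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or _is_header(line):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise QbedParseError("expected at least 2 columns", lineno)
            try:
                positions.setdefault(fields[0], []).append(int(fields[1]))
            except ValueError:
                raise QbedParseError("non-integer start", lineno) from None
    return TTAAIndex(positions)


def write_ttaa_bed(index: TTAAIndex, path) -> None:
    with _open_text(path, "wt") as fh:
        for chrom in index.chromosomes:
            for p in index.positions(chrom):
                fh.write(f"{chrom}\t{p}\t{p + 4}\n")


# ---------------------------------------------------------------------------
# Genes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneRecord:
    chrom: str
    start: int
    end: int
    name: str
    strand: str = "."

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"gene {self.name}: start must be < end")


def read_gene_table(path, fmt: str | None = None) -> list[GeneRecord]:
    """Read genes from BED6 or GTF (gene-level features only).

    ``fmt`` is "bed", "gtf" or None (infer from extension).  Returns
    genes sorted by (chrom, start).
    """
    path = Path(path)
    if fmt is None:
        stem = path.name[:-3] if path.suffix == ".gz" else path.name
        fmt = "gtf" if stem.endswith((".gtf", ".gff")) else "bed"
    genes: list[GeneRecord] = []
    with _open_text(path) as fh:
        if fmt == "bed":
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line or _is_header(line):
                    continue
                f = line.split("\t")
                if len(f) < 4:
                    raise QbedParseError("BED gene table needs >= 4 columns", lineno)
                strand = f[5] if len(f) >= 6 else "."
                genes.append(GeneRecord(f[0], int(f[1]), int(f[2]), f[3], strand))
        elif fmt == "gtf":
            for raw in fh:
                if _is_header(raw):
                    continue
                f = raw.rstrip("\n").split("\t")
                if len(f) < 9 or f[2] != "gene":
                    continue
                attrs = _parse_gtf_attributes(f[8])
                name = attrs.get("gene_name") or attrs.get("gene_id") or "NA"
                # GTF is 1-based closed; convert to 0-based half-open
                genes.append(GeneRecord(f[0], int(f[3]) - 1, int(f[4]), name, f[6]))
        else:
            raise ValueError(f"unknown gene table format {fmt!r}")
    genes.sort(key=lambda g: (g.chrom, g.start, g.end, g.name))
    return genes


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out = {}
    for chunk in attr.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " in chunk:
            key, _, val = chunk.partition(" ")
            out[key] = val.strip().strip('"')
    return out


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def read_bedgraph(path) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Read 4-column bedGraph into {chrom: (starts, ends, values)} sorted arrays."""
    data: dict[str, list[tuple[int, int, float]]] = {}
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or _is_header(line):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise QbedParseError("bedGraph needs 4 columns", lineno)
            try:
                data.setdefault(f[0], []).append((int(f[1]), int(f[2]), float(f[3])))
            except ValueError:
                raise QbedParseError("malformed bedGraph fields", lineno) from None
    out = {}
    for chrom, rows in data.items():
        rows.sort()
        s = np.array([r[0] for r in rows], dtype=np.int64)
        e = np.array([r[1] for r in rows], dtype=np.int64)
        v = np.array([r[2] for r in rows], dtype=float)
        out[chrom] = (s, e, v)
    return out


# ---------------------------------------------------------------------------
# BED output for peaks
# ---------------------------------------------------------------------------

def bed_score(pvalue: float) -> int:
    """BED score column: -10*log10(p), capped at 1000 (p=0 -> 1000)."""
    if pvalue <= 0:
        return 1000
    return min(1000, int(round(-10.0 * math.log10(pvalue))))


def write_bed(peaks, path) -> None:
    """Write a PeakSet as BED6 (name=peak_i, score=-10 log10 p, strand '.')."""
    with _open_text(path, "wt") as fh:
        for i, pk in enumerate(peaks, start=1):
            fh.write(
                f"{pk.chrom}\t{pk.start}\t{pk.end}\tpeak_{i}\t{bed_score(pk.pvalue)}\t.\n"
            )


def read_bed_intervals(path) -> list[tuple[str, int, int, str]]:
    """Read (chrom, start, end, name) tuples from a BED file."""
    out = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or _is_header(line):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise QbedParseError("BED needs >= 3 columns", lineno)
            name = f[3] if len(f) >= 4 else f"interval_{lineno}"
            out.append((f[0], int(f[1]), int(f[2]), name))
    return out
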