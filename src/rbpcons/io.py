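"""Readers and writers for the text formats the pipeline touches.

Formats: MAF (UCSC multiz dialect), BED3-BED6, GMT, Newick, and a
gene-annotation TSV. All coordinates are 0-based half-open internally;
MAF ``start + size`` on a '+' reference row converts directly. All
readers accept a file path (plain or gzip-compressed) or an open text
stream.
"""

from __future__ import annotations

import gzip
import io as _stdio
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Union

import dendropy

logger = logging.getLogger(__name__)

PathOrStream = Union[str, Path, IO[str]]


class ParseError(ValueError):
    """Malformed record in an input file; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


def _open_text(source: PathOrStream):
    """Return (stream, should_close). Transparently handles gzip paths."""
    if hasattr(source, "read"):
        return source, False
    path = Path(source)
    raw = open(path, "rb")
    if raw.read(2) == b"\x1f\x8b":
        raw.seek(0)
        return _stdio.TextIOWrapper(gzip.GzipFile(fileobj=raw)), True
    raw.seek(0)
    return _stdio.TextIOWrapper(raw), True


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlignmentRow:
    """One species row ('s' line) of a MAF alignment block.

    ``src`` is "species.chrom"; the species identifier is the substring
    before the first '.', or the whole src when no '.' is present.
    ``start`` is 0-based and strand-relative, ``size`` the ungapped
    length, ``text`` the aligned sequence including '-' gaps.
    """

    src: str
    start: int
    size: int
    strand: str
    src_size: int
    text: str

    @property
    def species(self) -> str:
        return self.src.split(".", 1)[0]


@dataclass
class MafBlock:
    """One alignment block, anchored to the reference (first) row.

    ``ref_start``/``ref_end`` are 0-based half-open reference-genome
    coordinates derived from the first 's' line.
    """

    score: float
    rows: list[AlignmentRow]

    @property
    def ref_row(self) -> AlignmentRow:
        return self.rows[0]

    @property
    def ref_chrom(self) -> str:
        src = self.ref_row.src
        return src.split(".", 1)[1] if "." in src else src

    @property
    def ref_start(self) -> int:
        return self.ref_row.start

    @property
    def ref_end(self) -> int:
        return self.ref_row.start + self.ref_row.size

    @property
    def species_set(self) -> frozenset[str]:
        """Distinct species with at least one row in the block."""
        return frozenset(r.species for r in self.rows)


@dataclass
class GenomicInterval:
    """A 0-based half-open genomic interval (BED semantics)."""

    chrom: str
    start: int
    end: int
    name: str = ""
    score: float = 0.0
    strand: str = "."

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(
                f"end ({self.end}) must exceed start ({self.start}) "
                f"for {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class GeneModel:
    """A gene span with mandatory strand (never '.')."""

    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if self.end <= self.start:
            raise ValueError(f"gene {self.gene_id}: end must exceed start")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class GeneSet:
    name: str
    description: str
    genes: frozenset[str]

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")


# ---------------------------------------------------------------------------
# MAF
# ---------------------------------------------------------------------------


def _parse_s_line(fields: list[str], lineno: int) -> AlignmentRow:
    if len(fields) != 7:
        raise ParseError(
            f"'s' line has {len(fields)} fields, expected 7", lineno
        )
    _, src, start, size, strand, src_size, text = fields
    try:
        start_i, size_i, src_size_i = int(start), int(size), int(src_size)
    except ValueError as exc:
        raise ParseError(f"non-integer coordinate in 's' line: {exc}", lineno)
    if strand not in ("+", "-"):
        raise ParseError(f"invalid strand {strand!r}", lineno)
    ungapped = len(text) - text.count("-")
    if ungapped != size_i:
        raise ParseError(
            f"aligned text has {ungapped} non-gap characters, size says {size_i}",
            lineno,
        )
    if start_i + size_i > src_size_i:
        raise ParseError("start + size exceeds srcSize", lineno)
    return AlignmentRow(src, start_i, size_i, strand, src_size_i, text)


def read_maf(source: PathOrStream) -> Iterator[MafBlock]:
    """Stream alignment blocks from MAF text, in file order.

    'a' lines open a block (``score=`` is optional, defaulting to 0);
    's' lines add species rows; 'i'/'e'/'q' annotation lines are
    skipped. Blocks whose reference (first) row is on the '-' strand
    are rejected with a logged warning, not an error: multiz reference
    rows are always '+'.
    """
    stream, close = _open_text(source)
    try:
        score: float | None = None
        rows: list[AlignmentRow] = []
        in_block = False

        def finish() -> MafBlock | None:
            if not rows:
                return None
            if rows[0].strand != "+":
                logger.warning(
                    "rejecting MAF block at %s:%d: reference row on '-' strand",
                    rows[0].src,
                    rows[0].start,
                )
                return None
            return MafBlock(score=score or 0.0, rows=list(rows))

        for lineno, line in enumerate(stream, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            tag = line.split(None, 1)[0]
            if tag == "a":
                block = finish()
                if block is not None:
                    yield block
                rows.clear()
                in_block = True
                score = 0.0
                for kv in line.split()[1:]:
                    if kv.startswith("score="):
                        try:
                            score = float(kv[len("score="):])
                        except ValueError:
                            raise ParseError(f"bad score in 'a' line: {kv}", lineno)
            elif tag == "s":
                if not in_block:
                    raise ParseError("'s' line outside of a block", lineno)
                rows.append(_parse_s_line(line.split(), lineno))
            elif tag in ("i", "e", "q"):
                continue
            else:
                raise ParseError(f"unrecognized MAF line tag {tag!r}", lineno)
        block = finish()
        if block is not None:
            yield block
    finally:
        if close:
            stream.close()


def write_maf(blocks: Iterable[MafBlock], dest: PathOrStream) -> None:
    stream, close = _open_text_w(dest)
    try:
        stream.write("##maf version=1\n")
        for b in blocks:
            stream.write(f"a score={b.score:g}\n")
            for r in b.rows:
                stream.write(
                    f"s {r.src} {r.start} {r.size} {r.strand} {r.src_size} {r.text}\n"
                )
            stream.write("\n")
    finally:
        if close:
            stream.close()


def _open_text_w(dest: PathOrStream):
    if hasattr(dest, "write"):
        return dest, False
    path = Path(dest)
    if path.suffix == ".gz":
        return gzip.open(path, "wt"), True
    return open(path, "w"), True


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_bed(source: PathOrStream, strict20: bool = False) -> list[GenomicInterval]:
    """Read BED3-BED6 into 0-based half-open intervals.

    Missing name defaults to "", score to 0, strand to '.'. With
    ``strict20`` every record must be exactly 20 bp (the binding-site
    length this pipeline analyses); violations are record-level errors.
    """
    out: list[GenomicInterval] = []
    stream, close = _open_text(source)
    try:
        for lineno, line in enumerate(stream, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError("BED record needs >= 3 tab-separated columns", lineno)
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"non-integer BED coordinate: {exc}", lineno)
            if end <= start:
                raise ParseError(f"end {end} <= start {start}", lineno)
            if strict20 and end - start != 20:
                raise ParseError(
                    f"binding site length {end - start} != 20 bp", lineno
                )
            name = fields[3] if len(fields) > 3 else ""
            try:
                score = float(fields[4]) if len(fields) > 4 and fields[4] else 0.0
            except ValueError:
                raise ParseError(f"non-numeric BED score {fields[4]!r}", lineno)
            strand = fields[5] if len(fields) > 5 else "."
            if strand not in ("+", "-", "."):
                raise ParseError(f"invalid strand {strand!r}", lineno)
            out.append(GenomicInterval(chrom, start, end, name, score, strand))
    finally:
        if close:
            stream.close()
    return out


def write_bed(intervals: Iterable[GenomicInterval], dest: PathOrStream) -> None:
    stream, close = _open_text_w(dest)
    try:
        for iv in intervals:
            stream.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.score:g}\t{iv.strand}\n"
            )
    finally:
        if close:
            stream.close()


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------


def read_gmt(source: PathOrStream) -> list[GeneSet]:
    """Read gene sets (one per line: name, description, genes...).

    Duplicate genes within a line are deduplicated; a repeated set name
    replaces the earlier definition with a warning.
    """
    by_name: dict[str, GeneSet] = {}
    order: list[str] = []
    stream, close = _open_text(source)
    try:
        for lineno, line in enumerate(stream, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    "GMT line needs name, description and >= 1 gene", lineno
                )
            name, desc = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise ParseError(f"gene set {name!r} has no genes", lineno)
            if name in by_name:
                warnings.warn(f"duplicate gene set {name!r}; later definition wins")
            else:
                order.append(name)
            by_name[name] = GeneSet(name, desc, genes)
    finally:
        if close:
            stream.close()
    return [by_name[n] for n in order]


def write_gmt(sets: Iterable[GeneSet], dest: PathOrStream) -> None:
    stream, close = _open_text_w(dest)
    try:
        for gs in sets:
            genes = "\t".join(sorted(gs.genes))
            stream.write(f"{gs.name}\t{gs.description}\t{genes}\n")
    finally:
        if close:
            stream.close()


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------


def read_newick(source: PathOrStream) -> dendropy.Tree:
    """Parse a single Newick tree; missing branch lengths become 0.

    Leaf labels must be unique; unbalanced parentheses raise a parse
    error.
    """
    stream, close = _open_text(source)
    try:
        text = stream.read()
    finally:
        if close:
            stream.close()
    try:
        tree = dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:  # dendropy raises several error classes
        raise ParseError(f"invalid Newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ParseError(f"duplicate leaf labels: {dupes}")
    for edge in tree.preorder_edge_iter():
        if edge.length is None:
            edge.length = 0.0
    return tree


# ---------------------------------------------------------------------------
# Gene-annotation TSV
# ---------------------------------------------------------------------------

_GENE_COLUMNS = ["geneId", "symbol", "chrom", "start", "end", "strand"]


def read_genes(source: PathOrStream) -> list[GeneModel]:
    """Read the gene-annotation TSV (geneId, symbol, chrom, start, end,
    strand; 0-based half-open). A header row is recognized and skipped."""
    out: list[GeneModel] = []
    stream, close = _open_text(source)
    try:
        for lineno, line in enumerate(stream, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[:2] == _GENE_COLUMNS[:2]:
                continue
            if len(fields) < 6:
                raise ParseError("gene TSV needs 6 columns", lineno)
            try:
                out.append(
                    GeneModel(
                        gene_id=fields[0],
                        symbol=fields[1],
                        chrom=fields[2],
                        start=int(fields[3]),
                        end=int(fields[4]),
                        strand=fields[5],
                    )
                )
            except ValueError as exc:
                raise ParseError(str(exc), lineno)
    finally:
        if close:
            stream.close()
    return out


def write_genes(genes: Iterable[GeneModel], dest: PathOrStream) -> None:
    stream, close = _open_text_w(dest)
    try:
        stream.write("\t".join(_GENE_COLUMNS) + "\n")
        for g in genes:
            stream.write(
                f"{g.gene_id}\t{g.symbol}\t{g.chrom}\t{g.start}\t{g.end}\t{g.strand}\n"
            )
    finally:
        if close:
            stream.close()
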