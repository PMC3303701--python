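"""Readers and writers for every external representation the tool touches.

Internal coordinates are 0-based half-open everywhere.  All external formats
(XML core blocks, tabular hits, library files) are 1-based inclusive and are
converted exactly once, at the I/O boundary.
"""

from __future__ import annotations

import io
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import DataError

AA20 = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
#: profile alphabet: the 20 residues followed by the gap symbol
PROFILE_ALPHABET = AA20 + GAP
AA_INDEX = {a: i for i, a in enumerate(AA20)}

# ambiguity codes collapsed to 'X'; the emission model is defined over 20
# letters plus unknown
_NONSTANDARD = str.maketrans({c: "X" for c in "BZUOJbzuoj"})


def _clean_residues(raw: str) -> str:
    s = str(raw).upper().replace("*", "").translate(_NONSTANDARD)
    bad = set(s) - set(AA20) - {"X"}
    if bad:
        raise DataError(f"invalid residue letters: {sorted(bad)!r}")
    return s


@dataclass(frozen=True)
class Sequence:
    """An identified, ungapped protein sequence."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise DataError("sequence id must be non-empty")
        if not self.residues:
            raise DataError(f"sequence {self.id!r} has no residues")
        if GAP in self.residues:
            raise DataError(f"sequence {self.id!r} contains gap characters")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class MultipleAlignment:
    """An MSA: parallel gapped rows over a shared column space."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise DataError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise DataError("duplicate sequence ids in alignment")
        if self.rows:
            n = len(self.rows[0])
            for sid, row in zip(self.ids, self.rows):
                if len(row) != n:
                    raise DataError(
                        f"alignment row {sid!r} has length {len(row)}, "
                        f"expected {n}"
                    )

    @property
    def ncols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def nrows(self) -> int:
        return len(self.rows)

    def row(self, sid: str) -> str:
        try:
            return self.rows[self.ids.index(sid)]
        except ValueError:
            raise DataError(f"unknown sequence id {sid!r}") from None

    def degapped(self) -> dict[str, str]:
        return {sid: row.replace(GAP, "") for sid, row in zip(self.ids, self.rows)}

    def to_sequences(self) -> list[Sequence]:
        return [Sequence(sid, row.replace(GAP, ""))
                for sid, row in zip(self.ids, self.rows)]

    def reorder(self, ids: Iterable[str]) -> "MultipleAlignment":
        ids = tuple(ids)
        if sorted(ids) != sorted(self.ids):
            raise DataError("reorder ids do not match alignment ids")
        return MultipleAlignment(ids, tuple(self.row(sid) for sid in ids))

    def drop_all_gap_columns(self) -> "MultipleAlignment":
        keep = [c for c in range(self.ncols)
                if any(row[c] != GAP for row in self.rows)]
        return MultipleAlignment(
            self.ids, tuple("".join(row[c] for c in keep) for row in self.rows)
        )


@dataclass(frozen=True)
class CoreAnnotation:
    """Reference core blocks, per sequence row, in alignment-column space.

    ``blocks`` maps sequence id to a tuple of 0-based half-open column
    intervals; ``columns`` optionally records the declared column count of
    the reference alignment the blocks refer to.
    """

    blocks: Mapping[str, tuple[tuple[int, int], ...]]
    columns: int | None = None

    def __post_init__(self) -> None:
        for sid, spans in self.blocks.items():
            prev_end = -1
            for start, end in sorted(spans):
                if start < 0 or end <= start:
                    raise DataError(
                        f"invalid core block [{start},{end}) on {sid!r}")
                if self.columns is not None and end > self.columns:
                    raise DataError(
                        f"core block [{start},{end}) on {sid!r} exceeds "
                        f"declared column count {self.columns}")
                if start < prev_end:
                    raise DataError(f"overlapping core blocks on {sid!r}")
                prev_end = end

    def mask(self, sid: str, ncols: int) -> list[bool]:
        """Boolean per-column core mask for one sequence row."""
        m = [False] * ncols
        for start, end in self.blocks.get(sid, ()):
            if end > ncols:
                raise DataError(
                    f"core block [{start},{end}) on {sid!r} exceeds "
                    f"alignment width {ncols}")
            for c in range(start, end):
                m[c] = True
        return m

    @classmethod
    def whole_columns(cls, ids: Iterable[str],
                      spans: Iterable[tuple[int, int]],
                      columns: int | None = None) -> "CoreAnnotation":
        spans = tuple(spans)
        return cls({sid: spans for sid in ids}, columns=columns)


# ---------------------------------------------------------------------------
# coordinate conversion (single site for the 1-based <-> 0-based boundary)

def to_internal_span(start1: int, end1: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    if start1 < 1 or end1 < start1:
        raise DataError(f"invalid 1-based span {start1}..{end1}")
    return start1 - 1, end1


def to_external_span(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    if start0 < 0 or end0 <= start0:
        raise DataError(f"invalid 0-based span [{start0},{end0})")
    return start0 + 1, end0


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> list[Sequence]:
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise DataError(f"no FASTA records in {path}")
    out: list[Sequence] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise DataError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        out.append(Sequence(rec.id, _clean_residues(str(rec.seq)), desc))
    return out


def write_fasta(seqs: Iterable[Sequence], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            header = f">{s.id} {s.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# alignments (aligned FASTA or Clustal blocks)

def _clean_gapped(raw: str) -> str:
    s = str(raw).upper().replace("*", "").replace(".", GAP).translate(_NONSTANDARD)
    bad = set(s) - set(AA20) - {"X", GAP}
    if bad:
        raise DataError(f"invalid residue letters in alignment: {sorted(bad)!r}")
    return s


def read_alignment(path) -> MultipleAlignment:
    path = Path(path)
    with open(path) as fh:
        head = fh.read(4096).lstrip()
    if head.upper().startswith("CLUSTAL"):
        aln = AlignIO.read(str(path), "clustal")
        ids = tuple(rec.id for rec in aln)
        rows = tuple(_clean_gapped(str(rec.seq)) for rec in aln)
        return MultipleAlignment(ids, rows)
    if not head.startswith(">"):
        raise DataError(f"{path}: not aligned FASTA or Clustal format")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise DataError(f"no alignment records in {path}")
    ids, rows = [], []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise DataError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        ids.append(rec.id)
        rows.append(_clean_gapped(str(rec.seq)))
    n = len(rows[0])
    for sid, row in zip(ids, rows):
        if len(row) != n:
            raise DataError(
                f"{path}: row {sid!r} has length {len(row)}, expected {n}")
    return MultipleAlignment(tuple(ids), tuple(rows))


def write_alignment(msa: MultipleAlignment, path, fmt: str = "fasta",
                    width: int = 60) -> None:
    if fmt == "fasta":
        with open(path, "w") as fh:
            for sid, row in zip(msa.ids, msa.rows):
                fh.write(f">{sid}\n")
                for i in range(0, len(row), width):
                    fh.write(row[i:i + width] + "\n")
    elif fmt == "clustal":
        records = [SeqRecord(Seq(row), id=sid, description="")
                   for sid, row in zip(msa.ids, msa.rows)]
        AlignIO.write(MultipleSeqAlignment(records), str(path), "clustal")
    else:
        raise DataError(f"unknown alignment format {fmt!r}")


# ---------------------------------------------------------------------------
# core-block annotation XML
#
# Self-defined schema (the original benchmark's XML was never published):
#   <family name="..." columns="N">
#     <sequence id="...">
#       <block start="1" end="40"/>   <!-- 1-based inclusive columns -->
#     </sequence>
#   </family>

def read_core_annotation(path) -> CoreAnnotation:
    try:
        tree = ET.parse(str(path))
    except ET.ParseError as exc:
        raise DataError(f"malformed core-annotation XML {path}: {exc}") from exc
    root = tree.getroot()
    if root.tag != "family":
        raise DataError(f"{path}: expected <family> root, got <{root.tag}>")
    columns = root.get("columns")
    columns = int(columns) if columns is not None else None
    blocks: dict[str, tuple[tuple[int, int], ...]] = {}
    for seq_el in root.findall("sequence"):
        sid = seq_el.get("id")
        if not sid:
            raise DataError(f"{path}: <sequence> without id attribute")
        spans = []
        for blk in seq_el.findall("block"):
            try:
                start1 = int(blk.get("start"))
                end1 = int(blk.get("end"))
            except (TypeError, ValueError):
                raise DataError(
                    f"{path}: non-integer block coordinates on {sid!r}") from None
            spans.append(to_internal_span(start1, end1))
        blocks[sid] = tuple(sorted(spans))
    return CoreAnnotation(blocks, columns=columns)


def write_core_annotation(core: CoreAnnotation, path,
                          name: str = "family") -> None:
    root = ET.Element("family", attrib={"name": name})
    if core.columns is not None:
        root.set("columns", str(core.columns))
    for sid in core.blocks:
        seq_el = ET.SubElement(root, "sequence", attrib={"id": sid})
        for start0, end0 in core.blocks[sid]:
            start1, end1 = to_external_span(start0, end0)
            ET.SubElement(seq_el, "block",
                          attrib={"start": str(start1), "end": str(end1)})
    ET.indent(root)
    ET.ElementTree(root).write(str(path), encoding="unicode")
    with open(path, "a") as fh:
        fh.write("\n")


# ---------------------------------------------------------------------------
# tabular hits (BLAST+ outfmt-6 style, extended with qlen/qseq/sseq)

#: column order of the tabular hit format
HIT_COLUMNS = ("qseqid", "sseqid", "pident", "length", "qstart", "qend",
               "sstart", "send", "evalue", "qlen", "qseq", "sseq")


def read_tabular_hits(path) -> list:
    from .extension import SearchHit  # deferred: avoids an import cycle

    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < len(HIT_COLUMNS):
                raise DataError(
                    f"{path}:{lineno}: expected {len(HIT_COLUMNS)} columns "
                    f"(incl. aligned qseq/sseq strings), got {len(fields)}")
            (qid, sid, pident, _length, qstart, qend, sstart, send,
             evalue, qlen, qseq, sseq) = fields[:12]
            qs, qe = to_internal_span(int(qstart), int(qend))
            ss, se = to_internal_span(int(sstart), int(send))
            qlen = int(qlen)
            if qe > qlen:
                raise DataError(f"{path}:{lineno}: query end exceeds qlen")
            coverage = 100.0 * (qe - qs) / qlen
            hits.append(SearchHit(
                query_id=qid, subject_id=sid, identity=float(pident),
                qstart=qs, qend=qe, sstart=ss, send=se,
                aligned_query=_clean_gapped(qseq),
                aligned_subject=_clean_gapped(sseq),
                evalue=float(evalue), coverage=coverage,
            ))
    return hits


def write_tabular_hits(hits: Iterable, path, qlen_by_id: Mapping[str, int]) -> None:
    with open(path, "w") as fh:
        for h in hits:
            qs1, qe1 = to_external_span(h.qstart, h.qend)
            ss1, se1 = to_external_span(h.sstart, h.send)
            fh.write("\t".join(map(str, (
                h.query_id, h.subject_id, f"{h.identity:.2f}",
                len(h.aligned_query), qs1, qe1, ss1, se1,
                f"{h.evalue:.3g}", qlen_by_id[h.query_id],
                h.aligned_query, h.aligned_subject))) + "\n")


# ---------------------------------------------------------------------------
# constraint library (T-Coffee style text format)

_LIB_MAGIC = "! TC_LIB_FORMAT_01"


def write_library(lib, path) -> None:
    """Serialize a ConstraintLibrary; header lists sequences with lengths,
    body holds per-pair blocks of 1-based "posA posB weight" lines."""
    ids = list(lib.lengths)
    index = {sid: k for k, sid in enumerate(ids)}
    with open(path, "w") as fh:
        fh.write(_LIB_MAGIC + "\n")
        fh.write(f"{len(ids)}\n")
        for sid in ids:
            fh.write(f"{sid} {lib.lengths[sid]}\n")
        for a in ids:
            for b in ids:
                if index[a] >= index[b]:
                    continue
                items = lib.pair_items(a, b)
                if not items:
                    continue
                fh.write(f"#{index[a] + 1} {index[b] + 1}\n")
                for i, j, w in sorted(items):
                    fh.write(f"{i + 1} {j + 1} {w}\n")
        fh.write("! SEQ_1_TO_N\n")


def read_library(path):
    from .consistency import ConstraintLibrary  # deferred import cycle

    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines or lines[0] != _LIB_MAGIC:
        raise DataError(f"{path}: missing library magic line")
    try:
        nseq = int(lines[1])
    except (IndexError, ValueError):
        raise DataError(f"{path}: bad sequence count") from None
    lengths: dict[str, int] = {}
    ids: list[str] = []
    for ln in lines[2:2 + nseq]:
        sid, slen = ln.split()
        ids.append(sid)
        lengths[sid] = int(slen)
    lib = ConstraintLibrary(lengths)
    a = b = None
    for ln in lines[2 + nseq:]:
        if not ln or ln.startswith("!"):
            continue
        if ln.startswith("#"):
            ia, ib = ln[1:].split()
            a, b = ids[int(ia) - 1], ids[int(ib) - 1]
            continue
        if a is None:
            raise DataError(f"{path}: constraint line before pair header")
        i1, j1, w = ln.split()
        lib.add(a, int(i1) - 1, b, int(j1) - 1, int(w))
    return lib
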