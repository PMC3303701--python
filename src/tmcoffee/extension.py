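"""Homology extension: database search per input sequence, hit filtering,
and construction of one extended profile per query.

Three search backends satisfy the same contract:

* :class:`BuiltinSWBackend` — an affine-gap local aligner over a FASTA
  database (Biopython's ``PairwiseAligner``), used by tests and the
  synthetic pipeline; its e-values are raw-score surrogates, not BLAST
  statistics.
* :class:`BlastBackend` — wraps an external ``blastp`` binary against a
  formatted database.
* :class:`PrecomputedBackend` — a directory of tabular hit files keyed by
  query id.
"""

from __future__ import annotations

import math
import re
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence as TSequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import ConfigError, DataError
from .formats import (AA20, AA_INDEX, GAP, PROFILE_ALPHABET, Sequence,
                      read_fasta, read_tabular_hits)

# Karlin-Altschul style surrogate constants for the builtin backend
# (gapped BLOSUM62); parity with blast+ statistics is not claimed.
_LAMBDA = 0.267
_K = 0.041


@dataclass(frozen=True)
class SearchHit:
    """One local alignment between a query and a database subject.

    Spans are 0-based half-open on the respective ungapped sequences;
    identity and coverage are percentages in [0, 100].
    """

    query_id: str
    subject_id: str
    identity: float
    qstart: int
    qend: int
    sstart: int
    send: int
    aligned_query: str
    aligned_subject: str
    evalue: float
    coverage: float
    score: float = 0.0

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_subject):
            raise DataError(
                f"hit {self.query_id}/{self.subject_id}: aligned segments "
                "differ in length")
        if self.evalue < 0:
            raise DataError("negative e-value")

    def validate_against(self, query: Sequence) -> None:
        degapped = self.aligned_query.replace(GAP, "")
        if degapped != query.residues[self.qstart:self.qend]:
            raise DataError(
                f"hit {self.query_id}/{self.subject_id}: aligned query "
                "segment does not match the query residues over its span")


# ---------------------------------------------------------------------------
# backends

class SearchBackend:
    """Contract: ``search(query, evalue_max)`` returns hits for that query."""

    def search(self, query: Sequence, evalue_max: float | None = None
               ) -> list[SearchHit]:
        raise NotImplementedError


class BuiltinSWBackend(SearchBackend):
    """Affine-gap Smith-Waterman over an in-memory FASTA database."""

    def __init__(self, database, matrix: str = "BLOSUM62",
                 gap_open: float = -11.0, gap_extend: float = -1.0):
        if isinstance(database, (str, Path)):
            try:
                self.records = read_fasta(database)
            except DataError:  # an empty database yields no hits
                self.records = []
        else:
            self.records = list(database)
        self._aligner = Align.PairwiseAligner()
        self._aligner.mode = "local"
        self._aligner.substitution_matrix = substitution_matrices.load(matrix)
        self._aligner.open_gap_score = gap_open
        self._aligner.extend_gap_score = gap_extend

    def search(self, query: Sequence, evalue_max: float | None = None
               ) -> list[SearchHit]:
        hits: list[SearchHit] = []
        m = len(query)
        for rec in self.records:
            alns = self._aligner.align(query.residues, rec.residues)
            if alns.score <= 0:
                continue
            aln = alns[0]
            qseq, sseq, qspan, sspan = _gapped_strings(
                aln, query.residues, rec.residues)
            ncols = len(qseq)
            ident = sum(a == b for a, b in zip(qseq, sseq)) / ncols * 100.0
            evalue = _K * m * len(rec) * math.exp(-_LAMBDA * alns.score)
            if evalue_max is not None and evalue > evalue_max:
                continue
            hits.append(SearchHit(
                query_id=query.id, subject_id=rec.id, identity=ident,
                qstart=qspan[0], qend=qspan[1],
                sstart=sspan[0], send=sspan[1],
                aligned_query=qseq, aligned_subject=sseq,
                evalue=evalue, score=float(alns.score),
                coverage=100.0 * (qspan[1] - qspan[0]) / m,
            ))
        hits.sort(key=lambda h: (h.evalue, h.subject_id))
        return hits


def _gapped_strings(aln, qres: str, sres: str):
    """Reconstruct gapped aligned strings from a Biopython alignment's
    aligned blocks (covers the locally aligned region only)."""
    qblocks, sblocks = aln.aligned[0], aln.aligned[1]
    # Biopython orders (target, query); we aligned (query, subject)
    qparts, sparts = [], []
    prev_q, prev_s = qblocks[0][0], sblocks[0][0]
    for (q0, q1), (s0, s1) in zip(qblocks, sblocks):
        dq, ds = q0 - prev_q, s0 - prev_s
        if dq:
            qparts.append(qres[prev_q:q0])
            sparts.append(GAP * dq)
        if ds:
            qparts.append(GAP * ds)
            sparts.append(sres[prev_s:s0])
        qparts.append(qres[q0:q1])
        sparts.append(sres[s0:s1])
        prev_q, prev_s = q1, s1
    qspan = (int(qblocks[0][0]), int(qblocks[-1][1]))
    sspan = (int(sblocks[0][0]), int(sblocks[-1][1]))
    return "".join(qparts), "".join(sparts), qspan, sspan


class PrecomputedBackend(SearchBackend):
    """Directory of ``<query id>.tsv`` tabular hit files."""

    def __init__(self, directory):
        self.directory = Path(directory)
        if not self.directory.is_dir():
            raise ConfigError(
                f"precomputed-hit backend: {directory} is not a directory")

    def search(self, query: Sequence, evalue_max: float | None = None
               ) -> list[SearchHit]:
        path = self.directory / f"{query.id}.tsv"
        if not path.exists():
            return []
        hits = [h for h in read_tabular_hits(path) if h.query_id == query.id]
        if evalue_max is not None:
            hits = [h for h in hits if h.evalue <= evalue_max]
        return hits


class BlastBackend(SearchBackend):
    """External blast+ ``blastp`` against a formatted protein database."""

    _OUTFMT = ("6 qseqid sseqid pident length qstart qend sstart send "
               "evalue qlen qseq sseq")

    def __init__(self, db_path, binary: str = "blastp"):
        if shutil.which(binary) is None:
            raise ConfigError(
                f"blast backend unavailable: {binary!r} not on PATH")
        self.db_path = str(db_path)
        self.binary = binary

    def search(self, query: Sequence, evalue_max: float | None = None
               ) -> list[SearchHit]:
        with tempfile.NamedTemporaryFile("w", suffix=".fasta") as qf, \
                tempfile.NamedTemporaryFile("r", suffix=".tsv") as of:
            qf.write(f">{query.id}\n{query.residues}\n")
            qf.flush()
            cmd = [self.binary, "-query", qf.name, "-db", self.db_path,
                   "-outfmt", self._OUTFMT, "-out", of.name]
            if evalue_max is not None:
                cmd += ["-evalue", str(evalue_max)]
            proc = subprocess.run(cmd, capture_output=True, text=True)
            if proc.returncode != 0:
                raise DataError(f"blastp failed: {proc.stderr.strip()}")
            return read_tabular_hits(of.name)


def resolve_backend(database) -> SearchBackend:
    """Map a database handle (backend, directory, FASTA path, or list of
    sequences) onto a search backend."""
    if isinstance(database, SearchBackend):
        return database
    if isinstance(database, (str, Path)):
        p = Path(database)
        if p.is_dir():
            return PrecomputedBackend(p)
        return BuiltinSWBackend(p)
    return BuiltinSWBackend(database)


def search(query: Sequence, database, evalue_max: float | None = None
           ) -> list[SearchHit]:
    """Run one query against a database handle; hits reference the query."""
    backend = resolve_backend(database)
    hits = backend.search(query, evalue_max=evalue_max)
    for h in hits:
        if h.query_id != query.id:
            raise DataError(
                f"backend returned hit for {h.query_id!r}, expected "
                f"{query.id!r}")
    return hits


# ---------------------------------------------------------------------------
# filtering

@dataclass(frozen=True)
class FilterParams:
    id_min: float = 50.0
    id_max: float = 90.0
    cov_min: float = 70.0
    evalue_max: float | None = None
    max_hits: int | None = None

    def __post_init__(self) -> None:
        if self.id_min > self.id_max:
            raise ConfigError(
                f"id_min ({self.id_min}) exceeds id_max ({self.id_max})")


def filter_hits(hits: Iterable[SearchHit], id_min: float = 50.0,
                id_max: float = 90.0, cov_min: float = 70.0,
                evalue_max: float | None = None,
                max_hits: int | None = None) -> list[SearchHit]:
    """Keep hits with id_min <= identity <= id_max (inclusive), coverage
    strictly above cov_min, and e-value <= evalue_max when set."""
    if id_min > id_max:
        raise ConfigError(f"id_min ({id_min}) exceeds id_max ({id_max})")
    kept = [h for h in hits
            if id_min <= h.identity <= id_max
            and h.coverage > cov_min
            and (evalue_max is None or h.evalue <= evalue_max)]
    if max_hits is not None:
        kept = kept[:max_hits]
    return kept


# ---------------------------------------------------------------------------
# profiles

@dataclass(frozen=True)
class ExtendedProfile:
    """Per-query position-wise frequency matrix over the 21-letter alphabet
    (20 residues + gap), with a per-column supporting-sequence count."""

    query: Sequence
    freqs: np.ndarray   # (len(query), 21), rows sum to 1
    support: np.ndarray  # (len(query),) non-gap contributors per column
    n_hits: int = 0

    def __post_init__(self) -> None:
        if self.freqs.shape != (len(self.query), len(PROFILE_ALPHABET)):
            raise DataError("profile shape does not match query length")
        if np.any(self.freqs < 0):
            raise DataError("negative profile frequencies")
        if np.max(np.abs(self.freqs.sum(axis=1) - 1.0)) > 1e-9:
            raise DataError("profile columns must sum to 1")

    @classmethod
    def from_sequence(cls, query: Sequence) -> "ExtendedProfile":
        """Degenerate self-profile: a point mass on the query residue at
        every position ('X' spreads uniformly over the 20 residues)."""
        return build_profile(query, [])


def _residue_counts(ch: str) -> np.ndarray:
    v = np.zeros(21)
    if ch == GAP:
        v[20] = 1.0
    elif ch == "X":
        v[:20] = 1.0 / 20.0
    else:
        v[AA_INDEX[ch]] = 1.0
    return v


def build_profile(query: Sequence, kept_hits: TSequence[SearchHit]
                  ) -> ExtendedProfile:
    """Stack the query and each kept hit into a one-against-all profile.

    Subject residues opposite query gaps are discarded; subject gaps inside
    a hit's span contribute the gap symbol; query positions outside a hit's
    span receive the gap symbol for that hit.  Gap symbols count toward the
    column denominator (occupancy weighting happens downstream).
    """
    L = len(query)
    counts = np.zeros((L, 21))
    for p, ch in enumerate(query.residues):
        counts[p] += _residue_counts(ch)
    for h in kept_hits:
        if h.query_id != query.id:
            raise DataError(
                f"hit for {h.query_id!r} passed with query {query.id!r}")
        h.validate_against(query)
        row = np.zeros((L, 21))
        row[:, 20] = 1.0  # outside the span: gap
        p = h.qstart
        for qc, sc in zip(h.aligned_query, h.aligned_subject):
            if qc == GAP:
                continue  # column unaligned to the query: dropped
            row[p] = _residue_counts(sc)
            p += 1
        counts += row
    denom = 1 + len(kept_hits)
    freqs = counts / denom
    support = np.asarray(np.round((1.0 - freqs[:, 20]) * denom), dtype=int)
    return ExtendedProfile(query=query, freqs=freqs, support=support,
                           n_hits=len(kept_hits))


def extend_all(sequences: TSequence[Sequence], database,
               filters: FilterParams | None = None
               ) -> dict[str, ExtendedProfile]:
    """One extended profile per input sequence; sequences without surviving
    hits (or with no database) get the degenerate self-profile."""
    filters = filters or FilterParams()
    ids = [s.id for s in sequences]
    if len(set(ids)) != len(ids):
        raise DataError("duplicate sequence ids in input")
    backend = resolve_backend(database) if database is not None else None
    profiles: dict[str, ExtendedProfile] = {}
    for seq in sequences:
        if backend is None:
            profiles[seq.id] = ExtendedProfile.from_sequence(seq)
            continue
        hits = backend.search(seq, evalue_max=filters.evalue_max)
        kept = filter_hits(hits, id_min=filters.id_min, id_max=filters.id_max,
                           cov_min=filters.cov_min,
                           evalue_max=filters.evalue_max,
                           max_hits=filters.max_hits)
        # drop trivial self-hits so the query is not double counted
        kept = [h for h in kept if not (h.subject_id == seq.id
                                        and h.identity >= 100.0)]
        profiles[seq.id] = build_profile(seq, kept)
    return profiles


# ---------------------------------------------------------------------------
# keyword subsetting

_TOKEN_SPLIT = re.compile(r"[\s:;,=|]+")


def filter_database_by_keyword(records: Iterable[Sequence], keyword: str
                               ) -> list[Sequence]:
    """Keep records whose description contains ``keyword`` as a
    case-insensitive token (split on whitespace and common annotation
    punctuation; hyphenated variants do not match)."""
    kw = keyword.lower()
    out = []
    for rec in records:
        tokens = [t.lower() for t in _TOKEN_SPLIT.split(rec.description) if t]
        if kw in tokens:
            out.append(rec)
    return out
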