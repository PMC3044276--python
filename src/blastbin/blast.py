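"""BLAST tabular (outfmt 6) reading and the pre-assignment score filters.

The binning logic never looks at alignment coordinates or percent identity;
the bit score is the sole ranking key, with ties broken by ascending
subject accession so that "the highest scoring hit" is deterministic.
Two filters precede every assignment:

* a bit-score floor (``min_score``, default 35 bits), and
* a top-percent window: only hits whose score is within ``top_percent``
  (default 10%) of the best score that survived the floor are kept.

These defaults mirror the standard import defaults of LCA-based binning
tools and are configurable everywhere they are consumed.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterator

logger = logging.getLogger(__name__)

__all__ = [
    "BlastHit",
    "ReadHits",
    "AssignmentParams",
    "ParseStats",
    "parse_blast_tab",
    "filter_hits",
]


@dataclass(frozen=True)
class BlastHit:
    """One line of BLAST tabular output (the fields the pipeline uses).

    Alignment coordinates and gap counts are carried opaquely in ``extra``;
    no arithmetic is ever performed on them.
    """

    query_id: str
    subject_id: str
    identity: float
    evalue: float
    bit_score: float
    extra: tuple[str, ...] = ()

    def sort_key(self) -> tuple[float, str]:
        return (-self.bit_score, self.subject_id)


@dataclass
class ReadHits:
    """All hits for one read, ordered by descending bit score.

    Equal scores are ordered by ascending subject accession; the ordering
    invariant is established at construction and preserved by filtering.
    """

    read_id: str
    hits: list[BlastHit] = field(default_factory=list)

    def __post_init__(self) -> None:
        for h in self.hits:
            if h.query_id != self.read_id:
                raise ValueError(
                    f"hit for {h.query_id!r} placed under read {self.read_id!r}"
                )
        self.hits = sorted(self.hits, key=BlastHit.sort_key)

    def __len__(self) -> int:
        return len(self.hits)

    def __iter__(self) -> Iterator[BlastHit]:
        return iter(self.hits)

    @property
    def best_score(self) -> float | None:
        return self.hits[0].bit_score if self.hits else None


@dataclass(frozen=True)
class AssignmentParams:
    """Shared import parameters: score floor, top-percent window, min-support.

    ``min_support`` is consumed by the taxonomic post-processing step (nodes
    attracting fewer reads push them to their parent), not by the per-read
    filters.
    """

    min_score: float = 35.0
    top_percent: float = 10.0
    min_support: int = 5

    def __post_init__(self) -> None:
        if self.min_score < 0:
            raise ValueError("min_score must be >= 0")
        if not 0 <= self.top_percent <= 100:
            raise ValueError("top_percent must be in [0, 100]")
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")


@dataclass
class ParseStats:
    """Bookkeeping for one parse: kept hits + rejected lines = data lines."""

    hits: int = 0
    rejected: int = 0
    lines: int = 0


def _open_maybe_gzip(path: Path) -> IO[str]:
    if path.suffix == ".gz":
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, encoding="utf-8")


def parse_blast_tab(
    path: str | Path, stats: ParseStats | None = None
) -> Iterator[ReadHits]:
    """Stream one :class:`ReadHits` per distinct query id in a tabular file.

    The 12-column outfmt-6 layout is expected (qseqid sseqid pident length
    mismatch gapopen qstart qend sstart send evalue bitscore); gzip input is
    accepted.  Query ids need not be contiguous — hits are buffered by read
    id, and reads are yielded in order of first appearance.  Malformed lines
    (wrong column count, non-numeric score/evalue/identity) are counted,
    logged and skipped.  Pass a :class:`ParseStats` to collect the counts.
    """
    path = Path(path)
    if stats is None:
        stats = ParseStats()
    buffered: dict[str, list[BlastHit]] = {}
    with _open_maybe_gzip(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            stats.lines += 1
            fields = line.split("\t")
            if len(fields) < 12:
                stats.rejected += 1
                logger.warning("%s:%d: expected 12 columns, got %d", path.name, lineno, len(fields))
                continue
            try:
                hit = BlastHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    identity=float(fields[2]),
                    evalue=float(fields[10]),
                    bit_score=float(fields[11]),
                    extra=tuple(fields[3:10]),
                )
            except ValueError:
                stats.rejected += 1
                logger.warning("%s:%d: non-numeric field, line skipped", path.name, lineno)
                continue
            if hit.evalue < 0:
                stats.rejected += 1
                logger.warning("%s:%d: negative e-value, line skipped", path.name, lineno)
                continue
            stats.hits += 1
            buffered.setdefault(hit.query_id, []).append(hit)
    for read_id, hits in buffered.items():
        yield ReadHits(read_id, hits)


def filter_hits(
    rh: ReadHits, min_score: float = 35.0, top_percent: float = 10.0
) -> ReadHits:
    """Apply the score floor, then the top-percent window.

    A hit survives iff its bit score is >= ``min_score`` AND >=
    ``(1 - top_percent/100) * best``, where ``best`` is the highest score
    among hits passing the floor.  The operation is idempotent and preserves
    the score ordering.
    """
    if min_score < 0:
        raise ValueError("min_score must be >= 0")
    if not 0 <= top_percent <= 100:
        raise ValueError("top_percent must be in [0, 100]")
    above_floor = [h for h in rh.hits if h.bit_score >= min_score]
    if not above_floor:
        return ReadHits(rh.read_id, [])
    cutoff = (1.0 - top_percent / 100.0) * above_floor[0].bit_score
    return ReadHits(rh.read_id, [h for h in above_floor if h.bit_score >= cutoff])
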