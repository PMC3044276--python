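"""Per-read functional assignment: SEED roles and KEGG orthologies.

Each read goes to the functional role (or KO) of its best-scoring hit whose
accession has a known mapping, after the score filters.  A read with no
hits at all lands in the ``NoHits`` bin; a read whose filtered hits are all
unmapped lands in ``NotAssigned``.  A ``strict`` mode restricts SEED
assignment to the single overall top hit (binning the read if that hit is
unmapped), the more literal reading of "the highest scoring gene".
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .blast import AssignmentParams, BlastHit, ReadHits, filter_hits
from .reference import FunctionMap, KoMap

__all__ = [
    "NO_HITS",
    "NOT_ASSIGNED",
    "BINS",
    "Assignment",
    "assign_seed",
    "assign_ko",
    "write_assignments",
    "read_assignments",
]

NO_HITS = "NoHits"
NOT_ASSIGNED = "NotAssigned"
BINS = (NO_HITS, NOT_ASSIGNED)


@dataclass(frozen=True)
class Assignment:
    """Outcome of binning one read.

    ``target`` is a role name, taxon node id or KO id — or one of the
    special bins.  ``hit`` is the supporting BLAST hit (absent for bins).
    """

    read_id: str
    kind: str  # {"seed-role", "taxon", "ko"}
    target: str
    hit: BlastHit | None = None

    @property
    def is_binned(self) -> bool:
        return self.target in BINS


def _best_mapped(
    rh: ReadHits, mapping: Mapping[str, str] | None, params: AssignmentParams
) -> BlastHit | None:
    """Highest-scoring filtered hit with a known mapping (None if none).

    Hits are already ordered by (-score, accession), so the first mapped
    one is the winner and equal scores resolve to the lexicographically
    smaller accession.
    """
    kept = filter_hits(rh, params.min_score, params.top_percent)
    for hit in kept:
        if mapping is None or hit.subject_id in mapping:
            return hit
    return None


def assign_seed(
    rh: ReadHits,
    fm: FunctionMap,
    params: AssignmentParams | None = None,
    strict: bool = False,
) -> Assignment:
    """Assign a read to the functional role of its best mapped hit.

    With ``strict=True`` only the overall best filtered hit is considered;
    if its accession is unmapped the read is NotAssigned.
    """
    params = params or AssignmentParams()
    if not rh.hits:
        return Assignment(rh.read_id, "seed-role", NO_HITS)
    if strict:
        kept = filter_hits(rh, params.min_score, params.top_percent)
        top = kept.hits[0] if kept.hits else None
        role = fm.get(top.subject_id) if top else None
        if role is None:
            return Assignment(rh.read_id, "seed-role", NOT_ASSIGNED)
        return Assignment(rh.read_id, "seed-role", role, top)
    hit = _best_mapped(rh, fm.entries, params)
    if hit is None:
        return Assignment(rh.read_id, "seed-role", NOT_ASSIGNED)
    return Assignment(rh.read_id, "seed-role", fm.entries[hit.subject_id], hit)


def assign_ko(
    rh: ReadHits, km: KoMap, params: AssignmentParams | None = None
) -> Assignment:
    """Assign a read to the KO of its best hit with a known KO accession.

    The best *mapped* hit wins, not the overall best: a top hit without a
    KO does not block assignment via a lower-scoring mapped hit.
    """
    params = params or AssignmentParams()
    if not rh.hits:
        return Assignment(rh.read_id, "ko", NO_HITS)
    hit = _best_mapped(rh, km.entries, params)
    if hit is None:
        return Assignment(rh.read_id, "ko", NOT_ASSIGNED)
    return Assignment(rh.read_id, "ko", km.entries[hit.subject_id], hit)


def write_assignments(assignments: Iterable[Assignment], path: str | Path) -> None:
    """Write the per-read assignment table.

    TSV columns: read_id, kind, target, bitscore (empty for binned reads) —
    the machine-readable twin of drilling down to individual reads and
    their matches.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#read_id\tkind\ttarget\tbitscore\n")
        for a in assignments:
            score = "" if a.hit is None else f"{a.hit.bit_score:g}"
            fh.write(f"{a.read_id}\t{a.kind}\t{a.target}\t{score}\n")


def read_assignments(path: str | Path) -> dict[str, list[Assignment]]:
    """Read an assignment table back, keyed by kind.

    The supporting hit is not reconstructed (only its bit score was
    serialized); downstream aggregation never needs it.
    """
    out: dict[str, list[Assignment]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            read_id, kind, target = line.split("\t")[:3]
            out.setdefault(kind, []).append(Assignment(read_id, kind, target))
    return out
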