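"""Count profiles over a hierarchy and multi-sample comparison tables.

A :class:`CountProfile` records, for one sample, how many reads were
assigned exactly at each node (``assigned``) and how many fall anywhere in
the subtree below it (``summarized``, the bottom-up recurrence
``summarized(n) = assigned(n) + sum over children of summarized``).

On the multi-labeled SEED tree one read assigned to a role that labels k
leaves is displayed at all k leaves (tree-view counts), while a separate
unique-read tally keeps conservation auditable: summing unique counts over
distinct roles recovers the number of functionally assigned reads, whereas
tree-view counts deliberately overcount by the multiplicity.  On the
(single-labeled) taxonomy the two views coincide and
``summarized(root) + NoHits + NotAssigned = total reads``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .assign import BINS, NO_HITS, NOT_ASSIGNED, Assignment
from .errors import DegenerateInputError, StructuralError
from .reference import Hierarchy

__all__ = ["CountProfile", "ComparisonTable", "build_profile", "join_profiles", "normalize"]


@dataclass
class CountProfile:
    """Per-sample read counts on the nodes of one hierarchy."""

    sample_id: str
    hierarchy: Hierarchy
    assigned: dict[str, int] = field(default_factory=dict)
    bins: dict[str, int] = field(default_factory=lambda: {NO_HITS: 0, NOT_ASSIGNED: 0})
    #: distinct reads assigned to >=1 node (equals sum(assigned.values())
    #: on single-labeled trees; smaller on multi-labeled ones)
    unique_assigned: int = 0
    #: unique reads per target label (role name for SEED, node id otherwise)
    unique_by_target: dict[str, int] = field(default_factory=dict)

    def summarized(self) -> dict[str, int]:
        """Subtree totals, computed bottom-up from ``assigned``."""
        out: dict[str, int] = dict(self.assigned)
        for node in sorted(self.hierarchy.nodes, key=self.hierarchy.depth, reverse=True):
            if node == self.hierarchy.root:
                continue
            if out.get(node):
                parent = self.hierarchy.parent[node]
                out[parent] = out.get(parent, 0) + out[node]
        return {n: c for n, c in out.items() if c}

    @property
    def total_reads(self) -> int:
        return self.unique_assigned + self.bins[NO_HITS] + self.bins[NOT_ASSIGNED]

    def replace_assigned(self, assigned: Mapping[str, int]) -> "CountProfile":
        return CountProfile(
            sample_id=self.sample_id,
            hierarchy=self.hierarchy,
            assigned={n: c for n, c in assigned.items() if c},
            bins=dict(self.bins),
            unique_assigned=self.unique_assigned,
            unique_by_target=dict(self.unique_by_target),
        )

    def __add__(self, other: "CountProfile") -> "CountProfile":
        if other.hierarchy is not self.hierarchy and other.hierarchy != self.hierarchy:
            raise StructuralError("cannot add profiles over different hierarchies")
        merged = Counter(self.assigned)
        merged.update(other.assigned)
        targets = Counter(self.unique_by_target)
        targets.update(other.unique_by_target)
        return CountProfile(
            sample_id=self.sample_id,
            hierarchy=self.hierarchy,
            assigned=dict(merged),
            bins={b: self.bins[b] + other.bins[b] for b in BINS},
            unique_assigned=self.unique_assigned + other.unique_assigned,
            unique_by_target=dict(targets),
        )

    def write_tsv(self, path: str | Path) -> None:
        """Node id, label, assigned count, summarized count (DFS row order)."""
        summarized = self.summarized()
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("#node\tlabel\tassigned\tsummarized\n")
            for node in self.hierarchy.dfs():
                a = self.assigned.get(node, 0)
                s = summarized.get(node, 0)
                if a or s:
                    fh.write(f"{node}\t{self.hierarchy.label.get(node, node)}\t{a}\t{s}\n")
            for b in BINS:
                fh.write(f"{b}\t{b}\t{self.bins[b]}\t{self.bins[b]}\n")


def build_profile(
    assignments: Iterable[Assignment], h: Hierarchy, sample_id: str = "sample"
) -> CountProfile:
    """Aggregate one sample's per-read assignments onto ``h``.

    SEED-role assignments are placed on *every* leaf bearing the role
    (multi-labeled placement); taxon assignments land on their node.  A
    role that labels no leaf, or a taxon absent from the tree, routes the
    read to NotAssigned.
    """
    profile = CountProfile(sample_id=sample_id, hierarchy=h)
    assigned: Counter[str] = Counter()
    for a in assignments:
        if a.target == NO_HITS:
            profile.bins[NO_HITS] += 1
            continue
        if a.target == NOT_ASSIGNED:
            profile.bins[NOT_ASSIGNED] += 1
            continue
        if a.kind == "seed-role":
            leaves = h.leaves_for_role(a.target)
            if not leaves:
                profile.bins[NOT_ASSIGNED] += 1
                continue
            for leaf in leaves:
                assigned[leaf] += 1
        else:
            if a.target not in h:
                profile.bins[NOT_ASSIGNED] += 1
                continue
            assigned[a.target] += 1
        profile.unique_assigned += 1
        profile.unique_by_target[a.target] = profile.unique_by_target.get(a.target, 0) + 1
    profile.assigned = dict(assigned)
    return profile


@dataclass
class ComparisonTable:
    """Row x sample count matrix (rows are hierarchy nodes or role names)."""

    data: pd.DataFrame  # index: row ids, columns: sample ids
    hierarchy: Hierarchy | None = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def drop_bins(self) -> "ComparisonTable":
        keep = [r for r in self.data.index if r not in BINS]
        return ComparisonTable(self.data.loc[keep], self.hierarchy)

    def select_rows(self, rows: Sequence[str]) -> "ComparisonTable":
        return ComparisonTable(self.data.reindex(rows, fill_value=0), self.hierarchy)

    def write_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="node")

    def write_long_tsv(self, path: str | Path) -> None:
        long = self.data.stack().reset_index()
        long.columns = ["node", "sample", "count"]
        long = long[long["count"] != 0]
        long.to_csv(path, sep="\t", index=False)


def join_profiles(
    profiles: Sequence[CountProfile], mode: str = "assigned"
) -> ComparisonTable:
    """Join per-sample profiles into one node x sample table.

    ``mode`` selects assigned or summarized counts.  Rows are the union of
    nonzero nodes in DFS order, then the two bins; missing entries are 0.
    """
    if mode not in ("assigned", "summarized", "unique"):
        raise ValueError(f"unknown mode {mode!r}")
    if not profiles:
        raise ValueError("need at least one profile")
    h = profiles[0].hierarchy
    for p in profiles[1:]:
        if p.hierarchy is not h and p.hierarchy != h:
            raise StructuralError("profiles span different hierarchies")
    if mode == "unique":
        columns = {p.sample_id: p.unique_by_target for p in profiles}
        rows = sorted({t for col in columns.values() for t in col})
    else:
        columns = {
            p.sample_id: (p.assigned if mode == "assigned" else p.summarized())
            for p in profiles
        }
        nonzero = {n for col in columns.values() for n, c in col.items() if c}
        rows = [n for n in h.dfs() if n in nonzero]
    index = rows + list(BINS)
    data = pd.DataFrame(0, index=index, columns=[p.sample_id for p in profiles], dtype=float)
    for p in profiles:
        col = columns[p.sample_id]
        for n, c in col.items():
            data.loc[n, p.sample_id] = c
        for b in BINS:
            data.loc[b, p.sample_id] = p.bins[b]
    return ComparisonTable(data, h)


def role_table(profiles: Sequence[CountProfile]) -> ComparisonTable:
    """Role x sample table of unique-read counts (no double counting).

    This is the default input for the ecological distance indices: each
    read contributes once to its role regardless of how many leaves the
    role labels, and ancestors are not mixed with their descendants.
    """
    table = join_profiles(profiles, mode="unique")
    return table.drop_bins()


def table_from_columns(
    columns: Mapping[str, Mapping[str, float]], hierarchy: Hierarchy | None = None
) -> ComparisonTable:
    """Build a ComparisonTable from per-sample ``{row: count}`` maps."""
    rows = sorted({r for col in columns.values() for r in col})
    data = pd.DataFrame(0.0, index=rows, columns=list(columns))
    for sample, col in columns.items():
        for r, c in col.items():
            data.loc[r, sample] = c
    return ComparisonTable(data, hierarchy)


def read_profile_tsv(
    path: str | Path, h: Hierarchy, sample_id: str | None = None
) -> CountProfile:
    """Read a profile written by :meth:`CountProfile.write_tsv`.

    Summarized counts are recomputed rather than trusted; on multi-labeled
    trees the unique-read tallies are not recoverable from node counts and
    are re-derived as if the tree were single-labeled.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.name.split(".")[0]
    assigned: dict[str, int] = {}
    bins = {NO_HITS: 0, NOT_ASSIGNED: 0}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            node, _label, a, _s = line.split("\t")[:4]
            if node in BINS:
                bins[node] = int(a)
            elif int(a):
                assigned[node] = int(a)
    return CountProfile(
        sample_id=sample_id,
        hierarchy=h,
        assigned=assigned,
        bins=bins,
        unique_assigned=sum(assigned.values()),
        unique_by_target=dict(assigned),
    )


def normalize(table: ComparisonTable, mode: str = "relative") -> ComparisonTable:
    """Column-normalize a table; ``relative`` columns sum to 1."""
    if mode == "none":
        return table
    if mode != "relative":
        raise ValueError(f"unknown normalization mode {mode!r}")
    totals = table.data.sum(axis=0)
    zero = [s for s, t in totals.items() if t == 0]
    if zero:
        raise DegenerateInputError(
            "zero-total sample(s) in relative normalization: " + ", ".join(map(str, zero))
        )
    return ComparisonTable(table.data / totals, table.hierarchy)
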