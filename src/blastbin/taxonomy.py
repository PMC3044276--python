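"""Taxonomic binning: LCA placement, min-support promotion, taxon selection.

A read is placed on the lowest common ancestor of the taxa of its filtered,
mapped hits — the most specific taxon consistent with every strong match.
A post-processing pass then promotes reads on weakly supported nodes
(assigned count below ``min_support``) to their parents, so that isolated
one-off placements do not masquerade as confident species calls.  Finally,
``reads_under_taxa`` supports restricting downstream analyses (e.g. KEGG
pathways) to a chosen clade.
"""

from __future__ import annotations

from typing import Iterable

from .assign import NO_HITS, NOT_ASSIGNED, Assignment
from .blast import AssignmentParams, ReadHits, filter_hits
from .reference import Hierarchy, TaxonMap

__all__ = ["assign_taxon", "apply_min_support", "reads_under_taxa"]


def assign_taxon(
    rh: ReadHits,
    tm: TaxonMap,
    tax: Hierarchy,
    params: AssignmentParams | None = None,
) -> Assignment:
    """Place a read on the LCA of the taxa of its filtered, mapped hits.

    Hits whose accession is unmapped, or mapped to a taxon absent from the
    tree (version drift), are ignored; if none remain the read is
    NotAssigned.  The supporting hit recorded is the best-scoring one that
    contributed a taxon.
    """
    params = params or AssignmentParams()
    if not rh.hits:
        return Assignment(rh.read_id, "taxon", NO_HITS)
    kept = filter_hits(rh, params.min_score, params.top_percent)
    taxa = []
    support = None
    for hit in kept:
        taxon = tm.get(hit.subject_id)
        if taxon is None or taxon not in tax:
            continue
        taxa.append(taxon)
        if support is None:
            support = hit
    if not taxa:
        return Assignment(rh.read_id, "taxon", NOT_ASSIGNED)
    return Assignment(rh.read_id, "taxon", tax.lca(taxa), support)


def apply_min_support(profile, tax: Hierarchy, min_support: int):
    """Promote reads on under-supported taxa to their parents.

    Every node (other than the root) whose assigned count is positive but
    below ``min_support`` has its reads moved to its immediate parent,
    deepest nodes first, repeated until no node changes.  Total assigned
    reads are conserved; the NoHits/NotAssigned bins are untouched.

    Takes and returns a :class:`blastbin.profiles.CountProfile` over ``tax``.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    assigned = {n: c for n, c in profile.assigned.items() if c}
    by_depth = sorted(tax.nodes, key=tax.depth, reverse=True)
    changed = True
    while changed:
        changed = False
        for node in by_depth:
            count = assigned.get(node, 0)
            if node == tax.root or count == 0:
                continue
            if count < min_support:
                parent = tax.parent[node]
                assigned[parent] = assigned.get(parent, 0) + count
                del assigned[node]
                changed = True
    return profile.replace_assigned(assigned)


def reads_under_taxa(
    assignments: Iterable[Assignment], tax: Hierarchy, selected: Iterable[str]
) -> set[str]:
    """Read ids assigned to a selected taxon or any of its descendants."""
    allowed: set[str] = set()
    for node in selected:
        allowed |= tax.subtree(node)  # raises UnknownNodeError for bad ids
    return {
        a.read_id
        for a in assignments
        if a.kind == "taxon" and not a.is_binned and a.target in allowed
    }
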