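"""Independent brute-force reference implementations for oracle tests.

Everything here works on raw parent dicts and hit lists, never on blastbin
objects' own query methods, so agreement with the package is a real
cross-check and not a tautology.
"""

from __future__ import annotations


def path_to_root(parent: dict[str, str], node: str) -> list[str]:
    path = [node]
    while parent.get(path[-1]) not in (None, path[-1], "", "-"):
        path.append(parent[path[-1]])
    return path


def brute_lca(parent: dict[str, str], nodes: list[str]) -> str:
    """Deepest node on every input's root path, by exhaustive intersection."""
    common = set(path_to_root(parent, nodes[0]))
    for n in nodes[1:]:
        common &= set(path_to_root(parent, n))
    return max(common, key=lambda c: len(path_to_root(parent, c)))


def brute_filter(hits, min_score, top_percent):
    """hits: list of (subject_id, bit_score)."""
    ok = [h for h in hits if h[1] >= min_score]
    if not ok:
        return []
    best = max(s for _, s in ok)
    cutoff = (1 - top_percent / 100.0) * best
    return [h for h in ok if h[1] >= cutoff]


def brute_best_mapped(hits, mapping, min_score, top_percent):
    """Target of the best mapped filtered hit, or a bin name.

    ``hits``: (subject_id, bit_score) pairs; ties to the smaller accession.
    """
    if not hits:
        return "NoHits"
    mapped = [h for h in brute_filter(hits, min_score, top_percent) if h[0] in mapping]
    if not mapped:
        return "NotAssigned"
    acc, _ = min(mapped, key=lambda h: (-h[1], h[0]))
    return mapping[acc]


def brute_taxon(hits, mapping, parent, min_score, top_percent):
    if not hits:
        return "NoHits"
    taxa = [
        mapping[h[0]]
        for h in brute_filter(hits, min_score, top_percent)
        if h[0] in mapping and mapping[h[0]] in set(parent) | set(parent.values())
    ]
    if not taxa:
        return "NotAssigned"
    return brute_lca(parent, taxa)


def brute_unifrac(parent, root, counts_a, counts_b, variant):
    """Explicit per-branch enumeration; unit branch lengths."""
    nodes = set(parent) | set(parent.values()) | {root}

    def subtree_mass(branch, counts):
        return sum(
            c for n, c in counts.items() if branch in path_to_root(parent, n)
        )

    branches = sorted(n for n in nodes if n != root)
    ta, tb = sum(counts_a.values()), sum(counts_b.values())
    if variant == "unweighted":
        unique = shared = 0
        for b in branches:
            a, bb = subtree_mass(b, counts_a) > 0, subtree_mass(b, counts_b) > 0
            if a or bb:
                shared += 1
                if a != bb:
                    unique += 1
        return unique / shared if shared else 0.0
    num = den = 0.0
    for b in branches:
        pa = subtree_mass(b, counts_a) / ta
        pb = subtree_mass(b, counts_b) / tb
        num += abs(pa - pb)
        den += pa + pb
    return num / den if den else 0.0


def random_tree(rng, n_nodes: int) -> dict[str, str]:
    """Random rooted tree as a parent dict (root maps to itself)."""
    names = [f"n{i}" for i in range(n_nodes)]
    parent = {names[0]: names[0]}
    for i in range(1, n_nodes):
        parent[names[i]] = names[int(rng.integers(0, i))]
    return parent
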