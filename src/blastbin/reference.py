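"""Reference model: classification hierarchies and accession mapping tables.

Two kinds of rooted trees drive every assignment step:

* a taxonomy (NCBI-style), in which each node is a taxon and every read is
  eventually placed on exactly one node;
* a SEED-style functional classification, in which internal nodes are
  subsystems and leaves carry functional-role names.  The SEED tree is
  *multi-labeled*: the same role name may label several leaves when a role
  participates in more than one subsystem.

Both are represented by :class:`Hierarchy`.  Mapping tables translate the
subject accessions found in BLAST output into functional roles
(:class:`FunctionMap`), taxon nodes (:class:`TaxonMap`) or KEGG orthology
identifiers (:class:`KoMap`, which also knows the KO -> pathway membership).

Interchange formats are deliberately plain: hierarchies are 3/4-column TSV
edge lists (child, parent, label[, role]) with ``#`` comments, Newick is
accepted read-only (labels only; branch lengths ignored, unit lengths
assumed); mapping tables are 2+-column TSVs (accession, target, extra
columns ignored).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .errors import FormatError, StructuralError, UnknownNodeError

logger = logging.getLogger(__name__)

__all__ = [
    "Hierarchy",
    "FunctionMap",
    "TaxonMap",
    "KoMap",
    "ReferenceData",
    "load_hierarchy",
    "write_hierarchy",
    "lca",
    "leaves_for_role",
    "load_mapping",
    "load_pathway_map",
]


class Hierarchy:
    """A validated rooted tree of named nodes.

    Parameters
    ----------
    parent
        Map ``node -> parent``.  The root may map to itself, to the empty
        string, or to ``"-"``; all three conventions mark it as root.
    label
        Optional display names; nodes default to their own id.
    leaf_role
        Optional map ``leaf -> functional-role name`` (SEED variant).  The
        same role may appear on several leaves.

    Raises
    ------
    StructuralError
        If the edge set has no root, more than one root, a cycle, or a
        role-labeled node that is not a leaf.
    """

    def __init__(
        self,
        parent: Mapping[str, str],
        label: Mapping[str, str] | None = None,
        leaf_role: Mapping[str, str] | None = None,
    ) -> None:
        cleaned: dict[str, str] = {}
        roots: list[str] = []
        for child, par in parent.items():
            if par in ("", "-", child):
                roots.append(child)
            else:
                cleaned[child] = par
        # parents that never appear as children are implicit roots
        children_ids = set(cleaned)
        for par in set(cleaned.values()):
            if par not in children_ids and par not in roots:
                roots.append(par)
        if not roots:
            raise StructuralError("no root found (every node has a parent)")
        if len(roots) > 1:
            raise StructuralError(
                "multiple roots: " + ", ".join(sorted(roots))
            )
        self.root: str = roots[0]
        self.parent: dict[str, str] = cleaned
        self._nodes: set[str] = {self.root} | set(cleaned) | set(cleaned.values())

        self._children: dict[str, list[str]] = defaultdict(list)
        for child, par in cleaned.items():
            self._children[par].append(child)
        for kids in self._children.values():
            kids.sort()

        # cycle check: walk every parent chain; it must reach the root
        # within |nodes| steps
        self._depth: dict[str, int] = {self.root: 0}
        for node in self._nodes:
            chain = []
            cur = node
            while cur not in self._depth:
                chain.append(cur)
                cur = self.parent.get(cur)
                if cur is None or len(chain) > len(self._nodes):
                    raise StructuralError(f"cycle detected at node {chain[-1]!r}")
            base = self._depth[cur]
            for i, n in enumerate(reversed(chain), start=1):
                self._depth[n] = base + i

        self.label: dict[str, str] = {n: n for n in self._nodes}
        if label:
            self.label.update({n: v for n, v in label.items() if n in self._nodes})

        self.leaf_role: dict[str, str] = {}
        if leaf_role:
            for node, role in leaf_role.items():
                if node not in self._nodes:
                    continue
                if self._children.get(node):
                    raise StructuralError(
                        f"role {role!r} on internal node {node!r}; roles label leaves only"
                    )
                self.leaf_role[node] = role
        self._role_index: dict[str, set[str]] = defaultdict(set)
        for leaf, role in self.leaf_role.items():
            self._role_index[role].add(leaf)

    # -- queries ---------------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return set(self._nodes)

    def __len__(self) -> int:
        return len(self._nodes)

    def __contains__(self, node: str) -> bool:
        return node in self._nodes

    def children(self, node: str) -> list[str]:
        self._require(node)
        return list(self._children.get(node, ()))

    def is_leaf(self, node: str) -> bool:
        self._require(node)
        return not self._children.get(node)

    def leaves(self) -> set[str]:
        return {n for n in self._nodes if not self._children.get(n)}

    def depth(self, node: str) -> int:
        self._require(node)
        return self._depth[node]

    def ancestors(self, node: str) -> list[str]:
        """Path from ``node`` up to the root, inclusive of both."""
        self._require(node)
        path = [node]
        while path[-1] != self.root:
            path.append(self.parent[path[-1]])
        return path

    def subtree(self, node: str) -> set[str]:
        """All nodes in the subtree rooted at ``node`` (including it)."""
        self._require(node)
        out = {node}
        stack = [node]
        while stack:
            for child in self._children.get(stack.pop(), ()):
                out.add(child)
                stack.append(child)
        return out

    def dfs(self) -> list[str]:
        """Depth-first preorder with children in lexicographic order.

        Used for stable row ordering in exported tables.
        """
        out: list[str] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(self._children.get(node, ())))
        return out

    def lca(self, nodes: Iterable[str]) -> str:
        """Deepest node that is an ancestor-or-self of every input node."""
        nodes = list(nodes)
        if not nodes:
            raise ValueError("lca of an empty node set is undefined")
        for n in nodes:
            self._require(n)
        common: set[str] | None = None
        for n in nodes:
            anc = set(self.ancestors(n))
            common = anc if common is None else common & anc
        assert common  # root is always shared
        return max(common, key=self._depth.__getitem__)

    def leaves_for_role(self, role: str) -> set[str]:
        """Every leaf labeled with ``role``; empty set if the role is unknown."""
        return set(self._role_index.get(role, ()))

    def roles(self) -> set[str]:
        return set(self._role_index)

    def _require(self, node: str) -> None:
        if node not in self._nodes:
            raise UnknownNodeError(f"unknown node {node!r}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Hierarchy):
            return NotImplemented
        return (
            self.root == other.root
            and self.parent == other.parent
            and self.label == other.label
            and self.leaf_role == other.leaf_role
        )

    def __repr__(self) -> str:
        return (
            f"<Hierarchy root={self.root!r} nodes={len(self._nodes)} "
            f"leaves={len(self.leaves())} roles={len(self._role_index)}>"
        )


# -- hierarchy I/O -------------------------------------------------------


def load_hierarchy(path: str | Path, format: str = "edge-tsv") -> Hierarchy:
    """Read a hierarchy from ``path``.

    ``edge-tsv`` is the native format: tab-delimited ``child  parent
    label  [role]`` with a header line and ``#`` comments; the root row has
    ``parent`` equal to itself, empty, or ``-``.  ``newick`` is accepted for
    convenience (labels only; branch lengths are discarded and unnamed
    internal nodes receive synthetic ids).
    """
    path = Path(path)
    if format == "edge-tsv":
        return _load_edge_tsv(path)
    if format == "newick":
        return _load_newick(path)
    raise ValueError(f"unknown hierarchy format {format!r}")


def _load_edge_tsv(path: Path) -> Hierarchy:
    parent: dict[str, str] = {}
    label: dict[str, str] = {}
    role: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        first = True
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if first:
                first = False
                if fields[0].lower() in ("child", "node", "child_id"):
                    continue  # header
            if len(fields) < 2:
                raise FormatError(f"{path.name}:{lineno}: expected >=2 tab-separated fields")
            child, par = fields[0], fields[1]
            if child in parent and parent[child] != par:
                raise FormatError(
                    f"{path.name}:{lineno}: node {child!r} listed with two parents"
                )
            parent[child] = par
            if len(fields) >= 3 and fields[2]:
                label[child] = fields[2]
            if len(fields) >= 4 and fields[3]:
                role[child] = fields[3]
    if not parent:
        raise FormatError(f"{path.name}: no edges found")
    return Hierarchy(parent, label=label, leaf_role=role)


def _load_newick(path: Path) -> Hierarchy:
    import skbio  # deferred: heavy import

    tree = skbio.TreeNode.read(str(path), format="newick")
    parent: dict[str, str] = {}
    counter = 0

    names: dict[int, str] = {}

    def name_of(node) -> str:
        nonlocal counter
        key = id(node)
        if key not in names:
            if node.name:
                names[key] = str(node.name)
            else:
                counter += 1
                names[key] = f"_node{counter}"
        return names[key]

    root_name = name_of(tree)
    parent[root_name] = root_name
    for node in tree.preorder(include_self=False):
        parent[name_of(node)] = name_of(node.parent)
    return Hierarchy(parent)


def write_hierarchy(h: Hierarchy, path: str | Path) -> None:
    """Write ``h`` as edge TSV (inverse of ``load_hierarchy`` round-trips)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#child\tparent\tlabel\trole\n")
        for node in h.dfs():
            par = h.parent.get(node, node)  # root -> itself
            fh.write(
                f"{node}\t{par}\t{h.label.get(node, node)}\t{h.leaf_role.get(node, '')}\n"
            )


def lca(h: Hierarchy, nodes: Iterable[str]) -> str:
    return h.lca(nodes)


def leaves_for_role(h: Hierarchy, role: str) -> set[str]:
    return h.leaves_for_role(role)


# -- mapping tables ------------------------------------------------------


@dataclass
class FunctionMap:
    """Subject accession -> SEED functional-role name."""

    entries: dict[str, str]

    def get(self, accession: str) -> str | None:
        return self.entries.get(accession)

    def validate(self, seed: Hierarchy) -> list[str]:
        """Role names that label no leaf of ``seed`` (dangling; warnings)."""
        return sorted({r for r in self.entries.values() if not seed.leaves_for_role(r)})


@dataclass
class TaxonMap:
    """Subject accession -> taxonomy node id."""

    entries: dict[str, str]

    def get(self, accession: str) -> str | None:
        return self.entries.get(accession)

    def validate(self, taxonomy: Hierarchy) -> list[str]:
        return sorted({t for t in self.entries.values() if t not in taxonomy})


@dataclass
class KoMap:
    """Subject accession -> KEGG orthology (KO) id, plus KO -> pathway sets.

    A KO may belong to several pathways; a KO with no known pathway simply
    has no entry in :attr:`pathways` and is reported under a synthetic
    ``unmapped-KO`` pathway by the aggregation step.
    """

    entries: dict[str, str]
    pathways: dict[str, set[str]] = field(default_factory=dict)
    pathway_label: dict[str, str] = field(default_factory=dict)

    def get(self, accession: str) -> str | None:
        return self.entries.get(accession)

    def pathways_of(self, ko: str) -> set[str]:
        return set(self.pathways.get(ko, ()))

    def with_pathways(
        self, pathways: Mapping[str, set[str]], labels: Mapping[str, str] | None = None
    ) -> "KoMap":
        return KoMap(
            entries=dict(self.entries),
            pathways={k: set(v) for k, v in pathways.items()},
            pathway_label=dict(labels or {}),
        )


_KINDS = {"function": FunctionMap, "taxon": TaxonMap, "ko": KoMap}


def load_mapping(path: str | Path, kind: str) -> FunctionMap | TaxonMap | KoMap:
    """Load an accession->target TSV (``accession<TAB>target[<TAB>ignored]``).

    Duplicate accessions with identical targets collapse silently; with
    conflicting targets they raise :class:`FormatError` naming the
    accession.  An empty file yields an empty map with a warning.
    """
    if kind not in _KINDS:
        raise ValueError(f"unknown mapping kind {kind!r}; expected one of {sorted(_KINDS)}")
    path = Path(path)
    entries: dict[str, str] = {}
    conflicts: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path.name}:{lineno}: expected >=2 tab-separated fields")
            acc, target = fields[0], fields[1]
            if acc in entries and entries[acc] != target:
                conflicts.append(acc)
            entries[acc] = target
    if conflicts:
        raise FormatError(
            "conflicting duplicate accessions: " + ", ".join(sorted(set(conflicts)))
        )
    if not entries:
        logger.warning("mapping file %s is empty", path)
    return _KINDS[kind](entries)


def load_pathway_map(path: str | Path) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Read a KO -> pathway TSV (``ko<TAB>pathway_id[<TAB>pathway_name]``).

    Returns ``(pathways, pathway_label)`` for :meth:`KoMap.with_pathways`.
    """
    path = Path(path)
    pathways: dict[str, set[str]] = defaultdict(set)
    labels: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path.name}:{lineno}: expected >=2 tab-separated fields")
            ko, pw = fields[0], fields[1]
            pathways[ko].add(pw)
            if len(fields) >= 3 and fields[2]:
                labels[pw] = fields[2]
    return dict(pathways), labels


@dataclass
class ReferenceData:
    """Bundle of everything the assignment pipeline consults."""

    seed: Hierarchy
    taxonomy: Hierarchy
    functions: FunctionMap
    taxa: TaxonMap
    kos: KoMap

    @classmethod
    def load(cls, directory: str | Path) -> "ReferenceData":
        """Load a fixture-style reference directory.

        Expects ``seed_tree.tsv``, ``taxonomy.tsv``, ``acc2role.tsv``,
        ``acc2taxon.tsv``, ``acc2ko.tsv`` and optionally ``ko2pathway.tsv``
        (the layout written by :func:`blastbin.simulate.generate`).
        """
        d = Path(directory)
        kos = load_mapping(d / "acc2ko.tsv", "ko")
        pw_file = d / "ko2pathway.tsv"
        if pw_file.exists():
            pathways, labels = load_pathway_map(pw_file)
            kos = kos.with_pathways(pathways, labels)
        return cls(
            seed=load_hierarchy(d / "seed_tree.tsv"),
            taxonomy=load_hierarchy(d / "taxonomy.tsv"),
            functions=load_mapping(d / "acc2role.tsv", "function"),
            taxa=load_mapping(d / "acc2taxon.tsv", "taxon"),
            kos=kos,
        )
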