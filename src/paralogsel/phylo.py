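"""Rooted phylogenies: newick I/O, MRCA queries, and branch-class tagging.

Trees are consumed, never inferred.  The in-memory representation is a flat
node table (parent links + branch lengths) so that downstream likelihood
engines can build index arrays from it cheaply; newick tokenization is
delegated to :mod:`dendropy`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import dendropy

__all__ = [
    "Node",
    "Phylogeny",
    "BranchClassSpec",
    "NewickParseError",
    "DuplicateTipLabelError",
    "BranchClassError",
    "read_newick",
    "write_newick",
    "DEFAULT_CLASS",
]

DEFAULT_CLASS = "default"


class NewickParseError(ValueError):
    """Raised when newick text cannot be parsed; carries position info when known."""

    def __init__(self, message: str, offset: int | None = None):
        super().__init__(message)
        self.offset = offset


class DuplicateTipLabelError(ValueError):
    pass


class BranchClassError(ValueError):
    pass


@dataclass
class Node:
    """One tree node; ``length`` is the branch above it (None for the root)."""

    id: int
    parent: int | None
    length: float | None
    label: str | None = None
    children: list[int] = field(default_factory=list)
    branch_class: str = DEFAULT_CLASS

    @property
    def is_tip(self) -> bool:
        return not self.children


class Phylogeny:
    """Rooted tree with branch lengths and optional per-branch class labels.

    Invariants: exactly one root, unique tip labels, finite non-negative
    branch lengths (checked at construction).
    """

    def __init__(self, nodes: Sequence[Node]):
        self.nodes: list[Node] = list(nodes)
        roots = [n for n in self.nodes if n.parent is None]
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, found {len(roots)}")
        self.root: int = roots[0].id
        labels = [n.label for n in self.nodes if n.is_tip]
        if any(lbl is None for lbl in labels):
            raise ValueError("every tip must be labeled")
        dupes = {lbl for lbl in labels if labels.count(lbl) > 1}
        if dupes:
            raise DuplicateTipLabelError(f"duplicate tip labels: {sorted(dupes)}")
        for n in self.nodes:
            if n.parent is None:
                continue
            if n.length is None:
                n.length = 0.0
            if not (n.length >= 0.0 and n.length < float("inf")):
                raise ValueError(f"branch length of node {n.id} must be finite and >= 0, got {n.length}")
        self._tip_index = {n.label: n.id for n in self.nodes if n.is_tip}

    # ------------------------------------------------------------------ basic
    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def n_tips(self) -> int:
        return len(self._tip_index)

    @property
    def tip_labels(self) -> list[str]:
        return [self.nodes[i].label for i in self.tips()]

    def tips(self) -> list[int]:
        return [n.id for n in self.nodes if n.is_tip]

    def tip_id(self, label: str) -> int:
        try:
            return self._tip_index[label]
        except KeyError:
            raise KeyError(f"unknown taxon: {label!r}") from None

    def postorder(self) -> Iterator[int]:
        """Children before parents (iterative, safe for deep trees)."""
        stack = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                yield node
            else:
                stack.append((node, True))
                for c in self.nodes[node].children:
                    stack.append((c, False))

    def preorder(self) -> Iterator[int]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(self.nodes[node].children))

    def copy(self) -> "Phylogeny":
        return Phylogeny(
            [
                Node(n.id, n.parent, n.length, n.label, list(n.children), n.branch_class)
                for n in self.nodes
            ]
        )

    # ------------------------------------------------------------------- mrca
    def descendant_tips(self, node: int) -> set[str]:
        out: set[str] = set()
        stack = [node]
        while stack:
            i = stack.pop()
            n = self.nodes[i]
            if n.is_tip:
                out.add(n.label)
            stack.extend(n.children)
        return out

    def mrca(self, taxa: Iterable[str]) -> int:
        """Deepest node whose descendant tip set contains ``taxa``."""
        taxa = set(taxa)
        if not taxa:
            raise ValueError("taxa set must be non-empty")
        ids = {self.tip_id(t) for t in taxa}
        count = [0] * len(self.nodes)
        for i in self.postorder():
            n = self.nodes[i]
            if n.is_tip:
                count[i] = 1 if i in ids else 0
            else:
                count[i] = sum(count[c] for c in n.children)
            if count[i] == len(ids):
                return i
        raise RuntimeError("unreachable: root must contain all taxa")

    # ------------------------------------------------------------ class tags
    def tag_branches(self, spec: "BranchClassSpec", include_stem: bool = True) -> "Phylogeny":
        """Return a copy with branch classes assigned.

        A branch (the edge above a node) gets class ``c`` iff every tip below
        it belongs to ``c``'s taxon set; the clade's stem branch is included
        unless ``include_stem`` is False, in which case the clade root's own
        edge stays at the default class.  Nested clades resolve to the most
        specific (later/smaller) class; non-nested overlap is an error.
        """
        tree = self.copy()
        for n in tree.nodes:
            n.branch_class = spec.default
        tip_sets = {i: self.descendant_tips(i) for i in range(len(self.nodes))}
        assigned_by: dict[int, str] = {}
        for class_name, taxa in spec.classes:
            taxa = set(taxa)
            unknown = taxa - set(self._tip_index)
            if unknown:
                raise BranchClassError(f"class {class_name!r} references unknown taxa: {sorted(unknown)}")
            clade_root = self.mrca(taxa)
            for i in range(len(tree.nodes)):
                if tree.nodes[i].parent is None:
                    continue
                if tip_sets[i] <= taxa:
                    if not include_stem and i == clade_root:
                        continue
                    prev = assigned_by.get(i)
                    if prev is not None and prev != class_name:
                        prev_taxa = dict(spec.classes)[prev]
                        if not (taxa <= set(prev_taxa) or set(prev_taxa) <= taxa):
                            raise BranchClassError(
                                f"branch above node {i} eligible for classes "
                                f"{prev!r} and {class_name!r} (overlapping, non-nested taxon sets)"
                            )
                    assigned_by[i] = class_name
                    tree.nodes[i].branch_class = class_name
        return tree

    # ---------------------------------------------------------------- reroot
    def reroot_on_tip(self, label: str) -> "Phylogeny":
        """Reroot on the edge leading to ``label``, splitting it at midpoint."""
        dtree = _to_dendropy(self)
        leaf = dtree.find_node_with_taxon_label(label)
        if leaf is None:
            raise KeyError(f"unknown taxon: {label!r}")
        edge = leaf.edge
        half = (edge.length or 0.0) / 2.0
        dtree.reroot_at_edge(edge, length1=half, length2=half, update_bipartitions=False)
        return _from_dendropy(dtree)

    # ------------------------------------------------------------------- I/O
    def write_newick(self) -> str:
        return write_newick(self)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Phylogeny n_tips={self.n_tips} n_nodes={len(self.nodes)}>"


@dataclass
class BranchClassSpec:
    """Clade-based branch classes: ordered (class_name, taxon_set) pairs."""

    classes: list[tuple[str, set[str]]] = field(default_factory=list)
    default: str = DEFAULT_CLASS

    def __post_init__(self) -> None:
        names = [c for c, _ in self.classes]
        if len(names) != len(set(names)):
            raise BranchClassError("class names must be unique")
        if self.default in names:
            raise BranchClassError("default class name collides with a clade class")


# ---------------------------------------------------------------------------
# dendropy bridge
# ---------------------------------------------------------------------------

def _from_dendropy(dtree: dendropy.Tree) -> Phylogeny:
    nodes: list[Node] = []
    index: dict[int, int] = {}
    for dnode in dtree.preorder_node_iter():
        i = len(nodes)
        index[id(dnode)] = i
        parent = index[id(dnode.parent_node)] if dnode.parent_node is not None else None
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label is not None:
            label = dnode.label
        nodes.append(Node(i, parent, dnode.edge.length, label))
        if parent is not None:
            nodes[parent].children.append(i)
    return Phylogeny(nodes)


def _to_dendropy(tree: Phylogeny) -> dendropy.Tree:
    taxa = dendropy.TaxonNamespace()
    dtree = dendropy.Tree(taxon_namespace=taxa)
    dnodes: dict[int, dendropy.Node] = {}
    for i in tree.preorder():
        n = tree.nodes[i]
        if i == tree.root:
            dnode = dtree.seed_node
        else:
            dnode = dnodes[n.parent].new_child()
        dnode.edge.length = n.length
        if n.is_tip:
            dnode.taxon = taxa.new_taxon(n.label)
        elif n.label:
            dnode.label = n.label
        dnodes[i] = dnode
    return dtree


def read_newick(text: str) -> Phylogeny:
    """Parse a newick string (quoted labels and [comments] accepted)."""
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        if "Duplicate taxon labels" in str(exc):
            raise DuplicateTipLabelError(str(exc)) from exc
        offset = getattr(exc, "col_num", None)
        raise NewickParseError(f"newick parse error: {exc}", offset=offset) from exc
    return _from_dendropy(dtree)


def read_newick_file(path) -> Phylogeny:
    with open(path) as fh:
        return read_newick(fh.read())


def _newick_label(label: str) -> str:
    if any(ch in label for ch in " ()[]':;,"):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: Phylogeny) -> str:
    parts: dict[int, str] = {}
    for i in tree.postorder():
        n = tree.nodes[i]
        if n.is_tip:
            s = _newick_label(n.label)
        else:
            s = "(" + ",".join(parts.pop(c) for c in n.children) + ")"
            if n.label:
                s += _newick_label(n.label)
        if n.parent is not None:
            s += f":{n.length:.12g}"
        parts[i] = s
    return parts[tree.root] + ";"
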