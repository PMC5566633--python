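"""Rooted gene trees: data model, Newick/NHX I/O, event labeling, subdivision.

Trees are rooted and binary.  Tips carry a species id and a transcript id
(label ``species:transcript``); internal nodes carry an event label,
``speciation`` or ``duplication``, either parsed from NHX ``D=Y/N`` tags or
inferred from species overlap.
"""

from __future__ import annotations

import io
import itertools
from dataclasses import dataclass, field
from typing import Callable, Iterator

import dendropy

SPECIATION = "speciation"
DUPLICATION = "duplication"

__all__ = [
    "Node",
    "GeneTree",
    "TreeError",
    "read_gene_tree",
    "write_gene_tree",
    "label_events_species_overlap",
    "subdivide_at_outgroup",
]


class TreeError(ValueError):
    """Raised for malformed or unusable trees."""


@dataclass
class Node:
    """A node of a rooted gene tree.

    ``length`` is the length of the edge above the node (0.0 at the root).
    """

    name: str | None = None
    length: float = 0.0
    children: list["Node"] = field(default_factory=list)
    parent: "Node | None" = field(default=None, repr=False, compare=False)
    event: str | None = None
    species: str | None = None
    transcript: str | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def label(self) -> str:
        if self.species is not None and self.transcript is not None:
            return f"{self.species}:{self.transcript}"
        return self.name or ""

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child


class GeneTree:
    """A rooted binary tree over (species, transcript) tips."""

    def __init__(self, root: Node, name: str | None = None):
        self.root = root
        self.name = name

    # -- traversal ---------------------------------------------------------
    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            nd = stack.pop()
            yield nd
            stack.extend(reversed(nd.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            nd = stack.pop()
            out.append(nd)
            stack.extend(nd.children)
        return iter(reversed(out))

    def tips(self) -> list[Node]:
        return [nd for nd in self.preorder() if nd.is_leaf]

    def internal_nodes(self) -> list[Node]:
        return [nd for nd in self.preorder() if not nd.is_leaf]

    def branches(self) -> list[tuple[Node, Node]]:
        """(parent, child) pairs; the root has no branch above it."""
        return [(nd.parent, nd) for nd in self.preorder() if nd.parent is not None]

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    def species_set(self) -> set[str]:
        return {t.species for t in self.tips() if t.species is not None}

    def depth(self) -> float:
        """Maximum root-to-tip path length."""
        best = 0.0
        depths: dict[int, float] = {id(self.root): 0.0}
        for nd in self.preorder():
            if nd.parent is not None:
                d = depths[id(nd.parent)] + nd.length
                depths[id(nd)] = d
                if nd.is_leaf:
                    best = max(best, d)
        return best

    def validate_binary(self) -> None:
        for nd in self.preorder():
            if nd.children and len(nd.children) != 2:
                raise TreeError(
                    f"non-binary node with {len(nd.children)} children: {nd.label!r}"
                )

    def assign_node_ids(self) -> None:
        """Give every unnamed internal node a stable preorder id (n0, n1, ...)."""
        counter = itertools.count()
        for nd in self.preorder():
            if not nd.is_leaf and not nd.name:
                nd.name = f"n{next(counter)}"
            elif not nd.is_leaf:
                next(counter)

    def find(self, name: str) -> Node:
        for nd in self.preorder():
            if nd.name == name or nd.label == name:
                return nd
        raise KeyError(f"no node named {name!r}")

    def copy(self) -> "GeneTree":
        def _clone(nd: Node) -> Node:
            new = Node(
                name=nd.name,
                length=nd.length,
                event=nd.event,
                species=nd.species,
                transcript=nd.transcript,
            )
            for ch in nd.children:
                new.add_child(_clone(ch))
            return new

        return GeneTree(_clone(self.root), name=self.name)


def _split_tip_label(label: str) -> tuple[str | None, str | None]:
    if ":" in label:
        sp, tx = label.split(":", 1)
        return sp, tx
    return None, None


def _from_dendropy(dtree: dendropy.Tree) -> GeneTree:
    def _convert(dnode) -> Node:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        nd = Node(name=label, length=dnode.edge.length or 0.0)
        for ann in dnode.annotations:
            if ann.name == "D":
                nd.event = DUPLICATION if str(ann.value) == "Y" else SPECIATION
        for ch in dnode.child_nodes():
            nd.add_child(_convert(ch))
        if nd.is_leaf and label:
            nd.species, nd.transcript = _split_tip_label(label)
        return nd

    root = _convert(dtree.seed_node)
    root.length = 0.0
    return GeneTree(root)


def read_gene_tree(text: str, allow_polytomies: bool = False) -> GeneTree:
    """Parse a single Newick/NHX tree string into a :class:`GeneTree`.

    NHX ``D=Y`` marks a duplication node, ``D=N`` a speciation node; nodes
    without a tag are left unlabeled for downstream event inference.
    """
    dtree = dendropy.Tree.get(
        data=text,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    tree = _from_dendropy(dtree)
    if not allow_polytomies:
        tree.validate_binary()
    return tree


def _newick_node(nd: Node) -> str:
    def quote(label: str) -> str:
        if any(c in label for c in "()[]{}:;, \t'"):
            if ":" in label and all(c not in label for c in "()[]{}; \t'"):
                # species:transcript tips keep the raw colon inside quotes
                return "'" + label.replace("'", "''") + "'"
            return "'" + label.replace("'", "''") + "'"
        return label

    nhx = ""
    if nd.event is not None:
        nhx = "[&&NHX:D=%s]" % ("Y" if nd.event == DUPLICATION else "N")
    if nd.is_leaf:
        return f"{quote(nd.label)}:{nd.length!r}{nhx}"
    inner = ",".join(_newick_node(ch) for ch in nd.children)
    name = quote(nd.name) if nd.name else ""
    if nd.parent is None:
        return f"({inner}){name}{nhx}"
    return f"({inner}){name}:{nd.length!r}{nhx}"


def write_gene_tree(tree: GeneTree) -> str:
    """Serialize a tree to Newick with NHX ``D=`` duplication flags."""
    return _newick_node(tree.root) + ";"


def label_events_species_overlap(tree: GeneTree) -> GeneTree:
    """Label internal nodes by the species-overlap rule (in place).

    A node is a duplication iff its two child subtrees share at least one
    species; otherwise it is a speciation.  Returns the same tree.
    """
    species_below: dict[int, set[str]] = {}
    for nd in tree.postorder():
        if nd.is_leaf:
            species_below[id(nd)] = {nd.species} if nd.species else set()
        else:
            sets = [species_below[id(ch)] for ch in nd.children]
            species_below[id(nd)] = set().union(*sets)
            overlap = set.intersection(*sets) if sets else set()
            nd.event = DUPLICATION if overlap else SPECIATION
    return tree


def subdivide_at_outgroup(
    tree: GeneTree, outgroup_species: set[str], min_tips: int = 2
) -> list[GeneTree]:
    """Detach and return all maximal subtrees containing no outgroup species.

    A tree with no outgroup tips is returned unchanged (as a single-element
    list).  Subtrees with fewer than ``min_tips`` tips are dropped.  A tree
    that is entirely outgroup yields an empty list.
    """
    ingroup: set[str] = tree.species_set() - set(outgroup_species)
    if not ingroup & tree.species_set() and tree.species_set():
        return []

    has_outgroup: dict[int, bool] = {}
    for nd in tree.postorder():
        if nd.is_leaf:
            has_outgroup[id(nd)] = nd.species in outgroup_species
        else:
            has_outgroup[id(nd)] = any(has_outgroup[id(ch)] for ch in nd.children)

    out: list[GeneTree] = []

    def _collect(nd: Node) -> None:
        if not has_outgroup[id(nd)]:
            sub = GeneTree(nd, name=tree.name)
            if sub.n_tips >= min_tips:
                clone = sub.copy()
                clone.root.parent = None
                clone.root.length = 0.0
                out.append(clone)
            return
        for ch in nd.children:
            _collect(ch)

    _collect(tree.root)
    return out
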