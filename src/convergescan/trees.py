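"""Master species topology, per-element trees, and branch correspondence.

Every analysis in this package runs on a *fixed* rooted species topology
(the master tree).  Individual genetic elements (genes, conserved non-coding
elements, enhancers) each come with their own branch-length tree, estimated
externally on that same topology but possibly missing some taxa.  To compare
branch lengths across elements with unequal taxon sets, each branch of a
pruned element tree is mapped to the *path* of master branches it spans.

Branches are identified by the taxon set of their child clade, which makes
the identification stable under pruning: a pruned element branch with child
clade ``X`` corresponds exactly to the master branches whose child clade,
intersected with the element's taxa, equals ``X``.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy

logger = logging.getLogger(__name__)

__all__ = [
    "TreeBatchError",
    "MasterTree",
    "ElementTree",
    "BranchMapping",
    "Rejection",
    "read_master_tree",
    "read_element_trees",
    "write_element_trees",
    "map_branches",
]


class TreeBatchError(ValueError):
    """Raised for malformed tree input (bad newick, duplicate ids, unknown taxa)."""


@dataclass(frozen=True)
class Rejection:
    """Record of an element dropped during validation or filtering."""

    element_id: str
    rule: str
    detail: str


def _parse_newick(text: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(
        data=text,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    return tree


def _child_clades(tree: dendropy.Tree) -> dict[frozenset, float | None]:
    """Map each non-root edge (keyed by child-clade taxon set) to its length."""
    clades: dict[frozenset, float | None] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        leaves = frozenset(
            lf.taxon.label for lf in node.leaf_iter() if lf.taxon is not None
        )
        if not leaves:
            raise TreeBatchError("node with no labelled leaves")
        if leaves in clades:
            raise TreeBatchError(f"duplicate clade {sorted(leaves)} in tree")
        clades[leaves] = node.edge.length
    return clades


@dataclass
class _Node:
    taxon: str | None
    children: list["_Node"]
    clade: frozenset
    branch_id: str | None = None  # None only for the root


class MasterTree:
    """Fixed rooted binary species topology with canonical branch ids.

    Parameters
    ----------
    newick : str
        Rooted binary newick over the full taxon set.  Branch lengths, if
        present, are stored as ``avg_lengths`` (expected divergence per
        branch, substitutions/site); a topology-only newick leaves them
        unset.

    Attributes
    ----------
    taxa : tuple of str
        Sorted taxon labels.
    branch_ids : tuple of str
        Canonical ordering of the ``2S - 2`` non-root branches.  Terminal
        branches are named by their taxon; internal branches ``anc01`` ...
        in order of increasing clade size.
    avg_lengths : dict or None
        Per-branch expected divergence, if set.
    """

    def __init__(self, newick: str):
        tree = _parse_newick(newick)
        self._root = self._build(tree.seed_node)
        if len(self._root.children) != 2:
            raise TreeBatchError("master tree must be rooted with a bifurcating root")
        self.taxa: tuple[str, ...] = tuple(sorted(self._root.clade))
        if len(self.taxa) != len(self._root.clade):
            raise TreeBatchError("duplicate taxon labels in master tree")
        self._clades: dict[str, frozenset] = {}
        self._assign_ids()
        self.branch_ids: tuple[str, ...] = tuple(
            sorted(
                self._clades,
                key=lambda b: (len(self._clades[b]), tuple(sorted(self._clades[b]))),
            )
        )
        self.avg_lengths: dict[str, float] | None = None
        lengths = _child_clades(tree)
        if all(v is not None for v in lengths.values()):
            by_clade = {c: float(v) for c, v in lengths.items()}
            self.avg_lengths = {b: by_clade[self._clades[b]] for b in self.branch_ids}

    # -- construction -----------------------------------------------------
    def _build(self, dnode) -> _Node:
        kids = dnode.child_nodes()
        if not kids:
            if dnode.taxon is None:
                raise TreeBatchError("unlabelled leaf in master tree")
            label = dnode.taxon.label
            return _Node(taxon=label, children=[], clade=frozenset([label]))
        if len(kids) != 2:
            raise TreeBatchError("master tree must be strictly bifurcating")
        children = [self._build(k) for k in kids]
        clade = frozenset().union(*(c.clade for c in children))
        return _Node(taxon=None, children=children, clade=clade)

    def _assign_ids(self) -> None:
        internal: list[_Node] = []

        def walk(node: _Node, is_root: bool) -> None:
            if not is_root:
                if node.taxon is not None:
                    node.branch_id = node.taxon
                else:
                    internal.append(node)
            for c in node.children:
                walk(c, False)

        walk(self._root, True)
        internal.sort(key=lambda n: (len(n.clade), tuple(sorted(n.clade))))
        for i, node in enumerate(internal, start=1):
            node.branch_id = f"anc{i:02d}"

        def record(node: _Node) -> None:
            if node.branch_id is not None:
                self._clades[node.branch_id] = node.clade
            for c in node.children:
                record(c)

        record(self._root)

    @classmethod
    def from_newick_file(cls, path) -> "MasterTree":
        with open(path) as fh:
            return cls(fh.read())

    # -- queries -----------------------------------------------------------
    def clade_of(self, branch_id: str) -> frozenset:
        return self._clades[branch_id]

    @property
    def terminal_ids(self) -> tuple[str, ...]:
        return tuple(b for b in self.branch_ids if len(self._clades[b]) == 1)

    @property
    def internal_ids(self) -> tuple[str, ...]:
        return tuple(b for b in self.branch_ids if len(self._clades[b]) > 1)

    def with_avg_lengths(self, avg: Mapping[str, float]) -> "MasterTree":
        """Return a copy of this topology carrying the given branch averages."""
        missing = set(self.branch_ids) - set(avg)
        if missing:
            raise ValueError(f"avg lengths missing for branches {sorted(missing)}")
        out = MasterTree(self.to_newick(lengths={b: 0.0 for b in self.branch_ids}))
        out.avg_lengths = {b: float(avg[b]) for b in self.branch_ids}
        return out

    def branch_paths(self, taxa: Iterable[str]) -> dict[frozenset, tuple[str, ...]]:
        """Group master branches into the paths spanned by a pruned tree.

        For a taxon subset ``T``, every branch of the induced (degree-2
        suppressed) tree with child clade ``X`` corresponds to the master
        branches ``b`` with ``clade(b) & T == X``.  Branches ancestral to all
        of ``T`` (``X == T``) lie above the induced root and are unobserved.

        Returns a dict keyed by the element-branch clade ``X``; each value is
        the tuple of master branch ids on the path, ordered deepest first
        (smallest master clade first).
        """
        T = frozenset(taxa)
        unknown = T - set(self.taxa)
        if unknown:
            raise TreeBatchError(f"unknown taxa {sorted(unknown)}")
        groups: dict[frozenset, list[str]] = {}
        for b in self.branch_ids:
            X = self._clades[b] & T
            if not X or X == T:
                continue
            groups.setdefault(X, []).append(b)
        return {
            X: tuple(sorted(members, key=lambda b: len(self._clades[b])))
            for X, members in groups.items()
        }

    # -- rendering ---------------------------------------------------------
    def to_newick(self, lengths: Mapping[str, float] | None = None) -> str:
        """Render the full topology; defaults to ``avg_lengths`` if set."""
        if lengths is None and self.avg_lengths is not None:
            lengths = self.avg_lengths
        by_clade = None
        if lengths is not None:
            by_clade = {self._clades[b]: lengths[b] for b in self.branch_ids}
        return self._render(self._root, self._root.clade, by_clade) + ";"

    def subset_newick(self, taxa: Iterable[str], lengths: Mapping[frozenset, float]) -> str:
        """Render the induced tree over ``taxa`` with element-branch lengths.

        ``lengths`` is keyed by the child-clade taxon set of each induced
        branch (the keys of :meth:`branch_paths`).
        """
        T = frozenset(taxa)
        if len(T) < 2:
            raise ValueError("need at least two taxa to render a tree")
        node = self._root
        while True:
            kids = [c for c in node.children if c.clade & T]
            if len(kids) > 1:
                break
            node = kids[0]
        return self._render(node, T, lengths) + ";"

    def _render(
        self,
        node: _Node,
        taxa: frozenset,
        lengths: Mapping[frozenset, float] | None,
    ) -> str:
        if node.taxon is not None:
            return node.taxon
        parts = []
        for child in node.children:
            X = child.clade & taxa
            if not X:
                continue
            sub = child
            while sub.taxon is None:
                kids = [c for c in sub.children if c.clade & taxa]
                if len(kids) > 1:
                    break
                sub = kids[0]
            text = self._render(sub, taxa, lengths)
            if lengths is not None:
                text += f":{lengths[frozenset(X)]:.10g}"
            parts.append(text)
        return "(" + ",".join(parts) + ")"


@dataclass
class ElementTree:
    """Branch lengths of one genetic element on the induced master topology.

    ``lengths`` is keyed by the child-clade taxon set of each branch of the
    pruned tree; terminal branches therefore have singleton keys.
    """

    element_id: str
    taxa: frozenset
    lengths: dict[frozenset, float]

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def terminal_lengths(self) -> dict[str, float]:
        return {t: self.lengths[frozenset([t])] for t in self.taxa}

    def zero_terminal_fraction(self) -> float:
        term = self.terminal_lengths()
        return sum(1 for v in term.values() if v == 0.0) / len(term)


@dataclass(frozen=True)
class BranchMapping:
    """Master-branch paths spanned by each branch of one element tree."""

    element_id: str
    paths: dict[frozenset, tuple[str, ...]]

    def representative(self, key: frozenset) -> str:
        """The deepest master branch of a path carries the observed value."""
        return self.paths[key][0]


def read_master_tree(path) -> MasterTree:
    return MasterTree.from_newick_file(path)


def _validate_element(
    element_id: str,
    newick: str,
    master: MasterTree,
) -> ElementTree:
    try:
        tree = _parse_newick(newick)
    except Exception as exc:  # dendropy raises assorted error types
        raise TreeBatchError(f"element {element_id!r}: malformed newick ({exc})")
    labels = [lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon is not None]
    taxa = frozenset(labels)
    if len(labels) != len(taxa):
        raise TreeBatchError(f"element {element_id!r}: duplicate taxon labels")
    unknown = taxa - set(master.taxa)
    if unknown:
        raise TreeBatchError(
            f"element {element_id!r}: unknown taxon {sorted(unknown)[0]!r}"
        )
    if len(taxa) < 2:
        raise TreeBatchError(f"element {element_id!r}: fewer than two taxa")
    clades = _child_clades(tree)
    clades.pop(taxa, None)  # a root edge, if written, carries no information
    lengths: dict[frozenset, float] = {}
    for clade, length in clades.items():
        if length is None:
            raise TreeBatchError(
                f"element {element_id!r}: missing branch length on clade "
                f"{sorted(clade)}"
            )
        if length < 0:
            raise TreeBatchError(
                f"element {element_id!r}: negative branch length {length}"
            )
        lengths[clade] = float(length)
    expected = set(master.branch_paths(taxa))
    if set(lengths) != expected:
        raise _TopologyConflict(
            f"induced topology over {len(taxa)} taxa conflicts with master"
        )
    return ElementTree(element_id=element_id, taxa=taxa, lengths=lengths)


class _TopologyConflict(Exception):
    pass


def read_element_trees(
    path, master: MasterTree
) -> tuple[list[ElementTree], list[Rejection]]:
    """Read a ``id<TAB>newick`` batch file, validating against the master.

    Elements whose induced topology conflicts with the master are rejected
    (returned in the rejection log, and logged); malformed lines, duplicate
    ids and unknown taxa raise :class:`TreeBatchError`.
    """
    trees: list[ElementTree] = []
    rejections: list[Rejection] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if "\t" not in line:
                raise TreeBatchError(f"line {lineno}: expected 'id<TAB>newick'")
            element_id, newick = line.split("\t", 1)
            if element_id in seen:
                raise TreeBatchError(
                    f"line {lineno}: duplicate element id {element_id!r}"
                )
            seen.add(element_id)
            try:
                trees.append(_validate_element(element_id, newick, master))
            except _TopologyConflict as exc:
                logger.warning("rejected element %s: %s", element_id, exc)
                rejections.append(Rejection(element_id, "topology_conflict", str(exc)))
            except TreeBatchError as exc:
                raise TreeBatchError(f"line {lineno}: {exc}") from exc
    return trees, rejections


def write_element_trees(trees: Sequence[ElementTree], master: MasterTree, path) -> None:
    """Write elements back to the ``id<TAB>newick`` batch format."""
    with open(path, "w") as fh:
        for tree in trees:
            fh.write(f"{tree.element_id}\t{master.subset_newick(tree.taxa, tree.lengths)}\n")


def map_branches(tree: ElementTree, master: MasterTree) -> BranchMapping:
    """Assign each element branch the master-branch path it spans."""
    return BranchMapping(element_id=tree.element_id, paths=master.branch_paths(tree.taxa))
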