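"""Dated (ultrametric) species trees and per-branch records.

A :class:`DatedTree` wraps a rooted dendropy tree whose branch lengths are in
absolute time (e.g. Ga, 10^9 years before present) and annotates every node
with an *age*: its height above the tips, so larger ages are older and extant
tips sit at age 0. All downstream window logic works on ``[death_age,
birth_age]`` intervals in this age convention, which keeps every comparison
sign-free.

Branches are identified by their child node. A branch id is the pair
``"<alphabetically first descendant tip>:<number of descendant tips>"``;
within one tree this is unique (two distinct clades sharing their minimum tip
are nested, hence differ in size) and it is stable under pruning of other
tips, which makes audit logs comparable across runs.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Mapping

import dendropy

from .errors import InputError, TreeError

__all__ = [
    "DatedTree",
    "BranchRecord",
    "CladeMap",
    "read_dated_tree",
    "prune_tips",
    "branch_records",
    "read_tip_set",
    "read_clade_map",
]

#: label given to tips absent from a partial clade map
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class BranchRecord:
    """One tree edge, as a time interval with a clade annotation.

    ``birth_age`` is the age of the parent node, ``death_age`` the age of the
    child node (0 for extant tips); ``birth_age > death_age >= 0`` always.
    ``in_domain`` flags membership in the eligible donor domain (e.g.
    Bacteria): true iff every descendant tip belongs to the domain tip set.
    """

    branch_id: str
    birth_age: float
    death_age: float
    clade_label: str
    in_domain: bool

    def __post_init__(self) -> None:
        if not self.birth_age > self.death_age >= 0.0:
            raise ValueError(
                f"branch {self.branch_id}: require birth_age > death_age >= 0, "
                f"got ({self.birth_age}, {self.death_age})"
            )

    @property
    def duration(self) -> float:
        return self.birth_age - self.death_age


class CladeMap:
    """Tip→clade-label assignments plus an optional donor-domain tip set.

    The map may be partial; unmapped tips get the label ``"unassigned"``.
    An empty domain set means no tip is in the donor domain.
    """

    def __init__(
        self,
        labels: Mapping[str, str] | None = None,
        domain_tips: Iterable[str] | None = None,
    ) -> None:
        self.labels = dict(labels or {})
        for tip, lab in self.labels.items():
            if not lab:
                raise InputError(f"empty clade label for tip {tip!r}")
        self.domain_tips = frozenset(domain_tips or ())

    def label_of(self, tip: str) -> str:
        return self.labels.get(tip, UNASSIGNED)

    def validate_against(self, tree: "DatedTree") -> None:
        tips = set(tree.tip_names)
        missing = sorted(set(self.labels) - tips)
        if missing:
            raise InputError(f"clade map names unknown tips: {missing[:5]}")
        missing = sorted(self.domain_tips - tips)
        if missing:
            raise InputError(f"domain tip set names unknown tips: {missing[:5]}")


class DatedTree:
    """Rooted ultrametric tree with node ages in time before present."""

    def __init__(self, dtree: dendropy.Tree, ultrametric_tol: float = 1e-6):
        self._tree = dtree
        self._tol = ultrametric_tol
        self._annotate_ages()

    # -- construction helpers -------------------------------------------------

    def _annotate_ages(self) -> None:
        """Compute node ages as height above tips and validate ultrametricity."""
        root = self._tree.seed_node
        root.depth = 0.0
        for node in self._tree.preorder_node_iter():
            if node is root:
                continue
            if node.edge.length is None:
                name = node.taxon.label if node.taxon else "<internal>"
                raise TreeError(f"missing branch length on edge above {name!r}")
            if node.edge.length < 0:
                raise TreeError("negative branch length in input tree")
            node.depth = node.parent_node.depth + node.edge.length

        leaves = self._tree.leaf_node_iter()
        depths = {lf: lf.depth for lf in leaves}
        if len(depths) < 2:
            raise TreeError("tree must have at least 2 tips")
        root_age = max(depths.values())
        if root_age <= 0:
            raise TreeError("tree has zero depth (all branch lengths 0)")
        worst = max(depths, key=lambda lf: abs(depths[lf] - root_age))
        dev = abs(depths[worst] - root_age)
        if dev > self._tol * root_age:
            raise TreeError(
                f"tree is not ultrametric within relative tolerance {self._tol:g}: "
                f"tip {worst.taxon.label!r} deviates by {dev:g} "
                f"from root age {root_age:g}"
            )
        for node in self._tree.preorder_node_iter():
            node.age = 0.0 if node.is_leaf() else root_age - node.depth
        names = [lf.taxon.label for lf in self._tree.leaf_node_iter()]
        if len(names) != len(set(names)):
            raise TreeError("duplicate tip names in input tree")
        # branch ids: (min descendant tip, clade size)
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                node.min_tip, node.n_tips = node.taxon.label, 1
            else:
                node.min_tip = min(c.min_tip for c in node.child_nodes())
                node.n_tips = sum(c.n_tips for c in node.child_nodes())

    # -- basic accessors ------------------------------------------------------

    @property
    def root_age(self) -> float:
        return self._tree.seed_node.age

    @property
    def tip_names(self) -> list[str]:
        return [lf.taxon.label for lf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    def node_ages(self) -> dict[str, float]:
        """Map branch id → age of the branch's child node (root included as 'root')."""
        out = {"root": self.root_age}
        for node in self._tree.preorder_node_iter():
            if node is not self._tree.seed_node:
                out[_branch_id(node)] = node.age
        return out

    def mrca_age(self, tips: Iterable[str]) -> float:
        """Age of the most recent common ancestor of the given tips."""
        tips = list(tips)
        unknown = sorted(set(tips) - set(self.tip_names))
        if unknown:
            raise InputError(f"tips not found in tree: {unknown[:5]}")
        if len(tips) == 1:
            return 0.0
        node = self._tree.mrca(taxon_labels=tips)
        if node is None:  # pragma: no cover - dendropy returns root at worst
            raise InputError("MRCA lookup failed")
        return node.age

    def to_newick(self) -> str:
        # full precision so parse -> write -> parse preserves node ages
        return self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            real_value_format_specifier=".17g",
        ).strip()

    def __repr__(self) -> str:
        return f"<DatedTree n_tips={self.n_tips} root_age={self.root_age:g}>"


def _branch_id(node) -> str:
    return f"{node.min_tip}:{node.n_tips}"


def read_dated_tree(newick_text: str, ultrametric_tol: float = 1e-6) -> DatedTree:
    """Parse a rooted Newick string with branch lengths into a :class:`DatedTree`.

    Node ages are computed as height above the tips (root age = maximum
    root-to-tip path length); ultrametricity is enforced within
    ``ultrametric_tol`` relative to the root age, and tip ages are snapped to
    exactly 0 afterwards so strict age inequalities hold downstream.
    """
    try:
        dtree = dendropy.Tree.get(
            data=newick_text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise TreeError(f"cannot parse Newick input: {exc}") from exc
    if dtree.seed_node is None or dtree.seed_node.is_leaf():
        raise TreeError("input tree is empty or trivial")
    dtree.is_rooted = True  # required: MRCA queries are age lookups on a rooted tree
    return DatedTree(dtree, ultrametric_tol=ultrametric_tol)


def prune_tips(tree: DatedTree, drop: Iterable[str]) -> DatedTree:
    """Return a copy of *tree* without the tips in *drop*.

    Unary nodes left behind are suppressed by summing edge durations, so the
    ages of all surviving nodes are unchanged. Used to remove organellar
    clades (chloroplast/mitochondrial tips) before building the donor space.
    """
    drop = set(drop)
    if not drop:
        return read_dated_tree(tree.to_newick(), ultrametric_tol=tree._tol)
    unknown = sorted(drop - set(tree.tip_names))
    if unknown:
        raise InputError(f"cannot prune non-existent tips: {unknown[:5]}")
    keep = [t for t in tree.tip_names if t not in drop]
    if len(keep) < 2:
        raise InputError("pruning would leave fewer than 2 tips")
    clone = dendropy.Tree.get(
        data=tree.to_newick(),
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    clone.is_rooted = True
    clone.retain_taxa_with_labels(keep)
    clone.purge_taxon_namespace()
    return DatedTree(clone, ultrametric_tol=tree._tol)


def branch_records(tree: DatedTree, clades: CladeMap | None = None) -> list[BranchRecord]:
    """One :class:`BranchRecord` per edge of *tree* (the root has none).

    The clade label of a branch is the label shared by all its descendant
    tips if unique; otherwise the distinct descendant labels, sorted and
    joined with ``"+"`` — a mechanical placeholder for the ancestor of
    several named clades. ``in_domain`` is true iff every descendant tip is
    in the clade map's domain tip set.
    """
    clades = clades or CladeMap()
    clades.validate_against(tree)
    records: list[BranchRecord] = []
    root = tree._tree.seed_node
    for node in tree._tree.postorder_node_iter():
        if node.is_leaf():
            node.tip_labels = {clades.label_of(node.taxon.label)}
            node.all_in_domain = node.taxon.label in clades.domain_tips
        else:
            node.tip_labels = set().union(*(c.tip_labels for c in node.child_nodes()))
            node.all_in_domain = all(c.all_in_domain for c in node.child_nodes())
        if node is root:
            continue
        label = "+".join(sorted(node.tip_labels))
        records.append(
            BranchRecord(
                branch_id=_branch_id(node),
                birth_age=node.parent_node.age,
                death_age=node.age,
                clade_label=label,
                in_domain=node.all_in_domain,
            )
        )
    records.sort(key=lambda r: r.branch_id)
    return records


# -- plain-text input formats -------------------------------------------------


def read_tip_set(path_or_text: str, *, is_path: bool = True) -> set[str]:
    """Read a tip set: one name per line, blank lines and '#' comments skipped."""
    if is_path:
        try:
            with open(path_or_text) as fh:
                text = fh.read()
        except OSError as exc:
            raise InputError(f"cannot read tip set {path_or_text!r}: {exc}") from exc
    else:
        text = path_or_text
    tips = set()
    for line in io.StringIO(text):
        line = line.split("#", 1)[0].strip()
        if line:
            tips.add(line)
    return tips


def read_clade_map(path: str, domain_tips: Iterable[str] | None = None) -> CladeMap:
    """Read a 2-column TSV ``tip<TAB>label`` into a :class:`CladeMap`."""
    labels: dict[str, str] = {}
    try:
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2 or not parts[0] or not parts[1]:
                    raise InputError(f"{path}:{ln}: expected 'tip<TAB>label', got {line!r}")
                labels[parts[0]] = parts[1]
    except OSError as exc:
        raise InputError(f"cannot read clade map {path!r}: {exc}") from exc
    return CladeMap(labels, domain_tips)
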