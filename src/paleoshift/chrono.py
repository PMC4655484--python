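"""Reading and time-calibrating fossil phylogenies.

Conventions
-----------
All ages are in Ma before present; larger numbers are older.  A calibrated
tree stores one ``age`` per node: internal-node ages are cladogenesis times,
tip ages are the taxon's last appearance (LAD).  The branch subtending a node
therefore runs from its parent's age (origin) down to the node's own age
(end).  The portion of a tip branch older than the taxon's first appearance
(FAD) is its ghost lineage.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

__all__ = [
    "DatedTaxon",
    "TimeScaleBin",
    "TimeScale",
    "CalibratedTree",
    "read_taxon_ranges",
    "read_tree",
    "resolve_polytomies",
    "calibrate",
]


class RangeTableError(ValueError):
    """Raised for malformed stratigraphic-range tables."""


@dataclass(frozen=True)
class DatedTaxon:
    """A taxon with an observed stratigraphic range [fad, lad] in Ma."""

    name: str
    fad: float
    lad: float

    def __post_init__(self):
        if not (self.fad >= self.lad >= 0):
            raise ValueError(
                f"taxon {self.name!r}: require fad >= lad >= 0, "
                f"got fad={self.fad}, lad={self.lad}"
            )


@dataclass(frozen=True)
class TimeScaleBin:
    label: str
    old_bound: float
    young_bound: float

    def __post_init__(self):
        if not self.old_bound > self.young_bound:
            raise ValueError(
                f"bin {self.label!r}: old_bound must exceed young_bound "
                f"({self.old_bound} vs {self.young_bound})"
            )

    @property
    def duration(self) -> float:
        return self.old_bound - self.young_bound


class TimeScale:
    """An ordered, contiguous sequence of time bins, oldest first.

    Point events at a shared bin boundary belong to the *older* bin: a bin
    contains ages ``young_bound <= a < old_bound``, except the oldest bin,
    which is closed at its old bound.  Presence of a lineage in a bin always
    means positive-duration overlap, which is insensitive to this rule.
    """

    def __init__(self, bins: Sequence[TimeScaleBin]):
        bins = list(bins)
        if not bins:
            raise ValueError("timescale needs at least one bin")
        for a, b in zip(bins, bins[1:]):
            if a.young_bound != b.old_bound:
                raise ValueError(
                    f"bins {a.label!r} and {b.label!r} are not contiguous "
                    f"({a.young_bound} != {b.old_bound})"
                )
        self.bins = bins

    def __len__(self):
        return len(self.bins)

    def __iter__(self):
        return iter(self.bins)

    def __getitem__(self, i):
        return self.bins[i]

    @property
    def old_edge(self) -> float:
        return self.bins[0].old_bound

    @property
    def young_edge(self) -> float:
        return self.bins[-1].young_bound

    def bin_of(self, age: float) -> int | None:
        """Index of the bin containing a point event at ``age``.

        Boundary events go to the older bin; the window's outer edges fall in
        the oldest and youngest bins respectively.  Returns None outside the
        window.
        """
        if age > self.old_edge or age < self.young_edge:
            return None
        for i, b in enumerate(self.bins):
            if b.young_bound <= age < b.old_bound:
                return i
        return 0 if age == self.old_edge else None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_label": [b.label for b in self.bins],
                "old_bound": [b.old_bound for b in self.bins],
                "young_bound": [b.young_bound for b in self.bins],
            }
        )


class CalibratedTree:
    """A rooted binary tree with node ages and tip stratigraphic ranges.

    Wraps a :class:`dendropy.Tree` whose every node carries an ``age``
    attribute (Ma).  Tip ages equal their taxon's LAD.
    """

    def __init__(self, tree: dendropy.Tree, ranges: Mapping[str, DatedTaxon]):
        self.tree = tree
        self.ranges = dict(ranges)
        self._validate()

    def _validate(self):
        for node in self.tree.preorder_node_iter():
            if not hasattr(node, "age"):
                raise ValueError("every node of a CalibratedTree needs an age")
            if node.age < 0:
                raise ValueError("negative node age")
            if node.parent_node is not None and node.parent_node.age < node.age:
                raise ValueError(
                    f"age monotonicity violated: parent {node.parent_node.age} "
                    f"< child {node.age}"
                )
        for leaf in self.tree.leaf_node_iter():
            name = leaf.taxon.label
            if name not in self.ranges:
                raise ValueError(f"tip {name!r} lacks a stratigraphic range")

    # -- convenience ----------------------------------------------------
    @property
    def root_age(self) -> float:
        return self.tree.seed_node.age

    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def tip_labels(self) -> list[str]:
        return [l.taxon.label for l in self.tree.leaf_node_iter()]

    def branch_origin(self, node) -> float:
        """Origin age of the branch subtending ``node`` (root: its own age)."""
        return node.parent_node.age if node.parent_node is not None else node.age

    def ghost_length(self, leaf) -> float:
        """Ghost-lineage duration of a tip: branch origin minus FAD."""
        return self.branch_origin(leaf) - self.ranges[leaf.taxon.label].fad

    def clone(self) -> "CalibratedTree":
        t = self.tree.clone(depth=1)
        # dendropy shallow clone copies nodes; re-attach ages explicitly
        for src, dst in zip(
            self.tree.preorder_node_iter(), t.preorder_node_iter()
        ):
            dst.age = src.age
        return CalibratedTree(t, self.ranges)


# ---------------------------------------------------------------------------
# readers


def read_taxon_ranges(path) -> dict[str, DatedTaxon]:
    """Read a taxon/fad/lad table (comma- or tab-delimited) into DatedTaxa."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"taxon", "fad", "lad"}
    missing = required - set(df.columns)
    if missing:
        raise RangeTableError(f"missing column(s): {sorted(missing)}")
    out: dict[str, DatedTaxon] = {}
    for i, row in df.iterrows():
        name = str(row["taxon"])
        try:
            fad = float(row["fad"])
            lad = float(row["lad"])
        except (TypeError, ValueError) as exc:
            raise RangeTableError(f"row {i} ({name!r}): non-numeric age") from exc
        if pd.isna(fad) or pd.isna(lad):
            raise RangeTableError(f"row {i} ({name!r}): non-numeric age")
        if fad < lad:
            raise RangeTableError(f"row {i} ({name!r}): fad {fad} < lad {lad}")
        if name in out:
            raise RangeTableError(f"row {i}: duplicate taxon {name!r}")
        out[name] = DatedTaxon(name, fad, lad)
    return out


def read_tree(source, schema: str = "newick") -> dendropy.Tree:
    """Read a rooted tree; polytomies are permitted at this stage."""
    from dendropy.dataio.newickreader import NewickReader

    try:
        if isinstance(source, str) and ("(" in source and ";" in source):
            tree = dendropy.Tree.get(data=source, schema=schema)
        else:
            tree = dendropy.Tree.get(path=str(source), schema=schema)
    except NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValueError(f"duplicate tip labels: {exc}") from exc
    tree.is_rooted = True
    labels = [l.taxon.label for l in tree.leaf_node_iter() if l.taxon is not None]
    if len(labels) != len(set(labels)):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ValueError(f"duplicate tip labels: {dupes}")
    if any(l.taxon is None for l in tree.leaf_node_iter()):
        raise ValueError("unlabeled tip in input tree")
    return tree


# ---------------------------------------------------------------------------
# polytomy resolution


def _resolve_node(node, rng: random.Random):
    """Replace one polytomy by a uniformly drawn rooted binary refinement.

    Children are re-attached by random-edge insertion: the i-th subtree is
    grafted onto one of the 2i-3 edges (root edge included) of the partial
    local tree, which yields the uniform distribution over rooted labeled
    shapes.
    """
    children = list(node.child_nodes())
    if len(children) <= 2:
        return
    for c in children:
        node.remove_child(c)
    order = children[:]
    rng.shuffle(order)
    # local root joining the first two subtrees
    local_root = dendropy.Node()
    local_root.add_child(order[0])
    local_root.add_child(order[1])
    # nodes whose parent edge (incl. the edge above local_root) may be split
    attachable = [order[0], order[1], local_root]
    for sub in order[2:]:
        target = rng.choice(attachable)
        joint = dendropy.Node()
        parent = target.parent_node
        if parent is None:  # insert above the local root
            joint.add_child(target)
            joint.add_child(sub)
            local_root = joint
        else:
            parent.remove_child(target)
            joint.add_child(target)
            joint.add_child(sub)
            parent.add_child(joint)
        attachable.extend([sub, joint])
    # graft the binary local tree back in place of the polytomy
    for c in list(local_root.child_nodes()):
        local_root.remove_child(c)
        node.add_child(c)


def resolve_polytomies(
    tree: dendropy.Tree, n_replicates: int, seed: int
) -> list[dendropy.Tree]:
    """Return ``n_replicates`` fully binary refinements of ``tree``.

    Each polytomy is refined uniformly at random over rooted labeled shapes;
    a binary input yields identical copies.  Reproducible from ``seed``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = random.Random(seed)
    out = []
    for _ in range(n_replicates):
        t = dendropy.Tree(tree)  # deep copy sharing the taxon namespace
        t.is_rooted = True
        for node in list(t.preorder_internal_node_iter()):
            _resolve_node(node, rng)
        out.append(t)
    return out


# ---------------------------------------------------------------------------
# calibration


def calibrate(
    tree: dendropy.Tree,
    ranges: Mapping[str, DatedTaxon],
    min_branch: float = 1.0,
) -> CalibratedTree:
    """Time-calibrate a binary topology from tip stratigraphic ranges.

    Each internal node's base age is the maximum FAD among its descendant
    tips.  Internal branches shorter than ``min_branch`` are then expanded by
    shifting ancestors older (nodes are never moved younger than their base
    age).  Tip branches end at the taxon's LAD and are exempt from the
    minimum-duration rule, since a tip's LAD is data, not a free parameter.
    """
    if min_branch < 0:
        raise ValueError("min_branch must be >= 0")
    t = dendropy.Tree(tree)
    t.is_rooted = True
    for node in t.postorder_node_iter():
        kids = node.child_nodes()
        if len(kids) not in (0, 2):
            raise ValueError("calibrate requires a fully binary tree")
        if node.is_leaf():
            name = node.taxon.label if node.taxon else None
            if name not in ranges:
                raise ValueError(f"tip {name!r} lacks a stratigraphic range")
            taxon = ranges[name]
            node.age = taxon.lad
            node.max_fad = taxon.fad
        else:
            node.max_fad = max(k.max_fad for k in kids)
            age = node.max_fad
            for k in kids:
                if not k.is_leaf():
                    age = max(age, k.age + min_branch)
            node.age = age
    for node in t.preorder_node_iter():
        del node.max_fad
    used = {l.taxon.label: ranges[l.taxon.label] for l in t.leaf_node_iter()}
    return CalibratedTree(t, used)
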