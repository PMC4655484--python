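"""Time slicing: substage bins, per-bin tree pruning, mean-delta2 series.

Tree-shape shift statistics assume all descendants of a node have had equal
time to diversify; slicing the calibrated tree into short bins and scoring
each slice separately restores that assumption approximately.  A tip belongs
to a slice if its lineage — from branch origin down to last appearance,
ghost portion included — overlaps the bin with positive duration.
"""

from __future__ import annotations

import dendropy
import numpy as np
import pandas as pd

from .chrono import CalibratedTree, TimeScale, TimeScaleBin
from .shiftstat import NullCache, delta_statistics, shift_pvalues

__all__ = [
    "read_stage_table",
    "make_substage_bins",
    "slice_tree",
    "delta2_series",
]


def read_stage_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python")
    missing = {"name", "old_bound", "young_bound"} - set(df.columns)
    if missing:
        raise ValueError(f"stage table missing column(s): {sorted(missing)}")
    return df


def make_substage_bins(stages) -> TimeScale:
    """Split each stage into early/late halves at its temporal midpoint.

    ``stages`` is a DataFrame (name, old_bound, young_bound) or an iterable
    of such triples, ordered old to young and contiguous.
    """
    if isinstance(stages, pd.DataFrame):
        rows = [
            (str(r["name"]), float(r["old_bound"]), float(r["young_bound"]))
            for _, r in stages.iterrows()
        ]
    else:
        rows = [(str(a), float(b), float(c)) for a, b, c in stages]
    bins = []
    for name, old, young in rows:
        if old <= young:
            raise ValueError(f"stage {name!r} has non-positive duration")
        mid = 0.5 * (old + young)
        bins.append(TimeScaleBin(f"{name}-early", old, mid))
        bins.append(TimeScaleBin(f"{name}-late", mid, young))
    return TimeScale(bins)  # contiguity of input checked here too


def _overlap(old_a, young_a, old_b, young_b) -> float:
    return min(old_a, old_b) - max(young_a, young_b)


def slice_tree(ctree: CalibratedTree, bin: TimeScaleBin) -> CalibratedTree | None:
    """Prune to tips whose lineage interval crosses ``bin`` with positive duration.

    The lineage interval of a tip runs from its branch origin (parent node
    age; ghost lineage included) down to its LAD.  Internal nodes left with a
    single child are suppressed; node ages are unchanged.  Returns ``None``
    when no tip crosses the bin.
    """
    keep = set()
    for leaf in ctree.tree.leaf_node_iter():
        origin = ctree.branch_origin(leaf)
        lad = ctree.ranges[leaf.taxon.label].lad
        if _overlap(origin, lad, bin.old_bound, bin.young_bound) > 0:
            keep.add(leaf.taxon.label)
    if not keep:
        return None

    ns = dendropy.TaxonNamespace()

    def prune(node):
        if node.is_leaf():
            if node.taxon.label in keep:
                new = dendropy.Node()
                new.taxon = ns.new_taxon(label=node.taxon.label)
                new.age = node.age
                return new
            return None
        kids = [k for k in (prune(c) for c in node.child_nodes()) if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        new = dendropy.Node()
        new.age = node.age
        for k in kids:
            new.add_child(k)
        return new

    root = prune(ctree.tree.seed_node)
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = root
    tree.is_rooted = True
    ranges = {name: ctree.ranges[name] for name in keep}
    return CalibratedTree(tree, ranges)


def delta2_series(
    ctree: CalibratedTree,
    timescale: TimeScale,
    n_sims: int = 10_000,
    rng: np.random.Generator | None = None,
    null_cache: NullCache | None = None,
    detected_only: bool = False,
) -> pd.DataFrame:
    """Mean delta2 and shift counts per time bin from sliced analyses.

    By default the mean is over *all* scored nodes of each slice, so the
    series reflects magnitude and number of shifts jointly; with
    ``detected_only`` it averages only significant/substantial nodes.
    Bins whose slice has fewer than 3 tips contribute zeros.
    """
    if null_cache is None:
        if rng is None:
            raise ValueError("provide rng or null_cache")
        null_cache = NullCache(n_sims, rng)
    rows = []
    for b in timescale:
        sliced = slice_tree(ctree, b)
        mean_d2, n_sig, n_sub = 0.0, 0, 0
        if sliced is not None and sliced.n_tips() >= 3:
            results = shift_pvalues(sliced.tree, n_sims, null_cache=null_cache)
            n_sig = sum(r.klass == "significant" for r in results)
            n_sub = sum(r.klass == "substantial" for r in results)
            pool = [r for r in results if r.klass != "none"] if detected_only else results
            if pool:
                mean_d2 = float(np.mean([r.delta2 for r in pool]))
        rows.append(
            {
                "bin_label": b.label,
                "old_bound": b.old_bound,
                "young_bound": b.young_bound,
                "mean_delta2": mean_d2,
                "n_significant": n_sig,
                "n_substantial": n_sub,
            }
        )
    return pd.DataFrame(rows)
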