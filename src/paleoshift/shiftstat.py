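"""Tree-imbalance diversification-shift statistics under the ERM null.

Under the equal-rates Markov (ERM) model every extant lineage is equally
likely to split next, so the two daughter clade sizes (l, n-l) of an n-tip
clade follow the uniform split law: each *ordered* split has probability
1/(n-1).  The nodal "surprise" S of a split is the negative log of the
probability of a split at least as asymmetric as the one observed.  For the
larger child c of an internal node i we score

    delta1(c) = S(i)
    delta2(c) = max(0, S(i) - S(c))

so that delta2 discounts parent-level imbalance already explained by
imbalance at c itself.  Significance is assessed by Monte-Carlo simulation
of the statistic under ERM at the parent clade's size.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "erm_split_probability",
    "erm_tail_probability",
    "nodal_surprise",
    "delta_statistics",
    "simulate_erm_topology",
    "sample_null_delta2",
    "NullCache",
    "shift_pvalues",
    "consensus_shifts",
    "results_table",
    "ShiftResult",
]

ALPHA_SIGNIFICANT = 0.05
ALPHA_SUBSTANTIAL = 0.10


@dataclass(frozen=True)
class ShiftResult:
    """Shift score at the larger child of one internal node.

    ``clade`` is the tip-label set subtended by the scored node (the larger
    child), which identifies it across replicate trees; ``n`` is the parent
    clade's tip count, ``l``/``r`` the larger/smaller daughter sizes.
    """

    clade: frozenset
    n: int
    l: int
    r: int
    delta1: float
    delta2: float
    p_value: float | None = None
    klass: str = "none"


def _classify(p: float) -> str:
    # p exactly 0.05 is classed substantial (the open boundary case)
    if p < ALPHA_SIGNIFICANT:
        return "significant"
    if p < ALPHA_SUBSTANTIAL:
        return "substantial"
    return "none"


# ---------------------------------------------------------------------------
# ERM split law


def erm_split_probability(l: int, r: int) -> float:
    """Probability of the unordered split (l, r) of an n = l + r clade."""
    if l < 1 or r < 1:
        raise ValueError("both sides of a split must have >= 1 tip")
    n = l + r
    if n == 2:
        return 1.0
    return (1.0 if l == r else 2.0) / (n - 1)


def erm_tail_probability(l: int, r: int) -> float:
    """Probability of a split at least as asymmetric as (l, r), l >= r."""
    if r < 1:
        raise ValueError("both sides of a split must have >= 1 tip")
    if l < r:
        raise ValueError("require l >= r")
    n = l + r
    if n == 2:
        return 1.0
    return min(1.0, 2.0 * (n - l) / (n - 1))


def nodal_surprise(l: int, r: int) -> float:
    """S = -ln of the ERM tail probability of the split (l, r), l >= r."""
    return 0.0 - math.log(erm_tail_probability(l, r))


def _surprise_vec(n, l):
    """Vectorized surprise for larger-side count l of clade size n."""
    n = np.asarray(n, dtype=float)
    l = np.asarray(l, dtype=float)
    tail = np.minimum(1.0, 2.0 * (n - l) / np.maximum(n - 1.0, 1.0))
    return -np.log(tail)


# ---------------------------------------------------------------------------
# observed statistics


def _tip_counts(tree: dendropy.Tree) -> dict:
    counts = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            counts[node] = 1
        else:
            counts[node] = sum(counts[k] for k in node.child_nodes())
    return counts


def _clade_labels(node) -> frozenset:
    return frozenset(l.taxon.label for l in node.leaf_iter())


def delta_statistics(tree: dendropy.Tree) -> list[ShiftResult]:
    """Score delta1/delta2 at the larger child of every internal node.

    Nodes subtending fewer than 3 tips carry no information under ERM (the
    split of 2 is forced) and are skipped.  Ties in daughter size are
    maximally balanced splits (S = 0); the first child is scored.
    """
    counts = _tip_counts(tree)
    results = []
    for node in tree.preorder_internal_node_iter():
        kids = node.child_nodes()
        if len(kids) != 2:
            raise ValueError("delta_statistics requires a binary tree")
        n = counts[node]
        if n < 3:
            continue
        a, b = kids
        big = a if counts[a] >= counts[b] else b
        l, r = counts[big], n - counts[big]
        s_parent = nodal_surprise(l, r)
        if counts[big] >= 3:
            ka, kb = big.child_nodes()
            lc = max(counts[ka], counts[kb])
            s_child = nodal_surprise(lc, counts[big] - lc)
        else:
            s_child = 0.0  # cherries are the forced split of 2
        results.append(
            ShiftResult(
                clade=_clade_labels(big),
                n=n,
                l=l,
                r=r,
                delta1=s_parent,
                delta2=max(0.0, s_parent - s_child),
            )
        )
    return results


# ---------------------------------------------------------------------------
# ERM simulation


def simulate_erm_topology(
    n: int, rng: np.random.Generator, label_prefix: str = "t"
) -> dendropy.Tree:
    """Simulate an n-tip topology by uniform random lineage splitting."""
    if n < 2:
        raise ValueError("need n >= 2 tips")
    tree = dendropy.Tree()
    tree.is_rooted = True
    root = tree.seed_node
    leaves = [root]
    for _ in range(n - 1):
        idx = int(rng.integers(0, len(leaves)))
        node = leaves[idx]
        c1, c2 = dendropy.Node(), dendropy.Node()
        node.add_child(c1)
        node.add_child(c2)
        leaves[idx] = c1
        leaves.append(c2)
    ns = tree.taxon_namespace
    for i, leaf in enumerate(leaves, 1):
        leaf.taxon = ns.new_taxon(label=f"{label_prefix}{i}")
    return tree


def sample_null_delta2(n: int, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw the ERM null of delta2 at the larger root child of n-tip trees.

    Under ERM the subtree of a clade of known size is itself ERM, so the
    statistic depends only on the root split (l, n-l) and the larger child's
    own split: both are drawn from the uniform ordered split law.  This is
    distributionally identical to scoring full simulated topologies and is
    O(1) per draw.
    """
    if n < 3:
        raise ValueError("delta2 is undefined for clades of fewer than 3 tips")
    k = rng.integers(1, n, size)
    l = np.maximum(k, n - k)
    j = rng.integers(1, l)  # l >= 2 always for n >= 3
    l2 = np.maximum(j, l - j)
    return np.maximum(0.0, _surprise_vec(n, l) - _surprise_vec(l, l2))


class NullCache:
    """Reusable per-clade-size cache of ERM null delta2 samples.

    Sharing one null sample across nodes of equal parent-clade size is
    statistically equivalent for each individual p-value and makes repeated
    whole-tree and time-sliced analyses cheap.
    """

    def __init__(self, n_sims: int, rng: np.random.Generator):
        self.n_sims = n_sims
        self.rng = rng
        self._store: dict[int, np.ndarray] = {}

    def get(self, n: int) -> np.ndarray:
        if n not in self._store:
            self._store[n] = np.sort(sample_null_delta2(n, self.n_sims, self.rng))
        return self._store[n]


def _benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adj[i] = running
    return adj


def shift_pvalues(
    tree: dendropy.Tree,
    n_sims: int = 10_000,
    rng: np.random.Generator | None = None,
    null_cache: NullCache | None = None,
    correction: str | None = None,
) -> list[ShiftResult]:
    """Monte-Carlo p-values for delta2 at every scored node of ``tree``.

    For a scored node with parent clade size n_i the null is ``n_sims``
    draws of the statistic on ERM trees of n_i tips; ties count toward the
    tail, so p = (1 + #{null >= obs}) / (n_sims + 1) is never zero.
    ``correction="bh"`` applies Benjamini-Hochberg before classification
    (the default applies none).
    """
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100")
    if null_cache is None:
        if rng is None:
            raise ValueError("provide rng or null_cache")
        null_cache = NullCache(n_sims, rng)
    scored = delta_statistics(tree)
    out = []
    for res in scored:
        null = null_cache.get(res.n)
        m = len(null)
        n_ge = m - np.searchsorted(null, res.delta2, side="left")
        p = (1.0 + n_ge) / (m + 1.0)
        out.append(replace(res, p_value=p))
    if correction == "bh" and out:
        adj = _benjamini_hochberg(np.array([r.p_value for r in out]))
        out = [replace(r, p_value=float(q)) for r, q in zip(out, adj)]
    elif correction not in (None, "bh"):
        raise ValueError(f"unknown correction {correction!r}")
    return [replace(r, klass=_classify(r.p_value)) for r in out]


# ---------------------------------------------------------------------------
# consensus across polytomy-resolution replicates


def consensus_shifts(
    replicate_results: Sequence[Iterable[ShiftResult]],
    tip_sets: Sequence[frozenset] | None = None,
) -> list[ShiftResult]:
    """Retain shifts detected (significant or substantial) in every replicate.

    Clades are matched by their subtended tip-label set; retained delta2 and
    p are across-replicate means, and the class is re-derived from the mean
    p.  Pass the replicates' full tip sets via ``tip_sets`` to enforce that
    all replicates analyse the same taxa (scored clades alone cannot verify
    this, since which nodes are scored depends on the resolution).
    """
    reps = [list(r) for r in replicate_results]
    if not reps:
        raise ValueError("need at least one replicate")
    if tip_sets is not None:
        if len(tip_sets) != len(reps):
            raise ValueError("one tip set per replicate required")
        if len({frozenset(t) for t in tip_sets}) > 1:
            raise ValueError("replicates analyse different tip sets")
    detected = [
        {r.clade: r for r in rep if r.klass != "none"} for rep in reps
    ]
    common = set(detected[0])
    for d in detected[1:]:
        common &= set(d)
    out = []
    for clade in sorted(common, key=sorted):
        hits = [d[clade] for d in detected]
        mean_p = float(np.mean([h.p_value for h in hits]))
        out.append(
            ShiftResult(
                clade=clade,
                n=hits[0].n,
                l=hits[0].l,
                r=hits[0].r,
                delta1=float(np.mean([h.delta1 for h in hits])),
                delta2=float(np.mean([h.delta2 for h in hits])),
                p_value=mean_p,
                klass=_classify(mean_p),
            )
        )
    return out


def results_table(results: Iterable[ShiftResult]) -> pd.DataFrame:
    """Tabulate shift results, identifying clades by a stable tip-set hash."""
    rows = []
    for r in results:
        key = ";".join(sorted(r.clade))
        digest = hashlib.md5(key.encode()).hexdigest()[:8]
        rows.append(
            {
                "clade_tips_hash": digest,
                "clade_tips": key,
                "n": r.n,
                "l": r.l,
                "r": r.r,
                "delta1": r.delta1,
                "delta2": r.delta2,
                "p_value": r.p_value,
                "klass": r.klass,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "clade_tips_hash", "clade_tips", "n", "l", "r",
            "delta1", "delta2", "p_value", "klass",
        ],
    )
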