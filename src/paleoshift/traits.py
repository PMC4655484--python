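"""Two-state Mk ancestral-state inference and trait-group rate series.

Binary ecological codings (0 = absent, 1 = present) evolve along the
calibrated tree as a continuous-time Markov chain with rates q01, q10 per
Ma; branch lengths are durations from the calibrated tree.  Tip-state
likelihoods use Felsenstein pruning; marginal ancestral probabilities come
from the standard up-down (rerooting-equivalent) pass at the ML rates.
Lineages "descended from" a trait-positive ancestor form a hereditary group
whose per-lineage origination rates can be compared with the complement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar

from .chrono import CalibratedTree, TimeScale
from .paleorates import _present, lineage_intervals

__all__ = [
    "read_trait_table",
    "mk_transition_matrix",
    "mk_loglik",
    "fit_mk",
    "AncestralStates",
    "group_lineages",
    "group_origination_series",
]

_MIN_RATE = 1e-9
_MAX_RATE = 50.0  # per Ma; far beyond saturation on Ma-scale branches


class MkFitError(RuntimeError):
    """Raised when rate optimization fails; carries solver diagnostics."""


def read_trait_table(path) -> dict[str, int]:
    df = pd.read_csv(path, sep=None, engine="python")
    missing = {"taxon", "state"} - set(df.columns)
    if missing:
        raise ValueError(f"trait table missing column(s): {sorted(missing)}")
    out = {}
    for i, row in df.iterrows():
        state = int(row["state"])
        if state not in (0, 1):
            raise ValueError(f"row {i}: state must be 0 or 1, got {row['state']}")
        out[str(row["taxon"])] = state
    return out


def mk_transition_matrix(q01: float, q10: float, t: float) -> np.ndarray:
    """P(t) for the 2-state chain with instantaneous rates q01, q10."""
    if q01 < 0 or q10 < 0 or t < 0:
        raise ValueError("rates and durations must be non-negative")
    q = q01 + q10
    if q == 0 or t == 0:
        return np.eye(2)
    e = math.exp(-q * t)
    return np.array(
        [
            [(q10 + q01 * e) / q, q01 * (1 - e) / q],
            [q10 * (1 - e) / q, (q01 + q10 * e) / q],
        ]
    )


def _root_prior(q01: float, q10: float, kind: str) -> np.ndarray:
    if kind == "uniform":
        return np.array([0.5, 0.5])
    if kind == "stationary":
        q = q01 + q10
        if q == 0:
            return np.array([0.5, 0.5])
        return np.array([q10 / q, q01 / q])
    raise ValueError(f"unknown root prior {kind!r}")


def _check_coding(ctree: CalibratedTree, coding: Mapping[str, int]) -> None:
    for name in ctree.tip_labels():
        if name not in coding:
            raise ValueError(f"tip {name!r} has no trait coding")
        if coding[name] not in (0, 1):
            raise ValueError(f"tip {name!r}: state must be 0 or 1")


def _branch_length(node) -> float:
    return node.parent_node.age - node.age


def _down_pass(ctree, coding, q01, q10):
    """Felsenstein partial likelihoods, tips to root."""
    partials = {}
    for node in ctree.tree.postorder_node_iter():
        if node.is_leaf():
            part = np.zeros(2)
            part[coding[node.taxon.label]] = 1.0
        else:
            part = np.ones(2)
            for child in node.child_nodes():
                P = mk_transition_matrix(q01, q10, _branch_length(child))
                part = part * (P @ partials[child])
        partials[node] = part
    return partials


def mk_loglik(
    ctree: CalibratedTree,
    coding: Mapping[str, int],
    rates: tuple[float, float],
    root_prior: str = "uniform",
) -> float:
    """Log-likelihood of the tip states under the 2-state Mk model.

    Impossible configurations (e.g. conflicting states across zero-length
    branches at zero rates) yield ``-inf`` rather than an exception.
    """
    q01, q10 = rates
    if q01 < 0 or q10 < 0:
        raise ValueError("rates must be >= 0")
    _check_coding(ctree, coding)
    partials = _down_pass(ctree, coding, q01, q10)
    prior = _root_prior(q01, q10, root_prior)
    lik = float(prior @ partials[ctree.tree.seed_node])
    return math.log(lik) if lik > 0 else -math.inf


@dataclass
class AncestralStates:
    """ML rates and marginal node probabilities for one binary trait.

    ``node_probs`` maps each node's subtended tip-label set to
    (P(state 0), P(state 1)); tip entries reproduce their coding.
    """

    q01: float
    q10: float
    model: str
    root_prior: str
    loglik: float
    node_probs: dict[frozenset, tuple[float, float]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        import hashlib

        rows = []
        for clade, (p0, p1) in sorted(
            self.node_probs.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))
        ):
            key = ";".join(sorted(clade))
            rows.append(
                {
                    "clade_tips_hash": hashlib.md5(key.encode()).hexdigest()[:8],
                    "n_tips": len(clade),
                    "p_state0": p0,
                    "p_state1": p1,
                }
            )
        return pd.DataFrame(rows)


def _marginals(ctree, coding, q01, q10, root_prior):
    """Up-down pass: exact marginal state probabilities at every node."""
    partials = _down_pass(ctree, coding, q01, q10)
    prior = _root_prior(q01, q10, root_prior)
    ups = {ctree.tree.seed_node: prior.copy()}
    for node in ctree.tree.preorder_node_iter():
        if node.is_leaf():
            continue
        kids = node.child_nodes()
        for child in kids:
            sib_msg = ups[node].copy()
            for sib in kids:
                if sib is child:
                    continue
                Ps = mk_transition_matrix(q01, q10, _branch_length(sib))
                sib_msg = sib_msg * (Ps @ partials[sib])
            Pc = mk_transition_matrix(q01, q10, _branch_length(child))
            ups[child] = sib_msg @ Pc
    probs = {}
    for node in ctree.tree.preorder_node_iter():
        m = ups[node] * partials[node]
        tot = m.sum()
        m = m / tot if tot > 0 else np.array([0.5, 0.5])
        clade = frozenset(l.taxon.label for l in node.leaf_iter())
        probs[clade] = (float(m[0]), float(m[1]))
    return probs


def fit_mk(
    ctree: CalibratedTree,
    coding: Mapping[str, int],
    model: str = "ER",
    root_prior: str = "uniform",
) -> AncestralStates:
    """Fit Mk rates by maximum likelihood and compute marginal ancestral states.

    ``model`` is ``"ER"`` (q01 = q10, one parameter) or ``"ARD"`` (two
    parameters); optimization is bounded on log-rates.  When all tips share
    one state the rates pin to the lower bound and ancestors inherit that
    state with probability ~1.
    """
    _check_coding(ctree, coding)
    if model not in ("ER", "ARD"):
        raise ValueError("model must be 'ER' or 'ARD'")
    lo, hi = math.log(_MIN_RATE), math.log(_MAX_RATE)

    _CAP = 1e12  # finite stand-in for -inf likelihoods inside the optimizer

    if model == "ER":
        def nll(x):
            q = math.exp(x)
            return min(_CAP, -mk_loglik(ctree, coding, (q, q), root_prior))

        res = minimize_scalar(nll, bounds=(lo, hi), method="bounded")
        if not res.success:
            raise MkFitError(f"ER rate optimization failed: {res}")
        q01 = q10 = math.exp(res.x)
        loglik = -res.fun
    else:
        def nll(x):
            return min(
                _CAP,
                -mk_loglik(
                    ctree, coding, (math.exp(x[0]), math.exp(x[1])), root_prior
                ),
            )

        best = None
        for start in ([math.log(0.01)] * 2, [math.log(0.1)] * 2, [lo + 1] * 2):
            res = minimize(nll, start, method="L-BFGS-B", bounds=[(lo, hi)] * 2)
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise MkFitError(f"ARD rate optimization failed: {best}")
        q01, q10 = math.exp(best.x[0]), math.exp(best.x[1])
        loglik = -best.fun

    probs = _marginals(ctree, coding, q01, q10, root_prior)
    return AncestralStates(
        q01=q01, q10=q10, model=model, root_prior=root_prior,
        loglik=loglik, node_probs=probs,
    )


def group_lineages(
    ctree: CalibratedTree,
    asr: AncestralStates,
    coding: Mapping[str, int] | None = None,
    cutoff: float = 0.5,
    hereditary: bool = True,
) -> set:
    """Branches descended from a trait-positive ancestor.

    A branch (identified by the node it subtends) is in the group iff its
    parent node has P(state 1) > cutoff, any ancestor does (hereditary
    membership), or it is a trait-positive tip whose parent is negative.
    With ``hereditary=False`` membership requires the branch's own parent to
    be trait-positive (strict-state variant).
    """
    if not (0 < cutoff < 1):
        raise ValueError("cutoff must lie strictly between 0 and 1")

    def node_positive(node) -> bool:
        if node.is_leaf():
            if coding is not None:
                return coding[node.taxon.label] == 1
            clade = frozenset([node.taxon.label])
            return asr.node_probs[clade][1] > cutoff
        clade = frozenset(l.taxon.label for l in node.leaf_iter())
        return asr.node_probs[clade][1] > cutoff

    group = set()

    def walk(node, ancestor_positive):
        pos = ancestor_positive or node_positive(node)
        for child in node.child_nodes():
            parent_positive = pos if hereditary else node_positive(node)
            if parent_positive or (child.is_leaf() and node_positive(child)):
                group.add(child)
            walk(child, pos)

    walk(ctree.tree.seed_node, False)
    return group


def group_origination_series(
    ctree: CalibratedTree,
    group: set,
    timescale: TimeScale,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-lineage origination rates inside and outside a branch group.

    Cladogenesis events are attributed to the group of the branch carrying
    them (the branch subtending the splitting node; the root's event goes to
    the group iff both root-adjacent branches are in it).  Lineage counts
    are PDE restricted to each branch subset.
    """
    ivs = lineage_intervals(ctree)
    node_list = list(ctree.tree.preorder_node_iter())
    nonroot = [n for n in node_list if n.parent_node is not None]
    iv_by_node = dict(zip(nonroot, ivs))

    def make_series(members) -> pd.DataFrame:
        nbins = len(timescale)
        orig = np.zeros(nbins, dtype=int)
        lineages = np.zeros(nbins, dtype=int)
        for node in node_list:
            if node.parent_node is None:
                in_set = all(c in members for c in node.child_nodes())
            else:
                in_set = node in members
                iv = iv_by_node[node]
                for i in range(nbins):
                    if in_set and _present(iv, timescale, i):
                        lineages[i] += 1
            if not node.is_leaf() and in_set:
                i = timescale.bin_of(node.age)
                if i is not None:
                    orig[i] += 1
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = np.where(lineages > 0, orig / np.maximum(lineages, 1), 0.0)
        df = timescale.to_frame()
        df["lineages"] = lineages
        df["orig_events"] = orig
        df["orig_rate"] = rate
        return df

    complement = set(nonroot) - set(group)
    return make_series(set(group)), make_series(complement)
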