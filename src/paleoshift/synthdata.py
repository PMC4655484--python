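"""Synthetic fossil phylogenies, traits, and sampling regimes.

The generator produces the statistical structure the analysis pipeline
assumes: binary time-calibrated trees with extinct tips, clade-specific
diversification-rate shifts, instantaneous extinction pulses whose survival
lottery depends on a binary trait evolving along the tree, and Poisson
fossil sampling that creates ghost lineages and range truncation.  Every
bundle carries a manifest of the true parameters so recovery can be scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .chrono import CalibratedTree, DatedTaxon, read_taxon_ranges, read_tree
from .timeslice import make_substage_bins
from .traits import read_trait_table

__all__ = [
    "ScenarioSpec",
    "RateShift",
    "ExtinctionPulse",
    "SimulationResult",
    "simulate_bd_tree",
    "simulate_trait_history",
    "simulate_fossil_sampling",
    "scenario_generator",
    "Bundle",
    "PRESETS",
]


class TotalExtinctionError(RuntimeError):
    """All lineages died before the window closed; the draw can be repeated."""


class TreeTooLargeError(RuntimeError):
    """The simulation exceeded the spec's tip-count guard."""


class EmptyFossilRecordError(RuntimeError):
    """No lineage accrued a single fossil sample."""


@dataclass(frozen=True)
class RateShift:
    """At ``age`` one extant lineage (and its descendants) switches rates.

    ``select`` picks the lineage: ``"random"`` chooses uniformly among all
    extant lineages; ``"state1"`` chooses uniformly among trait-positive
    lineages (falling back to any lineage if none is positive), which ties
    the radiation to trait-buffered survivors of a preceding pulse.
    """

    age: float
    new_lam: float
    new_mu: float
    select: str = "random"


@dataclass(frozen=True)
class ExtinctionPulse:
    """Survival lottery at ``age``: P(survive) depends on the trait state."""

    age: float
    survival: tuple[float, float]  # (state 0, state 1)

    def __post_init__(self):
        if not all(0 <= s <= 1 for s in self.survival):
            raise ValueError("survival probabilities must lie in [0, 1]")


@dataclass
class ScenarioSpec:
    lam: float = 0.1
    mu: float = 0.04
    window: tuple[float, float] = (320.0, 260.0)
    shifts: Sequence[RateShift] = field(default_factory=tuple)
    pulses: Sequence[ExtinctionPulse] = field(default_factory=tuple)
    q01: float = 0.02
    q10: float = 0.02
    sampling_rate: float = 0.5
    seed: int = 0
    max_tips: int = 5000  # guard against runaway radiations

    def __post_init__(self):
        if min(self.lam, self.mu, self.q01, self.q10, self.sampling_rate) < 0:
            raise ValueError("all rates must be >= 0")
        old, young = self.window
        if not old > young:
            raise ValueError("window must run old > young")


class _Lineage:
    __slots__ = ("node", "lam", "mu", "state", "tag")

    def __init__(self, node, lam, mu, state, tag):
        self.node = node
        self.lam = lam
        self.mu = mu
        self.state = state
        self.tag = tag


@dataclass
class SimulationResult:
    """Complete (perfect-knowledge) outcome of one birth-death simulation."""

    ctree: CalibratedTree
    tip_states: dict[str, int]
    extant: set[str]
    shift_clades: list[frozenset]
    spec: ScenarioSpec


def _stationary_state(q01: float, q10: float, rng) -> int:
    q = q01 + q10
    if q == 0:
        return 0
    return int(rng.random() < q01 / q)


def simulate_bd_tree(
    spec: ScenarioSpec,
    rng: np.random.Generator | None = None,
    require_survival: bool = True,
) -> SimulationResult:
    """Simulate a crown birth-death tree over the window, pulses included.

    Two lineages start at the window's old edge (the root's cladogenesis).
    Lineage-specific rates switch at each :class:`RateShift`; at each
    :class:`ExtinctionPulse` every extant lineage survives independently
    with its trait-state probability; the binary trait flips along branches
    at rates q01/q10.  Raises :class:`TotalExtinctionError` if the clade
    dies before the window closes.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    old, young = spec.window

    tree = dendropy.Tree()
    tree.is_rooted = True
    root = tree.seed_node
    root.age = old
    root.state = _stationary_state(spec.q01, spec.q10, rng)

    def new_child(parent):
        node = dendropy.Node()
        parent.add_child(node)
        return node

    active = [
        _Lineage(new_child(root), spec.lam, spec.mu, root.state, None)
        for _ in range(2)
    ]
    schedule = sorted(
        [("shift", s.age, s) for s in spec.shifts]
        + [("pulse", p.age, p) for p in spec.pulses],
        key=lambda e: -e[1],
    )
    shift_roots: list = []
    tips: list[tuple[dendropy.Node, float, int, bool]] = []  # node, lad, state, extant
    age = old

    def close(lin, at_age, extant):
        tips.append((lin.node, at_age, lin.state, extant))

    while active:
        total = sum(l.lam + l.mu + (spec.q10 if l.state else spec.q01) for l in active)
        cand = age - (rng.exponential(1.0 / total) if total > 0 else math.inf)
        if schedule and young < schedule[0][1] and schedule[0][1] >= cand:
            # a scheduled shift/pulse happens first; the exponential clock is
            # memoryless, so discarding the draw and restarting is exact
            kind, ev_age, ev = schedule.pop(0)
            age = ev_age
            if kind == "shift":
                pool = active
                if ev.select == "state1":
                    positives = [l for l in active if l.state == 1]
                    pool = positives or active
                lin = pool[int(rng.integers(0, len(pool)))]
                lin.lam, lin.mu = ev.new_lam, ev.new_mu
                lin.tag = len(shift_roots)
                shift_roots.append(lin.node)
            else:
                survivors = []
                for lin in active:
                    if rng.random() < ev.survival[lin.state]:
                        survivors.append(lin)
                    else:
                        close(lin, ev_age, False)
                active = survivors
            continue
        if cand <= young:
            for lin in active:
                close(lin, young, True)
            active = []
            break
        age = cand
        weights = np.array(
            [l.lam + l.mu + (spec.q10 if l.state else spec.q01) for l in active]
        )
        lin = active[int(rng.choice(len(active), p=weights / weights.sum()))]
        u = rng.random() * (lin.lam + lin.mu + (spec.q10 if lin.state else spec.q01))
        if u < lin.lam:  # cladogenesis
            if len(tips) + len(active) > spec.max_tips:
                raise TreeTooLargeError(
                    f"more than {spec.max_tips} tips; lower the rates or window"
                )
            lin.node.age = age
            lin.node.state = lin.state
            c1, c2 = new_child(lin.node), new_child(lin.node)
            active.remove(lin)
            active.append(_Lineage(c1, lin.lam, lin.mu, lin.state, lin.tag))
            active.append(_Lineage(c2, lin.lam, lin.mu, lin.state, lin.tag))
        elif u < lin.lam + lin.mu:  # extinction
            close(lin, age, False)
            active.remove(lin)
        else:  # trait flip
            lin.state = 1 - lin.state

    if require_survival and not any(extant for *_, extant in tips):
        raise TotalExtinctionError("clade died before the window closed")

    ns = tree.taxon_namespace
    ranges, tip_states, extant_set = {}, {}, set()
    for i, (node, lad, state, extant) in enumerate(tips, 1):
        name = f"T{i}"
        node.taxon = ns.new_taxon(label=name)
        node.age = lad
        node.state = state
        fad = node.parent_node.age
        ranges[name] = DatedTaxon(name, fad, lad)
        tip_states[name] = state
        if extant:
            extant_set.add(name)
    shift_clades = [
        frozenset(l.taxon.label for l in node.leaf_iter()) for node in shift_roots
    ]
    ctree = CalibratedTree(tree, ranges)
    return SimulationResult(ctree, tip_states, extant_set, shift_clades, spec)


def simulate_trait_history(
    ctree: CalibratedTree, q01: float, q10: float, seed: int
) -> tuple[dict[frozenset, int], dict[str, int]]:
    """Forward Mk simulation along an existing calibrated tree.

    The root state is drawn from the stationary distribution (state 0 when
    both rates are zero).  Returns node states keyed by subtended tip set
    and tip states keyed by label.
    """
    if q01 < 0 or q10 < 0:
        raise ValueError("rates must be >= 0")
    rng = np.random.default_rng(seed)
    states = {}
    root = ctree.tree.seed_node
    states[root] = _stationary_state(q01, q10, rng)
    for node in ctree.tree.preorder_node_iter():
        if node is root:
            continue
        s = states[node.parent_node]
        t = node.parent_node.age - node.age
        while t > 0:
            rate = q01 if s == 0 else q10
            if rate == 0:
                break
            wait = rng.exponential(1.0 / rate)
            if wait >= t:
                break
            s = 1 - s
            t -= wait
        states[node] = s
    node_states = {
        frozenset(l.taxon.label for l in n.leaf_iter()): st
        for n, st in states.items()
    }
    tip_states = {
        n.taxon.label: st for n, st in states.items() if n.is_leaf()
    }
    return node_states, tip_states


def simulate_fossil_sampling(
    sim: SimulationResult | CalibratedTree,
    r: float,
    seed: int,
    observe_extant_at_close: bool = True,
) -> tuple[dendropy.Tree, dict[str, DatedTaxon]]:
    """Degrade a true tree into an observed topology and range table.

    Each tip lineage accrues Poisson(r per Ma) fossil samples along its
    branch; its FAD/LAD are the extreme sample ages.  Unsampled tips are
    dropped and the topology pruned.  Lineages alive at window close are
    always observed there (their survival is known), unless
    ``observe_extant_at_close`` is disabled.
    """
    if r < 0:
        raise ValueError("sampling rate must be >= 0")
    rng = np.random.default_rng(seed)
    if isinstance(sim, SimulationResult):
        ctree, extant = sim.ctree, sim.extant
    else:
        ctree, extant = sim, set()
    sampled: dict[str, DatedTaxon] = {}
    for leaf in ctree.tree.leaf_node_iter():
        name = leaf.taxon.label
        origin = ctree.branch_origin(leaf)
        end = ctree.ranges[name].lad
        n = rng.poisson(r * (origin - end))
        ages = list(origin - rng.random(n) * (origin - end)) if n else []
        if name in extant and observe_extant_at_close:
            ages.append(end)
        if ages:
            sampled[name] = DatedTaxon(name, max(ages), min(ages))
    if not sampled:
        raise EmptyFossilRecordError("no lineage was sampled")

    ns = dendropy.TaxonNamespace()

    def prune(node):
        if node.is_leaf():
            if node.taxon.label in sampled:
                new = dendropy.Node()
                new.taxon = ns.new_taxon(label=node.taxon.label)
                return new
            return None
        kids = [k for k in (prune(c) for c in node.child_nodes()) if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        new = dendropy.Node()
        for k in kids:
            new.add_child(k)
        return new

    root = prune(ctree.tree.seed_node)
    topo = dendropy.Tree(taxon_namespace=ns)
    topo.seed_node = root
    topo.is_rooted = True
    return topo, sampled


# ---------------------------------------------------------------------------
# presets


def _stage_frame(old: float, young: float, stage_len: float) -> pd.DataFrame:
    n = int(round((old - young) / stage_len))
    rows = [
        {
            "name": f"S{i + 1}",
            "old_bound": old - i * stage_len,
            "young_bound": old - (i + 1) * stage_len,
        }
        for i in range(n)
    ]
    return pd.DataFrame(rows)


# Per-phase survival for the protracted extinction episode of the pulse
# preset: three lotteries compounding to (0.2, 0.8) survival by trait state.
_PHASE_SURVIVAL = (0.2 ** (1 / 3), 0.8 ** (1 / 3))

PRESETS: dict[str, dict] = {
    # Homogeneous rates: the ERM-like control condition.
    "erm-null": dict(
        lam=0.1, mu=0.04, window=(320.0, 260.0), shifts=(), pulses=(),
        q01=0.02, q10=0.02, sampling_rate=0.5,
        stages_window=(300.0, 260.0), stage_len=10.0, n_tips_range=None,
    ),
    # One lineage switches to 5x speciation 10 Ma before window close.
    "clade-shift": dict(
        lam=0.1, mu=0.04, window=(320.0, 260.0),
        shifts=(RateShift(age=270.0, new_lam=0.5, new_mu=0.04),),
        pulses=(), q01=0.02, q10=0.02, sampling_rate=0.5,
        stages_window=(300.0, 260.0), stage_len=10.0, n_tips_range=None,
    ),
    # Trait-buffered extinction: a three-phase terminal episode whose
    # survival lottery compounds to 0.8 for trait-positive vs 0.2 for
    # trait-negative lineages, followed by a modest radiation seeded in a
    # trait-positive survivor (the innovation buffers extinction; the
    # diversification of survivors is deferred to the crisis).
    "trait-buffered-pulse": dict(
        lam=0.1, mu=0.04, window=(320.0, 260.0),
        shifts=(RateShift(age=271.9, new_lam=0.2, new_mu=0.04, select="state1"),),
        pulses=(
            ExtinctionPulse(age=272.0, survival=_PHASE_SURVIVAL),
            ExtinctionPulse(age=268.0, survival=_PHASE_SURVIVAL),
            ExtinctionPulse(age=264.0, survival=_PHASE_SURVIVAL),
        ),
        q01=0.02, q10=0.02, sampling_rate=1.0,
        stages_window=(300.0, 260.0), stage_len=10.0, n_tips_range=(60, 500),
    ),
}


@dataclass
class Bundle:
    """One synthetic dataset: truth, observations, and file-format views."""

    preset: str
    seed: int
    sim: SimulationResult
    topology: dendropy.Tree
    ranges: dict[str, DatedTaxon]
    traits: dict[str, int]
    stages: pd.DataFrame
    manifest: dict


def scenario_generator(preset: str, seed: int, out_dir=None, max_attempts: int = 1000) -> Bundle:
    """Generate a full synthetic dataset bundle for a named preset.

    Total-extinction draws are redrawn (deterministically, from the seeded
    stream) up to ``max_attempts`` times.  With ``out_dir`` the bundle is
    written as Newick + delimited tables + a flat key=value manifest, in the
    dialects the chrono readers consume.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; options: {sorted(PRESETS)}")
    cfg = dict(PRESETS[preset])
    stage_len = cfg.pop("stage_len")
    stages_window = cfg.pop("stages_window")
    n_tips_range = cfg.pop("n_tips_range")
    spec = ScenarioSpec(seed=seed, **cfg)
    rng = np.random.default_rng(seed)
    sim = None
    for _ in range(max_attempts):
        try:
            candidate = simulate_bd_tree(spec, rng)
        except (TotalExtinctionError, TreeTooLargeError):
            continue
        if n_tips_range is not None:
            lo, hi = n_tips_range
            if not (lo <= candidate.ctree.n_tips() <= hi):
                continue
        sim = candidate
        break
    if sim is None:
        raise TotalExtinctionError(
            f"no acceptable clade in {max_attempts} attempts for preset {preset!r}"
        )
    sample_seed = int(rng.integers(0, 2**31 - 1))
    topo, ranges = simulate_fossil_sampling(sim, spec.sampling_rate, sample_seed)
    traits = {name: sim.tip_states[name] for name in ranges}
    stages = _stage_frame(*stages_window, stage_len)
    manifest = {
        "preset": preset,
        "seed": seed,
        "lambda": spec.lam,
        "mu": spec.mu,
        "window_old": spec.window[0],
        "window_young": spec.window[1],
        "q01": spec.q01,
        "q10": spec.q10,
        "sampling_rate": spec.sampling_rate,
        "stage_len": stage_len,
        "n_tips_true": sim.ctree.n_tips(),
        "n_tips_observed": len(ranges),
    }
    manifest["stages_old"] = stages_window[0]
    manifest["stages_young"] = stages_window[1]
    for i, s in enumerate(spec.shifts):
        manifest[f"shift{i}_age"] = s.age
        manifest[f"shift{i}_lambda"] = s.new_lam
        manifest[f"shift{i}_mu"] = s.new_mu
        manifest[f"shift{i}_select"] = s.select
        observed_clade = sorted(sim.shift_clades[i] & set(ranges))
        manifest[f"shift{i}_clade"] = ";".join(observed_clade)
    for i, p in enumerate(spec.pulses):
        manifest[f"pulse{i}_age"] = p.age
        manifest[f"pulse{i}_survival0"] = p.survival[0]
        manifest[f"pulse{i}_survival1"] = p.survival[1]

    bundle = Bundle(preset, seed, sim, topo, ranges, traits, stages, manifest)
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _write_bundle(bundle: Bundle, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    newick = bundle.topology.as_string(schema="newick", suppress_rooting=True)
    (out_dir / "tree.nwk").write_text(newick)
    pd.DataFrame(
        {
            "taxon": list(bundle.ranges),
            "fad": [t.fad for t in bundle.ranges.values()],
            "lad": [t.lad for t in bundle.ranges.values()],
        }
    ).to_csv(out_dir / "ranges.csv", index=False)
    pd.DataFrame(
        {"taxon": list(bundle.traits), "state": list(bundle.traits.values())}
    ).to_csv(out_dir / "traits.csv", index=False)
    bundle.stages.to_csv(out_dir / "stages.csv", index=False)
    with open(out_dir / "manifest.txt", "w") as fh:
        for k, v in bundle.manifest.items():
            fh.write(f"{k}={v}\n")


def load_bundle_inputs(out_dir):
    """Round-trip helper: read a written bundle back through the chrono readers."""
    out_dir = Path(out_dir)
    topo = read_tree(str(out_dir / "tree.nwk"))
    ranges = read_taxon_ranges(out_dir / "ranges.csv")
    traits = read_trait_table(out_dir / "traits.csv")
    stages = pd.read_csv(out_dir / "stages.csv")
    return topo, ranges, traits, stages
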