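"""Phylogenetic diversity and per-bin origination/extinction rates.

The phylogenetic diversity estimate (PDE) counts, per time bin, every branch
of the calibrated tree crossing the bin — observed ranges, range extensions
and ghost lineages alike.  Per-lineage rates divide the cladogenetic
(origination) and lineage-termination (extinction) events of a bin by its
PDE.  A ghost-lineage sampling proportion damps the raw rates in poorly
sampled bins, and bins whose corrected extinction rate exceeds 30% are
flagged as mass extinctions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .chrono import CalibratedTree, DatedTaxon, TimeScale

__all__ = [
    "LineageInterval",
    "lineage_intervals",
    "pde_series",
    "taxic_series",
    "raw_rates",
    "sampling_proportion",
    "corrected_rates",
    "mass_extinction_flags",
    "mean_over_trees",
    "rate_series",
]

MASS_EXTINCTION_THRESHOLD = 0.30


@dataclass(frozen=True)
class LineageInterval:
    """One branch of the calibrated tree as a time interval [end, origin]."""

    branch_id: int
    origin: float
    end: float
    terminal: bool
    taxon: DatedTaxon | None = None

    def __post_init__(self):
        if self.origin < self.end:
            raise ValueError("branch origin must be >= end (ages in Ma)")


def lineage_intervals(ctree: CalibratedTree) -> list[LineageInterval]:
    """One interval per branch (2n-2 for n tips); tips end at their LAD."""
    out = []
    for i, node in enumerate(ctree.tree.preorder_node_iter()):
        if node.parent_node is None:
            continue  # the root subtends no branch
        if node.is_leaf():
            taxon = ctree.ranges[node.taxon.label]
            out.append(
                LineageInterval(i, node.parent_node.age, taxon.lad, True, taxon)
            )
        else:
            out.append(
                LineageInterval(i, node.parent_node.age, node.age, False)
            )
    return out


def _overlap(iv: LineageInterval, old: float, young: float) -> float:
    return min(iv.origin, old) - max(iv.end, young)


def _present(iv: LineageInterval, timescale: TimeScale, i: int) -> bool:
    b = timescale[i]
    if _overlap(iv, b.old_bound, b.young_bound) > 0:
        return True
    # zero-duration branches count where their point event falls
    if iv.origin == iv.end:
        return timescale.bin_of(iv.end) == i
    return False


def pde_series(ctree: CalibratedTree, timescale: TimeScale) -> np.ndarray:
    """Per-bin phylogenetic diversity estimate (branch count)."""
    ivs = lineage_intervals(ctree)
    return np.array(
        [sum(_present(iv, timescale, i) for iv in ivs) for i in range(len(timescale))],
        dtype=int,
    )


def taxic_series(ctree: CalibratedTree, timescale: TimeScale) -> np.ndarray:
    """Per-bin taxic richness from observed ranges only (no tree inference)."""
    counts = np.zeros(len(timescale), dtype=int)
    for taxon in ctree.ranges.values():
        for i, b in enumerate(timescale):
            if min(taxon.fad, b.old_bound) - max(taxon.lad, b.young_bound) > 0:
                counts[i] += 1
            elif taxon.fad == taxon.lad and timescale.bin_of(taxon.lad) == i:
                counts[i] += 1
    return counts


def raw_rates(ctree: CalibratedTree, timescale: TimeScale) -> pd.DataFrame:
    """Per-bin origination and extinction events and per-lineage rates.

    Origination events are internal-node (cladogenesis) ages; extinction
    events are tip LADs, except tips whose LAD sits exactly at the window's
    young edge, which are treated as extant at window close.  Rates divide
    events by the bin's PDE; empty bins yield rate 0.
    """
    nbins = len(timescale)
    orig = np.zeros(nbins, dtype=int)
    ext = np.zeros(nbins, dtype=int)
    for node in ctree.tree.preorder_node_iter():
        if node.is_leaf():
            lad = ctree.ranges[node.taxon.label].lad
            if lad == timescale.young_edge:
                continue  # extant at window close
            i = timescale.bin_of(lad)
            if i is not None:
                ext[i] += 1
        else:
            i = timescale.bin_of(node.age)
            if i is not None:
                orig[i] += 1
    pde = pde_series(ctree, timescale)
    with np.errstate(invalid="ignore", divide="ignore"):
        orig_rate = np.where(pde > 0, orig / np.maximum(pde, 1), 0.0)
        ext_rate = np.where(pde > 0, ext / np.maximum(pde, 1), 0.0)
    df = timescale.to_frame()
    df["pde"] = pde
    df["orig_events"] = orig
    df["ext_events"] = ext
    df["orig_rate"] = orig_rate
    df["ext_rate"] = ext_rate
    return df


def sampling_proportion(ctree: CalibratedTree, timescale: TimeScale) -> np.ndarray:
    """Per-bin proportion of lineages backed by an observed range.

    A branch crossing a bin counts as observed iff the tip's [lad, fad] span
    overlaps the bin with positive duration along that branch; ghost
    portions of tip branches and all internal branches count as ghost.
    Bins crossed by no lineage default to s = 1.
    """
    ivs = lineage_intervals(ctree)
    s = np.ones(len(timescale))
    for i, b in enumerate(timescale):
        n_obs = n_ghost = 0
        for iv in ivs:
            if not _present(iv, timescale, i):
                continue
            if iv.terminal and (
                min(iv.taxon.fad, b.old_bound) - max(iv.taxon.lad, b.young_bound) > 0
                or (iv.taxon.fad == iv.taxon.lad and timescale.bin_of(iv.taxon.lad) == i)
            ):
                n_obs += 1
            else:
                n_ghost += 1
        if n_obs + n_ghost > 0:
            s[i] = n_obs / (n_obs + n_ghost)
    return s


def mass_extinction_flags(
    ext_rate: Sequence[float], threshold: float = MASS_EXTINCTION_THRESHOLD
) -> np.ndarray:
    """1 where the extinction rate is strictly above the threshold, else 0."""
    ext_rate = np.asarray(ext_rate, dtype=float)
    if np.any(ext_rate < 0) or np.any(ext_rate > 1):
        raise ValueError("extinction rates must lie in [0, 1]")
    return (ext_rate > threshold).astype(int)


def _damping(raw: np.ndarray, s: np.ndarray) -> np.ndarray:
    return raw * s


def _identity(raw: np.ndarray, s: np.ndarray) -> np.ndarray:
    return raw


CORRECTIONS: dict[str, Callable] = {"damping": _damping, "identity": _identity}


def corrected_rates(
    raw: pd.DataFrame,
    s: Sequence[float],
    correction: str | Callable = "damping",
    threshold: float = MASS_EXTINCTION_THRESHOLD,
) -> pd.DataFrame:
    """Apply the sampling correction and the mass-extinction flag.

    The default correction damps each raw rate by the bin's sampling
    proportion; the correction is pluggable (name or callable
    ``f(raw_rates, s) -> corrected``).
    """
    s = np.asarray(s, dtype=float)
    if len(s) != len(raw):
        raise ValueError("sampling series length does not match rate table")
    fn = CORRECTIONS[correction] if isinstance(correction, str) else correction
    out = raw.copy()
    out["sampling"] = s
    out["orig_rate"] = fn(raw["orig_rate"].to_numpy(), s)
    out["ext_rate"] = fn(raw["ext_rate"].to_numpy(), s)
    out["mass_ext"] = mass_extinction_flags(out["ext_rate"], threshold)
    return out


def rate_series(
    ctree: CalibratedTree,
    timescale: TimeScale,
    correction: str | Callable = "damping",
    threshold: float = MASS_EXTINCTION_THRESHOLD,
) -> pd.DataFrame:
    """Full per-bin rate table: PDE, events, corrected rates, flags."""
    raw = raw_rates(ctree, timescale)
    s = sampling_proportion(ctree, timescale)
    return corrected_rates(raw, s, correction=correction, threshold=threshold)


def mean_over_trees(series: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Element-wise mean of per-bin tables computed on replicate trees."""
    if not series:
        raise ValueError("need at least one series")
    first = series[0]
    for df in series[1:]:
        if len(df) != len(first) or not (
            df["bin_label"].tolist() == first["bin_label"].tolist()
        ):
            raise ValueError("replicate series use different timescales")
    out = first.copy()
    num_cols = [c for c in first.columns if c not in ("bin_label",)]
    for c in num_cols:
        out[c] = np.mean([df[c].to_numpy(dtype=float) for df in series], axis=0)
    return out
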