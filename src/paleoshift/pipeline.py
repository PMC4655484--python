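"""Full-analysis orchestration: calibrate -> shifts -> slices -> rates ->
traits -> model comparison, from a flat configuration."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import chrono, modelsel, paleorates, shiftstat, timeslice, traits

__all__ = ["RunConfig", "read_config", "run_full_analysis", "write_table"]

log = logging.getLogger("paleoshift")


@dataclass
class RunConfig:
    tree: str
    ranges: str
    stages: str
    out_dir: str
    traits: str | None = None
    n_polytomy_replicates: int = 10
    n_sims: int = 10_000
    min_branch: float = 1.0
    alpha: float = 0.05
    alpha_substantial: float = 0.10
    mass_ext_threshold: float = 0.30
    correction: str = "damping"
    error_model: str = "ar1"
    trait_model: str = "ER"
    trait_cutoff: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.alpha < self.alpha_substantial < 1):
            raise ValueError("thresholds must satisfy 0 < alpha < alpha_substantial < 1")
        if self.n_polytomy_replicates < 1 or self.n_sims < 100:
            raise ValueError("counts must be positive (n_sims >= 100)")


_FLOATS = {"min_branch", "alpha", "alpha_substantial", "mass_ext_threshold",
           "trait_cutoff"}
_INTS = {"n_polytomy_replicates", "n_sims", "seed"}


def read_config(path) -> RunConfig:
    """Parse a flat ``key = value`` configuration file."""
    kwargs = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key in _FLOATS:
            kwargs[key] = float(value)
        elif key in _INTS:
            kwargs[key] = int(value)
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)


def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Write a delimited table with ``# key=value`` metadata header lines."""
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, index=False)


def _plot(run_dir, delta2_df, rates_df, group_df=None, comp_df=None):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mid = 0.5 * (delta2_df["old_bound"] + delta2_df["young_bound"])

    fig, ax1 = plt.subplots(figsize=(7, 4))
    ax1.plot(mid, rates_df["pde"], "k-", label="PDE")
    ax2 = ax1.twinx()
    ax2.plot(mid, delta2_df["mean_delta2"], "--", color="grey", label="mean $\\Delta_2$")
    ax1.invert_xaxis()
    ax1.set_xlabel("age (Ma)")
    ax1.set_ylabel("phylogenetic diversity estimate")
    ax2.set_ylabel("mean $\\Delta_2$")
    fig.tight_layout()
    fig.savefig(run_dir / "delta2_vs_pde.png", dpi=120)
    plt.close(fig)

    fig, ax1 = plt.subplots(figsize=(7, 4))
    ax1.plot(mid, rates_df["ext_rate"], "k-", label="extinction rate")
    ax2 = ax1.twinx()
    ax2.plot(mid, delta2_df["mean_delta2"], "--", color="grey")
    ax1.invert_xaxis()
    ax1.set_xlabel("age (Ma)")
    ax1.set_ylabel("per-lineage extinction rate")
    ax2.set_ylabel("mean $\\Delta_2$")
    fig.tight_layout()
    fig.savefig(run_dir / "delta2_vs_extinction.png", dpi=120)
    plt.close(fig)

    if group_df is not None:
        grp, comp = group_df
        fig, ax = plt.subplots(figsize=(7, 4))
        ax.plot(mid, grp["orig_rate"], "k-", label="trait group")
        ax.plot(mid, comp["orig_rate"], "--", color="grey", label="other lineages")
        ax.invert_xaxis()
        ax.set_xlabel("age (Ma)")
        ax.set_ylabel("per-lineage origination rate")
        ax.legend()
        fig.tight_layout()
        fig.savefig(run_dir / "group_origination.png", dpi=120)
        plt.close(fig)


def run_full_analysis(config: RunConfig) -> Path:
    """Run the whole pipeline; outputs land in ``config.out_dir``.

    Stage failures abort with the stage named; tables written before the
    failure are preserved.
    """
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(run_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    meta = {"paleoshift_version": __version__, **asdict(config)}
    stage = "setup"
    try:
        stage = "read-inputs"
        topo = chrono.read_tree(config.tree)
        ranges = chrono.read_taxon_ranges(config.ranges)
        stages_df = timeslice.read_stage_table(config.stages)
        timescale = timeslice.make_substage_bins(stages_df)
        log.info("read %d tips, %d stages", len(topo.leaf_nodes()), len(stages_df))

        stage = "resolve-polytomies"
        replicates = chrono.resolve_polytomies(
            topo, config.n_polytomy_replicates, config.seed
        )

        stage = "calibrate"
        ctrees = [
            chrono.calibrate(t, ranges, min_branch=config.min_branch)
            for t in replicates
        ]

        stage = "shift-analysis"
        rng = np.random.default_rng(config.seed)
        cache = shiftstat.NullCache(config.n_sims, rng)
        per_rep = [
            shiftstat.shift_pvalues(ct.tree, config.n_sims, null_cache=cache)
            for ct in ctrees
        ]
        consensus = shiftstat.consensus_shifts(
            per_rep, tip_sets=[frozenset(ct.tip_labels()) for ct in ctrees]
        )
        write_table(shiftstat.results_table(consensus), run_dir / "consensus_shifts.csv", meta)
        for i, rep in enumerate(per_rep):
            write_table(
                shiftstat.results_table(rep),
                run_dir / f"shifts_replicate_{i}.csv", meta,
            )

        stage = "time-slices"
        d2_series = [
            timeslice.delta2_series(ct, timescale, config.n_sims, null_cache=cache)
            for ct in ctrees
        ]
        d2_mean = paleorates.mean_over_trees(d2_series)
        write_table(d2_mean, run_dir / "delta2_series.csv", meta)

        stage = "rates"
        rate_tables = [
            paleorates.rate_series(
                ct, timescale, correction=config.correction,
                threshold=config.mass_ext_threshold,
            )
            for ct in ctrees
        ]
        for i, tbl in enumerate(rate_tables):
            write_table(tbl, run_dir / f"rates_replicate_{i}.csv", meta)
        rates_mean = paleorates.mean_over_trees(rate_tables)
        rates_mean["mass_ext"] = paleorates.mass_extinction_flags(
            rates_mean["ext_rate"], config.mass_ext_threshold
        )
        write_table(rates_mean, run_dir / "rates_mean.csv", meta)

        group_pair = None
        if config.traits:
            stage = "traits"
            coding = traits.read_trait_table(config.traits)
            asr = traits.fit_mk(ctrees[0], coding, model=config.trait_model)
            write_table(asr.to_frame(), run_dir / "ancestral_states.csv", meta)
            group = traits.group_lineages(
                ctrees[0], asr, coding, cutoff=config.trait_cutoff
            )
            grp_df, comp_df = traits.group_origination_series(
                ctrees[0], group, timescale
            )
            write_table(grp_df, run_dir / "group_origination.csv", meta)
            write_table(comp_df, run_dir / "complement_origination.csv", meta)
            group_pair = (grp_df, comp_df)

        stage = "model-comparison"
        comp = modelsel.compare_models(d2_mean, rates_mean, error_model=config.error_model)
        write_table(comp, run_dir / "model_comparison.csv", meta)

        stage = "plots"
        _plot(run_dir, d2_mean, rates_mean, group_pair, comp)

        log.info("run complete")
        return run_dir
    except Exception as exc:
        log.error("stage %r failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()
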