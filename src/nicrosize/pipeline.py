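"""End-to-end orchestration of the body-size analysis.

``run_all`` drives every stage over a given (or synthetic) dataset:
species summaries -> size-distribution statistics and the two distribution
null models -> phylogenetic signal and ancestral states -> equal-area
gridding with the richness ANOVA and assemblage null -> sister-pair tests
and the contrast ANCOVA -> the latitude regression. It writes tables, a
machine-readable results summary (JSON) in which every statistic is tagged
with its generating stage and seed, and map-ready exports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml

from . import cooccurrence, data_io, phylo_comparative, sister_pairs, size_distribution
from .data_io import DatedTree, SpeciesSummary
from .synthetic_data import SyntheticConfig, generate_dataset

__all__ = ["RunConfig", "LatitudeRegression", "latitude_regression", "run_all"]

log = logging.getLogger("nicrosize")


@dataclass(frozen=True)
class LatitudeRegression:
    slope: float  # mm per degree latitude
    se: float
    p: float
    r2: float


@dataclass
class RunConfig:
    """Inputs, stage toggles and per-stage seeds for a full run."""

    occurrences: str | None = None  # paths; None with synthetic=True generates inputs
    tree: str | None = None
    pairs: str | None = None
    outdir: str = "results"
    synthetic: bool = False
    seed: int = 0
    # stage toggles
    run_distribution: bool = True
    run_nullmodels: bool = True
    run_signal: bool = True
    run_grid: bool = True
    run_sisters: bool = True
    run_biogeo: bool = True
    # stochastic-stage controls
    uniform_null_reps: int = 10_000
    speciation_null_reps: int = 1000
    assemblage_null_reps: int = 1000
    n_perm: int = 1000
    min_records: int = 10
    cell_km: float = 200.0
    k_cap: int = 7
    log_level: str = "INFO"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text(encoding="utf-8")))


def latitude_regression(summaries: Sequence[SpeciesSummary]) -> LatitudeRegression:
    """OLS of species mean pronotal width on species mean latitude."""
    if len(summaries) < 3:
        raise ValueError("latitude regression needs at least 3 species")
    lat = np.array([s.mean_latitude for s in summaries])
    w = np.array([s.mean_width_mm for s in summaries])
    if np.ptp(lat) == 0:
        raise ValueError("zero variance in mean latitude")
    if np.ptp(w) == 0:
        return LatitudeRegression(slope=0.0, se=0.0, p=1.0, r2=0.0)
    fit = sm.OLS(w, sm.add_constant(lat)).fit()
    return LatitudeRegression(slope=float(fit.params[1]), se=float(fit.bse[1]),
                              p=float(fit.pvalues[1]), r2=float(fit.rsquared))


def _stage_seeds(seed: int) -> dict[str, int]:
    names = ["synthetic", "uniform_null", "speciation_null", "assemblage_null", "k_perm"]
    state = np.random.SeedSequence(seed).generate_state(len(names)) % (2**31)
    return {n: int(s) for n, s in zip(names, state)}


def _tag(stage: str, seed: int | None, **values: Any) -> dict[str, Any]:
    d: dict[str, Any] = {"stage": stage}
    if seed is not None:
        d["seed"] = seed
    d.update(values)
    return d


def run_all(config: RunConfig) -> dict[str, Any]:
    """Execute the configured stages; returns (and writes) the results bundle."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    results: dict[str, Any] = {"seed": config.seed, "stage_seeds": seeds}

    # ---- inputs -----------------------------------------------------------
    if config.synthetic:
        log.info("generating synthetic dataset (seed %d)", seeds["synthetic"])
        ds = generate_dataset(SyntheticConfig(seed=seeds["synthetic"]))
        ds.write(outdir / "synthetic_inputs")
        records, tree, pair_table = ds.records, ds.tree, ds.pairs
    else:
        if config.occurrences is None:
            raise ValueError("either synthetic=True or an occurrence table is required")
        records, row_errors = data_io.read_occurrence_table(config.occurrences)
        if row_errors:
            log.warning("rejected %d malformed occurrence rows", len(row_errors))
        tree = data_io.read_newick(config.tree) if config.tree else None
        pair_table = sister_pairs.read_pair_table(config.pairs) if config.pairs else None

    records, unimputable = data_io.impute_literature_widths(records)
    if unimputable:
        log.warning("excluded %d literature records with no museum widths", len(unimputable))
    summaries = data_io.species_summaries(records, source_filter="museum_only")
    sframe = data_io.summaries_frame(summaries)
    sframe.to_csv(outdir / "species_summaries.csv")
    means = dict(zip(sframe.index, sframe["mean_width_mm"]))
    mvals = sframe["mean_width_mm"].to_numpy()
    ci = 1.96 * mvals.std(ddof=1) / np.sqrt(len(mvals))
    results["species"] = _tag("data_io", None, n_species=len(mvals),
                              grand_mean_mm=float(mvals.mean()),
                              grand_mean_ci=[float(mvals.mean() - ci), float(mvals.mean() + ci)])

    # ---- size distribution ------------------------------------------------
    if config.run_distribution:
        hist = size_distribution.species_histogram(
            np.clip(mvals, 4.0, 11.0))  # guard: synthetic means stay inside by design
        skew = size_distribution.dagostino_skew_test(mvals)
        gap, gap_loc = size_distribution.has_internal_gap(hist)
        results["distribution"] = _tag(
            "size_distribution", None,
            histogram=hist.counts.tolist(), g1=skew.g1, z=skew.z, p=skew.p,
            internal_gap=bool(gap), gap_bins=list(gap_loc) if gap_loc else None)

    if config.run_nullmodels:
        u = size_distribution.random_selection_null(size_distribution.RandomSelectionConfig(
            reps=config.uniform_null_reps, seed=seeds["uniform_null"]))
        s = size_distribution.speciation_null(size_distribution.SpeciationModelConfig(
            reps=config.speciation_null_reps, seed=seeds["speciation_null"]))
        results["null_random_selection"] = _tag(
            "size_distribution", seeds["uniform_null"],
            p_mean=u.p_mean, p_skew=u.p_skew, p_gap=u.p_gap, reps=u.reps_run)
        results["null_speciation"] = _tag(
            "size_distribution", seeds["speciation_null"],
            p_mean=s.p_mean, p_skew=s.p_skew, p_gap=s.p_gap, reps=s.reps_run)

    # ---- phylogenetic signal ----------------------------------------------
    if config.run_signal and tree is not None:
        in_tree = {sp: m for sp, m in means.items() if sp in set(tree.tip_names)}
        dropped = sorted(set(tree.tip_names) - set(in_tree))
        if dropped:
            log.warning("tips without trait values dropped from the tree: %s", dropped)
        use_tree = tree.prune_to(in_tree) if dropped else tree
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lam = phylo_comparative.pagel_lambda(use_tree, in_tree)
            K = phylo_comparative.blomberg_k(use_tree, in_tree, n_perm=config.n_perm,
                                             seed=seeds["k_perm"])
            anc = phylo_comparative.ancestral_states(use_tree, in_tree)
        root_label = use_tree.tree.seed_node.label
        pd.DataFrame({
            "node": list(anc.node_states),
            "state_mm": list(anc.node_states.values()),
            "ci_lo": [anc.ci95[n][0] for n in anc.node_states],
            "ci_hi": [anc.ci95[n][1] for n in anc.node_states],
        }).to_csv(outdir / "ancestral_states.csv", index=False)
        results["signal"] = _tag(
            "phylo_comparative", seeds["k_perm"],
            lambda_hat=lam.lambda_hat, lambda_lrt_p=lam.lrt_p,
            K=K.K, K_p=K.K_p, n_perm=K.n_perm,
            root_state_mm=anc.node_states[root_label],
            root_ci=list(anc.ci95[root_label]))

    # ---- co-occurrence grid -----------------------------------------------
    if config.run_grid:
        cells = cooccurrence.summarize_cells(records, means,
                                             min_records=config.min_records,
                                             k_cap=config.k_cap,
                                             cell_m=config.cell_km * 1000.0)
        cooccurrence.cells_frame(cells).to_csv(outdir / "grid_cells.csv", index=False)
        (outdir / "grid_cells.geojson").write_text(
            cooccurrence.cells_geojson(cells, cell_m=config.cell_km * 1000.0), encoding="utf-8")
        anovas = {}
        if len({c.k_class for c in cells}) >= 2:
            anovas = {name: dataclasses.asdict(res) for name, res in
                      cooccurrence.richness_anovas(cells).items()}
        null = cooccurrence.random_assemblage_null(
            reps=config.assemblage_null_reps, seed=seeds["assemblage_null"])
        null.table.to_csv(outdir / "assemblage_null.csv")
        results["grid"] = _tag(
            "cooccurrence", seeds["assemblage_null"],
            n_cells_retained=len(cells), anova=anovas,
            null_mean_mm=float(null.table["mean_mean"].mean()),
            null_divergence_max_k7=null.divergence_max(config.k_cap))

    # ---- sister pairs ------------------------------------------------------
    if config.run_sisters and tree is not None and pair_table is not None and len(pair_table):
        pairs = sister_pairs.build_sister_pairs(pair_table, records, tree)
        battery = sister_pairs.pair_test_battery(pairs)
        battery.to_csv(outdir / "sister_pair_tests.csv", index=False)
        entry: dict[str, Any] = {
            "n_pairs": len(pairs),
            "n_significant": int(battery["significant"].sum()),
        }
        try:
            rc = sister_pairs.ratio_comparison(pairs)
            entry["ratio"] = dataclasses.asdict(rc)
            anc2 = sister_pairs.contrasts_vs_time_ancova(pairs)
            entry["ancova"] = dataclasses.asdict(anc2)
        except ValueError as e:
            log.warning("sister-pair group comparisons skipped: %s", e)
        results["sisters"] = _tag("sister_pairs", None, **entry)

    # ---- biogeography ------------------------------------------------------
    if config.run_biogeo:
        reg = latitude_regression(summaries)
        results["latitude"] = _tag("pipeline", None, **dataclasses.asdict(reg))

    (outdir / "results.json").write_text(json.dumps(results, indent=2, sort_keys=True),
                                         encoding="utf-8")
    return results
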