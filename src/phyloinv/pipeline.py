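"""Config-driven orchestration of the full invasion analysis.

``run_pipeline`` executes, in order: data load/validate (or simulate) ->
country and plot relatedness -> group comparisons and mixed models ->
phylogenetic signal of invasiveness (D by group) -> spatial congruence
and loess residuals -> design matrix and model averaging.  Each stage
writes one CSV; a machine-readable run report records versions, seeds,
filter counts, warnings and failures.  A stage failure is recorded and
its dependents skipped while independent stages still run.  Identical
config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import relatedness, signal_d, spatial_stats, synthetic_data, trait_models
from .phylo_core import DatedTree, check_ultrametric, read_newick, write_newick

logger = logging.getLogger("phyloinv")

__all__ = ["RunConfig", "run_pipeline", "validate_inputs"]

FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Pipeline configuration: input paths *or* a simulate block."""

    tree: str | None = None
    species: str | None = None
    plots: str | None = None
    grid: str | None = None
    simulate: synthetic_data.SimConfig | None = None
    stages: tuple[str, ...] = (
        "relatedness",
        "signal",
        "spatial",
        "model",
    )
    n_randomizations: int = 10000
    max_model_size: int = 5
    loess_span: float = 0.75
    dutilleul_classes: int = 13
    seed: int = 0
    out_dir: str = "phyloinv_out"

    def __post_init__(self):
        has_paths = self.tree is not None and self.species is not None
        if self.simulate is None and not has_paths:
            raise ValueError(
                "config needs either input paths (tree + species) or a "
                "simulate block"
            )
        if self.n_randomizations < 100:
            raise ValueError(
                "n_randomizations must be >= 100 for reported p-values"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "simulate" in raw and raw["simulate"] is not None:
            raw["simulate"] = synthetic_data.SimConfig(**raw["simulate"])
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def validate_inputs(
    tree: DatedTree, species: pd.DataFrame, plots: pd.DataFrame | None = None
) -> dict:
    """Schema and coverage checks; hard violations raise, soft ones warn.

    Reported: tip/table label coverage, status vocabulary, Ellenberg
    ranges, duplicate records, and a preview of how many plots survive
    the >= 1 native & >= 1 alien filter.
    """
    report: dict = {"errors": [], "warnings": []}
    required = {"species", "status"}
    missing = required - set(species.columns)
    if missing:
        raise ValueError(f"species table missing columns: {sorted(missing)}")
    allowed = {
        relatedness.NATIVE,
        synthetic_data.NON_INVASIVE,
        synthetic_data.INVASIVE,
    }
    bad = species.loc[~species["status"].isin(allowed)]
    if len(bad):
        raise ValueError(
            f"unknown status token(s) {sorted(bad['status'].unique())} in "
            f"row(s) {bad.index[:5].tolist()}"
        )
    dup = species["species"].duplicated()
    if dup.any():
        raise ValueError(
            f"duplicate species records: {sorted(species.loc[dup, 'species'])[:5]}"
        )
    matched, unmatched_species, unmatched_tips = relatedness._match_species(
        tree, species
    )
    report["n_species"] = int(len(species))
    report["n_tips"] = int(tree.n_tips)
    report["coverage_species_on_tree"] = float(len(matched) / len(species))
    report["unmatched_species"] = unmatched_species[:20]
    report["unmatched_tips"] = unmatched_tips[:20]
    if unmatched_species:
        report["warnings"].append(
            f"{len(unmatched_species)} species absent from the tree"
        )
    for col in [c for c in species.columns if c.startswith("ellenberg_")]:
        vals = species[col].dropna()
        lo = 0 if col.endswith("_S") else 1
        if len(vals) and (vals.min() < lo or vals.max() > 9):
            report["warnings"].append(f"{col} outside [{lo}, 9]")
    ultra, dev = check_ultrametric(tree, tol=1e-6)
    report["ultrametric"] = bool(ultra)
    report["ultrametric_max_deviation"] = float(dev)
    if plots is not None:
        needed = {"square", "plot", "species"}
        if needed - set(plots.columns):
            raise ValueError(
                f"plots table missing columns: {sorted(needed - set(plots.columns))}"
            )
        status = species.set_index("species")["status"]
        known = plots["species"].isin(status.index)
        retained = 0
        total = 0
        for _, grp in plots.loc[known].groupby(["square", "plot"]):
            total += 1
            st = status.loc[grp["species"].unique()]
            if (st == relatedness.NATIVE).any() and (st != relatedness.NATIVE).any():
                retained += 1
        n_all = plots.groupby(["square", "plot"]).ngroups
        report["plots_total"] = int(n_all)
        report["plots_retained_preview"] = int(retained)
        report["plots_retained_fraction"] = (
            retained / n_all if n_all else 0.0
        )
        report["plot_occurrences_unknown_species"] = int((~known).sum())
    return report


def _load_inputs(cfg: RunConfig, out: Path) -> dict:
    if cfg.simulate is not None:
        sim = dataclasses.replace(cfg.simulate, seed=cfg.seed)
        data = synthetic_data.simulate_dataset(sim)
        write_newick(data["tree"], out / "tree.nwk")
        _write_csv(data["species"], out / "species.csv")
        _write_csv(data["plots"], out / "plots.csv")
        _write_csv(data["grid"], out / "grid.csv")
        return data
    data = {
        "tree": read_newick(cfg.tree),
        "species": pd.read_csv(cfg.species),
        "plots": pd.read_csv(cfg.plots) if cfg.plots else None,
        "grid": pd.read_csv(cfg.grid) if cfg.grid else None,
    }
    return data


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the configured stages; returns the run report (also written)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    report: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config": {
            k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
            for k, v in dataclasses.asdict(cfg).items()
        },
        "stages": {},
        "errors": [],
        "warnings": [],
    }
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1000]))

    # stage name -> config toggle group
    toggles = {
        "country_relatedness": "relatedness",
        "plot_relatedness": "relatedness",
        "group_lm": "relatedness",
        "plot_lmm": "relatedness",
        "change_index": "relatedness",
        "signal": "signal",
        "spatial": "spatial",
        "model_averaging": "model",
    }

    def stage(name, fn, *deps):
        if toggles.get(name, name) not in cfg.stages and name not in (
            "load",
            "validate",
        ):
            report["stages"][name] = {"status": "disabled"}
            return None
        for dep in deps:
            if dep is None:
                report["stages"][name] = {"status": "skipped (missing input)"}
                logger.info("stage %s skipped", name)
                return None
        t0 = time.time()
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                result = fn()
            for wmsg in caught:
                report["warnings"].append(f"{name}: {wmsg.message}")
            report["stages"][name] = {
                "status": "ok",
                "seconds": round(time.time() - t0, 3),
            }
            logger.info("stage %s ok (%.2fs)", name, time.time() - t0)
            return result
        except Exception as exc:  # noqa: BLE001 - stage isolation by design
            report["stages"][name] = {"status": "failed", "error": str(exc)}
            report["errors"].append(f"{name}: {exc}")
            logger.exception("stage %s failed", name)
            return None

    data = stage("load", lambda: _load_inputs(cfg, out))
    if data is None:
        data = {"tree": None, "species": None, "plots": None, "grid": None}
    tree, species = data.get("tree"), data.get("species")
    plots, grid = data.get("plots"), data.get("grid")

    val = stage(
        "validate",
        lambda: validate_inputs(tree, species, plots),
        tree,
        species,
    )
    if val is not None:
        report["validation"] = val

    country = stage(
        "country_relatedness",
        lambda: relatedness.country_relatedness(tree, species),
        tree,
        species,
    )
    if country is not None:
        _write_csv(country, out / "relatedness_country.csv")

    plot_rel = stage(
        "plot_relatedness",
        lambda: relatedness.plot_relatedness(tree, species, plots),
        tree,
        species,
        plots,
    )
    if plot_rel is not None:
        plot_records, filt = plot_rel
        _write_csv(plot_records, out / "relatedness_plot.csv")
        report["plot_filter"] = {
            "plots_total": filt.plots_total,
            "plots_retained": filt.plots_retained,
            "retained_fraction": filt.retained_fraction,
            "dropped_no_native": filt.plots_dropped_no_native,
            "dropped_no_alien": filt.plots_dropped_no_alien,
            "unknown_species": len(filt.unknown_species),
        }
    else:
        plot_records = None

    def _group_lm():
        return trait_models.country_group_lm(country)

    group_lm = stage("group_lm", _group_lm, country)
    if group_lm is not None:
        _write_csv(group_lm, out / "group_lm.csv")

    def _lmm():
        rows = []
        for resp in ("pnnd", "mpd"):
            r = trait_models.fit_nested_lmm(plot_records, resp)
            rows.append(dataclasses.asdict(r))
        return pd.DataFrame(rows)

    lmm = stage("plot_lmm", _lmm, plot_records)
    if lmm is not None:
        _write_csv(lmm, out / "table2_lmm.csv")

    def _signal():
        return signal_d.d_by_group(
            tree, species, n=cfg.n_randomizations, seed=rng
        )

    dtab = stage("signal", _signal, tree, species)
    if dtab is not None:
        _write_csv(dtab, out / "table1_signal.csv")

    def _change_index():
        if "change_index" not in species.columns:
            raise ValueError("species table has no change_index column")
        aliens = species.loc[species["status"] != relatedness.NATIVE]
        res = trait_models.wilcoxon_rank_sum(
            aliens.loc[aliens["invasive"] == 1, "change_index"],
            aliens.loc[aliens["invasive"] == 0, "change_index"],
            alternative="greater",
        )
        return pd.DataFrame([dataclasses.asdict(res)])

    chg = stage("change_index", _change_index, species)
    if chg is not None:
        _write_csv(chg, out / "change_index_test.csv")

    def _spatial():
        cleaned, n_removed = spatial_stats.drop_empty_cells(grid)
        test = spatial_stats.dutilleul_test(
            cleaned["richness_invasive"],
            cleaned["richness_noninvasive"],
            cleaned[["x", "y"]].to_numpy(),
            n_classes=cfg.dutilleul_classes,
        )
        resid = spatial_stats.residual_hotspots(cleaned, span=cfg.loess_span)
        summary = pd.DataFrame(
            [
                {
                    "spearman_r": test.r if test.method == "spearman"
                    else spatial_stats.spearman(
                        cleaned["richness_invasive"],
                        cleaned["richness_noninvasive"],
                    ),
                    "effective_df": test.effective_df,
                    "F": test.F,
                    "p": test.p,
                    "n_cells": test.n,
                    "n_cells_dropped": n_removed,
                    "loess_pseudo_r2": resid.attrs["pseudo_r2"],
                }
            ]
        )
        return summary, resid

    spat = stage("spatial", _spatial, grid)
    if spat is not None:
        summary, resid = spat
        _write_csv(summary, out / "spatial_summary.csv")
        _write_csv(resid, out / "residuals.csv")
        # spearman here is the rank correlation the Dutilleul test used
        report["spatial"] = summary.iloc[0].to_dict()

    def _model():
        design = trait_models.trait_contrasts(species, country)
        variables = [
            v for v in trait_models.DESIGN_VARIABLES if v in design.columns
        ]
        cands = trait_models.enumerate_candidates(
            variables, cfg.max_model_size
        )
        fits = []
        for c in cands:
            try:
                fits.append(trait_models.fit_binomial_glm(design, c))
            except ValueError:
                continue
        return trait_models.model_average(fits, variables=variables)

    ma = stage("model_averaging", _model, country, species)
    if ma is not None:
        _write_csv(ma, out / "table3_model_averaging.csv")

    report["runtime_seconds"] = round(time.time() - t_start, 3)
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    return report
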