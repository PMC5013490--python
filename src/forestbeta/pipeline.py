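"""End-to-end orchestration of the turnover analysis.

``run_analysis`` sweeps the configured factorial — grains x levels x dbh
size classes x statistics — and produces, per cell: the pair table, the
tip-shuffle null envelopes, the pruned mixed-model report with contrasts,
the residual correlogram, and a consolidated verdict table answering the
two study questions (is there a regime trend? is turnover outside the null
envelope?).  All outputs are TSV plus a JSON manifest echoing the resolved
configuration, so every number is recomputable from the bundle.
"""

from __future__ import annotations

import json
import logging
import time
import traceback
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from forestbeta import data_io
from forestbeta.beta_diversity import pair_table
from forestbeta.data_io import SIZE_CLASSES, grid_stems
from forestbeta.inference import (
    ModelSpec,
    backward_prune,
    regime_contrasts,
    residual_correlogram,
    satterthwaite_tests,
)
from forestbeta.null_models import envelope_table, null_envelope
from forestbeta.phylo_signal import signal_table
from forestbeta.synthetic import AssemblyScenario, SyntheticDataset, simulate_dataset
from forestbeta.trait_space import (
    composite_trait_distance,
    per_trait_distances,
    phylo_cophenetic_distance,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved run configuration (flat key-value; echoed into the manifest)."""

    # data source: a directory of TSV/newick inputs, or a simulation scenario
    input_dir: str | None = None
    mode: str = "neutral"
    seed: int = 0
    n_species: int = 180
    n_regimes: int = 3
    n_plots_per_regime: int = 3
    stems_per_plot: int = 6500
    trait_signal_w: float = 0.5
    filter_strength_sigma: float = 1.0
    dispersal_sigma: float = 20.0
    priority_fraction: float = 0.5
    regime_heterogeneity: tuple = (0.5, 0.75, 1.0)
    pool_fractions: tuple = (0.6, 0.8, 1.0)
    # analysis factorial
    grains: tuple = (10, 20)
    levels: tuple = ("within", "between")
    size_classes: tuple = ("all",)  # "all" and/or keys of SIZE_CLASSES
    statistics: tuple = ("cj_dissim", "bst", "tau_all")
    per_trait: bool = False
    n_reps_null: int = 999
    n_perm_signal: int = 999
    variant: str = "species-centered"
    trait_distance: str = "cophenetic"  # cophenetic | raw
    elev_coding: str = "mean"
    out_dir: str = "forestbeta_results"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("regime_heterogeneity", "pool_fractions", "grains", "levels",
                    "size_classes", "statistics"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def scenario(self) -> AssemblyScenario:
        return AssemblyScenario(
            mode=self.mode,
            n_species=self.n_species,
            n_regimes=self.n_regimes,
            n_plots_per_regime=self.n_plots_per_regime,
            stems_per_plot=self.stems_per_plot,
            trait_signal_w=self.trait_signal_w,
            filter_strength_sigma=self.filter_strength_sigma,
            dispersal_sigma=self.dispersal_sigma,
            priority_fraction=self.priority_fraction,
            regime_heterogeneity=tuple(self.regime_heterogeneity),
            pool_fractions=tuple(self.pool_fractions),
            seed=self.seed,
        )


@dataclass
class Bundle:
    """In-memory result bundle; ``write`` lays it out as TSV + manifest."""

    config: RunConfig
    signal: pd.DataFrame | None = None
    pair_tables: dict = field(default_factory=dict)
    envelopes: dict = field(default_factory=dict)
    model_reports: dict = field(default_factory=dict)
    contrasts: dict = field(default_factory=dict)
    correlograms: dict = field(default_factory=dict)
    figure_tables: dict = field(default_factory=dict)
    verdicts: pd.DataFrame | None = None
    manifest: dict = field(default_factory=dict)
    partial: bool = False

    def write(self, outdir: str | Path | None = None) -> Path:
        outdir = Path(outdir or self.config.out_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        if self.signal is not None:
            self.signal.to_csv(outdir / "phylo_signal.tsv", sep="\t", index=False)
        for name, df in self.pair_tables.items():
            df.to_csv(outdir / f"pairs_{name}.tsv", sep="\t", index=False)
        for name, df in self.envelopes.items():
            df.to_csv(outdir / f"envelope_{name}.tsv", sep="\t", index=False)
        for name, df in self.model_reports.items():
            df.to_csv(outdir / f"model_{name}.tsv", sep="\t", index=False)
        for name, df in self.contrasts.items():
            df.to_csv(outdir / f"contrasts_{name}.tsv", sep="\t", index=False)
        for name, df in self.correlograms.items():
            df.to_csv(outdir / f"correlogram_{name}.tsv", sep="\t", index=False)
        for name, df in self.figure_tables.items():
            df.to_csv(outdir / f"figure_{name}.tsv", sep="\t", index=False)
        if self.verdicts is not None:
            self.verdicts.to_csv(outdir / "verdicts.tsv", sep="\t", index=False)
        (outdir / "manifest.json").write_text(json.dumps(self.manifest, indent=2, default=str) + "\n")
        return outdir


def _load_dataset(config: RunConfig) -> SyntheticDataset:
    if config.input_dir is None:
        return simulate_dataset(config.scenario(), grains=tuple(config.grains))
    d = Path(config.input_dir)
    stems = data_io.read_stem_table(d / "stems.tsv")
    phy = data_io.read_phylogeny(d / "phylogeny.nwk")
    traits = data_io.read_trait_table(d / "traits.tsv")
    habitat = data_io.read_habitat_table(d / "habitat.tsv")
    plots = data_io.read_plot_table(d / "plots.tsv")
    ds = SyntheticDataset.__new__(SyntheticDataset)
    ds.stems, ds.phylogeny, ds.traits, ds.habitat, ds.plots = stems, phy, traits, habitat, plots
    ds.scenario = AssemblyScenario(seed=config.seed)
    stems.check_cross_references(phy, traits)
    return ds


def run_analysis(config: RunConfig) -> Bundle:
    """Run the full factorial analysis; stage failures mark the bundle
    partial and skip dependent stages for that cell only."""
    t0 = time.time()
    bundle = Bundle(config=config)
    manifest: dict = {"config": asdict(config), "timings": {}, "excluded_pairs": {}, "errors": []}
    rng = np.random.default_rng(config.seed)

    ds = _load_dataset(config)
    manifest["n_stems"] = len(ds.stems)
    manifest["n_species"] = len(ds.stems.species)

    Dphy = phylo_cophenetic_distance(ds.phylogeny)
    _, Dfun_all = composite_trait_distance(ds.traits, distance=config.trait_distance)
    Dper = per_trait_distances(ds.traits, distance=config.trait_distance) if config.per_trait else {}

    try:
        bundle.signal = signal_table(
            ds.phylogeny, ds.traits, n_perm=config.n_perm_signal,
            seed=int(rng.integers(2**31)),
        )
    except Exception as exc:  # pragma: no cover - defensive
        bundle.partial = True
        manifest["errors"].append(f"phylo_signal: {exc}")

    verdict_rows = []
    stats_for_envelope = {"bst": Dphy, "tau_all": Dfun_all}
    stats_for_envelope.update({f"tau_{t}": dm for t, dm in Dper.items()})
    statistics = list(config.statistics) + [f"tau_{t}" for t in Dper]

    for grain in config.grains:
        for sc in config.size_classes:
            size_class = None if sc == "all" else SIZE_CLASSES[sc]
            cm = grid_stems(ds.stems, grain, size_class=size_class)
            for level in config.levels:
                cell = f"g{grain}_{level}_{sc.replace('>', 'gt')}"
                t1 = time.time()
                try:
                    pairs = pair_table(
                        cm, Dphy, Dfun_all, Dper or None,
                        habitat=ds.habitat, plots=ds.plots,
                        level=level, size_class=sc, variant=config.variant,
                    )
                except Exception as exc:
                    bundle.partial = True
                    manifest["errors"].append(f"{cell}/pairs: {exc}\n{traceback.format_exc(limit=2)}")
                    continue
                bundle.pair_tables[cell] = pairs
                manifest["excluded_pairs"][cell] = pairs.attrs.get("excluded_pairs", {})

                env_frames = []
                for stat, D in stats_for_envelope.items():
                    if stat not in pairs.columns:
                        continue
                    try:
                        envs = null_envelope(
                            cm, D, pairs, statistic=stat,
                            group_cols=("regime",),
                            n_reps=config.n_reps_null,
                            seed=int(rng.integers(2**31)),
                            variant=config.variant,
                        )
                        env_frames.append(envelope_table(envs, ("regime",)))
                    except Exception as exc:
                        bundle.partial = True
                        manifest["errors"].append(f"{cell}/envelope/{stat}: {exc}")
                if env_frames:
                    bundle.envelopes[cell] = pd.concat(env_frames, ignore_index=True)

                for stat in statistics:
                    if stat not in pairs.columns:
                        continue
                    key = f"{cell}_{stat}"
                    try:
                        spec = ModelSpec(response=stat, elev_coding=config.elev_coding)
                        res = backward_prune(spec, pairs)
                        report = satterthwaite_tests(res)
                        report["pruned"] = False
                        for step in res.pruning_log:
                            report.loc[len(report)] = {
                                "term": step["dropped"], "F": step["F"], "p": step["p"],
                                "ndf": np.nan, "ddf": np.nan, "pruned": True,
                            }
                        bundle.model_reports[key] = report
                        ct = regime_contrasts(res)
                        bundle.contrasts[key] = ct
                        try:
                            bundle.correlograms[key] = residual_correlogram(
                                res, seed=int(rng.integers(2**31))
                            )
                        except Exception as exc:
                            manifest["errors"].append(f"{key}/correlogram: {exc}")

                        regime_row = report[(report["term"] == "regime") & (~report["pruned"])]
                        trend = bool(len(regime_row) and (regime_row["p"] <= 0.05).any())
                        inter_row = report[(report["term"] == "regime:log_hd") & (~report["pruned"])]
                        inter = bool(len(inter_row) and (inter_row["p"] <= 0.05).any())
                        inside = None
                        if cell in bundle.envelopes and stat in set(bundle.envelopes[cell]["statistic"]):
                            sub = bundle.envelopes[cell]
                            inside = bool(sub.loc[sub["statistic"] == stat, "inside"].all())
                        verdict_rows.append(
                            {
                                "grain": grain,
                                "level": level,
                                "size_class": sc,
                                "statistic": stat,
                                "regime_trend_significant": trend,
                                "regime_x_habitat_significant": inter,
                                "inside_null_envelope": inside,
                            }
                        )
                    except Exception as exc:
                        bundle.partial = True
                        manifest["errors"].append(f"{key}/model: {exc}\n{traceback.format_exc(limit=2)}")
                manifest["timings"][cell] = round(time.time() - t1, 2)

    bundle.verdicts = pd.DataFrame(verdict_rows)
    bundle.figure_tables = make_figure_tables(bundle)
    manifest["timings"]["total"] = round(time.time() - t0, 2)
    manifest["partial"] = bundle.partial
    bundle.manifest = manifest
    return bundle


def make_figure_tables(bundle: Bundle) -> dict[str, pd.DataFrame]:
    """Per-panel numeric summaries: regime, observed mean +/- SE over pair
    values, null CI bounds, and significance letters from the contrasts."""
    out: dict[str, pd.DataFrame] = {}
    for cell, pairs in bundle.pair_tables.items():
        env = bundle.envelopes.get(cell)
        stats = [c for c in pairs.columns if c in ("cj_dissim", "bst", "tau_all") or c.startswith("tau_")]
        for stat in stats:
            rows = []
            letters = {}
            key = f"{cell}_{stat}"
            if key in bundle.contrasts:
                letters = bundle.contrasts[key].attrs.get("letters", {})
            for regime, grp in pairs.groupby("regime"):
                vals = grp[stat].dropna()
                row = {
                    "regime": regime,
                    "mean": vals.mean(),
                    "se": vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan,
                    "n_pairs": len(vals),
                    "letter": letters.get(regime, ""),
                }
                if env is not None and stat in set(env["statistic"]):
                    sub = env[(env["statistic"] == stat) & (env["regime"] == regime)]
                    if len(sub):
                        row["null_ci_lower"] = float(sub["ci_lower"].iloc[0])
                        row["null_ci_upper"] = float(sub["ci_upper"].iloc[0])
                rows.append(row)
            out[key] = pd.DataFrame(rows)
    return out
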