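"""Synthetic forest chronosequence generator.

Produces complete datasets — Yule phylogeny, six lognormal traits with
tunable phylogenetic signal, smooth topographic habitat surfaces, plot
layout, and a stem-mapped census — with the statistical structure the
downstream analysis assumes.  Three assembly modes control whether
composition is coupled to traits and habitat:

``neutral``
    species drawn from a lognormal regional abundance distribution with
    conspecific clumping (a Thomas cluster process around parent stems);
    composition is independent of traits and phylogeny.
``filtering``
    per-stem species choice weighted by regional abundance times a Gaussian
    match between the species' standardized composite trait and the local
    standardized habitat surface (environmental filtering).
``priority``
    a neutral first cohort plus a fraction of stems cloned from earlier
    stems nearby (resprouting / priority effect).

A dataset is a pure function of its :class:`AssemblyScenario`, seed
included.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from forestbeta.data_io import (
    HabitatTable,
    Phylogeny,
    PlotTable,
    StemTable,
    TraitTable,
    TRAIT_NAMES,
    ValidationError,
    phylogeny_from_newick,
    subplot_id,
    write_habitat_table,
    write_phylogeny,
    write_plot_table,
    write_stem_table,
    write_trait_table,
)
from forestbeta.phylo_signal import phylo_vcv
from forestbeta.trait_space import pca_scores, standardize_traits

#: lognormal location/scale (of ln trait) per trait, chosen to give realistic
#: magnitudes: SLA ~ 15 mm^2/mg, LA ~ 20 cm^2, WD ~ 0.55 g/cm^3,
#: LPC ~ 1.2 mg/g, LNC ~ 18 mg/g, MH ~ 12 m.
TRAIT_LOGNORMAL = {
    "SLA": (2.71, 0.40),
    "LA": (3.00, 1.00),
    "WD": (-0.60, 0.15),
    "LPC": (0.18, 0.30),
    "LNC": (2.89, 0.30),
    "MH": (2.48, 0.60),
}

ELEVATION_SPAN = (372.6, 772.9)  # m a.s.l., span of plot base elevations
BASE_GRAIN = 5  # m; habitat fields are simulated on this grid and aggregated
GRF_RANGE = 30.0  # m; squared-exponential correlation range of habitat fields


@dataclass
class AssemblyScenario:
    """Parameter set fully determining one synthetic dataset.

    ``regime_heterogeneity`` multiplies the amplitude of the habitat surfaces
    per disturbance regime (the chronosequence is encoded as recovering
    habitat variation); ``pool_fractions`` truncates the regional species
    pool per regime (disturbed plots start from a homogenized subset).
    """

    mode: str = "neutral"  # neutral | filtering | priority
    n_species: int = 180
    n_regimes: int = 3
    n_plots_per_regime: int = 3
    stems_per_plot: int = 6500  # Poisson mean
    trait_signal_w: float = 0.5
    filter_strength_sigma: float = 1.0  # standardized trait units
    dispersal_sigma: float = 20.0  # m
    cluster_size: float = 25.0  # mean stems per Thomas-process parent
    regime_heterogeneity: tuple[float, ...] = (0.5, 0.75, 1.0)
    pool_fractions: tuple[float, ...] = (0.6, 0.8, 1.0)
    priority_fraction: float = 0.5
    sad_sigma: float = 1.2  # sd of log regional abundance
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in {"neutral", "filtering", "priority"}:
            raise ValidationError(f"unknown assembly mode {self.mode!r}")
        for name in ("n_species", "n_regimes", "n_plots_per_regime", "stems_per_plot"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("trait_signal_w", "priority_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if len(self.regime_heterogeneity) < self.n_regimes:
            raise ValidationError("regime_heterogeneity must cover every regime")
        if len(self.pool_fractions) < self.n_regimes:
            raise ValidationError("pool_fractions must cover every regime")

    @property
    def n_plots(self) -> int:
        return self.n_regimes * self.n_plots_per_regime


@dataclass
class SyntheticDataset:
    """Internally cross-referenced synthetic dataset plus provenance."""

    stems: StemTable
    phylogeny: Phylogeny
    traits: TraitTable
    habitat: HabitatTable
    plots: PlotTable
    scenario: AssemblyScenario

    def __post_init__(self) -> None:
        self.stems.check_cross_references(self.phylogeny, self.traits)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_stem_table(self.stems, outdir / "stems.tsv")
        write_phylogeny(self.phylogeny, outdir / "phylogeny.nwk")
        write_trait_table(self.traits, outdir / "traits.tsv")
        write_habitat_table(self.habitat, outdir / "habitat.tsv")
        write_plot_table(self.plots, outdir / "plots.tsv")
        manifest = {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(self.scenario).items()}
        manifest["note"] = (
            "synthetic dataset; scenario parameters are generator constructs, "
            "not estimates from any field census"
        )
        import json

        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------


def simulate_tree(n_species: int, seed: int | None = None) -> Phylogeny:
    """Pure-birth (Yule) ultrametric tree scaled to root depth 1.

    Lineages split at rate 1 each; after the n-th tip appears the tree is
    extended by a final exponential waiting time so no terminal branch has
    zero length.  Tips are labelled ``sp001``... in random attachment order.
    """
    if n_species < 3:
        raise ValidationError("need at least 3 species")
    rng = np.random.default_rng(seed)
    # each live lineage: (birth_time, subtree-newick or tip index)
    split_time = {0: 0.0, 1: 0.0}
    children: dict[int, tuple[int, int]] = {}
    parent_birth = {0: 0.0, 1: 0.0}
    live = [0, 1]
    next_id = 2
    t = 0.0
    while len(live) < n_species:
        t += rng.exponential(1.0 / len(live))
        k = int(rng.integers(len(live)))
        node = live[k]
        a, b = next_id, next_id + 1
        next_id += 2
        children[node] = (a, b)
        split_time[node] = t
        parent_birth[a] = parent_birth[b] = t
        live[k] = a
        live.append(b)
    t += rng.exponential(1.0 / len(live))
    depth = t

    labels = {}
    for i, node in enumerate(sorted(live)):
        labels[node] = f"sp{i + 1:03d}"

    def newick(node: int) -> str:
        if node in children:
            a, b = children[node]
            length = (split_time[node] - parent_birth[node]) / depth
            return f"({newick(a)},{newick(b)}):{length:.12g}"
        length = (depth - parent_birth[node]) / depth
        return f"{labels[node]}:{length:.12g}"

    nwk = f"({newick(0)},{newick(1)});"
    return phylogeny_from_newick(nwk)


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------


def brownian_trait(phy: Phylogeny, seed: int | None = None, rng: np.random.Generator | None = None) -> pd.Series:
    """One Brownian-motion trait realization on the tree (unit-rate)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    labels, V = phylo_vcv(phy)
    L = np.linalg.cholesky(V + 1e-12 * np.trace(V) / len(labels) * np.eye(len(labels)))
    return pd.Series(L @ rng.standard_normal(len(labels)), index=labels)


def simulate_traits(
    phy: Phylogeny,
    trait_signal_w: float = 0.5,
    n_traits: int = 6,
    seed: int | None = None,
    names: Sequence[str] | None = None,
) -> TraitTable:
    """Six positive traits with tunable phylogenetic signal.

    Each trait is ``z = sqrt(w) b + sqrt(1-w) e`` with ``b`` a
    Brownian-motion realization standardized to unit variance across tips and
    ``e`` standardized white noise, then mapped to a physical scale as
    ``exp(z*s + m)`` with per-trait lognormal location/scale defaults.
    ``w = 1`` gives Brownian traits (Blomberg's K near 1), ``w = 0`` no
    phylogenetic signal.
    """
    if not 0.0 <= trait_signal_w <= 1.0:
        raise ValidationError("trait_signal_w must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    labels, V = phylo_vcv(phy)
    n = len(labels)
    L = np.linalg.cholesky(V + 1e-12 * np.trace(V) / n * np.eye(n))
    if names is None:
        names = list(TRAIT_NAMES)[:n_traits]
    cols = {}
    for name in names:
        b = L @ rng.standard_normal(n)
        b = (b - b.mean()) / b.std(ddof=1)
        e = rng.standard_normal(n)
        e = (e - e.mean()) / e.std(ddof=1)
        z = np.sqrt(trait_signal_w) * b + np.sqrt(1.0 - trait_signal_w) * e
        m, s = TRAIT_LOGNORMAL.get(name, (0.0, 0.5))
        cols[name] = np.exp(z * s + m)
    return TraitTable(pd.DataFrame(cols, index=labels))


# ---------------------------------------------------------------------------
# Habitat
# ---------------------------------------------------------------------------


def _grf(rng: np.random.Generator, coords: np.ndarray, range_m: float = GRF_RANGE) -> np.ndarray:
    """Unit-variance Gaussian random field with squared-exponential
    correlation over the given coordinates."""
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    K = np.exp(-d2 / (2.0 * range_m**2)) + 1e-8 * np.eye(len(coords))
    return np.linalg.cholesky(K) @ rng.standard_normal(len(coords))


def _circular_mean_deg(deg: np.ndarray) -> float:
    rad = np.deg2rad(deg)
    ang = np.rad2deg(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean()))
    return float(ang % 360.0)


def simulate_habitat(
    n_plots: int = 9,
    grains: Sequence[int] = (10, 20),
    regime_heterogeneity: Sequence[float] = (0.5, 0.75, 1.0),
    seed: int | None = None,
    plot_regimes: Sequence[int] | None = None,
) -> HabitatTable:
    """Smooth per-plot topography, aggregated to the requested grains.

    Fields are simulated on a 5 m base grid from squared-exponential Gaussian
    random fields (range 30 m), so nearby subplots have similar habitat.
    Plot base elevations are uniform on the realistic span
    [372.6, 772.9] m; per-regime heterogeneity multiplies the within-plot
    amplitude of elevation, convexity and slope.  Aspect comes from two
    smooth fields via atan2 and is aggregated circularly.
    """
    if any(h <= 0 for h in regime_heterogeneity):
        raise ValidationError("heterogeneity multipliers must be positive")
    for g in grains:
        if g % BASE_GRAIN != 0 or 100 % g != 0:
            raise ValidationError(f"grain {g} must be a multiple of {BASE_GRAIN} dividing 100")
    if plot_regimes is None:
        per = int(np.ceil(n_plots / len(regime_heterogeneity)))
        plot_regimes = [i // per + 1 for i in range(n_plots)]
    rng = np.random.default_rng(seed)

    ncell = 100 // BASE_GRAIN
    xs = (np.arange(ncell) + 0.5) * BASE_GRAIN
    gx, gy = np.meshgrid(xs, xs)
    coords = np.column_stack([gx.ravel(), gy.ravel()])

    rows = []
    for p in range(n_plots):
        plot = p + 1
        regime = plot_regimes[p]
        het = regime_heterogeneity[regime - 1]
        base = rng.uniform(*ELEVATION_SPAN)
        elev = base + 12.0 * het * _grf(rng, coords)
        conv = 1.5 * het * _grf(rng, coords)
        slope = np.clip(20.0 + 8.0 * het * _grf(rng, coords), 0.0, 60.0)
        u, v = _grf(rng, coords), _grf(rng, coords)
        aspect = (np.rad2deg(np.arctan2(u, v))) % 360.0
        for grain in grains:
            k = grain // BASE_GRAIN
            ng = 100 // grain
            E = elev.reshape(ncell, ncell)
            C = conv.reshape(ncell, ncell)
            S = slope.reshape(ncell, ncell)
            A = aspect.reshape(ncell, ncell)
            for r in range(ng):
                for c in range(ng):
                    blk = np.s_[r * k : (r + 1) * k, c * k : (c + 1) * k]
                    rows.append(
                        {
                            "subplot_id": subplot_id(plot, grain, r, c),
                            "plot_id": plot,
                            "grain": grain,
                            "row": r,
                            "col": c,
                            "mean_elevation": float(E[blk].mean()),
                            "convexity": float(C[blk].mean()),
                            "slope": float(S[blk].mean()),
                            "aspect": _circular_mean_deg(A[blk].ravel()),
                        }
                    )
    return HabitatTable(pd.DataFrame(rows))


def plot_layout(
    n_regimes: int, n_plots_per_regime: int, seed: int | None = None
) -> PlotTable:
    """Plot origins on a jittered grid in a shared reserve frame (metres)."""
    rng = np.random.default_rng(seed)
    n = n_regimes * n_plots_per_regime
    side = int(np.ceil(np.sqrt(n)))
    rows = []
    for p in range(n):
        r, c = divmod(p, side)
        rows.append(
            {
                "plot_id": p + 1,
                "regime": p // n_plots_per_regime + 1,
                "origin_x": c * 400.0 + rng.uniform(0, 150),
                "origin_y": r * 400.0 + rng.uniform(0, 150),
            }
        )
    return PlotTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Census assembly
# ---------------------------------------------------------------------------


def _reflect(x: np.ndarray, hi: float = 100.0) -> np.ndarray:
    """Reflect coordinates into [0, hi) (mirror at the boundaries)."""
    x = np.mod(x, 2 * hi)
    x = np.where(x >= hi, 2 * hi - x, x)
    return np.clip(x, 0.0, np.nextafter(hi, 0.0))


def _truncated_exp_dbh(rng: np.random.Generator, n: int, scale: float = 8.0, lo: float = 1.0, hi: float = 80.0) -> np.ndarray:
    u = rng.uniform(size=n)
    # inverse CDF of Exp(scale) truncated to [lo, hi]
    a, b = np.exp(-(lo) / scale), np.exp(-(hi) / scale)
    return -scale * np.log(a - u * (a - b))


def _habitat_surface(habitat: HabitatTable, plot: int) -> tuple[np.ndarray, int] | None:
    """Within-plot standardized elevation anomaly on the finest grain
    available for this plot, as the environmental-filtering surface."""
    sub = habitat.data[habitat.data["plot_id"] == plot]
    if sub.empty:
        return None
    grain = int(sub["grain"].min())
    sub = sub[sub["grain"] == grain]
    ng = 100 // grain
    surf = np.full((ng, ng), np.nan)
    surf[sub["row"].to_numpy(), sub["col"].to_numpy()] = sub["mean_elevation"].to_numpy()
    anom = surf - np.nanmean(surf)
    sd = np.nanstd(anom)
    return (anom / sd if sd > 0 else anom * 0.0), grain


def assemble_census(
    scenario: AssemblyScenario,
    phy: Phylogeny,
    traits: TraitTable,
    habitat: HabitatTable,
    plots: PlotTable | None = None,
) -> StemTable:
    """Place stems and assign species per plot under the scenario's mode.

    All modes share the spatial skeleton (Thomas cluster process with
    parent-scale clumping at ``dispersal_sigma``); they differ only in how a
    stem's species is chosen, which is what the downstream turnover analysis
    must detect.
    """
    tips = set(phy.tip_labels)
    tr_species = set(traits.species)
    if tips != tr_species:
        raise ValidationError("phylogeny tips and trait species differ")
    species = sorted(tips)
    if len(species) != scenario.n_species:
        raise ValidationError(
            f"scenario expects {scenario.n_species} species, inputs have {len(species)}"
        )
    if plots is None:
        plots = plot_layout(scenario.n_regimes, scenario.n_plots_per_regime, seed=scenario.seed)

    ss = np.random.SeedSequence([int(scenario.seed), 2**20 + 11])
    rng = np.random.default_rng(ss)

    # regional species-abundance distribution (lognormal), fixed across plots
    regional = np.exp(rng.normal(0.0, scenario.sad_sigma, size=len(species)))
    regional /= regional.sum()
    order = np.argsort(-regional)  # most abundant first, for pool truncation

    # standardized composite trait (first PCA axis of log-z traits)
    z = standardize_traits(traits)
    pc1 = pca_scores(z).iloc[:, 0]
    pc1 = (pc1 - pc1.mean()) / pc1.std(ddof=1)
    tvec = pc1.reindex(species).to_numpy()

    frames = []
    for prow in plots.data.itertuples(index=False):  # itertuples keeps dtypes
        plot = prow.plot_id
        regime = int(prow.regime)
        pool_frac = scenario.pool_fractions[regime - 1]
        n_pool = max(2, int(np.ceil(pool_frac * len(species))))
        pool = np.zeros(len(species), dtype=bool)
        pool[order[:n_pool]] = True
        p_local = np.where(pool, regional, 0.0)
        p_local /= p_local.sum()

        n_stems = int(rng.poisson(scenario.stems_per_plot))
        n_stems = max(n_stems, 2)

        # Thomas-process skeleton
        n_parents = max(1, int(np.round(n_stems / scenario.cluster_size)))
        px = rng.uniform(0, 100, n_parents)
        py = rng.uniform(0, 100, n_parents)
        assign = rng.integers(n_parents, size=n_stems)
        x = _reflect(px[assign] + rng.normal(0, scenario.dispersal_sigma, n_stems))
        y = _reflect(py[assign] + rng.normal(0, scenario.dispersal_sigma, n_stems))

        if scenario.mode == "neutral":
            parent_species = rng.choice(len(species), size=n_parents, p=p_local)
            sp_idx = parent_species[assign]
        elif scenario.mode == "filtering":
            surface = _habitat_surface(habitat, plot)
            if surface is None:
                raise ValidationError(f"no habitat records for plot {plot}")
            surf, grain = surface
            h = surf[
                np.floor(y / grain).astype(int), np.floor(x / grain).astype(int)
            ]
            sig = max(scenario.filter_strength_sigma, 1e-6)
            w = p_local[None, :] * np.exp(
                -((tvec[None, :] - h[:, None]) ** 2) / (2.0 * sig**2)
            )
            wsum = w.sum(axis=1, keepdims=True)
            # guard: if filtering kills every species at a location, fall back
            w = np.where(wsum > 0, w, p_local[None, :])
            w /= w.sum(axis=1, keepdims=True)
            cum = np.cumsum(w, axis=1)
            u = rng.uniform(size=n_stems)
            sp_idx = (u[:, None] > cum).sum(axis=1)
        else:  # priority
            n_seed = max(1, int(np.ceil((1.0 - scenario.priority_fraction) * n_stems)))
            parent_species = rng.choice(len(species), size=n_parents, p=p_local)
            sp_idx = np.empty(n_stems, dtype=int)
            sp_idx[:n_seed] = parent_species[assign[:n_seed]]
            for i in range(n_seed, n_stems):
                j = int(rng.integers(i))  # resprout from an earlier stem
                sp_idx[i] = sp_idx[j]
                x[i] = _reflect(np.array([x[j] + rng.normal(0, scenario.dispersal_sigma)]))[0]
                y[i] = _reflect(np.array([y[j] + rng.normal(0, scenario.dispersal_sigma)]))[0]

        frames.append(
            pd.DataFrame(
                {
                    "stem_id": [f"{plot}-{i}" for i in range(n_stems)],
                    "species": np.asarray(species, dtype=object)[sp_idx],
                    "plot_id": plot,
                    "regime": regime,
                    "x": x,
                    "y": y,
                    "dbh": _truncated_exp_dbh(rng, n_stems),
                }
            )
        )
    return StemTable(pd.concat(frames, ignore_index=True))


def simulate_dataset(scenario: AssemblyScenario, grains: Sequence[int] = (10, 20)) -> SyntheticDataset:
    """Generate a full dataset from a scenario (deterministic in the seed)."""
    ss = np.random.SeedSequence(int(scenario.seed))
    s_tree, s_traits, s_hab, s_layout = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(4)]
    phy = simulate_tree(scenario.n_species, seed=s_tree)
    traits = simulate_traits(phy, scenario.trait_signal_w, seed=s_traits)
    plots = plot_layout(scenario.n_regimes, scenario.n_plots_per_regime, seed=s_layout)
    habitat = simulate_habitat(
        n_plots=scenario.n_plots,
        grains=grains,
        regime_heterogeneity=scenario.regime_heterogeneity,
        seed=s_hab,
        plot_regimes=list(plots.data["regime"]),
    )
    stems = assemble_census(scenario, phy, traits, habitat, plots)
    return SyntheticDataset(stems, phy, traits, habitat, plots, scenario)
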