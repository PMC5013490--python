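"""Domain types and on-disk formats for stem-mapped forest census analysis.

All tabular formats are UTF-8 tab-separated text with a mandatory header row
and ``.`` as decimal separator; phylogenies are newick.  The census convention
is a 100 x 100 m plot with half-open coordinates in ``[0, 100)`` per axis and
a dbh census threshold of 1 cm.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

PLOT_SIZE = 100.0
TRAIT_NAMES = ("SLA", "LA", "WD", "LPC", "LNC", "MH")
REGIME_LABELS = {1: "twice-cut", 2: "once-cut", 3: "old-growth"}
#: dbh size classes in cm, half-open on the left, used throughout the analysis.
SIZE_CLASSES = {"1-5": (1.0, 5.0), "5-10": (5.0, 10.0), ">10": (10.0, np.inf)}

STEM_COLUMNS = ["stem_id", "species", "plot_id", "regime", "x", "y", "dbh"]
HABITAT_COLUMNS = [
    "subplot_id",
    "plot_id",
    "grain",
    "row",
    "col",
    "mean_elevation",
    "convexity",
    "slope",
    "aspect",
]


class FormatError(ValueError):
    """A file does not conform to the expected on-disk layout."""


class ValidationError(ValueError):
    """Parsed data violates a domain invariant."""


# ---------------------------------------------------------------------------
# StemTable
# ---------------------------------------------------------------------------


@dataclass
class StemTable:
    """Stem-mapped census: one row per stem with species, location and dbh.

    Coordinates are metres within the 100 x 100 m plot, half-open ``[0, 100)``.
    ``regime`` codes the disturbance chronosequence: 1 = twice-cut (~20 yr),
    2 = once-cut (~50 yr), 3 = old-growth (>100 yr).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in STEM_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"stem table missing required columns: {missing}")
        self.data = self.data.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        df = self.data
        bad_dbh = df.index[~(df["dbh"] >= 1.0)].tolist()
        if bad_dbh:
            raise ValidationError(
                f"dbh below the 1 cm census threshold (or non-positive) in rows {bad_dbh[:10]}"
            )
        in_bounds = (
            (df["x"] >= 0.0)
            & (df["x"] < PLOT_SIZE)
            & (df["y"] >= 0.0)
            & (df["y"] < PLOT_SIZE)
        )
        bad_xy = df.index[~in_bounds].tolist()
        if bad_xy:
            raise ValidationError(
                f"coordinates outside the half-open [0, {PLOT_SIZE:g}) plot bounds "
                f"in rows {bad_xy[:10]}"
            )
        if not df["regime"].isin(REGIME_LABELS).all():
            raise ValidationError("regime must be coded 1, 2 or 3")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def species(self) -> list[str]:
        return sorted(self.data["species"].unique())

    @property
    def plot_ids(self) -> list:
        return sorted(self.data["plot_id"].unique())

    def check_cross_references(
        self, phylogeny: "Phylogeny | None" = None, traits: "TraitTable | None" = None
    ) -> None:
        """Every census species must have a phylogeny tip and a trait row."""
        sp = set(self.data["species"])
        if phylogeny is not None:
            missing = sp - set(phylogeny.tip_labels)
            if missing:
                raise ValidationError(f"species missing from phylogeny: {sorted(missing)[:10]}")
        if traits is not None:
            missing = sp - set(traits.data.index)
            if missing:
                raise ValidationError(f"species missing from trait table: {sorted(missing)[:10]}")


def read_stem_table(path: str | Path) -> StemTable:
    df = pd.read_csv(path, sep="\t")
    return StemTable(df)


def write_stem_table(stems: StemTable, path: str | Path) -> None:
    stems.data.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------


@dataclass
class Phylogeny:
    """Rooted tree with species-coded tips and nonnegative branch lengths.

    Intended to be ultrametric (equal root-to-tip depths); departures beyond
    a relative tolerance of 1e-6 are recorded in :attr:`ultrametric_deviation`
    and warned about at read time, not rejected.
    """

    tree: dendropy.Tree
    ultrametric_tol: float = 1e-6
    ultrametric_deviation: float = field(init=False, default=0.0)

    def __post_init__(self) -> None:
        labels = self.tip_labels
        if len(labels) != len(set(labels)):
            dupes = sorted({t for t in labels if labels.count(t) > 1})
            raise ValidationError(f"duplicate tip labels: {dupes}")
        for e in self.tree.edges():
            if e.length is not None and e.length < 0:
                raise ValidationError("negative branch length")
        depths = np.asarray(self.tip_depths())
        depth = depths.max()
        self.ultrametric_deviation = float((depth - depths.min()) / depth) if depth > 0 else 0.0

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def tip_depths(self) -> list[float]:
        return [leaf.distance_from_root() for leaf in self.tree.leaf_node_iter()]

    @property
    def depth(self) -> float:
        return max(self.tip_depths())

    @property
    def is_ultrametric(self) -> bool:
        return self.ultrametric_deviation <= self.ultrametric_tol

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


def read_phylogeny(path: str | Path) -> Phylogeny:
    """Read a newick phylogeny; warn (do not fail) if not ultrametric."""
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick")
    except Exception as exc:  # dendropy raises assorted parse errors
        raise FormatError(f"unparseable newick file {path}: {exc}") from exc
    phy = Phylogeny(tree)
    if not phy.is_ultrametric:
        warnings.warn(
            f"phylogeny in {path} is not ultrametric "
            f"(relative root-to-tip depth spread {phy.ultrametric_deviation:.3g} "
            f"> tolerance {phy.ultrametric_tol:g})",
            stacklevel=2,
        )
    return phy


def phylogeny_from_newick(newick: str) -> Phylogeny:
    try:
        tree = dendropy.Tree.get(data=newick, schema="newick")
    except Exception as exc:
        raise FormatError(f"unparseable newick string: {exc}") from exc
    return Phylogeny(tree)


def write_phylogeny(phy: Phylogeny, path: str | Path) -> None:
    Path(path).write_text(phy.as_newick() + "\n")


# ---------------------------------------------------------------------------
# TraitTable
# ---------------------------------------------------------------------------


@dataclass
class TraitTable:
    """Species-level means of six functional traits.

    SLA (mm^2/mg), LA (cm^2), WD (g/cm^3), LPC (mg/g), LNC (mg/g), MH (m).
    All values must be finite and strictly positive so the log transform used
    for standardization is defined.
    """

    data: pd.DataFrame  # index = species code, columns = TRAIT_NAMES

    def __post_init__(self) -> None:
        missing = [c for c in TRAIT_NAMES if c not in self.data.columns]
        if missing:
            raise FormatError(f"trait table missing traits: {missing}")
        self.data = self.data[list(TRAIT_NAMES)].astype(float)
        self.data.index.name = "species"
        vals = self.data.to_numpy()
        if not np.all(np.isfinite(vals)) or not np.all(vals > 0):
            bad = self.data.index[~(np.isfinite(vals).all(axis=1) & (vals > 0).all(axis=1))]
            raise ValidationError(
                f"non-finite or non-positive trait values for species {list(bad[:10])}"
            )

    @property
    def species(self) -> list[str]:
        return list(self.data.index)


def read_trait_table(path: str | Path) -> TraitTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return TraitTable(df)


def write_trait_table(traits: TraitTable, path: str | Path) -> None:
    traits.data.to_csv(path, sep="\t", index_label="species")


# ---------------------------------------------------------------------------
# Habitat and plot layout
# ---------------------------------------------------------------------------


@dataclass
class HabitatTable:
    """Topographic habitat descriptors, one record per subplot per grain.

    mean_elevation (m), convexity (m), slope (degrees), aspect (degrees in
    [0, 360), interpreted circularly downstream).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in HABITAT_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"habitat table missing columns: {missing}")
        self.data = self.data.reset_index(drop=True)
        asp = self.data["aspect"]
        if ((asp < 0) | (asp >= 360)).any():
            raise ValidationError("aspect must lie in [0, 360)")
        if self.data.duplicated(["subplot_id"]).any():
            raise ValidationError("duplicate subplot records in habitat table")


def read_habitat_table(path: str | Path) -> HabitatTable:
    return HabitatTable(pd.read_csv(path, sep="\t"))


def write_habitat_table(habitat: HabitatTable, path: str | Path) -> None:
    habitat.data.to_csv(path, sep="\t", index=False)


@dataclass
class PlotTable:
    """Plot-level layout: disturbance regime and plot origin in a shared
    reserve coordinate frame (metres), so between-plot subplot distances are
    well defined."""

    data: pd.DataFrame  # columns plot_id, regime, origin_x, origin_y

    def __post_init__(self) -> None:
        req = ["plot_id", "regime", "origin_x", "origin_y"]
        missing = [c for c in req if c not in self.data.columns]
        if missing:
            raise FormatError(f"plot table missing columns: {missing}")
        self.data = self.data.reset_index(drop=True)

    def regime_of(self, plot_id) -> int:
        row = self.data.loc[self.data["plot_id"] == plot_id]
        if row.empty:
            raise ValidationError(f"unknown plot {plot_id}")
        return int(row["regime"].iloc[0])


def read_plot_table(path: str | Path) -> PlotTable:
    return PlotTable(pd.read_csv(path, sep="\t"))


def write_plot_table(plots: PlotTable, path: str | Path) -> None:
    plots.data.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# CommunityMatrix
# ---------------------------------------------------------------------------


def subplot_id(plot_id, grain: int, row: int, col: int) -> str:
    return f"{plot_id}:g{grain}:{row}:{col}"


@dataclass
class CommunityMatrix:
    """Subplot x species abundance counts with subplot metadata.

    ``counts`` is indexed by subplot id with species columns; ``meta`` carries
    plot id, regime, grain, grid row/col, centroid x/y in the plot frame and
    an ``empty`` flag.  Empty subplots are retained (all-zero rows) but must
    be excluded from pairwise dissimilarity by the caller.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.meta.index):
            raise ValidationError("counts and meta must share the subplot index")
        arr = self.counts.to_numpy()
        if (arr < 0).any() or not np.issubdtype(arr.dtype, np.integer):
            raise ValidationError("counts must be nonnegative integers")

    @property
    def species(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_subplots(self) -> int:
        return len(self.counts)

    def total_stems(self) -> int:
        return int(self.counts.to_numpy().sum())

    def relative_abundances(self) -> pd.DataFrame:
        """Row-normalised relative abundances f_ik; empty rows stay zero."""
        arr = self.counts.to_numpy(dtype=float)
        sums = arr.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(sums > 0, arr / sums, 0.0)
        return pd.DataFrame(f, index=self.counts.index, columns=self.counts.columns)

    def nonempty(self) -> "CommunityMatrix":
        keep = ~self.meta["empty"].to_numpy()
        return CommunityMatrix(self.counts.loc[keep], self.meta.loc[keep])


def grid_stems(
    stems: StemTable,
    grain: int,
    size_class: tuple[float, float] | str | None = None,
    species: Sequence[str] | None = None,
) -> CommunityMatrix:
    """Aggregate stems into a grid of square subplots of side ``grain`` metres.

    The standard analysis grains are 10 and 20 m; any divisor of the plot side
    is accepted.  ``size_class`` is a half-open dbh interval ``[lo, hi)`` in cm
    (or a key of :data:`SIZE_CLASSES`) applied *before* gridding.  Every grid
    cell of every plot appears in the output, including empty cells, which are
    flagged in ``meta['empty']``.
    """
    if PLOT_SIZE % grain != 0:
        raise ValueError(f"grain {grain} must divide the plot side {PLOT_SIZE:g}")
    ncell = int(PLOT_SIZE // grain)

    df = stems.data
    if isinstance(size_class, str):
        size_class = SIZE_CLASSES[size_class]
    if size_class is not None:
        lo, hi = size_class
        df = df[(df["dbh"] >= lo) & (df["dbh"] < hi)]

    if species is None:
        species = sorted(stems.data["species"].unique())
    species = list(species)
    sp_index = {s: i for i, s in enumerate(species)}

    plot_info = (
        stems.data.groupby("plot_id")["regime"].first().sort_index()
    )  # all plots, even if empty after filtering

    rows_meta = []
    index = []
    for plot_id, regime in plot_info.items():
        for r in range(ncell):
            for c in range(ncell):
                index.append(subplot_id(plot_id, grain, r, c))
                rows_meta.append(
                    {
                        "plot_id": plot_id,
                        "regime": int(regime),
                        "grain": grain,
                        "row": r,
                        "col": c,
                        "cx": (c + 0.5) * grain,
                        "cy": (r + 0.5) * grain,
                    }
                )
    meta = pd.DataFrame(rows_meta, index=index)
    counts = np.zeros((len(index), len(species)), dtype=np.int64)
    pos = {sid: i for i, sid in enumerate(index)}

    if len(df):
        rr = np.floor(df["y"].to_numpy() / grain).astype(int)
        cc = np.floor(df["x"].to_numpy() / grain).astype(int)
        for plot_id, r, c, sp in zip(df["plot_id"], rr, cc, df["species"]):
            counts[pos[subplot_id(plot_id, grain, r, c)], sp_index[sp]] += 1

    counts_df = pd.DataFrame(counts, index=index, columns=species)
    meta["empty"] = counts_df.sum(axis=1).to_numpy() == 0
    return CommunityMatrix(counts_df, meta)


def read_community_matrix(counts_path: str | Path, meta_path: str | Path) -> CommunityMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    meta["empty"] = meta["empty"].astype(bool)
    return CommunityMatrix(counts.astype(np.int64), meta)


def write_community_matrix(cm: CommunityMatrix, counts_path: str | Path, meta_path: str | Path) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="subplot_id")
    cm.meta.to_csv(meta_path, sep="\t", index_label="subplot_id")
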