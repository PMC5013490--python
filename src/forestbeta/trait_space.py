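"""Functional and phylogenetic distance matrices between species.

Functional distances follow the dendrogram route: per-trait UPGMA
(average-linkage) clustering on Euclidean distances, and a composite
all-traits distance built from PCA axes of the log-transformed, standardized
trait table.  The distance delivered downstream is the cophenetic distance on
the dendrogram — the average-linkage merge distance of the pair's first
common cluster — which is ultrametric by construction.  Raw (pre-dendrogram)
Euclidean distances are available behind ``distance="raw"`` for sensitivity
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from forestbeta.data_io import Phylogeny, TraitTable, ValidationError


@dataclass
class DistanceMatrix:
    """Symmetric species x species distances with an explicit label order.

    ``source`` records provenance: ``phylogeny-cophenetic``, ``trait:<name>``
    or ``traits:all``.
    """

    labels: list[str]
    values: np.ndarray
    source: str = "unknown"

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValidationError(f"distance matrix shape {v.shape} != ({n}, {n})")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("distance matrix not symmetric")
        if (v < 0).any():
            raise ValidationError("negative distances")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValidationError("nonzero diagonal")
        v = (v + v.T) / 2.0
        np.fill_diagonal(v, 0.0)
        self.values = v

    @property
    def n(self) -> int:
        return len(self.labels)

    def reindex(self, labels) -> "DistanceMatrix":
        """Reorder/subset to ``labels`` (all must be present)."""
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)], self.source)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="species")

    @classmethod
    def read(cls, path, source: str = "unknown") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), df.to_numpy(), source)


def standardize_traits(traits: TraitTable, on_constant: str = "error") -> pd.DataFrame:
    """Natural-log transform, then per-trait z-score across species.

    Trait values are physical magnitudes (> 0, enforced by
    :class:`~forestbeta.data_io.TraitTable`), so the log is always defined.
    A zero-variance column is an error by default; ``on_constant="zero"``
    maps it to all-zero scores instead.
    """
    logged = np.log(traits.data)
    mu = logged.mean(axis=0)
    sd = logged.std(axis=0, ddof=1) if len(logged) > 1 else logged.std(axis=0)
    z = logged.copy()
    for col in logged.columns:
        if not np.isfinite(sd[col]) or sd[col] == 0:
            if on_constant == "zero":
                z[col] = 0.0
                continue
            raise ValidationError(f"trait {col!r} has zero variance across species")
        z[col] = (logged[col] - mu[col]) / sd[col]
    return z


def _upgma(values: np.ndarray) -> np.ndarray:
    """Average-linkage linkage matrix on Euclidean distances."""
    if values.ndim == 1:
        values = values[:, None]
    if len(values) < 2:
        raise ValidationError("dendrogram needs at least 2 species")
    dvec = pdist(values, metric="euclidean")
    return hierarchy.linkage(dvec, method="average")


def _cophenetic(linkage: np.ndarray) -> np.ndarray:
    return squareform(hierarchy.cophenet(linkage))


def linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Export a linkage matrix as an ultrametric newick string.

    Node heights are half the merge distance, so tip-to-tip path lengths on
    the exported tree equal the cophenetic distances.
    """
    n = len(labels)
    height = {i: 0.0 for i in range(n)}
    rep = {i: labels[i] for i in range(n)}
    for k, (a, b, dist, _) in enumerate(linkage):
        a, b = int(a), int(b)
        h = dist / 2.0
        left = f"{rep[a]}:{h - height[a]:.10g}"
        right = f"{rep[b]}:{h - height[b]:.10g}"
        node = n + k
        rep[node] = f"({left},{right})"
        height[node] = h
    return rep[n + len(linkage) - 1] + ";"


def trait_dendrogram(
    values: pd.Series | pd.DataFrame, source: str = "trait:unnamed"
) -> tuple[np.ndarray, DistanceMatrix]:
    """UPGMA dendrogram on per-species values (scalar or vector per species).

    Returns the scipy linkage matrix and the cophenetic
    :class:`DistanceMatrix`.  scipy's deterministic nearest-pair ordering
    resolves merge-height ties, so output is platform-stable.
    """
    if isinstance(values, pd.Series):
        labels = list(values.index)
        arr = values.to_numpy(dtype=float)[:, None]
    else:
        labels = list(values.index)
        arr = values.to_numpy(dtype=float)
    link = _upgma(arr)
    return link, DistanceMatrix(labels, _cophenetic(link), source)


def pca_scores(z: pd.DataFrame, drop_tol: float = 1e-12) -> pd.DataFrame:
    """Scores on all PCA axes of a standardized trait table.

    All axes with non-negligible variance are retained; zero-variance axes of
    a rank-deficient table are dropped.  Because the rotation is orthogonal,
    Euclidean distances between the retained scores equal those between the
    standardized traits themselves.
    """
    centered = z - z.mean(axis=0)
    u, s, _ = np.linalg.svd(centered.to_numpy(), full_matrices=False)
    keep = s > drop_tol * max(s.max(), 1.0)
    scores = u[:, keep] * s[keep]
    return pd.DataFrame(scores, index=z.index, columns=[f"PC{i+1}" for i in range(keep.sum())])


def composite_trait_distance(
    traits: TraitTable, distance: str = "cophenetic"
) -> tuple[np.ndarray, DistanceMatrix]:
    """All-traits functional distance: PCA of standardized traits, Euclidean
    distance over all retained axes, UPGMA dendrogram, cophenetic output.

    ``distance="raw"`` skips the dendrogram and returns the Euclidean
    distances in PCA space directly (the linkage matrix is still returned for
    inspection).
    """
    if len(traits.species) < 3:
        raise ValidationError("composite trait distance needs at least 3 species")
    z = standardize_traits(traits)
    scores = pca_scores(z)
    link = _upgma(scores.to_numpy())
    if distance == "raw":
        vals = squareform(pdist(scores.to_numpy()))
        return link, DistanceMatrix(list(scores.index), vals, "traits:all")
    return link, DistanceMatrix(list(scores.index), _cophenetic(link), "traits:all")


def per_trait_distances(
    traits: TraitTable, distance: str = "cophenetic"
) -> dict[str, DistanceMatrix]:
    """Cophenetic (or raw Euclidean) distance matrix for each single trait,
    computed on the log-standardized values."""
    z = standardize_traits(traits)
    out: dict[str, DistanceMatrix] = {}
    for trait in z.columns:
        if distance == "raw":
            vals = squareform(pdist(z[trait].to_numpy()[:, None]))
            out[trait] = DistanceMatrix(list(z.index), vals, f"trait:{trait}")
        else:
            _, dm = trait_dendrogram(z[trait], source=f"trait:{trait}")
            out[trait] = dm
    return out


def phylo_cophenetic_distance(phy: Phylogeny) -> DistanceMatrix:
    """Patristic (cophenetic) distances between tips of the phylogeny."""
    pdm = phy.tree.phylogenetic_distance_matrix()
    taxa = sorted(phy.tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[i], taxa[j])
            vals[i, j] = vals[j, i] = d
    return DistanceMatrix(labels, vals, "phylogeny-cophenetic")
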