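"""Pairwise turnover statistics between subplot communities.

Three statistics per subplot pair:

* **Chao-Jaccard dissimilarity** — abundance-based Jaccard-type index with
  the Chao correction for unseen shared species (singleton/doubleton
  frequencies of shared species).
* **B_st** — abundance-weighted phylogenetic turnover,
  ``1 - ((D_kk + D_ll)/2) / D_kl`` where D terms are mean pairwise
  phylogenetic distances between/within communities.
* **tau_st** — the same statistic on a functional distance matrix (composite
  or per-trait).

The default D_kl normalization is *species-centered*: the mean distance
between two individuals drawn from the two communities conditional on their
being different species, ``sum_{i!=j} d_ij f_ik f_jl / sum_{i!=j} f_ik f_jl``.
The unnormalized ``raw`` variant (plain abundance-weighted mean over all
ordered pairs) is available for sensitivity analysis.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd

from forestbeta.data_io import CommunityMatrix, HabitatTable, PlotTable, ValidationError
from forestbeta.trait_space import DistanceMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Chao-Jaccard
# ---------------------------------------------------------------------------


def chao_jaccard_dissimilarity(x, y) -> float:
    """Abundance-based Chao-Jaccard dissimilarity between two count vectors.

    ``U`` estimates the total relative abundance in sample 1 of the species
    shared with sample 2 (including unseen shared species, via the shared
    singletons/doubletons of sample 2), ``V`` symmetrically; similarity is
    ``UV / (U + V - UV)`` and the dissimilarity its complement.  Communities
    with no shared species have dissimilarity 1; empty samples are an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("count vectors must share the species order")
    n, m = x.sum(), y.sum()
    if n <= 0 or m <= 0:
        raise ValidationError("empty sample: Chao-Jaccard undefined")
    shared = (x > 0) & (y > 0)
    if not shared.any():
        return 1.0

    def _u(a, na, b, nb):
        # estimated shared-species abundance share of sample a, corrected by
        # shared species that are singletons/doubletons in sample b
        f1 = np.count_nonzero(shared & (b == 1))
        f2 = np.count_nonzero(shared & (b == 2))
        f2 = f2 if f2 > 0 else 1
        base = a[shared].sum() / na
        corr = ((nb - 1) / nb) * (f1 / (2 * f2)) * a[shared & (b == 1)].sum() / na
        return min(1.0, base + corr)

    U = _u(x, n, y, m)
    V = _u(y, m, x, n)
    if U == 0 or V == 0:  # unreachable when species are shared, kept defensive
        return 1.0
    sim = U * V / (U + V - U * V)
    return float(1.0 - sim)


# ---------------------------------------------------------------------------
# Abundance-weighted mean pairwise distances and B_st / tau_st
# ---------------------------------------------------------------------------


def _check_f(f, D: DistanceMatrix) -> np.ndarray:
    if isinstance(f, pd.Series):
        if list(f.index) != list(D.labels):
            raise ValidationError("relative-abundance labels do not match the distance matrix")
        f = f.to_numpy(dtype=float)
    f = np.asarray(f, dtype=float)
    if f.shape != (D.n,):
        raise ValidationError("abundance vector length does not match the distance matrix")
    if f.sum() <= 0:
        raise ValidationError("empty community")
    return f / f.sum()


def mean_pairwise_between(
    f_k, f_l, D: DistanceMatrix, variant: str = "species-centered"
) -> tuple[float, bool]:
    """Mean abundance-weighted distance D_kl between two communities.

    Returns ``(value, degenerate)``; degenerate means the conditioning weight
    was zero (both communities monospecific on the same species), in which
    case D_kl is reported as 0.
    """
    fk = _check_f(f_k, D)
    fl = _check_f(f_l, D)
    num = float(fk @ D.values @ fl)
    if variant == "raw":
        return num, False
    w = 1.0 - float(fk @ fl)
    if w <= 0:
        return 0.0, True
    return num / w, False


def mean_pairwise_within(f_k, D: DistanceMatrix, variant: str = "species-centered") -> tuple[float, bool]:
    """Mean abundance-weighted distance D_kk within one community.

    Monospecific communities are degenerate (no distinct-species pair) and
    report 0 with the flag set.
    """
    return mean_pairwise_between(f_k, f_k, D, variant=variant)


def bst_pair(f_k, f_l, D: DistanceMatrix, variant: str = "species-centered") -> float:
    """B_st (or tau_st with a functional D): ``1 - mean(within)/between``.

    Pairs with D_kl = 0 — identical monocultures — are undefined and return
    NaN; callers exclude them with a logged count.
    """
    dkl, _ = mean_pairwise_between(f_k, f_l, D, variant=variant)
    dkk, _ = mean_pairwise_within(f_k, D, variant=variant)
    dll, _ = mean_pairwise_within(f_l, D, variant=variant)
    if dkl == 0.0:
        return float("nan")
    return 1.0 - ((dkk + dll) / 2.0) / dkl


def pairwise_stats(
    F: np.ndarray, D: np.ndarray, ki: np.ndarray, li: np.ndarray, variant: str = "species-centered"
) -> dict[str, np.ndarray]:
    """Vectorized D_kl, D_kk, D_ll and B_st for an index set of pairs.

    ``F`` is the subplot x species relative-abundance matrix (rows sum to 1),
    ``D`` the species distance matrix in the same species order, ``ki``/``li``
    the row indices of each pair.  NaN marks pairs with D_kl = 0.
    """
    M = F @ D @ F.T  # unnormalized cross means
    S = F @ F.T  # probability both draws are the same species
    if variant == "raw":
        dcross = M
        dwithin = np.diag(M).copy()
    else:
        W = 1.0 - S
        with np.errstate(invalid="ignore", divide="ignore"):
            dcross = np.where(W > 1e-12, M / np.where(W > 1e-12, W, 1.0), 0.0)
        dwithin = np.diag(dcross).copy()
    dkl = dcross[ki, li]
    dkk = dwithin[ki]
    dll = dwithin[li]
    with np.errstate(invalid="ignore", divide="ignore"):
        bst = np.where(dkl > 0, 1.0 - ((dkk + dll) / 2.0) / np.where(dkl > 0, dkl, 1.0), np.nan)
    return {"d_kl": dkl, "d_kk": dkk, "d_ll": dll, "bst": bst}


# ---------------------------------------------------------------------------
# Pair enumeration and the full pair table
# ---------------------------------------------------------------------------


def enumerate_pairs(meta: pd.DataFrame, level: str) -> tuple[np.ndarray, np.ndarray]:
    """Row-index pairs at a level: ``within`` = unordered subplot pairs inside
    each plot; ``between`` = subplot pairs spanning two different plots of the
    same disturbance regime."""
    ki: list[int] = []
    li: list[int] = []
    pos = np.arange(len(meta))
    if level == "within":
        for _, idx in meta.groupby("plot_id", sort=True).indices.items():
            idx = np.sort(idx)
            for a, b in itertools.combinations(idx, 2):
                ki.append(a)
                li.append(b)
    elif level == "between":
        for _, sub in meta.groupby("regime", sort=True):
            plots = sorted(sub["plot_id"].unique())
            for pa, pb in itertools.combinations(plots, 2):
                ia = pos[(meta["plot_id"] == pa).to_numpy()]
                ib = pos[(meta["plot_id"] == pb).to_numpy()]
                for a in ia:
                    for b in ib:
                        ki.append(a)
                        li.append(b)
    else:
        raise ValueError(f"unknown level {level!r}")
    return np.asarray(ki, dtype=int), np.asarray(li, dtype=int)


def pair_table(
    cm: CommunityMatrix,
    Dphy: DistanceMatrix | None = None,
    Dfun_all: DistanceMatrix | None = None,
    Dfun_per_trait: dict[str, DistanceMatrix] | None = None,
    habitat: HabitatTable | None = None,
    plots: PlotTable | None = None,
    level: str = "within",
    size_class: str = "all",
    variant: str = "species-centered",
) -> pd.DataFrame:
    """One row per subplot pair with all turnover statistics and covariates.

    Empty subplots are excluded before pairing; relative abundances are
    recomputed from the (size-class-filtered) counts of this matrix.  The
    returned frame's ``attrs['excluded_pairs']`` counts pairs whose B_st or
    tau_st was undefined (D_kl = 0).
    """
    nz = cm.nonempty()
    meta = nz.meta
    ki, li = enumerate_pairs(meta, level)
    F = nz.relative_abundances().to_numpy()
    species = nz.species

    sub_ids = np.asarray(nz.counts.index)
    out = pd.DataFrame(
        {
            "k": sub_ids[ki],
            "l": sub_ids[li],
            "level": level,
            "plot_k": meta["plot_id"].to_numpy()[ki],
            "plot_l": meta["plot_id"].to_numpy()[li],
            "regime": meta["regime"].to_numpy()[ki],
            "grain": meta["grain"].to_numpy()[ki],
            "size_class": size_class,
        }
    )
    if level == "within":
        out["group"] = out["plot_k"].astype(str)
    else:
        out["group"] = [
            "|".join(sorted((str(a), str(b)))) for a, b in zip(out["plot_k"], out["plot_l"])
        ]

    # species dissimilarity (abundance-based, unaffected by any label shuffle)
    counts = nz.counts.to_numpy()
    cj = np.empty(len(ki))
    for r, (a, b) in enumerate(zip(ki, li)):
        cj[r] = chao_jaccard_dissimilarity(counts[a], counts[b])
    out["cj_dissim"] = cj

    excluded: dict[str, int] = {}
    if Dphy is not None:
        stats = pairwise_stats(F, Dphy.reindex(species).values, ki, li, variant)
        out["d_kl"] = stats["d_kl"]
        out["d_kk"] = stats["d_kk"]
        out["d_ll"] = stats["d_ll"]
        out["bst"] = stats["bst"]
        excluded["bst"] = int(np.isnan(stats["bst"]).sum())
    if Dfun_all is not None:
        stats = pairwise_stats(F, Dfun_all.reindex(species).values, ki, li, variant)
        out["tau_all"] = stats["bst"]
        excluded["tau_all"] = int(np.isnan(stats["bst"]).sum())
    for trait, dm in (Dfun_per_trait or {}).items():
        stats = pairwise_stats(F, dm.reindex(species).values, ki, li, variant)
        out[f"tau_{trait}"] = stats["bst"]
        excluded[f"tau_{trait}"] = int(np.isnan(stats["bst"]).sum())

    if habitat is not None:
        from forestbeta.inference import habitat_coordinates

        coords = habitat_coordinates(habitat)
        hc = coords.reindex(nz.counts.index).to_numpy()
        if np.isnan(hc).any():
            raise ValidationError("habitat table does not cover all subplots")
        out["habitat_distance"] = np.linalg.norm(hc[ki] - hc[li], axis=1)

    if plots is not None:
        origins = plots.data.set_index("plot_id")[["origin_x", "origin_y"]]
        ox = origins["origin_x"].reindex(meta["plot_id"]).to_numpy()
        oy = origins["origin_y"].reindex(meta["plot_id"]).to_numpy()
        gx = ox + meta["cx"].to_numpy()
        gy = oy + meta["cy"].to_numpy()
        out["spatial_distance"] = np.hypot(gx[ki] - gx[li], gy[ki] - gy[li])
        out["mid_x"] = (gx[ki] + gx[li]) / 2.0
        out["mid_y"] = (gy[ki] + gy[li]) / 2.0

    if habitat is not None:
        elev = habitat.data.set_index("subplot_id")["mean_elevation"]
        plot_elev = (
            habitat.data.groupby("plot_id")["mean_elevation"].mean()
        )
        ek = plot_elev.reindex(meta["plot_id"]).to_numpy()
        out["plot_mean_elev"] = (ek[ki] + ek[li]) / 2.0
        out["plot_elev_absdiff"] = np.abs(ek[ki] - ek[li])
        _ = elev  # subplot-level elevations live in habitat_distance

    n_excl = {k: v for k, v in excluded.items() if v}
    if n_excl:
        logger.warning("pairs with undefined turnover excluded downstream: %s", n_excl)
    out.attrs["excluded_pairs"] = excluded
    out.attrs["variant"] = variant
    return out
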