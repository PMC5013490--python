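"""Tip-label randomization null model and permutation envelopes.

The null model shuffles species names across the tips of the phylogeny (or
functional dendrogram) — equivalently, applies one label permutation jointly
to the rows and columns of the species distance matrix — while community
composition stays fixed.  Species abundance, richness and species beta
diversity are therefore preserved exactly; only phylogenetic/functional
relatedness is randomized.  One shared permutation is used per replicate
across all pairs, preserving the cross-pair correlation structure of the
null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from forestbeta.beta_diversity import pairwise_stats
from forestbeta.data_io import CommunityMatrix, ValidationError
from forestbeta.trait_space import DistanceMatrix


def shuffle_labels(D: DistanceMatrix, rng: np.random.Generator) -> DistanceMatrix:
    """Randomly permute which species carries which row/column of ``D``.

    The label vector is unchanged; the distance values are moved, so the
    multiset of off-diagonal distances is conserved.
    """
    perm = rng.permutation(D.n)
    return DistanceMatrix(D.labels, D.values[np.ix_(perm, perm)], D.source + ":shuffled")


@dataclass
class NullEnvelope:
    """Permutation-envelope summary for one statistic in one grouping cell.

    ``ci`` holds the empirical 2.5/97.5 percentiles of the null grouping
    means; SES is (observed - null mean)/null sd; ``p_rank`` is the
    upper-tail rank p-value ``(#{null >= obs} + 1)/(n_reps + 1)``.
    """

    statistic: str
    grouping: tuple
    observed: float
    null_means: np.ndarray
    ci: tuple[float, float]
    ses: float
    p_rank: float
    n_reps: int

    @property
    def inside(self) -> bool:
        return self.ci[0] <= self.observed <= self.ci[1]


def _group_means(values: np.ndarray, codes: np.ndarray, n_groups: int) -> np.ndarray:
    """Mean of ``values`` per group code, ignoring NaN."""
    ok = ~np.isnan(values)
    sums = np.bincount(codes[ok], weights=values[ok], minlength=n_groups)
    cnts = np.bincount(codes[ok], minlength=n_groups)
    with np.errstate(invalid="ignore"):
        return np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)


def null_envelope(
    cm: CommunityMatrix,
    D: DistanceMatrix,
    pairs: pd.DataFrame,
    statistic: str = "bst",
    group_cols: tuple[str, ...] = ("regime", "level"),
    n_reps: int = 999,
    seed: int | None = None,
    percentiles: tuple[float, float] = (2.5, 97.5),
    variant: str = "species-centered",
) -> list[NullEnvelope]:
    """Tip-shuffle envelopes for grouping means of B_st (or tau_st).

    ``pairs`` must have been built from ``cm`` (columns ``k``/``l`` index its
    subplots and carry the observed statistic).  For each of ``n_reps``
    replicates one label permutation of ``D`` is applied and the statistic is
    recomputed for every pair; envelopes summarise the distribution of the
    grouping means.  The community matrix itself is never touched, so
    abundance, richness and Chao-Jaccard dissimilarities are identical across
    replicates by construction.
    """
    if n_reps < 99:
        raise ValidationError("n_reps must be at least 99")
    nz = cm.nonempty()
    index = pd.Index(nz.counts.index)
    ki = index.get_indexer(pairs["k"])
    li = index.get_indexer(pairs["l"])
    if (ki < 0).any() or (li < 0).any():
        raise ValidationError("pair table references subplots absent from the community matrix")
    F = nz.relative_abundances().to_numpy()
    Dm = D.reindex(nz.species).values

    groups = pairs[list(group_cols)].apply(tuple, axis=1)
    group_keys, codes = np.unique(groups.to_numpy(dtype=object), return_inverse=True)
    n_groups = len(group_keys)

    observed = _group_means(pairs[statistic].to_numpy(dtype=float), codes, n_groups)

    master = np.random.SeedSequence(seed)
    children = master.spawn(n_reps)
    null = np.empty((n_reps, n_groups))
    for r in range(n_reps):
        rng = np.random.default_rng(children[r])
        perm = rng.permutation(len(nz.species))
        Dr = Dm[np.ix_(perm, perm)]
        stats = pairwise_stats(F, Dr, ki, li, variant=variant)
        null[r] = _group_means(stats["bst"], codes, n_groups)

    out = []
    for g in range(n_groups):
        col = null[:, g]
        lo, hi = np.percentile(col, percentiles)
        sd = col.std(ddof=1)
        ses = (observed[g] - col.mean()) / sd if sd > 0 else float("nan")
        p = (np.count_nonzero(col >= observed[g]) + 1) / (n_reps + 1)
        out.append(
            NullEnvelope(
                statistic=statistic,
                grouping=tuple(group_keys[g]),
                observed=float(observed[g]),
                null_means=col,
                ci=(float(lo), float(hi)),
                ses=float(ses),
                p_rank=float(p),
                n_reps=n_reps,
            )
        )
    return out


def envelope_table(envelopes: list[NullEnvelope], group_cols: tuple[str, ...] = ("regime", "level")) -> pd.DataFrame:
    rows = []
    for e in envelopes:
        row = dict(zip(group_cols, e.grouping))
        row.update(
            statistic=e.statistic,
            observed=e.observed,
            null_mean=float(e.null_means.mean()),
            ci_lower=e.ci[0],
            ci_upper=e.ci[1],
            ses=e.ses,
            p_rank=e.p_rank,
            inside=e.inside,
            n_reps=e.n_reps,
        )
        rows.append(row)
    return pd.DataFrame(rows)
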