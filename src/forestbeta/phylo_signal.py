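"""Blomberg's K phylogenetic signal and its tip-shuffle significance test.

K compares the observed ratio of trait variance among tips to the variance
expected under Brownian motion on the given tree.  K = 1 matches Brownian
expectation; K < 1 indicates less phylogenetic signal than Brownian motion,
K > 1 more.  Significance is assessed against a null distribution obtained
by randomly permuting trait values across tips.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from forestbeta.data_io import Phylogeny, TraitTable, ValidationError


def phylo_vcv(phy: Phylogeny) -> tuple[list[str], np.ndarray]:
    """Brownian-motion covariance among tips.

    V_ij is the root-to-MRCA shared path length of tips i and j; V_ii is the
    root-to-tip depth.  Tips are returned in sorted label order.
    """
    tree = phy.tree
    if tree.seed_node is None:
        raise ValidationError("tree has no root")
    leaves = sorted(tree.leaf_node_iter(), key=lambda l: l.taxon.label)
    labels = [l.taxon.label for l in leaves]
    depth = {l.taxon.label: l.distance_from_root() for l in leaves}
    pdm = tree.phylogenetic_distance_matrix()
    n = len(labels)
    V = np.zeros((n, n))
    for i in range(n):
        V[i, i] = depth[labels[i]]
        for j in range(i + 1, n):
            d = pdm.patristic_distance(leaves[i].taxon, leaves[j].taxon)
            # shared path = (depth_i + depth_j - patristic_ij) / 2
            V[i, j] = V[j, i] = (depth[labels[i]] + depth[labels[j]] - d) / 2.0
    return labels, V


class _KEngine:
    """Precomputed quantities for repeated K evaluations on one tree."""

    def __init__(self, V: np.ndarray):
        n = V.shape[0]
        jitter = 0.0
        for _ in range(3):
            try:
                self._cho = cho_factor(V + jitter * np.eye(n), lower=True)
                break
            except np.linalg.LinAlgError:
                jitter = max(jitter * 10, 1e-10 * np.trace(V) / n)
        else:  # pragma: no cover - pathological input
            raise ValidationError("phylogenetic covariance not positive definite")
        self.n = n
        ones = np.ones(n)
        self.Vinv_1 = cho_solve(self._cho, ones)
        self.s_1V1 = float(ones @ self.Vinv_1)
        # expected MSE0/MSE ratio under Brownian motion
        self.expected = (np.trace(V) - n / self.s_1V1) / (n - 1)

    def k(self, x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float)
        a_hat = float(self.Vinv_1 @ x) / self.s_1V1
        r = x - a_hat
        num = float(r @ r)
        den = float(r @ cho_solve(self._cho, r))
        if num == 0.0 or den == 0.0:
            raise ValidationError("constant trait: Blomberg's K undefined")
        return (num / den) / self.expected


def blomberg_k(phy: Phylogeny, x: pd.Series | dict | np.ndarray) -> float:
    """Blomberg's K for one continuous trait.

    ``x`` maps species to values (Series/dict) or is an array already in the
    sorted-tip order of :func:`phylo_vcv`.  The GLS mean uses a Cholesky
    solve of V (jittered if near-singular), never an explicit inverse.
    """
    labels, V = phylo_vcv(phy)
    vec = _align_trait(x, labels)
    return _KEngine(V).k(vec)


def _align_trait(x, labels: list[str]) -> np.ndarray:
    if isinstance(x, pd.Series):
        missing = set(labels) - set(x.index)
        extra = set(x.index) - set(labels)
        if missing or extra:
            raise ValidationError(
                f"trait/tip mismatch: missing {sorted(missing)[:5]}, extra {sorted(extra)[:5]}"
            )
        return x.reindex(labels).to_numpy(dtype=float)
    if isinstance(x, dict):
        return _align_trait(pd.Series(x), labels)
    arr = np.asarray(x, dtype=float)
    if arr.shape != (len(labels),):
        raise ValidationError("trait vector length does not match tip count")
    return arr


@dataclass
class SignalResult:
    """Observed K, its tip-shuffle null distribution and the two-sided 95% CI.

    ``significant`` is one-sided: observed K above the null upper bound
    (more signal than chance).
    """

    trait: str
    k: float
    null_k: np.ndarray
    ci: tuple[float, float]
    significant: bool
    n_perm: int
    p_upper: float = field(default=np.nan)

    def __post_init__(self) -> None:
        if self.ci[0] > self.ci[1]:
            raise ValidationError("CI bounds out of order")


def k_significance(
    phy: Phylogeny,
    x: pd.Series | dict | np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
    trait: str = "trait",
) -> SignalResult:
    """Tip-shuffle significance test for Blomberg's K.

    Trait values are permuted across tips ``n_perm`` times; the empirical
    2.5/97.5 percentiles of the null K form the 95% CI.  At least 99
    permutations are required for the percentiles to be estimable.
    """
    if n_perm < 99:
        raise ValidationError("n_perm must be at least 99")
    labels, V = phylo_vcv(phy)
    vec = _align_trait(x, labels)
    engine = _KEngine(V)
    k_obs = engine.k(vec)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for r in range(n_perm):
        null[r] = engine.k(rng.permutation(vec))
    lo, hi = np.percentile(null, [2.5, 97.5])
    p_upper = (np.count_nonzero(null >= k_obs) + 1) / (n_perm + 1)
    return SignalResult(
        trait=trait,
        k=k_obs,
        null_k=null,
        ci=(float(lo), float(hi)),
        significant=bool(k_obs > hi),
        n_perm=n_perm,
        p_upper=float(p_upper),
    )


def signal_table(
    phy: Phylogeny,
    traits: TraitTable,
    n_perm: int = 999,
    seed: int | None = None,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Per-trait K, CI bounds and significance flags (one row per trait).

    Traits are log-transformed by default before testing, matching the
    standardization used throughout the functional analyses (K itself is
    affine-invariant, so the subsequent z-scoring is immaterial).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for name in traits.data.columns:
        vals = traits.data[name]
        if log_transform:
            vals = np.log(vals)
        res = k_significance(
            phy, vals, n_perm=n_perm, seed=int(rng.integers(2**31)), trait=name
        )
        rows.append(
            {
                "trait": name,
                "K": res.k,
                "ci_lower": res.ci[0],
                "ci_upper": res.ci[1],
                "p_upper": res.p_upper,
                "significant": res.significant,
                "n_perm": res.n_perm,
            }
        )
    return pd.DataFrame(rows)
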