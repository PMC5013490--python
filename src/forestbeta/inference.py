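"""Mixed-model tests of turnover along the disturbance gradient.

A pair-level response (Chao-Jaccard, B_st or tau_st) is regressed on the
disturbance regime (categorical), the log habitat distance between the two
subplots, their interaction, the plot mean elevation, and the log spatial
distance, with random intercepts for the disturbance regime and for the
plot (within-plot pairs) or unordered plot pair (between-plot pairs) nested
in it.  Term significance uses F tests with Satterthwaite denominator df;
insignificant terms are pruned backwards (interactions before main
effects); random structures are compared by a boundary-aware LRT; the
pairwise regime contrasts are adjusted by the single-step (max-|t|) method;
and residuals are screened for spatial autocorrelation with a Moran's I
correlogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from forestbeta.data_io import HabitatTable, ValidationError
from forestbeta.lmm import (
    LmmFit,
    RandomInterceptLMM,
    f_test,
    lrt_random,
    satterthwaite_df,
    vcov_varpar,
)

__all__ = [
    "habitat_coordinates",
    "habitat_distance",
    "ModelSpec",
    "fit_lmm",
    "satterthwaite_tests",
    "backward_prune",
    "lrt_random",
    "regime_contrasts",
    "residual_correlogram",
]


# ---------------------------------------------------------------------------
# Habitat distance
# ---------------------------------------------------------------------------


def habitat_coordinates(habitat: HabitatTable) -> pd.DataFrame:
    """5-D habitat coordinates per subplot: z-scored mean elevation, slope
    and convexity plus sine/cosine of aspect (easting/northing).

    Standardization statistics are computed once per grain over all subplots
    present (the analysis set); zero-variance columns contribute 0.
    """
    frames = []
    for _, sub in habitat.data.groupby("grain"):
        out = pd.DataFrame(index=sub["subplot_id"])
        for col in ("mean_elevation", "slope", "convexity"):
            v = sub[col].to_numpy(dtype=float)
            sd = v.std(ddof=1) if len(v) > 1 else 0.0
            out[f"z_{col}"] = (v - v.mean()) / sd if sd > 0 else 0.0
        rad = np.deg2rad(sub["aspect"].to_numpy(dtype=float))
        out["sin_aspect"] = np.sin(rad)
        out["cos_aspect"] = np.cos(rad)
        frames.append(out)
    return pd.concat(frames)


def habitat_distance(h_k: pd.Series, h_l: pd.Series, coords: pd.DataFrame | None = None) -> float:
    """Euclidean habitat distance between two subplots.

    ``h_k``/``h_l`` are habitat records (or subplot ids when ``coords`` from
    :func:`habitat_coordinates` is supplied, which is the standard route so
    the z-scoring uses the whole analysis set).
    """
    if coords is not None:
        return float(np.linalg.norm(coords.loc[h_k] - coords.loc[h_l]))
    table = HabitatTable(pd.DataFrame([h_k, h_l]))
    c = habitat_coordinates(table)
    return float(np.linalg.norm(c.iloc[0] - c.iloc[1]))


# ---------------------------------------------------------------------------
# Model specification and design building
# ---------------------------------------------------------------------------

FIXED_TERMS = ("regime", "log_hd", "regime:log_hd", "plot_mean_elev", "log_sd")


@dataclass
class ModelSpec:
    """Fixed/random structure for one turnover response.

    ``fixed`` lists term names from :data:`FIXED_TERMS`; ``random`` lists
    grouping columns of the pair table (``regime`` and/or ``group``).
    ``elev_coding`` selects how plot mean elevation enters for between-plot
    pairs: mean of the two plots (default) or absolute difference.
    """

    response: str
    fixed: tuple[str, ...] = FIXED_TERMS
    random: tuple[str, ...] = ("regime", "group")
    reml: bool = True
    elev_coding: str = "mean"  # mean | absdiff
    log_eps_factor: float = 1e-6

    def __post_init__(self) -> None:
        unknown = set(self.fixed) - set(FIXED_TERMS)
        if unknown:
            raise ValidationError(f"unknown fixed terms: {sorted(unknown)}")
        if "regime:log_hd" in self.fixed and not {"regime", "log_hd"} <= set(self.fixed):
            raise ValidationError("interaction requires both main effects")


def _log_guard(d: np.ndarray, eps_factor: float) -> np.ndarray:
    """log(d + eps) with eps a small fraction of the median positive d."""
    pos = d[d > 0]
    eps = eps_factor * (np.median(pos) if len(pos) else 1.0)
    return np.log(d + eps)


def build_design(spec: ModelSpec, pairs: pd.DataFrame):
    """Response vector, fixed design matrix with term slices, and random
    grouping codes for a pair table."""
    y = pairs[spec.response].to_numpy(dtype=float)
    ok = np.isfinite(y)
    pairs = pairs.loc[ok].reset_index(drop=True)
    y = y[ok]

    regimes = np.sort(pairs["regime"].unique())
    if len(regimes) < 2 and "regime" in spec.fixed:
        raise ValidationError("at least 2 regimes are needed to test the regime effect")

    cols = [np.ones(len(pairs))]
    names = ["(Intercept)"]
    slices: dict[str, list[int]] = {}

    reg_dummies = {}
    for r in regimes[1:]:
        reg_dummies[r] = (pairs["regime"] == r).to_numpy(dtype=float)

    log_hd = None
    if "log_hd" in spec.fixed or "regime:log_hd" in spec.fixed:
        log_hd = _log_guard(pairs["habitat_distance"].to_numpy(dtype=float), spec.log_eps_factor)

    for term in spec.fixed:
        if term == "regime":
            for r in regimes[1:]:
                slices.setdefault("regime", []).append(len(cols))
                cols.append(reg_dummies[r])
                names.append(f"regime[{r}]")
        elif term == "log_hd":
            slices.setdefault("log_hd", []).append(len(cols))
            cols.append(log_hd)
            names.append("log_hd")
        elif term == "regime:log_hd":
            for r in regimes[1:]:
                slices.setdefault("regime:log_hd", []).append(len(cols))
                cols.append(reg_dummies[r] * log_hd)
                names.append(f"regime[{r}]:log_hd")
        elif term == "plot_mean_elev":
            col = "plot_mean_elev" if spec.elev_coding == "mean" else "plot_elev_absdiff"
            v = pairs[col].to_numpy(dtype=float)
            if np.ptp(v) == 0:  # constant (single plot); skip silently
                continue
            slices.setdefault("plot_mean_elev", []).append(len(cols))
            cols.append((v - v.mean()) / v.std(ddof=1))
            names.append("plot_mean_elev")
        elif term == "log_sd":
            slices.setdefault("log_sd", []).append(len(cols))
            cols.append(np.log(pairs["spatial_distance"].to_numpy(dtype=float)))
            names.append("log_sd")

    X = np.column_stack(cols)
    # drop columns collinear with earlier terms (e.g. plot mean elevation is
    # confounded with regime when each regime contributes one plot pair)
    keep: list[int] = []
    rank = 0
    for j in range(X.shape[1]):
        cand = X[:, keep + [j]]
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            keep.append(j)
            rank = r
    if len(keep) < X.shape[1]:
        dropped = [names[j] for j in range(X.shape[1]) if j not in keep]
        remap = {old: new for new, old in enumerate(keep)}
        X = X[:, keep]
        names = [names[j] for j in keep]
        slices = {
            t: [remap[j] for j in idx if j in remap]
            for t, idx in slices.items()
        }
        slices = {t: idx for t, idx in slices.items() if idx}
    else:
        dropped = []
    groups = {}
    for g in spec.random:
        codes = pd.factorize(pairs[g])[0]
        if len(np.unique(codes)) > 1:
            groups[g] = codes
    meta = {"names": names, "slices": slices, "regimes": regimes, "pairs": pairs,
            "dropped_collinear": dropped,
            "log_hd_mean": float(np.mean(log_hd)) if log_hd is not None else 0.0}
    return y, X, groups, meta


@dataclass
class FitResult:
    """An :class:`~forestbeta.lmm.LmmFit` plus design metadata."""

    fit: LmmFit
    spec: ModelSpec
    names: list[str]
    slices: dict[str, list[int]]
    regimes: np.ndarray
    pairs: pd.DataFrame
    log_hd_mean: float
    pruning_log: list[dict] = field(default_factory=list)
    dropped_collinear: list[str] = field(default_factory=list)


def fit_lmm(spec: ModelSpec, pairs: pd.DataFrame) -> FitResult:
    """Fit the mixed model for one response on a pair table (REML)."""
    y, X, groups, meta = build_design(spec, pairs)
    fit = RandomInterceptLMM(y, X, groups, reml=spec.reml).fit()
    return FitResult(
        fit=fit,
        spec=spec,
        names=meta["names"],
        slices=meta["slices"],
        regimes=meta["regimes"],
        pairs=meta["pairs"],
        log_hd_mean=meta["log_hd_mean"],
        dropped_collinear=meta["dropped_collinear"],
    )


def satterthwaite_tests(res: FitResult) -> pd.DataFrame:
    """Per-term F table (Satterthwaite ddf) for all fixed terms in the fit."""
    fit = res.fit
    columns = ["term", "F", "ndf", "ddf", "p"]
    if not res.slices:
        return pd.DataFrame(columns=columns)
    A, keep = vcov_varpar(fit)
    rows = []
    for term, idx in res.slices.items():
        C = np.zeros((len(idx), fit.p))
        for r, j in enumerate(idx):
            C[r, j] = 1.0
        t = f_test(fit, C, A, keep)
        rows.append({"term": term, **t})
    return pd.DataFrame(rows)[columns]


def backward_prune(spec: ModelSpec, pairs: pd.DataFrame, alpha: float = 0.05) -> FitResult:
    """Backward elimination of insignificant fixed terms.

    At each step the least significant term with p > alpha is removed and
    the model refitted, interactions before the main effects they contain;
    the intercept always stays.  Each step is recorded in ``pruning_log``.
    """
    current = spec
    log: list[dict] = []
    while True:
        res = fit_lmm(current, pairs)
        table = satterthwaite_tests(res)
        if table.empty:
            res.pruning_log = log
            return res
        protected = set()
        if "regime:log_hd" in current.fixed:
            protected |= {"regime", "log_hd"}
        cand = table[(table["p"] > alpha) & (~table["term"].isin(protected))]
        if cand.empty:
            res.pruning_log = log
            return res
        worst = cand.sort_values("p", ascending=False).iloc[0]
        log.append({"dropped": worst["term"], "p": float(worst["p"]), "F": float(worst["F"])})
        current = replace(current, fixed=tuple(t for t in current.fixed if t != worst["term"]))


def simulate_pair_table(
    n_plots: int = 9,
    pairs_per_plot: int = 300,
    beta0: float = 0.3,
    beta_hd: float = 0.08,
    regime_effects: tuple[float, ...] = (0.0, 0.0, 0.0),
    sigma_plot: float = 0.05,
    sigma: float = 0.1,
    seed: int | None = None,
) -> pd.DataFrame:
    """Pair-level data drawn from the fitted model class itself.

    Used for calibration studies (parameter recovery, type-I error of the
    Satterthwaite F test, LRT boundary behaviour): plots are assigned to
    regimes in equal blocks, habitat distances are lognormal, and the
    response is ``beta0 + regime effect + beta_hd log(hd) + plot intercept +
    noise``.  Midpoint coordinates are i.i.d. uniform so residuals carry no
    spatial structure.
    """
    rng = np.random.default_rng(seed)
    n_regimes = len(regime_effects)
    per = max(1, n_plots // n_regimes)
    rows = []
    b_plot = rng.normal(0.0, sigma_plot, n_plots)
    for p in range(n_plots):
        regime = min(p // per, n_regimes - 1) + 1
        hd = rng.lognormal(0.0, 0.6, pairs_per_plot)
        sd = rng.uniform(10.0, 140.0, pairs_per_plot)
        elev = 400.0 + 40.0 * p / n_plots
        y = (
            beta0
            + regime_effects[regime - 1]
            + beta_hd * np.log(hd)
            + b_plot[p]
            + rng.normal(0.0, sigma, pairs_per_plot)
        )
        for i in range(pairs_per_plot):
            rows.append(
                {
                    "y": y[i],
                    "regime": regime,
                    "group": f"plot{p + 1}",
                    "habitat_distance": hd[i],
                    "spatial_distance": sd[i],
                    "plot_mean_elev": elev,
                    "plot_elev_absdiff": 0.0,
                    "level": "within",
                    "mid_x": rng.uniform(0, 1000),
                    "mid_y": rng.uniform(0, 1000),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Regime contrasts with single-step adjustment
# ---------------------------------------------------------------------------


def _regime_contrast_matrix(res: FitResult) -> tuple[np.ndarray, list[str]]:
    """All pairwise regime-difference contrasts, evaluated (when the
    regime x log-habitat-distance interaction is in the model) at the mean
    log habitat distance."""
    fit = res.fit
    regimes = list(res.regimes)
    if "regime" not in res.slices:
        return np.zeros((0, fit.p)), []
    cellvec = {regimes[0]: np.zeros(fit.p)}
    for r, j in zip(regimes[1:], res.slices["regime"]):
        v = np.zeros(fit.p)
        v[j] = 1.0
        cellvec[r] = v
    if "regime:log_hd" in res.slices:
        for r, j in zip(regimes[1:], res.slices["regime:log_hd"]):
            cellvec[r][j] = res.log_hd_mean
    rows, labels = [], []
    for i in range(len(regimes)):
        for j in range(i + 1, len(regimes)):
            rows.append(cellvec[regimes[j]] - cellvec[regimes[i]])
            labels.append(f"{regimes[j]}-{regimes[i]}")
    return np.asarray(rows), labels


def _letters(regimes: list, labels: list[str], adj_p: np.ndarray, alpha: float = 0.05) -> dict:
    """Compact letter display: regimes share a letter iff not significantly
    different (insert-and-absorb over the non-significance graph)."""
    same = {r: {r} for r in regimes}
    for lab, p in zip(labels, adj_p):
        b, a = lab.split("-")
        a = type(regimes[0])(a)
        b = type(regimes[0])(b)
        if p > alpha:
            same[a].add(b)
            same[b].add(a)
    # greedy clique cover on the "not different" graph
    letters: dict = {r: "" for r in regimes}
    groups: list[set] = []
    for r in regimes:
        placed = False
        for g in groups:
            if all(x in same[r] for x in g):
                g.add(r)
                placed = True
        if not placed:
            groups.append({r})
    for gi, g in enumerate(groups):
        ch = chr(ord("a") + gi)
        for r in g:
            letters[r] += ch
    return letters


def regime_contrasts(
    res: FitResult, n_draws: int = 2**14, seed: int = 20160907, alpha: float = 0.05
) -> pd.DataFrame:
    """Pairwise regime comparisons with single-step adjusted p-values.

    The adjusted p of a contrast is ``P(max_j |T_j| >= |t_obs|)`` under the
    joint multivariate t of all contrast statistics (correlation from the
    fixed-effect covariance, df from Satterthwaite, averaged across
    contrasts), evaluated by seeded Monte-Carlo integration.  Adjusted p is
    never below the unadjusted p.  An empty frame is returned when the
    regime term was pruned.
    """
    C, labels = _regime_contrast_matrix(res)
    if len(labels) == 0:
        df = pd.DataFrame(columns=["contrast", "estimate", "se", "t", "df", "p", "adj_p"])
        df.attrs["note"] = "regime term not in the model (pruned)"
        return df
    fit = res.fit
    A, keep = vcov_varpar(fit)
    M = C @ fit.cov_beta @ C.T
    est = C @ fit.beta
    se = np.sqrt(np.diag(M))
    tstat = est / se
    dfs = np.array([max(2.0001, satterthwaite_df(fit, c, A, keep)) for c in C])
    df_use = float(np.mean(dfs))
    R = M / np.outer(se, se)
    # seeded MC draws from the multivariate t with correlation R
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(R + 1e-10 * np.eye(len(se)))
    Z = rng.standard_normal((n_draws, len(se))) @ L.T
    s = np.sqrt(rng.chisquare(df_use, size=n_draws) / df_use)
    T = np.abs(Z / s[:, None]).max(axis=1)
    unadj = 2.0 * stats.t.sf(np.abs(tstat), dfs)
    adj = np.array([(np.count_nonzero(T >= abs(t)) + 1) / (n_draws + 1) for t in tstat])
    adj = np.maximum(adj, unadj)
    out = pd.DataFrame(
        {
            "contrast": labels,
            "estimate": est,
            "se": se,
            "t": tstat,
            "df": dfs,
            "p": unadj,
            "adj_p": adj,
        }
    )
    out.attrs["letters"] = _letters(list(res.regimes), labels, adj, alpha)
    return out


# ---------------------------------------------------------------------------
# Residual spatial correlogram
# ---------------------------------------------------------------------------


def _morans_i(z: np.ndarray, W: np.ndarray) -> float:
    n = len(z)
    s0 = W.sum()
    denom = float(z @ z)
    if denom == 0 or s0 == 0:
        raise ValidationError("Moran's I undefined (constant residuals or empty class)")
    return float(n / s0 * (z @ W @ z) / denom)


def residual_correlogram(
    res: FitResult,
    coords: np.ndarray | None = None,
    n_classes: int = 10,
    n_perm: int = 499,
    seed: int | None = None,
    max_points: int = 1500,
) -> pd.DataFrame:
    """Moran's I of model residuals per distance class, with permutation p.

    Each pair record is located at the midpoint of its two subplot centroids
    in the shared frame; distance classes are equal-frequency over the
    midpoint distances.  Large pair tables are thinned to ``max_points``
    midpoints (seeded) to bound the O(n^2) weight matrices.  The summary
    attr ``no_autocorrelation`` is True when every class has Bonferroni-
    adjusted p > 0.05.
    """
    z = np.asarray(res.fit.residuals, dtype=float)
    if coords is None:
        if "mid_x" not in res.pairs:
            raise ValidationError("pair table lacks midpoint coordinates")
        coords = res.pairs[["mid_x", "mid_y"]].to_numpy(dtype=float)
    if np.allclose(z, z[0]):
        raise ValidationError("constant residuals: Moran's I undefined")
    rng = np.random.default_rng(seed)
    if len(z) > max_points:
        idx = rng.choice(len(z), size=max_points, replace=False)
        z = z[idx]
        coords = coords[idx]
    z = z - z.mean()
    n = len(z)
    D = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    iu = np.triu_indices(n, 1)
    dists = D[iu]
    while n_classes > 1 and len(dists) / n_classes < 2:
        n_classes -= 1
    edges = np.quantile(dists, np.linspace(0, 1, n_classes + 1))
    edges[-1] += 1e-9

    rows = []
    perms = [rng.permutation(n) for _ in range(n_perm)]
    for c in range(n_classes):
        W = ((D >= edges[c]) & (D < edges[c + 1])).astype(float)
        np.fill_diagonal(W, 0.0)
        if W.sum() == 0:
            continue
        obs = _morans_i(z, W)
        null = np.array([_morans_i(z[p], W) for p in perms])
        # two-sided rank p
        p = (np.count_nonzero(np.abs(null) >= abs(obs)) + 1) / (n_perm + 1)
        rows.append(
            {
                "class": c + 1,
                "d_lower": edges[c],
                "d_upper": edges[c + 1],
                "n_links": int(W.sum() / 2),
                "morans_i": obs,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = np.minimum(1.0, out["p"] * len(out))
    out.attrs["no_autocorrelation"] = bool((out["p_bonferroni"] > 0.05).all())
    return out
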