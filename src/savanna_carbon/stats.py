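"""Statistical analyses: group comparisons, predictor selection, driver
models and derived summaries.

Carbon-stock differences between land-use types are tested with the
Games-Howell post hoc procedure (robust to unequal sample sizes and
variances; Welch-Satterthwaite degrees of freedom, studentized-range
reference distribution), preceded by Bartlett's variance-homogeneity
check. Damage shares between land-use types use one-way ANOVA with Tukey
HSD and a compact letter display. Candidate plot predictors are reduced by
a pairwise Spearman correlation filter (|rho| < 0.75) and summarised by a
standardized PCA. Driver models are penalized additive mixed models (see
:mod:`savanna_carbon.gamm`); each predictor's relative importance is
estimated by hierarchical partitioning of explained deviance over all
predictor subsets.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .gamm import GammFit, GammSpec, default_gamm_spec, fit_gamm

__all__ = [
    "SPEARMAN_THRESHOLD",
    "spearman_filter",
    "pca_overview",
    "bartlett_variance_test",
    "GamesHowellResult",
    "games_howell",
    "games_howell_fwer",
    "anova_tukey",
    "fit_gamm",
    "GammSpec",
    "GammFit",
    "default_gamm_spec",
    "deviance_partition",
    "percent_change",
    "below_above_ratio",
]

SPEARMAN_THRESHOLD = 0.75


# --------------------------------------------------------------------------
# Predictor selection
# --------------------------------------------------------------------------


def spearman_filter(
    predictors: pd.DataFrame, threshold: float = SPEARMAN_THRESHOLD
) -> tuple[list[str], pd.DataFrame]:
    """Greedily drop predictors until all pairwise |Spearman rho| are below
    the threshold.

    From the worst-correlated pair, the member with the higher mean
    absolute correlation against the remaining set is removed. Returns the
    retained column names and a removal report (step, dropped, partner,
    |rho| at removal).
    """
    if predictors.shape[1] < 2:
        raise ValueError("need at least two candidate predictors")
    for col in predictors.columns:
        if predictors[col].nunique() < 2:
            raise ValueError(f"constant column {col!r} cannot be rank-correlated")
    cols = list(predictors.columns)
    corr = sps.spearmanr(predictors[cols].to_numpy()).statistic
    corr = np.atleast_2d(corr)
    np.fill_diagonal(corr, 0.0)
    corr = pd.DataFrame(np.abs(corr), index=cols, columns=cols)
    report = []
    step = 0
    while True:
        sub = corr.loc[cols, cols]
        max_val = sub.to_numpy().max()
        if max_val < threshold:
            break
        step += 1
        i, j = np.unravel_index(np.argmax(sub.to_numpy()), sub.shape)
        a, b = cols[i], cols[j]
        drop = a if sub.loc[a].mean() >= sub.loc[b].mean() else b
        partner = b if drop == a else a
        report.append({"step": step, "dropped": drop, "partner": partner, "abs_rho": max_val})
        cols.remove(drop)
    return cols, pd.DataFrame(report, columns=["step", "dropped", "partner", "abs_rho"])


def pca_overview(predictors: pd.DataFrame) -> dict:
    """Standardized PCA of the predictor matrix (descriptive only).

    Variables are zero-centred and scaled to unit variance; variance
    shares are the eigenvalues of the correlation matrix normalised to
    sum to 1. Returns variance shares and loadings.
    """
    if len(predictors) < 3:
        raise ValueError("PCA needs at least 3 rows")
    x = predictors.to_numpy(dtype=float)
    x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    corr = np.corrcoef(x, rowvar=False)
    corr = np.atleast_2d(corr)
    w, v = np.linalg.eigh(corr)
    order = np.argsort(w)[::-1]
    w, v = np.maximum(w[order], 0.0), v[:, order]
    shares = w / w.sum()
    loadings = pd.DataFrame(
        v,
        index=predictors.columns,
        columns=[f"PC{i + 1}" for i in range(len(w))],
    )
    return {"variance_shares": shares, "loadings": loadings, "eigenvalues": w}


# --------------------------------------------------------------------------
# Group comparisons
# --------------------------------------------------------------------------


def bartlett_variance_test(groups: list[np.ndarray]) -> tuple[float, float]:
    """Bartlett's test of variance homogeneity across k groups."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        g = np.asarray(g, dtype=float)
        if len(g) < 2:
            raise ValueError("each group needs n >= 2")
        if np.var(g, ddof=1) == 0:
            raise ValueError("zero-variance group")
    stat, p = sps.bartlett(*groups)
    return float(stat), float(p)


@dataclass(frozen=True)
class GamesHowellResult:
    """One pairwise Games-Howell comparison."""

    group_1: str
    group_2: str
    mean_diff: float
    se: float
    df: float
    q_statistic: float
    p_adjusted: float


def _welch_df(v1: float, n1: int, v2: float, n2: int) -> float:
    num = (v1 / n1 + v2 / n2) ** 2
    den = (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
    return num / den


def games_howell(groups: dict[str, np.ndarray]) -> list[GamesHowellResult]:
    """Games-Howell post hoc comparisons for unequal sample sizes and
    variances.

    Per pair: SE = sqrt(s_i^2/n_i + s_j^2/n_j), Welch-Satterthwaite df,
    and the adjusted p from the studentized-range distribution with the
    total number of groups k, using q = |diff| / (SE / sqrt(2)).
    """
    names = list(groups)
    k = len(names)
    if k < 2:
        raise ValueError("need at least two groups")
    stats = {}
    for name in names:
        g = np.asarray(groups[name], dtype=float)
        if len(g) < 2:
            raise ValueError(f"group {name!r} needs n >= 2")
        stats[name] = (g.mean(), g.var(ddof=1), len(g))
    results = []
    for a, b in itertools.combinations(names, 2):
        m1, v1, n1 = stats[a]
        m2, v2, n2 = stats[b]
        diff = m1 - m2
        se = math.sqrt(v1 / n1 + v2 / n2)
        df = _welch_df(v1, n1, v2, n2)
        if se == 0:
            q, p = 0.0, 1.0
        else:
            q = abs(diff) / (se / math.sqrt(2.0))
            p = float(sps.studentized_range.sf(q, k, df))
        results.append(
            GamesHowellResult(
                group_1=a, group_2=b, mean_diff=float(diff), se=float(se),
                df=float(df), q_statistic=float(q), p_adjusted=min(max(p, 0.0), 1.0),
            )
        )
    return results


def games_howell_fwer(
    k: int,
    group_sizes: list[int],
    group_sds: list[float],
    n_reps: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Monte-Carlo familywise type-I error of the Games-Howell procedure
    under an equal-means null with the given (possibly unequal) group
    standard deviations.

    Critical studentized-range values are precomputed on a log-spaced df
    grid and interpolated, which makes 1e4 replicates tractable.
    """
    if len(group_sizes) != k or len(group_sds) != k:
        raise ValueError("group_sizes and group_sds must have length k")
    rng = np.random.default_rng(seed)
    df_grid = np.geomspace(2.0, 500.0, 160)
    crit_grid = sps.studentized_range.ppf(1.0 - alpha, k, df_grid)

    sizes = np.asarray(group_sizes)
    sds = np.asarray(group_sds, dtype=float)
    means = np.empty((n_reps, k))
    variances = np.empty((n_reps, k))
    for g in range(k):
        x = rng.normal(0.0, sds[g], size=(n_reps, sizes[g]))
        means[:, g] = x.mean(axis=1)
        variances[:, g] = x.var(axis=1, ddof=1)

    any_reject = np.zeros(n_reps, dtype=bool)
    for i, j in itertools.combinations(range(k), 2):
        vi, vj = variances[:, i] / sizes[i], variances[:, j] / sizes[j]
        se2 = vi + vj
        df = se2**2 / (vi**2 / (sizes[i] - 1) + vj**2 / (sizes[j] - 1))
        q = np.abs(means[:, i] - means[:, j]) / np.sqrt(se2 / 2.0)
        crit = np.interp(np.clip(df, df_grid[0], df_grid[-1]), df_grid, crit_grid)
        any_reject |= q > crit
    return float(any_reject.mean())


def anova_tukey(groups: dict[str, np.ndarray], alpha: float = 0.05) -> dict:
    """One-way ANOVA with Tukey HSD post hoc test and a compact letter
    display (groups sharing a letter do not differ significantly)."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    names = list(groups)
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    f_stat, p = sps.f_oneway(*arrays)
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.concatenate(arrays)
    labels = np.concatenate([[n] * len(a) for n, a in zip(names, arrays)])
    tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
    pairs = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    sig = {
        frozenset((row["group1"], row["group2"])): bool(row["reject"])
        for _, row in pairs.iterrows()
    }
    letters = _compact_letters(names, sig)
    return {
        "f_statistic": float(f_stat),
        "p_value": float(p),
        "pairwise": pairs,
        "letters": letters,
    }


def _compact_letters(names: list[str], sig: dict[frozenset, bool]) -> dict[str, str]:
    """Greedy compact letter display: assign each group to every letter
    class it is compatible with (no significant difference to any
    member), creating new classes as needed."""
    classes: list[set[str]] = []
    for name in names:
        placed = False
        for cls in classes:
            if all(not sig.get(frozenset((name, other)), False) for other in cls):
                cls.add(name)
                placed = True
        if not placed:
            classes.append({name})
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {n: "" for n in names}
    for letter, cls in zip(alphabet, classes):
        for n in names:
            if n in cls:
                out[n] += letter
    return out


# --------------------------------------------------------------------------
# Deviance partitioning
# --------------------------------------------------------------------------


def deviance_partition(
    data: pd.DataFrame,
    spec: GammSpec,
    predictors: list[str] | None = None,
    *,
    max_exhaustive: int = 10,
) -> pd.DataFrame:
    """Hierarchical partitioning of explained deviance across predictors.

    Each predictor's share is its Shapley value over the 2^p predictor
    subsets: the average, over orderings, of the gain in deviance
    explained when the predictor enters the model. Terms not listed in
    ``predictors`` (intercept, random intercept, unlisted parametric
    terms) form the base model present in every subset fit; tensor
    interactions are included only in subsets containing both margins.
    Negative averages are floored at zero with a warning. Shares are
    reported in percentage points of explained deviance and sum (before
    flooring) to the full model's gain over the base model.
    """
    if predictors is None:
        predictors = [*spec.smooth, *[p for p in spec.parametric if p != spec.random_intercept]]
    p = len(predictors)
    if p < 1:
        raise ValueError("need at least one predictor to partition")
    if p > max_exhaustive:
        raise ValueError(
            f"exhaustive partitioning over {p} predictors exceeds max_exhaustive={max_exhaustive}"
        )

    cache: dict[frozenset, float] = {}

    def dev(subset: frozenset) -> float:
        if subset in cache:
            return cache[subset]
        sub_spec = replace(
            spec,
            smooth=[s for s in spec.smooth if s not in predictors or s in subset],
            parametric=[s for s in spec.parametric if s not in predictors or s in subset],
            tensor=[t for t in spec.tensor if all(m not in predictors or m in subset for m in t)],
        )
        fit = fit_gamm(data, sub_spec)
        cache[subset] = fit.deviance_explained
        return cache[subset]

    base = dev(frozenset())
    shares = {}
    fact = math.factorial
    for pred in predictors:
        others = [q for q in predictors if q != pred]
        total = 0.0
        for r in range(len(others) + 1):
            weight = fact(r) * fact(p - r - 1) / fact(p)
            for combo in itertools.combinations(others, r):
                s = frozenset(combo)
                total += weight * (dev(s | {pred}) - dev(s))
        shares[pred] = total
    full = dev(frozenset(predictors))
    floored = {}
    for pred, val in shares.items():
        if val < 0:
            warnings.warn(
                f"negative deviance share for {pred!r} ({val:.4f}); floored at 0",
                RuntimeWarning,
            )
        floored[pred] = max(val, 0.0)
    return pd.DataFrame(
        {
            "predictor": list(floored),
            "share_pct": [100.0 * v for v in floored.values()],
            "raw_share_pct": [100.0 * shares[k] for k in floored],
            "base_dev_pct": 100.0 * base,
            "full_dev_pct": 100.0 * full,
        }
    )


# --------------------------------------------------------------------------
# Derived summaries
# --------------------------------------------------------------------------


def percent_change(ref_mean: float, end_mean: float) -> float:
    """Relative change in % between a reference and an endpoint mean;
    negative values are losses."""
    if ref_mean <= 0:
        raise ValueError("reference mean must be positive")
    return 100.0 * (end_mean - ref_mean) / ref_mean


def below_above_ratio(compartments) -> float:
    """Ratio of combined belowground pools (BGC + SOC) to AGC for one
    plot; NaN where AGC is zero (undefined)."""
    agc = compartments.agc
    if agc == 0:
        return float("nan")
    return (compartments.bgc + compartments.soc) / agc
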