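"""Statistical comparisons used across the pipeline.

Spearman rank correlation reported together with the classic S statistic
(sum of squared rank differences), Mann-Whitney U tests (exact null for
small tie-free samples), between-forest contrasts on per-unit metrics with
site as a grouping factor, and a linear evenness contrast.

Model-based estimation is delegated to statsmodels; the module's own code is
the exact/permutation machinery.  Forest contrasts use a between-site t
reference (df = number of sites - 2) for p-values: with 10 sites per forest
the site, not the card, is the independent replicate, and the normal
reference a mixed model prints would be anti-conservative.
"""

from __future__ import annotations

import itertools
import warnings as _warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats import rankdata

__all__ = [
    "CorrelationResult",
    "TestResult",
    "spearman",
    "rho_from_s",
    "mann_whitney",
    "forest_contrast",
    "evenness_contrast",
    "site_permutation_test",
]

SPEARMAN_EXACT_MAX_N = 9  # exact permutation p below this+1; t approximation from n >= 10


@dataclass
class CorrelationResult:
    """Spearman correlation with its rank-difference statistic.

    With no ties, ``rho = 1 - 6 S / (n (n^2 - 1))``; with ties rho is the
    product-moment correlation of fractional ranks and S (still reported as
    the raw sum of squared rank differences) no longer satisfies that
    identity, so ``ties`` flags it.
    """

    n: int
    S: float
    rho: float
    p: float
    ties: bool = False
    method: str = ""
    degenerate: bool = False


@dataclass
class TestResult:
    statistic_name: str
    statistic: float
    p: float
    effect_direction: str
    group_means: dict
    n_per_group: dict
    grouping: Optional[str] = None
    method: str = ""
    converged: bool = True
    note: str = ""
    extras: dict = field(default_factory=dict)


def rho_from_s(S: float, n: int) -> float:
    """Spearman rho recovered from the printed S statistic (no-ties identity)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    return 1.0 - 6.0 * S / (n * (n**2 - 1))


def _spearman_exact_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Exact two-sided p by enumerating all permutations of one rank vector."""
    n = len(rx)
    cx = rx - rx.mean()
    cy = ry - ry.mean()
    denom = np.sqrt((cx**2).sum() * (cy**2).sum())
    perms = np.array(list(itertools.permutations(cy)))
    rhos = perms @ cx / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation with S, rho and a two-sided p-value.

    Fractional (average) ranks throughout; rho is the product-moment
    correlation of the ranks, which reduces to ``1 - 6S/(n(n^2-1))`` when
    there are no ties.  p is exact (full permutation enumeration) for
    n <= 9 and from the t approximation otherwise.  A constant input vector
    gives an undefined rho, flagged ``degenerate``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    rx = rankdata(x, method="average")
    ry = rankdata(y, method="average")
    S = float(((rx - ry) ** 2).sum())
    ties = (len(np.unique(rx)) < n) or (len(np.unique(ry)) < n)
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        return CorrelationResult(n=n, S=S, rho=float("nan"), p=float("nan"),
                                 ties=ties, method="degenerate", degenerate=True)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= SPEARMAN_EXACT_MAX_N:
        p = _spearman_exact_p(rx, ry, rho)
        method = "exact"
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
        method = "t-approximation"
    return CorrelationResult(n=n, S=S, rho=rho, p=p, ties=ties, method=method)


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Uses the exact null distribution when the smaller sample has <= 8
    observations and the data are tie-free, and the tie-corrected normal
    approximation otherwise (estimation delegated to scipy).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    use_exact = min(a.size, b.size) <= 8 and not has_ties
    method = "exact" if use_exact else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    mean_a, mean_b = float(a.mean()), float(b.mean())
    direction = "a" if mean_a > mean_b else "b" if mean_b > mean_a else "tie"
    return TestResult(
        statistic_name="U",
        statistic=float(res.statistic),
        p=float(res.pvalue),
        effect_direction=direction,
        group_means={"a": mean_a, "b": mean_b},
        n_per_group={"a": int(a.size), "b": int(b.size)},
        method=f"mann-whitney-{method}",
    )


# ---------------------------------------------------------------------------
# Forest contrasts with site grouping
# ---------------------------------------------------------------------------

def _prep(df: pd.DataFrame, value_col: str) -> pd.DataFrame:
    out = df[[value_col, "forest", "site"]].dropna().copy()
    out.columns = ["value", "forest", "site"]
    # site labels must be globally unique (site 3 in primary != site 3 in logged)
    out["site"] = out["forest"].astype(str) + ":" + out["site"].astype(str)
    out["is_primary"] = (out["forest"] == "primary").astype(float)
    return out


def site_permutation_test(
    df: pd.DataFrame,
    value_col: str = "value",
    n_permutations: int = 10_000,
    seed: int = 20_160_201,
) -> TestResult:
    """Seeded permutation test of the forest effect on site means.

    The test statistic is the difference of forest means of per-site means;
    site labels are reassigned to forests at random (preserving the 10/10
    split), respecting the design's site-level independence.
    """
    d = _prep(df, value_col)
    site_means = d.groupby(["site", "forest"])["value"].mean().reset_index()
    vals = site_means["value"].to_numpy()
    is_primary = (site_means["forest"] == "primary").to_numpy()
    n_primary = int(is_primary.sum())
    if n_primary == 0 or n_primary == len(vals):
        raise ValueError("need sites in both forests")
    obs = vals[is_primary].mean() - vals[~is_primary].mean()
    rng = np.random.default_rng(seed)
    count = 0
    idx = np.arange(len(vals))
    for _ in range(n_permutations):
        perm = rng.permutation(idx)
        sel = np.zeros(len(vals), dtype=bool)
        sel[perm[:n_primary]] = True
        stat = vals[sel].mean() - vals[~sel].mean()
        if abs(stat) >= abs(obs) - 1e-12:
            count += 1
    p = count / n_permutations
    means = d.groupby("forest")["value"].mean().to_dict()
    return TestResult(
        statistic_name="mean-difference",
        statistic=float(obs),
        p=float(p),
        effect_direction=max(means, key=means.get),
        group_means=means,
        n_per_group=d.groupby("forest").size().to_dict(),
        grouping="site",
        method="site-permutation",
        extras={"n_permutations": n_permutations, "seed": seed},
    )


def forest_contrast(
    df: pd.DataFrame,
    family: str,
    value_col: str = "value",
    n_permutations: int = 10_000,
    seed: int = 20_160_201,
) -> TestResult:
    """Regression contrast of a per-unit metric between forest types.

    ``df`` needs columns ``value_col``, ``forest`` and ``site``.  Family
    selects the error model: ``count`` fits a quasi-Poisson GLM with
    cluster-robust (by site) standard errors, ``binary`` a binomial GEE with
    exchangeable within-site correlation, ``continuous`` a random-site-
    intercept linear model evaluated in its exact between-site reduction
    (Wald t on per-site means).  p-values use a t reference with between-
    site degrees of freedom (n_sites - 2).  Estimation failures fall back
    to the seeded site-permutation test, flagged ``converged=False``.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if family not in {"count", "binary", "continuous"}:
        raise ValueError(f"unknown family {family!r}")
    d = _prep(df, value_col)
    if d["forest"].nunique() < 2:
        raise ValueError("need data from both forests")
    sites_per_forest = d.groupby("forest")["site"].nunique()
    if (sites_per_forest < 2).any():
        raise ValueError("need at least 2 sites per forest")
    n_sites = int(d["site"].nunique())
    df_t = max(n_sites - 2, 1)

    try:
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            if family == "continuous":
                # Random-site-intercept linear model, tested in its exact
                # balanced-design reduction: the forest effect lives entirely
                # in the between-site stratum, so the Wald t on per-site
                # means with n_sites - 2 df is the exact mixed-model test
                # (REML Wald t from a direct MixedLM fit shrinks the tail at
                # the site-variance boundary and over-rejects nothing but
                # under-rejects badly).
                site_means = d.groupby(["site", "forest"])["value"].mean().reset_index()
                a = site_means.loc[site_means["forest"] == "primary", "value"].to_numpy()
                b = site_means.loc[site_means["forest"] != "primary", "value"].to_numpy()
                coef = float(a.mean() - b.mean())
                se = float(
                    np.sqrt(
                        ((a.var(ddof=1) * (len(a) - 1) + b.var(ddof=1) * (len(b) - 1)) / (len(a) + len(b) - 2))
                        * (1.0 / len(a) + 1.0 / len(b))
                    )
                )
                stat_name = "t"
            elif family == "count":
                model = smf.glm("value ~ is_primary", d, family=sm.families.Poisson())
                fit = model.fit(scale="X2", cov_type="cluster", cov_kwds={"groups": d["site"]})
                coef = float(fit.params["is_primary"])
                se = float(fit.bse["is_primary"])
                stat_name = "t"
            else:  # binary
                model = smf.gee(
                    "value ~ is_primary",
                    groups="site",
                    data=d,
                    family=sm.families.Binomial(),
                    cov_struct=sm.cov_struct.Exchangeable(),
                )
                fit = model.fit()
                coef = float(fit.params["is_primary"])
                se = float(fit.bse["is_primary"])
                stat_name = "t"
        if not np.isfinite(coef) or not np.isfinite(se) or se <= 0:
            raise RuntimeError("non-finite estimate")
        t_stat = coef / se
        p = float(2.0 * sps.t.sf(abs(t_stat), df=df_t))
    except Exception as exc:  # estimation failure -> permutation fallback
        fallback = site_permutation_test(df, value_col, n_permutations, seed)
        fallback.converged = False
        fallback.note = f"model estimation failed ({type(exc).__name__}: {exc}); permutation fallback"
        fallback.extras["family"] = family
        return fallback

    means = d.groupby("forest")["value"].mean().to_dict()
    return TestResult(
        statistic_name=stat_name,
        statistic=float(t_stat),
        p=p,
        effect_direction="primary" if coef > 0 else "logged" if coef < 0 else "tie",
        group_means=means,
        n_per_group=d.groupby("forest").size().to_dict(),
        grouping="site",
        method={"continuous": "site-means-t", "count": "glm-quasipoisson-cluster", "binary": "gee-binomial"}[family],
        extras={"coef": coef, "se": se, "df": df_t, "family": family},
    )


def evenness_contrast(df: pd.DataFrame, value_col: str = "H_prime") -> TestResult:
    """Linear regression of per-unit Shannon diversity on forest type.

    Returns the forest-effect t statistic and p.  If every unit has the same
    H' (e.g. single-genus units everywhere) the contrast is degenerate and
    flagged rather than fitted.
    """
    import statsmodels.formula.api as smf

    d = df[[value_col, "forest"]].dropna().copy()
    d.columns = ["value", "forest"]
    counts = d.groupby("forest").size()
    if len(counts) < 2 or (counts < 3).any():
        raise ValueError("need at least 3 units per forest")
    means = d.groupby("forest")["value"].mean().to_dict()
    if np.allclose(d["value"].var(ddof=0), 0.0):
        return TestResult(
            statistic_name="t", statistic=float("nan"), p=float("nan"),
            effect_direction="tie", group_means=means,
            n_per_group=counts.to_dict(), method="ols", converged=False,
            note="degenerate: H' constant across all units",
        )
    d["is_primary"] = (d["forest"] == "primary").astype(float)
    fit = smf.ols("value ~ is_primary", d).fit()
    t_stat = float(fit.tvalues["is_primary"])
    return TestResult(
        statistic_name="t",
        statistic=t_stat,
        p=float(fit.pvalues["is_primary"]),
        effect_direction="primary" if t_stat > 0 else "logged" if t_stat < 0 else "tie",
        group_means=means,
        n_per_group=counts.to_dict(),
        method="ols",
        extras={"df_resid": float(fit.df_resid)},
    )
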