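"""Phenotypic and genotypic correlations among traits.

Phenotypic correlations are Pearson coefficients over genotype entry means
within one environment, pairwise-complete, with p-values from the t
distribution on n-2 df. Genotypic covariances come from mean cross products
of the genotype x replicate two-way layout (the bivariate analogue of the
single-environment ANOVA):

    cov_g(x, y) = (MCP_G - MCP_E) / r

whose diagonal reproduces the per-environment sigma2_g. Genotypic
correlations are cov_g normalised by the genotypic variances, clamped to
[-1, 1] (sampling noise can push the ratio outside) with the clamp flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import parse_env
from .anova import significance_stars


@dataclass
class CorrelationMatrix:
    """Trait x trait correlations with per-pair p-values and sample sizes."""

    r: pd.DataFrame
    p: pd.DataFrame | None
    n: pd.DataFrame
    kind: str
    clamped: list[tuple[str, str]] = field(default_factory=list)
    degenerate: list[str] = field(default_factory=list)

    def stars(self) -> pd.DataFrame:
        """Significance annex (* at 0.05, ** at 0.01) matching the p-values."""
        if self.p is None:
            raise ValueError(f"{self.kind} correlations carry no p-values")
        return self.p.map(significance_stars)


def phenotypic_correlation(means: pd.DataFrame) -> CorrelationMatrix:
    """Pearson correlations over genotypes, pairwise-complete.

    ``means`` is a genotype x trait entry-mean matrix. Pairs with fewer than
    3 complete genotypes, or involving a constant trait, get NaN (constant
    traits are listed in ``degenerate``).
    """
    traits = list(means.columns)
    k = len(traits)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    degenerate = []
    x = means.to_numpy(dtype=float)
    for i in range(k):
        col = x[:, i]
        if np.nanstd(col[np.isfinite(col)]) == 0:
            degenerate.append(traits[i])
    for i in range(k):
        r[i, i] = 1.0
        p[i, i] = 0.0
        n[i, i] = int(np.isfinite(x[:, i]).sum())
        for j in range(i + 1, k):
            ok = np.isfinite(x[:, i]) & np.isfinite(x[:, j])
            n[i, j] = n[j, i] = int(ok.sum())
            if ok.sum() < 3:
                continue
            xi, xj = x[ok, i], x[ok, j]
            if xi.std() == 0 or xj.std() == 0:
                continue
            res = stats.pearsonr(xi, xj)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    idx = pd.Index(traits)
    return CorrelationMatrix(
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        n=pd.DataFrame(n, index=idx, columns=idx),
        kind="phenotypic",
        degenerate=degenerate,
    )


def genetic_covariance(
    obs: pd.DataFrame, environment: str, traits: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genotypic covariance G and entry-mean phenotypic covariance P.

    Both are trait x trait DataFrames computed within one environment from
    the genotype x replicate layout; genotypes with any missing plot value
    for the requested traits are dropped (complete-case). G is returned
    unclamped (its diagonal equals the raw per-environment sigma2_g).
    """
    treatment, year = parse_env(environment)
    sub = obs.loc[(obs["treatment"] == treatment) & (obs["year"] == year)]
    if sub.empty:
        raise ValueError(f"unknown environment label {environment!r}")
    if traits is None:
        traits = list(dict.fromkeys(sub["trait"]))
    sub = sub.loc[sub["trait"].isin(traits)]
    wide = sub.pivot_table(
        index="genotype", columns=["rep", "trait"], values="value", sort=True
    )
    reps = sorted({c[0] for c in wide.columns})
    if len(reps) < 2:
        raise ValueError(f"environment {environment!r} has fewer than 2 replicates")
    full_cols = pd.MultiIndex.from_product([reps, traits])
    wide = wide.reindex(columns=full_cols).dropna(axis=0, how="any")
    g = len(wide)
    if g < 3:
        raise ValueError(
            f"environment {environment!r}: only {g} complete genotypes"
        )
    r = len(reps)
    t = len(traits)
    x = wide.to_numpy(dtype=float).reshape(g, r, t)

    gm = x.mean(axis=(0, 1))
    m_g = x.mean(axis=1)
    m_r = x.mean(axis=0)
    dev_g = m_g - gm
    mcp_g = r * (dev_g.T @ dev_g) / (g - 1)
    resid = x - m_g[:, None, :] - m_r[None, :, :] + gm
    e = resid.reshape(g * r, t)
    mcp_e = (e.T @ e) / ((g - 1) * (r - 1))
    cov_g = (mcp_g - mcp_e) / r

    p_cov = np.cov(m_g.T, ddof=1).reshape(t, t)
    idx = pd.Index(traits)
    return (
        pd.DataFrame(cov_g, index=idx, columns=idx),
        pd.DataFrame(p_cov, index=idx, columns=idx),
    )


def genotypic_correlation(G: pd.DataFrame) -> CorrelationMatrix:
    """Normalise a genotypic covariance matrix to correlations.

    r_g(i, j) = G_ij / sqrt(G_ii G_jj), clamped to [-1, 1] with the clamp
    recorded. Traits with non-positive genotypic variance are flagged and
    their rows/columns set missing. No p-values are attached (no standard
    errors are defined for the MCP estimator here).
    """
    traits = list(G.columns)
    g = G.to_numpy(dtype=float)
    diag = np.diag(g).copy()
    bad = diag <= 0
    degenerate = [t for t, flag in zip(traits, bad) if flag]
    safe = np.where(bad, np.nan, diag)
    denom = np.sqrt(np.outer(safe, safe))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = g / denom
    clamped = []
    k = len(traits)
    for i in range(k):
        for j in range(i + 1, k):
            if np.isfinite(r[i, j]) and abs(r[i, j]) > 1.0:
                clamped.append((traits[i], traits[j]))
    r = np.clip(r, -1.0, 1.0)
    for i in range(k):
        if not bad[i]:
            r[i, i] = 1.0
    idx = pd.Index(traits)
    n = pd.DataFrame(0, index=idx, columns=idx)
    return CorrelationMatrix(
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=None,
        n=n,
        kind="genotypic",
        clamped=clamped,
        degenerate=degenerate,
    )
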