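"""Variance components, F-tests and broad-sense heritability.

The combined analysis follows the crossed random-effects model

    Y_iknj = mu + y_k + t_n + g_i + r_j + (yg)_ik + (tg)_in + e

for genotype i, year k, treatment n, replicate j, with years, genotypes and
replicates random and treatment fixed. Any strata not listed (including the
three-way G x Y x T) are pooled into the error term. Method-of-moments
estimators from the balanced expected mean squares:

    sigma2_e  = MS_E
    sigma2_gy = (MS_GY - MS_E) / (b r)
    sigma2_gt = (MS_GT - MS_E) / (a r)
    sigma2_g  = (MS_G - MS_GY - MS_GT + MS_E) / (a b r)

with a years, b treatments, r replicates. Broad-sense heritability on an
entry-mean basis:

    H2 = sigma2_g / (sigma2_g + sigma2_gy/a + sigma2_gt/b + sigma2_e/(a b r))

The genotype F-test uses the synthesised denominator MS_GY + MS_GT - MS_E
with Satterthwaite degrees of freedom; interaction mean squares are tested
against MS_E, the year (treatment) main effect against its interaction with
genotype, and replicates against MS_E. Negative component estimates are
clamped to zero for reporting, with the raw values retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import parse_env


def significance_stars(p: float) -> str:
    """Two-tailed stars: ``**`` at 0.01, ``*`` at 0.05, empty otherwise."""
    if not np.isfinite(p):
        return ""
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


@dataclass
class VarianceComponents:
    """Combined-ANOVA summary for one trait."""

    trait: str
    df: dict[str, float]
    ms: dict[str, float]
    f: dict[str, float]
    p: dict[str, float]
    sigma2: dict[str, float]
    sigma2_raw: dict[str, float]
    h2: float
    f_g_denominator_df: float
    n_imputed: int = 0

    def to_row(self) -> dict:
        row: dict[str, float | str] = {"trait": self.trait}
        for k in ("Y", "T", "R", "G", "GY", "GT", "E"):
            row[f"MS_{k}"] = self.ms[k]
            row[f"df_{k}"] = self.df[k]
        for k, fv in self.f.items():
            row[f"F_{k}"] = fv
            row[f"sig_{k}"] = significance_stars(self.p[k])
        for k, v in self.sigma2.items():
            row[f"sigma2_{k}"] = v
        row["H2"] = self.h2
        return row


@dataclass
class EnvComponents:
    """Single-environment (year x treatment) RCBD ANOVA for one trait."""

    environment: str
    trait: str
    df: dict[str, float]
    ms: dict[str, float]
    f_g: float
    p_g: float
    sigma2_g: float
    sigma2_e: float
    sigma2_g_raw: float
    h2: float
    clamped: bool = False


def _pivot_balanced(
    sub: pd.DataFrame, levels: list[np.ndarray], names: list[str]
) -> np.ndarray:
    full = pd.MultiIndex.from_product(levels, names=names)
    s = sub.set_index(names)["value"]
    if s.index.has_duplicates:
        dups = s.index[s.index.duplicated()].tolist()
        raise ValueError(f"duplicate observations for keys {dups[:5]}")
    return s.reindex(full).to_numpy().reshape([len(lv) for lv in levels])


def _impute_cells(arr: np.ndarray, max_missing_frac: float, trait: str) -> tuple[np.ndarray, int]:
    """Replace missing replicate values by their (genotype, year, treatment)
    cell mean; error when a whole cell is empty or missingness is too high."""
    n_missing = int(np.isnan(arr).sum())
    if n_missing == 0:
        return arr, 0
    frac = n_missing / arr.size
    if frac > max_missing_frac:
        raise ValueError(
            f"trait {trait!r}: {frac:.1%} missing exceeds the "
            f"{max_missing_frac:.0%} imbalance tolerance"
        )
    cell_mean = np.nanmean(arr, axis=-1, keepdims=True)
    if np.isnan(cell_mean).any():
        raise ValueError(
            f"trait {trait!r}: at least one design cell has no observations"
        )
    out = np.where(np.isnan(arr), cell_mean, arr)
    warnings.warn(
        f"trait {trait!r}: imputed {n_missing} missing plot values by cell means",
        stacklevel=3,
    )
    return out, n_missing


def combined_anova(
    obs: pd.DataFrame, trait: str, max_missing_frac: float = 0.1
) -> VarianceComponents:
    """Combined ANOVA over years and treatments for one trait.

    Requires >= 2 levels of genotype, year, treatment and replicate; data
    must be balanced up to a tolerated fraction of missing plots, which are
    cell-mean imputed with a warning.
    """
    sub = obs.loc[obs["trait"] == trait]
    if sub.empty:
        raise ValueError(f"trait {trait!r} not present in the observations")
    names = ["genotype", "year", "treatment", "rep"]
    levels = [np.sort(sub[n].unique()) for n in names]
    g, a, b, r = (len(lv) for lv in levels)
    for n_lv, name in zip((g, a, b, r), names):
        if n_lv < 2:
            raise ValueError(
                f"trait {trait!r}: factor {name!r} has {n_lv} level(s); "
                "the combined analysis needs at least 2"
            )
    arr = _pivot_balanced(sub, levels, names)
    arr, n_imputed = _impute_cells(arr, max_missing_frac, trait)

    gm = arr.mean()
    m_g = arr.mean(axis=(1, 2, 3))
    m_y = arr.mean(axis=(0, 2, 3))
    m_t = arr.mean(axis=(0, 1, 3))
    m_r = arr.mean(axis=(0, 1, 2))
    m_gy = arr.mean(axis=(2, 3))
    m_gt = arr.mean(axis=(1, 3))

    ss = {
        "G": a * b * r * float(((m_g - gm) ** 2).sum()),
        "Y": g * b * r * float(((m_y - gm) ** 2).sum()),
        "T": g * a * r * float(((m_t - gm) ** 2).sum()),
        "R": g * a * b * float(((m_r - gm) ** 2).sum()),
        "GY": b * r * float(
            ((m_gy - m_g[:, None] - m_y[None, :] + gm) ** 2).sum()
        ),
        "GT": a * r * float(
            ((m_gt - m_g[:, None] - m_t[None, :] + gm) ** 2).sum()
        ),
    }
    ss_total = float(((arr - gm) ** 2).sum())
    df = {
        "G": g - 1.0,
        "Y": a - 1.0,
        "T": b - 1.0,
        "R": r - 1.0,
        "GY": (g - 1.0) * (a - 1.0),
        "GT": (g - 1.0) * (b - 1.0),
    }
    ss["E"] = ss_total - sum(ss.values())
    df["E"] = g * a * b * r - 1.0 - sum(df.values())
    ms = {k: (ss[k] / df[k] if df[k] > 0 else np.nan) for k in ss}

    # EMS method-of-moments components (see module docstring)
    raw = {
        "e": ms["E"],
        "gy": (ms["GY"] - ms["E"]) / (b * r),
        "gt": (ms["GT"] - ms["E"]) / (a * r),
        "g": (ms["G"] - ms["GY"] - ms["GT"] + ms["E"]) / (a * b * r),
    }
    clamped = {k: max(0.0, v) for k, v in raw.items()}
    denom = (
        clamped["g"] + clamped["gy"] / a + clamped["gt"] / b + clamped["e"] / (a * b * r)
    )
    h2 = float(np.clip(clamped["g"] / denom, 0.0, 1.0)) if denom > 0 else np.nan

    f: dict[str, float] = {}
    p: dict[str, float] = {}

    def _ftest(key: str, ms_num: float, ms_den: float, df_num: float, df_den: float):
        if ms_den <= 0:
            f[key] = np.inf if ms_num > 0 else np.nan
            p[key] = 0.0 if ms_num > 0 else np.nan
        else:
            f[key] = ms_num / ms_den
            p[key] = float(stats.f.sf(f[key], df_num, df_den))

    _ftest("Y", ms["Y"], ms["GY"], df["Y"], df["GY"])
    _ftest("T", ms["T"], ms["GT"], df["T"], df["GT"])
    _ftest("R", ms["R"], ms["E"], df["R"], df["E"])
    _ftest("GY", ms["GY"], ms["E"], df["GY"], df["E"])
    _ftest("GT", ms["GT"], ms["E"], df["GT"], df["E"])

    # genotype test against the synthesised denominator MS_GY + MS_GT - MS_E
    den = ms["GY"] + ms["GT"] - ms["E"]
    if den > 0:
        sat_df = den**2 / (
            ms["GY"] ** 2 / df["GY"] + ms["GT"] ** 2 / df["GT"] + ms["E"] ** 2 / df["E"]
        )
        f["G"] = ms["G"] / den
        p["G"] = float(stats.f.sf(f["G"], df["G"], sat_df))
    else:
        sat_df = np.nan
        f["G"] = np.nan
        p["G"] = np.nan

    return VarianceComponents(
        trait=trait,
        df=df,
        ms=ms,
        f=f,
        p=p,
        sigma2=clamped,
        sigma2_raw=raw,
        h2=h2,
        f_g_denominator_df=float(sat_df),
        n_imputed=n_imputed,
    )


def per_env_anova(obs: pd.DataFrame, trait: str, environment: str) -> EnvComponents:
    """RCBD genotype x replicate ANOVA within one year x treatment.

    sigma2_g = (MS_G - MS_E)/r and H2_env = sigma2_g/(sigma2_g + sigma2_e/r);
    a negative genotypic component is clamped to zero and flagged.
    """
    treatment, year = parse_env(environment)
    sub = obs.loc[
        (obs["trait"] == trait)
        & (obs["treatment"] == treatment)
        & (obs["year"] == year)
    ]
    if sub.empty:
        raise ValueError(f"environment {environment!r} has no data for {trait!r}")
    names = ["genotype", "rep"]
    levels = [np.sort(sub[n].unique()) for n in names]
    g, r = len(levels[0]), len(levels[1])
    if r < 2:
        raise ValueError(
            f"environment {environment!r} has a single replicate; no error df"
        )
    if g < 2:
        raise ValueError(f"environment {environment!r} has fewer than 2 genotypes")
    arr = _pivot_balanced(sub, levels, names)
    if np.isnan(arr).any():
        arr, _ = _impute_cells(arr[:, None, :], 0.1, trait)  # cell = genotype here
        arr = arr[:, 0, :]

    gm = arr.mean()
    m_g = arr.mean(axis=1)
    m_r = arr.mean(axis=0)
    ss_g = r * float(((m_g - gm) ** 2).sum())
    ss_r = g * float(((m_r - gm) ** 2).sum())
    ss_e = float(((arr - m_g[:, None] - m_r[None, :] + gm) ** 2).sum())
    df = {"G": g - 1.0, "R": r - 1.0, "E": (g - 1.0) * (r - 1.0)}
    ms = {"G": ss_g / df["G"], "R": ss_r / df["R"], "E": ss_e / df["E"]}

    sigma2_e = ms["E"]
    raw_g = (ms["G"] - ms["E"]) / r
    sigma2_g = max(0.0, raw_g)
    denom = sigma2_g + sigma2_e / r
    h2 = float(np.clip(sigma2_g / denom, 0.0, 1.0)) if denom > 0 else np.nan
    if ms["E"] > 0:
        f_g = ms["G"] / ms["E"]
        p_g = float(stats.f.sf(f_g, df["G"], df["E"]))
    else:
        f_g = np.inf if ms["G"] > 0 else np.nan
        p_g = 0.0 if ms["G"] > 0 else np.nan
    return EnvComponents(
        environment=environment,
        trait=trait,
        df=df,
        ms=ms,
        f_g=f_g,
        p_g=p_g,
        sigma2_g=sigma2_g,
        sigma2_e=sigma2_e,
        sigma2_g_raw=raw_g,
        h2=h2,
        clamped=raw_g < 0,
    )


def genotype_means(
    obs: pd.DataFrame,
    environment: str | None = None,
    traits: list[str] | None = None,
) -> pd.DataFrame:
    """Entry means (genotype x trait) within one environment.

    Means are taken over the replicates that are present; a genotype/trait
    cell is missing only when every replicate is missing. With
    ``environment=None`` the mean is over the whole trial.
    """
    sub = obs
    if environment is not None:
        treatment, year = parse_env(environment)
        sub = obs.loc[(obs["treatment"] == treatment) & (obs["year"] == year)]
        if sub.empty:
            raise ValueError(f"unknown environment label {environment!r}")
    if traits is not None:
        sub = sub.loc[sub["trait"].isin(traits)]
    trait_order = (
        [t for t in traits if t in set(sub["trait"])]
        if traits is not None
        else list(dict.fromkeys(sub["trait"]))
    )
    means = (
        sub.groupby(["genotype", "trait"], sort=True)["value"]
        .mean()
        .unstack("trait")
        .reindex(columns=trait_order)
    )
    means.columns.name = None
    return means


def anova_report(components: list[VarianceComponents]) -> pd.DataFrame:
    """One row per trait with MS, df, F, sigma2 and H2 columns."""
    return pd.DataFrame([vc.to_row() for vc in components]).set_index("trait")
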