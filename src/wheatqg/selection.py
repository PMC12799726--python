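"""Smith-Hazel selection indices and extreme-genotype selection.

The Smith-Hazel index is the linear phenotype combination b'x maximising
the correlation with the aggregate genotypic value H = w'g; its
coefficients solve P b = G w, with P the phenotypic and G the genotypic
trait covariance matrix and w the economic weights. Here the spike index
(SI) applies it to grain yield per spike and its secondary traits, the
peduncle index (PI) to peduncle weight and diameter, and the drought index
standardises and averages the two:

    DI = 1/2 * (SI / SD_SI + PI / SD_PI)

with SD the sample (n-1) standard deviation of each index over genotypes.
High DI identifies the best-performing genotypes under drought; per-year
top/bottom sets are intersected across years to find consistently extreme
genotypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg


def bend_psd(mat: np.ndarray, floor_frac: float = 1e-8) -> np.ndarray:
    """Clamp negative eigenvalues to a small positive floor (bending).

    Sampling noise can make an estimated covariance matrix indefinite; the
    floor is ``floor_frac`` of the trace, keeping the matrix usable in the
    index solve without materially changing it.
    """
    mat = np.asarray(mat, dtype=float)
    mat = (mat + mat.T) / 2.0
    vals, vecs = np.linalg.eigh(mat)
    floor = floor_frac * max(np.trace(mat), np.finfo(float).tiny)
    if vals.min() >= floor:
        return mat
    vals = np.clip(vals, floor, None)
    return (vecs * vals) @ vecs.T


def smith_hazel_coefficients(
    P: pd.DataFrame | np.ndarray,
    G: pd.DataFrame | np.ndarray,
    w: np.ndarray | list[float],
    bend: bool = True,
    cond_threshold: float = 1e12,
    residual_tol: float = 1e-8,
) -> np.ndarray:
    """Solve P b = G w for the index coefficient vector b.

    For a single trait this reduces to b = sigma2_g / sigma2_p, the trait's
    heritability. ``bend=True`` repairs indefinite estimated P (and G)
    before solving; a P that is still numerically singular raises with a
    suggestion to bend. The solution is verified to satisfy
    ``||P b - G w|| / ||G w|| <= residual_tol``.
    """
    p = np.asarray(P, dtype=float)
    g = np.asarray(G, dtype=float)
    w = np.asarray(w, dtype=float)
    k = w.shape[0]
    if p.shape != (k, k) or g.shape != (k, k):
        raise ValueError(
            f"dimension mismatch: P {p.shape}, G {g.shape}, w ({k},)"
        )
    if not np.allclose(p, p.T, atol=1e-8 * max(1.0, np.abs(p).max())):
        raise ValueError("P must be symmetric")
    if bend:
        p = bend_psd(p)
        g_solve = bend_psd(g)
    else:
        g_solve = g
    if np.linalg.cond(p) > cond_threshold:
        raise np.linalg.LinAlgError(
            "P is numerically singular; consider bending (bend=True) or "
            "removing collinear traits"
        )
    rhs = g_solve @ w
    b = linalg.solve(p, rhs, assume_a="sym")
    denom = np.linalg.norm(rhs)
    if denom > 0:
        resid = np.linalg.norm(p @ b - rhs) / denom
        if resid > residual_tol:
            raise np.linalg.LinAlgError(
                f"index solve residual {resid:.2e} exceeds {residual_tol:.0e}"
            )
    return b


def expected_index_accuracy(
    P: np.ndarray, G: np.ndarray, w: np.ndarray
) -> float:
    """Closed-form corr(b'x, w'g) = sqrt(w'G P^-1 G w / w'G w)."""
    P = np.asarray(P, float)
    G = np.asarray(G, float)
    w = np.asarray(w, float)
    gw = G @ w
    num = float(gw @ np.linalg.solve(P, gw))
    den = float(w @ gw)
    return float(np.sqrt(num / den))


def index_values(
    b: np.ndarray | list[float], means: pd.DataFrame
) -> pd.Series:
    """Per-genotype index b'x over a genotype x trait entry-mean matrix.

    Trait order of ``b`` must match the columns. A genotype missing any
    trait value gets a missing index (and is reported via a warning).
    """
    b = np.asarray(b, dtype=float)
    if b.shape[0] != means.shape[1]:
        raise ValueError(
            f"{b.shape[0]} coefficients for {means.shape[1]} trait columns"
        )
    x = means.to_numpy(dtype=float)
    out = x @ b
    incomplete = ~np.isfinite(x).all(axis=1)
    if incomplete.any():
        out = out.copy()
        out[incomplete] = np.nan
        warnings.warn(
            f"{int(incomplete.sum())} genotype(s) with missing trait values "
            "have a missing index",
            stacklevel=2,
        )
    return pd.Series(out, index=means.index, name="index")


@dataclass
class IndexResult:
    """SI, PI and the standardised drought index DI per genotype."""

    si: pd.Series
    pi: pd.Series
    di: pd.Series
    sd_si: float
    sd_pi: float
    year: str | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"SI": self.si, "PI": self.pi, "DI": self.di})
        df.index.name = "genotype"
        df["rank"] = df["DI"].rank(ascending=False, method="min").astype("Int64")
        return df


def drought_index(
    si: pd.Series, pi: pd.Series, year: str | None = None
) -> IndexResult:
    """DI = 1/2 (SI/SD_SI + PI/SD_PI) over the shared genotype set.

    SDs are sample (n-1) standard deviations over genotypes; a constant
    index (zero SD) is an error. Mismatched genotype sets are intersected
    with a warning.
    """
    if not si.index.equals(pi.index):
        common = si.index.intersection(pi.index)
        if len(common) == 0:
            raise ValueError("SI and PI genotype sets are disjoint")
        warnings.warn(
            f"SI and PI genotype sets differ; using the {len(common)} common genotypes",
            stacklevel=2,
        )
        si, pi = si.loc[common], pi.loc[common]
    sd_si = float(si.std(ddof=1))
    sd_pi = float(pi.std(ddof=1))
    if not np.isfinite(sd_si) or sd_si == 0:
        raise ValueError("SI is constant (zero SD); DI undefined")
    if not np.isfinite(sd_pi) or sd_pi == 0:
        raise ValueError("PI is constant (zero SD); DI undefined")
    di = 0.5 * (si / sd_si + pi / sd_pi)
    return IndexResult(si=si, pi=pi, di=di.rename("DI"), sd_si=sd_si, sd_pi=sd_pi, year=year)


@dataclass
class SelectionOutcome:
    """Top-k and bottom-k genotype lists for one year."""

    top: list[str]
    bottom: list[str]
    k: int
    tie_at_boundary: bool = False
    year: str | None = None


def select_extremes(di: pd.Series, k: int, year: str | None = None) -> SelectionOutcome:
    """Select the k highest- and k lowest-DI genotypes.

    Ties are broken lexicographically by genotype id (deterministic) and a
    tie crossing the rank-k boundary is flagged. Selecting k = n (top and
    bottom covering the whole set) is allowed with a warning.
    """
    di = di.dropna()
    n = len(di)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} genotypes with defined DI")
    desc_ids = sorted(di.index, key=lambda g: (-di[g], g))
    asc_ids = sorted(di.index, key=lambda g: (di[g], g))
    top = desc_ids[:k]
    bottom = asc_ids[:k]
    tie_top = k < n and di[desc_ids[k - 1]] == di[desc_ids[k]]
    tie_bottom = k < n and di[asc_ids[k - 1]] == di[asc_ids[k]]
    if set(top) & set(bottom):
        warnings.warn(
            "top and bottom selections overlap (k is large relative to n)",
            stacklevel=2,
        )
    return SelectionOutcome(
        top=top,
        bottom=bottom,
        k=k,
        tie_at_boundary=bool(tie_top or tie_bottom),
        year=year,
    )


@dataclass
class YearIntersection:
    """Cross-year common genotypes and per-year exclusives."""

    common: set[str]
    exclusives: dict[str, set[str]] = field(default_factory=dict)


def intersect_years(sets: dict[str, set[str] | list[str]]) -> YearIntersection:
    """Intersect per-year genotype sets (replaces a Venn-diagram tool)."""
    if len(sets) < 2:
        raise ValueError("need at least 2 per-year sets to intersect")
    as_sets = {y: set(s) for y, s in sets.items()}
    common = set.intersection(*as_sets.values())
    exclusives = {
        y: s - set.union(*(t for z, t in as_sets.items() if z != y))
        for y, s in as_sets.items()
    }
    return YearIntersection(common=common, exclusives=exclusives)
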