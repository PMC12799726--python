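"""Reduction due to drought (RDD) and soil-moisture unit conversion.

RDD expresses how much a trait mean drops under drought relative to the
well-watered control, as a percentage:

    RDD = (Xn - Xd) / Xn * 100

where Xn and Xd are the trait means under normal irrigation and drought.
Negative values are allowed (the trait was higher under drought, as can
happen for thousand-kernel weight). RDD is undefined when Xn = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def rdd(xn: float, xd: float) -> float:
    """Percent reduction due to drought; NaN (undefined) when ``xn`` is 0."""
    if xn == 0:
        return float("nan")
    return (xn - xd) / xn * 100.0


@dataclass
class RddTable:
    """Per-genotype RDD values plus two per-trait summaries.

    ``rdd_of_means`` applies the RDD formula to the trait means over
    genotypes (the headline convention: the formula operates on the overall
    trait averages); ``mean_of_rdd`` averages the per-genotype RDD values.
    The two coincide only when Xn is constant across genotypes, so both are
    reported, clearly labelled.
    """

    values: pd.DataFrame
    rdd_of_means: pd.Series
    mean_of_rdd: pd.Series
    n_only_normal: int = 0
    n_only_drought: int = 0

    @property
    def trait_mean(self) -> pd.Series:
        """Headline per-trait RDD (the rdd-of-means convention)."""
        return self.rdd_of_means


def rdd_table(means_n: pd.DataFrame, means_d: pd.DataFrame) -> RddTable:
    """Elementwise RDD between two genotype x trait entry-mean matrices.

    Genotypes present under only one condition are excluded and counted.
    Raises ``ValueError`` when the genotype sets are disjoint.
    """
    common = means_n.index.intersection(means_d.index)
    if len(common) == 0:
        raise ValueError("genotype sets under N and D are disjoint")
    traits = means_n.columns.intersection(means_d.columns)
    xn = means_n.loc[common, traits].to_numpy(dtype=float)
    xd = means_d.loc[common, traits].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.where(xn == 0, np.nan, (xn - xd) / xn * 100.0)
    values = pd.DataFrame(vals, index=common, columns=traits)
    col_n = np.nanmean(xn, axis=0)
    col_d = np.nanmean(xd, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rom = np.where(col_n == 0, np.nan, (col_n - col_d) / col_n * 100.0)
    return RddTable(
        values=values,
        rdd_of_means=pd.Series(rom, index=traits),
        mean_of_rdd=values.mean(axis=0, skipna=True),
        n_only_normal=int(len(means_n.index.difference(means_d.index))),
        n_only_drought=int(len(means_d.index.difference(means_n.index))),
    )


def gravimetric_to_volumetric(theta_g: float, bulk_density: float = 1.2) -> float:
    """Convert gravimetric soil moisture (mass %) to volumetric (vol %).

    Volumetric content is the gravimetric content multiplied by the soil
    bulk density (g/cm^3); the default 1.2 g/cm^3 is typical of a clay-loam
    field soil.
    """
    if theta_g < 0:
        raise ValueError("gravimetric moisture must be >= 0")
    if bulk_density <= 0:
        raise ValueError("bulk density must be > 0")
    return theta_g * bulk_density
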