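"""Synthetic multi-environment wheat trials and SNP panels.

The phenotype generator draws from the crossed random-effects model used by
the analysis: an observation on genotype *i*, year *k*, treatment *n*,
replicate *j* is

    y = mu + year_k + treat_n + g_i + gy_ik + gt_in + r_j + e

with g, gy, gt multivariate Gaussian across traits (covariances Sigma_g,
Sigma_gy, Sigma_gt) and plot residual e ~ N(0, Sigma_e). Treatment is a
fixed shift (drought reduces yield-type traits); years and genotypes are
random. The SNP generator emulates an inbred-line array panel: markers are
independent, per-marker alternate-allele frequency drawn uniformly in a MAF
window, with optional planted group-differentiating markers and planted
marker-trait effects for recovery tests.

A single master seed deterministically derives per-component substreams
(genotype, G x Y, G x T, replicate, residual, missingness) via
``numpy.random.SeedSequence.spawn``, so any fixture can be regenerated.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .snp import SnpMatrix

TREATMENT_LABELS = ("N", "D")

# 21 bread-wheat chromosomes, used to lay simulated markers out on a map
WHEAT_CHROMOSOMES = tuple(f"{n}{g}" for n in range(1, 8) for g in "ABD")


@dataclass(frozen=True)
class TrialDesign:
    """Balanced crossed trial layout: genotypes x years x treatments x reps."""

    n_genotypes: int
    n_years: int = 2
    n_treatments: int = 2
    n_reps: int = 2
    trait_names: tuple[str, ...] = ("GYPS",)
    first_year: int = 2020

    def __post_init__(self) -> None:
        for name in ("n_genotypes", "n_years", "n_treatments", "n_reps"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_treatments > len(TREATMENT_LABELS):
            raise ValueError(
                f"at most {len(TREATMENT_LABELS)} treatments supported "
                f"(labels {TREATMENT_LABELS})"
            )
        if len(set(self.trait_names)) != len(self.trait_names):
            raise ValueError("trait names must be unique")
        if not self.trait_names:
            raise ValueError("at least one trait is required")

    @property
    def genotype_ids(self) -> list[str]:
        width = max(3, len(str(self.n_genotypes)))
        return [f"G{i + 1:0{width}d}" for i in range(self.n_genotypes)]

    @property
    def year_labels(self) -> list[str]:
        return [str(self.first_year + k) for k in range(self.n_years)]

    @property
    def treatment_labels(self) -> list[str]:
        return list(TREATMENT_LABELS[: self.n_treatments])

    @property
    def rep_labels(self) -> list[str]:
        return [f"R{j + 1}" for j in range(self.n_reps)]

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)


def _check_psd(mat: np.ndarray, name: str, dim: int) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if mat.shape != (dim, dim):
        raise ValueError(f"{name} has shape {mat.shape}, expected ({dim}, {dim})")
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError(f"{name} is not symmetric")
    eig = np.linalg.eigvalsh(mat)
    tol = 1e-8 * max(1.0, float(np.trace(mat)))
    if eig.min() < -tol:
        raise ValueError(f"{name} is not positive semi-definite (min eigenvalue {eig.min():.3g})")
    return mat


def _psd_sqrt(mat: np.ndarray) -> np.ndarray:
    """Symmetric square root with tiny negative eigenvalues clamped to 0."""
    vals, vecs = np.linalg.eigh(mat)
    vals = np.clip(vals, 0.0, None)
    return vecs * np.sqrt(vals)


@dataclass
class TrueComponents:
    """Ground-truth (co)variances and fixed effects for ``simulate_trial``.

    All covariance matrices are trait x trait, in squared trait units.
    ``year_effects`` has one row per year, ``treatment_effects`` one row per
    treatment (the drought row should be <= 0 for yield-type traits when
    emulating a stress trial). ``rep_sigma2`` gives per-trait variances of the
    random replicate main effect (default zero).
    """

    mu: np.ndarray
    sigma_g: np.ndarray
    sigma_gy: np.ndarray
    sigma_gt: np.ndarray
    sigma_e: np.ndarray
    year_effects: np.ndarray | None = None
    treatment_effects: np.ndarray | None = None
    rep_sigma2: np.ndarray | None = None

    @classmethod
    def diagonal(
        cls,
        n_traits: int,
        mu: float | np.ndarray = 0.0,
        sigma2_g: float = 1.0,
        sigma2_gy: float = 0.0,
        sigma2_gt: float = 0.0,
        sigma2_e: float = 1.0,
        **kwargs,
    ) -> "TrueComponents":
        """Uncorrelated-trait shortcut with equal variances per component."""
        eye = np.eye(n_traits)
        return cls(
            mu=np.full(n_traits, mu, dtype=float) if np.isscalar(mu) else np.asarray(mu, float),
            sigma_g=sigma2_g * eye,
            sigma_gy=sigma2_gy * eye,
            sigma_gt=sigma2_gt * eye,
            sigma_e=sigma2_e * eye,
            **kwargs,
        )

    def validate(self, design: TrialDesign) -> None:
        t = design.n_traits
        self.mu = np.asarray(self.mu, dtype=float)
        if self.mu.shape != (t,):
            raise ValueError(f"mu has shape {self.mu.shape}, expected ({t},)")
        self.sigma_g = _check_psd(self.sigma_g, "sigma_g", t)
        self.sigma_gy = _check_psd(self.sigma_gy, "sigma_gy", t)
        self.sigma_gt = _check_psd(self.sigma_gt, "sigma_gt", t)
        self.sigma_e = _check_psd(self.sigma_e, "sigma_e", t)
        if self.year_effects is not None:
            self.year_effects = np.asarray(self.year_effects, float)
            if self.year_effects.shape != (design.n_years, t):
                raise ValueError("year_effects shape must be (n_years, n_traits)")
        if self.treatment_effects is not None:
            self.treatment_effects = np.asarray(self.treatment_effects, float)
            if self.treatment_effects.shape != (design.n_treatments, t):
                raise ValueError("treatment_effects shape must be (n_treatments, n_traits)")
        if self.rep_sigma2 is not None:
            self.rep_sigma2 = np.asarray(self.rep_sigma2, float)
            if self.rep_sigma2.shape != (t,):
                raise ValueError("rep_sigma2 shape must be (n_traits,)")
            if (self.rep_sigma2 < 0).any():
                raise ValueError("rep_sigma2 must be non-negative")


def simulate_trial(
    design: TrialDesign,
    truth: TrueComponents,
    seed: int,
    missing_rate: float = 0.0,
    return_effects: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one balanced trial as a long-format observation table.

    Returns a DataFrame with columns ``genotype, year, treatment, rep,
    trait, value`` — one row per plot x trait, in canonical (product) order.
    Identical ``(design, truth, seed)`` yields an identical table. With
    ``return_effects=True`` also returns the drawn true genotypic effects
    as a genotype x trait DataFrame (for recovery tests); the observation
    table itself is unaffected by the flag.
    """
    truth.validate(design)
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")

    g, a, b, r, t = (
        design.n_genotypes,
        design.n_years,
        design.n_treatments,
        design.n_reps,
        design.n_traits,
    )
    streams = np.random.SeedSequence(seed).spawn(6)
    rng_g, rng_gy, rng_gt, rng_rep, rng_e, rng_miss = (
        np.random.default_rng(s) for s in streams
    )

    g_eff = rng_g.standard_normal((g, t)) @ _psd_sqrt(truth.sigma_g).T
    gy_eff = rng_gy.standard_normal((g, a, t)) @ _psd_sqrt(truth.sigma_gy).T
    gt_eff = rng_gt.standard_normal((g, b, t)) @ _psd_sqrt(truth.sigma_gt).T
    e_eff = rng_e.standard_normal((g, a, b, r, t)) @ _psd_sqrt(truth.sigma_e).T
    if truth.rep_sigma2 is not None:
        rep_eff = rng_rep.standard_normal((r, t)) * np.sqrt(truth.rep_sigma2)
    else:
        rep_eff = np.zeros((r, t))

    values = (
        truth.mu[None, None, None, None, :]
        + g_eff[:, None, None, None, :]
        + gy_eff[:, :, None, None, :]
        + gt_eff[:, None, :, None, :]
        + rep_eff[None, None, None, :, :]
        + e_eff
    )
    if truth.year_effects is not None:
        values = values + truth.year_effects[None, :, None, None, :]
    if truth.treatment_effects is not None:
        values = values + truth.treatment_effects[None, None, :, None, :]

    flat = values.reshape(-1)
    if missing_rate > 0.0:
        mask = rng_miss.random(flat.shape) < missing_rate
        flat = flat.copy()
        flat[mask] = np.nan

    index = pd.MultiIndex.from_product(
        [
            design.genotype_ids,
            design.year_labels,
            design.treatment_labels,
            design.rep_labels,
            list(design.trait_names),
        ],
        names=["genotype", "year", "treatment", "rep", "trait"],
    )
    out = index.to_frame(index=False)
    out["value"] = flat
    if return_effects:
        effects = pd.DataFrame(
            g_eff, index=design.genotype_ids, columns=list(design.trait_names)
        )
        effects.index.name = "genotype"
        return out, effects
    return out


def true_entry_mean_variance(design: TrialDesign, truth: TrueComponents) -> np.ndarray:
    """Closed-form covariance of genotype entry means over the whole trial.

    Var(mean over years/treatments/reps per genotype) =
    Sigma_g + Sigma_gy/a + Sigma_gt/b + Sigma_e/(a*b*r).
    """
    a, b, r = design.n_years, design.n_treatments, design.n_reps
    return (
        np.asarray(truth.sigma_g, float)
        + np.asarray(truth.sigma_gy, float) / a
        + np.asarray(truth.sigma_gt, float) / b
        + np.asarray(truth.sigma_e, float) / (a * b * r)
    )


# ---------------------------------------------------------------------------
# Default study-like parameterisation
# ---------------------------------------------------------------------------

#: Trait order used by the example truth: spike traits then peduncle traits.
EXAMPLE_TRAITS = ("GYPS", "GNPS", "NSPS", "PW", "PD")

#: Spike/peduncle grouping matching the selection indices.
EXAMPLE_TRAIT_GROUPS = {"spike": ["GYPS", "GNPS", "NSPS"], "peduncle": ["PW", "PD"]}


def example_design(n_genotypes: int = 200) -> TrialDesign:
    """Two years x two treatments (N/D) x two replicates, five traits."""
    return TrialDesign(
        n_genotypes=n_genotypes,
        n_years=2,
        n_treatments=2,
        n_reps=2,
        trait_names=EXAMPLE_TRAITS,
    )


def example_truth() -> TrueComponents:
    """Study-like ground truth for the five spike/peduncle traits.

    Trait means and drought shifts are on the scale of a spring-wheat trial
    (grain yield per spike ~2.8 g, ~63 grains and ~26 spikelets per spike,
    peduncle weight ~0.66 g, diameter ~3.5 mm; drought reduces every trait,
    peduncle weight most strongly). Genetic correlations are moderate and
    positive within and between the spike and peduncle groups; residual
    correlations are deliberately weaker than genetic ones, so genotypic
    correlations exceed phenotypic ones, and entry-mean heritabilities come
    out high (~0.9).
    """
    mu = np.array([2.8, 63.0, 26.0, 0.66, 3.5])
    sd_g = np.array([0.42, 9.0, 2.4, 0.10, 0.35])
    corr_g = np.array(
        [
            [1.00, 0.80, 0.20, 0.45, 0.50],
            [0.80, 1.00, 0.35, 0.35, 0.45],
            [0.20, 0.35, 1.00, 0.10, 0.20],
            [0.45, 0.35, 0.10, 1.00, 0.70],
            [0.50, 0.45, 0.20, 0.70, 1.00],
        ]
    )
    sigma_g = np.outer(sd_g, sd_g) * corr_g
    sd_e = 0.5 * sd_g
    corr_e = 0.3 * corr_g + 0.7 * np.eye(5)
    sigma_e = np.outer(sd_e, sd_e) * corr_e
    year_effects = np.array([[0.0] * 5, [-0.05, -1.0, -0.3, -0.02, -0.10]])
    # Drought shifts sized so trait reductions land near the observed range
    # (peduncle weight ~24%, diameter ~16%, spikelet number only ~2.5%).
    treatment_effects = np.array(
        [[0.0] * 5, [-0.25, -3.1, -0.67, -0.157, -0.56]]
    )
    return TrueComponents(
        mu=mu,
        sigma_g=sigma_g,
        sigma_gy=0.06 * sigma_g,
        sigma_gt=0.08 * sigma_g,
        sigma_e=sigma_e,
        year_effects=year_effects,
        treatment_effects=treatment_effects,
    )


# ---------------------------------------------------------------------------
# SNP panel
# ---------------------------------------------------------------------------


@dataclass
class SnpPanel:
    """A simulated panel plus its planted ground truth."""

    matrix: SnpMatrix
    distinct_markers: list[str] = field(default_factory=list)
    qtl: list[tuple[str, str, float]] = field(default_factory=list)

    def truth_dict(self) -> dict:
        """JSON-serialisable sidecar recording what was planted."""
        return {
            "distinct_markers": list(self.distinct_markers),
            "qtl": [
                {"marker": m, "trait": tr, "effect": float(eff)}
                for m, tr, eff in self.qtl
            ],
        }


def simulate_snp_panel(
    n_markers: int,
    sample_ids: list[str],
    maf_low: float = 0.05,
    maf_high: float = 0.5,
    planted_distinct: int = 0,
    group_a: list[str] | tuple[str, ...] = (),
    group_b: list[str] | tuple[str, ...] = (),
    planted_qtl: list[tuple[str, float]] | tuple = (),
    seed: int = 0,
    het_rate: float = 0.0,
    missing_rate: float = 0.0,
) -> SnpPanel:
    """Simulate an inbred-line biallelic marker panel.

    Per marker, the alternate-allele frequency is drawn uniformly in
    ``[maf_low, maf_high]`` and each line's call is 0 or 2 (inbred lines are
    homozygous); ``het_rate``/``missing_rate`` optionally corrupt calls for
    QC testing. Exactly ``planted_distinct`` markers are constructed with
    ``group_a`` fixed alternate-homozygous and ``group_b`` fixed
    reference-homozygous. ``planted_qtl`` is a list of ``(trait, effect)``
    pairs; each gets its own marker, and the returned panel records which,
    so marker-trait recovery tests can add ``effect * dosage / 2`` to the
    named trait (``effect`` is the alt-hom minus ref-hom class difference).
    """
    if n_markers < 0:
        raise ValueError("n_markers must be >= 0")
    if not 0.0 < maf_low <= maf_high <= 0.5:
        raise ValueError("require 0 < maf_low <= maf_high <= 0.5")
    group_a, group_b = list(group_a), list(group_b)
    unknown = (set(group_a) | set(group_b)) - set(sample_ids)
    if unknown:
        raise ValueError(f"group samples not in sample_ids: {sorted(unknown)}")
    if set(group_a) & set(group_b):
        raise ValueError("group_a and group_b must be disjoint")
    if planted_distinct > 0 and (not group_a or not group_b):
        raise ValueError("planted_distinct > 0 requires non-empty groups")
    n_special = planted_distinct + len(planted_qtl)
    if n_special > n_markers:
        raise ValueError(
            f"{n_special} planted markers exceed n_markers={n_markers}"
        )

    n_samples = len(sample_ids)
    streams = np.random.SeedSequence(seed).spawn(5)
    rng_freq, rng_calls, rng_place, rng_het, rng_miss = (
        np.random.default_rng(s) for s in streams
    )

    marker_ids = [f"M{i + 1:05d}" for i in range(n_markers)]
    chrom = [WHEAT_CHROMOSOMES[i % len(WHEAT_CHROMOSOMES)] for i in range(n_markers)]
    pos = np.arange(n_markers) // len(WHEAT_CHROMOSOMES) * 1000 + 1

    p = rng_freq.uniform(maf_low, maf_high, size=n_markers)
    calls = 2.0 * (rng_calls.random((n_markers, n_samples)) < p[:, None])

    special = rng_place.choice(n_markers, size=n_special, replace=False) if n_special else np.array([], int)
    distinct_idx = special[:planted_distinct]
    qtl_idx = special[planted_distinct:]

    a_cols = [sample_ids.index(s) for s in group_a]
    b_cols = [sample_ids.index(s) for s in group_b]
    for i in distinct_idx:
        calls[i, a_cols] = 2.0
        calls[i, b_cols] = 0.0

    if het_rate > 0.0:
        het_mask = rng_het.random(calls.shape) < het_rate
        het_mask[distinct_idx, :] = False
        calls[het_mask] = 1.0
    if missing_rate > 0.0:
        miss_mask = rng_miss.random(calls.shape) < missing_rate
        miss_mask[distinct_idx, :] = False
        calls[miss_mask] = np.nan

    matrix = SnpMatrix(
        marker_ids=marker_ids,
        chrom=chrom,
        pos=pos + 1,
        samples=list(sample_ids),
        calls=calls,
        meta={"source": "simulated", "seed": int(seed)},
    )
    qtl = [
        (marker_ids[i], trait, float(effect))
        for i, (trait, effect) in zip(qtl_idx, planted_qtl)
    ]
    return SnpPanel(
        matrix=matrix,
        distinct_markers=[marker_ids[i] for i in distinct_idx],
        qtl=qtl,
    )


def simulate_ld_pair(
    n_samples: int, r: float, maf: float = 0.3, seed: int = 0
) -> SnpMatrix:
    """Two-marker panel with correlated inbred calls, for LD r^2 testing.

    The second marker copies the first's call with probability chosen so the
    dosage correlation is approximately ``r`` at the given allele frequency.
    """
    if not -1.0 <= r <= 1.0:
        raise ValueError("r must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    x = 2.0 * (rng.random(n_samples) < maf)
    copy = rng.random(n_samples) < abs(r)
    y_indep = 2.0 * (rng.random(n_samples) < maf)
    y = np.where(copy, x if r >= 0 else 2.0 - x, y_indep)
    return SnpMatrix(
        marker_ids=["L1", "L2"],
        chrom=["6D", "6D"],
        pos=np.array([1000, 2000]),
        samples=[f"S{i + 1:03d}" for i in range(n_samples)],
        calls=np.vstack([x, y]),
        meta={"source": "simulated-ld-pair"},
    )


def qtl_phenotype(panel: SnpPanel, trait: str) -> pd.Series:
    """Per-sample additive contribution of the planted QTL for one trait."""
    contrib = np.zeros(panel.matrix.n_samples)
    for marker, tr, effect in panel.qtl:
        if tr != trait:
            continue
        row = panel.matrix.calls[panel.matrix.marker_index(marker)]
        contrib = contrib + effect * np.nan_to_num(row) / 2.0
    return pd.Series(contrib, index=panel.matrix.samples, name=trait)
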