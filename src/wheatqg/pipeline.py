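"""End-to-end orchestration of the phenotype and marker analysis stages.

The phenotype stage runs, per trait: combined and per-environment ANOVA
with variance components and heritability; phenotypic and genotypic
correlations per environment; per-year drought-reduction (RDD) tables and
their cross-trait correlations; Smith-Hazel spike/peduncle indices and the
standardised drought index in each drought environment; top-k/bottom-k
selection per year and the cross-year intersection. The marker stage runs
panel QC, the distinct-SNP screen between the consistently-extreme groups,
single-marker association of the screened markers with the indices, the
significance thresholds, and per-sample target-allele counts.

Every run writes a JSON manifest with SHA-256 checksums of inputs and
outputs (no timestamps), so a rerun with the same inputs and seed is
bit-identical and verifiable.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import anova, correlation, drought, io, markers, selection, simulate

DEFAULT_QC = {
    "max_marker_missing": 0.20,
    "min_maf": 0.05,
    "max_sample_missing": 0.20,
    "drop_het": True,
}


@dataclass
class AnalysisConfig:
    """Paths, trait groups and parameters driving a full run."""

    phenotypes: Path
    out_dir: Path
    genotypes: Path | None = None
    trait_groups: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in simulate.EXAMPLE_TRAIT_GROUPS.items()}
    )
    k: int = 20
    weights: dict[str, float] = field(default_factory=dict)
    qc: dict = field(default_factory=lambda: dict(DEFAULT_QC))
    missing_policy: str = "strict"
    seed: int = 0

    def __post_init__(self) -> None:
        self.phenotypes = Path(self.phenotypes)
        self.out_dir = Path(self.out_dir)
        if self.genotypes is not None:
            self.genotypes = Path(self.genotypes)
        if self.k < 1:
            raise ValueError("k must be >= 1")
        qc = dict(DEFAULT_QC)
        qc.update(self.qc)
        self.qc = qc
        for key in ("max_marker_missing", "min_maf", "max_sample_missing"):
            if not 0.0 <= float(self.qc[key]) <= 1.0:
                raise ValueError(f"qc threshold {key} must be in [0, 1]")
        if "spike" not in self.trait_groups or "peduncle" not in self.trait_groups:
            raise ValueError("trait_groups must define 'spike' and 'peduncle'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        path = Path(path)
        cfg = io.read_config(path)
        base = path.parent

        def _resolve(p):
            p = Path(p)
            return p if p.is_absolute() else base / p

        kwargs: dict = {}
        kwargs["phenotypes"] = _resolve(cfg["phenotypes"])
        kwargs["out_dir"] = _resolve(cfg["out_dir"])
        if cfg.get("genotypes"):
            kwargs["genotypes"] = _resolve(cfg["genotypes"])
        for key in ("trait_groups", "k", "weights", "qc", "missing_policy", "seed"):
            if key in cfg:
                kwargs[key] = cfg[key]
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "phenotypes": str(self.phenotypes),
            "genotypes": None if self.genotypes is None else str(self.genotypes),
            "out_dir": str(self.out_dir),
            "trait_groups": self.trait_groups,
            "k": self.k,
            "weights": self.weights,
            "qc": self.qc,
            "missing_policy": self.missing_policy,
            "seed": self.seed,
        }

    def index_traits(self) -> list[str]:
        return list(self.trait_groups["spike"]) + list(self.trait_groups["peduncle"])

    def weight_vector(self, traits: list[str]) -> np.ndarray:
        return np.array([float(self.weights.get(t, 1.0)) for t in traits])


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(
    out_dir: Path, name: str, config: AnalysisConfig, inputs: list[Path], outputs: list[Path]
) -> Path:
    manifest = {
        "stage": name,
        "seed": config.seed,
        "config": config.to_dict(),
        "inputs": {p.name: _sha256(p) for p in inputs},
        "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
    }
    path = out_dir / f"{name}_manifest.json"
    io.write_json(manifest, path)
    return path


@dataclass
class PhenotypeReport:
    """In-memory results of the phenotype stage plus the files written."""

    anova: dict[str, anova.VarianceComponents]
    env_anova: dict[tuple[str, str], anova.EnvComponents]
    means: dict[str, pd.DataFrame]
    pheno_corr: dict[str, correlation.CorrelationMatrix]
    geno_corr: dict[str, correlation.CorrelationMatrix]
    rdd: dict[str, drought.RddTable]
    indices: dict[str, selection.IndexResult]
    selections: dict[str, selection.SelectionOutcome]
    intersection_top: selection.YearIntersection | None
    intersection_bottom: selection.YearIntersection | None
    outputs: list[Path]


def run_phenotype_stage(config: AnalysisConfig) -> PhenotypeReport:
    """Run ANOVA, correlations, RDD, indices and selection; write reports."""
    obs = io.read_phenotypes(config.phenotypes)
    traits = list(dict.fromkeys(obs["trait"]))
    missing_traits = [t for t in config.index_traits() if t not in traits]
    if missing_traits:
        raise ValueError(
            f"config names trait(s) {missing_traits} absent from "
            f"{config.phenotypes}"
        )
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    years = sorted(obs["year"].unique())
    treatments = sorted(obs["treatment"].unique())
    envs = [io.env_label(t, y) for y in years for t in treatments]

    # combined ANOVA per trait
    combined = {t: anova.combined_anova(obs, t) for t in sorted(traits)}
    path = out / "anova_combined.csv"
    anova.anova_report(list(combined.values())).to_csv(path)
    outputs.append(path)

    # per-environment ANOVA
    env_rows = []
    env_anova: dict[tuple[str, str], anova.EnvComponents] = {}
    for env in envs:
        for t in sorted(traits):
            ec = anova.per_env_anova(obs, t, env)
            env_anova[(env, t)] = ec
            env_rows.append(
                {
                    "environment": env,
                    "trait": t,
                    "MS_G": ec.ms["G"],
                    "MS_R": ec.ms["R"],
                    "MS_E": ec.ms["E"],
                    "F_G": ec.f_g,
                    "p_G": ec.p_g,
                    "sig_G": anova.significance_stars(ec.p_g),
                    "sigma2_g": ec.sigma2_g,
                    "sigma2_e": ec.sigma2_e,
                    "H2_env": ec.h2,
                }
            )
    path = out / "anova_per_env.csv"
    pd.DataFrame(env_rows).to_csv(path, index=False)
    outputs.append(path)

    # entry means and correlations per environment
    means: dict[str, pd.DataFrame] = {}
    pheno_corr: dict[str, correlation.CorrelationMatrix] = {}
    geno_corr: dict[str, correlation.CorrelationMatrix] = {}
    for env in envs:
        m = anova.genotype_means(obs, env)
        means[env] = m
        path = out / f"means_{env}.csv"
        m.to_csv(path)
        outputs.append(path)

        pc = correlation.phenotypic_correlation(m)
        pheno_corr[env] = pc
        path = out / f"pheno_corr_{env}.csv"
        pc.r.round(6).to_csv(path)
        outputs.append(path)
        path = out / f"pheno_corr_{env}_stars.csv"
        pc.stars().to_csv(path)
        outputs.append(path)

        G, _P = correlation.genetic_covariance(obs, env)
        gc = correlation.genotypic_correlation(G)
        geno_corr[env] = gc
        path = out / f"geno_corr_{env}.csv"
        gc.r.round(6).to_csv(path)
        outputs.append(path)

    # per-year RDD and RDD correlations
    rdd_tables: dict[str, drought.RddTable] = {}
    summary_rows = []
    for y in years:
        n_env, d_env = io.env_label("N", y), io.env_label("D", y)
        if n_env not in means or d_env not in means:
            continue
        table = drought.rdd_table(means[n_env], means[d_env])
        rdd_tables[y] = table
        path = out / f"rdd_{y}.csv"
        table.values.round(6).to_csv(path)
        outputs.append(path)
        rc = correlation.phenotypic_correlation(table.values)
        path = out / f"rdd_corr_{y}.csv"
        rc.r.round(6).to_csv(path)
        outputs.append(path)
        for t in table.values.columns:
            summary_rows.append(
                {
                    "year": y,
                    "trait": t,
                    "rdd_of_means": table.rdd_of_means[t],
                    "mean_of_rdd": table.mean_of_rdd[t],
                }
            )
    if summary_rows:
        path = out / "rdd_summary.csv"
        pd.DataFrame(summary_rows).round(6).to_csv(path, index=False)
        outputs.append(path)

    # Smith-Hazel indices and selection in each drought environment
    spike = list(config.trait_groups["spike"])
    peduncle = list(config.trait_groups["peduncle"])
    indices: dict[str, selection.IndexResult] = {}
    selections: dict[str, selection.SelectionOutcome] = {}
    for y in years:
        env = io.env_label("D", y)
        if env not in means:
            continue
        si = _smith_hazel_index(obs, env, spike, config, means[env])
        pi = _smith_hazel_index(obs, env, peduncle, config, means[env])
        result = selection.drought_index(si, pi, year=y)
        indices[y] = result
        path = out / f"index_{y}.csv"
        result.to_frame().round(6).to_csv(path)
        outputs.append(path)
        selections[y] = selection.select_extremes(result.di, config.k, year=y)

    inter_top = inter_bottom = None
    if len(selections) >= 2:
        inter_top = selection.intersect_years(
            {y: s.top for y, s in selections.items()}
        )
        inter_bottom = selection.intersect_years(
            {y: s.bottom for y, s in selections.items()}
        )
    sel_payload = {
        "k": config.k,
        "per_year": {
            y: {"top": s.top, "bottom": s.bottom, "tie_at_boundary": s.tie_at_boundary}
            for y, s in selections.items()
        },
        "common_top": sorted(inter_top.common) if inter_top else None,
        "common_bottom": sorted(inter_bottom.common) if inter_bottom else None,
        "venn": {
            "n_common_top": len(inter_top.common) if inter_top else None,
            "n_common_bottom": len(inter_bottom.common) if inter_bottom else None,
        },
    }
    path = out / "selection.json"
    io.write_json(sel_payload, path)
    outputs.append(path)

    _write_manifest(out, "phenotype", config, [config.phenotypes], outputs)
    return PhenotypeReport(
        anova=combined,
        env_anova=env_anova,
        means=means,
        pheno_corr=pheno_corr,
        geno_corr=geno_corr,
        rdd=rdd_tables,
        indices=indices,
        selections=selections,
        intersection_top=inter_top,
        intersection_bottom=inter_bottom,
        outputs=outputs,
    )


def _smith_hazel_index(
    obs: pd.DataFrame,
    env: str,
    traits: list[str],
    config: AnalysisConfig,
    env_means: pd.DataFrame,
) -> pd.Series:
    """b from the environment's MCP (G, P); index applied to entry means."""
    G, P = correlation.genetic_covariance(obs, env, traits)
    w = config.weight_vector(traits)
    b = selection.smith_hazel_coefficients(P, G, w)
    return selection.index_values(b, env_means[traits].dropna())


@dataclass
class MarkerReport:
    """In-memory results of the marker stage plus the files written."""

    qc_summary: markers.FilterSummary
    screen: markers.ScreenResult
    thresholds: markers.SignificanceThresholds
    assoc: pd.DataFrame
    allele_counts: pd.Series
    outputs: list[Path]


def _read_genotypes(path: Path):
    if path.suffix.lower() == ".vcf":
        return io.read_genotypes_vcf(path)
    return io.read_genotypes_csv(path)


def run_marker_stage(
    config: AnalysisConfig,
    top_set: list[str],
    bottom_set: list[str],
    index_values: pd.DataFrame | None = None,
) -> MarkerReport:
    """Run QC, the distinct-SNP screen and single-marker association.

    ``top_set``/``bottom_set`` are the contrasting genotype groups (e.g.
    cross-year common extremes); ``index_values`` is an optional genotype x
    index table (SI/PI/DI columns) used for association and target-allele
    counting.
    """
    if config.genotypes is None:
        raise ValueError("config has no genotypes path")
    if not top_set or not bottom_set:
        raise ValueError("both contrast groups must be non-empty")
    snp = _read_genotypes(config.genotypes)
    missing = sorted((set(top_set) | set(bottom_set)) - set(snp.samples))
    if missing:
        raise ValueError(
            f"genotype file is missing listed sample(s): {missing}"
        )
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []

    filtered, summary = markers.filter_markers(
        snp,
        max_marker_missing=float(config.qc["max_marker_missing"]),
        min_maf=float(config.qc["min_maf"]),
        max_sample_missing=float(config.qc["max_sample_missing"]),
        drop_het=bool(config.qc["drop_het"]),
    )
    if filtered.n_markers == 0:
        raise ValueError("no markers remain after QC filtering")
    path = out / "qc_summary.json"
    io.write_json(summary.to_dict(), path)
    outputs.append(path)

    screen = markers.distinct_snp_screen(
        filtered, top_set, bottom_set, missing_policy=config.missing_policy
    )
    path = out / "screen.csv"
    screen.to_frame().to_csv(path, index=False)
    outputs.append(path)

    thresholds = markers.significance_thresholds(filtered.n_markers)
    path = out / "thresholds.json"
    io.write_json(
        {
            "n_markers": filtered.n_markers,
            "fixed": thresholds.fixed,
            "suggestive": thresholds.suggestive,
            "screen_fraction_of_panel": screen.fraction,
        },
        path,
    )
    outputs.append(path)

    assoc_rows = []
    target_map: dict[str, float] = {}
    if index_values is not None:
        di_cols = [c for c in index_values.columns if c.startswith("DI")]
        target_col = di_cols[0] if di_cols else index_values.columns[0]
        for marker_id in screen.marker_ids:
            for col in index_values.columns:
                res = markers.single_marker_assoc(
                    filtered, marker_id, index_values[col].rename(col)
                )
                assoc_rows.append(
                    {
                        "marker": marker_id,
                        "index": col,
                        "mean_ref_hom": res.mean_by_state[0.0],
                        "mean_alt_hom": res.mean_by_state[2.0],
                        "n_ref_hom": res.n_by_state[0.0],
                        "n_alt_hom": res.n_by_state[2.0],
                        "effect": res.effect,
                        "target_state": res.target_state,
                        "t": res.statistic,
                        "p": res.p_value,
                        "flag": res.flag or "",
                    }
                )
                if col == target_col and res.target_state is not None:
                    target_map[marker_id] = res.target_state
    assoc = pd.DataFrame(
        assoc_rows,
        columns=[
            "marker", "index", "mean_ref_hom", "mean_alt_hom", "n_ref_hom",
            "n_alt_hom", "effect", "target_state", "t", "p", "flag",
        ],
    )
    path = out / "assoc.csv"
    assoc.to_csv(path, index=False)
    outputs.append(path)

    counts = pd.Series(
        {
            s: markers.count_target_alleles(filtered, s, target_map)
            for s in top_set
        },
        name="n_target_alleles",
        dtype=int,
    ).sort_index()
    path = out / "allele_counts.csv"
    counts.rename_axis("genotype").to_csv(path)
    outputs.append(path)

    _write_manifest(out, "marker", config, [config.genotypes], outputs)
    return MarkerReport(
        qc_summary=summary,
        screen=screen,
        thresholds=thresholds,
        assoc=assoc,
        allele_counts=counts,
        outputs=outputs,
    )


def run_all(config: AnalysisConfig) -> tuple[PhenotypeReport, MarkerReport | None]:
    """Phenotype stage, then (when genotypes are configured) the marker
    stage on the cross-year common extreme groups."""
    pheno = run_phenotype_stage(config)
    if config.genotypes is None:
        return pheno, None
    if pheno.intersection_top is not None:
        top = sorted(pheno.intersection_top.common)
        bottom = sorted(pheno.intersection_bottom.common)
    else:  # single drought environment: use that year's extremes
        (sel,) = pheno.selections.values()
        top, bottom = sel.top, sel.bottom
    idx = {}
    for y, res in pheno.indices.items():
        idx[f"SI_{y}"] = res.si
        idx[f"PI_{y}"] = res.pi
        idx[f"DI_{y}"] = res.di
    index_df = pd.DataFrame(idx)
    if len(pheno.indices) > 1:
        index_df["DI_mean"] = index_df[
            [c for c in index_df.columns if c.startswith("DI_")]
        ].mean(axis=1)
    marker = run_marker_stage(config, top, bottom, index_values=index_df)
    return pheno, marker


# ---------------------------------------------------------------------------
# Demo dataset
# ---------------------------------------------------------------------------


def make_demo_dataset(
    directory: str | Path,
    n_genotypes: int = 120,
    n_markers: int = 500,
    n_distinct: int = 3,
    seed: int = 0,
) -> dict[str, Path]:
    """Write a self-consistent synthetic dataset plus a ready-to-run config.

    The trial uses the study-like design and truth; the SNP panel plants
    ``n_distinct`` markers fixed between the genotypes with the highest and
    lowest true aggregate genotypic values (7 vs 10, mirroring a
    tolerant-vs-susceptible contrast). The planted markers tag a tolerance
    haplotype: each alternate-homozygous call adds a stable effect to grain
    yield per spike and peduncle weight, so index-marker associations are
    recoverable across the whole panel, not just the contrast groups.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    design = simulate.example_design(n_genotypes)
    truth = simulate.example_truth()
    obs, effects = simulate.simulate_trial(
        design, truth, seed=seed, return_effects=True
    )
    pheno_path = directory / "phenotypes.csv"
    aggregate = effects.sum(axis=1) / effects.std(axis=0).sum()  # scale-free
    ranked = aggregate.sort_values(ascending=False)
    group_a = list(ranked.index[:7])
    group_b = list(ranked.index[-10:])
    panel = simulate.simulate_snp_panel(
        n_markers=n_markers,
        sample_ids=design.genotype_ids,
        planted_distinct=n_distinct,
        group_a=group_a,
        group_b=group_b,
        seed=seed + 1,
    )

    # planted markers act as a tolerance haplotype with stable additive
    # effects on GYPS and PW (per alternate-homozygous call)
    marker_effects = {"GYPS": 0.45, "PW": 0.10}
    dosage = pd.DataFrame(
        panel.matrix.calls[[panel.matrix.marker_index(m) for m in panel.distinct_markers]],
        index=panel.distinct_markers,
        columns=panel.matrix.samples,
    )
    haplotype_load = dosage.sum(axis=0) / 2.0  # copies of the tolerance allele
    for trait, eff in marker_effects.items():
        shift = obs["genotype"].map(haplotype_load) * eff
        obs.loc[obs["trait"] == trait, "value"] += shift[obs["trait"] == trait]
    io.write_phenotypes(obs, pheno_path)

    geno_csv = directory / "genotypes.csv"
    io.write_genotypes_csv(panel.matrix, geno_csv)
    geno_vcf = directory / "genotypes.vcf"
    io.write_genotypes_vcf(panel.matrix, geno_vcf)
    truth_path = directory / "truth.json"
    io.write_json(
        {
            "seed": seed,
            "group_a": group_a,
            "group_b": group_b,
            "marker_effects": marker_effects,
            **panel.truth_dict(),
        },
        truth_path,
    )
    config = {
        "phenotypes": "phenotypes.csv",
        "genotypes": "genotypes.csv",
        "out_dir": "results",
        "trait_groups": {k: list(v) for k, v in simulate.EXAMPLE_TRAIT_GROUPS.items()},
        "k": max(2, n_genotypes // 10),
        "seed": seed,
    }
    config_path = directory / "config.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return {
        "phenotypes": pheno_path,
        "genotypes_csv": geno_csv,
        "genotypes_vcf": geno_vcf,
        "truth": truth_path,
        "config": config_path,
    }
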