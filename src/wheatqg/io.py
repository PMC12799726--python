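"""Readers and writers for phenotype tables, genotype matrices and configs.

Phenotype long format (CSV, header exactly)::

    genotype,year,treatment,rep,trait,value

with treatment in {N, D}, value numeric or NA/empty for missing, and the
key (genotype, year, treatment, rep, trait) unique. Genotype matrices are
read either from minimal VCF 4.x (GT field, biallelic records) via cyvcf2
or from a marker x sample CSV whose first three columns are
``marker,chrom,pos`` followed by one column per sample; calls are coded
0/1/2 with NA (or empty) for missing, plus an optional het token dialect.
Both genotype writers round-trip bit-exactly with their readers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .snp import SnpMatrix

PHENO_COLUMNS = ["genotype", "year", "treatment", "rep", "trait", "value"]
PHENO_KEY = PHENO_COLUMNS[:5]
VALID_TREATMENTS = {"N", "D"}
_MISSING_TOKENS = {"", "NA"}


# ---------------------------------------------------------------------------
# Environment labels (treatment x year), e.g. "D2020"
# ---------------------------------------------------------------------------


def env_label(treatment: str, year: str) -> str:
    return f"{treatment}{year}"


def parse_env(label: str) -> tuple[str, str]:
    """Split an environment label into (treatment, year)."""
    if not label or label[0] not in VALID_TREATMENTS:
        raise ValueError(
            f"environment label {label!r} must start with one of {sorted(VALID_TREATMENTS)}"
        )
    return label[0], label[1:]


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a long-format phenotype table, validating keys and values.

    Missing values (``NA`` or empty) are kept as NaN rows, not dropped.
    Duplicate keys and unknown treatment labels raise ``ValueError`` naming
    the offending file lines (1-based, header = line 1).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != PHENO_COLUMNS:
        raise ValueError(
            f"{path}: header {list(df.columns)} does not match {PHENO_COLUMNS}"
        )
    bad_treat = ~df["treatment"].isin(VALID_TREATMENTS)
    if bad_treat.any():
        i = int(np.flatnonzero(bad_treat)[0])
        raise ValueError(
            f"{path}: unknown treatment label {df['treatment'].iloc[i]!r} "
            f"on line {i + 2}"
        )
    dup = df.duplicated(PHENO_KEY, keep=False)
    if dup.any():
        lines = [int(i) + 2 for i in np.flatnonzero(dup)]
        key = tuple(df.loc[np.flatnonzero(dup)[0], PHENO_KEY])
        raise ValueError(
            f"{path}: duplicate observation key {key} on lines {lines}"
        )
    raw = df["value"].str.strip()
    missing = raw.isin(_MISSING_TOKENS)
    values = pd.to_numeric(raw.mask(missing), errors="coerce")
    bad = values.isna() & ~missing
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"{path}: non-numeric value {raw.iloc[i]!r} on line {i + 2}"
        )
    out = df[PHENO_KEY].copy()
    out["value"] = values.astype(float)
    return out


def write_phenotypes(obs: pd.DataFrame, path: str | Path) -> None:
    obs = obs[PHENO_COLUMNS]
    obs.to_csv(path, index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# Genotypes: VCF
# ---------------------------------------------------------------------------

_GT_STRINGS = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def read_genotypes_vcf(path: str | Path) -> SnpMatrix:
    """Read a biallelic GT-only VCF into an ``SnpMatrix``.

    Multi-allelic records are skipped and counted in
    ``meta['skipped_multiallelic']``. Phased separators are accepted.
    0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2, ./. -> missing.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF has no sample columns")
    marker_ids: list[str] = []
    chrom: list[str] = []
    pos: list[int] = []
    ref: list[str] = []
    alt: list[str] = []
    rows: list[np.ndarray] = []
    skipped = 0
    for var in vcf:
        if "GT" not in (var.FORMAT or []):
            raise ValueError(f"{path}: record at {var.CHROM}:{var.POS} lacks GT")
        if len(var.ALT) != 1:
            skipped += 1
            continue
        # with gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        g = var.gt_types.astype(float)
        g[g == 3] = np.nan
        rows.append(g)
        marker_ids.append(var.ID or f"{var.CHROM}_{var.POS}")
        chrom.append(var.CHROM)
        pos.append(var.POS)
        ref.append(var.REF)
        alt.append(var.ALT[0])
    calls = np.vstack(rows) if rows else np.empty((0, len(samples)))
    return SnpMatrix(
        marker_ids=marker_ids,
        chrom=chrom,
        pos=np.asarray(pos, dtype=np.int64) if pos else np.empty(0, np.int64),
        samples=samples,
        calls=calls,
        ref=ref,
        alt=alt,
        meta={"source": str(path), "skipped_multiallelic": skipped},
    )


def write_genotypes_vcf(snp: SnpMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 (GT only, one ALT per record)."""
    ref = snp.ref or ["A"] * snp.n_markers
    alt = snp.alt or ["T"] * snp.n_markers
    seen: list[str] = []
    for c in snp.chrom:
        if c not in seen:
            seen.append(c)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in seen:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(snp.samples)
            + "\n"
        )
        for i in range(snp.n_markers):
            gts = "\t".join(
                _GT_STRINGS.get(c, "./.") if np.isfinite(c) else "./."
                for c in snp.calls[i]
            )
            fh.write(
                f"{snp.chrom[i]}\t{snp.pos[i]}\t{snp.marker_ids[i]}\t"
                f"{ref[i]}\t{alt[i]}\t.\t.\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Genotypes: CSV dialect
# ---------------------------------------------------------------------------


def read_genotypes_csv(path: str | Path, het_token: str | None = None) -> SnpMatrix:
    """Read a marker x sample call table (``marker,chrom,pos,<samples...>``).

    Calls are 0/1/2, NA or empty for missing; with ``het_token`` set
    (e.g. ``"H"``) that token decodes to 1. Any other token raises a
    ``ValueError`` naming the marker and sample.
    """
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: ragged or malformed CSV ({exc})") from exc
    if list(df.columns[:3]) != ["marker", "chrom", "pos"]:
        raise ValueError(
            f"{path}: first three columns must be marker,chrom,pos "
            f"(got {list(df.columns[:3])})"
        )
    samples = list(df.columns[3:])
    token_map = {"0": 0.0, "1": 1.0, "2": 2.0}
    if het_token is not None:
        token_map[het_token] = 1.0
    calls = np.full((len(df), len(samples)), np.nan)
    for j, s in enumerate(samples):
        col = df[s].str.strip()
        known = col.isin(token_map) | col.isin(_MISSING_TOKENS)
        if not known.all():
            i = int(np.flatnonzero(~known)[0])
            raise ValueError(
                f"{path}: unrecognized call token {col.iloc[i]!r} for marker "
                f"{df['marker'].iloc[i]!r}, sample {s!r}"
            )
        calls[:, j] = col.map(token_map).to_numpy(dtype=float)
    return SnpMatrix(
        marker_ids=list(df["marker"]),
        chrom=list(df["chrom"]),
        pos=pd.to_numeric(df["pos"]).to_numpy(dtype=np.int64)
        if len(df)
        else np.empty(0, np.int64),
        samples=samples,
        calls=calls,
        meta={"source": str(path)},
    )


def write_genotypes_csv(snp: SnpMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("marker,chrom,pos," + ",".join(snp.samples) + "\n")
        for i in range(snp.n_markers):
            tokens = [
                f"{int(c)}" if np.isfinite(c) else "NA" for c in snp.calls[i]
            ]
            fh.write(
                f"{snp.marker_ids[i]},{snp.chrom[i]},{snp.pos[i]},"
                + ",".join(tokens)
                + "\n"
            )


# ---------------------------------------------------------------------------
# Config and sidecars
# ---------------------------------------------------------------------------


def read_config(path: str | Path) -> dict:
    """Load an analysis configuration (YAML) as a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return cfg


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
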