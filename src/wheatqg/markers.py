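"""Marker QC, contrasting-group SNP screens and single-marker association.

QC mirrors standard array-panel filtering for inbred wheat lines:
heterozygous calls are treated as missing, markers with more than 20%
missing data or a minor allele frequency below 5% are excluded, then
samples with more than 20% missing calls are dropped (in that order, with
the MAF recomputed after the het step).

The distinct-SNP screen looks for markers fixed for opposite homozygous
states in two contrasting groups (e.g. drought-tolerant vs susceptible
lines selected on an index) — a deliberately simple complement to GWAS
that is immune to its genotype-by-environment blind spots. Association at
a single marker is a Welch two-sample t-test between the two homozygote
classes; the target allele is the state with the higher trait (or index)
mean, and the allele effect is the difference of class means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .snp import SnpMatrix


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------


@dataclass
class FilterSummary:
    n_markers_in: int
    n_markers_out: int
    n_samples_in: int
    n_samples_out: int
    n_het_calls_masked: int
    n_markers_dropped_missing: int
    n_markers_dropped_maf: int
    n_samples_dropped_missing: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def filter_markers(
    snp: SnpMatrix,
    max_marker_missing: float = 0.20,
    min_maf: float = 0.05,
    max_sample_missing: float = 0.20,
    drop_het: bool = True,
) -> tuple[SnpMatrix, FilterSummary]:
    """Apply the panel QC filters in their stated order.

    1. heterozygous calls masked to missing (``drop_het``);
    2. markers with missing fraction strictly above ``max_marker_missing``
       excluded;
    3. markers with MAF strictly below ``min_maf`` excluded (MAF exactly at
       the floor is retained);
    4. samples with missing fraction strictly above ``max_sample_missing``
       excluded.

    An empty result is valid (a warning-level situation for the caller, not
    an error); counts at every step are returned.
    """
    calls = snp.calls.copy()
    n_het = 0
    if drop_het:
        het = calls == 1.0
        n_het = int(het.sum())
        calls[het] = np.nan
    work = SnpMatrix(
        marker_ids=list(snp.marker_ids),
        chrom=list(snp.chrom),
        pos=snp.pos.copy(),
        samples=list(snp.samples),
        calls=calls,
        ref=None if snp.ref is None else list(snp.ref),
        alt=None if snp.alt is None else list(snp.alt),
        meta=dict(snp.meta),
    )
    miss = work.marker_missing_rate()
    keep_missing = miss <= max_marker_missing
    n_drop_missing = int((~keep_missing).sum())
    work = work.subset(marker_idx=np.flatnonzero(keep_missing))

    maf = work.maf()
    keep_maf = ~(maf < min_maf)  # NaN maf (no calls) is unreachable after step 2
    n_drop_maf = int((~keep_maf).sum())
    work = work.subset(marker_idx=np.flatnonzero(keep_maf))

    smiss = work.sample_missing_rate()
    keep_samples = smiss <= max_sample_missing
    n_drop_samples = int((~keep_samples).sum())
    work = work.subset(sample_idx=np.flatnonzero(keep_samples))

    summary = FilterSummary(
        n_markers_in=snp.n_markers,
        n_markers_out=work.n_markers,
        n_samples_in=snp.n_samples,
        n_samples_out=work.n_samples,
        n_het_calls_masked=n_het,
        n_markers_dropped_missing=n_drop_missing,
        n_markers_dropped_maf=n_drop_maf,
        n_samples_dropped_missing=n_drop_samples,
    )
    return work, summary


# ---------------------------------------------------------------------------
# Distinct-SNP screen
# ---------------------------------------------------------------------------


@dataclass
class ScreenResult:
    """Markers fixed for opposite homozygous states in two groups."""

    records: list[tuple[str, float, float]]  # (marker_id, state in A, state in B)
    n_tested: int
    n_reported: int
    missing_policy: str

    @property
    def marker_ids(self) -> list[str]:
        return [m for m, _, _ in self.records]

    @property
    def fraction(self) -> float:
        return self.n_reported / self.n_tested if self.n_tested else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.records, columns=["marker", "state_group_a", "state_group_b"]
        )


def distinct_snp_screen(
    snp: SnpMatrix,
    group_a: list[str],
    group_b: list[str],
    missing_policy: str = "strict",
) -> ScreenResult:
    """Find markers perfectly differentiating two sample groups.

    A marker is reported iff every (non-missing, under ``ignore_missing``)
    call in group A equals one homozygous state and every call in group B
    equals the other. ``strict`` additionally requires no missing calls in
    either group. Heterozygous calls disqualify a marker under both
    policies (the states must be homozygous).
    """
    if missing_policy not in ("strict", "ignore_missing"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    a_idx = [snp.sample_index(s) for s in group_a]
    b_idx = [snp.sample_index(s) for s in group_b]

    a = snp.calls[:, a_idx]
    b = snp.calls[:, b_idx]
    records: list[tuple[str, float, float]] = []
    for i in range(snp.n_markers):
        ai, bi = a[i], b[i]
        a_miss, b_miss = np.isnan(ai), np.isnan(bi)
        if missing_policy == "strict" and (a_miss.any() or b_miss.any()):
            continue
        a_ok, b_ok = ai[~a_miss], bi[~b_miss]
        if a_ok.size == 0 or b_ok.size == 0:
            continue
        a_state, b_state = a_ok[0], b_ok[0]
        if a_state not in (0.0, 2.0) or b_state not in (0.0, 2.0):
            continue
        if a_state == b_state:
            continue
        if (a_ok == a_state).all() and (b_ok == b_state).all():
            records.append((snp.marker_ids[i], float(a_state), float(b_state)))
    return ScreenResult(
        records=records,
        n_tested=snp.n_markers,
        n_reported=len(records),
        missing_policy=missing_policy,
    )


# ---------------------------------------------------------------------------
# Single-marker association
# ---------------------------------------------------------------------------


@dataclass
class AssocResult:
    """Welch t-test between homozygote classes at one marker."""

    marker_id: str
    name: str
    mean_by_state: dict[float, float]
    n_by_state: dict[float, int]
    effect: float | None
    target_state: float | None
    statistic: float | None
    p_value: float | None
    test: str = "welch_t"
    flag: str | None = None

    @property
    def testable(self) -> bool:
        return self.flag is None


def single_marker_assoc(
    snp: SnpMatrix,
    marker_id: str,
    values: pd.Series,
    min_class_size: int = 2,
) -> AssocResult:
    """Associate one biallelic marker with a per-sample trait or index.

    Heterozygous calls are excluded (consistent with upstream QC on inbred
    lines); the two homozygote classes are compared with a two-sided Welch
    t-test. ``values`` is indexed by sample id. The target allele is the
    homozygous state with the higher mean value; the effect is the target
    class mean minus the other class mean (trait units). Monomorphic
    markers or classes below ``min_class_size`` yield a flagged,
    untestable result.
    """
    row = snp.calls[snp.marker_index(marker_id)]
    values = values.dropna()
    sample_pos = {s: j for j, s in enumerate(snp.samples)}
    common = [s for s in values.index if s in sample_pos]
    calls = np.array([row[sample_pos[s]] for s in common])
    vals = values.loc[common].to_numpy(dtype=float)

    classes: dict[float, np.ndarray] = {}
    for state in (0.0, 2.0):
        classes[state] = vals[calls == state]
    mean_by_state = {
        s: (float(v.mean()) if v.size else float("nan")) for s, v in classes.items()
    }
    n_by_state = {s: int(v.size) for s, v in classes.items()}

    flag = None
    if n_by_state[0.0] == 0 or n_by_state[2.0] == 0:
        flag = "monomorphic"
    elif n_by_state[0.0] < min_class_size or n_by_state[2.0] < min_class_size:
        flag = "class_too_small"
    if flag is not None:
        return AssocResult(
            marker_id=marker_id,
            name=str(values.name or "value"),
            mean_by_state=mean_by_state,
            n_by_state=n_by_state,
            effect=None,
            target_state=None,
            statistic=None,
            p_value=None,
            flag=flag,
        )

    target = max((0.0, 2.0), key=lambda s: mean_by_state[s])
    other = 2.0 - target
    res = stats.ttest_ind(classes[target], classes[other], equal_var=False)
    return AssocResult(
        marker_id=marker_id,
        name=str(values.name or "value"),
        mean_by_state=mean_by_state,
        n_by_state=n_by_state,
        effect=mean_by_state[target] - mean_by_state[other],
        target_state=target,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
    )


def allele_effect_stability(
    effects_year1: pd.Series, effects_year2: pd.Series
) -> tuple[float, float, int]:
    """Pearson correlation of per-marker allele effects across two years.

    Returns ``(r, p, n_shared)`` over markers present in both years;
    fewer than 3 shared markers is an error.
    """
    common = effects_year1.dropna().index.intersection(effects_year2.dropna().index)
    if len(common) < 3:
        raise ValueError(
            f"only {len(common)} shared markers; need at least 3"
        )
    res = stats.pearsonr(
        effects_year1.loc[common].to_numpy(dtype=float),
        effects_year2.loc[common].to_numpy(dtype=float),
    )
    return float(res.statistic), float(res.pvalue), int(len(common))


def ld_r2(snp: SnpMatrix, marker_i: str, marker_j: str) -> float:
    """Squared Pearson correlation of dosages at two markers.

    Computed over samples non-missing at both markers; invariant to an
    allele-label swap (0 <-> 2) at either marker.
    """
    xi = snp.calls[snp.marker_index(marker_i)]
    xj = snp.calls[snp.marker_index(marker_j)]
    ok = np.isfinite(xi) & np.isfinite(xj)
    if ok.sum() < 2:
        raise ValueError("fewer than 2 samples with calls at both markers")
    xi, xj = xi[ok], xj[ok]
    if xi.std() == 0 or xj.std() == 0:
        raise ValueError("zero call variance at one of the markers")
    r = np.corrcoef(xi, xj)[0, 1]
    return float(r * r)


def count_target_alleles(
    snp: SnpMatrix, sample_id: str, target_map: dict[str, float]
) -> int:
    """Number of markers where the sample carries the target allele state.

    Missing calls are not counted. All markers in ``target_map`` must be
    present in the matrix.
    """
    j = snp.sample_index(sample_id)
    count = 0
    for marker, state in target_map.items():
        call = snp.calls[snp.marker_index(marker), j]
        if np.isfinite(call) and call == state:
            count += 1
    return count


@dataclass(frozen=True)
class SignificanceThresholds:
    fixed: float
    suggestive: float


def significance_thresholds(n_markers: int) -> SignificanceThresholds:
    """The fixed 0.001 threshold and the suggestive 1/N threshold."""
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    return SignificanceThresholds(fixed=1e-3, suggestive=1.0 / n_markers)
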