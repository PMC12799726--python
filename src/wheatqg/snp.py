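"""Dense biallelic SNP call matrices shared by the simulator, IO and screens.

Calls are stored as alternate-allele dosages in a dense float array:
0.0 = reference homozygote, 1.0 = heterozygote, 2.0 = alternate homozygote,
NaN = missing. Positions are 1-based, as in VCF; they are never re-based
internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

_VALID_CALLS = frozenset({0.0, 1.0, 2.0})


@dataclass
class SnpMatrix:
    """Marker x sample matrix of biallelic genotype calls.

    Parameters
    ----------
    marker_ids
        Unique marker identifiers, one per row of ``calls``.
    chrom
        Chromosome label per marker (e.g. ``"6D"``).
    pos
        1-based physical or array position per marker.
    samples
        Sample (genotype line) identifiers, one per column of ``calls``.
    calls
        Float array of shape ``(n_markers, n_samples)`` holding dosages in
        {0, 1, 2} with NaN for missing calls.
    ref, alt
        Optional allele labels per marker; default to ``A``/``B`` array-style
        labels when written to VCF.
    meta
        Free-form provenance (e.g. source file, skipped-record counts).
    """

    marker_ids: list[str]
    chrom: list[str]
    pos: np.ndarray
    samples: list[str]
    calls: np.ndarray
    ref: list[str] | None = None
    alt: list[str] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype=float)
        n_m, n_s = len(self.marker_ids), len(self.samples)
        if self.calls.shape != (n_m, n_s):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{n_m} markers x {n_s} samples"
            )
        if len(self.chrom) != n_m or len(self.pos) != n_m:
            raise ValueError("chrom/pos length does not match marker count")
        if n_m and (self.pos < 1).any():
            raise ValueError("positions must be >= 1 (1-based)")
        if len(set(self.marker_ids)) != n_m:
            raise ValueError("marker ids are not unique")
        if len(set(self.samples)) != n_s:
            raise ValueError("sample ids are not unique")
        finite = self.calls[np.isfinite(self.calls)]
        if finite.size and not set(np.unique(finite)) <= _VALID_CALLS:
            bad = sorted(set(np.unique(finite)) - _VALID_CALLS)
            raise ValueError(f"invalid call codes {bad}; expected 0/1/2/NaN")

    # -- basic shape ---------------------------------------------------

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def marker_index(self, marker_id: str) -> int:
        try:
            return self.marker_ids.index(marker_id)
        except ValueError:
            raise KeyError(f"unknown marker id {marker_id!r}") from None

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.samples.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id {sample_id!r}") from None

    # -- per-marker / per-sample summaries -----------------------------

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per marker over non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.calls, axis=1) / 2.0

    def maf(self) -> np.ndarray:
        """Minor allele frequency per marker: min(p, 1-p); NaN if no calls."""
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def marker_missing_rate(self) -> np.ndarray:
        return np.isnan(self.calls).mean(axis=1)

    def sample_missing_rate(self) -> np.ndarray:
        if self.n_markers == 0:
            return np.zeros(self.n_samples)
        return np.isnan(self.calls).mean(axis=0)

    # -- views ----------------------------------------------------------

    def subset(
        self,
        marker_idx: np.ndarray | list[int] | None = None,
        sample_idx: np.ndarray | list[int] | None = None,
    ) -> "SnpMatrix":
        """Row/column subset preserving order of the given indices."""
        mi = np.arange(self.n_markers) if marker_idx is None else np.asarray(marker_idx)
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        return replace(
            self,
            marker_ids=[self.marker_ids[i] for i in mi],
            chrom=[self.chrom[i] for i in mi],
            pos=self.pos[mi],
            samples=[self.samples[j] for j in si],
            calls=self.calls[np.ix_(mi, si)].copy(),
            ref=None if self.ref is None else [self.ref[i] for i in mi],
            alt=None if self.alt is None else [self.alt[i] for i in mi],
            meta=dict(self.meta),
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Calls as a DataFrame indexed by marker id, columns = samples."""
        return pd.DataFrame(self.calls, index=self.marker_ids, columns=self.samples)
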