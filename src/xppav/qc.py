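"""Marker-level quality control and a deterministic imputation stand-in.

Filters mirror standard chip-data practice: markers with minor allele
frequency below ``maf_min`` or missing-call proportion above ``miss_max``
are removed (boundary values retained — the inequalities are strict).
MAF is computed on non-missing calls as ``min(p, 1 - p)`` with
``p = mean(code) / 2``.

:func:`impute_simple` fills missing calls with the per-SNP rounded mean of
observed codes. It is a deterministic desk-scale device, not a
haplotype-aware imputer, and is documented as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotype_io import MISSING, GenotypePanel


@dataclass(frozen=True)
class QcThresholds:
    """MAF and missingness cut-offs; defaults remove MAF < 0.05 and missing > 0.05."""

    maf_min: float = 0.05
    miss_max: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_min <= 0.5:
            raise ValueError(f"maf_min must be in [0, 0.5], got {self.maf_min}")
        if not 0.0 <= self.miss_max <= 1.0:
            raise ValueError(f"miss_max must be in [0, 1], got {self.miss_max}")


@dataclass
class QcReport:
    """Bookkeeping for one filter pass; a SNP failing both filters counts under MAF."""

    n_input_snps: int
    n_removed_maf: int
    n_removed_missing: int
    n_retained: int
    removed_ids: list[tuple[str, str]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_input_snps": self.n_input_snps,
            "n_removed_maf": self.n_removed_maf,
            "n_removed_missing": self.n_removed_missing,
            "n_retained": self.n_retained,
            "removed": [{"snp_id": i, "reason": r} for i, r in self.removed_ids],
        }


def snp_stats(panel: GenotypePanel) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP (counted-allele frequency, MAF, missing proportion).

    Frequency is NaN for all-missing columns (their missingness is 1).
    """
    g = panel.genotypes.astype(float)
    miss = g == MISSING
    n_obs = (~miss).sum(axis=0)
    totals = np.where(miss, 0.0, g).sum(axis=0)
    p = np.divide(totals, 2.0 * n_obs, out=np.full(panel.n_snps, np.nan),
                  where=n_obs > 0)
    maf = np.minimum(p, 1.0 - p)
    miss_prop = miss.mean(axis=0) if g.size else np.empty(0)
    return p, maf, miss_prop


def qc_filter(
    panel: GenotypePanel, thresholds: QcThresholds = QcThresholds()
) -> tuple[GenotypePanel, QcReport]:
    """Remove SNPs with MAF < ``maf_min`` or missingness > ``miss_max``.

    Samples are untouched. All-missing columns fall to the missingness
    filter (missingness 1). Idempotent: filtering a filtered panel removes
    nothing.
    """
    if panel.n_snps == 0:
        raise ValueError("qc_filter requires a non-empty panel")
    _, maf, miss_prop = snp_stats(panel)
    fails_maf = np.isnan(maf) | (maf < thresholds.maf_min)
    fails_maf &= miss_prop < 1.0  # all-missing columns belong to the miss filter
    fails_miss = miss_prop > thresholds.miss_max
    removed_ids: list[tuple[str, str]] = []
    n_maf = n_miss = 0
    keep = np.ones(panel.n_snps, dtype=bool)
    for j, snp in enumerate(panel.snps):
        if fails_maf[j]:
            removed_ids.append((snp.snp_id, "maf"))
            n_maf += 1
            keep[j] = False
        elif fails_miss[j]:
            removed_ids.append((snp.snp_id, "missing"))
            n_miss += 1
            keep[j] = False
    retained = panel.subset_snps(np.flatnonzero(keep))
    report = QcReport(
        n_input_snps=panel.n_snps,
        n_removed_maf=n_maf,
        n_removed_missing=n_miss,
        n_retained=retained.n_snps,
        removed_ids=removed_ids,
    )
    return retained, report


def impute_simple(panel: GenotypePanel) -> GenotypePanel:
    """Replace each MISSING call by the per-SNP rounded mean of observed codes.

    Rounding is numpy's round-half-to-even; results are clamped to {0,1,2}.
    Raises if any SNP has no observed genotype (run :func:`qc_filter` first).
    """
    g = panel.genotypes
    miss = g == MISSING
    if not miss.any():
        return panel
    n_obs = (~miss).sum(axis=0)
    if (n_obs == 0).any():
        j = int(np.argmin(n_obs))
        raise ValueError(
            f"SNP {panel.snps[j].snp_id} has no observed genotypes; "
            "apply qc_filter before imputation"
        )
    gf = g.astype(float)
    gf[miss] = np.nan
    fill = np.clip(np.round(np.nanmean(gf, axis=0)), 0, 2).astype(np.int8)
    out = g.copy()
    out[miss] = np.broadcast_to(fill, g.shape)[miss]
    return GenotypePanel(
        samples=list(panel.samples), snps=list(panel.snps), genotypes=out
    )
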