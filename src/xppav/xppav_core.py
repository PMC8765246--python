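"""The cross-population phenotype-associated variant (XP-PAV) statistic.

For SNP j with per-population GWAS slopes u (population 1) and v
(population 2), the test compares the two *beta-scaled allele-coding
vectors*

    x = g1_j * u   and   y = g2_j * v,

where g1_j, g2_j are the additive 0/1/2 codes of the two populations at a
shared counted allele, with a two-sample t-test:

    t_j = (mean(x) - mean(y)) / sqrt(s2_x / n1 + s2_y / n2).

Because the scaled vectors take only three support points per SNP and the
cohorts are large, the raw per-marker t-test's nominal p-values are
uninformatively small. Significance is therefore judged genome-wide: the
t-values of all non-degenerate SNPs are standardized to z-scores

    z_j = (t_j - mean(t)) / sd(t),      p_j = 2 * (1 - Phi(|z_j|)),

(the default, ``p_mode='z'``), or ranked directly into empirical two-sided
tail probabilities (``p_mode='empirical'``). Both are reported.

A SNP is *degenerate* — excluded from standardization and from significance
— when either population's scaled vector has zero variance (monomorphic
column or beta = 0) or either beta is unavailable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import MISSING, GenotypePanel
from .gwas import GwasRecord


@dataclass(frozen=True)
class ScaledVector:
    """Per-individual allele codes at one SNP multiplied by that population's beta."""

    snp_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


@dataclass(frozen=True)
class XpPavRecord:
    """One SNP's cross-population test result.

    ``mean_effect_pop1/2`` = (mean additive code in that population) x its
    beta, in trait units — the genome-track quantity for differential-effect
    plots. ``z``/``p`` are NaN for degenerate records.
    """

    snp_id: str
    chrom: str
    pos: int
    t_raw: float
    z: float
    p: float
    p_empirical: float
    mean_effect_pop1: float
    mean_effect_pop2: float
    beta1: float
    beta2: float
    status: Literal["ok", "degenerate"]


def scaled_vector(codes: np.ndarray, beta: float, snp_id: str = "") -> ScaledVector:
    """Element-wise product of imputed additive codes with the marker beta."""
    codes = np.asarray(codes)
    if (codes == MISSING).any():
        raise ValueError("codes contain MISSING entries; impute first")
    if not math.isfinite(beta):
        raise ValueError(f"beta must be finite, got {beta}")
    return ScaledVector(snp_id=snp_id, values=codes.astype(float) * beta)


def welch_t(x: ScaledVector | np.ndarray, y: ScaledVector | np.ndarray) -> tuple[float, float]:
    """Welch's unequal-variance two-sample t and Welch–Satterthwaite df.

    Returns (nan, nan) when both sample variances are zero (degenerate).
    """
    xv = x.values if isinstance(x, ScaledVector) else np.asarray(x, dtype=float)
    yv = y.values if isinstance(y, ScaledVector) else np.asarray(y, dtype=float)
    if xv.size < 2 or yv.size < 2:
        raise ValueError("welch_t requires at least 2 observations per group")
    nx, ny = xv.size, yv.size
    vx, vy = xv.var(ddof=1), yv.var(ddof=1)
    ax, ay = vx / nx, vy / ny
    denom = ax + ay
    if denom == 0.0:
        return (math.nan, math.nan)
    t = (xv.mean() - yv.mean()) / math.sqrt(denom)
    df = denom**2 / (ax**2 / (nx - 1) + ay**2 / (ny - 1))
    return (float(t), float(df))


def pooled_t(x: ScaledVector | np.ndarray, y: ScaledVector | np.ndarray) -> tuple[float, float]:
    """Equal-variance (pooled) two-sample t with n1 + n2 - 2 df."""
    xv = x.values if isinstance(x, ScaledVector) else np.asarray(x, dtype=float)
    yv = y.values if isinstance(y, ScaledVector) else np.asarray(y, dtype=float)
    if xv.size < 2 or yv.size < 2:
        raise ValueError("pooled_t requires at least 2 observations per group")
    nx, ny = xv.size, yv.size
    df = nx + ny - 2
    sp2 = ((nx - 1) * xv.var(ddof=1) + (ny - 1) * yv.var(ddof=1)) / df
    if sp2 == 0.0:
        return (math.nan, math.nan)
    t = (xv.mean() - yv.mean()) / math.sqrt(sp2 * (1 / nx + 1 / ny))
    return (float(t), float(df))


def standardize_t(t_values: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Genome-wide z-scores and normal-tail p-values for a vector of t-values.

    z = (t - mean(t)) / sd(t) with the sample standard deviation; p is the
    two-sided standard-normal tail. Requires >= 2 finite values with
    nonzero spread.
    """
    t = np.asarray(t_values, dtype=float)
    if t.size < 2 or not np.isfinite(t).all():
        raise ValueError("standardize_t requires >= 2 finite t-values")
    sd = t.std(ddof=1)
    if sd == 0.0:
        raise ValueError("t-values have zero spread; standardization undefined")
    z = (t - t.mean()) / sd
    p = 2.0 * stats.norm.sf(np.abs(z))
    return z, p


def empirical_p(t_values: Sequence[float]) -> np.ndarray:
    """Rank-based two-sided empirical tail probability among the tested markers.

    p_j = (1 + #{k != j : |t_k| >= |t_j|}) / m — the most extreme marker
    gets 1/m and p is never 0; complete ties give p = 1.
    """
    t = np.asarray(t_values, dtype=float)
    if t.size < 2 or not np.isfinite(t).all():
        raise ValueError("empirical_p requires >= 2 finite t-values")
    a = np.abs(t)
    order = np.sort(a)
    m = t.size
    # #{k: |t_k| >= |t_j|} counts j itself, which supplies the +1
    n_ge = m - np.searchsorted(order, a, side="left")
    return n_ge / m


def xppav_scan(
    panel1: GenotypePanel,
    gwas1: Sequence[GwasRecord],
    panel2: GenotypePanel,
    gwas2: Sequence[GwasRecord],
    test: Literal["welch", "pooled"] = "welch",
) -> list[XpPavRecord]:
    """Run the cross-population scan over harmonized panels.

    Panels must share the SNP list, order and counted alleles (see
    ``genotype_io.harmonize``) and be imputed; ``gwas1``/``gwas2`` are the
    per-population association results aligned to the panel SNPs. SNPs with
    a degenerate beta on either side, or zero scaled-vector variance on
    either side, carry status ``degenerate`` and do not enter the
    genome-wide standardization.
    """
    if panel1.snp_ids != panel2.snp_ids:
        raise ValueError("panels are not harmonized: SNP lists differ")
    for a, b in zip(panel1.snps, panel2.snps):
        if a.allele_counted != b.allele_counted:
            raise ValueError(
                f"panels are not harmonized: counted allele differs at {a.snp_id}"
            )
    g1, g2 = panel1.genotypes, panel2.genotypes
    if (g1 == MISSING).any() or (g2 == MISSING).any():
        raise ValueError("panels contain MISSING genotypes; impute first")
    by_id1 = {r.snp_id: r for r in gwas1}
    by_id2 = {r.snp_id: r for r in gwas2}
    missing = [sid for sid in panel1.snp_ids if sid not in by_id1 or sid not in by_id2]
    if missing:
        raise ValueError(f"GWAS records missing for {len(missing)} SNPs (first: {missing[0]})")

    n1, n2 = panel1.n_samples, panel2.n_samples
    beta1 = np.array([by_id1[sid].beta for sid in panel1.snp_ids])
    beta2 = np.array([by_id2[sid].beta for sid in panel1.snp_ids])

    m1 = g1.mean(axis=0, dtype=float)
    m2 = g2.mean(axis=0, dtype=float)
    v1 = g1.var(axis=0, ddof=1, dtype=float) * beta1**2
    v2 = g2.var(axis=0, ddof=1, dtype=float) * beta2**2

    ok = np.isfinite(beta1) & np.isfinite(beta2) & (v1 > 0) & (v2 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        if test == "welch":
            denom = v1 / n1 + v2 / n2
        elif test == "pooled":
            sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
            denom = sp2 * (1.0 / n1 + 1.0 / n2)
        else:
            raise ValueError(f"unknown test {test!r}")
        t_raw = np.where(ok, (m1 * beta1 - m2 * beta2) / np.sqrt(denom), np.nan)

    n_ok = int(ok.sum())
    if n_ok < 2:
        raise ValueError(f"only {n_ok} non-degenerate SNPs; standardization impossible")
    z = np.full(t_raw.shape, np.nan)
    p_z = np.full(t_raw.shape, np.nan)
    p_emp = np.full(t_raw.shape, np.nan)
    z[ok], p_z[ok] = standardize_t(t_raw[ok])
    p_emp[ok] = empirical_p(t_raw[ok])

    records = []
    for j, snp in enumerate(panel1.snps):
        records.append(
            XpPavRecord(
                snp_id=snp.snp_id,
                chrom=snp.chrom,
                pos=snp.pos,
                t_raw=float(t_raw[j]),
                z=float(z[j]),
                p=float(p_z[j]),
                p_empirical=float(p_emp[j]),
                mean_effect_pop1=float(m1[j] * beta1[j]),
                mean_effect_pop2=float(m2[j] * beta2[j]),
                beta1=float(beta1[j]),
                beta2=float(beta2[j]),
                status="ok" if ok[j] else "degenerate",
            )
        )
    return records


def significant(
    records: Iterable[XpPavRecord],
    alpha: float = 0.05,
    p_mode: Literal["z", "empirical"] = "z",
) -> set[str]:
    """SNP ids of ok records with p < alpha (strict), under the chosen p mode."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    key = (lambda r: r.p) if p_mode == "z" else (lambda r: r.p_empirical)
    return {r.snp_id for r in records if r.status == "ok" and key(r) < alpha}


def records_to_frame(records: Sequence[XpPavRecord]) -> pd.DataFrame:
    """Tabular scan export with both p modes and per-population mean effects."""
    return pd.DataFrame(
        [
            (r.snp_id, r.chrom, r.pos, r.beta1, r.beta2, r.mean_effect_pop1,
             r.mean_effect_pop2, r.t_raw, r.z, r.p, r.p_empirical, r.status)
            for r in records
        ],
        columns=["snp_id", "chrom", "pos", "beta1", "beta2", "mean_effect1",
                 "mean_effect2", "t_raw", "z", "p_z", "p_empirical", "status"],
    )
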