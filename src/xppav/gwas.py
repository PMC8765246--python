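"""Single-marker linear-model association scan.

Each SNP is tested with ordinary least squares,

    trait ~ intercept + covariates + additive genotype code,

and the genotype slope (the per-allele beta effect, in trait units) is the
quantity the cross-population test consumes. Sex and parity are the default
covariates, each entering as a single numeric column.

The scan residualizes the trait and every genotype column on the shared
covariate block once (Frisch–Waugh–Lovell), which is algebraically
identical to solving the full normal equations per SNP but runs in one
matrix product for the whole panel. Standard errors use the residual
variance with n - k degrees of freedom, where k counts intercept,
covariates and the genotype column.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import MISSING, GenotypePanel

PHENOTYPE_COLUMNS = ("sample_id", "trait", "sex", "parity")


@dataclass(frozen=True)
class GwasRecord:
    """Per-SNP OLS result; ``beta`` is the genotype slope in trait units per allele.

    ``degenerate`` marks SNPs whose genotype column is constant (or collinear
    with the covariates) among the analyzed samples — beta is NaN there and
    such records are excluded downstream. ``exact_fit`` marks zero residual
    variance (se = 0, p = 0 reported as the limit).
    """

    snp_id: str
    beta: float
    se: float
    stat: float
    p: float
    n_used: int
    degenerate: bool = False
    exact_fit: bool = False


def read_phenotypes(path: str | Path, trait: str = "trait") -> pd.DataFrame:
    """Read a delimited phenotype/covariate table (comma or tab separated).

    Requires a ``sample_id`` column and the named trait column; ``sex`` and
    ``parity`` are picked up when present. The returned frame is indexed by
    sample_id with the trait under the column name ``trait``.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: no 'sample_id' column (found {list(df.columns)})")
    if trait not in df.columns:
        raise ValueError(f"{path}: no trait column {trait!r} (found {list(df.columns)})")
    out = df.rename(columns={trait: "trait"}).set_index("sample_id")
    return out


def _design_block(
    phen: pd.DataFrame, sample_ids: Sequence[str], covariates: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Align phenotypes to panel order; drop samples with missing trait/covariates.

    Returns (row mask into the panel, trait vector, covariate block with
    intercept).
    """
    missing_ids = [s for s in sample_ids if s not in phen.index]
    if missing_ids:
        raise ValueError(
            f"{len(missing_ids)} panel samples absent from the phenotype table "
            f"(first: {missing_ids[0]!r})"
        )
    aligned = phen.loc[list(sample_ids)]
    cols = ["trait", *covariates]
    for c in covariates:
        if c not in aligned.columns:
            raise ValueError(f"covariate {c!r} not in phenotype table")
    block = aligned[cols].apply(pd.to_numeric, errors="coerce")
    used = block.notna().all(axis=1).to_numpy()
    y = block["trait"].to_numpy(float)[used]
    X = np.column_stack(
        [np.ones(used.sum())]
        + [block[c].to_numpy(float)[used] for c in covariates]
    )
    # reject covariates indistinguishable from the intercept
    if np.linalg.matrix_rank(X) < X.shape[1]:
        for i, c in enumerate(covariates, start=1):
            if np.allclose(X[:, i], X[0, i]):
                raise ValueError(f"covariate {c!r} is constant (collinear with intercept)")
        raise ValueError("covariate block is rank-deficient")
    return used, y, X


def gwas_scan(
    panel: GenotypePanel,
    phen: pd.DataFrame,
    covariates: Sequence[str] = ("sex", "parity"),
) -> list[GwasRecord]:
    """OLS scan of every SNP in ``panel`` against the trait in ``phen``.

    The panel must be imputed (no MISSING entries). Samples with a missing
    trait or covariate value are dropped listwise; ``n_used`` records the
    count analyzed. Constant genotype columns yield degenerate records with
    beta = NaN.
    """
    if (panel.genotypes == MISSING).any():
        raise ValueError("panel contains MISSING genotypes; impute before gwas_scan")
    used, y, X = _design_block(phen, panel.sample_ids, covariates)
    n, c = X.shape
    k = c + 1  # + genotype column
    if n <= k:
        raise ValueError(f"only {n} usable samples for {k} parameters")

    G = panel.genotypes[used].astype(float)
    # residualize on the covariate block via thin QR
    Q, _ = np.linalg.qr(X)
    y_r = y - Q @ (Q.T @ y)
    G_r = G - Q @ (Q.T @ G)

    gg = np.einsum("ij,ij->j", G_r, G_r)
    gy = G_r.T @ y_r
    yy = float(y_r @ y_r)
    df = n - k

    # scale-aware degeneracy: genotype residual variance ~ 0
    tol = max(n, 1) * np.finfo(float).eps * 4.0  # codes are O(1)
    degenerate = gg <= tol

    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(degenerate, np.nan, gy / gg)
        rss = np.maximum(yy - beta**2 * gg, 0.0)
        sigma2 = rss / df
        se = np.sqrt(sigma2 / gg)
        tstat = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df)

    records: list[GwasRecord] = []
    for j, snp in enumerate(panel.snps):
        if degenerate[j]:
            records.append(
                GwasRecord(snp.snp_id, math.nan, math.nan, math.nan, math.nan,
                           n, degenerate=True)
            )
            continue
        exact = sigma2[j] <= yy * np.finfo(float).eps * n or rss[j] == 0.0
        records.append(
            GwasRecord(
                snp_id=snp.snp_id,
                beta=float(beta[j]),
                se=0.0 if exact else float(se[j]),
                stat=float(tstat[j]) if not exact else math.inf * np.sign(beta[j]),
                p=float(pvals[j]) if not exact else 0.0,
                n_used=n,
                exact_fit=bool(exact),
            )
        )
    return records


def bonferroni_sig(
    records: Iterable[GwasRecord],
    alpha: float,
    mode: str = "bonferroni",
) -> set[str]:
    """SNPs significant at ``alpha``: raw ``p < alpha`` or Bonferroni ``p * m < alpha``.

    ``m`` counts the non-degenerate tested records. Degenerate records are
    never returned.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if mode not in ("bonferroni", "raw"):
        raise ValueError(f"unknown mode {mode!r}")
    recs = [r for r in records if not r.degenerate]
    m = len(recs)
    if mode == "raw":
        return {r.snp_id for r in recs if r.p < alpha}
    return {r.snp_id for r in recs if r.p * m < alpha}


def records_to_frame(records: Sequence[GwasRecord], panel: GenotypePanel) -> pd.DataFrame:
    """Tabular scan export: snp_id, chrom, pos, beta, se, stat, p, n_used."""
    meta = {s.snp_id: s for s in panel.snps}
    rows = []
    for r in records:
        s = meta[r.snp_id]
        rows.append(
            (r.snp_id, s.chrom, s.pos, r.beta, r.se, r.stat, r.p, r.n_used,
             "degenerate" if r.degenerate else ("exact_fit" if r.exact_fit else "ok"))
        )
    return pd.DataFrame(
        rows, columns=["snp_id", "chrom", "pos", "beta", "se", "stat", "p",
                       "n_used", "status"]
    )
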