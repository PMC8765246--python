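"""Genomic relationship matrix and principal components for structure checks.

The realized relationship matrix follows VanRaden's first method:

    G = Z Z' / (2 * sum_j p_j (1 - p_j)),

with Z the genotype matrix column-centered at twice the counted-allele
frequency (code - 2 p_j). Its eigendecomposition gives the genetic
principal components used to confirm that two breeds separate before a
cross-population comparison. When both populations are compared in one
space, frequencies for centering come from the merged panel.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .genotype_io import MISSING, GenotypePanel


@dataclass
class Grm:
    """Symmetric realized-relationship matrix with its sample order."""

    sample_ids: list[str]
    values: np.ndarray
    n_snps_used: int = 0
    n_snps_skipped: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError(f"GRM shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("GRM is not symmetric to 1e-10")


@dataclass
class PcaResult:
    """Top-k eigenpairs of a GRM.

    ``pve`` is each eigenvalue over the sum of *all* eigenvalues (negative
    numerical eigenvalues floored at 0); ``coordinates`` are eigenvectors
    scaled by sqrt(eigenvalue), samples x components.
    """

    eigenvalues: np.ndarray
    pve: np.ndarray
    coordinates: np.ndarray
    sample_ids: list[str]


def merge_panels(panel1: GenotypePanel, panel2: GenotypePanel) -> GenotypePanel:
    """Stack two harmonized panels into one (samples concatenated)."""
    if panel1.snp_ids != panel2.snp_ids:
        raise ValueError("panels must share the SNP list (harmonize first)")
    return GenotypePanel(
        samples=list(panel1.samples) + list(panel2.samples),
        snps=list(panel1.snps),
        genotypes=np.vstack([panel1.genotypes, panel2.genotypes]),
    )


def grm_vanraden(panel: GenotypePanel) -> Grm:
    """VanRaden genomic relationship matrix of an imputed panel.

    Monomorphic SNPs (frequency 0 or 1) contribute nothing; they are skipped
    and counted in ``n_snps_skipped``. All-monomorphic input raises.
    """
    g = panel.genotypes
    if (g == MISSING).any():
        raise ValueError("panel contains MISSING genotypes; impute first")
    gf = g.astype(float)
    p = gf.mean(axis=0) / 2.0
    poly = (p > 0.0) & (p < 1.0)
    denom = float(2.0 * np.sum(p[poly] * (1.0 - p[poly])))
    if denom == 0.0:
        raise ValueError("all SNPs monomorphic; GRM denominator is zero")
    Z = gf[:, poly] - 2.0 * p[poly]
    G = (Z @ Z.T) / denom
    G = (G + G.T) / 2.0  # enforce exact symmetry against rounding
    return Grm(
        sample_ids=panel.sample_ids,
        values=G,
        n_snps_used=int(poly.sum()),
        n_snps_skipped=int((~poly).sum()),
    )


def pca_grm(grm: Grm, k: int = 10) -> PcaResult:
    """Top-k eigendecomposition of a GRM.

    Eigenvalues are returned non-increasing; each eigenvector's sign is
    fixed so its largest-magnitude loading is positive (determinism across
    linear-algebra backends).
    """
    n = len(grm.sample_ids)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    vals, vecs = np.linalg.eigh(grm.values)
    vals, vecs = vals[::-1], vecs[:, ::-1]
    total = float(np.maximum(vals, 0.0).sum())
    top_vals = vals[:k]
    top_vecs = vecs[:, :k]
    for j in range(k):
        i = int(np.argmax(np.abs(top_vecs[:, j])))
        if top_vecs[i, j] < 0:
            top_vecs[:, j] = -top_vecs[:, j]
    floored = np.maximum(top_vals, 0.0)
    pve = floored / total if total > 0 else np.zeros(k)
    coords = top_vecs * np.sqrt(floored)
    return PcaResult(
        eigenvalues=top_vals.copy(),
        pve=pve,
        coordinates=coords,
        sample_ids=list(grm.sample_ids),
    )


def write_pca(result: PcaResult, out_prefix: str | Path) -> tuple[Path, Path]:
    """GCTA-style text outputs: one eigenvalue per line, and a PC table."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    val_path = Path(str(out_prefix) + ".eigenval")
    vec_path = Path(str(out_prefix) + ".eigenvec")
    val_path.write_text("".join(f"{v:.10g}\n" for v in result.eigenvalues))
    k = result.coordinates.shape[1]
    with open(vec_path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(f"PC{i+1}" for i in range(k)) + "\n")
        for sid, row in zip(result.sample_ids, result.coordinates):
            fh.write(sid + "\t" + "\t".join(f"{x:.10g}" for x in row) + "\n")
    return val_path, vec_path
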