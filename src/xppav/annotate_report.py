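"""SNP-to-gene assignment, GWAS/XP-PAV overlap counts, and plot exports.

Gene annotations come from a user-supplied BED (0-based half-open,
converted to 1-based inclusive at ingestion) or GFF3 (1-based inclusive,
``gene``-type features). A SNP maps to every gene whose interval, extended
by ``window`` bp on both sides, contains its position; the default window
is 0 (strict containment). Assigned gene lists are emitted ranked for
external enrichment tools — enrichment itself is not computed here.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import SnpMeta
from .xppav_core import XpPavRecord


@dataclass(frozen=True)
class GeneModel:
    """One gene interval, 1-based inclusive."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class OverlapCounts:
    """Disjoint partition of the union of two significant-SNP sets."""

    n_gwas_only: int
    n_xppav_only: int
    n_shared: int

    @property
    def total(self) -> int:
        return self.n_gwas_only + self.n_xppav_only + self.n_shared


def _frame_to_genes(df: "pd.DataFrame", id_cols: Sequence[str]) -> list[GeneModel]:
    # pyranges holds 0-based half-open intervals; convert to 1-based inclusive
    genes = []
    for _, row in df.iterrows():
        gene_id = None
        for col in id_cols:
            val = row.get(col)
            if isinstance(val, str) and val:
                gene_id = val
                break
        chrom = str(row["Chromosome"])
        start, end = int(row["Start"]) + 1, int(row["End"])
        if gene_id is None:
            gene_id = f"{chrom}:{start}-{end}"
        strand = row.get("Strand")
        strand = strand if strand in ("+", "-") else "."
        genes.append(GeneModel(gene_id, chrom, start, end, strand))
    return genes


def read_genes_bed(path: str | Path) -> list[GeneModel]:
    """BED 3+ columns; 0-based half-open intervals become 1-based inclusive."""
    import pyranges as pr

    return _frame_to_genes(pr.read_bed(str(path)).df, ("Name",))


def read_genes_gff3(path: str | Path, feature_types: Sequence[str] = ("gene",)) -> list[GeneModel]:
    """GFF3 gene-type features (1-based inclusive in the file)."""
    import pyranges as pr

    df = pr.read_gff3(str(path)).df
    if "Feature" in df.columns:
        df = df[df["Feature"].isin(feature_types)]
    return _frame_to_genes(df, ("ID", "gene_id", "Name"))


def read_genes(path: str | Path) -> list[GeneModel]:
    """Dispatch on extension: .bed -> BED, .gff/.gff3 -> GFF3."""
    suffix = Path(path).suffix.lower()
    if suffix == ".bed":
        return read_genes_bed(path)
    if suffix in (".gff", ".gff3"):
        return read_genes_gff3(path)
    raise ValueError(f"cannot infer annotation format from {path!r} (use .bed/.gff3)")


def assign_genes(
    snps: Sequence[SnpMeta],
    genes: Sequence[GeneModel],
    window: int = 0,
) -> dict[str, list[str]]:
    """Map each SNP to the genes whose window-extended interval contains it.

    Multi-gene hits preserve annotation order; SNPs without a hit map to an
    empty list. Disjoint chromosome name sets between the two inputs raise,
    catching convention mismatches ('1' vs 'chr1').
    """
    if window < 0:
        raise ValueError(f"window must be non-negative, got {window}")
    snp_chroms = {s.chrom for s in snps}
    gene_chroms = {g.chrom for g in genes}
    if snps and genes and not (snp_chroms & gene_chroms):
        raise ValueError(
            "no chromosome name overlap between SNPs and genes "
            f"(SNPs use {sorted(snp_chroms)[:5]}, genes use {sorted(gene_chroms)[:5]})"
        )
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append((g.start - window, g.end + window, g.gene_id))
    out: dict[str, list[str]] = {}
    for s in snps:
        hits = [gid for lo, hi, gid in by_chrom.get(s.chrom, ()) if lo <= s.pos <= hi]
        out[s.snp_id] = hits
    return out


def venn(gwas_sig: Iterable[str], xppav_sig: Iterable[str]) -> OverlapCounts:
    """Exact partition counts of two significant-SNP sets."""
    g, x = set(gwas_sig), set(xppav_sig)
    return OverlapCounts(
        n_gwas_only=len(g - x),
        n_xppav_only=len(x - g),
        n_shared=len(g & x),
    )


def _natural_chrom_key(chrom: str):
    m = re.fullmatch(r"(?:chr)?(\d+)", chrom, flags=re.IGNORECASE)
    return (0, int(m.group(1)), "") if m else (1, 0, chrom)


def manhattan_table(records: Sequence[XpPavRecord]) -> pd.DataFrame:
    """Plot-ready rows: chrom, pos, neglog10p, cumulative genome coordinate.

    Degenerate records are omitted; chromosomes follow natural sort order,
    record order preserved within each chromosome. ``cum_pos`` offsets each
    chromosome by the prefix sum of preceding chromosomes' maximum position.
    """
    ok = [r for r in records if r.status == "ok"]
    chroms = sorted({r.chrom for r in ok}, key=_natural_chrom_key)
    offsets: dict[str, int] = {}
    acc = 0
    max_pos = {c: max(r.pos for r in ok if r.chrom == c) for c in chroms}
    for c in chroms:
        offsets[c] = acc
        acc += max_pos[c]
    rows = [
        (r.chrom, r.pos, -math.log10(r.p), offsets[r.chrom] + r.pos, r.snp_id)
        for c in chroms
        for r in ok
        if r.chrom == c
    ]
    return pd.DataFrame(rows, columns=["chrom", "pos", "neglog10p", "cum_pos", "snp_id"])


def ranked_gene_list(
    records: Sequence[XpPavRecord],
    assignment: Mapping[str, Sequence[str]],
    alpha: float = 0.05,
) -> list[str]:
    """Genes hit by significant SNPs, ranked by their best (smallest) p-value.

    The output order is the input expected by external enrichment tools;
    duplicates collapse to the best-ranked occurrence.
    """
    best: dict[str, float] = {}
    for r in records:
        if r.status != "ok" or r.p >= alpha:
            continue
        for gid in assignment.get(r.snp_id, ()):
            if gid not in best or r.p < best[gid]:
                best[gid] = r.p
    return sorted(best, key=lambda gid: (best[gid], gid))
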