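"""End-to-end run orchestration: simulate/load -> QC -> GWAS x2 -> scan -> report.

A :class:`RunConfig` captures every stage parameter plus the seed, so a
persisted config re-runs to identical outputs for the deterministic stages.
Each run writes its stage outputs and a JSON manifest (parameters, input
checksums, per-stage record counts, completion flags) into the output
directory. Stages hand objects forward in memory and are recomputed on
every run: with a fixed seed the pipeline is deterministic end to end, so
re-running is itself the resume mechanism.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .annotate_report import assign_genes, manhattan_table, ranked_gene_list, read_genes, venn
from .genotype_io import GenotypePanel, harmonize, read_panel, write_panel
from .gwas import bonferroni_sig, gwas_scan, read_phenotypes
from .gwas import records_to_frame as gwas_frame
from .qc import QcThresholds, impute_simple, qc_filter
from .simulator import SimConfig, simulate_two_pop
from .xppav_core import significant, xppav_scan
from .xppav_core import records_to_frame as xppav_frame

log = logging.getLogger("xppav")


@dataclass
class RunConfig:
    """Serializable parameterization of one pipeline run."""

    outdir: str
    seed: int = 0
    # either simulate...
    simulate: Optional[dict] = None
    # ...or load existing filesets
    geno1: Optional[str] = None
    geno2: Optional[str] = None
    geno_format: str = "bed"
    pheno1: Optional[str] = None
    pheno2: Optional[str] = None
    trait: str = "trait"
    covariates: list[str] = field(default_factory=lambda: ["sex", "parity"])
    maf_min: float = 0.05
    miss_max: float = 0.05
    harmonize_mode: str = "union"
    p_mode: str = "z"
    xppav_alpha: float = 0.05
    gwas_alpha: float = 0.01
    gwas_mode: str = "bonferroni"
    genes: Optional[str] = None
    window: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown RunConfig keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if self.simulate is None:
            missing = [k for k in ("geno1", "geno2", "pheno1", "pheno2")
                       if getattr(self, k) is None]
            if missing:
                raise ValueError(
                    f"config must set 'simulate' or provide inputs; missing {missing}"
                )
        if self.p_mode not in ("z", "empirical"):
            raise ValueError(f"p_mode must be 'z' or 'empirical', got {self.p_mode!r}")
        if self.harmonize_mode not in ("union", "intersection"):
            raise ValueError(f"bad harmonize_mode {self.harmonize_mode!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def fill_union_missing(
    panel1: GenotypePanel, panel2: GenotypePanel
) -> tuple[GenotypePanel, GenotypePanel]:
    """Fill all-MISSING columns of each panel from the other's rounded mean.

    After a union-mode harmonization a SNP typed in only one population is
    an all-MISSING column in the other; there is no within-population
    information to impute from, so the counterpart population's rounded
    mean code is the only deterministic fill available.
    """
    import numpy as np

    from .genotype_io import MISSING

    out = []
    for panel, other in ((panel1, panel2), (panel2, panel1)):
        g = panel.genotypes.copy()
        all_missing = (g == MISSING).all(axis=0)
        for j in np.flatnonzero(all_missing):
            src = other.genotypes[:, j]
            obs = src[src != MISSING]
            if obs.size == 0:
                raise ValueError(
                    f"SNP {panel.snps[j].snp_id} missing in both populations"
                )
            g[:, j] = np.int8(np.clip(np.round(obs.mean()), 0, 2))
        out.append(
            GenotypePanel(samples=list(panel.samples), snps=list(panel.snps), genotypes=g)
        )
    return out[0], out[1]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage; returns the run directory.

    Any stage failure propagates after the manifest records the partial
    state (the CLI maps this to a non-zero exit naming the stage).
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)

    manifest: dict = {
        "tool": "xppav",
        "version": __version__,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": config.to_dict(),
        "inputs": {},
        "stages": {},
    }
    manifest_path = outdir / "manifest.json"

    def _flush(stage: str, status: str, **counts) -> None:
        manifest["stages"][stage] = {"status": status, **counts}
        manifest_path.write_text(json.dumps(manifest, indent=1))

    current = "setup"
    try:
        # ---- input stage -------------------------------------------------
        if config.simulate is not None:
            current = "simulate"
            sim_cfg = SimConfig(**{**config.simulate, "seed": config.seed})
            panel1, phen1, panel2, phen2, truth = simulate_two_pop(sim_cfg)
            truth.to_json(outdir / "truth.json")
            for tag, (panel, phen) in (("pop1", (panel1, phen1)),
                                       ("pop2", (panel2, phen2))):
                write_panel(panel, outdir / f"sim_{tag}", format="bed")
                phen.reset_index().to_csv(outdir / f"sim_{tag}.pheno.csv", index=False)
            _flush("simulate", "complete", n1=panel1.n_samples, n2=panel2.n_samples,
                   m=panel1.n_snps)
        else:
            current = "load"
            for key in ("geno1", "geno2", "pheno1", "pheno2", "genes"):
                val = getattr(config, key)
                if val is None:
                    continue
                p = Path(val)
                probe = p if p.exists() else Path(str(p) + "." + config.geno_format)
                if probe.exists() and probe.is_file():
                    manifest["inputs"][key] = _sha256(probe)
            panel1 = read_panel(config.geno1, format=config.geno_format)
            panel2 = read_panel(config.geno2, format=config.geno_format)
            phen1 = read_phenotypes(config.pheno1, trait=config.trait)
            phen2 = read_phenotypes(config.pheno2, trait=config.trait)
            _flush("load", "complete", n1=panel1.n_samples, n2=panel2.n_samples)

        # ---- qc ----------------------------------------------------------
        current = "qc"
        thresholds = QcThresholds(maf_min=config.maf_min, miss_max=config.miss_max)
        panel1, report1 = qc_filter(panel1, thresholds)
        panel2, report2 = qc_filter(panel2, thresholds)
        (outdir / "qc_pop1.json").write_text(json.dumps(report1.to_dict(), indent=1))
        (outdir / "qc_pop2.json").write_text(json.dumps(report2.to_dict(), indent=1))
        panel1 = impute_simple(panel1)
        panel2 = impute_simple(panel2)
        _flush("qc", "complete", retained1=report1.n_retained, retained2=report2.n_retained)

        # ---- harmonize ---------------------------------------------------
        current = "harmonize"
        panel1, panel2 = harmonize(panel1, panel2, mode=config.harmonize_mode)
        if config.harmonize_mode == "union":
            # SNPs absent from one population come back as all-MISSING
            # columns; fill them from the other population's rounded mean
            # (the desk-scale counterpart of cross-panel imputation), then
            # mean-impute any remaining holes.
            panel1, panel2 = fill_union_missing(panel1, panel2)
            panel1, panel2 = impute_simple(panel1), impute_simple(panel2)
        _flush("harmonize", "complete", n_shared_snps=panel1.n_snps)

        # ---- gwas x2 -----------------------------------------------------
        current = "gwas"
        recs1 = gwas_scan(panel1, phen1, covariates=config.covariates)
        recs2 = gwas_scan(panel2, phen2, covariates=config.covariates)
        gwas_frame(recs1, panel1).to_csv(outdir / "gwas_pop1.tsv", sep="\t", index=False)
        gwas_frame(recs2, panel2).to_csv(outdir / "gwas_pop2.tsv", sep="\t", index=False)
        _flush("gwas", "complete", n_records1=len(recs1), n_records2=len(recs2))

        # ---- xppav scan --------------------------------------------------
        current = "scan"
        records = xppav_scan(panel1, recs1, panel2, recs2)
        xppav_frame(records).to_csv(outdir / "xppav.tsv", sep="\t", index=False)
        manhattan_table(records).to_csv(outdir / "manhattan.tsv", sep="\t", index=False)
        n_ok = sum(r.status == "ok" for r in records)
        _flush("scan", "complete", n_records=len(records), n_ok=n_ok)

        # ---- report ------------------------------------------------------
        current = "report"
        xppav_sig = significant(records, alpha=config.xppav_alpha, p_mode=config.p_mode)
        gwas_sig = (
            bonferroni_sig(recs1, config.gwas_alpha, mode=config.gwas_mode)
            | bonferroni_sig(recs2, config.gwas_alpha, mode=config.gwas_mode)
        )
        counts = venn(gwas_sig, xppav_sig)
        summary = {
            "n_xppav_significant": len(xppav_sig),
            "n_gwas_significant": len(gwas_sig),
            "venn": {"gwas_only": counts.n_gwas_only,
                     "xppav_only": counts.n_xppav_only,
                     "shared": counts.n_shared},
        }
        if config.genes is not None:
            genes = read_genes(config.genes)
            sig_snps = [s for s in panel1.snps if s.snp_id in xppav_sig]
            assignment = assign_genes(sig_snps, genes, window=config.window)
            ranked = ranked_gene_list(records, assignment, alpha=config.xppav_alpha)
            (outdir / "genes_ranked.txt").write_text("".join(g + "\n" for g in ranked))
            pd.DataFrame(
                [(sid, ";".join(gids)) for sid, gids in assignment.items()],
                columns=["snp_id", "genes"],
            ).to_csv(outdir / "snp_genes.tsv", sep="\t", index=False)
            summary["n_genes"] = len(ranked)
        (outdir / "summary.json").write_text(json.dumps(summary, indent=1))
        _flush("report", "complete", **summary["venn"])
    except Exception:
        _flush(current, "failed")
        log.error("pipeline failed at stage %r", current)
        raise

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return outdir
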