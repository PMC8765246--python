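"""Two-population genotype/phenotype simulator with known differential effects.

Population allele frequencies follow the Balding–Nichols model: an
ancestral frequency p is drawn uniformly from ``maf_range`` per SNP, and
each population's frequency is Beta(p (1-F)/F, (1-p) (1-F)/F) with F the
differentiation parameter (Fst); F = 0 is the degenerate limit where both
populations share the ancestral frequency. Genotypes are Binomial(2, freq)
under Hardy–Weinberg equilibrium — per-SNP frequency divergence with no
linkage disequilibrium, which is all the per-marker cross-population test
exercises.

The additive trait is

    y = intercept + sex * sex_effect + parity * parity_effect
        + sum_causal g_j * beta_j + e,

with shared causal effects beta ~ N(0, effect_sd^2) and, at a chosen subset
of *divergent* SNPs, beta2 = beta1 + delta in population 2. Environmental
noise is scaled per population so the genetic fraction of trait variance
matches the target heritability h2.

The truth object records causal/divergent sets, both beta maps and all
frequencies, so power and recovery are checkable without external data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .genotype_io import GenotypePanel, SampleMeta, SnpMeta


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of the two-population generator.

    Defaults are the calibration-scale study conditions used throughout the
    test-suite: two cohorts of 400 and 800 individuals (the smaller first,
    mirroring the Landrace/Yorkshire imbalance), 2,000 SNPs, Fst 0.05,
    50 causal SNPs of which 20 carry a population-2 effect shift ``delta``,
    and heritability 0.3.
    """

    n1: int = 400
    n2: int = 800
    m: int = 2000
    fst: float = 0.05
    maf_range: tuple[float, float] = (0.05, 0.95)
    n_causal: int = 50
    effect_sd: float = 1.0
    n_divergent: int = 20
    delta: float = 0.5
    h2: float = 0.3
    sex_effect: float = 10.0
    parity_effect: float = 2.0
    trait_intercept: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_divergent < 0 or self.n_causal < 0:
            raise ValueError("counts must be non-negative")
        if self.n_causal > self.m or self.n_divergent > self.n_causal:
            raise ValueError("need n_divergent <= n_causal <= m")
        if min(self.n1, self.n2, self.m) < 1:
            raise ValueError("n1, n2, m must be positive")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError(f"fst must be in [0, 1), got {self.fst}")
        if not 0.0 < self.h2 < 1.0:
            raise ValueError(f"h2 must be in (0, 1), got {self.h2}")
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi < 1.0:
            raise ValueError(f"maf_range must satisfy 0 < lo <= hi < 1, got {self.maf_range}")


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset."""

    causal_ids: list[str]
    divergent_ids: list[str]
    beta1: dict[str, float]
    beta2: dict[str, float]
    ancestral_freqs: dict[str, float]
    pop_freqs: dict[str, tuple[float, float]]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def _balding_nichols_freqs(
    rng: np.random.Generator, p_anc: np.ndarray, fst: float, equal: bool
) -> tuple[np.ndarray, np.ndarray]:
    if fst == 0.0:
        return p_anc.copy(), p_anc.copy()
    a = p_anc * (1.0 - fst) / fst
    b = (1.0 - p_anc) * (1.0 - fst) / fst
    f1 = rng.beta(a, b)
    f2 = f1.copy() if equal else rng.beta(a, b)
    return f1, f2


def _population(
    rng: np.random.Generator,
    n: int,
    freqs: np.ndarray,
    snps: list[SnpMeta],
    betas: np.ndarray,
    cfg: SimConfig,
    pop_tag: str,
) -> tuple[GenotypePanel, pd.DataFrame]:
    m = len(snps)
    g = rng.binomial(2, freqs, size=(n, m)).astype(np.int8)
    sex = rng.integers(1, 3, size=n)
    parity = rng.integers(1, 7, size=n)
    genetic = g.astype(float) @ betas
    var_g = genetic.var()
    if var_g == 0.0:
        raise ValueError(
            "zero genetic variance in simulated cohort; h2 target infeasible "
            "(no causal SNPs or all betas zero)"
        )
    noise_sd = float(np.sqrt(var_g * (1.0 - cfg.h2) / cfg.h2))
    y = (
        cfg.trait_intercept
        + sex * cfg.sex_effect
        + parity * cfg.parity_effect
        + genetic
        + rng.normal(0.0, noise_sd, size=n)
    )
    ids = [f"{pop_tag}{i + 1:05d}" for i in range(n)]
    samples = [SampleMeta(sample_id=sid, sex=int(s)) for sid, s in zip(ids, sex)]
    panel = GenotypePanel(samples=samples, snps=list(snps), genotypes=g)
    phen = pd.DataFrame(
        {"sample_id": ids, "trait": y, "sex": sex, "parity": parity}
    ).set_index("sample_id")
    return panel, phen


def simulate_two_pop(
    config: SimConfig, _force_null: bool = False
) -> tuple[GenotypePanel, pd.DataFrame, GenotypePanel, pd.DataFrame, SimTruth]:
    """Generate (panel1, phen1, panel2, phen2, truth) under ``config``.

    Reproducible given the seed; the two panels share SNP ids and counted
    alleles (already harmonized).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    m = cfg.m
    snp_ids = [f"snp{j + 1:06d}" for j in range(m)]
    # one autosome, roughly chip-like inter-marker spacing
    positions = np.cumsum(rng.integers(20_000, 80_000, size=m))
    snps = [
        SnpMeta(snp_id=sid, chrom="1", pos=int(pos), allele_counted="A", allele_other="B")
        for sid, pos in zip(snp_ids, positions)
    ]

    lo, hi = cfg.maf_range
    p_anc = rng.uniform(lo, hi, size=m)
    f1, f2 = _balding_nichols_freqs(rng, p_anc, cfg.fst, equal=_force_null)

    causal_idx = np.sort(rng.choice(m, size=cfg.n_causal, replace=False))
    n_div = 0 if _force_null else cfg.n_divergent
    divergent_idx = np.sort(rng.choice(causal_idx, size=n_div, replace=False)) if n_div else np.array([], dtype=int)

    beta1 = np.zeros(m)
    beta1[causal_idx] = rng.normal(0.0, cfg.effect_sd, size=cfg.n_causal)
    beta2 = beta1.copy()
    beta2[divergent_idx] += cfg.delta

    panel1, phen1 = _population(rng, cfg.n1, f1, snps, beta1, cfg, "LL")
    panel2, phen2 = _population(rng, cfg.n2, f2, snps, beta2, cfg, "YY")

    truth = SimTruth(
        causal_ids=[snp_ids[j] for j in causal_idx],
        divergent_ids=[snp_ids[j] for j in divergent_idx],
        beta1={snp_ids[j]: float(beta1[j]) for j in causal_idx},
        beta2={snp_ids[j]: float(beta2[j]) for j in causal_idx},
        ancestral_freqs={sid: float(p) for sid, p in zip(snp_ids, p_anc)},
        pop_freqs={sid: (float(a), float(b)) for sid, a, b in zip(snp_ids, f1, f2)},
    )
    return panel1, phen1, panel2, phen2, truth


def null_dataset(
    config: SimConfig,
) -> tuple[GenotypePanel, pd.DataFrame, GenotypePanel, pd.DataFrame, SimTruth]:
    """Global-null dataset: no divergent effects and equal per-SNP frequencies.

    Both populations share one Balding–Nichols frequency draw per SNP and an
    identical beta map, so any cross-population signal is pure noise — the
    type-I-error calibration fixture.
    """
    return simulate_two_pop(config, _force_null=True)
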