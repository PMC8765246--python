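"""PLINK-format genotype ingestion and cross-population allele harmonization.

Genotypes are held additively coded: each entry counts copies of the SNP's
``allele_counted`` (0, 1 or 2), with :data:`MISSING` (-1) for absent calls.
The XP-PAV statistic is *not* invariant to which allele is counted —
flipping maps ``g * beta`` to ``(2 - g) * (-beta)`` — so two panels must be
harmonized to a common counted allele before any cross-population
comparison. :func:`harmonize` enforces one deterministic convention:
panel 1 wins all coding conflicts.

Both PLINK 1.9 text (.ped/.map) and binary SNP-major (.bed/.bim/.fam)
layouts are supported, bit-exact for round trips.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np

MISSING: int = -1

_BED_MAGIC = b"\x6c\x1b"
_BED_SNP_MAJOR = b"\x01"

# PLINK 2-bit codes (SNP-major .bed): 00=hom A1, 01=missing, 10=het, 11=hom A2.
# Our additive code counts A1 (allele_counted), hence the mapping below.
_BED_TO_CODE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_CODE_TO_BED = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


class FormatError(ValueError):
    """Inconsistent or malformed genotype files."""


class HarmonizeError(ValueError):
    """Allele pair at a shared SNP cannot be reconciled between panels."""


@dataclass(frozen=True)
class SnpMeta:
    """One marker: identifier, 1-based map position, and its allele pair.

    ``allele_counted`` is the allele whose copies the additive code counts
    (PLINK's A1); ``allele_other`` is the alternative (A2).
    """

    snp_id: str
    chrom: str
    pos: int
    allele_counted: str
    allele_other: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.snp_id}: position must be >= 1, got {self.pos}")
        if self.allele_counted == self.allele_other:
            raise ValueError(f"{self.snp_id}: counted and other allele are identical")

    def flipped(self) -> "SnpMeta":
        """The same SNP with the counted/other alleles swapped."""
        return replace(
            self, allele_counted=self.allele_other, allele_other=self.allele_counted
        )


@dataclass(frozen=True)
class SampleMeta:
    """One individual: identifier plus the sex/parity covariates.

    ``sex`` uses the PLINK coding (1/2); ``None`` marks a missing value for
    either covariate. Parity (litter number) only travels through phenotype
    tables — PLINK files have no slot for it.
    """

    sample_id: str
    sex: Optional[int] = None
    parity: Optional[int] = None

    def __post_init__(self) -> None:
        if self.sex is not None and self.sex not in (1, 2):
            raise ValueError(f"{self.sample_id}: sex must be 1, 2 or None")
        if self.parity is not None and self.parity < 0:
            raise ValueError(f"{self.sample_id}: parity must be non-negative")


@dataclass
class GenotypePanel:
    """Additively coded genotypes for one population.

    ``genotypes`` is an int8 matrix, rows = samples, columns = SNPs, entries
    in {0, 1, 2, MISSING}; each code counts copies of that SNP's
    ``allele_counted``.
    """

    samples: list[SampleMeta]
    snps: list[SnpMeta]
    genotypes: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"({len(self.samples)} samples, {len(self.snps)} SNPs)"
            )
        valid = np.isin(self.genotypes, (0, 1, 2, MISSING))
        if not valid.all():
            bad = self.genotypes[~valid][0]
            raise ValueError(f"invalid genotype code {bad}; expected 0/1/2/{MISSING}")
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate snp_id in panel")
        sids = [s.sample_id for s in self.samples]
        if len(set(sids)) != len(sids):
            raise ValueError("duplicate sample_id in panel")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def subset_snps(self, indices: Sequence[int]) -> "GenotypePanel":
        idx = np.asarray(indices, dtype=int)
        return GenotypePanel(
            samples=list(self.samples),
            snps=[self.snps[i] for i in idx],
            genotypes=self.genotypes[:, idx].copy(),
        )


# ---------------------------------------------------------------------------
# Readers


def read_panel(path_prefix: str | Path, format: Literal["bed", "ped"] = "bed") -> GenotypePanel:
    """Read a PLINK fileset (``PREFIX.bed/.bim/.fam`` or ``PREFIX.ped/.map``).

    Codes count the fileset's A1 allele; missing genotypes map to
    :data:`MISSING`. Raises :class:`FormatError` on inconsistent companion
    files or non-biallelic records.
    """
    prefix = Path(path_prefix)
    if format == "bed":
        return _read_bed(prefix)
    if format == "ped":
        return _read_ped(prefix)
    raise ValueError(f"unknown format {format!r}; expected 'bed' or 'ped'")


def _parse_fam_line(line: str, path: Path) -> SampleMeta:
    parts = line.split()
    if len(parts) < 6:
        raise FormatError(f"{path}: expected 6 .fam columns, got {len(parts)}")
    sex = int(parts[4]) if parts[4] in ("1", "2") else None
    return SampleMeta(sample_id=parts[1], sex=sex)


def _read_bim(path: Path) -> list[SnpMeta]:
    snps = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) != 6:
                raise FormatError(f"{path}: expected 6 .bim columns, got {len(parts)}")
            chrom, snp_id, _cm, pos, a1, a2 = parts
            snps.append(
                SnpMeta(
                    snp_id=snp_id, chrom=chrom, pos=int(pos),
                    allele_counted=a1, allele_other=a2,
                )
            )
    return snps


def _read_bed(prefix: Path) -> GenotypePanel:
    bed, bim, fam = (Path(str(prefix) + s) for s in (".bed", ".bim", ".fam"))
    for p in (bed, bim, fam):
        if not p.exists():
            raise FormatError(f"missing companion file {p}")
    with open(fam) as fh:
        samples = [_parse_fam_line(line, fam) for line in fh if line.strip()]
    snps = _read_bim(bim)
    n, m = len(samples), len(snps)

    raw = bed.read_bytes()
    if raw[:2] != _BED_MAGIC:
        raise FormatError(f"{bed}: bad magic bytes; not a PLINK .bed file")
    if raw[2:3] != _BED_SNP_MAJOR:
        raise FormatError(f"{bed}: only SNP-major .bed files are supported")
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != bytes_per_snp * m:
        raise FormatError(
            f"{bed}: {body.size} data bytes inconsistent with "
            f"{n} samples x {m} SNPs ({bytes_per_snp * m} expected)"
        )
    blocks = body.reshape(m, bytes_per_snp)
    # unpack 2-bit fields, low bits first within each byte
    pairs = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        pairs[:, k::4] = (blocks >> (2 * k)) & 0b11
    codes = _BED_TO_CODE[pairs[:, :n]].T  # samples x SNPs
    return GenotypePanel(samples=samples, snps=snps, genotypes=np.ascontiguousarray(codes))


def _read_ped(prefix: Path) -> GenotypePanel:
    ped, map_ = Path(str(prefix) + ".ped"), Path(str(prefix) + ".map")
    for p in (ped, map_):
        if not p.exists():
            raise FormatError(f"missing companion file {p}")
    map_rows = []
    with open(map_) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) != 4:
                raise FormatError(f"{map_}: expected 4 .map columns, got {len(parts)}")
            map_rows.append((parts[0], parts[1], int(parts[3])))
    m = len(map_rows)

    samples: list[SampleMeta] = []
    allele_calls: list[list[tuple[str, str]]] = []
    with open(ped) as fh:
        for line in fh:
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise FormatError(
                    f"{ped}: row for '{parts[1] if len(parts) > 1 else '?'}' has "
                    f"{len(parts)} fields, expected {6 + 2 * m} for {m} map SNPs"
                )
            samples.append(_parse_fam_line(line, ped))
            alleles = parts[6:]
            allele_calls.append(
                [(alleles[2 * j], alleles[2 * j + 1]) for j in range(m)]
            )

    # Optional PLINK-style reference-allele sidecar written by write_panel:
    # "snp_id counted_allele" per line. Text ped/map pairs cannot otherwise
    # record which allele the additive code counts, so without it A1 falls
    # back to the first allele seen in sample order.
    ref_path = Path(str(prefix) + ".ref")
    ref_allele: dict[str, tuple[str, ...]] = {}
    if ref_path.exists():
        for line in ref_path.read_text().splitlines():
            parts = line.split()
            if len(parts) >= 2:
                ref_allele[parts[0]] = tuple(parts[1:3])

    snps: list[SnpMeta] = []
    codes = np.full((len(samples), m), MISSING, dtype=np.int8)
    for j, (chrom, snp_id, pos) in enumerate(map_rows):
        seen: list[str] = []
        for i, (a, b) in enumerate(c[j] for c in allele_calls):
            for al in (a, b):
                if al != "0" and al not in seen:
                    seen.append(al)
        if len(seen) > 2:
            raise FormatError(f"{ped}: SNP {snp_id} is not biallelic (alleles {seen})")
        if not seen:
            raise FormatError(f"{ped}: SNP {snp_id} has no called genotypes")
        ref = ref_allele.get(snp_id)
        a1 = ref[0] if ref else seen[0]
        if a1 not in seen and len(seen) == 2:
            raise FormatError(
                f"{ped}: SNP {snp_id} reference allele {a1!r} not among "
                f"observed alleles {seen}"
            )
        rest = [s for s in seen if s != a1]
        if ref is not None and len(ref) > 1:
            a2 = ref[1]
            if rest and rest[0] != a2:
                raise FormatError(
                    f"{ped}: SNP {snp_id} observed allele {rest[0]!r} conflicts "
                    f"with sidecar pair {ref}"
                )
        else:
            a2 = rest[0] if rest else ("A" if a1 != "A" else "B")
        for i, (a, b) in enumerate(c[j] for c in allele_calls):
            if a == "0" or b == "0":
                continue
            codes[i, j] = (a == a1) + (b == a1)
        snps.append(
            SnpMeta(snp_id=snp_id, chrom=chrom, pos=pos, allele_counted=a1, allele_other=a2)
        )
    return GenotypePanel(samples=samples, snps=snps, genotypes=codes)


# ---------------------------------------------------------------------------
# Writers


def write_panel(
    panel: GenotypePanel, path_prefix: str | Path, format: Literal["bed", "ped"] = "bed"
) -> list[Path]:
    """Write ``panel`` as a PLINK fileset; returns the paths written.

    Round-trip contract: ``read_panel(write_panel(p))`` reproduces codes,
    SNP order and sample order exactly.
    """
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if format == "bed":
        return _write_bed(panel, prefix)
    if format == "ped":
        return _write_ped(panel, prefix)
    raise ValueError(f"unknown format {format!r}; expected 'bed' or 'ped'")


def _fam_lines(panel: GenotypePanel) -> str:
    return "".join(
        f"{s.sample_id} {s.sample_id} 0 0 {s.sex if s.sex is not None else 0} -9\n"
        for s in panel.samples
    )


def _write_bed(panel: GenotypePanel, prefix: Path) -> list[Path]:
    bed, bim, fam = (Path(str(prefix) + s) for s in (".bed", ".bim", ".fam"))
    fam.write_text(_fam_lines(panel))
    bim.write_text(
        "".join(
            f"{s.chrom}\t{s.snp_id}\t0\t{s.pos}\t{s.allele_counted}\t{s.allele_other}\n"
            for s in panel.snps
        )
    )
    n, m = panel.n_samples, panel.n_snps
    bytes_per_snp = (n + 3) // 4
    two_bit = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    two_bit.fill(_CODE_TO_BED[0])  # pad slots: arbitrary but deterministic
    lut = np.zeros(256, dtype=np.uint8)
    for code, bits in _CODE_TO_BED.items():
        lut[np.int8(code).view(np.uint8)] = bits
    two_bit[:, :n] = lut[panel.genotypes.T.view(np.uint8)]
    packed = np.zeros((m, bytes_per_snp), dtype=np.uint8)
    for k in range(4):
        packed |= two_bit[:, k::4] << (2 * k)
    with open(bed, "wb") as fh:
        fh.write(_BED_MAGIC + _BED_SNP_MAJOR)
        fh.write(packed.tobytes())
    return [bed, bim, fam]


def _write_ped(panel: GenotypePanel, prefix: Path) -> list[Path]:
    ped, map_ = Path(str(prefix) + ".ped"), Path(str(prefix) + ".map")
    map_.write_text(
        "".join(f"{s.chrom}\t{s.snp_id}\t0\t{s.pos}\n" for s in panel.snps)
    )
    # reference-allele sidecar: text ped/map cannot carry the counted allele
    Path(str(prefix) + ".ref").write_text(
        "".join(
            f"{s.snp_id}\t{s.allele_counted}\t{s.allele_other}\n"
            for s in panel.snps
        )
    )
    with open(ped, "w") as fh:
        for i, s in enumerate(panel.samples):
            fields = [s.sample_id, s.sample_id, "0", "0",
                      str(s.sex if s.sex is not None else 0), "-9"]
            row = panel.genotypes[i]
            for j, snp in enumerate(panel.snps):
                g = row[j]
                if g == MISSING:
                    fields += ["0", "0"]
                elif g == 0:
                    fields += [snp.allele_other, snp.allele_other]
                elif g == 1:
                    fields += [snp.allele_counted, snp.allele_other]
                else:
                    fields += [snp.allele_counted, snp.allele_counted]
            fh.write(" ".join(fields) + "\n")
    return [ped, map_]


# ---------------------------------------------------------------------------
# Harmonization


def flip_column(codes: np.ndarray) -> np.ndarray:
    """Reflect additive codes to count the other allele (2 - g), keeping MISSING."""
    out = codes.copy()
    ok = out != MISSING
    out[ok] = 2 - out[ok]
    return out


def harmonize(
    panel_a: GenotypePanel,
    panel_b: GenotypePanel,
    mode: Literal["intersection", "union"] = "union",
) -> tuple[GenotypePanel, GenotypePanel]:
    """Put two panels on an identical SNP list with a common counted allele.

    Panel A's counted allele wins every coding conflict; panel B columns with
    a swapped allele pair are flipped (``g -> 2 - g``, alleles swapped).
    Under ``union``, SNPs absent from one panel become all-MISSING columns
    there (panel A's allele designation is used for its exclusive SNPs and
    vice versa). Shared SNPs whose allele *pair* differs even after a swap
    raise :class:`HarmonizeError`.
    """
    if mode not in ("intersection", "union"):
        raise ValueError(f"unknown mode {mode!r}")
    a_by_id = {s.snp_id: j for j, s in enumerate(panel_a.snps)}
    b_by_id = {s.snp_id: j for j, s in enumerate(panel_b.snps)}
    if mode == "intersection":
        kept = [sid for sid in a_by_id if sid in b_by_id]
    else:
        kept = list(a_by_id) + [sid for sid in b_by_id if sid not in a_by_id]

    n_a, n_b = panel_a.n_samples, panel_b.n_samples
    out_a = np.full((n_a, len(kept)), MISSING, dtype=np.int8)
    out_b = np.full((n_b, len(kept)), MISSING, dtype=np.int8)
    snps_out: list[SnpMeta] = []
    for k, sid in enumerate(kept):
        ja, jb = a_by_id.get(sid), b_by_id.get(sid)
        if ja is not None:
            ref = panel_a.snps[ja]
            out_a[:, k] = panel_a.genotypes[:, ja]
        else:
            ref = panel_b.snps[jb]  # B-exclusive SNP keeps B's designation
        if jb is not None:
            bsnp = panel_b.snps[jb]
            if (bsnp.allele_counted, bsnp.allele_other) == (
                ref.allele_counted, ref.allele_other
            ):
                out_b[:, k] = panel_b.genotypes[:, jb]
            elif (bsnp.allele_other, bsnp.allele_counted) == (
                ref.allele_counted, ref.allele_other
            ):
                out_b[:, k] = flip_column(panel_b.genotypes[:, jb])
            else:
                raise HarmonizeError(
                    f"SNP {sid}: allele pair {{{bsnp.allele_counted},"
                    f"{bsnp.allele_other}}} in panel B cannot be reconciled "
                    f"with {{{ref.allele_counted},{ref.allele_other}}} in panel A"
                )
        snps_out.append(ref)

    return (
        GenotypePanel(samples=list(panel_a.samples), snps=list(snps_out), genotypes=out_a),
        GenotypePanel(samples=list(panel_b.samples), snps=list(snps_out), genotypes=out_b),
    )
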