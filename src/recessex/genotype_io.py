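"""Genotype and phased-marker containers and their on-disk formats.

Two containers flow through every stage of the workflow:

* :class:`GenotypeMatrix` — unphased alt-allele dosages (0/1/2, or missing)
  per sample over biallelic variants, the shape of a multi-sample VCF.
* :class:`PhasedHaplotypeMatrix` — phased, imputed, complete biallelic
  marker data: two 0/1 haplotype vectors per sample over position-ordered
  markers, the shape of phased SNP-array genotypes.

Coordinates are 1-based and inclusive throughout (VCF convention), and
indels use VCF anchoring (e.g. a 1-bp deletion written ref="TC", alt="T").
Only diploid autosomal samples are supported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "MISSING",
    "VariantRecord",
    "GenotypeMatrix",
    "PhasedHaplotypeMatrix",
    "VcfParseError",
    "PhasedMatrixError",
    "read_vcf",
    "write_vcf",
    "read_phased_matrix",
    "write_phased_matrix",
]

logger = logging.getLogger(__name__)

#: Sentinel dosage for a missing genotype call.
MISSING: int = -1


class VcfParseError(ValueError):
    """Raised when a VCF cannot be parsed into a :class:`GenotypeMatrix`."""


class PhasedMatrixError(ValueError):
    """Raised for malformed phased-marker tables."""


@dataclass
class VariantRecord:
    """One biallelic variant with per-sample alt-allele dosages.

    ``dosages`` holds one entry per cohort sample, in the cohort's sample
    order: 0, 1 or 2 alternate alleles, or :data:`MISSING`.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical at {self.chrom}:{self.pos}")
        bad = ~np.isin(self.dosages, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError(f"invalid dosage values at {self.chrom}:{self.pos}")

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)

    @property
    def label(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass
class GenotypeMatrix:
    """Ordered samples × ordered variants with unphased dosage calls."""

    samples: list[str]
    variants: list[VariantRecord]

    def __post_init__(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample labels must be unique")
        for v in self.variants:
            if len(v.dosages) != len(self.samples):
                raise ValueError(
                    f"variant {v.label} has {len(v.dosages)} dosages for "
                    f"{len(self.samples)} samples"
                )
        self.variants = sorted(self.variants, key=lambda v: (v.chrom, v.pos))

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample label: {sample!r}") from None

    def dosage_array(self) -> np.ndarray:
        """(n_variants, n_samples) int8 array of dosages (-1 = missing)."""
        if not self.variants:
            return np.empty((0, len(self.samples)), dtype=np.int8)
        return np.vstack([v.dosages for v in self.variants])

    def find_variant(self, chrom: str, pos: int) -> VariantRecord:
        for v in self.variants:
            if v.chrom == chrom and v.pos == pos:
                return v
        raise KeyError(f"no variant at {chrom}:{pos}")


@dataclass
class PhasedHaplotypeMatrix:
    """Phased biallelic markers × two haplotypes per sample.

    ``markers`` is a DataFrame with columns ``label, chrom, pos, allele0,
    allele1`` sorted by position within chromosome; ``haplotypes`` has shape
    ``(n_samples, 2, n_markers)`` with entries in {0, 1} (phased and
    imputed — no missing values).
    """

    samples: list[str]
    markers: pd.DataFrame
    haplotypes: np.ndarray

    def __post_init__(self) -> None:
        required = ["label", "chrom", "pos", "allele0", "allele1"]
        if list(self.markers.columns[: len(required)]) != required:
            raise PhasedMatrixError(
                f"marker table must start with columns {required}"
            )
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        n = len(self.samples)
        m = len(self.markers)
        if self.haplotypes.shape != (n, 2, m):
            raise PhasedMatrixError(
                f"haplotype array shape {self.haplotypes.shape} != ({n}, 2, {m})"
            )
        if m and not np.isin(self.haplotypes, (0, 1)).all():
            raise PhasedMatrixError("haplotype entries must be 0/1")
        for chrom, grp in self.markers.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if (np.diff(pos) <= 0).any():
                i = int(np.nonzero(np.diff(pos) <= 0)[0][0]) + 1
                raise PhasedMatrixError(
                    f"marker positions not strictly increasing on {chrom} at "
                    f"marker {grp['label'].iloc[i]!r}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def positions(self) -> np.ndarray:
        return self.markers["pos"].to_numpy()

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample label: {sample!r}") from None


# ---------------------------------------------------------------------------
# VCF (v4.2, GT only)
# ---------------------------------------------------------------------------

def _dosage_from_gt(gt: tuple | None) -> int:
    if gt is None:
        return MISSING
    alleles = [a for a in gt if a is not None]
    if len(alleles) != 2:
        return MISSING
    return int(sum(1 for a in alleles if a > 0))


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Parse a VCF (v4.x, GT genotypes) into a :class:`GenotypeMatrix`.

    Biallelic rows are converted to dosages ("0/1" and "0|1" alike count
    one alt allele); rows with more than one ALT allele are skipped with a
    warning; a missing GT becomes :data:`MISSING`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"{path}: malformed VCF header ({exc})") from exc
    samples = list(vf.header.samples)
    variants: list[VariantRecord] = []
    try:
        for rec in vf:
            alts = rec.alts
            if alts is None or len(alts) != 1:
                logger.warning(
                    "skipping non-biallelic record %s:%d", rec.chrom, rec.pos
                )
                continue
            dosages = np.array(
                [_dosage_from_gt(rec.samples[s].get("GT")) for s in samples],
                dtype=np.int8,
            )
            variants.append(
                VariantRecord(rec.chrom, rec.pos, rec.ref, alts[0], dosages)
            )
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"{path}: malformed VCF record ({exc})") from exc
    finally:
        vf.close()
    return GenotypeMatrix(samples=samples, variants=variants)


_GT_BY_DOSAGE = {0: (0, 0), 1: (0, 1), 2: (1, 1)}


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF v4.2 with GT-only records, samples in order."""
    header = pysam.VariantHeader()
    header.add_meta("FORMAT", items=[("ID", "GT"), ("Number", "1"),
                                     ("Type", "String"),
                                     ("Description", "Genotype")])
    chroms: list[str] = []
    for v in matrix.variants:
        if v.chrom not in chroms:
            chroms.append(v.chrom)
    for chrom in chroms:
        header.contigs.add(chrom)
    for s in matrix.samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in matrix.variants:
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, stop=v.pos - 1 + len(v.ref),
                alleles=(v.ref, v.alt),
            )
            for s, d in zip(matrix.samples, v.dosages):
                if d == MISSING:
                    rec.samples[s]["GT"] = (None, None)
                else:
                    rec.samples[s]["GT"] = _GT_BY_DOSAGE[int(d)]
            out.write(rec)


# ---------------------------------------------------------------------------
# Phased-marker matrix (tab-separated)
# ---------------------------------------------------------------------------
#
# Layout: header line, then one row per marker:
#   label  chrom  pos  allele0  allele1  <S>_h1  <S>_h2  ...  (two columns
# per sample).  A 3-marker example lives in the README.

def write_phased_matrix(matrix: PhasedHaplotypeMatrix, path: str | Path) -> None:
    cols = {}
    for i, s in enumerate(matrix.samples):
        cols[f"{s}_h1"] = matrix.haplotypes[i, 0, :]
        cols[f"{s}_h2"] = matrix.haplotypes[i, 1, :]
    df = pd.concat(
        [matrix.markers.iloc[:, :5].reset_index(drop=True),
         pd.DataFrame(cols)], axis=1,
    )
    df.to_csv(path, sep="\t", index=False)


def read_phased_matrix(path: str | Path) -> PhasedHaplotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "label": str})
    required = ["label", "chrom", "pos", "allele0", "allele1"]
    if list(df.columns[:5]) != required:
        raise PhasedMatrixError(f"{path}: expected leading columns {required}")
    hap_cols = list(df.columns[5:])
    if len(hap_cols) % 2:
        raise PhasedMatrixError(f"{path}: odd number of haplotype columns")
    samples = []
    for c1, c2 in zip(hap_cols[::2], hap_cols[1::2]):
        if not (c1.endswith("_h1") and c2.endswith("_h2") and c1[:-3] == c2[:-3]):
            raise PhasedMatrixError(
                f"{path}: haplotype columns must pair as <sample>_h1/<sample>_h2, "
                f"got {c1!r}, {c2!r}"
            )
        samples.append(c1[:-3])
    values = df[hap_cols].to_numpy()
    if values.size and not np.isin(values, (0, 1)).all():
        raise PhasedMatrixError(f"{path}: haplotype entries must be 0/1")
    hap = np.empty((len(samples), 2, len(df)), dtype=np.uint8)
    for i in range(len(samples)):
        hap[i, 0, :] = values[:, 2 * i]
        hap[i, 1, :] = values[:, 2 * i + 1]
    return PhasedHaplotypeMatrix(
        samples=samples, markers=df[required].copy(), haplotypes=hap
    )
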