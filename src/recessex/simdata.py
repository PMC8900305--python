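"""Gene-drop simulator for a recessive loss-of-function allele.

Generates, under one seeded configuration, every input the downstream
stages consume: a phased marker matrix with a causal 1-bp deletion
segregating identical-by-descent from a single ancestral haplotype,
coverage-dependent sequence genotype calls (with heterozygote
undercalling at low depth), RNA evidence of nonsense-mediated decay
(depleted alternate-allele read fractions in heterozygotes and reduced
transcript abundance), and genotype-dependent semen phenotypes.

The simulation is a plain gene drop: founder haplotypes are drawn
marker-wise from per-marker allele frequencies, the causal allele is
seeded as replicated copies of one ancestral carrier haplotype (so every
descendant copy is identical by descent), and offspring haplotypes are
formed by Haldane recombination (Poisson crossover count, breakpoints
uniform along the chromosome, no interference) through discrete
generations of random mating.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .consequence import GeneModel
from .expression_tests import AlleleCounts
from .genotype_io import (
    MISSING,
    GenotypeMatrix,
    PhasedHaplotypeMatrix,
    VariantRecord,
)
from .semen_qc import EjaculateRecord

__all__ = [
    "SemenParams",
    "SimConfig",
    "TruthTable",
    "emit_call",
    "simulate_population",
    "simulate_sequence_genotypes",
    "simulate_rna_data",
    "simulate_ejaculates",
    "simulate_gene_model",
]


@dataclass(frozen=True)
class SemenParams:
    """Normal-distribution parameters for one genotype class's ejaculates.

    Concentration is in 10⁹ sperm per mL (the unit semen reports print);
    draws are truncated at zero and percentages clipped to [0, 100].
    """

    volume_mean: float
    volume_sd: float
    concentration_mean: float  # 1e9 sperm per mL
    concentration_sd: float
    motile_mean: float  # percent
    motile_sd: float
    abnormal_mean: float  # percent
    abnormal_sd: float

    def __post_init__(self) -> None:
        for name in ("volume_sd", "concentration_sd", "motile_sd", "abnormal_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


#: Bulls of normal genotype: concentration 1.3 ± 0.5 × 10⁹/mL, volume
#: 4.7 ± 2.0 mL, 83 ± 11% motile, few abnormal sperm.
NORMAL_SEMEN = SemenParams(4.7, 2.0, 1.3, 0.5, 83.0, 11.0, 5.0, 3.0)
#: Homozygous-affected bulls: 0.2 ± 0.2 × 10⁹/mL, near-zero motility,
#: ≥97% morphologically abnormal sperm.
AFFECTED_SEMEN = SemenParams(4.0, 0.9, 0.2, 0.2, 0.5, 0.5, 99.0, 1.0)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated cohort.

    The defaults are the conditions of the analyses this package
    reproduces: a causal allele at ~5% founder frequency, ~12× genome
    coverage, an alternate-allele RNA read fraction of 0.28 in
    heterozygotes at ~292× site depth, gene abundance 32.13 ± 7.01 TPM in
    wild-type vs 23.29 ± 6.76 TPM in heterozygous animals, and the semen
    parameter blocks above.
    """

    n_founders: int = 400
    n_generations: int = 3
    n_markers: int = 200
    chrom: str = "19"
    chrom_length_bp: int = 5_000_000
    recomb_rate: float = 0.05  # expected crossovers per meiosis (~1 cM/Mb)
    marker_freq_range: tuple[float, float] = (0.1, 0.9)
    causal_freq: float = 0.05
    focal_pos_bp: int | None = None  # default: midway between the two central markers
    focal_ref: str = "TC"
    focal_alt: str = "T"
    mean_coverage: float = 12.0
    nmd_alt_fraction: float = 0.28
    rna_depth_mean: float = 292.0
    tpm_wt_mean: float = 32.13
    tpm_wt_sd: float = 7.01
    tpm_het_mean: float = 23.29
    tpm_het_sd: float = 6.76
    n_exons: int = 30
    n_depleted_exons: int = 18
    exon_rel_sd: float = 0.15  # per-exon noise relative to the exon baseline
    expression_n_het: int = 6  # expression-cohort design: het carriers
    expression_n_wt: int = 70  # and wild-type animals
    semen_normal: SemenParams = NORMAL_SEMEN
    semen_affected: SemenParams = AFFECTED_SEMEN
    ejaculates_per_bull: int = 7
    age_window_days: tuple[float, float] = (330.0, 550.0)
    ensure_homozygote: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_markers < 3:
            raise ValueError("need at least 3 markers")
        if self.n_founders < 2 or self.n_generations < 1:
            raise ValueError("need at least 2 founders and 1 generation")
        if not 0 < self.causal_freq < 0.5:
            raise ValueError("causal_freq must be in (0, 0.5)")
        if not 0 < self.nmd_alt_fraction <= 0.5:
            raise ValueError("nmd_alt_fraction must be in (0, 0.5]")
        if self.recomb_rate < 0:
            raise ValueError("recomb_rate must be >= 0")
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be positive")
        lo, hi = self.marker_freq_range
        if not 0 < lo <= hi < 1:
            raise ValueError("marker_freq_range must satisfy 0 < lo <= hi < 1")
        for name in ("tpm_wt_sd", "tpm_het_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_seed_copies < 1:
            raise ValueError(
                f"causal_freq={self.causal_freq} cannot seed one copy among "
                f"{2 * self.n_founders} founder haplotypes"
            )

    @property
    def n_seed_copies(self) -> int:
        """Founder haplotype slots carrying the ancestral causal copy."""
        return int(round(2 * self.n_founders * self.causal_freq))

    def marker_positions(self) -> np.ndarray:
        """Evenly spaced 1-based marker positions along the chromosome."""
        spacing = self.chrom_length_bp // (self.n_markers + 1)
        if spacing < 2:
            raise ValueError("chromosome too short for this marker count")
        return spacing * np.arange(1, self.n_markers + 1)

    def resolved_focal_pos(self) -> int:
        """Focal position, strictly between two adjacent markers."""
        pos = self.marker_positions()
        if self.focal_pos_bp is None:
            mid = len(pos) // 2
            return int((pos[mid - 1] + pos[mid]) // 2)
        fp = int(self.focal_pos_bp)
        i = int(np.searchsorted(pos, fp))
        if i == 0 or i == len(pos) or pos[i] == fp or pos[i - 1] == fp:
            raise ValueError(
                f"focal_pos_bp={fp} must fall strictly between two adjacent "
                "markers"
            )
        return fp


@dataclass
class TruthTable:
    """Ground truth emitted alongside the phased matrix.

    ``ancestry`` records, per sample haplotype and marker, the founder
    haplotype index the allele descends from; ``causal`` flags haplotypes
    carrying the causal deletion; ``diplotypes`` is the per-sample copy
    count of the causal allele.  ``marker_dosages`` are the true (noise
    free) marker dosages used to emit sequence genotype calls.
    """

    samples: list[str]
    diplotypes: np.ndarray  # (n,) 0/1/2
    ancestry: np.ndarray  # (n, 2, m) founder haplotype ids
    causal: np.ndarray  # (n, 2) bool
    marker_dosages: np.ndarray  # (n, m) true dosages
    marker_positions: np.ndarray  # (m,)
    founder_carrier_haplotype: np.ndarray  # (m,) alleles of the ancestral copy
    chrom: str
    focal_pos: int
    focal_ref: str
    focal_alt: str
    seed: int

    @property
    def het_samples(self) -> list[str]:
        return [s for s, d in zip(self.samples, self.diplotypes) if d == 1]

    @property
    def hom_samples(self) -> list[str]:
        return [s for s, d in zip(self.samples, self.diplotypes) if d == 2]

    @property
    def wt_samples(self) -> list[str]:
        return [s for s, d in zip(self.samples, self.diplotypes) if d == 0]

    def carrier_frequency(self) -> float:
        return float(self.diplotypes.sum() / (2 * len(self.samples)))

    def subset(self, samples: list[str]) -> "TruthTable":
        """Truth restricted to a sample subset (e.g. an expression cohort)."""
        idx = [self.samples.index(s) for s in samples]
        return TruthTable(
            samples=list(samples),
            diplotypes=self.diplotypes[idx],
            ancestry=self.ancestry[idx],
            causal=self.causal[idx],
            marker_dosages=self.marker_dosages[idx],
            marker_positions=self.marker_positions,
            founder_carrier_haplotype=self.founder_carrier_haplotype,
            chrom=self.chrom,
            focal_pos=self.focal_pos,
            focal_ref=self.focal_ref,
            focal_alt=self.focal_alt,
            seed=self.seed,
        )

    def expression_cohort(self, n_het: int, n_wt: int) -> "TruthTable":
        """A deterministic het/wt sub-cohort of the study's design size.

        Takes the first ``n_het`` heterozygotes and ``n_wt`` wild-type
        animals in sample order (capped at availability).
        """
        chosen = self.het_samples[:n_het] + self.wt_samples[:n_wt]
        return self.subset(chosen)


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    """Independent stream per simulation stage, reproducible from one seed."""
    return np.random.default_rng(np.random.SeedSequence((seed, stage)))


def _gamete(
    alleles: np.ndarray,  # (2, m)
    anc: np.ndarray,  # (2, m)
    causal: np.ndarray,  # (2,)
    positions: np.ndarray,
    focal_pos: int,
    chrom_length: int,
    recomb_rate: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """One recombinant haplotype (Haldane model, uniform breakpoints)."""
    n_cross = rng.poisson(recomb_rate)
    start = int(rng.integers(2))
    if n_cross == 0:
        return alleles[start].copy(), anc[start].copy(), bool(causal[start])
    breaks = np.sort(rng.uniform(0, chrom_length, size=n_cross))
    phase_at = lambda p: (start + np.searchsorted(breaks, p)) % 2
    phases = phase_at(positions)
    out_alleles = np.where(phases == 0, alleles[0], alleles[1])
    out_anc = np.where(phases == 0, anc[0], anc[1])
    focal_phase = int(phase_at(np.array([focal_pos]))[0])
    return out_alleles, out_anc, bool(causal[focal_phase])


def simulate_population(
    config: SimConfig,
) -> tuple[PhasedHaplotypeMatrix, TruthTable]:
    """Gene-drop a causal haplotype through random-mating generations.

    Founder haplotypes are drawn marker-wise from per-marker allele
    frequencies; the causal allele is seeded as identical copies of one
    ancestral carrier haplotype, so every carrier copy in the final
    generation is identical by descent.  Each generation keeps the
    population size constant, with offspring produced by random unions of
    distinct parents.  When ``ensure_homozygote`` is set and the final
    generation lacks a homozygote, one extra animal is produced from a
    carrier × carrier mating (a consanguineous loop, mirroring how such
    cases arise through inbreeding).
    """
    rng = _stage_rng(config.seed, 0)
    m = config.n_markers
    positions = config.marker_positions()
    focal_pos = config.resolved_focal_pos()
    freqs = rng.uniform(*config.marker_freq_range, size=m)

    n = config.n_founders
    alleles = (rng.random((n, 2, m)) < freqs).astype(np.uint8)
    anc = np.arange(2 * n, dtype=np.int32).reshape(n, 2)[:, :, None] \
        * np.ones(m, dtype=np.int32)
    causal = np.zeros((n, 2), dtype=bool)

    # one ancestral carrier haplotype, replicated into k founder slots
    carrier_hap = (rng.random(m) < freqs).astype(np.uint8)
    k = config.n_seed_copies
    slots = rng.choice(2 * n, size=k, replace=False)
    for s in slots:
        alleles[s // 2, s % 2, :] = carrier_hap
        causal[s // 2, s % 2] = True

    def drop(alleles, anc, causal):
        n_off = len(alleles)
        out_a = np.empty_like(alleles)
        out_n = np.empty_like(anc)
        out_c = np.empty((n_off, 2), dtype=bool)
        for i in range(n_off):
            pa, pb = rng.choice(n_off, size=2, replace=False)
            for h, parent in enumerate((pa, pb)):
                out_a[i, h], out_n[i, h], out_c[i, h] = _gamete(
                    alleles[parent], anc[parent], causal[parent], positions,
                    focal_pos, config.chrom_length_bp, config.recomb_rate, rng,
                )
        return out_a, out_n, out_c

    prev = (alleles, anc, causal)
    for _ in range(config.n_generations):
        prev_prev = prev
        prev = drop(*prev)
    alleles, anc, causal = prev

    diplo = causal.sum(axis=1)
    if config.ensure_homozygote and not (diplo == 2).any():
        extra = _consanguineous_offspring(
            prev, prev_prev, positions, focal_pos, config, rng
        )
        if extra is not None:
            ea, en, ec = extra
            alleles = np.concatenate([alleles, ea[None]], axis=0)
            anc = np.concatenate([anc, en[None]], axis=0)
            causal = np.concatenate([causal, ec[None]], axis=0)
            diplo = causal.sum(axis=1)

    samples = [f"S{i:04d}" for i in range(len(alleles))]
    markers = pd.DataFrame({
        "label": [f"M{i:04d}" for i in range(m)],
        "chrom": config.chrom,
        "pos": positions,
        "allele0": "A",
        "allele1": "B",
    })
    matrix = PhasedHaplotypeMatrix(
        samples=samples, markers=markers, haplotypes=alleles.astype(np.uint8)
    )
    truth = TruthTable(
        samples=samples,
        diplotypes=diplo.astype(np.int8),
        ancestry=anc,
        causal=causal,
        marker_dosages=alleles.sum(axis=1).astype(np.int8),
        marker_positions=positions,
        founder_carrier_haplotype=carrier_hap,
        chrom=config.chrom,
        focal_pos=focal_pos,
        focal_ref=config.focal_ref,
        focal_alt=config.focal_alt,
        seed=config.seed,
    )
    return matrix, truth


def _consanguineous_offspring(gen, parent_gen, positions, focal_pos, config, rng):
    """Mate two carriers (current, else previous, generation) to a homozygote."""
    for alleles, anc, causal in (gen, parent_gen):
        carriers = np.nonzero(causal.any(axis=1))[0]
        if len(carriers) < 2:
            continue
        for _ in range(1000):
            pa, pb = rng.choice(carriers, size=2, replace=False)
            out_a = np.empty((2, config.n_markers), dtype=np.uint8)
            out_n = np.empty((2, config.n_markers), dtype=np.int32)
            out_c = np.empty(2, dtype=bool)
            for h, parent in enumerate((pa, pb)):
                out_a[h], out_n[h], out_c[h] = _gamete(
                    alleles[parent], anc[parent], causal[parent], positions,
                    focal_pos, config.chrom_length_bp, config.recomb_rate, rng,
                )
            if out_c.all():
                return out_a, out_n, out_c
    return None


def emit_call(true_dosage: int, depth: int, alt_reads: int) -> int:
    """The genotype-call rule applied to one site's reads.

    A true heterozygote is called heterozygous only when both alleles were
    observed at least once; with a single observed allele the call is
    homozygous for it; zero depth is missing (-1), never a reference call.
    True homozygotes can only yield their own allele.
    """
    if depth == 0:
        return MISSING
    if true_dosage != 1:
        return true_dosage
    if alt_reads == 0:
        return 0
    if alt_reads == depth:
        return 2
    return 1


def simulate_sequence_genotypes(
    truth: TruthTable,
    mean_coverage: float,
    seed: int | None = None,
) -> GenotypeMatrix:
    """Emit sequence genotype calls with depth-dependent undercalling.

    Per sample and site, read depth is Poisson(``mean_coverage``).  A true
    heterozygote draws its alternate reads Binomial(depth, 0.5) and is
    called heterozygous only when both alleles are observed at least once;
    when a single allele is sampled the call is homozygous for it, and a
    site with zero depth is missing (no data is not a reference call).
    The emitted matrix covers all markers plus the focal deletion.
    """
    if mean_coverage <= 0:
        raise ValueError("mean_coverage must be positive")
    rng = _stage_rng(truth.seed if seed is None else seed, 1)
    n = len(truth.samples)
    true_dosages = np.concatenate(
        [truth.marker_dosages, truth.diplotypes[:, None]], axis=1
    )  # (n, m+1); last column is the focal variant
    m1 = true_dosages.shape[1]
    depth = rng.poisson(mean_coverage, size=(n, m1))
    alt_reads = rng.binomial(depth, 0.5)

    calls = np.full((n, m1), MISSING, dtype=np.int8)
    hom = true_dosages != 1
    calls[hom] = true_dosages[hom]
    het = ~hom
    both_seen = het & (alt_reads > 0) & (alt_reads < depth)
    only_alt = het & (alt_reads == depth) & (depth > 0)
    only_ref = het & (alt_reads == 0) & (depth > 0)
    calls[both_seen] = 1
    calls[only_alt] = 2
    calls[only_ref] = 0
    calls[depth == 0] = MISSING

    variants = [
        VariantRecord(truth.chrom, int(p), "A", "G", calls[:, j])
        for j, p in enumerate(truth.marker_positions)
    ]
    variants.append(VariantRecord(
        truth.chrom, truth.focal_pos, truth.focal_ref, truth.focal_alt,
        calls[:, -1],
    ))
    return GenotypeMatrix(samples=list(truth.samples), variants=variants)


def simulate_rna_data(
    truth: TruthTable,
    config: SimConfig,
    seed: int | None = None,
) -> tuple[list[AlleleCounts], pd.DataFrame]:
    """RNA evidence of decay: allele counts in heterozygotes plus abundance.

    Each heterozygote's site depth is Poisson(``rna_depth_mean``) (zero
    depths redrawn to one read) with alternate reads
    Binomial(depth, ``nmd_alt_fraction``) — the decay-depleted fraction.
    The abundance table holds one gene-level feature plus ``n_exons``
    exon features (TPM, truncated at zero): heterozygotes draw the gene
    from the depleted distribution, and ``n_depleted_exons`` of the exons
    scale their baseline by the het/wt abundance ratio.  Homozygotes for
    the deletion reuse the heterozygote block (none were observed in the
    expression cohort that fixed these parameters).
    """
    rng = _stage_rng(truth.seed if seed is None else seed, 2)
    hets = truth.het_samples
    if not hets:
        raise ValueError("no heterozygous samples: allele counts undefined")
    counts: list[AlleleCounts] = []
    for s in hets:
        total = int(rng.poisson(config.rna_depth_mean))
        total = max(total, 1)
        alt = int(rng.binomial(total, config.nmd_alt_fraction))
        counts.append(AlleleCounts(sample=s, ref_count=total - alt,
                                   alt_count=alt))

    ratio = config.tpm_het_mean / config.tpm_wt_mean
    exon_base = rng.uniform(1.0, 8.0, size=config.n_exons)
    depleted = np.zeros(config.n_exons, dtype=bool)
    depleted[: config.n_depleted_exons] = True

    features = ["GENE"] + [f"EX{i + 1:02d}" for i in range(config.n_exons)]
    table = pd.DataFrame(index=features, columns=list(truth.samples),
                         dtype=float)
    for s, d in zip(truth.samples, truth.diplotypes):
        if d == 0:
            gene = rng.normal(config.tpm_wt_mean, config.tpm_wt_sd)
            means = exon_base
        else:
            gene = rng.normal(config.tpm_het_mean, config.tpm_het_sd)
            means = np.where(depleted, exon_base * ratio, exon_base)
        exons = rng.normal(means, config.exon_rel_sd * exon_base)
        table[s] = np.clip(np.concatenate([[gene], exons]), 0.0, None)
    return counts, table


def simulate_ejaculates(
    truth: TruthTable,
    config: SimConfig,
    seed: int | None = None,
) -> list[EjaculateRecord]:
    """Genotype-dependent semen phenotypes for every bull in the cohort.

    Homozygous-alt bulls draw from the affected parameter block, everyone
    else from the normal block; draws are truncated at zero, percentages
    clipped to [0, 100], and collection ages fall uniformly in the QC age
    window.
    """
    rng = _stage_rng(truth.seed if seed is None else seed, 3)
    lo, hi = config.age_window_days
    records: list[EjaculateRecord] = []
    for s, d in zip(truth.samples, truth.diplotypes):
        params = config.semen_affected if d == 2 else config.semen_normal
        for _ in range(config.ejaculates_per_bull):
            records.append(EjaculateRecord(
                bull=s,
                age_days=float(rng.uniform(lo, hi)),
                volume_ml=max(0.0, float(rng.normal(params.volume_mean,
                                                    params.volume_sd))),
                concentration=max(0.0, float(rng.normal(
                    params.concentration_mean, params.concentration_sd
                ))) * 1000.0,  # 1e9/mL -> million/mL
                motile_pct=float(np.clip(rng.normal(params.motile_mean,
                                                    params.motile_sd), 0, 100)),
                abnormal_pct=float(np.clip(rng.normal(params.abnormal_mean,
                                                      params.abnormal_sd),
                                           0, 100)),
            ))
    return records


# toy gene model construction ------------------------------------------------

_NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]

_EXON_LENGTHS = (200, 180, 220, 200, 180, 250)
_INTRON_LENGTH = 400
_FOCAL_EXON = 3  # 0-based: deletion sits in the 4th of 6 exons
_FOCAL_OFFSET = 100  # nt into that exon
_UTR5, _UTR3 = 30, 150


def simulate_gene_model(
    config: SimConfig, seed: int | None = None
) -> tuple[GeneModel, VariantRecord]:
    """A toy multi-exon transcript with the focal deletion in its CDS.

    Builds a plus-strand six-exon model positioned so that the focal 1-bp
    deletion falls inside an internal coding exon at a codon boundary that
    keeps the reference frame stop-free, then returns the model together
    with the anchored deletion record (ref ``TC``, alt ``T``).  The
    construction retries its random coding sequence until the shifted
    frame terminates before the transcript end, so the annotated
    consequence is always a frameshift with a known Ter offset.
    """
    rng = _stage_rng(config.seed if seed is None else seed, 4)
    focal_pos = config.resolved_focal_pos()
    total = sum(_EXON_LENGTHS)
    cds_len = total - _UTR5 - _UTR3
    assert cds_len % 3 == 0

    # genomic coordinates: walk back from the focal position
    offset_in_gene = sum(_EXON_LENGTHS[:_FOCAL_EXON]) \
        + _FOCAL_EXON * _INTRON_LENGTH + _FOCAL_OFFSET
    g0 = focal_pos - offset_in_gene + 1
    if g0 < 1:
        raise ValueError("focal position too close to the chromosome start")
    exons = []
    start = g0
    for L in _EXON_LENGTHS:
        exons.append((start, start + L - 1))
        start += L + _INTRON_LENGTH

    tx_focal = sum(_EXON_LENGTHS[:_FOCAL_EXON]) + _FOCAL_OFFSET
    # the deleted base is the C following the anchor T; both sit at the
    # start of a codon so the reference codon is TCx (serine, never stop)
    assert (tx_focal - _UTR5 - 1) % 3 == 0

    bases = np.array(list("ACGT"))
    for _ in range(100):
        utr5 = "".join(rng.choice(bases, _UTR5))
        utr3 = "".join(rng.choice(bases, _UTR3))
        cds = "".join(rng.choice(_NON_STOP_CODONS, cds_len // 3 - 1))
        cds += "TAA"
        seq = list(utr5 + cds + utr3)
        seq[tx_focal - 1] = "T"
        seq[tx_focal] = "C"
        model = GeneModel(
            transcript_id="TOYT0001",
            chrom=config.chrom,
            strand="+",
            exons=exons,
            cds_start=_UTR5 + 1,
            cds_end=_UTR5 + cds_len,
            transcript_seq="".join(seq),
        )
        variant = VariantRecord(
            config.chrom, focal_pos, config.focal_ref, config.focal_alt,
            np.zeros(0, dtype=np.int8),
        )
        from .consequence import apply_variant_and_annotate, predict_nmd

        cons = apply_variant_and_annotate(model, variant)
        if cons.kind == "frameshift" and cons.ter_offset is not None:
            call = predict_nmd(model, cons)
            if call.canonical_rule == "triggering":
                return model, variant
    raise RuntimeError("could not construct a decay-triggering toy model")
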