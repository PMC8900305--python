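"""Carrier-haplotype construction, population screening and carrier statistics.

Sequenced carriers of a recessive allele that descends from a common
ancestor share, in the heterozygous state, a marker haplotype around the
causal position.  :func:`extend_shared_haplotype` recovers that diagnostic
haplotype from phased array data by extending outward from the focal
position for as long as an allele consistent with every carrier exists;
:func:`screen_population` then counts haplotype copies per animal in a
large genotyped cohort, and :func:`carrier_statistics` summarizes carrier
counts against Hardy–Weinberg expectations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

from .genotype_io import MISSING, GenotypeMatrix, PhasedHaplotypeMatrix

__all__ = [
    "FocalVariant",
    "SharedHaplotype",
    "CarrierReport",
    "Discordance",
    "extend_shared_haplotype",
    "screen_population",
    "carrier_statistics",
    "concordance_check",
    "hwe_exact_test",
]


@dataclass(frozen=True)
class FocalVariant:
    """The causal variant: sequence-only, sits between two array markers."""

    chrom: str
    pos: int
    ref: str
    alt: str

    @property
    def label(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass
class SharedHaplotype:
    """Diagnostic haplotype: a marker-index interval plus its allele vector."""

    chrom: str
    start_index: int  # inclusive, into the phased matrix marker table
    end_index: int
    alleles: np.ndarray  # 0/1 per marker over [start_index, end_index]
    start_bp: int
    end_bp: int

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        n = self.end_index - self.start_index + 1
        if len(self.alleles) != n:
            raise ValueError(
                f"allele vector length {len(self.alleles)} != interval size {n}"
            )

    @property
    def n_markers(self) -> int:
        return len(self.alleles)

    @property
    def span_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass
class CarrierReport:
    """Carrier counts, haplotype frequency and Hardy–Weinberg statistics."""

    n_samples: int
    n_het: int
    n_hom: int
    frequency: float
    expected_hom: float
    expected_hom_rounded: int
    hwe_chi2: float
    hwe_p: float
    hwe_exact_p: float
    carriers: list[str] = field(default_factory=list)

    @property
    def frequency_pct(self) -> float:
        """Frequency in percent, rounded to 1 decimal (report layer)."""
        return round(100.0 * self.frequency, 1)


def _flank_indices(phased: PhasedHaplotypeMatrix, focal: FocalVariant
                   ) -> tuple[int, int]:
    """(last marker before focal, first marker after focal), same chrom."""
    on_chrom = phased.markers["chrom"] == focal.chrom
    if not on_chrom.any():
        raise ValueError(f"no markers on chromosome {focal.chrom}")
    idx = np.nonzero(on_chrom.to_numpy())[0]
    pos = phased.markers["pos"].to_numpy()[idx]
    if focal.pos <= pos[0] or focal.pos >= pos[-1]:
        raise ValueError(
            f"focal position {focal.pos} outside marker range "
            f"[{pos[0]}, {pos[-1]}] on {focal.chrom}"
        )
    if (pos == focal.pos).any():
        raise ValueError("focal variant coincides with an array marker")
    right = idx[int(np.searchsorted(pos, focal.pos))]
    return right - 1, right


def extend_shared_haplotype(
    phased: PhasedHaplotypeMatrix,
    focal: FocalVariant,
    carriers: set[str] | list[str],
) -> SharedHaplotype:
    """Find the longest haplotype shared by all carriers around the focal site.

    Each carrier starts with both phased haplotypes "alive".  Moving outward
    marker-by-marker (left and right of the focal position, each direction
    independent), the allele kept at a marker must leave every carrier at
    least one alive haplotype carrying it; haplotypes without it are pruned.
    When both alleles are feasible the one retaining more alive haplotypes
    in total wins, ties to allele 0.  A direction stops when neither allele
    is feasible.

    With a single heterozygous carrier both of its haplotypes stay alive at
    every marker, so the extension reaches both chromosome ends — the
    documented degenerate behaviour.
    """
    carriers = list(carriers)
    if not carriers:
        raise ValueError("carrier set is empty")
    rows = [phased.sample_index(c) for c in carriers]
    H = phased.haplotypes[rows]  # (n_carriers, 2, n_markers)
    left_start, right_start = _flank_indices(phased, focal)
    n_markers = phased.n_markers
    chrom_mask = (phased.markers["chrom"] == focal.chrom).to_numpy()

    def sweep(start: int, step: int) -> list[tuple[int, int]]:
        alive = np.ones((len(carriers), 2), dtype=bool)
        out: list[tuple[int, int]] = []
        m = start
        while 0 <= m < n_markers and chrom_mask[m]:
            chosen = None
            best_alive = -1
            for a in (0, 1):
                keep = alive & (H[:, :, m] == a)
                if keep.any(axis=1).all():
                    total = int(keep.sum())
                    # ties break toward allele 0 (strict improvement required)
                    if total > best_alive:
                        best_alive = total
                        chosen = a
            if chosen is None:
                break
            alive &= H[:, :, m] == chosen
            out.append((m, chosen))
            m += step
        return out

    left = sweep(left_start, -1)
    right = sweep(right_start, +1)
    if not left and not right:
        raise ValueError("no shared allele at either focal flank")
    picked = left[::-1] + right
    indices = [m for m, _ in picked]
    alleles = np.array([a for _, a in picked], dtype=np.uint8)
    i, j = indices[0], indices[-1]
    pos = phased.markers["pos"].to_numpy()
    return SharedHaplotype(
        chrom=focal.chrom, start_index=i, end_index=j, alleles=alleles,
        start_bp=int(pos[i]), end_bp=int(pos[j]),
    )


def screen_population(
    phased: PhasedHaplotypeMatrix, hap: SharedHaplotype
) -> dict[str, int]:
    """Per-sample copy count of the diagnostic haplotype (exact match)."""
    i, j = hap.start_index, hap.end_index
    if not (0 <= i <= j < phased.n_markers):
        raise ValueError("haplotype indices outside the phased matrix")
    window = phased.haplotypes[:, :, i : j + 1]
    match = (window == hap.alleles[None, None, :]).all(axis=2)
    copies = match.sum(axis=1)
    return {s: int(c) for s, c in zip(phased.samples, copies)}


def hwe_exact_test(n_het: int, n_hom_rare: int, n_hom_common: int) -> float:
    """Exact test of Hardy–Weinberg proportions for a biallelic site.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts no more likely than the observed one (the
    standard exact HWE formulation).  Returns 1.0 when no rare allele is
    present.
    """
    n = n_het + n_hom_rare + n_hom_common
    rare = n_het + 2 * min(n_hom_rare, n_hom_common)
    if n == 0:
        raise ValueError("no samples")
    if rare == 0:
        return 1.0
    from scipy.special import gammaln

    def log_prob(h: int) -> float:
        # P(het = h | n, rare) up to the shared normalizer
        r = (rare - h) // 2
        c = n - h - r
        return (
            h * np.log(2)
            - gammaln(h + 1) - gammaln(r + 1) - gammaln(c + 1)
        )

    hets = np.arange(rare % 2, rare + 1, 2)
    hets = hets[(rare - hets) // 2 + hets <= n]
    logp = np.array([log_prob(int(h)) for h in hets])
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    obs = p[hets == n_het]
    if obs.size == 0:
        raise ValueError("observed het count inconsistent with allele count")
    return float(min(1.0, p[p <= obs[0] * (1 + 1e-12)].sum()))


def carrier_statistics(
    copies: dict[str, int] | None = None,
    *,
    n_het: int | None = None,
    n_hom: int | None = None,
    n_samples: int | None = None,
) -> CarrierReport:
    """Carrier counts, haplotype frequency, and Hardy–Weinberg test.

    Accepts either the per-sample copy counts from
    :func:`screen_population` or explicit ``n_het``/``n_hom``/``n_samples``
    counts.  Frequency q = (n_het + 2·n_hom) / 2N; expected homozygotes
    N·q² (also rounded); the HWE test is the 1-df chi-square on observed vs
    expected genotype counts without continuity correction, with the exact
    test reported alongside.
    """
    carriers: list[str] = []
    if copies is not None:
        n_samples = len(copies)
        n_het = sum(1 for c in copies.values() if c == 1)
        n_hom = sum(1 for c in copies.values() if c == 2)
        carriers = sorted(s for s, c in copies.items() if c >= 1)
    if not n_samples:
        raise ValueError("no samples")
    if n_het is None or n_hom is None:
        raise ValueError("n_het and n_hom are required without copy counts")
    N = n_samples
    q = (n_het + 2 * n_hom) / (2 * N)
    exp_hom = N * q * q
    exp_het = 2 * N * q * (1 - q)
    exp_ref = N * (1 - q) ** 2
    obs = np.array([n_hom, n_het, N - n_het - n_hom], dtype=float)
    exp = np.array([exp_hom, exp_het, exp_ref])
    if q in (0.0, 1.0):
        stat, p = 0.0, 1.0
    else:
        stat = float(((obs - exp) ** 2 / exp).sum())
        p = float(chi2.sf(stat, df=1))
    exact_p = hwe_exact_test(n_het, n_hom, N - n_het - n_hom)
    return CarrierReport(
        n_samples=N, n_het=n_het, n_hom=n_hom, frequency=q,
        expected_hom=exp_hom, expected_hom_rounded=int(round(exp_hom)),
        hwe_chi2=stat, hwe_p=p, hwe_exact_p=exact_p, carriers=carriers,
    )


@dataclass
class Discordance:
    """A sample where haplotype copies and sequence dosage disagree."""

    sample: str
    copies: int
    dosage: int


def concordance_check(
    copies: dict[str, int],
    matrix: GenotypeMatrix,
    focal: FocalVariant,
) -> list[Discordance]:
    """Compare haplotype copy counts with sequence dosages at the focal site.

    Returns one entry per shared sample where the two disagree (an empty
    list means full concordance).  Samples with a missing sequence genotype
    are skipped — there is nothing to compare.
    """
    variant = matrix.find_variant(focal.chrom, focal.pos)
    out: list[Discordance] = []
    for s in matrix.samples:
        if s not in copies:
            continue
        d = int(variant.dosages[matrix.sample_index(s)])
        if d == MISSING:
            continue
        if copies[s] != d:
            out.append(Discordance(sample=s, copies=copies[s], dosage=d))
    return out
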