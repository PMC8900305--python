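"""Recessive case/control variant filtering and autozygosity scanning.

A recessive causal allele must be homozygous in the affected animal and
never homozygous in fertile controls.  :func:`find_compatible_variants`
applies exactly that filter to a genotype matrix;
:func:`rank_candidates` prioritizes the surviving variants by predicted
protein impact and testis expression; and
:func:`heterozygosity_windows` / :func:`roh_segments` locate the extended
runs of homozygosity in the case genome within which such an allele —
inherited twice from a common ancestor — is expected to reside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix, VariantRecord

__all__ = [
    "CandidateVariant",
    "HetWindow",
    "find_compatible_variants",
    "rank_candidates",
    "heterozygosity_windows",
    "roh_segments",
]

#: Consequence labels counted as high impact (protein-truncating or
#: splice-disrupting), mirroring the usual high/moderate dichotomy of
#: variant effect predictors without re-implementing their ontology.
HIGH_IMPACT = {"stop_gained", "nonsense", "frameshift", "splice_disrupting"}
MODERATE_IMPACT = {"missense", "inframe_indel"}


def impact_class(consequence: str) -> str:
    if consequence in HIGH_IMPACT:
        return "high"
    if consequence in MODERATE_IMPACT:
        return "moderate"
    return "other"


@dataclass
class CandidateVariant:
    """A compatibility-filter survivor with its prioritization evidence."""

    variant: VariantRecord
    consequence: str
    gene: str
    tpm: float  # mean testis abundance over the expression cohort

    @property
    def impact(self) -> str:
        return impact_class(self.consequence)


def find_compatible_variants(
    matrix: GenotypeMatrix, case: str, controls: set[str] | list[str]
) -> list[VariantRecord]:
    """Variants homozygous-alt in the case and never homozygous-alt in controls.

    A missing case genotype excludes the site (homozygosity cannot be
    asserted); missing control genotypes do not disqualify a variant.
    Output is sorted by (chrom, pos) — the matrix invariant.
    """
    controls = list(controls)
    if case in controls:
        raise ValueError(f"case {case!r} also appears among controls")
    ci = matrix.sample_index(case)
    idx = [matrix.sample_index(c) for c in controls]
    out: list[VariantRecord] = []
    for v in matrix.variants:
        if v.dosages[ci] != 2:
            continue
        if idx and (v.dosages[idx] == 2).any():
            continue
        out.append(v)
    return out


def rank_candidates(
    candidates: list[VariantRecord],
    consequences: dict[str, str],
    gene_of: dict[str, str],
    abundance: dict[str, float],
    min_tpm: float = 1.0,
) -> list[tuple[CandidateVariant, bool]]:
    """Prioritize compatible variants by impact and testis expression.

    ``consequences`` and ``gene_of`` map variant labels
    (``chrom:pos:ref:alt``) to a consequence term and gene; ``abundance``
    maps genes to mean testis TPM (absent gene → 0).  Only high-impact
    candidates are retained; they are ordered with genes expressed at
    ``min_tpm`` or more first, then by descending TPM, ties by position.
    Every retained candidate is reported with its pass/fail flag rather
    than silently dropped.
    """
    rows: list[CandidateVariant] = []
    for v in candidates:
        cons = consequences.get(v.label, "unknown")
        if impact_class(cons) != "high":
            continue
        gene = gene_of.get(v.label, v.label)
        rows.append(CandidateVariant(
            variant=v, consequence=cons, gene=gene,
            tpm=float(abundance.get(gene, 0.0)),
        ))
    rows.sort(key=lambda c: (c.tpm < min_tpm, -c.tpm,
                             c.variant.chrom, c.variant.pos))
    return [(c, c.tpm >= min_tpm) for c in rows]


@dataclass
class HetWindow:
    """Heterozygous genotype fraction in one tiling window."""

    chrom: str
    start_bp: int  # 1-based inclusive
    end_bp: int
    n_variants: int  # non-missing genotypes in the window
    het_fraction: float  # NaN when the window is empty

    @property
    def empty(self) -> bool:
        return self.n_variants == 0


def heterozygosity_windows(
    matrix: GenotypeMatrix, sample: str, window_bp: int = 125_000
) -> list[HetWindow]:
    """Heterozygosity fraction in non-overlapping windows tiled from base 1.

    Windows tile each chromosome from coordinate 1 (reproducible
    boundaries) up to the last variant; ``het_fraction`` is the share of
    heterozygous calls among non-missing genotypes in the window, NaN for
    windows without any.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    si = matrix.sample_index(sample)
    by_chrom: dict[str, list[VariantRecord]] = {}
    for v in matrix.variants:
        by_chrom.setdefault(v.chrom, []).append(v)
    out: list[HetWindow] = []
    for chrom, variants in by_chrom.items():
        last = variants[-1].pos
        n_windows = (last - 1) // window_bp + 1
        het = np.zeros(n_windows, dtype=int)
        tot = np.zeros(n_windows, dtype=int)
        for v in variants:
            d = v.dosages[si]
            if d == MISSING:
                continue
            w = (v.pos - 1) // window_bp
            tot[w] += 1
            het[w] += d == 1
        for w in range(n_windows):
            frac = het[w] / tot[w] if tot[w] else float("nan")
            out.append(HetWindow(
                chrom=chrom, start_bp=w * window_bp + 1,
                end_bp=(w + 1) * window_bp, n_variants=int(tot[w]),
                het_fraction=frac,
            ))
    return out


def roh_segments(
    windows: list[HetWindow],
    max_het_fraction: float = 0.02,
    min_len_bp: int = 1_000_000,
) -> list[tuple[str, int, int]]:
    """Merge runs of low-heterozygosity windows into homozygosity segments.

    Maximal runs of consecutive non-empty windows with ``het_fraction`` at
    most ``max_het_fraction`` are merged (an empty window terminates a
    run); runs spanning less than ``min_len_bp`` are discarded.  Segments
    are reported as (chrom, start_bp, end_bp), 1-based inclusive.  The
    default thresholds (2% heterozygosity, 1 Mb) are tunable — windowed
    autozygosity scans have no canonical cutoffs.
    """
    segments: list[tuple[str, int, int]] = []
    run: list[HetWindow] = []

    def flush() -> None:
        if run:
            start, end = run[0].start_bp, run[-1].end_bp
            if end - start + 1 >= min_len_bp:
                segments.append((run[0].chrom, start, end))
            run.clear()

    prev: HetWindow | None = None
    for w in windows:
        contiguous = (
            prev is not None and w.chrom == prev.chrom
            and w.start_bp == prev.end_bp + 1
        )
        if not contiguous:
            flush()
        if not w.empty and w.het_fraction <= max_het_fraction:
            if not contiguous:
                run.clear()
            run.append(w)
        else:
            flush()
        prev = w
    flush()
    return segments
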