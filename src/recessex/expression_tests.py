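"""Transcript-level evidence for nonsense-mediated decay.

Two lines of evidence that a premature termination codon destabilizes a
transcript are quantified here:

* allelic imbalance — among RNA reads of heterozygous animals, the
  mutant allele is supported by fewer reads than the 0.5 expected from
  balanced expression (exact binomial test);
* abundance depletion — heterozygotes show lower gene and exon abundance
  (TPM) than wild-type animals (Wilcoxon rank-sum test).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import binomtest, mannwhitneyu

__all__ = [
    "AlleleCounts",
    "binomial_ai_test",
    "pool_and_summarize",
    "PooledSummary",
    "wilcoxon_rank_sum",
    "exon_level_de",
    "read_allele_counts",
    "write_allele_counts",
    "read_abundance_table",
    "write_abundance_table",
]


@dataclass
class AlleleCounts:
    """Reference/alternate read support at the focal variant for one sample."""

    sample: str
    ref_count: int
    alt_count: int

    def __post_init__(self) -> None:
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def total(self) -> int:
        return self.ref_count + self.alt_count

    @property
    def alt_fraction(self) -> float:
        if self.total == 0:
            raise ValueError("no reads")
        return self.alt_count / self.total


def binomial_ai_test(ref_count: int, alt_count: int, p0: float = 0.5) -> float:
    """Exact two-sided binomial test of the alternate-allele read fraction.

    Tests alt_count successes in ref_count + alt_count trials against
    success probability ``p0``.  The two-sided p-value is the sum of the
    probabilities of all outcomes no more likely than the observed one
    (within a 1e-7 relative tolerance — the convention of R's binom.test),
    computed stably for totals in the thousands where the p-value can fall
    below 1e-79.
    """
    n = ref_count + alt_count
    if n < 1:
        raise ValueError("total read count must be at least 1")
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    return float(binomtest(alt_count, n, p0, alternative="two-sided").pvalue)


@dataclass
class PooledSummary:
    """Pooled allele counts plus per-sample moments of read support."""

    n_samples: int
    pooled_ref: int
    pooled_alt: int
    mean_total: float
    sd_total: float | None  # None when a single sample (sd undefined)
    mean_alt: float
    sd_alt: float | None

    @property
    def pooled_alt_fraction(self) -> float:
        return self.pooled_alt / (self.pooled_ref + self.pooled_alt)


def pool_and_summarize(counts: list[AlleleCounts]) -> PooledSummary:
    """Pool per-sample allele counts and summarize per-sample read depth."""
    if not counts:
        raise ValueError("no allele counts supplied")
    totals = np.array([c.total for c in counts], dtype=float)
    alts = np.array([c.alt_count for c in counts], dtype=float)
    n = len(counts)
    sd_total = float(totals.std(ddof=1)) if n > 1 else None
    sd_alt = float(alts.std(ddof=1)) if n > 1 else None
    return PooledSummary(
        n_samples=n,
        pooled_ref=int(sum(c.ref_count for c in counts)),
        pooled_alt=int(sum(c.alt_count for c in counts)),
        mean_total=float(totals.mean()), sd_total=sd_total,
        mean_alt=float(alts.mean()), sd_alt=sd_alt,
    )


def wilcoxon_rank_sum(group_a, group_b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) p-value.

    Uses the exact null distribution when both groups have at most 20
    observations and no ties; otherwise the normal approximation with
    continuity and tie correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == pooled.size
    method = "exact" if (a.size <= 20 and b.size <= 20 and no_ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method,
                       use_continuity=True)
    return float(res.pvalue)


def exon_level_de(
    table: pd.DataFrame,
    het: list[str] | set[str],
    wt: list[str] | set[str],
    alpha: float = 0.05,
    correction: str | None = None,
) -> pd.DataFrame:
    """Per-feature rank-sum tests of heterozygote vs wild-type abundance.

    ``table`` is features × samples (TPM).  Returns a DataFrame indexed by
    feature with columns ``p``, ``flag`` (nominal p < alpha, the default
    reporting) and, when ``correction='bh'``, ``p_adj``/``flag_adj``
    (Benjamini–Hochberg).
    """
    het, wt = sorted(het), sorted(wt)
    if set(het) & set(wt):
        raise ValueError("heterozygote and wild-type groups overlap")
    missing = [s for s in list(het) + list(wt) if s not in table.columns]
    if missing:
        raise KeyError(f"samples not in abundance table: {missing}")
    pvals = np.array([
        wilcoxon_rank_sum(row[het].to_numpy(), row[wt].to_numpy())
        for _, row in table.iterrows()
    ])
    out = pd.DataFrame({"p": pvals, "flag": pvals < alpha}, index=table.index)
    if correction == "bh":
        from scipy.stats import false_discovery_control

        p_adj = false_discovery_control(pvals, method="bh")
        out["p_adj"] = p_adj
        out["flag_adj"] = p_adj < alpha
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    return out


# ---------------------------------------------------------------------------
# Tab-separated interchange
# ---------------------------------------------------------------------------

def write_allele_counts(counts: list[AlleleCounts], path: str | Path) -> None:
    pd.DataFrame(
        [(c.sample, c.ref_count, c.alt_count) for c in counts],
        columns=["sample", "ref_count", "alt_count"],
    ).to_csv(path, sep="\t", index=False)


def read_allele_counts(path: str | Path) -> list[AlleleCounts]:
    df = pd.read_csv(path, sep="\t")
    return [AlleleCounts(str(r.sample), int(r.ref_count), int(r.alt_count))
            for r in df.itertuples()]


def write_abundance_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=True, index_label="feature")


def read_abundance_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df.set_index("feature")
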