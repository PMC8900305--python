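import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from recessex.genotype_io import GenotypeMatrix, PhasedHaplotypeMatrix, VariantRecord
from recessex.haplotype_screen import (
    FocalVariant,
    SharedHaplotype,
    carrier_statistics,
    concordance_check,
    extend_shared_haplotype,
    hwe_exact_test,
    screen_population,
)
from recessex.simdata import SimConfig, simulate_population


def phased_from_haplotypes(hap, positions=None, chrom="19"):
    """hap: (n_samples, 2, m) array of 0/1."""
    hap = np.asarray(hap, dtype=np.uint8)
    m = hap.shape[2]
    positions = positions if positions is not None \
        else (np.arange(m) + 1) * 100
    markers = pd.DataFrame({
        "label": [f"M{i}" for i in range(m)], "chrom": chrom,
        "pos": positions, "allele0": "A", "allele1": "B",
    })
    samples = [f"S{i}" for i in range(hap.shape[0])]
    return PhasedHaplotypeMatrix(samples=samples, markers=markers,
                                 haplotypes=hap)


def focal_between(phased, left_index):
    pos = phased.positions
    return FocalVariant(str(phased.markers["chrom"].iloc[0]),
                        int((pos[left_index] + pos[left_index + 1]) // 2),
                        "TC", "T")


def brute_force_widest_window(phased, focal, carriers):
    """Widest contiguous marker window around the focal flanks for which an
    allele vector carried by every carrier exists.

    A feasible shared vector must coincide with one of the first carrier's
    haplotype restrictions, so those two candidates are checked against
    every carrier for every window — an exhaustive search over windows.
    """
    pos = phased.positions
    right = int(np.searchsorted(pos, focal.pos))
    left = right - 1
    rows = [phased.sample_index(c) for c in carriers]
    H = phased.haplotypes[rows]
    best = None
    for i in range(left + 1):
        for j in range(right, phased.n_markers):
            feasible = False
            for h in range(2):
                v = H[0, h, i : j + 1]
                if all(((H[c, 0, i : j + 1] == v).all()
                        or (H[c, 1, i : j + 1] == v).all())
                       for c in range(len(rows))):
                    feasible = True
                    break
            if feasible and (best is None or j - i > best[1] - best[0]):
                best = (i, j)
    return best


class TestExtendSharedHaplotype:
    def test_single_het_carrier_spans_whole_chromosome(self):
        rng = np.random.default_rng(0)
        hap = rng.integers(0, 2, size=(5, 2, 20))
        phased = phased_from_haplotypes(hap)
        focal = focal_between(phased, 9)
        out = extend_shared_haplotype(phased, focal, ["S2"])
        # both haplotypes stay alive everywhere: documented degenerate case
        assert (out.start_index, out.end_index) == (0, 19)

    def test_no_recombination_recovers_full_founder_haplotype(self):
        cfg = SimConfig(n_founders=60, n_generations=2, n_markers=30,
                        recomb_rate=0.0, ensure_homozygote=False, seed=4)
        phased, truth = simulate_population(cfg)
        carriers = truth.het_samples
        assert len(carriers) >= 2
        focal = FocalVariant(truth.chrom, truth.focal_pos, "TC", "T")
        out = extend_shared_haplotype(phased, focal, carriers)
        assert (out.start_index, out.end_index) == (0, 29)
        assert np.array_equal(out.alleles, truth.founder_carrier_haplotype)

    @pytest.mark.parametrize("seed", range(6))
    def test_equals_brute_force_window_oracle_on_planted_instances(self, seed):
        # carriers share a planted vector on nested windows around the
        # focal flanks (IBD segments with recombination breakpoints);
        # remaining alleles are random background
        rng = np.random.default_rng(seed)
        m = 40
        shared = rng.integers(0, 2, size=m)
        # >= 3 carriers: with fewer, random backgrounds make coincidental
        # windows likely (the documented few-carrier ambiguity)
        n_carriers = int(rng.integers(3, 7))
        hap = rng.integers(0, 2, size=(n_carriers + 3, 2, m))
        left_flank, right_flank = 19, 20
        for c in range(n_carriers):
            a = int(rng.integers(0, left_flank + 1))
            b = int(rng.integers(right_flank, m))
            hap[c, 0, a : b + 1] = shared[a : b + 1]
        phased = phased_from_haplotypes(hap)
        focal = focal_between(phased, left_flank)
        carriers = [f"S{c}" for c in range(n_carriers)]
        out = extend_shared_haplotype(phased, focal, carriers)
        i, j = brute_force_widest_window(phased, focal, carriers)
        assert (out.start_index, out.end_index) == (i, j)

    def test_adding_a_carrier_never_widens_interval(self, population):
        phased, truth = population
        focal = FocalVariant(truth.chrom, truth.focal_pos, "TC", "T")
        hets = truth.het_samples
        prev = None
        for k in (2, 4, 8, len(hets)):
            out = extend_shared_haplotype(phased, focal, hets[:k])
            if prev is not None:
                assert out.start_index >= prev.start_index
                assert out.end_index <= prev.end_index
            prev = out

    def test_errors(self):
        rng = np.random.default_rng(0)
        phased = phased_from_haplotypes(rng.integers(0, 2, size=(3, 2, 10)))
        focal = focal_between(phased, 4)
        with pytest.raises(ValueError, match="empty"):
            extend_shared_haplotype(phased, focal, [])
        outside = FocalVariant("19", 10_000, "TC", "T")
        with pytest.raises(ValueError, match="outside"):
            extend_shared_haplotype(phased, outside, ["S0"])


class TestScreenPopulation:
    def test_exact_match_copy_counts(self):
        v = np.array([1, 0, 1, 1])
        hap = np.stack([
            np.stack([v, v]),  # both haplotypes match -> 2
            np.stack([v, 1 - v]),  # one matches -> 1
            np.stack([1 - v, 1 - v]),  # none -> 0
        ])
        phased = phased_from_haplotypes(hap)
        shared = SharedHaplotype("19", 0, 3, v, 100, 400)
        copies = screen_population(phased, shared)
        assert copies == {"S0": 2, "S1": 1, "S2": 0}

    def test_single_marker_haplotype_counts_het(self):
        hap = np.array([[[1], [0]]])
        phased = phased_from_haplotypes(hap)
        shared = SharedHaplotype("19", 0, 0, [1], 100, 100)
        assert screen_population(phased, shared) == {"S0": 1}

    def test_simulated_screen_tracks_truth(self, population):
        phased, truth = population
        focal = FocalVariant(truth.chrom, truth.focal_pos, "TC", "T")
        carriers = truth.het_samples
        shared = extend_shared_haplotype(phased, focal, carriers)
        copies = screen_population(phased, shared)
        # self-consistency: every input carrier carries >= 1 copy
        assert all(copies[c] >= 1 for c in carriers)
        # samples whose causal haplotype is the un-recombined founder copy
        # must screen at >= their true diplotype; overall concordance high
        agree = sum(copies[s] == int(d)
                    for s, d in zip(truth.samples, truth.diplotypes))
        assert agree / len(truth.samples) > 0.9


class TestCarrierStatistics:
    def test_expected_homozygotes_round_to_79(self):
        r = carrier_statistics(n_het=2712, n_hom=54, n_samples=25243)
        assert r.expected_hom_rounded == 79
        assert r.frequency == pytest.approx((2712 + 108) / (2 * 25243))
        assert 0 < r.hwe_p < 1

    @pytest.mark.parametrize("n_het,n,pct", [(25, 244, 5.1), (3, 124, 1.2)])
    def test_cohort_allele_frequencies(self, n_het, n, pct):
        r = carrier_statistics(n_het=n_het, n_hom=0, n_samples=n)
        assert r.frequency_pct == pct

    def test_no_carriers_degenerate(self):
        r = carrier_statistics(n_het=0, n_hom=0, n_samples=50)
        assert r.frequency == 0.0
        assert r.expected_hom == 0.0
        assert r.hwe_p == 1.0
        assert r.hwe_exact_p == 1.0

    def test_perfect_hwe_counts_give_zero_statistic(self):
        # q = 0.5 with exactly p^2, 2pq, q^2 counts
        r = carrier_statistics(n_het=50, n_hom=25, n_samples=100)
        assert r.hwe_chi2 == pytest.approx(0.0, abs=1e-12)
        assert r.hwe_p == pytest.approx(1.0)

    def test_counts_conserve_and_copies_input(self):
        copies = {"a": 0, "b": 1, "c": 2, "d": 1, "e": 0}
        r = carrier_statistics(copies)
        assert (r.n_het, r.n_hom, r.n_samples) == (2, 1, 5)
        assert r.carriers == ["b", "c", "d"]
        assert r.n_het + r.n_hom <= r.n_samples
        assert r.frequency == pytest.approx(4 / 10)

    def test_requires_samples(self):
        with pytest.raises(ValueError):
            carrier_statistics(n_het=0, n_hom=0, n_samples=0)

    @given(n_het=st.integers(0, 300), n_hom=st.integers(0, 100),
           n_ref=st.integers(0, 5000))
    @settings(derandomize=True, max_examples=200, deadline=None)
    def test_invariants_hold_for_arbitrary_counts(self, n_het, n_hom, n_ref):
        n = n_het + n_hom + n_ref
        assume(n > 0)
        r = carrier_statistics(n_het=n_het, n_hom=n_hom, n_samples=n)
        assert 0 <= r.frequency <= 1
        assert r.frequency == pytest.approx((n_het + 2 * n_hom) / (2 * n))
        assert 0 <= r.expected_hom <= n
        # p-values live in (0, 1] up to float underflow at extreme deviations
        assert 0 <= r.hwe_p <= 1
        assert 0 <= r.hwe_exact_p <= 1


def exact_hwe_oracle(n_het, n_hom_rare, n_hom_common):
    """Exact-integer enumeration of the conditional het distribution."""
    n = n_het + n_hom_rare + n_hom_common
    rare = n_het + 2 * min(n_hom_rare, n_hom_common)
    if rare == 0:
        return 1.0
    weights = {}
    h = rare % 2
    while h <= rare:
        r = (rare - h) // 2
        c = n - h - r
        if c >= 0:
            weights[h] = Fraction(2 ** h,
                                  math.factorial(h) * math.factorial(r)
                                  * math.factorial(c))
        h += 2
    total = sum(weights.values())
    obs = weights[n_het]
    return float(sum(w for w in weights.values() if w <= obs) / total)


class TestExactHwe:
    def test_matches_exact_enumeration_for_all_small_tables(self):
        for n in range(1, 9):
            for n_hom in range(n + 1):
                for n_het in range(n - n_hom + 1):
                    got = hwe_exact_test(n_het, n_hom, n - n_hom - n_het)
                    want = exact_hwe_oracle(n_het, n_hom, n - n_hom - n_het)
                    assert got == pytest.approx(want, rel=1e-9), \
                        (n_het, n_hom, n)

    def test_large_table_runs_and_is_small(self):
        p = hwe_exact_test(2712, 54, 22477)
        assert 0 < p < 0.05


class TestConcordance:
    def _matrix(self, dosages):
        samples = [f"S{i}" for i in range(len(dosages))]
        v = VariantRecord("19", 1500, "TC", "T",
                          np.asarray(dosages, dtype=np.int8))
        return GenotypeMatrix(samples=samples, variants=[v])

    def test_identical_truth_is_fully_concordant(self):
        copies = {"S0": 0, "S1": 1, "S2": 2}
        m = self._matrix([0, 1, 2])
        assert concordance_check(copies, m, FocalVariant("19", 1500, "TC", "T")) == []

    def test_het_undercall_pattern_reported(self):
        # haplotype says carrier, sequencing called hom-ref at low depth
        copies = {"S0": 1, "S1": 1}
        m = self._matrix([0, 1])
        out = concordance_check(copies, m, FocalVariant("19", 1500, "TC", "T"))
        assert len(out) == 1
        assert (out[0].sample, out[0].copies, out[0].dosage) == ("S0", 1, 0)

    def test_k_perturbations_give_k_discordances(self):
        rng = np.random.default_rng(5)
        n = 60
        truth = rng.integers(0, 3, size=n)
        copies = {f"S{i}": int(t) for i, t in enumerate(truth)}
        perturbed = truth.copy()
        k = 7
        idx = rng.choice(n, size=k, replace=False)
        for i in idx:
            perturbed[i] = (perturbed[i] + 1) % 3
        m = self._matrix(perturbed)
        out = concordance_check(copies, m, FocalVariant("19", 1500, "TC", "T"))
        assert len(out) == k
        assert {d.sample for d in out} == {f"S{i}" for i in idx}

    def test_missing_dosage_skipped_and_missing_focal_errors(self):
        copies = {"S0": 1}
        m = self._matrix([-1])
        assert concordance_check(copies, m,
                                 FocalVariant("19", 1500, "TC", "T")) == []
        with pytest.raises(KeyError):
            concordance_check(copies, m, FocalVariant("19", 99, "TC", "T"))
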