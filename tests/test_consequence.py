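import numpy as np
import pytest
from Bio.Seq import Seq

from recessex.consequence import (
    GeneModel,
    NotInCdsError,
    UnsupportedVariantError,
    apply_variant_and_annotate,
    map_genomic_to_cds,
    predict_nmd,
    read_gene_model,
    write_gene_model,
)
from recessex.genotype_io import VariantRecord

_COMP = str.maketrans("ACGT", "TGCA")
_NON_STOP = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
             if a + b + c not in ("TAA", "TAG", "TGA")]
_STOPS = ("TAA", "TAG", "TGA")


def _revcomp(s):
    return s.translate(_COMP)[::-1]


def build_model(exon_lengths, utr5, cds_codons, utr3, strand="+", g0=1000,
                intron=120, rng=None, tid="T1"):
    """Construct a toy model from explicit part lengths and a random CDS."""
    rng = rng or np.random.default_rng(0)
    cds = "".join(rng.choice(_NON_STOP, cds_codons - 1)) + \
        str(rng.choice(list(_STOPS)))
    bases = np.array(list("ACGT"))
    seq = "".join(rng.choice(bases, utr5)) + cds + \
        "".join(rng.choice(bases, utr3))
    assert sum(exon_lengths) == len(seq)
    exons, start = [], g0
    for L in exon_lengths:
        exons.append((start, start + L - 1))
        start += L + intron
    return GeneModel(tid, "19", strand, exons, utr5 + 1, utr5 + 3 * cds_codons,
                     seq)


def tx_to_genomic(model):
    """Genomic position of every transcript base, in transcript order."""
    out = []
    for a, b in model.exons_tx_order:
        block = range(a, b + 1)
        out.extend(block if model.strand == "+" else reversed(block))
    return out


def genome_level_oracle(model, variant):
    """Independent consequence computation by editing a genomic sequence.

    Builds the full locus as a genomic string, applies the VCF-anchored
    allele on the genome, re-splices the exons with shifted coordinates,
    and translates — a different route from the transcript-space edit in
    the implementation.
    """
    g_lo = model.exons[0][0]
    g_hi = model.exons[-1][1]
    genome = ["N"] * (g_hi - g_lo + 1)
    gmap = tx_to_genomic(model)
    for t, g in enumerate(gmap):
        base = model.transcript_seq[t]
        genome[g - g_lo] = base if model.strand == "+" else base.translate(_COMP)
    genome = "".join(genome)

    i = variant.pos - g_lo
    assert genome[i : i + len(variant.ref)] == variant.ref
    edited = genome[:i] + variant.alt + genome[i + len(variant.ref):]
    delta = len(variant.alt) - len(variant.ref)

    # re-splice with coordinates shifted for exons past the edit
    pieces = []
    for a, b in model.exons:
        a2, b2 = a - g_lo, b - g_lo
        if a > variant.pos + len(variant.ref) - 1:
            a2 += delta
        if b > variant.pos:
            b2 += delta
        pieces.append(edited[a2 : b2 + 1])
    tx = "".join(pieces)
    if model.strand == "-":
        tx = _revcomp(tx)

    ref_protein = model.protein()
    tail = tx[model.cds_start - 1:]
    tail = tail[: len(tail) - len(tail) % 3]
    mutant = str(Seq(tail).translate())
    limit = min(len(ref_protein), len(mutant))
    first = next((k for k in range(limit)
                  if ref_protein[k] != mutant[k]), None)
    ter = None
    if first is not None:
        stop = mutant.find("*", first)
        ter = stop - first + 1 if stop >= 0 else None
    return first, mutant, ter


def random_model_and_variant(rng):
    """A random toy model plus a random coding SNV or frameshift indel."""
    n_exons = int(rng.integers(2, 6))
    cds_codons = int(rng.integers(8, 30))
    utr5 = int(rng.integers(3, 20))
    utr3 = int(rng.integers(15, 50))
    total = utr5 + 3 * cds_codons + utr3
    cuts = np.sort(rng.choice(np.arange(5, total - 5), n_exons - 1,
                              replace=False))
    lens = np.diff(np.concatenate([[0], cuts, [total]])).tolist()
    strand = "+" if rng.random() < 0.5 else "-"
    model = build_model(lens, utr5, cds_codons, utr3, strand=strand, rng=rng)

    gmap = tx_to_genomic(model)
    seq = model.transcript_seq
    while True:
        t = int(rng.integers(model.cds_start, model.cds_end - 3))  # 1-based
        kind = rng.choice(["snv", "del", "ins"])
        if strand == "+":
            if kind == "snv":
                pos, ref = gmap[t - 1], seq[t - 1]
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            elif kind == "del":
                # anchor t, delete t+1; both must share an exon
                pos, ref, alt = gmap[t - 1], seq[t - 1 : t + 1], seq[t - 1]
                if gmap[t] != pos + 1:
                    continue
            else:
                # inserted base must stay inside the exon after re-splicing
                if gmap[t] != gmap[t - 1] + 1:
                    continue
                pos, ref = gmap[t - 1], seq[t - 1]
                alt = ref + str(rng.choice(list("ACGT")))
        else:
            if kind == "snv":
                pos = gmap[t - 1]
                ref = seq[t - 1].translate(_COMP)
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            elif kind == "del":
                # delete transcript base t (genomic gmap[t-1]), anchored at
                # the genomic base to its left (= transcript base t+1)
                if gmap[t] != gmap[t - 1] - 1:
                    continue
                pos = gmap[t]
                ref = seq[t - 1 : t + 1].translate(_COMP)[::-1]
                alt = ref[0]
            else:
                # insertion lands between pos and pos+1 genomically; both
                # must share an exon
                if t < 2 or gmap[t - 2] != gmap[t - 1] + 1:
                    continue
                pos = gmap[t - 1]
                ref = seq[t - 1].translate(_COMP)
                alt = ref + str(rng.choice(list("ACGT")))
        return model, VariantRecord(model.chrom, int(pos), ref, alt,
                                    np.zeros(0, dtype=np.int8))


class TestCoordinateMapping:
    def test_plus_strand_exon_boundary(self):
        # two exons of 30 coding nt each, no UTR: first base of exon 2 = c.31
        model = build_model([30, 30], 0, 20, 0, g0=500, intron=100)
        assert map_genomic_to_cds(model, 500) == 1
        assert map_genomic_to_cds(model, 630) == 31
        assert map_genomic_to_cds(model, 659) == 60

    def test_minus_strand_full_coordinate_walk(self):
        model = build_model([30, 30], 0, 20, 0, g0=500, intron=100,
                            strand="-")
        # independent walk: transcript runs from the 3'-most genomic base
        expected = {}
        c = 0
        for a, b in reversed(model.exons):
            for g in range(b, a - 1, -1):
                c += 1
                expected[g] = c
        for g, want in expected.items():
            assert map_genomic_to_cds(model, g) == want

    def test_intronic_and_utr_positions_classified(self):
        model = build_model([40, 40], 10, 20, 10, g0=500, intron=100)
        with pytest.raises(NotInCdsError) as e:
            map_genomic_to_cds(model, 560)  # between exons
        assert e.value.region == "intron"
        with pytest.raises(NotInCdsError) as e:
            map_genomic_to_cds(model, 505)  # first 10 nt are 5' UTR
        assert e.value.region == "5_prime_utr"
        with pytest.raises(NotInCdsError) as e:
            map_genomic_to_cds(model, 679)  # last 10 nt are 3' UTR
        assert e.value.region == "3_prime_utr"
        with pytest.raises(NotInCdsError) as e:
            map_genomic_to_cds(model, 1)
        assert e.value.region == "intergenic"


class TestAnnotate:
    def test_constructed_frameshift_with_known_ter(self):
        # deleting codon 4's third base re-translates codon 4 identically
        # (CTG -> CTG), changes residue 5 (GAA Glu -> AAA Lys), and stops
        # three codons after the first change: p.Glu5LysfsTer3
        cds = "ATG" "GCT" "TCT" "CTG" "GAA" "ATT" "ATG" "ATT" "AAA" "TAA"
        model = GeneModel("T1", "19", "+", [(100, 100 + len(cds) - 1)],
                          1, len(cds), cds)
        variant = VariantRecord("19", 110, "TG", "T",
                                np.zeros(0, dtype=np.int8))
        cons = apply_variant_and_annotate(model, variant)
        assert cons.kind == "frameshift"
        assert cons.first_changed_residue == 5
        assert (cons.ref_aa, cons.alt_aa) == ("E", "K")
        assert cons.ter_offset == 3
        assert cons.hgvs_p == "p.Glu5LysfsTer3"

    def test_synonymous_snv(self):
        cds = "ATGCTGTAA"
        model = GeneModel("T1", "19", "+", [(10, 18)], 1, 9, cds)
        # CTG -> CTA is still leucine
        v = VariantRecord("19", 15, "G", "A", np.zeros(0, dtype=np.int8))
        cons = apply_variant_and_annotate(model, v)
        assert cons.kind == "synonymous"
        assert cons.hgvs_p == "p.(=)"

    def test_reference_allele_is_no_change(self):
        cds = "ATGCTGTAA"
        model = GeneModel("T1", "19", "+", [(10, 18)], 1, 9, cds)
        v = VariantRecord("19", 15, "G", "G2", np.zeros(0, dtype=np.int8))
        v.alt = "G"  # bypass ref != alt validation to probe the annotator
        assert apply_variant_and_annotate(model, v).kind == "no_change"

    def test_nonsense_snv(self):
        cds = "ATGTGCCTGTAA"  # M C L *
        model = GeneModel("T1", "19", "+", [(10, 21)], 1, 12, cds)
        # TGC -> TGA at codon 2
        v = VariantRecord("19", 15, "C", "A", np.zeros(0, dtype=np.int8))
        cons = apply_variant_and_annotate(model, v)
        assert cons.kind == "nonsense"
        assert cons.hgvs_p == "p.Cys2Ter"

    def test_non_coding_variant_rejected(self):
        model = build_model([40, 40], 10, 20, 10, g0=500, intron=100)
        v = VariantRecord("19", 560, "A", "G", np.zeros(0, dtype=np.int8))
        with pytest.raises(NotInCdsError):
            apply_variant_and_annotate(model, v)

    def test_inframe_indel_unsupported(self):
        cds = "ATGGCTGCAGCCTAA"
        model = GeneModel("T1", "19", "+", [(10, 24)], 1, 15, cds)
        v = VariantRecord("19", 13, "GCTG", "G", np.zeros(0, dtype=np.int8))
        with pytest.raises(UnsupportedVariantError):
            apply_variant_and_annotate(model, v)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_genome_level_translation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(50):
            model, variant = random_model_and_variant(rng)
            cons = apply_variant_and_annotate(model, variant)
            first, mutant, ter = genome_level_oracle(model, variant)
            if first is None:
                assert cons.kind in ("synonymous", "no_change") or \
                    cons.first_changed_residue == len(model.protein()) + 1
            else:
                assert cons.first_changed_residue == first + 1
                assert cons.alt_aa == mutant[first]
                if cons.kind == "frameshift":
                    assert cons.ter_offset == ter


def mirror_model_and_variant(model, variant):
    """Reverse-complement a locus: mirrored coordinates, flipped strand."""
    G = model.exons[-1][1] + 50
    exons = sorted((G + 1 - b, G + 1 - a) for a, b in model.exons)
    mirrored = GeneModel(model.transcript_id, model.chrom,
                         "-" if model.strand == "+" else "+",
                         exons, model.cds_start, model.cds_end,
                         model.transcript_seq)
    if len(variant.ref) == len(variant.alt) == 1:  # SNV
        mv = VariantRecord(variant.chrom, G + 1 - variant.pos,
                           variant.ref.translate(_COMP),
                           variant.alt.translate(_COMP),
                           np.zeros(0, dtype=np.int8))
        return mirrored, mv
    raise NotImplementedError


class TestStrandSymmetry:
    @pytest.mark.parametrize("seed", range(3))
    def test_snv_consequence_invariant_under_reverse_complement(self, seed):
        rng = np.random.default_rng(100 + seed)
        done = 0
        while done < 25:
            model, variant = random_model_and_variant(rng)
            if len(variant.ref) != 1 or len(variant.alt) != 1:
                continue
            mirrored, mv = mirror_model_and_variant(model, variant)
            a = apply_variant_and_annotate(model, variant)
            b = apply_variant_and_annotate(mirrored, mv)
            assert (a.kind, a.first_changed_residue, a.hgvs_p) == \
                (b.kind, b.first_changed_residue, b.hgvs_p)
            done += 1


class TestNmd:
    def _nonsense_at(self, residue):
        from recessex.consequence import ProteinConsequence
        return ProteinConsequence(kind="nonsense",
                                  first_changed_residue=residue,
                                  ref_aa="Q", alt_aa="*",
                                  hgvs_p=f"p.Gln{residue}Ter")

    def test_deep_ptc_triggers_decay(self):
        model = build_model([90, 90, 90, 90], 9, 100, 51, g0=100)
        # PTC early in the CDS: far more than 50 nt upstream of the last
        # junction
        call = predict_nmd(model, self._nonsense_at(10))
        assert call.canonical_rule == "triggering"
        assert not call.last_exon

    def test_last_exon_ptc_escapes(self):
        model = build_model([90, 90, 90, 90], 9, 100, 51, g0=100)
        call = predict_nmd(model, self._nonsense_at(99))
        assert call.canonical_rule == "escaping"
        assert call.last_exon

    def test_start_proximal_flag(self):
        model = build_model([90, 90, 90, 90], 9, 100, 51, g0=100)
        assert predict_nmd(model, self._nonsense_at(20)).start_proximal
        assert not predict_nmd(model, self._nonsense_at(40)).start_proximal

    def test_single_exon_rule_not_applicable(self):
        model = build_model([60], 6, 15, 9, g0=100)
        call = predict_nmd(model, self._nonsense_at(5))
        assert call.canonical_rule == "not_applicable"
        assert call.distance_to_last_junction is None

    def test_exhaustive_ptc_sweep_matches_inequality(self):
        # brute-force the 50-nt rule at every codon of a 4-exon model
        model = build_model([90, 90, 90, 90], 9, 100, 51, g0=100)
        exon_lens = [b - a + 1 for a, b in model.exons_tx_order]
        last_junction = sum(exon_lens[:-1])
        for residue in range(1, 101):
            call = predict_nmd(model, self._nonsense_at(residue))
            ptc_start = model.cds_start + 3 * (residue - 1)
            ptc_end = ptc_start + 2
            in_last = ptc_start > last_junction
            expect = (not in_last) and (last_junction - ptc_end > 50)
            assert (call.canonical_rule == "triggering") == expect
            assert call.last_exon == in_last
            assert call.distance_to_last_junction == last_junction - ptc_end

    def test_requires_a_stop(self):
        from recessex.consequence import ProteinConsequence
        model = build_model([60], 6, 15, 9, g0=100)
        with pytest.raises(ValueError):
            predict_nmd(model, ProteinConsequence(kind="missense",
                                                  first_changed_residue=2,
                                                  ref_aa="A", alt_aa="V"))


def test_gene_model_io_round_trip(tmp_path):
    rng = np.random.default_rng(3)
    model = build_model([50, 70, 40], 10, 45, 15, rng=rng, tid="TX9")
    write_gene_model(model, tmp_path / "m.gff", tmp_path / "m.fa")
    back = read_gene_model(tmp_path / "m.gff", tmp_path / "m.fa")
    assert back.transcript_id == "TX9"
    assert back.exons == model.exons
    assert back.strand == model.strand
    assert (back.cds_start, back.cds_end) == (model.cds_start, model.cds_end)
    assert back.transcript_seq == model.transcript_seq


def test_gene_model_validation():
    with pytest.raises(ValueError, match="divisible"):
        GeneModel("T", "19", "+", [(1, 10)], 1, 10, "ATGCTGTAAA")
    with pytest.raises(ValueError, match="stop"):
        GeneModel("T", "19", "+", [(1, 9)], 1, 9, "ATGCTGCTG")
    with pytest.raises(ValueError, match="internal stop"):
        GeneModel("T", "19", "+", [(1, 12)], 1, 12, "ATGTAACTGTAA")
    with pytest.raises(ValueError, match="overlap"):
        GeneModel("T", "19", "+", [(1, 6), (5, 7)], 1, 6, "ATGTAAXXX")
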