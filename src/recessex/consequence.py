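"""Protein-level consequence annotation and premature-termination-codon rules.

Annotates SNVs and frame-shifting indels on toy transcript models and
classifies the resulting premature termination codon (PTC) under
nonsense-mediated decay (NMD) rules:

* canonical 50-nt rule — a PTC more than 50 nt upstream of the last
  exon–exon junction (in spliced coordinates) triggers decay;
* last-exon escape — a PTC in the terminal exon escapes;
* start-proximal tendency — a PTC within the first 100 coding nt tends to
  escape.

Frameshift nomenclature follows HGVS ``p.<Ref><pos><Alt>fsTer<k>``: the
first residue whose translation differs is position 1 of the shifted
peptide, and ``k`` counts codons from there to the first stop in the new
frame, inclusive (so Ter52 means 51 novel residues then a stop).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .genotype_io import VariantRecord

__all__ = [
    "GeneModel",
    "ProteinConsequence",
    "NmdCall",
    "NotInCdsError",
    "UnsupportedVariantError",
    "map_genomic_to_cds",
    "apply_variant_and_annotate",
    "predict_nmd",
    "read_gene_model",
    "write_gene_model",
]


class NotInCdsError(ValueError):
    """Position or variant does not fall in the model's coding sequence."""

    def __init__(self, message: str, region: str):
        super().__init__(message)
        self.region = region


class UnsupportedVariantError(ValueError):
    """Variant shape the annotator does not handle."""


@dataclass
class GeneModel:
    """A transcript model: genomic exons plus the spliced sequence.

    ``exons`` are genomic 1-based inclusive intervals sorted by start
    coordinate; for minus-strand models transcript order is the genomic
    reverse.  ``transcript_seq`` is the spliced mRNA in transcript (sense)
    orientation; the CDS occupies ``[cds_start, cds_end]`` of it (1-based,
    inclusive, stop codon included).
    """

    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int
    transcript_seq: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        for (a, b) in self.exons:
            if a > b:
                raise ValueError(f"exon ({a}, {b}) has start > end")
        for (_, b1), (a2, _) in zip(self.exons, self.exons[1:]):
            if a2 <= b1:
                raise ValueError("exons overlap or touch")
        total = sum(b - a + 1 for a, b in self.exons)
        if total != len(self.transcript_seq):
            raise ValueError(
                f"exon lengths sum to {total} but transcript has "
                f"{len(self.transcript_seq)} nt"
            )
        cds_len = self.cds_end - self.cds_start + 1
        if cds_len % 3:
            raise ValueError(f"CDS length {cds_len} not divisible by 3")
        protein = str(Seq(self.cds).translate())
        if not protein.endswith("*"):
            raise ValueError("reference CDS does not end in a stop codon")
        if "*" in protein[:-1]:
            raise ValueError("reference CDS contains an internal stop codon")

    @property
    def cds(self) -> str:
        return self.transcript_seq[self.cds_start - 1 : self.cds_end]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def exons_tx_order(self) -> list[tuple[int, int]]:
        """Exons in transcript (5'→3') order."""
        return self.exons if self.strand == "+" else self.exons[::-1]

    def genomic_to_transcript(self, pos: int) -> int | None:
        """1-based spliced-transcript coordinate of a genomic base, or None."""
        offset = 0
        for (a, b) in self.exons_tx_order:
            if a <= pos <= b:
                if self.strand == "+":
                    return offset + (pos - a + 1)
                return offset + (b - pos + 1)
            offset += b - a + 1
        return None

    def protein(self) -> str:
        """Reference protein without the trailing stop."""
        return str(Seq(self.cds).translate())[:-1]


@dataclass
class ProteinConsequence:
    """Outcome of applying one variant to a gene model."""

    kind: str  # synonymous | missense | nonsense | frameshift | no_change
    first_changed_residue: int | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None
    ter_offset: int | None = None  # frameshift only; None = no stop found
    hgvs_p: str = "p.(=)"
    mutant_protein: str | None = None

    @property
    def introduces_stop(self) -> bool:
        if self.kind == "nonsense":
            return True
        return self.kind == "frameshift" and self.ter_offset is not None

    def ptc_residue(self) -> int:
        """1-based residue index of the introduced stop in the mutant protein."""
        if self.kind == "nonsense":
            return self.first_changed_residue
        if self.kind == "frameshift" and self.ter_offset is not None:
            return self.first_changed_residue + self.ter_offset - 1
        raise ValueError("consequence does not introduce a termination codon")


@dataclass
class NmdCall:
    """NMD prediction for a premature termination codon."""

    ptc_tx_pos: int  # first nt of the stop codon, spliced coords
    distance_to_last_junction: int | None  # None for single-exon models
    canonical_rule: str  # triggering | escaping | not_applicable
    last_exon: bool
    start_proximal: bool


def map_genomic_to_cds(model: GeneModel, pos: int) -> int:
    """Map a genomic position to a 1-based coding-sequence coordinate.

    Strand-aware: on minus-strand models the count runs from the 3' genomic
    end.  Positions outside the CDS raise :class:`NotInCdsError` with the
    region classified as ``intron``, ``5_prime_utr``, ``3_prime_utr`` or
    ``intergenic``.
    """
    tx = model.genomic_to_transcript(pos)
    if tx is None:
        lo = model.exons[0][0]
        hi = model.exons[-1][1]
        region = "intron" if lo <= pos <= hi else "intergenic"
        raise NotInCdsError(f"position {pos} is {region}", region)
    if tx < model.cds_start:
        raise NotInCdsError(f"position {pos} is in the 5' UTR", "5_prime_utr")
    if tx > model.cds_end:
        raise NotInCdsError(f"position {pos} is in the 3' UTR", "3_prime_utr")
    return tx - model.cds_start + 1


_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def _edit_transcript(model: GeneModel, variant: VariantRecord) -> str:
    """Apply a VCF-anchored allele to the spliced transcript sequence."""
    ref, alt = variant.ref.upper(), variant.alt.upper()
    span = range(variant.pos, variant.pos + len(ref))
    # require the whole ref allele inside one exon
    exon = next(
        ((a, b) for a, b in model.exons if a <= span[0] and span[-1] <= b), None
    )
    if exon is None:
        tx0 = model.genomic_to_transcript(variant.pos)
        if tx0 is None:
            raise NotInCdsError(
                f"variant at {variant.pos} does not overlap an exon", "intron"
            )
        raise UnsupportedVariantError(
            "variant allele crosses an exon boundary"
        )
    if model.strand == "+":
        tx_start = model.genomic_to_transcript(span[0])
        tx_ref, tx_alt = ref, alt
    else:
        tx_start = model.genomic_to_transcript(span[-1])
        tx_ref, tx_alt = _revcomp(ref), _revcomp(alt)
    seq = model.transcript_seq.upper()
    observed = seq[tx_start - 1 : tx_start - 1 + len(tx_ref)]
    if observed != tx_ref:
        raise ValueError(
            f"reference allele mismatch at {variant.chrom}:{variant.pos}: "
            f"model has {observed!r}, variant says {tx_ref!r}"
        )
    return seq[: tx_start - 1] + tx_alt + seq[tx_start - 1 + len(tx_ref):]


def apply_variant_and_annotate(
    model: GeneModel, variant: VariantRecord
) -> ProteinConsequence:
    """Annotate the protein-level consequence of a variant on a gene model.

    Builds the mutant spliced transcript, translates reference and mutant
    coding sequences, and reports the first residue at which they differ.
    Frame-shifting alleles are translated through the transcript 3' end so
    the new frame can run into the UTR; the stop offset ``ter_offset`` is
    the codon count from the first changed residue to the first stop in the
    shifted frame (inclusive), or None when no stop occurs before the
    transcript end (reported as ``fsTer?``).
    """
    ref, alt = variant.ref.upper(), variant.alt.upper()
    if ref == alt:
        return ProteinConsequence(kind="no_change", hgvs_p="p.(=)")
    # the allele must touch the CDS
    cds_hit = False
    for gpos in range(variant.pos, variant.pos + len(ref)):
        try:
            map_genomic_to_cds(model, gpos)
            cds_hit = True
            break
        except NotInCdsError:
            continue
    if not cds_hit:
        raise NotInCdsError(
            f"variant {variant.label} does not overlap the coding sequence",
            "non_coding",
        )
    frame_shift = (len(alt) - len(ref)) % 3 != 0
    if len(ref) != len(alt) and not frame_shift:
        raise UnsupportedVariantError(
            "in-frame insertion/deletion annotation is not supported"
        )

    mutant_tx = _edit_transcript(model, variant)
    ref_protein = model.protein()
    # translate from the CDS start through the transcript end; a shifted
    # frame legitimately reads past the old stop into the 3' UTR
    tail = mutant_tx[model.cds_start - 1 :]
    tail = tail[: len(tail) - len(tail) % 3]
    mutant_full = str(Seq(tail).translate())

    stop_at = mutant_full.find("*")
    mutant_protein = mutant_full if stop_at < 0 else mutant_full[:stop_at]

    # first differing residue against the reference protein
    limit = min(len(ref_protein), len(mutant_full))
    first = None
    for i in range(limit):
        if ref_protein[i] != mutant_full[i]:
            first = i
            break
    if first is None:
        if not frame_shift and mutant_protein == ref_protein:
            return ProteinConsequence(kind="synonymous", hgvs_p="p.(=)",
                                      mutant_protein=mutant_protein)
        # translations agree over the overlap but lengths differ (e.g. a
        # frameshift in the final codons): call the change at the first
        # position past the shared prefix
        first = limit
    res = first + 1
    ref_aa = ref_protein[first] if first < len(ref_protein) else "*"
    alt_aa = mutant_full[first] if first < len(mutant_full) else "*"

    if frame_shift:
        downstream = mutant_full[first:]
        k = downstream.find("*")
        ter = k + 1 if k >= 0 else None
        ter_txt = str(ter) if ter is not None else "?"
        if alt_aa == "*":
            hgvs = f"p.{seq3(ref_aa)}{res}Ter"
        else:
            hgvs = f"p.{seq3(ref_aa)}{res}{seq3(alt_aa)}fsTer{ter_txt}"
        return ProteinConsequence(
            kind="frameshift", first_changed_residue=res, ref_aa=ref_aa,
            alt_aa=alt_aa, ter_offset=ter, hgvs_p=hgvs,
            mutant_protein=mutant_protein,
        )
    if alt_aa == "*":
        return ProteinConsequence(
            kind="nonsense", first_changed_residue=res, ref_aa=ref_aa,
            alt_aa="*", hgvs_p=f"p.{seq3(ref_aa)}{res}Ter",
            mutant_protein=mutant_protein,
        )
    return ProteinConsequence(
        kind="missense", first_changed_residue=res, ref_aa=ref_aa,
        alt_aa=alt_aa, hgvs_p=f"p.{seq3(ref_aa)}{res}{seq3(alt_aa)}",
        mutant_protein=mutant_protein,
    )


def predict_nmd(model: GeneModel, consequence: ProteinConsequence) -> NmdCall:
    """Classify a premature termination codon under NMD rules.

    The canonical rule triggers decay when the last nucleotide of the stop
    codon lies more than 50 nt upstream of the last exon–exon junction in
    spliced coordinates.  A PTC whose codon starts in the terminal exon
    escapes (``last_exon``); a PTC within the first 100 coding nt is
    flagged ``start_proximal`` (escape tendency).  Single-exon models have
    no junction: the canonical rule is reported ``not_applicable``.
    """
    if not consequence.introduces_stop:
        raise ValueError("consequence does not introduce a stop codon")
    ptc_res = consequence.ptc_residue()
    # first nt of the stop codon in spliced transcript coordinates
    ptc_tx = model.cds_start + 3 * (ptc_res - 1)
    cds_offset = ptc_tx - model.cds_start + 1
    start_proximal = cds_offset <= 100

    exon_lens = [b - a + 1 for a, b in model.exons_tx_order]
    if len(exon_lens) < 2:
        return NmdCall(
            ptc_tx_pos=ptc_tx, distance_to_last_junction=None,
            canonical_rule="not_applicable", last_exon=True,
            start_proximal=start_proximal,
        )
    last_junction = sum(exon_lens[:-1])  # junction sits after this nt
    ptc_end = ptc_tx + 2
    distance = last_junction - ptc_end
    last_exon = ptc_tx > last_junction
    triggering = (not last_exon) and distance > 50
    return NmdCall(
        ptc_tx_pos=ptc_tx,
        distance_to_last_junction=distance,
        canonical_rule="triggering" if triggering else "escaping",
        last_exon=last_exon,
        start_proximal=start_proximal,
    )


# ---------------------------------------------------------------------------
# On-disk gene models: GFF3-like exon table + FASTA transcript sequence
# ---------------------------------------------------------------------------

_GFF_COLS = ["seqid", "source", "type", "start", "end", "score", "strand",
             "phase", "attributes"]


def _parse_attrs(s: str) -> dict[str, str]:
    out = {}
    for part in s.strip().split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def write_gene_model(model: GeneModel, gff_path: str | Path,
                     fasta_path: str | Path) -> None:
    rows = []
    attrs = f"Parent={model.transcript_id}"
    for a, b in model.exons:
        rows.append([model.chrom, "recessex", "exon", a, b, ".",
                     model.strand, ".", attrs])
    rows.append([model.chrom, "recessex", "CDS", model.cds_start,
                 model.cds_end, ".", model.strand, ".",
                 f"Parent={model.transcript_id};coords=transcript"])
    pd.DataFrame(rows, columns=_GFF_COLS).to_csv(
        gff_path, sep="\t", index=False, header=False
    )
    with open(fasta_path, "w") as fh:
        fh.write(f">{model.transcript_id}\n")
        seq = model.transcript_seq
        for i in range(0, len(seq), 60):
            fh.write(seq[i : i + 60] + "\n")


def read_gene_model(gff_path: str | Path, fasta_path: str | Path,
                    transcript_id: str | None = None) -> GeneModel:
    """Load a gene model from an exon table (GFF3-like) plus FASTA.

    The CDS row carries transcript-space coordinates (``coords=transcript``
    attribute), matching :func:`write_gene_model`.
    """
    from Bio import SeqIO

    df = pd.read_csv(gff_path, sep="\t", names=_GFF_COLS, comment="#")
    records = {r.id: str(r.seq) for r in SeqIO.parse(str(fasta_path), "fasta")}
    if transcript_id is None:
        if len(records) != 1:
            raise ValueError("transcript_id required for multi-record FASTA")
        transcript_id = next(iter(records))
    if transcript_id not in records:
        raise KeyError(f"transcript {transcript_id!r} not in {fasta_path}")
    mask = df["attributes"].map(lambda s: _parse_attrs(s).get("Parent")
                                == transcript_id)
    sub = df[mask]
    exons = [(int(r.start), int(r.end))
             for r in sub[sub["type"] == "exon"].itertuples()]
    cds = sub[sub["type"] == "CDS"]
    if len(cds) != 1:
        raise ValueError(f"expected one CDS row for {transcript_id}")
    row = cds.iloc[0]
    return GeneModel(
        transcript_id=transcript_id,
        chrom=str(row["seqid"]),
        strand=str(row["strand"]),
        exons=exons,
        cds_start=int(row["start"]),
        cds_end=int(row["end"]),
        transcript_seq=records[transcript_id],
    )
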