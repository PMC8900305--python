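#!/usr/bin/env python
"""Annotate the frameshift and its predicted nonsense-mediated decay.

Builds the toy multi-exon transcript model around the causal 1-bp
deletion, annotates the protein consequence (HGVS fsTer nomenclature),
and applies the decay rules: the canonical 50-nt boundary relative to the
last exon-exon junction plus the last-exon and start-proximal escape
flags.
"""

from common import CONFIG, outdir

from recessex.consequence import (
    apply_variant_and_annotate,
    predict_nmd,
    write_gene_model,
)
from recessex.simdata import simulate_gene_model


def main() -> None:
    out = outdir()
    model, variant = simulate_gene_model(CONFIG)
    write_gene_model(model, out / "gene_model.gff", out / "gene_model.fa")

    cons = apply_variant_and_annotate(model, variant)
    print(f"variant {variant.label} on transcript {model.transcript_id} "
          f"({model.n_exons} exons, {len(model.protein())} aa)")
    print(f"consequence: {cons.kind}, {cons.hgvs_p}")

    call = predict_nmd(model, cons)
    print(f"premature termination codon at spliced nt {call.ptc_tx_pos}, "
          f"{call.distance_to_last_junction} nt upstream of the last "
          "exon-exon junction")
    print(f"canonical 50-nt rule: {call.canonical_rule}; "
          f"last exon: {call.last_exon}; "
          f"start-proximal: {call.start_proximal}")
    with open(out / "consequence.tsv", "w") as fh:
        fh.write("field\tvalue\n")
        fh.write(f"hgvs_p\t{cons.hgvs_p}\n")
        fh.write(f"kind\t{cons.kind}\n")
        fh.write(f"canonical_rule\t{call.canonical_rule}\n")
        fh.write(f"distance_to_last_junction\t"
                 f"{call.distance_to_last_junction}\n")


if __name__ == "__main__":
    main()
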