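#!/usr/bin/env python
"""Gene-drop a cattle cohort carrying a recessive 1-bp deletion.

Simulates the default study conditions — ~400 animals after three
generations of random mating, a causal deletion segregating
identical-by-descent at ~5% from one ancestral haplotype, 12× sequence
genotypes with heterozygote undercalling — and writes the phased marker
matrix, the genotype VCF and the ejaculate table that the later scripts
consume.
"""

from common import CONFIG, scratchdir

from recessex.genotype_io import write_phased_matrix, write_vcf
from recessex.semen_qc import write_ejaculate_table
from recessex.simdata import (
    simulate_ejaculates,
    simulate_population,
    simulate_sequence_genotypes,
)


def main() -> None:
    out = scratchdir()
    phased, truth = simulate_population(CONFIG)
    genotypes = simulate_sequence_genotypes(truth, CONFIG.mean_coverage)
    ejaculates = simulate_ejaculates(truth, CONFIG)

    write_phased_matrix(phased, out / "phased_markers.tsv")
    write_vcf(genotypes, out / "genotypes.vcf")
    write_ejaculate_table(ejaculates, out / "ejaculates.tsv")

    print(f"cohort: {len(truth.samples)} animals, "
          f"{len(truth.het_samples)} heterozygous and "
          f"{len(truth.hom_samples)} homozygous carrier(s)")
    print(f"realized carrier-allele frequency: "
          f"{100 * truth.carrier_frequency():.1f}%")
    print(f"causal deletion at {truth.chrom}:{truth.focal_pos} "
          f"({truth.focal_ref}>{truth.focal_alt})")
    print(f"inputs written to {out}")


if __name__ == "__main__":
    main()
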