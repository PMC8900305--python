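#!/usr/bin/env python
"""Filter the case genome for recessive-compatible variants and scan
autozygosity.

Keeps variants homozygous-alt in the affected bull and never
homozygous-alt in the fertile controls, then tiles the case genome into
125-kb windows of heterozygosity to locate the run of homozygosity in
which a recessive allele inherited twice from a common ancestor must sit.
"""

import pandas as pd
from common import CONFIG, outdir

from recessex.recessive_filter import (
    find_compatible_variants,
    heterozygosity_windows,
    roh_segments,
)
from recessex.semen_qc import find_affected_bulls
from recessex.simdata import (
    simulate_ejaculates,
    simulate_population,
    simulate_sequence_genotypes,
)


def main() -> None:
    out = outdir()
    _, truth = simulate_population(CONFIG)
    genotypes = simulate_sequence_genotypes(truth, CONFIG.mean_coverage)
    affected = find_affected_bulls(simulate_ejaculates(truth, CONFIG))
    case = affected[0]
    controls = [s for s in genotypes.samples
                if s != case and s not in affected]
    print(f"case {case} vs {len(controls)} fertile controls")

    compatible = find_compatible_variants(genotypes, case, controls)
    pd.DataFrame([(v.chrom, v.pos, v.ref, v.alt) for v in compatible],
                 columns=["chrom", "pos", "ref", "alt"]
                 ).to_csv(out / "compatible_variants.tsv", sep="\t",
                          index=False)
    print(f"recessive-compatible variants: {len(compatible)}")
    hit = any(v.pos == truth.focal_pos for v in compatible)
    print(f"implanted causal deletion among them: {hit}")

    windows = heterozygosity_windows(genotypes, case)
    segments = roh_segments(windows)
    pd.DataFrame(segments, columns=["chrom", "start_bp", "end_bp"]
                 ).to_csv(out / "roh_segments.tsv", sep="\t", index=False)
    for chrom, a, b in segments:
        covers = a <= truth.focal_pos <= b
        print(f"homozygosity segment {chrom}:{a:,}-{b:,} "
              f"({(b - a + 1) / 1e6:.2f} Mb){' <- contains the deletion' if covers else ''}")


if __name__ == "__main__":
    main()
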