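#!/usr/bin/env python
"""Flag the bull whose every ejaculate fails station quality control.

Applies the rejection rules (< 300 million sperm/mL, < 70% motile,
> 10% abnormal, < 1 mL) to the simulated ejaculate records, reports the
affected bull(s), and summarizes their semen parameters next to the
published records of the real homozygous bull.
"""

import pandas as pd
from common import CONFIG, outdir

from recessex.semen_qc import (
    AFFECTED_BULL_EJACULATES,
    MONTHS_TO_DAYS,
    find_affected_bulls,
    summarize_semen,
)
from recessex.simdata import simulate_ejaculates, simulate_population


def main() -> None:
    out = outdir()
    _, truth = simulate_population(CONFIG)
    records = simulate_ejaculates(truth, CONFIG)

    affected = find_affected_bulls(records)
    print(f"screened {len(records)} ejaculates from {len(truth.samples)} "
          f"bulls in the 330-550 day window")
    print(f"bulls with all ejaculates rejected: {affected}")
    assert affected == sorted(truth.hom_samples), \
        "QC screen should flag exactly the homozygous carriers"

    sim_summary = summarize_semen([r for r in records
                                   if r.bull in set(affected)])
    published = summarize_semen(
        [r for r in AFFECTED_BULL_EJACULATES
         if r.age_days > 15 * MONTHS_TO_DAYS])
    table = pd.concat({"simulated_affected": sim_summary,
                       "published_hom_bull": published}, axis=0)
    table.round(2).to_csv(out / "semen_screening.tsv", sep="\t")
    print(table.round(2))
    print("mean concentration of the published homozygous bull: "
          f"{published.loc['concentration', 'mean'] / 1000:.1f} x 10^9/mL "
          "(normal range is ~1.3)")


if __name__ == "__main__":
    main()
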