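# Methods

`recessex` implements the mapping workflow for a recessive loss-of-function
allele that abolishes semen quality in homozygous bulls: phenotype-driven
case detection, recessive case/control variant filtering, autozygosity
scanning, frameshift/PTC annotation with nonsense-mediated decay (NMD)
rules, carrier-haplotype recovery and population screening, and
transcript-level decay evidence. A gene-drop simulator generates cohorts
with the statistical structure this workflow assumes, so every stage is
testable end to end without external data. This note records the models,
the parameters that matter, and the design decisions that were genuinely
open.

## The gene-drop simulator

**Population model.** Founder haplotypes are drawn marker-wise from
per-marker allele frequencies (uniform on 0.1–0.9 by default) over a
single scaled-down chromosome of 5 Mb carrying 200 evenly spaced biallelic
markers (~25 kb spacing, array-like density). The causal allele — a 1-bp
deletion anchored VCF-style as `TC>T` at a position strictly between two
markers — is seeded by replicating one ancestral carrier haplotype into
`round(2·n_founders·causal_freq)` founder slots, so every causal copy in
any later generation is identical by descent, which is the property the
haplotype screen exploits. Each of the (default 3) discrete generations
keeps the population size (default 400) constant; offspring arise from
random unions of distinct parents, and each transmitted chromosome
recombines under the Haldane model: crossover count Poisson with mean
`recomb_rate`, breakpoints uniform along the chromosome, no interference.
The default `recomb_rate` of 0.05 crossovers per meiosis corresponds to
~1 cM/Mb on the 5-Mb chromosome, the usual mammalian scale. When the
final generation contains no homozygote and `ensure_homozygote` is set,
one extra animal is produced from a carrier × carrier mating — a
consanguineous loop, which is how such cases arise in real pedigrees.

**Sequence genotypes.** Per sample and site, read depth is
Poisson(`mean_coverage`, default 12 — the coverage regime of the cohorts
this emulates); a true heterozygote draws alternate reads
Binomial(depth, ½) and is *called* heterozygous only when both alleles
are seen, homozygous for the sole observed allele otherwise; zero depth
is missing, never hom-ref. At 12× a heterozygote is emitted homozygous
with probability 2(e⁻⁶ − e⁻¹²) ≈ 0.5% (half of these hom-alt). This
matters downstream: with ~38 heterozygous carriers among the controls,
roughly 9% of simulated cohorts contain at least one carrier miscalled
hom-alt at the causal site, and in those cohorts the compatibility filter
— by construction — discards the causal variant. The same undercalling
produces the haplotype/sequence discordances the concordance check is
designed to surface (carriers called hom-ref from few reads), so both the
success and the failure mode of the filter are faithful consequences of
the coverage model rather than artifacts.

**RNA evidence.** The expression stage operates on a sub-cohort of the
design size of testis expression panels: 6 heterozygotes and 70 wild-type
animals. Each heterozygote's read depth over the deletion is
Poisson(292) — the pooled mean is the only depth information available,
so a common Poisson mean is the modelling choice; real inter-bull depth
spread is certainly larger — with alternate reads
Binomial(depth, `nmd_alt_fraction` = 0.28), the decay-depleted fraction.
Gene-level abundance is Normal(32.13, 7.01) TPM in wild-type and
Normal(23.29, 6.76) in heterozygous animals, truncated at zero
(truncation bias is negligible four standard deviations from zero);
homozygotes reuse the heterozygote block since no expression data for
homozygotes informed these parameters. Exon tables carry 30 exons with
uniform baselines on 1–8 TPM; 18 of them scale their heterozygote mean by
the het/wt gene ratio (0.72). The per-exon noise is 0.15 of the baseline,
chosen so that exon-level depletion is detectable at nominal Wilcoxon
p < 0.05 with 6 vs 70 animals — consistent with 18 exons reaching
significance at that design size.

**Semen phenotypes.** Each bull contributes 7 ejaculates at ages uniform
in the 330–550-day screening window. Homozygous-affected bulls draw from
volume 4.0 ± 0.9 mL, concentration 0.2 ± 0.2 ×10⁹/mL, motility
0.5 ± 0.5%, abnormality 99 ± 1%; all others from 4.7 ± 2.0 mL,
1.3 ± 0.5 ×10⁹/mL, 83 ± 11%, 5 ± 3%. Negative draws are truncated at
zero and percentages clipped to [0, 100]; moments are therefore
reproduced approximately, which is all the QC stage needs (an affected
bull's records fail the motility and abnormality rules with probability
indistinguishable from 1).

## Stage-by-stage notes

**Quality control (`semen_qc`).** An ejaculate fails when concentration
< 300 million/mL, motility < 70%, abnormality > 10% (or anomaly score
≥ 2 — score 2 is defined as 10–30% anomalies, so ≥ 2 is the only mapping
consistent with "more than 10%"), or volume < 1 mL. The wording of the
rules uses strict inequalities on the failure side, so boundary values
pass; this convention is asserted in tests. Values recorded as bounds
("<1") are imputed at half the bound and flagged. Ages given in months
convert at 30.44 days/month. Affected bulls are those with at least 5
in-window ejaculates, all failing.

**Recessive filter (`recessive_filter`).** A variant is compatible with
recessive inheritance when the case is homozygous-alt and no control is;
a missing case genotype excludes the site (homozygosity cannot be
asserted — the conservative choice), while missing control genotypes do
not disqualify. Candidates are then restricted to high-impact
consequences (stop-gained / frameshift / splice-disrupting; the
high/moderate dichotomy of standard effect predictors without their full
ontology) and ordered by testis abundance, with a pass/fail flag at
`min_tpm` (default 1 TPM) rather than silent dropping. Heterozygosity is
profiled in non-overlapping 125-kb windows tiled from coordinate 1 (fixed
boundaries keep windows reproducible across cohorts); runs of homozygosity
merge consecutive non-empty windows with het fraction ≤ 0.02 and keep
runs ≥ 1 Mb. Windowed autozygosity scans have no canonical thresholds;
both values are exposed as parameters. An empty window (no genotyped
variants) terminates a run rather than bridging it.

**Consequence annotation (`consequence`).** Gene models are toy
transcripts: ordered genomic exons, strand, spliced sequence, CDS bounds.
Variants (SNVs and frame-shifting indels, VCF-anchored, confined to one
exon) are applied in transcript space; the mutant frame is translated
from the CDS start through the transcript end, since a shifted frame
legitimately reads past the old stop into the 3′ UTR. The reported
residue is the first whose translation differs — no 3′-normalization
beyond that rule — and `fsTer k` counts the changed residue as 1 and the
stop as k; when no stop occurs before the transcript end the extension is
unknown (`fsTer?`). In-frame indels are rejected as unsupported rather
than mislabeled. Decay rules: canonical triggering when the PTC ends more
than 50 nt upstream of the last exon–exon junction in spliced
coordinates; a PTC starting in the terminal exon escapes; a PTC within
the first 100 coding nt is flagged start-proximal (escape tendency). The
50-nt and 100-nt constants are the conventional values; single-exon
models report the junction rule as not applicable. Only the standard
nuclear code is supported.

**Haplotype screen (`haplotype_screen`).** The diagnostic haplotype is
grown outward from the two markers flanking the focal position, each
direction independently: every carrier starts with both phased haplotypes
alive; the allele kept at a marker must leave every carrier at least one
alive haplotype carrying it; when both alleles qualify the one retaining
more alive haplotypes wins, ties to allele 0 (a deterministic consensus
rule). Known limitations, deliberately accepted: with a single
heterozygous carrier both haplotypes stay alive everywhere and the
extension reaches the chromosome ends (degenerate by construction); an
exactly balanced tie can commit to a branch that dies earlier than the
alternative; and because directions are independent, a carrier may
support the left extension with one haplotype and the right with the
other. On cohorts with genuine identity by descent the consensus rule
tracks the shared background and the recovered interval contains the
causal position in ≈98–100% of replicates; the residual misses come from
carriers recombining inside the focal marker interval. Screening demands
an exact allele match over the interval (the phased input is imputed and
complete, so no mismatch tolerance is warranted). Carrier statistics
report q = (n_het + 2·n_hom)/2N, expected homozygotes N·q² (raw and
rounded), and Hardy–Weinberg tests: the 1-df chi-square without
continuity correction as the headline number, with the conditional exact
test alongside — the two can disagree noticeably for rare alleles, which
is why both are always reported. Frequencies print at one decimal in
percent; full precision is kept internally.

**Expression tests (`expression_tests`).** The allelic-imbalance test is
the exact two-sided binomial test (the sum of outcome probabilities no
more likely than the observed one, with the 1e-7 relative tolerance of
the conventional implementation), evaluated stably for totals in the
thousands where p-values reach 10⁻⁸⁰; on the pooled published counts
(1266 reference, 487 alternate) it reproduces 9.45 × 10⁻⁸⁰. Beyond
n ≈ 3000 at this imbalance the p-value leaves the range of double
precision and underflows to zero — the reason the pooled test is run on
the 6-bull design rather than all simulated carriers. Group contrasts use
the Wilcoxon rank-sum test, exact for tie-free groups of ≤ 20,
normal-approximated with continuity and tie correction otherwise.
Exon-level tests report nominal p-values (as abundance panels typically
do); Benjamini–Hochberg adjustment is available as an option.

**Pipeline (`pipeline`/`cli`).** Stages run in the discovery order with
one seed propagated to every stochastic stage through per-stage seed
sequences, so a rerun is byte-identical (the log carries timers and is
the only file excluded from that guarantee). Controls for the filter are
the bulls not flagged by semen QC — fertile by phenotype — which places
heterozygous carriers among the controls, as in the real design. Failures
abort with the stage named; stages whose inputs are absent are skipped
with a notice.

## What the simulations do and do not show

Passing end-to-end tests show that the workflow recovers an implanted
recessive allele under realistic coverage, carrier frequency and design
sizes, and that each statistic matches an independent oracle on its
domain. They do not show robustness to features the generator omits:
linkage disequilibrium among founder haplotypes, genotyping error beyond
binomial read sampling, imputation error in the phased matrix,
population structure across breeds, or inter-bull RNA depth variation.
The compatibility filter's sensitivity to a single miscalled control is
real and quantified above, not simulated away; production use would
re-inspect reads at candidate sites in all carriers, exactly as the
concordance check does for the haplotype.
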