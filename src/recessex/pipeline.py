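"""End-to-end orchestration: simulate → QC → filter → annotate → screen → test.

The pipeline mirrors the discovery narrative for a recessive semen-quality
defect: find the bull whose every ejaculate fails station QC, filter its
sequence genotypes against fertile controls for recessive-compatible
variants, locate the autozygosity segment around the causal site, annotate
the frameshift and its predicted nonsense-mediated decay, recover the
carrier-shared marker haplotype, screen the population for carriers with
Hardy–Weinberg statistics, and quantify allelic-imbalance and abundance
evidence of decay.

Every stage persists its table under the run's output directory, and a
rerun with the same configuration and seed reproduces byte-identical
outputs.
"""

from __future__ import annotations

import configparser
import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import consequence as cq
from . import expression_tests as et
from . import genotype_io as gio
from . import haplotype_screen as hs
from . import recessive_filter as rf
from . import semen_qc as sq
from . import simdata as sd

__all__ = ["RunConfig", "RunResult", "PipelineError", "run_pipeline",
           "generate_report"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for attribution."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """One reproducible run: an embedded simulation or explicit input paths."""

    outdir: Path
    seed: int = 0
    sim: sd.SimConfig | None = None
    # file-input mode (any subset; stages without inputs are skipped)
    vcf_path: Path | None = None
    phased_path: Path | None = None
    counts_path: Path | None = None
    tpm_path: Path | None = None
    ejaculates_path: Path | None = None
    case: str | None = None
    controls: list[str] = field(default_factory=list)
    carriers: list[str] = field(default_factory=list)
    focal: hs.FocalVariant | None = None
    # thresholds
    min_tpm: float = 1.0
    qc: sq.QCThresholds = field(default_factory=sq.QCThresholds)
    roh_max_het: float = 0.02
    roh_min_len_bp: int = 1_000_000
    het_window_bp: int = 125_000
    alpha: float = 0.05
    verbosity: int = 1

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.sim is not None and self.vcf_path is not None:
            raise ValueError(
                "configure either an embedded simulation or input paths, "
                "not both"
            )
        if self.sim is not None and self.sim.seed != self.seed:
            self.sim = dataclasses.replace(self.sim, seed=self.seed)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Parse a sectioned key = value config file.

        Sections: ``[run]`` (outdir, seed, thresholds, sample roles) and
        optional ``[sim]`` holding :class:`~recessex.simdata.SimConfig`
        scalar fields.
        """
        cp = configparser.ConfigParser()
        with open(path) as fh:
            cp.read_file(fh)
        run = cp["run"]
        kwargs: dict = {
            "outdir": Path(run.get("outdir", "recessex_run")),
            "seed": run.getint("seed", 0),
        }
        for key, conv in (
            ("min_tpm", run.getfloat), ("roh_max_het", run.getfloat),
            ("alpha", run.getfloat), ("roh_min_len_bp", run.getint),
            ("het_window_bp", run.getint), ("verbosity", run.getint),
        ):
            if key in run:
                kwargs[key] = conv(key)
        for key in ("vcf_path", "phased_path", "counts_path", "tpm_path",
                    "ejaculates_path"):
            if key in run:
                kwargs[key] = Path(run[key])
        if "case" in run:
            kwargs["case"] = run["case"]
        if "controls" in run:
            kwargs["controls"] = run["controls"].split()
        if "carriers" in run:
            kwargs["carriers"] = run["carriers"].split()
        if "focal" in run:
            chrom, pos, ref, alt = run["focal"].split(":")
            kwargs["focal"] = hs.FocalVariant(chrom, int(pos), ref, alt)
        if cp.has_section("sim"):
            sim_kwargs: dict = {}
            sim = cp["sim"]
            for f in dataclasses.fields(sd.SimConfig):
                if f.name not in sim:
                    continue
                if f.type in ("int", "int | None"):
                    sim_kwargs[f.name] = sim.getint(f.name)
                elif f.type == "float":
                    sim_kwargs[f.name] = sim.getfloat(f.name)
                elif f.type == "bool":
                    sim_kwargs[f.name] = sim.getboolean(f.name)
                elif f.type == "str":
                    sim_kwargs[f.name] = sim[f.name]
            kwargs["sim"] = sd.SimConfig(**sim_kwargs)
        return cls(**kwargs)


@dataclass
class RunResult:
    """Everything the stages produced, plus which stages were skipped."""

    config: RunConfig
    skipped: dict[str, str] = field(default_factory=dict)
    truth: sd.TruthTable | None = None
    phased: gio.PhasedHaplotypeMatrix | None = None
    genotypes: gio.GenotypeMatrix | None = None
    ejaculates: list[sq.EjaculateRecord] | None = None
    affected_bulls: list[str] | None = None
    case: str | None = None
    controls: list[str] | None = None
    semen_summary: pd.DataFrame | None = None
    compatible: list[gio.VariantRecord] | None = None
    ranked: list[tuple[rf.CandidateVariant, bool]] | None = None
    het_windows: list[rf.HetWindow] | None = None
    roh: list[tuple[str, int, int]] | None = None
    gene_model: cq.GeneModel | None = None
    protein_consequence: cq.ProteinConsequence | None = None
    nmd: cq.NmdCall | None = None
    focal: hs.FocalVariant | None = None
    shared_hap: hs.SharedHaplotype | None = None
    copies: dict[str, int] | None = None
    carrier_report: hs.CarrierReport | None = None
    discordances: list[hs.Discordance] | None = None
    allele_counts: list[et.AlleleCounts] | None = None
    abundance_table: pd.DataFrame | None = None
    expr_het: list[str] | None = None
    expr_wt: list[str] | None = None
    pooled: et.PooledSummary | None = None
    ai_p: float | None = None
    gene_tpm_p: float | None = None
    exon_de: pd.DataFrame | None = None


def _stage(name: str):
    def wrap(fn):
        def inner(result: RunResult, *args, **kwargs):
            t0 = time.perf_counter()
            try:
                fn(result, *args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - attribute the stage
                raise PipelineError(name, str(exc)) from exc
            logger.info("stage %-12s done in %.2fs", name,
                        time.perf_counter() - t0)
        return inner
    return wrap


@_stage("simulate")
def _simulate(result: RunResult) -> None:
    cfg = result.config
    if cfg.sim is None:
        result.skipped["simulate"] = "no embedded simulation configured"
        return
    phased, truth = sd.simulate_population(cfg.sim)
    result.phased, result.truth = phased, truth
    result.genotypes = sd.simulate_sequence_genotypes(
        truth, cfg.sim.mean_coverage
    )
    result.ejaculates = sd.simulate_ejaculates(truth, cfg.sim)
    result.focal = hs.FocalVariant(truth.chrom, truth.focal_pos,
                                   truth.focal_ref, truth.focal_alt)
    # RNA evidence is generated for an expression sub-cohort of the
    # study's design size (het carriers + wild-type animals)
    if truth.het_samples:
        cohort = truth.expression_cohort(cfg.sim.expression_n_het,
                                         cfg.sim.expression_n_wt)
        counts, table = sd.simulate_rna_data(cohort, cfg.sim)
        result.allele_counts = counts
        result.abundance_table = table
        result.expr_het = cohort.het_samples
        result.expr_wt = cohort.wt_samples
    d = cfg.outdir / "inputs"
    d.mkdir(parents=True, exist_ok=True)
    gio.write_phased_matrix(phased, d / "phased_markers.tsv")
    gio.write_vcf(result.genotypes, d / "genotypes.vcf")
    sq.write_ejaculate_table(result.ejaculates, d / "ejaculates.tsv")
    if result.allele_counts is not None:
        et.write_allele_counts(result.allele_counts, d / "allele_counts.tsv")
        et.write_abundance_table(result.abundance_table, d / "abundance.tsv")


@_stage("load")
def _load(result: RunResult) -> None:
    cfg = result.config
    if cfg.sim is not None:
        return
    if cfg.vcf_path:
        result.genotypes = gio.read_vcf(cfg.vcf_path)
    if cfg.phased_path:
        result.phased = gio.read_phased_matrix(cfg.phased_path)
    if cfg.ejaculates_path:
        result.ejaculates = sq.read_ejaculate_table(cfg.ejaculates_path)
    if cfg.counts_path:
        result.allele_counts = et.read_allele_counts(cfg.counts_path)
    result.focal = cfg.focal


@_stage("semen_qc")
def _semen_qc(result: RunResult) -> None:
    cfg = result.config
    if result.ejaculates is None:
        result.skipped["semen_qc"] = "no ejaculate records"
        return
    result.affected_bulls = sq.find_affected_bulls(
        result.ejaculates, cfg.sim.age_window_days if cfg.sim else (330, 550),
        thr=cfg.qc,
    )
    if result.affected_bulls:
        affected = set(result.affected_bulls)
        result.semen_summary = sq.summarize_semen(
            [r for r in result.ejaculates if r.bull in affected]
        )


@_stage("filter")
def _filter(result: RunResult) -> None:
    cfg = result.config
    if result.genotypes is None:
        result.skipped["filter"] = "no genotype matrix"
        return
    case = cfg.case
    if case is None and result.affected_bulls:
        case = result.affected_bulls[0]
    if case is None:
        result.skipped["filter"] = "no case sample identified"
        return
    controls = cfg.controls or [
        s for s in result.genotypes.samples
        if s != case and s not in (result.affected_bulls or [])
    ]
    result.case, result.controls = case, controls
    result.compatible = rf.find_compatible_variants(
        result.genotypes, case, controls
    )
    result.het_windows = rf.heterozygosity_windows(
        result.genotypes, case, cfg.het_window_bp
    )
    result.roh = rf.roh_segments(result.het_windows, cfg.roh_max_het,
                                 cfg.roh_min_len_bp)


@_stage("consequence")
def _consequence(result: RunResult) -> None:
    cfg = result.config
    if cfg.sim is None or result.focal is None:
        result.skipped["consequence"] = "no gene model available"
        return
    model, variant = sd.simulate_gene_model(cfg.sim)
    result.gene_model = model
    result.protein_consequence = cq.apply_variant_and_annotate(model, variant)
    if result.protein_consequence.introduces_stop:
        result.nmd = cq.predict_nmd(model, result.protein_consequence)


@_stage("rank")
def _rank(result: RunResult) -> None:
    cfg = result.config
    if result.compatible is None:
        result.skipped["rank"] = "no compatible variants"
        return
    focal_label = result.focal.label if result.focal else None
    consequences, genes, abundance = {}, {}, {}
    for v in result.compatible:
        if focal_label and v.label == focal_label:
            consequences[v.label] = (
                result.protein_consequence.kind
                if result.protein_consequence else "frameshift"
            )
            genes[v.label] = (
                result.gene_model.transcript_id if result.gene_model
                else "FOCAL_GENE"
            )
        else:
            consequences[v.label] = "intergenic"
            genes[v.label] = v.label
    if result.abundance_table is not None and genes:
        # mean testis TPM of the focal gene over the expression cohort
        gene_mean = float(result.abundance_table.loc["GENE"].mean())
        for g in set(genes.values()):
            if focal_label and genes.get(focal_label) == g:
                abundance[g] = gene_mean
    result.ranked = rf.rank_candidates(
        result.compatible, consequences, genes, abundance, cfg.min_tpm
    )


@_stage("haplotype")
def _haplotype(result: RunResult) -> None:
    cfg = result.config
    if result.phased is None or result.focal is None:
        result.skipped["haplotype"] = "no phased matrix or focal variant"
        return
    carriers = list(cfg.carriers)
    if not carriers and result.genotypes is not None:
        try:
            v = result.genotypes.find_variant(result.focal.chrom,
                                              result.focal.pos)
            carriers = [
                s for s, d in zip(result.genotypes.samples, v.dosages)
                if d == 1 and s in result.phased.samples
            ]
        except KeyError:
            carriers = []
    if not carriers:
        result.skipped["haplotype"] = "no carriers available"
        logger.info("haplotype stage skipped: no carriers available")
        return
    result.shared_hap = hs.extend_shared_haplotype(
        result.phased, result.focal, carriers
    )
    result.copies = hs.screen_population(result.phased, result.shared_hap)
    result.carrier_report = hs.carrier_statistics(result.copies)
    if result.genotypes is not None:
        result.discordances = hs.concordance_check(
            result.copies, result.genotypes, result.focal
        )


@_stage("expression")
def _expression(result: RunResult) -> None:
    cfg = result.config
    if result.abundance_table is not None and result.expr_het \
            and result.expr_wt:
        result.exon_de = et.exon_level_de(
            result.abundance_table.drop(index="GENE"), result.expr_het,
            result.expr_wt, cfg.alpha,
        )
        result.gene_tpm_p = et.wilcoxon_rank_sum(
            result.abundance_table.loc["GENE", result.expr_het],
            result.abundance_table.loc["GENE", result.expr_wt],
        )
    if not result.allele_counts:
        result.skipped["expression"] = "no allele counts"
        return
    result.pooled = et.pool_and_summarize(result.allele_counts)
    result.ai_p = et.binomial_ai_test(result.pooled.pooled_ref,
                                      result.pooled.pooled_alt)


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute all stages in order; see the module docstring.

    Stage failures abort the run with a :class:`PipelineError` naming the
    stage; stages whose inputs are absent are skipped with a notice in
    ``result.skipped``.
    """
    config.outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(config.outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    root = logging.getLogger("recessex")
    root.addHandler(handler)
    if config.verbosity:
        root.setLevel(logging.INFO)
    try:
        result = RunResult(config=config)
        _simulate(result)
        _load(result)
        _semen_qc(result)
        _filter(result)
        _consequence(result)
        _rank(result)
        _haplotype(result)
        _expression(result)
        generate_report(result)
        return result
    finally:
        root.removeHandler(handler)
        handler.close()


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def generate_report(result: RunResult) -> list[Path]:
    """Persist stage tables plus a human-readable summary; idempotent."""
    out = result.config.outdir
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, df: pd.DataFrame) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
        written.append(path)

    if result.ranked is not None:
        emit("candidates.tsv", pd.DataFrame([
            {"chrom": c.variant.chrom, "pos": c.variant.pos,
             "ref": c.variant.ref, "alt": c.variant.alt, "gene": c.gene,
             "consequence": c.consequence, "impact": c.impact,
             "tpm": c.tpm, "passes_tpm": ok}
            for c, ok in result.ranked
        ]))
    if result.roh is not None:
        emit("roh_segments.tsv", pd.DataFrame(
            result.roh, columns=["chrom", "start_bp", "end_bp"]
        ))
    if result.shared_hap is not None and result.phased is not None:
        hap = result.shared_hap
        mk = result.phased.markers.iloc[
            hap.start_index : hap.end_index + 1
        ].reset_index(drop=True)
        emit("haplotype.tsv", pd.DataFrame({
            "label": mk["label"], "chrom": mk["chrom"], "pos": mk["pos"],
            "allele": hap.alleles,
        }))
    if result.carrier_report is not None:
        r = result.carrier_report
        emit("carrier_report.tsv", pd.DataFrame([{
            "n_samples": r.n_samples, "n_het": r.n_het, "n_hom": r.n_hom,
            "frequency_pct": r.frequency_pct,
            "expected_hom": round(r.expected_hom, 2),
            "expected_hom_rounded": r.expected_hom_rounded,
            "hwe_chi2": round(r.hwe_chi2, 4), "hwe_p": r.hwe_p,
            "hwe_exact_p": r.hwe_exact_p,
        }]))
    if result.pooled is not None:
        p = result.pooled
        emit("ai_test.tsv", pd.DataFrame([{
            "n_samples": p.n_samples, "pooled_ref": p.pooled_ref,
            "pooled_alt": p.pooled_alt,
            "alt_fraction": round(p.pooled_alt_fraction, 4),
            "mean_total": round(p.mean_total, 1),
            "mean_alt": round(p.mean_alt, 1), "binomial_p": result.ai_p,
        }]))
    if result.semen_summary is not None:
        path = out / "semen_summary.tsv"
        result.semen_summary.round(6).to_csv(path, sep="\t")
        written.append(path)

    lines = ["# recessive-defect mapping run summary",
             f"seed: {result.config.seed}"]
    for stage, why in result.skipped.items():
        lines.append(f"skipped {stage}: {why}")
    if result.affected_bulls is not None:
        lines.append(f"bulls with all ejaculates rejected: "
                     f"{', '.join(result.affected_bulls) or 'none'}")
    if result.compatible is not None:
        lines.append(f"recessive-compatible variants: {len(result.compatible)}")
    if result.protein_consequence is not None:
        lines.append(f"focal consequence: {result.protein_consequence.hgvs_p}")
    if result.nmd is not None:
        lines.append(f"canonical decay rule: {result.nmd.canonical_rule}")
    if result.carrier_report is not None:
        r = result.carrier_report
        lines.append(
            f"carriers: {r.n_het} het + {r.n_hom} hom of {r.n_samples} "
            f"(frequency {r.frequency_pct}%, expected hom "
            f"{r.expected_hom_rounded}, HWE chi2 p {r.hwe_p:.3g})"
        )
    if result.ai_p is not None:
        lines.append(f"allelic imbalance binomial p: {result.ai_p:.3g}")
    path = out / "summary.txt"
    path.write_text("\n".join(lines) + "\n")
    written.append(path)
    return written
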