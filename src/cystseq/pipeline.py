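"""End-to-end orchestration: simulate -> call -> evaluate as one reproducible run.

A run is fully determined by its :class:`RunConfig` (serializable to YAML) and
seed.  The random stream is split hierarchically with ``numpy.SeedSequence``:
one child per control sample, one per cohort sample's reads and one for the
cohort covariate draws, so adding a sample or changing a covariate
distribution never perturbs another sample's reads.  The caller consumes only
reads, panel and controls — cyst-class labels never reach it, mirroring the
blinded design of the assay.
"""

from __future__ import annotations

import dataclasses
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .caller import (
    CallerConfig, ControlModel, VariantCall, build_control_model,
    call_mutations, call_sample,
)
from .diagnostics import diagnostic_summary, marker_report, wilcoxon_rank_sum
from .panel import Panel, load_panel, make_toy_panel, write_panel
from .simulate import (
    CohortConfig, SimulationConfig, simulate_cohort, simulate_sample, write_fastq,
)

logger = logging.getLogger(__name__)

DEFAULT_GENES = ("TP53", "KRAS", "BRAF", "NRAS", "PIK3CA", "PIK3R1", "PPP2R1A", "PTEN")


@dataclass
class RunConfig:
    """Everything needed to reproduce a run byte-for-byte."""

    seed: int = 0
    panel_tsv: str | None = None      # load a panel from disk ...
    panel_fasta: str | None = None
    n_amplicons: int = 8              # ... or generate a toy panel
    genes: tuple[str, ...] = DEFAULT_GENES
    n_controls: int = 8
    sim: SimulationConfig = field(default_factory=lambda: SimulationConfig(
        n_templates_per_amplicon=3000, family_size_mean=5.0,
    ))
    cohort: CohortConfig = field(default_factory=CohortConfig)
    caller: CallerConfig = field(default_factory=CallerConfig)
    alpha: float = 0.05
    write_fastq: bool = False

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        from .simulate import ClassParams

        raw = dict(raw)
        if "sim" in raw and isinstance(raw["sim"], dict):
            raw["sim"] = SimulationConfig(**raw["sim"])
        if "cohort" in raw and isinstance(raw["cohort"], dict):
            c = dict(raw["cohort"])
            if "classes" in c:
                c["classes"] = {
                    k: (ClassParams(**v) if isinstance(v, dict) else v)
                    for k, v in c["classes"].items()
                }
            for key in ("dna_surgery", "dna_benign", "ca125_surgery",
                        "ca125_benign", "he4", "maf_clip"):
                if key in c and isinstance(c[key], list):
                    c[key] = tuple(c[key])
            raw["cohort"] = CohortConfig(**c)
        if "caller" in raw and isinstance(raw["caller"], dict):
            raw["caller"] = CallerConfig(**raw["caller"])
        if "genes" in raw and isinstance(raw["genes"], list):
            raw["genes"] = tuple(raw["genes"])
        return cls(**raw)


@dataclass
class RunResult:
    outdir: Path
    panel: Panel
    cohort: pd.DataFrame
    truth: pd.DataFrame
    variants: pd.DataFrame
    summary_table: pd.DataFrame
    marker_table: pd.DataFrame
    control_model: ControlModel


def variant_table(sample_id: str, vcs: list[VariantCall], panel: Panel) -> pd.DataFrame:
    rows = []
    for vc in vcs:
        sc = vc.call
        rows.append({
            "sample_id": sample_id,
            "amplicon_id": sc.amplicon_id,
            "gene": vc.gene,
            "pos_1based": sc.position + 1,
            "ref": sc.ref,
            "alt": sc.alt,
            "consequence": vc.consequence.value,
            "protein_label": vc.protein_label or "",
            "n_supermutants": sc.n_supermutant_families,
            "n_families": sc.n_total_families,
            "maf": sc.maf,
            "flag_maf_gt_floor": vc.flag_maf_gt_floor,
            "flag_exceeds_control": vc.flag_exceeds_control,
            "flag_nonsilent": vc.flag_nonsilent,
            "final_call": vc.final_call,
        })
    cols = ["sample_id", "amplicon_id", "gene", "pos_1based", "ref", "alt",
            "consequence", "protein_label", "n_supermutants", "n_families", "maf",
            "flag_maf_gt_floor", "flag_exceeds_control", "flag_nonsilent", "final_call"]
    return pd.DataFrame(rows, columns=cols)


def write_vcf(variants: pd.DataFrame, panel: Panel, path: str | Path) -> None:
    """Minimal VCF 4.2 export of final calls; CHROM is the amplicon id."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=MAF,Number=1,Type=Float,Description="Mutant allele fraction">\n')
        fh.write('##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Sample id">\n')
        for amp in panel:
            fh.write(f"##contig=<ID={amp.amplicon_id},length={len(amp)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        final = variants[variants["final_call"]]
        for _, row in final.iterrows():
            fh.write(
                f"{row['amplicon_id']}\t{row['pos_1based']}\t.\t{row['ref']}\t{row['alt']}"
                f"\t.\tPASS\tMAF={row['maf']:.6g};SAMPLE={row['sample_id']}\n"
            )


def _get_panel(config: RunConfig, seed: int) -> Panel:
    if config.panel_tsv and config.panel_fasta:
        return load_panel(config.panel_tsv, config.panel_fasta)
    panel, _, _ = make_toy_panel(config.n_amplicons, config.genes, seed=seed)
    return panel


def run_end_to_end(config: RunConfig, outdir: str | Path) -> RunResult:
    """Simulate a cohort, call mutations blind to labels, and evaluate.

    Outputs are written atomically: everything goes to a staging directory
    that replaces ``outdir`` only on success, so failures leave no partial
    results behind.
    """
    outdir = Path(outdir)
    staging = outdir.parent / (outdir.name + ".partial")
    if staging.exists():
        shutil.rmtree(staging)
    staging.mkdir(parents=True)
    try:
        result = _run(config, staging)
    except Exception:
        shutil.rmtree(staging, ignore_errors=True)
        raise
    if outdir.exists():
        shutil.rmtree(outdir)
    staging.rename(outdir)
    result.outdir = outdir
    return result


def _run(config: RunConfig, outdir: Path) -> RunResult:
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("cystseq")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run_inner(config, outdir)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run_inner(config: RunConfig, outdir: Path) -> RunResult:
    ss = np.random.SeedSequence(config.seed)
    panel_seed, covariate_seed, controls_seed, samples_seed = ss.spawn(4)
    panel = _get_panel(config, seed=int(panel_seed.generate_state(1)[0] % 2**31))
    write_panel(panel, outdir / "panel.tsv", outdir / "panel.fasta")
    cfg_c = config.caller
    logger.info(
        "thresholds: min_family_size=%d concordance=%.2f q_uid=%d q_variant=%d "
        "maf_floor=%g control_sd=%g",
        cfg_c.min_family_size, cfg_c.concordance, cfg_c.q_uid, cfg_c.q_variant,
        cfg_c.maf_floor, cfg_c.control_sd_multiplier,
    )

    # --- controls: mutation-free samples, e.g. lymphocyte DNA ---
    control_tallies = []
    for i, child in enumerate(controls_seed.spawn(config.n_controls)):
        rng = np.random.default_rng(child)
        reads = simulate_sample(panel, [], config.sim, rng, sample_id=f"CTRL{i + 1:02d}")
        _, tally, qc = call_sample(reads, panel, config.caller)
        logger.info(
            "control %d: reads=%d discarded=%d unmatched=%d small_family=%d families=%d",
            i + 1, qc.n_reads, qc.n_uid_quality_discarded, qc.n_unmatched,
            qc.n_in_small_families, qc.n_families,
        )
        control_tallies.append(tally)
    control_model = build_control_model(control_tallies)

    # --- cohort: covariates drawn independently of read generation ---
    cohort, truth, spikes_by_sample = simulate_cohort(
        panel, config.cohort, np.random.default_rng(covariate_seed)
    )
    cohort.to_csv(outdir / "cohort.tsv", sep="\t", index=False)
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)

    sample_ids = list(cohort["sample_id"])
    variant_frames = []
    positives = {}
    max_mafs = {}
    fastq_dir = outdir / "fastq"
    if config.write_fastq:
        fastq_dir.mkdir()
    for sid, child in zip(sample_ids, samples_seed.spawn(len(sample_ids))):
        rng = np.random.default_rng(child)
        reads = simulate_sample(panel, spikes_by_sample[sid], config.sim, rng, sample_id=sid)
        if config.write_fastq:
            write_fastq(reads, fastq_dir / f"{sid}.fastq")
        candidates, _, qc = call_sample(reads, panel, config.caller)
        vcs = call_mutations(candidates, control_model, panel, config.caller)
        vt = variant_table(sid, vcs, panel)
        variant_frames.append(vt)
        final = vt[vt["final_call"]]
        positives[sid] = bool(len(final))
        max_mafs[sid] = float(final["maf"].max()) if len(final) else 0.0
        logger.info(
            "sample %s: reads=%d discarded=%d unmatched=%d families=%d "
            "candidates=%d final_calls=%d",
            sid, qc.n_reads, qc.n_uid_quality_discarded, qc.n_unmatched,
            qc.n_families, len(candidates), len(final),
        )

    non_empty = [f for f in variant_frames if len(f)]
    variants = pd.concat(non_empty, ignore_index=True) if non_empty \
        else variant_table("", [], panel)
    variants.to_csv(outdir / "variants.tsv", sep="\t", index=False)
    write_vcf(variants, panel, outdir / "variants.vcf")

    scored = cohort.copy()
    scored["positive"] = scored["sample_id"].map(positives)
    scored["max_maf"] = scored["sample_id"].map(max_mafs)
    scored.to_csv(outdir / "cohort_scored.tsv", sep="\t", index=False)

    result = evaluate_cohort(scored, outdir, alpha=config.alpha)
    config.to_yaml(outdir / "config_resolved.yaml")
    return RunResult(
        outdir=outdir, panel=panel, cohort=scored, truth=truth, variants=variants,
        summary_table=result["summary"], marker_table=result["markers"],
        control_model=control_model,
    )


def evaluate_cohort(scored: pd.DataFrame, outdir: Path | None = None,
                    alpha: float = 0.05) -> dict:
    """Diagnostic summary + marker report + DNA-yield Wilcoxon on a scored cohort."""
    from .diagnostics import needs_surgery

    summary = diagnostic_summary(scored, alpha=alpha)
    report = marker_report(scored)
    surgery_mask = scored["cyst_class"].map(needs_surgery)
    _, p_dna = wilcoxon_rank_sum(
        scored.loc[surgery_mask, "dna_ng"], scored.loc[~surgery_mask, "dna_ng"]
    )
    if outdir is not None:
        summary.table.to_csv(outdir / "summary.tsv", sep="\t", index=False)
        report.table.to_csv(outdir / "markers.tsv", sep="\t", index=False)
        for name, frame in report.figure_data.items():
            frame.to_csv(outdir / f"figure_{name}.tsv", sep="\t", index=False)
    logger.info("sensitivity=%.4f specificity=%.4f wilcoxon_dna_p=%.3g",
                summary.sensitivity, summary.specificity, p_dna)
    return {
        "summary": summary.table, "markers": report.table,
        "sensitivity": summary.sensitivity, "specificity": summary.specificity,
        "sensitivity_ci": summary.sensitivity_ci, "specificity_ci": summary.specificity_ci,
        "wilcoxon_dna_p": p_dna, "firth_pvalues": report.pvalues,
    }
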