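"""End-to-end orchestration and the QC-sensitivity sweep.

Stages run in a fixed order: SNP QC -> sample QC -> PC batch correction ->
post-correction differential-SNP exclusion -> HMM calling with fragment
merging -> CNV/CNVR QC -> association.  Every sample, SNP and call excluded
along the way is logged with a reason code, and runs are deterministic given
the seed.

QC "levels" bundle thresholds: the medium bundle is the pipeline's final
default configuration (0.95 call rate, 1.5xIQR mean fence, 3.5 SD DLRS and
wave fences, 24 components, all CNV-QC filters on).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import cnvr as cnvr_mod
from . import correct, io, sample_qc, snp_qc, stats
from .hmm import HmmParams, call_cnvs, merge_fragments
from .model import CnvCall, IntensityPanel, RegionSet, SampleSheet
from .simulate import TruthTables

SNP_QC_LEVELS = {
    "low": {"call_rate": 0.90, "hwe_p": 1e-12},
    "medium": {"call_rate": 0.95, "hwe_p": 1e-10},
    "high": {"call_rate": 0.99, "hwe_p": 1e-8},
}
SAMPLE_QC_LEVELS = {
    "low": {"mean_k": 2.0, "dlrs_k": 4.0, "wave_k": 4.0},
    "medium": {"mean_k": 1.5, "dlrs_k": 3.5, "wave_k": 3.5},
    "high": {"mean_k": 1.0, "dlrs_k": 3.0, "wave_k": 3.0},
}


@dataclass
class PipelineConfig:
    """Run configuration; defaults are the pipeline's final settings."""

    sample_qc_level: str = "medium"
    snp_qc_level: str = "medium"
    pc_components: int = 24
    cnv_qc: bool = True
    min_snps: int = 6
    quality_min: float = 0.95
    call_stage_max: float = 0.05
    rare_max: float = 0.01
    thin_fraction: float = 0.15
    window_bp: int = 1_000_000
    min_windows: int = 4
    hmm: dict = field(default_factory=dict)
    seed: int = 0
    manifest_path: str | None = None
    intensity_path: str | None = None
    sample_sheet_path: str | None = None
    mask_bed_paths: list[str] = field(default_factory=list)

    def hmm_params(self) -> HmmParams:
        return HmmParams(**self.hmm) if self.hmm else HmmParams()

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class PipelineResult:
    config: PipelineConfig
    panel: IntensityPanel              # corrected, post-QC panel
    sheet: SampleSheet                 # post-QC samples
    calls: list[CnvCall]               # post-filter calls
    cnvrs_del: list
    cnvrs_dup: list
    burden: list[stats.BurdenResult]
    scan: pd.DataFrame
    exclusions: pd.DataFrame           # kind, id, reason
    log: list[str]
    n_case: int = 0
    n_control: int = 0
    sample_metrics: pd.DataFrame | None = None   # one row per sample
    pc_scores: pd.DataFrame | None = None        # persisted for audit

    def mean_quality(self) -> float:
        return float(np.mean([c.quality for c in self.calls])) if self.calls else float("nan")

    def burden_or(self, cls: str) -> float:
        for b in self.burden:
            if b.stratum == f"{cls} all":
                return b.or_cmle
        return float("nan")

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.config.to_yaml(out / "config.yaml")
        io.write_cnv_calls(self.calls, out / "calls.txt")
        io.write_cnv_bed(self.calls, out / "calls.bed")
        self.exclusions.to_csv(out / "exclusions.tsv", sep="\t", index=False)
        self.scan.to_csv(out / "cnvr_scan.tsv", sep="\t", index=False)
        self.scan[["p", "expected_p"]].to_csv(out / "qq.tsv", sep="\t", index=False)
        pd.DataFrame([dataclasses.asdict(b) for b in self.burden]) \
            .to_csv(out / "burden.tsv", sep="\t", index=False)
        if self.sample_metrics is not None:
            self.sample_metrics.to_csv(out / "sample_qc_metrics.tsv", sep="\t")
        if self.pc_scores is not None:
            self.pc_scores.to_csv(out / "pc_scores.tsv", sep="\t")
        (out / "run.log").write_text("\n".join(self.log) + "\n")


def run_pipeline(config: PipelineConfig,
                 panel: IntensityPanel | None = None,
                 sheet: SampleSheet | None = None,
                 mask_regions: list[RegionSet] | None = None,
                 out_dir=None) -> PipelineResult:
    """Execute the full pipeline on a panel (loaded from config paths when
    not supplied)."""
    log: list[str] = []
    excl_rows: list[tuple[str, str, str]] = []

    if panel is None or sheet is None:
        if not (config.manifest_path and config.intensity_path
                and config.sample_sheet_path):
            raise ValueError("no panel given and input paths incomplete")
        manifest = io.read_manifest(config.manifest_path)
        sheet = io.read_sample_sheet(config.sample_sheet_path)
        panel = io.read_intensity_long(config.intensity_path, manifest, sheet)
    if mask_regions is None:
        mask_regions = [io.read_regions_bed(p, label=Path(p).stem)
                        for p in config.mask_bed_paths]

    snp_level = SNP_QC_LEVELS[config.snp_qc_level]
    sample_level = SAMPLE_QC_LEVELS[config.sample_qc_level]

    # ---- stage 1: SNP/genotype QC -------------------------------------
    report = snp_qc.call_rate_filter(panel, snp_threshold=snp_level["call_rate"],
                                     sample_threshold=snp_level["call_rate"])
    controls = np.array([sheet.phenotype_of(s) == "control" for s in panel.samples])
    if controls.sum() >= 10:
        snp_qc.hwe_filter(panel, report, p_threshold=snp_level["hwe_p"],
                          controls=controls)
    if panel.n_samples >= 10:
        snp_qc.het_outlier_filter(snp_qc.sample_het_rates(panel), report)
    keep_samples = [s for s in panel.samples if s not in report.excluded_samples]
    snp_mask = ~pd.Index(panel.manifest.snp_ids).isin(report.excluded_snps)
    excl_rows += [("sample", s, r) for s, r in report.excluded_samples.items()]
    excl_rows += [("snp", m, r) for m, r in report.excluded_snps.items()]
    panel = panel.subset_samples(keep_samples).subset_snps(np.asarray(snp_mask))
    log.append(f"snp_qc: kept {panel.n_samples} samples, {len(panel.manifest)} SNPs")

    # ---- stage 2: intensity sample QC ---------------------------------
    metrics, failed = sample_qc.run_sample_qc(
        panel, sheet, mean_k=sample_level["mean_k"], dlrs_k=sample_level["dlrs_k"],
        wave_k=sample_level["wave_k"], window_bp=config.window_bp,
        min_windows=config.min_windows)
    excl_rows += [("sample", s, metrics.flags[s]) for s in failed]
    panel = panel.subset_samples([s for s in panel.samples if s not in set(failed)])
    log.append(f"sample_qc: excluded {len(failed)} samples")

    # ---- stage 3: PC batch correction ---------------------------------
    pc_scores = None
    if config.pc_components > 0:
        subset = correct.select_correction_markers(
            panel.manifest, mask_regions, thin_fraction=config.thin_fraction,
            seed=config.seed)
        corrected, model = correct.fit_and_remove_components(
            panel.lrr, subset, k=min(config.pc_components, panel.n_samples - 1))
        panel = IntensityPanel(panel.samples, panel.manifest, corrected,
                               panel.baf, panel.genotype)
        pc_scores = pd.DataFrame(
            model.scores, index=panel.samples,
            columns=[f"PC{i + 1}" for i in range(model.k)])
        log.append(f"pc_correction: removed {model.k} components "
                   f"fit on {len(subset)} markers")
    else:
        log.append("pc_correction: skipped (k=0)")

    # ---- stage 4: post-correction differential-intensity SNPs ---------
    src = sheet.df.set_index("sample_id")["dna_source"].reindex(panel.samples)
    if src.nunique() == 2:
        rep2 = snp_qc.differential_intensity_filter(
            panel.lrr, src.to_numpy(), panel.manifest.snp_ids)
        bad = rep2.excluded_snps
        if bad:
            excl_rows += [("snp", m, r) for m, r in bad.items()]
            panel = panel.subset_snps(~pd.Index(panel.manifest.snp_ids).isin(bad))
        log.append(f"differential_snps: excluded {len(bad)}")

    # ---- stage 5: CNV calling -----------------------------------------
    raw_calls = call_cnvs(panel, config.hmm_params())
    calls = merge_fragments(raw_calls, panel.manifest)
    log.append(f"calling: {len(raw_calls)} raw -> {len(calls)} merged calls")

    # ---- stage 6: CNV / CNVR QC ---------------------------------------
    sheet_now = sheet.subset(panel.samples)
    if config.cnv_qc:
        calls, rep = cnvr_mod.apply_cnv_level_filters(
            calls, sheet_now, mask_regions, min_snps=config.min_snps,
            quality_min=config.quality_min)
        for rule, dropped in rep.dropped.items():
            excl_rows += [("call", f"{c.sample_id}:{c.chrom}:{c.start_bp}", rule)
                          for c in dropped]
        log.append(f"cnv_qc: kept {len(calls)} calls")
    else:
        calls = [c for c in calls if c.n_snps >= config.min_snps]
        log.append(f"cnv_qc off: kept {len(calls)} calls (min_snps only)")

    n_samples = panel.n_samples
    cnvrs = {}
    for cls in ("DEL", "DUP"):
        sub = [c for c in calls if c.cnv_class == cls]
        groups = cnvr_mod.group_cnvrs(sub, n_samples, sheet_now,
                                      id_prefix=f"{cls.lower()}_")
        groups = [g for g in groups if g.frequency <= config.call_stage_max]
        if config.cnv_qc:
            groups = cnvr_mod.filter_rare_cnvrs(
                groups, n_samples, call_stage_max=config.call_stage_max,
                rare_max=config.rare_max, quality_min=config.quality_min)
        else:
            groups = [g for g in groups if g.frequency <= config.rare_max]
        cnvr_mod.recount_carriers(groups, sheet_now)
        cnvrs[cls] = groups
    log.append(f"cnvr: {len(cnvrs['DEL'])} DEL, {len(cnvrs['DUP'])} DUP regions")

    # ---- stage 7: association -----------------------------------------
    phenos = sheet_now.df["phenotype"]
    n_case = int((phenos == "case").sum())
    n_control = int((phenos == "control").sum())
    burden = stats.burden_strata(calls, sheet_now, n_case, n_control) \
        if n_case and n_control else []
    scan = stats.cnvr_scan(cnvrs["DEL"] + cnvrs["DUP"], n_case, n_control) \
        if n_case and n_control else pd.DataFrame(
            columns=["cnvr_id", "p", "expected_p"])
    log.append(f"association: {len(burden)} burden strata, {len(scan)} CNVR tests")

    result = PipelineResult(
        config=config, panel=panel, sheet=sheet_now, calls=calls,
        cnvrs_del=cnvrs["DEL"], cnvrs_dup=cnvrs["DUP"], burden=burden, scan=scan,
        exclusions=pd.DataFrame(excl_rows, columns=["kind", "id", "reason"]),
        log=log, n_case=n_case, n_control=n_control,
        sample_metrics=pd.DataFrame({"lrr_mean": metrics.lrr_mean,
                                     "dlrs": metrics.dlrs,
                                     "swf": metrics.swf}),
        pc_scores=pc_scores)
    if out_dir is not None:
        result.write(out_dir)
    return result


# ------------------------------------------------------------------- sweep

def match_truth(calls: list[CnvCall], truth: pd.DataFrame,
                min_snps: int = 6,
                samples: Sequence[str] | None = None) -> tuple[float, float]:
    """(sensitivity, precision) of calls against simulator truth intervals.

    A truth interval counts as recovered when the same sample has a
    same-class call sharing >= 1 bp; a call is a true positive when it
    overlaps a truth interval of its sample and class.  Only truth events
    with at least ``min_snps`` supporting SNPs — and, when ``samples`` is
    given, belonging to a listed (QC-surviving) sample — enter the
    denominator.
    """
    def cls_of(cn): return "DEL" if cn < 2 else "DUP"
    by_sample: dict[str, list[CnvCall]] = {}
    for c in calls:
        by_sample.setdefault(c.sample_id, []).append(c)
    t = truth[truth["n_snps"] >= min_snps]
    if samples is not None:
        t = t[t["sample_id"].isin(set(samples))]
    recovered = 0
    for r in t.itertuples():
        hits = [c for c in by_sample.get(r.sample_id, [])
                if c.chrom == r.chrom and cls_of(r.copy_number) == c.cnv_class
                and c.start_bp <= r.end_bp and c.end_bp >= r.start_bp]
        recovered += bool(hits)
    sens = recovered / len(t) if len(t) else float("nan")
    tp = 0
    truth_by_sample = {s: g for s, g in truth.groupby("sample_id")}
    for c in calls:
        g = truth_by_sample.get(c.sample_id)
        if g is None:
            continue
        ok = ((g["chrom"] == c.chrom) & (g["start_bp"] <= c.end_bp)
              & (g["end_bp"] >= c.start_bp)
              & (g["copy_number"].map(cls_of) == c.cnv_class))
        tp += bool(ok.any())
    prec = tp / len(calls) if calls else float("nan")
    return sens, prec


def qc_sweep(base_config: PipelineConfig, panel: IntensityPanel,
             sheet: SampleSheet, truth: TruthTables | None = None,
             mask_regions: list[RegionSet] | None = None,
             sample_levels=("low", "medium", "high"),
             snp_levels=("low", "medium", "high"),
             pc_levels=(0, 12, 24),
             cnv_qc_levels=(False, True)) -> pd.DataFrame:
    """Run the pipeline over the QC-configuration grid (3 x 3 x 3 x 2 = 54
    cells by default) on shared inputs; one row per run with the mean call
    quality, burden ORs and, when truth is available, sensitivity/precision.
    Failed cells are recorded and the sweep continues."""
    rows = []
    for sq in sample_levels:
        for nq in snp_levels:
            for k in pc_levels:
                for cq in cnv_qc_levels:
                    cfg = dataclasses.replace(
                        base_config, sample_qc_level=sq, snp_qc_level=nq,
                        pc_components=k, cnv_qc=cq)
                    row = {"sample_qc": sq, "snp_qc": nq, "pc_components": k,
                           "cnv_qc": cq}
                    try:
                        res = run_pipeline(cfg, panel, sheet, mask_regions)
                        row.update(n_calls=len(res.calls),
                                   mean_quality=res.mean_quality(),
                                   burden_or_del=res.burden_or("DEL"),
                                   burden_or_dup=res.burden_or("DUP"),
                                   status="ok")
                        if truth is not None:
                            sens, prec = match_truth(res.calls, truth.cnv_truth,
                                                     cfg.min_snps)
                            row.update(sensitivity=sens, precision=prec)
                    except Exception as exc:  # recorded, sweep continues
                        row.update(status=f"failed: {exc}")
                    rows.append(row)
    return pd.DataFrame(rows)
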