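"""Synthetic SNP-array intensity data with the artefact structure the
pipeline is built to remove.

The generative model for the LRR of sample *s* at marker *m* is

    LRR(s, m) = mu_cohort + mu_plate + w_s * g(m)
                + sum_k u_{s,k} v_{m,k} + delta_state(s, m) + eps_{s,m}

with ``eps ~ N(0, sigma_s^2)``, ``g`` the standardised (zero-mean,
unit-variance) GC profile of the manifest, ``u, v`` latent linear batch
components whose sample scores have cohort-specific means (so batch structure
is confounded with phenotype, as when cases and controls are typed at
different centres), and ``delta_state`` the copy-number LRR shift inside
spiked CNVs.  State shifts default to the HMM caller's emission means so the
simulator and caller share one parameterisation; pass ``hmm_params`` with
different means to study mismatch.

BAF is generated from genotypes drawn at the population B-allele frequency
and transformed inside CNVs: a copy-1 deletion removes the heterozygous band,
a copy-0 deletion leaves uniform noise, duplications move bands to k/3 or
k/4.  All draws flow from one seeded generator; the stream order is the
order of the fields in :class:`SimConfig` followed by the per-sample matrix
draws, so identical configs give bit-identical panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .hmm import HmmParams
from .model import (GT_NC, IntensityPanel, Pedigree, SampleSheet, SnpManifest)


# ------------------------------------------------------------------ manifest

def build_manifest(n_snps: int = 2000,
                   chrom_layout: dict[str, float] | None = None,
                   gc_period_bp: float = 4e6,
                   gc_amplitude: float = 0.15,
                   monomorphic_fraction: float = 0.15,
                   seed: int = 0) -> SnpManifest:
    """Simulate a manifest with non-uniform marker spacing.

    ``chrom_layout`` maps chromosome name to its span in bp; ``n_snps`` is
    split across chromosomes proportionally to span.  The GC profile is a
    low-frequency oscillation plus jitter, clipped to [0.2, 0.8]; PFB is a
    mixture of monomorphic and uniformly polymorphic SNPs.
    """
    if chrom_layout is None:
        chrom_layout = {"chr1": 30e6, "chr2": 20e6}
    rng = np.random.default_rng(seed)
    spans = np.array(list(chrom_layout.values()), float)
    counts = np.maximum(2, np.round(n_snps * spans / spans.sum()).astype(int))
    frames = []
    for (chrom, span), k in zip(chrom_layout.items(), counts):
        if k < 2:
            raise ValueError(f"chromosome {chrom} needs >= 2 SNPs")
        pos = np.sort(rng.choice(np.arange(1, int(span)), size=k, replace=False))
        gc = 0.5 + gc_amplitude * np.sin(2 * np.pi * pos / gc_period_bp) \
            + rng.normal(0.0, 0.05, size=k)
        gc = np.clip(gc, 0.2, 0.8)
        mono = rng.random(k) < monomorphic_fraction
        pfb = rng.uniform(0.05, 0.95, size=k)
        pfb[mono] = rng.uniform(0.0, 0.01, size=mono.sum())
        frames.append(pd.DataFrame({
            "snp_id": [f"{chrom}_snp{i}" for i in range(k)],
            "chrom": chrom, "pos_bp": pos, "gc_fraction": gc, "pfb": pfb}))
    return SnpManifest(pd.concat(frames, ignore_index=True))


# -------------------------------------------------------------------- config

@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort and trio generators."""

    n_cases: int = 500
    n_controls: int = 500
    samples_per_plate: int = 96
    # cohort structure: cases and controls typed at different centres, so
    # cohort (and its batch structure) is confounded with phenotype
    case_cohort: str = "centreA_cases"
    control_cohort: str = "centreB_controls"
    cohort_offset_sd: float = 0.03     # LRR shift per cohort
    plate_offset_sd: float = 0.02      # LRR shift per plate
    noise_sd: float = 0.16             # base per-sample LRR noise (matches CN2 SD)
    noise_outlier_fraction: float = 0.02
    noise_outlier_sd: float = 0.35
    wave_sd: float = 0.01              # per-sample GC-wave amplitude w_s
    wave_outlier_fraction: float = 0.01
    wave_outlier_amplitude: float = 0.10
    n_latent_factors: int = 3
    factor_loading_amplitude: float = 0.08  # amplitude of the smooth loading profiles v_{m,k}
    factor_cohort_shift: float = 0.5   # cohort-mean offset of scores u_{s,k}
    baf_sd: float = 0.04               # BAF band noise (matches emission model)
    genotype_nc_rate: float = 0.005
    # spiked CNV truth
    n_cnv_loci: int = 20
    cnv_carrier_freq: float = 0.01
    cnv_len_snps: tuple[int, int] = (6, 30)
    # single-copy events dominate; homozygous deletions and double-copy
    # gains are rare among rare CNVs
    cnv_state_probs: dict[int, float] = field(
        default_factory=lambda: {1: 0.50, 3: 0.40, 0: 0.05, 4: 0.05})
    # Null-control design: draw exactly round(freq * n) carriers per
    # phenotype group at every locus, so any departure of the burden OR
    # from 1 measures pipeline-induced bias rather than carrier-sampling
    # noise.  Off by default (carriers i.i.d. across all samples).
    cnv_balance_phenotype: bool = False
    aberrant_chrom_fraction: float = 0.002
    failing_plate_fraction: float = 0.0
    # trios
    n_families: int = 100
    children_per_family: int = 2
    affected_child_fraction: float = 0.8
    de_novo_rate: float = 0.0          # expected de novo CNVs per child
    parent_cnv_freq: float = 0.05      # per-locus parental carrier frequency
    seed: int = 0

    def __post_init__(self):
        for name in ("cnv_carrier_freq", "noise_outlier_fraction",
                     "wave_outlier_fraction", "aberrant_chrom_fraction",
                     "failing_plate_fraction", "genotype_nc_rate",
                     "affected_child_fraction", "parent_cnv_freq"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class TruthTables:
    """Ground truth emitted alongside simulated panels."""

    sample_flags: pd.DataFrame   # sample_id, high_noise, aberrant_chrom, failing_plate
    cnv_truth: pd.DataFrame      # sample_id, chrom, start_bp, end_bp, copy_number, n_snps
    trio_truth: pd.DataFrame | None = None  # child_id, parent_id, locus, kind

    def write(self, prefix) -> None:
        self.sample_flags.to_csv(f"{prefix}.sample_flags.tsv", sep="\t", index=False)
        self.cnv_truth.to_csv(f"{prefix}.cnv_truth.tsv", sep="\t", index=False)
        if self.trio_truth is not None:
            self.trio_truth.to_csv(f"{prefix}.trio_truth.tsv", sep="\t", index=False)


# ----------------------------------------------------------------- internals

def _standardized_gc(manifest: SnpManifest) -> np.ndarray:
    g = manifest.gc_fraction
    return (g - g.mean()) / max(g.std(), 1e-12)


def _draw_cnv_loci(rng: np.random.Generator, manifest: SnpManifest,
                   config: SimConfig) -> list[tuple[str, int, int, int]]:
    """Random (chrom, start_idx, end_idx, copy_number) loci on the manifest."""
    slices = manifest.chrom_slices()
    chroms = list(slices)
    states = np.array(sorted(config.cnv_state_probs))
    probs = np.array([config.cnv_state_probs[s] for s in states], float)
    probs /= probs.sum()
    loci = []
    for _ in range(config.n_cnv_loci):
        chrom = chroms[rng.integers(len(chroms))]
        sl = slices[chrom]
        n_chrom = sl.stop - sl.start
        length = int(rng.integers(config.cnv_len_snps[0], config.cnv_len_snps[1] + 1))
        if length > n_chrom:
            raise ValueError(f"CNV of {length} SNPs exceeds chromosome {chrom}")
        start = int(rng.integers(0, n_chrom - length + 1))
        cn = int(rng.choice(states, p=probs))
        loci.append((chrom, sl.start + start, sl.start + start + length - 1, cn))
    return loci


def _apply_cnv(lrr_row: np.ndarray, baf_row: np.ndarray, gt_row: np.ndarray,
               idx: slice, cn: int, pfb: np.ndarray,
               rng: np.random.Generator, baf_sd: float,
               state_shift: dict[int, float]) -> None:
    """Overwrite one sample's intensities inside a CNV interval, in place."""
    n = idx.stop - idx.start
    lrr_row[idx] += state_shift[cn]
    if cn == 0:
        baf_row[idx] = rng.uniform(0.0, 1.0, size=n)
        gt_row[idx] = GT_NC
        return
    k = rng.binomial(cn, pfb[idx])
    baf_row[idx] = np.clip(k / cn + rng.normal(0.0, baf_sd, size=n), 0.0, 1.0)
    gt_row[idx] = np.where(k == 0, 0, np.where(k == cn, 2, 1)).astype(np.int8)


def _genotype_baf(rng: np.random.Generator, pfb: np.ndarray, n_samples: int,
                  baf_sd: float) -> tuple[np.ndarray, np.ndarray]:
    """Diploid genotypes (B-allele counts) and band BAF for all samples."""
    k = rng.binomial(2, pfb[None, :], size=(n_samples, len(pfb)))
    baf = np.clip(k / 2.0 + rng.normal(0.0, baf_sd, size=k.shape), 0.0, 1.0)
    return k.astype(np.int8), baf


def _state_shifts(hmm_params: HmmParams | None) -> dict[int, float]:
    p = hmm_params or HmmParams()
    return {cn: float(p.lrr_mean[i]) for i, cn in enumerate((0, 1, 2, 3, 4))}


# -------------------------------------------------------------------- cohort

def simulate_cohort(config: SimConfig, manifest: SnpManifest,
                    hmm_params: HmmParams | None = None
                    ) -> tuple[IntensityPanel, SampleSheet, TruthTables]:
    """Simulate a confounded case-control cohort with spiked CNVs."""
    rng = np.random.default_rng(config.seed)
    n_m = len(manifest)
    shifts = _state_shifts(hmm_params)

    sample_ids = [f"case{i:05d}" for i in range(config.n_cases)] + \
                 [f"ctrl{i:05d}" for i in range(config.n_controls)]
    phenotype = ["case"] * config.n_cases + ["control"] * config.n_controls
    cohort = [config.case_cohort] * config.n_cases + \
             [config.control_cohort] * config.n_controls
    n_s = len(sample_ids)

    # plates fill within cohort, in sample order
    plate_ids, plate_names = [], {}
    for i, co in enumerate(cohort):
        k = sum(c == co for c in cohort[:i])
        plate = f"{co}_p{k // config.samples_per_plate:03d}"
        plate_ids.append(plate)
        plate_names.setdefault(plate, None)
    sheet = SampleSheet(pd.DataFrame({
        "sample_id": sample_ids, "phenotype": phenotype, "plate_id": plate_ids,
        "cohort_id": cohort,
        "dna_source": ["cell_line" if p == "case" else "genomic" for p in phenotype],
        "sex": "unknown"}))

    # --- batch structure (fixed stream order; see module docstring) ---
    cohort_names = sorted(set(cohort))
    cohort_offset = {c: rng.normal(0.0, config.cohort_offset_sd) for c in cohort_names}
    plate_offset = {p: rng.normal(0.0, config.plate_offset_sd) for p in plate_names}
    failing_plates = {p for p in plate_names
                      if rng.random() < config.failing_plate_fraction}
    k_fac = config.n_latent_factors
    factor_cohort_mean = {c: rng.normal(0.0, config.factor_cohort_shift, size=k_fac)
                          for c in cohort_names}
    # loading profiles are regionally smooth (batch artefacts span Mb-scale
    # runs of markers, which is what creates artificial CNVs pre-correction)
    v = np.zeros((n_m, k_fac))
    pos_all = manifest.pos_bp.astype(float)
    for kk in range(k_fac):
        period = rng.uniform(2e6, 10e6)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        v[:, kk] = config.factor_loading_amplitude * np.sin(
            2.0 * np.pi * pos_all / period + phase)
    u = np.stack([rng.normal(factor_cohort_mean[c], 1.0) for c in cohort]) \
        if k_fac else np.zeros((n_s, 0))

    g = _standardized_gc(manifest)
    w = rng.normal(0.0, config.wave_sd, size=n_s)
    wave_outlier = rng.random(n_s) < config.wave_outlier_fraction
    w[wave_outlier] = config.wave_outlier_amplitude * np.sign(w[wave_outlier] + 1e-12)

    sigma = np.full(n_s, config.noise_sd)
    high_noise = rng.random(n_s) < config.noise_outlier_fraction
    sigma[high_noise] = config.noise_outlier_sd

    # --- baseline diploid panel ---
    gt_k, baf = _genotype_baf(rng, manifest.pfb, n_s, config.baf_sd)
    genotype = gt_k.copy()
    lrr = rng.normal(0.0, 1.0, size=(n_s, n_m)) * sigma[:, None]
    lrr += np.array([cohort_offset[c] for c in cohort])[:, None]
    lrr += np.array([plate_offset[p] for p in plate_ids])[:, None]
    failing_member = np.array([p in failing_plates for p in plate_ids])
    lrr[failing_member] += 0.25
    lrr += w[:, None] * g[None, :]
    if k_fac:
        lrr += u @ v.T
    nc = rng.random((n_s, n_m)) < config.genotype_nc_rate
    genotype[nc] = GT_NC

    # --- spiked CNVs ---
    loci = _draw_cnv_loci(rng, manifest, config)
    truth_rows = []
    pos = manifest.pos_bp
    chrom_arr = manifest.chrom
    case_idx = np.arange(config.n_cases)
    ctrl_idx = np.arange(config.n_cases, n_s)
    for chrom, a, b, cn in loci:
        if config.cnv_balance_phenotype:
            carriers = np.concatenate([
                rng.choice(case_idx, round(config.cnv_carrier_freq * len(case_idx)),
                           replace=False),
                rng.choice(ctrl_idx, round(config.cnv_carrier_freq * len(ctrl_idx)),
                           replace=False)])
        else:
            carriers = np.flatnonzero(rng.random(n_s) < config.cnv_carrier_freq)
        for s in carriers:
            _apply_cnv(lrr[s], baf[s], genotype[s], slice(a, b + 1), cn,
                       manifest.pfb, rng, config.baf_sd, shifts)
            truth_rows.append((sample_ids[s], chrom, int(pos[a]), int(pos[b]),
                               cn, b - a + 1))

    # --- whole-chromosome aberrations ---
    aberrant = {}
    ab_samples = np.flatnonzero(rng.random(n_s) < config.aberrant_chrom_fraction)
    slices = manifest.chrom_slices()
    chroms = list(slices)
    for s in ab_samples:
        chrom = chroms[rng.integers(len(chroms))]
        sl = slices[chrom]
        cn = 3 if rng.random() < 0.5 else 1
        _apply_cnv(lrr[s], baf[s], genotype[s], sl, cn, manifest.pfb, rng,
                   config.baf_sd, shifts)
        aberrant[sample_ids[s]] = chrom

    flags = pd.DataFrame({
        "sample_id": sample_ids,
        "high_noise": high_noise,
        "wave_outlier": wave_outlier,
        "aberrant_chrom": [aberrant.get(s, "") for s in sample_ids],
        "failing_plate": failing_member})
    cnv_truth = pd.DataFrame(truth_rows, columns=[
        "sample_id", "chrom", "start_bp", "end_bp", "copy_number", "n_snps"])
    panel = IntensityPanel(sample_ids, manifest, lrr, baf, genotype.astype(np.int8))
    return panel, sheet, TruthTables(flags, cnv_truth)


# --------------------------------------------------------------------- trios

def simulate_trios(config: SimConfig, manifest: SnpManifest,
                   hmm_params: HmmParams | None = None
                   ) -> tuple[IntensityPanel, Pedigree, SampleSheet, TruthTables]:
    """Simulate families: parental CNVs transmit with probability 1/2,
    de novo CNVs arise in children at the configured rate, genotypes are
    Mendelian."""
    if config.n_families < 1:
        raise ValueError("trio simulation needs at least one family")
    rng = np.random.default_rng(config.seed + 1)
    n_m = len(manifest)
    pfb = manifest.pfb
    shifts = _state_shifts(hmm_params)

    ped_rows, sample_ids, roles = [], [], []
    for f in range(config.n_families):
        fid = f"fam{f:04d}"
        fa, mo = f"{fid}_fa", f"{fid}_mo"
        ped_rows.append((fid, fa, None, None, "M", "unaffected"))
        ped_rows.append((fid, mo, None, None, "F", "unaffected"))
        sample_ids += [fa, mo]
        roles += [("parent", fid, None), ("parent", fid, None)]
        for c in range(config.children_per_family):
            cid = f"{fid}_ch{c}"
            aff = "affected" if rng.random() < config.affected_child_fraction \
                else "unaffected"
            ped_rows.append((fid, cid, fa, mo, "M" if rng.random() < 0.5 else "F", aff))
            sample_ids.append(cid)
            roles.append(("child", fid, (fa, mo)))
    ped = Pedigree(pd.DataFrame(ped_rows, columns=list(Pedigree.REQUIRED)))
    n_s = len(sample_ids)
    idx_of = {s: i for i, s in enumerate(sample_ids)}

    # Mendelian genotypes: parents carry two haplotypes each
    hap: dict[str, np.ndarray] = {}
    gt_k = np.zeros((n_s, n_m), dtype=np.int8)
    for i, (sid, (role, fid, parents)) in enumerate(zip(sample_ids, roles)):
        if role == "parent":
            h = rng.random((2, n_m)) < pfb[None, :]
            hap[sid] = h
            gt_k[i] = h.sum(axis=0)
    for i, (sid, (role, fid, parents)) in enumerate(zip(sample_ids, roles)):
        if role == "child":
            fa, mo = parents
            pick_f = hap[fa][rng.integers(0, 2, size=n_m), np.arange(n_m)]
            pick_m = hap[mo][rng.integers(0, 2, size=n_m), np.arange(n_m)]
            gt_k[i] = pick_f.astype(np.int8) + pick_m.astype(np.int8)

    baf = np.clip(gt_k / 2.0 + rng.normal(0.0, config.baf_sd, size=(n_s, n_m)),
                  0.0, 1.0)
    genotype = gt_k.copy()
    nc = rng.random((n_s, n_m)) < config.genotype_nc_rate
    genotype[nc] = GT_NC
    lrr = rng.normal(0.0, config.noise_sd, size=(n_s, n_m))

    # parental CNVs and their transmissions
    loci = _draw_cnv_loci(rng, manifest, config)
    pos = manifest.pos_bp
    truth_rows, trio_rows = [], []

    def spike(sample: str, a: int, b: int, chrom: str, cn: int):
        s = idx_of[sample]
        _apply_cnv(lrr[s], baf[s], genotype[s], slice(a, b + 1), cn, pfb, rng,
                   config.baf_sd, shifts)
        truth_rows.append((sample, chrom, int(pos[a]), int(pos[b]), cn, b - a + 1))

    for chrom, a, b, cn in loci:
        for i, (sid, (role, fid, parents)) in enumerate(zip(sample_ids, roles)):
            if role != "parent" or rng.random() >= config.parent_cnv_freq:
                continue
            spike(sid, a, b, chrom, cn)
            for cid, (crole, cfid, cparents) in zip(sample_ids, roles):
                if crole == "child" and cfid == fid:
                    transmitted = rng.random() < 0.5
                    if transmitted:
                        spike(cid, a, b, chrom, cn)
                    trio_rows.append((cid, sid, chrom, int(pos[a]), int(pos[b]), cn,
                                      "transmitted" if transmitted else "untransmitted"))

    # de novo CNVs in children
    if config.de_novo_rate > 0:
        for cid, (role, fid, parents) in zip(sample_ids, roles):
            if role != "child":
                continue
            for _ in range(rng.poisson(config.de_novo_rate)):
                chrom, a, b, cn = _draw_cnv_loci(rng, manifest, config)[0]
                spike(cid, a, b, chrom, cn)
                trio_rows.append((cid, "", chrom, int(pos[a]), int(pos[b]), cn,
                                  "de_novo"))

    sheet = SampleSheet(pd.DataFrame({
        "sample_id": sample_ids,
        "phenotype": ["unknown"] * n_s,
        "plate_id": [f"famplate{i // config.samples_per_plate:03d}" for i in range(n_s)],
        "cohort_id": "families", "dna_source": "cell_line", "sex": "unknown"}))
    flags = pd.DataFrame({"sample_id": sample_ids,
                          "high_noise": False, "wave_outlier": False,
                          "aberrant_chrom": "", "failing_plate": False})
    cnv_truth = pd.DataFrame(truth_rows, columns=[
        "sample_id", "chrom", "start_bp", "end_bp", "copy_number", "n_snps"])
    trio_truth = pd.DataFrame(trio_rows, columns=[
        "child_id", "parent_id", "chrom", "start_bp", "end_bp", "copy_number", "kind"])
    panel = IntensityPanel(sample_ids, manifest, lrr, baf, genotype.astype(np.int8))
    return panel, ped, sheet, TruthTables(flags, cnv_truth, trio_truth)
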