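"""Intensity-level sample quality control.

Metrics: overall LRR mean (Tukey-style 1.5*IQR fences), derivative log-ratio
spread (DLRS, a high-frequency noise measure), the signed total wave factor
(long-range LRR oscillation, signed by its correlation with regional GC),
whole-chromosome aberration flags, and plate-level failure fractions.

Exclusion order is fixed: call-rate -> mean fence -> DLRS -> wave ->
aberration -> plate; re-running on the surviving set is a no-op.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import IntensityPanel, SampleSheet, SnpManifest


@dataclass
class SampleQcMetrics:
    """Per-sample intensity metrics plus reason-coded flags."""

    lrr_mean: pd.Series
    dlrs: pd.Series
    swf: pd.Series
    chrom_means: pd.DataFrame            # samples x chromosomes
    flags: dict[str, str] = field(default_factory=dict)   # sample -> reason
    plate_failure: pd.Series | None = None

    def flag(self, sample_id: str, reason: str) -> None:
        self.flags.setdefault(sample_id, reason)


# ------------------------------------------------------------------ metrics

def dlrs(lrr: np.ndarray, chrom: np.ndarray) -> float:
    """SD of successive-marker LRR differences, within chromosomes, / sqrt(2).

    Missing values are skipped, so a difference spans the gap; the SD uses
    the n-1 denominator.
    """
    diffs = []
    for c in pd.unique(chrom):
        v = lrr[chrom == c]
        v = v[np.isfinite(v)]
        if len(v) >= 2:
            diffs.append(np.diff(v))
    if not diffs or sum(len(d) for d in diffs) < 2:
        raise ValueError("DLRS needs >= 3 usable values on some chromosome")
    pooled = np.concatenate(diffs)
    return float(pooled.std(ddof=1) / np.sqrt(2.0))


def _window_stats(lrr: np.ndarray, manifest: SnpManifest, window_bp: int,
                  min_snps: int) -> tuple[np.ndarray, np.ndarray]:
    """Median LRR and mean GC over non-overlapping windows with enough SNPs."""
    medians, gcs = [], []
    for chrom, sl in manifest.chrom_slices().items():
        pos = manifest.pos_bp[sl]
        vals = lrr[sl]
        gc = manifest.gc_fraction[sl]
        win = (pos - 1) // window_bp
        for wid in np.unique(win):
            m = win == wid
            v = vals[m]
            v = v[np.isfinite(v)]
            if len(v) >= min_snps:
                medians.append(np.median(v))
                gcs.append(gc[m].mean())
    return np.array(medians), np.array(gcs)


def wave_factor(lrr: np.ndarray, manifest: SnpManifest, window_bp: int = 1_000_000,
                min_snps_per_window: int = 10, min_windows: int = 10) -> float:
    """Signed total wave factor.

    Magnitude is the unscaled MAD of per-window median LRR (median absolute
    deviation from the median of window medians, no normal-consistency
    factor); the sign is that of the Pearson correlation between window
    medians and window mean GC.
    """
    med, gc = _window_stats(lrr, manifest, window_bp, min_snps_per_window)
    if len(med) < min_windows:
        raise ValueError(f"wave factor needs >= {min_windows} usable windows, "
                         f"got {len(med)}")
    centre = np.median(med)
    magnitude = float(np.median(np.abs(med - centre)))
    if magnitude == 0.0 or np.std(med) == 0 or np.std(gc) == 0:
        return 0.0
    sign = np.sign(np.corrcoef(med, gc)[0, 1])
    return float(sign * magnitude) if sign != 0 else magnitude


def compute_metrics(panel: IntensityPanel, window_bp: int = 1_000_000,
                    min_snps_per_window: int = 10,
                    min_windows: int = 10) -> SampleQcMetrics:
    man = panel.manifest
    chrom = man.chrom
    lrr_mean = pd.Series(np.nanmean(panel.lrr, axis=1), index=panel.samples)
    dlrs_vals = pd.Series([dlrs(panel.lrr[i], chrom) for i in range(panel.n_samples)],
                          index=panel.samples)
    swf = pd.Series([wave_factor(panel.lrr[i], man, window_bp,
                                 min_snps_per_window, min_windows)
                     for i in range(panel.n_samples)], index=panel.samples)
    cmeans = {c: np.nanmean(panel.lrr[:, sl], axis=1)
              for c, sl in man.chrom_slices().items()}
    chrom_means = pd.DataFrame(cmeans, index=panel.samples)
    return SampleQcMetrics(lrr_mean, dlrs_vals, swf, chrom_means)


# ---------------------------------------------------------------- exclusion

def lrr_mean_fence(means: pd.Series, metrics: SampleQcMetrics | None = None,
                   k: float = 1.5, min_samples: int = 10) -> list[str]:
    """Samples outside [Q1 - k*IQR, Q3 + k*IQR] of the overall LRR mean.

    Quantiles use linear interpolation (numpy default); a value exactly on a
    fence is retained.
    """
    if len(means) < min_samples:
        raise ValueError(f"mean fence needs >= {min_samples} samples")
    q1, q3 = np.quantile(means.to_numpy(float), [0.25, 0.75])
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    out = [s for s, v in means.items() if v < lo or v > hi]
    if metrics is not None:
        for s in out:
            metrics.flag(s, "lrr_mean")
    return out


def dlrs_fence(dlrs_vals: pd.Series, cohorts: pd.Series,
               metrics: SampleQcMetrics | None = None, k: float = 3.5) -> list[str]:
    """Samples with DLRS above the cohort mean + k*SD, fenced per cohort."""
    out = []
    for cohort, vals in dlrs_vals.groupby(cohorts):
        cut = vals.mean() + k * vals.std(ddof=1)
        if not np.isfinite(cut):
            continue
        out.extend(vals.index[vals > cut])
    if metrics is not None:
        for s in out:
            metrics.flag(s, "dlrs")
    return out


def wave_fence(swf: pd.Series, metrics: SampleQcMetrics | None = None,
               k: float = 3.5) -> list[str]:
    """Samples with |SWF| above the global mean + k*SD of |SWF|."""
    mag = swf.abs()
    cut = mag.mean() + k * mag.std(ddof=1)
    out = list(mag.index[mag > cut]) if np.isfinite(cut) else []
    if metrics is not None:
        for s in out:
            metrics.flag(s, "gc_wave")
    return out


def detect_aberrant_chromosomes(panel: IntensityPanel,
                                metrics: SampleQcMetrics | None = None,
                                z_threshold: float = 5.0,
                                min_fraction: float = 0.5,
                                window_bp: int = 1_000_000
                                ) -> list[tuple[str, str]]:
    """Flag (sample, chromosome) pairs that look like whole-chromosome events.

    A chromosome is flagged when its mean LRR deviates from the sample's
    autosomal mean by more than ``z_threshold`` cohort-SDs of that
    chromosome's mean, and windows deviating in the same direction by at
    least half that amount cover >= ``min_fraction`` of the chromosome.
    """
    man = panel.manifest
    slices = man.chrom_slices()
    cm_all = np.column_stack([np.nanmean(panel.lrr[:, sl], axis=1)
                              for sl in slices.values()])
    # per-sample reference: median of chromosome means (robust to one
    # aberrant chromosome); cohort spread: scaled MAD (robust to the
    # aberrant samples being screened for)
    ref = np.nanmedian(cm_all, axis=1)
    flags = []
    for ci, (chrom, sl) in enumerate(slices.items()):
        dev = cm_all[:, ci] - ref
        sd = 1.4826 * np.nanmedian(np.abs(dev - np.nanmedian(dev)))
        if not np.isfinite(sd) or sd == 0:
            continue
        pos = man.pos_bp[sl]
        win = (pos - 1) // window_bp
        wids = np.unique(win)
        for i in np.flatnonzero(np.abs(dev) > z_threshold * sd):
            n_dev = 0
            for wid in wids:
                wvals = panel.lrr[i, sl][win == wid]
                wvals = wvals[np.isfinite(wvals)]
                if len(wvals) == 0:
                    continue
                wdev = wvals.mean() - ref[i]
                if np.sign(wdev) == np.sign(dev[i]) and abs(wdev) >= abs(dev[i]) / 2:
                    n_dev += 1
            if n_dev >= min_fraction * len(wids):
                flags.append((panel.samples[i], chrom))
                if metrics is not None:
                    metrics.flag(panel.samples[i], "chrom_aberration")
    return flags


def exclude_failing_plates(failed_samples: set[str], sheet: SampleSheet,
                           failure_threshold: float = 0.40) -> list[str]:
    """Plates where the QC-failing fraction exceeds the threshold (strict >)."""
    out = []
    for plate, group in sheet.df.groupby("plate_id"):
        n = len(group)
        if n == 0:
            raise ValueError(f"plate {plate} has no samples")
        frac = sum(s in failed_samples for s in group["sample_id"]) / n
        if frac > failure_threshold:
            out.append(plate)
    return sorted(out)


def run_sample_qc(panel: IntensityPanel, sheet: SampleSheet,
                  mean_k: float = 1.5, dlrs_k: float = 3.5, wave_k: float = 3.5,
                  aberration_z: float = 5.0, plate_threshold: float = 0.40,
                  window_bp: int = 1_000_000, min_windows: int = 10
                  ) -> tuple[SampleQcMetrics, list[str]]:
    """Apply the full fence sequence; returns metrics and excluded samples."""
    metrics = compute_metrics(panel, window_bp=window_bp, min_windows=min_windows)
    cohorts = pd.Series(sheet.df.set_index("sample_id")["cohort_id"]
                        .reindex(panel.samples).to_numpy(), index=panel.samples)
    lrr_mean_fence(metrics.lrr_mean, metrics, k=mean_k)
    dlrs_fence(metrics.dlrs, cohorts, metrics, k=dlrs_k)
    wave_fence(metrics.swf, metrics, k=wave_k)
    detect_aberrant_chromosomes(panel, metrics, z_threshold=aberration_z,
                                window_bp=window_bp)
    failed = set(metrics.flags)
    plates = exclude_failing_plates(failed, sheet, plate_threshold)
    plate_of = sheet.df.set_index("sample_id")["plate_id"]
    for s in panel.samples:
        if plate_of.get(s) in plates:
            metrics.flag(s, "failing_plate")
    n_per_plate = sheet.df.groupby("plate_id")["sample_id"].count()
    fail_frac = {p: sum(plate_of.get(s) == p for s in failed) / n
                 for p, n in n_per_plate.items()}
    metrics.plate_failure = pd.Series(fail_frac)
    excluded = [s for s in panel.samples if s in metrics.flags]
    return metrics, excluded
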