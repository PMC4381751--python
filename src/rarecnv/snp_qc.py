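"""Marker-level quality control.

Call-rate filtering is two-pass (samples first, then SNPs on the surviving
samples), Hardy-Weinberg deviations are assessed with the exact conditional
test on the heterozygote count, heterozygosity outliers are fenced at
``k`` SD, and SNPs whose corrected LRR still differs between nuisance groups
(DNA source, typing centre) are removed with a Bonferroni-corrected Welch
t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import lgamma, log

import numpy as np
import pandas as pd
from scipy import stats

from .model import GT_AA, GT_AB, GT_BB, GT_NC, IntensityPanel


@dataclass
class SnpQcReport:
    """Accumulated marker/sample QC metrics and reason-coded exclusions."""

    snp_call_rate: pd.Series | None = None
    sample_call_rate: pd.Series | None = None
    sample_het_rate: pd.Series | None = None
    hwe_p: pd.Series | None = None
    differential_p: pd.Series | None = None
    excluded_snps: dict[str, str] = field(default_factory=dict)      # id -> reason
    excluded_samples: dict[str, str] = field(default_factory=dict)

    def exclude_snp(self, snp_id: str, reason: str) -> None:
        self.excluded_snps.setdefault(snp_id, reason)

    def exclude_sample(self, sample_id: str, reason: str) -> None:
        self.excluded_samples.setdefault(sample_id, reason)


def call_rate_filter(panel: IntensityPanel, report: SnpQcReport | None = None,
                     snp_threshold: float = 0.95,
                     sample_threshold: float = 0.95) -> SnpQcReport:
    """Exclude samples, then SNPs, with genotype call rate strictly below
    threshold.  SNP rates are computed after sample exclusion."""
    if panel.genotype.size == 0:
        raise ValueError("empty genotype matrix")
    report = report or SnpQcReport()
    called = panel.genotype != GT_NC

    sample_rate = called.mean(axis=1)
    report.sample_call_rate = pd.Series(sample_rate, index=panel.samples)
    keep_samples = sample_rate >= sample_threshold
    for s, ok in zip(panel.samples, keep_samples):
        if not ok:
            report.exclude_sample(s, "call_rate")

    snp_rate = called[keep_samples].mean(axis=0) if keep_samples.any() \
        else np.zeros(called.shape[1])
    report.snp_call_rate = pd.Series(snp_rate, index=panel.manifest.snp_ids)
    for m, rate in zip(panel.manifest.snp_ids, snp_rate):
        if rate < snp_threshold:
            report.exclude_snp(m, "call_rate")
    return report


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    Conditions on the allele counts and sums, over all heterozygote counts of
    the right parity, the probabilities of outcomes no more likely than the
    observed one (two-sided, minimum-likelihood convention).
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("need at least one genotyped sample")
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab

    def logw(h: int) -> float:
        aa = (n_a - h) // 2
        bb = (n_b - h) // 2
        return (lgamma(n + 1) - lgamma(aa + 1) - lgamma(h + 1) - lgamma(bb + 1)
                + h * log(2.0))

    hets = range(n_ab % 2, min(n_a, n_b) + 1, 2)
    lw = np.array([logw(h) for h in hets])
    w = np.exp(lw - lw.max())
    w /= w.sum()
    p_obs = w[list(hets).index(n_ab)]
    return float(w[w <= p_obs * (1 + 1e-12)].sum())


def hwe_filter(panel: IntensityPanel, report: SnpQcReport | None = None,
               p_threshold: float = 1e-10,
               controls: np.ndarray | None = None) -> SnpQcReport:
    """Exclude SNPs violating HWE; computed on controls only when a control
    mask is given (CNV-rich SNPs deviate in cases for genuine reasons)."""
    report = report or SnpQcReport()
    gt = panel.genotype if controls is None else panel.genotype[controls]
    pvals = np.ones(gt.shape[1])
    for j in range(gt.shape[1]):
        col = gt[:, j]
        n_aa = int((col == GT_AA).sum())
        n_ab = int((col == GT_AB).sum())
        n_bb = int((col == GT_BB).sum())
        if n_aa + n_ab + n_bb >= 1:
            pvals[j] = hwe_exact_test(n_aa, n_ab, n_bb)
    report.hwe_p = pd.Series(pvals, index=panel.manifest.snp_ids)
    for m, p in zip(panel.manifest.snp_ids, pvals):
        if p < p_threshold:
            report.exclude_snp(m, "hwe")
    return report


def het_outlier_filter(het_rates: pd.Series, report: SnpQcReport | None = None,
                       k: float = 3.5) -> SnpQcReport:
    """Exclude samples whose heterozygosity deviates more than k SD from the
    mean (two-sided).  With zero spread nothing is excluded."""
    if len(het_rates) < 10:
        raise ValueError("heterozygosity fence needs >= 10 samples")
    report = report or SnpQcReport()
    report.sample_het_rate = het_rates
    mu = float(het_rates.mean())
    sd = float(het_rates.std(ddof=1))
    if sd > 0 and np.isfinite(k):
        for s, h in het_rates.items():
            if abs(h - mu) > k * sd:
                report.exclude_sample(s, "heterozygosity")
    return report


def sample_het_rates(panel: IntensityPanel) -> pd.Series:
    gt = panel.genotype
    called = (gt != GT_NC).sum(axis=1)
    het = (gt == GT_AB).sum(axis=1)
    with np.errstate(invalid="ignore"):
        rate = np.where(called > 0, het / np.maximum(called, 1), np.nan)
    return pd.Series(rate, index=panel.samples)


def differential_intensity_filter(lrr: np.ndarray, group_labels: np.ndarray,
                                  snp_ids: np.ndarray,
                                  report: SnpQcReport | None = None,
                                  alpha_family: float = 0.05) -> SnpQcReport:
    """Exclude SNPs with significant two-group LRR differences.

    Welch (unequal-variance) t-test per SNP; the threshold is Bonferroni
    ``alpha_family / m`` over the m testable SNPs.  SNPs with fewer than two
    observations in a group, or zero variance in both, are skipped and
    flagged rather than excluded.
    """
    report = report or SnpQcReport()
    groups = np.unique(group_labels)
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {list(groups)}")
    a = lrr[group_labels == groups[0]]
    b = lrr[group_labels == groups[1]]

    with np.errstate(invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=0, equal_var=False, nan_policy="omit")
        pvals = np.asarray(res.pvalue, float)
    n_a = np.isfinite(a).sum(axis=0)
    n_b = np.isfinite(b).sum(axis=0)
    testable = (n_a >= 2) & (n_b >= 2) & np.isfinite(pvals)
    m = int(testable.sum())
    report.differential_p = pd.Series(np.where(testable, pvals, np.nan), index=snp_ids)
    if m == 0:
        return report
    cut = alpha_family / m
    for snp, p, ok in zip(snp_ids, pvals, testable):
        if ok and p < cut:
            report.exclude_snp(snp, "differential_intensity")
    return report
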