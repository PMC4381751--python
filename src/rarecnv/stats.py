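"""Case-control, family and power statistics for rare CNVs.

Exact 2x2 machinery (Fisher two-sided p by the minimum-likelihood
convention, sample and conditional-MLE odds ratios, exact conditional CI),
burden strata by CNV length/annotation, the CNVR frequency scan with
Bonferroni threshold and QQ export, trio transmission tallies, the exact
CNV TDT (tail-doubled binomial against 1/2), de novo burden, the >3 Mb
large-CNV report, and required-sample-size power grids.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats import contingency

from .hmm import HmmParams, parent_state_evidence
from .model import (CnvCall, CnvrRecord, IntensityPanel, Pedigree, SampleSheet)


# ------------------------------------------------------------------ exact 2x2

@dataclass
class Exact2x2:
    p_two_sided: float
    or_sample: float | None       # cross-product; None on a zero cell
    or_cmle: float                # conditional MLE (0 or inf allowed)
    ci_low: float | None          # exact conditional CI; None on a zero cell
    ci_high: float | None


def fisher_2x2(a: int, b: int, c: int, d: int, alpha: float = 0.05) -> Exact2x2:
    """Exact analysis of [[a, b], [c, d]] (rows: case/control; cols:
    event/non-event).

    p is the two-sided Fisher probability (sum of hypergeometric outcomes no
    more likely than the observed table); or_cmle is the conditional MLE of
    the noncentral hypergeometric odds ratio with its exact tail-inversion
    CI.  On a zero cell the sample OR and a finite CI are undefined and
    reported as None.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    table = np.array([[a, b], [c, d]])
    p = float(sps.fisher_exact(table, alternative="two-sided")[1])
    zero_cell = min(a, b, c, d) == 0
    or_sample = (a * d) / (b * c) if not zero_cell else None
    res = contingency.odds_ratio(table, kind="conditional")
    or_cmle = float(res.statistic)
    if zero_cell:
        ci_low = ci_high = None
    else:
        ci = res.confidence_interval(1 - alpha)
        ci_low, ci_high = float(ci.low), float(ci.high)
    return Exact2x2(p, or_sample, or_cmle, ci_low, ci_high)


# -------------------------------------------------------------------- burden

@dataclass
class BurdenResult:
    stratum: str
    events_case: int
    events_control: int
    n_case: int
    n_control: int
    or_sample: float | None
    or_cmle: float
    ci_low: float | None
    ci_high: float | None
    p_two_sided: float
    rate_ratio: float = float("nan")
    bonferroni_m: int = 1

    @property
    def significant(self) -> bool:
        return self.p_two_sided < 0.05 / self.bonferroni_m


def burden_2x2(events_case: int, events_control: int, n_case: int,
               n_control: int, stratum: str = "all", m: int = 1) -> BurdenResult:
    """Event-count 2x2: CNV events versus remaining samples per phenotype.

    The plain case/control rate ratio is always reported; the exact test and
    odds ratios are undefined (NaN) when event counts exceed the sample
    totals, which only happens in heavily artefactual, uncorrected runs.
    """
    rate_ratio = ((events_case / n_case) / (events_control / n_control)
                  if events_control and n_case and n_control else float("nan"))
    if events_case > n_case or events_control > n_control:
        return BurdenResult(stratum, events_case, events_control, n_case,
                            n_control, None, float("nan"), None, None,
                            float("nan"), rate_ratio, m)
    r = fisher_2x2(events_case, n_case - events_case,
                   events_control, n_control - events_control)
    return BurdenResult(stratum, events_case, events_control, n_case, n_control,
                        r.or_sample, r.or_cmle, r.ci_low, r.ci_high,
                        r.p_two_sided, rate_ratio, m)


# length strata: half-open (lo, hi] bins with strict > for the top bin
DEL_LENGTH_BINS = (("0-20 kb", 0, 20_000), ("20-400 kb", 20_000, 400_000),
                   (">400 kb", 400_000, None))
DUP_LENGTH_BINS = (("0-50 kb", 0, 50_000), ("50-400 kb", 50_000, 400_000),
                   (">400 kb", 400_000, None))


def burden_strata(calls: Sequence[CnvCall], sheet: SampleSheet,
                  n_case: int, n_control: int,
                  annotations: pd.DataFrame | None = None,
                  bonferroni_m: int = 6) -> list[BurdenResult]:
    """Per-class length-stratified burden (deletion bins 0-20/20-400/>400 kb,
    duplication bins 0-50/50-400/>400 kb) plus optional annotation strata."""
    pheno = sheet.df.set_index("sample_id")["phenotype"]
    results = []

    def count(calls_subset: Iterable[CnvCall]) -> tuple[int, int]:
        ca = sum(pheno.get(c.sample_id) == "case" for c in calls_subset)
        co = sum(pheno.get(c.sample_id) == "control" for c in calls_subset)
        return ca, co

    for cls, bins in (("DEL", DEL_LENGTH_BINS), ("DUP", DUP_LENGTH_BINS)):
        sub = [c for c in calls if c.cnv_class == cls]
        ca, co = count(sub)
        results.append(burden_2x2(ca, co, n_case, n_control, f"{cls} all",
                                  bonferroni_m))
        for label, lo, hi in bins:
            in_bin = [c for c in sub if c.length_bp > lo
                      and (hi is None or c.length_bp <= hi)]
            ca, co = count(in_bin)
            results.append(burden_2x2(ca, co, n_case, n_control,
                                      f"{cls} {label}", bonferroni_m))
        if annotations is not None:
            for col in ("gene", "exon", "reference"):
                if col in annotations.columns:
                    flagged = [c for c, f in zip(calls, annotations[col])
                               if f and c.cnv_class == cls]
                    ca, co = count(flagged)
                    results.append(burden_2x2(ca, co, n_case, n_control,
                                              f"{cls} {col}", bonferroni_m))
    return results


# ---------------------------------------------------------------- CNVR scan

def cnvr_scan(cnvrs: Sequence[CnvrRecord], n_case: int, n_control: int,
              fwe: float = 0.05) -> pd.DataFrame:
    """Fisher test of carriers versus non-carriers per CNVR.

    Returns a table sorted by p with the Bonferroni threshold ``fwe / m``
    attached, plus uniform quantiles for a QQ plot.
    """
    rows = []
    for r in cnvrs:
        res = fisher_2x2(r.carriers_case, n_case - r.carriers_case,
                         r.carriers_control, n_control - r.carriers_control)
        rows.append((r.cnvr_id, r.chrom, r.start_bp, r.end_bp, r.cnv_class,
                     r.carriers_case, r.carriers_control, res.or_sample,
                     res.or_cmle, res.p_two_sided))
    df = pd.DataFrame(rows, columns=["cnvr_id", "chrom", "start_bp", "end_bp",
                                     "cnv_class", "carriers_case",
                                     "carriers_control", "or_sample", "or_cmle",
                                     "p"])
    if df.empty:
        df["bonferroni_threshold"] = df["expected_p"] = []
        return df
    m = len(df)
    df = df.sort_values("p", kind="stable").reset_index(drop=True)
    df["bonferroni_threshold"] = fwe / m
    df["expected_p"] = (np.arange(m) + 0.5) / m   # uniform quantiles for QQ
    return df


def bonferroni_threshold(m: int, fwe: float = 0.05) -> float:
    if m < 1:
        raise ValueError("need at least one test")
    return fwe / m


# ------------------------------------------------------------------ families

def _overlaps(a: CnvCall, b: CnvCall, reciprocal: float = 0.5) -> bool:
    """Same-class calls sharing >= 1 bp with reciprocal overlap >= threshold."""
    if a.chrom != b.chrom or a.cnv_class != b.cnv_class:
        return False
    lo, hi = max(a.start_bp, b.start_bp), min(a.end_bp, b.end_bp)
    if lo > hi:
        return False
    shared = hi - lo + 1
    return shared >= reciprocal * a.length_bp and shared >= reciprocal * b.length_bp


@dataclass
class TransmissionTally:
    transmitted_affected: int = 0
    possible_affected: int = 0
    transmitted_unaffected: int = 0
    possible_unaffected: int = 0

    def rate(self, affection: str) -> float:
        t, n = ((self.transmitted_affected, self.possible_affected)
                if affection == "affected"
                else (self.transmitted_unaffected, self.possible_unaffected))
        return t / n if n else float("nan")

    @property
    def burden_ratio(self) -> float:
        return self.rate("affected") / self.rate("unaffected")


def transmission_counts(calls: Sequence[CnvCall], pedigree: Pedigree,
                        reciprocal: float = 0.5
                        ) -> tuple[pd.DataFrame, dict[str, TransmissionTally]]:
    """Tally CNV transmissions from carrier parents to children.

    The denominator is the number of children times the number of
    CNV-carrying parents in each family, summed across all CNVs; a child
    counts as transmitted-to when it carries an overlapping same-class call
    (>= 1 bp and >= ``reciprocal`` reciprocal overlap).  Children with both
    parents missing are excluded from denominators.  Returns per-parental-CNV
    rows and class-level aggregate tallies.
    """
    by_sample: dict[str, list[CnvCall]] = {}
    for c in calls:
        by_sample.setdefault(c.sample_id, []).append(c)
    ped = pedigree.df
    children = ped[ped["father_id"].notna() & ped["mother_id"].notna()]

    rows = []
    agg = {"DEL": TransmissionTally(), "DUP": TransmissionTally()}
    for r in children.itertuples():
        for parent_id in (r.father_id, r.mother_id):
            for pc in by_sample.get(parent_id, []):
                hit = any(_overlaps(pc, cc, reciprocal)
                          for cc in by_sample.get(r.individual_id, []))
                rows.append((parent_id, r.individual_id, r.affection, pc.chrom,
                             pc.start_bp, pc.end_bp, pc.cnv_class, hit))
                t = agg[pc.cnv_class]
                if r.affection == "affected":
                    t.possible_affected += 1
                    t.transmitted_affected += hit
                elif r.affection == "unaffected":
                    t.possible_unaffected += 1
                    t.transmitted_unaffected += hit
    df = pd.DataFrame(rows, columns=["parent_id", "child_id", "affection",
                                     "chrom", "start_bp", "end_bp", "cnv_class",
                                     "transmitted"])
    return df, agg


def tdt_exact(transmitted: int, possible: int) -> float:
    """Two-sided exact binomial test of transmission against 1/2 by doubling
    the smaller tail, capped at 1."""
    if possible < 1:
        raise ValueError("possible transmissions must be >= 1")
    if not 0 <= transmitted <= possible:
        raise ValueError("transmitted outside [0, possible]")
    lower = sps.binom.cdf(transmitted, possible, 0.5)
    upper = sps.binom.sf(transmitted - 1, possible, 0.5)
    return float(min(1.0, 2.0 * min(lower, upper)))


@dataclass
class TdtResult:
    cnvr_id: str
    transmitted_aff: int
    possible_aff: int
    transmitted_unaff: int
    possible_unaff: int
    p_affected: float


def tdt_per_cnvr(cnvrs: Sequence[CnvrRecord], calls: Sequence[CnvCall],
                 pedigree: Pedigree, reciprocal: float = 0.5) -> list[TdtResult]:
    """TDT per CNVR: transmissions of member-overlapping parental calls."""
    results = []
    for r in cnvrs:
        member = [c for c in calls if any(_overlaps(c, mc, 0.0)
                                          for mc in r.member_calls)]
        df, agg = transmission_counts(member, pedigree, reciprocal)
        t = agg[r.cnv_class]
        if t.possible_affected:
            results.append(TdtResult(r.cnvr_id, t.transmitted_affected,
                                     t.possible_affected,
                                     t.transmitted_unaffected,
                                     t.possible_unaffected,
                                     tdt_exact(t.transmitted_affected,
                                               t.possible_affected)))
    return results


# ------------------------------------------------------------------- de novo

def denovo_burden(calls: Sequence[CnvCall], pedigree: Pedigree,
                  panel: IntensityPanel, params: HmmParams | None = None,
                  reciprocal: float = 0.5, llr_threshold: float = 0.0
                  ) -> tuple[pd.DataFrame, Exact2x2]:
    """De novo calls (no parental overlap AND both parents' intensities
    unsupported under the relaxed re-test) and the affected-versus-unaffected
    exact test on children carrying at least one de novo.

    Children whose parental evidence is unknown for a call are excluded from
    that call; the 2x2 compares children-with-de-novo to children-without by
    affection.
    """
    params = params or HmmParams()
    by_sample: dict[str, list[CnvCall]] = {}
    for c in calls:
        by_sample.setdefault(c.sample_id, []).append(c)
    man = panel.manifest
    slices = man.chrom_slices()
    pos, pfb = man.pos_bp, man.pfb
    ped = pedigree.df
    children = ped[ped["father_id"].notna() & ped["mother_id"].notna()]

    rows = []
    denovo_children: dict[str, set[str]] = {"affected": set(), "unaffected": set()}
    counted_children: dict[str, set[str]] = {"affected": set(), "unaffected": set()}
    for r in children.itertuples():
        if r.affection not in denovo_children:
            continue
        counted_children[r.affection].add(r.individual_id)
        for call in by_sample.get(r.individual_id, []):
            inherited = any(_overlaps(call, pc, reciprocal)
                            for pid in (r.father_id, r.mother_id)
                            for pc in by_sample.get(pid, []))
            if inherited:
                continue
            sl = slices[call.chrom]
            j0 = sl.start + int(np.searchsorted(pos[sl], call.start_bp, "left"))
            j1 = sl.start + int(np.searchsorted(pos[sl], call.end_bp, "right"))
            verdicts = []
            for pid in (r.father_id, r.mother_id):
                pi = panel.sample_index(pid)
                verdicts.append(parent_state_evidence(
                    call, panel.lrr[pi, j0:j1], panel.baf[pi, j0:j1],
                    pfb[j0:j1], params, llr_threshold))
            if "unknown" in verdicts:
                status = "unknown"
            elif "supported" in verdicts:
                status = "parental_evidence"
            else:
                status = "de_novo"
                denovo_children[r.affection].add(r.individual_id)
            rows.append((r.individual_id, call.chrom, call.start_bp, call.end_bp,
                         call.cnv_class, call.copy_number, r.affection, status))
    df = pd.DataFrame(rows, columns=["child_id", "chrom", "start_bp", "end_bp",
                                     "cnv_class", "copy_number", "affection",
                                     "status"])
    n_aff = len(counted_children["affected"])
    n_unaff = len(counted_children["unaffected"])
    k_aff = len(denovo_children["affected"])
    k_unaff = len(denovo_children["unaffected"])
    test = fisher_2x2(k_aff, max(n_aff - k_aff, 0), k_unaff,
                      max(n_unaff - k_unaff, 0))
    return df, test


# --------------------------------------------------------------- large CNVs

def large_cnv_table(calls: Sequence[CnvCall], sheet: SampleSheet,
                    n_case: int, n_control: int,
                    gene_names: Sequence[list[str]] | None = None,
                    min_len_bp: int = 3_000_000) -> tuple[pd.DataFrame, Exact2x2]:
    """Report calls strictly longer than ``min_len_bp`` and test carriers.

    Rows follow the reporting convention locus/length/genes(+n)/phenotype/
    SNP support; the 2x2 compares distinct carrier counts by phenotype.
    """
    from .cnvr import gene_label
    pheno = sheet.df.set_index("sample_id")["phenotype"]
    rows, carriers = [], {"case": set(), "control": set()}
    for i, c in enumerate(calls):
        if c.length_bp <= min_len_bp:
            continue
        ph = pheno.get(c.sample_id, "unknown")
        if ph in carriers:
            carriers[ph].add(c.sample_id)
        genes = gene_names[i] if gene_names is not None else []
        rows.append((f"{c.chrom}:{c.start_bp / 1e6:.2f}-{c.end_bp / 1e6:.2f}",
                     c.length_bp / 1e6, gene_label(genes), c.cnv_class, ph,
                     c.n_snps, c.sample_id))
    df = pd.DataFrame(rows, columns=["locus", "length_mb", "genes", "cnv_class",
                                     "phenotype", "n_snps", "sample_id"])
    k_case, k_ctrl = len(carriers["case"]), len(carriers["control"])
    test = fisher_2x2(k_case, n_case - k_case, k_ctrl, n_control - k_ctrl)
    return df, test


# -------------------------------------------------------------------- power

@dataclass
class PowerGrid:
    or_values: np.ndarray
    freq_values: np.ndarray
    alpha: float
    power_target: float
    required_units: np.ndarray   # total N in units of 10,000; NaN = undefined

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.required_units, index=self.freq_values,
                            columns=self.or_values)


def _required_n_normal(or_value: float, freq: float, alpha: float,
                       power: float) -> float:
    """Total N (1:1) for a two-sided log-OR test by normal approximation."""
    p0 = freq
    p1 = or_value * p0 / (1.0 + p0 * (or_value - 1.0))
    z_a = sps.norm.ppf(1.0 - alpha / 2.0)
    z_b = sps.norm.ppf(power)
    var_terms = (1.0 / p1 + 1.0 / (1.0 - p1) + 1.0 / p0 + 1.0 / (1.0 - p0))
    return 2.0 * (z_a + z_b) ** 2 * var_terms / np.log(or_value) ** 2


def monte_carlo_power(or_value: float, freq: float, n_total: int,
                      alpha: float, n_rep: int = 400,
                      seed: int = 0) -> float:
    """Empirical power of the two-sided Fisher test at a 1:1 design."""
    rng = np.random.default_rng(seed)
    n1 = n0 = n_total // 2
    p0 = freq
    p1 = or_value * p0 / (1.0 + p0 * (or_value - 1.0))
    hits = 0
    for _ in range(n_rep):
        a = rng.binomial(n1, p1)
        c = rng.binomial(n0, p0)
        p = sps.fisher_exact([[a, n1 - a], [c, n0 - c]])[1]
        hits += p < alpha
    return hits / n_rep


def power_grid(or_values: Sequence[float], freq_values: Sequence[float],
               alpha: float = 5e-5, power: float = 0.8, ratio: float = 1.0,
               method: str = "normal", unit: int = 10_000,
               max_units: int = 10_000, seed: int = 0) -> PowerGrid:
    """Smallest total sample size (in ``unit`` multiples, 1:1 split) with the
    target power per (OR, frequency) cell.  OR <= 1 cells are undefined.

    method "normal": closed-form log-OR approximation rounded up to the next
    unit; "monte_carlo": smallest unit multiple whose simulated exact-test
    power reaches the target.
    """
    ors = np.asarray(or_values, float)
    freqs = np.asarray(freq_values, float)
    if np.any((freqs <= 0) | (freqs >= 1)):
        raise ValueError("frequencies must be in (0, 1)")
    out = np.full((len(freqs), len(ors)), np.nan)
    for i, f in enumerate(freqs):
        for j, o in enumerate(ors):
            if o <= 1.0:
                continue
            if method == "normal":
                n = _required_n_normal(o, f, alpha, power)
                units = int(np.ceil(n / unit))
            elif method == "monte_carlo":
                units = None
                u = 1
                while u <= max_units:
                    if monte_carlo_power(o, f, u * unit, alpha,
                                         seed=seed + 31 * u) >= power:
                        units = u
                        break
                    u = u * 2 if u >= 4 else u + 1
                if units is None:
                    continue
            else:
                raise ValueError(f"unknown method {method!r}")
            out[i, j] = min(units, max_units)
    return PowerGrid(ors, freqs, alpha, power, out)
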