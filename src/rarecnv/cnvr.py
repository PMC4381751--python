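"""CNV-level QC filters, CNVR grouping and annotation overlap.

A copy-number-variable region (CNVR) is a set of mutually overlapping calls
that share at least one common nucleotide; deletions and duplications are
grouped separately.  The grouping sweep reproduces PLINK ``--segment-group``
semantics, including a call belonging to more than one CNVR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import CnvCall, CnvrRecord, RegionSet, SampleSheet


@dataclass
class CnvFilterReport:
    """Reason-coded CNV exclusions plus per-sample / per-plate counts."""

    dropped: dict[str, list[CnvCall]] = field(default_factory=dict)
    quality_flagged: list[CnvCall] = field(default_factory=list)
    sample_counts: pd.DataFrame | None = None
    plate_rates: pd.Series | None = None

    def drop(self, rule: str, calls: Iterable[CnvCall]) -> None:
        self.dropped.setdefault(rule, []).extend(calls)


def _count_fence(counts: pd.Series, k: float) -> set[str]:
    """Index entries exceeding mean + k*SD (population over current cohort).

    The fence never drops below 1: when the cohort mean count is tiny the
    naive fence falls under one event and would label every carrier an
    outlier, which inverts the rule's purpose (removing contaminated
    samples with extreme counts).
    """
    if len(counts) < 2:
        return set()
    cut = max(counts.mean() + k * counts.std(ddof=1), 1.0)
    return set(counts.index[counts > cut])


def apply_cnv_level_filters(calls: Sequence[CnvCall], sheet: SampleSheet,
                            mask_regions: list[RegionSet] | None = None,
                            min_snps: int = 6, count_sd: float = 3.0,
                            plate_sd: float = 3.0, quality_min: float = 0.95
                            ) -> tuple[list[CnvCall], CnvFilterReport]:
    """Call-level QC in fixed order.

    1. drop calls supported by fewer than ``min_snps`` SNPs;
    2. drop all calls of samples whose total, DEL or DUP call count exceeds
       the cohort mean + ``count_sd`` SD;
    3. drop all calls on plates whose mean CNV count per sample exceeds the
       global mean + ``plate_sd`` SD;
    4. drop calls overlapping a masked region by >= 1 bp;
    5. flag (never drop here) calls with quality below ``quality_min`` —
       quality-based dropping happens at the CNVR stage.
    """
    report = CnvFilterReport()
    plate_of = sheet.df.set_index("sample_id")["plate_id"]
    for c in calls:
        if c.sample_id not in plate_of.index:
            raise ValueError(f"sample {c.sample_id!r} missing from the sample sheet")

    kept = [c for c in calls if c.n_snps >= min_snps]
    report.drop("min_snps", [c for c in calls if c.n_snps < min_snps])

    df = pd.DataFrame({"sample": [c.sample_id for c in kept],
                       "cls": [c.cnv_class for c in kept]})
    all_samples = pd.Index(sheet.sample_ids)
    totals = df.groupby("sample").size().reindex(all_samples, fill_value=0)
    outliers: set[str] = _count_fence(totals, count_sd)
    for cls in ("DEL", "DUP"):
        sub = df[df.cls == cls].groupby("sample").size().reindex(all_samples, fill_value=0)
        outliers |= _count_fence(sub, count_sd)
    report.sample_counts = pd.DataFrame({"total": totals})
    report.drop("sample_cnv_count", [c for c in kept if c.sample_id in outliers])
    kept = [c for c in kept if c.sample_id not in outliers]

    per_sample = pd.Series([c.sample_id for c in kept]).value_counts() \
        .reindex(all_samples, fill_value=0)
    plate_mean = per_sample.groupby(plate_of.reindex(all_samples)).mean()
    bad_plates = _count_fence(plate_mean, plate_sd)
    report.plate_rates = plate_mean
    report.drop("plate_cnv_rate", [c for c in kept if plate_of[c.sample_id] in bad_plates])
    kept = [c for c in kept if plate_of[c.sample_id] not in bad_plates]

    if mask_regions:
        masked = [c for c in kept if any(
            rs.overlapping(c.chrom, c.start_bp, c.end_bp) for rs in mask_regions)]
        report.drop("region_mask", masked)
        masked_set = set(map(id, masked))
        kept = [c for c in kept if id(c) not in masked_set]

    report.quality_flagged = [c for c in kept if c.quality < quality_min]
    return kept, report


# ----------------------------------------------------------------- grouping

def group_cnvrs(calls: Sequence[CnvCall], n_samples: int,
                sheet: SampleSheet | None = None,
                id_prefix: str = "cnvr") -> list[CnvrRecord]:
    """Group calls of one class into CNVRs by the common-intersection sweep.

    Calls are swept in (chrom, start, end) order while a running common
    interval is maintained; a call joins the open group iff it intersects
    that interval.  When it cannot, the group closes and a new one opens
    seeded with the incoming call plus any members of the closed group that
    overlap it (so a single call may belong to more than one CNVR).  Groups
    whose member set is contained in another's are discarded.  CNVR bounds
    are the min start / max end of members.
    """
    classes = {c.cnv_class for c in calls}
    if len(classes) > 1:
        raise ValueError("group DEL and DUP calls separately")
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    ordered = sorted(calls, key=lambda c: (c.chrom, c.start_bp, c.end_bp, c.sample_id))
    groups: list[list[CnvCall]] = []
    open_members: list[CnvCall] = []
    lo = hi = 0
    chrom = None
    for c in ordered:
        if open_members and c.chrom == chrom and c.start_bp <= hi and c.end_bp >= lo:
            open_members.append(c)
            lo, hi = max(lo, c.start_bp), min(hi, c.end_bp)
            continue
        if open_members:
            groups.append(open_members)
            if c.chrom == chrom:
                shared = [m for m in open_members
                          if m.start_bp <= c.end_bp and m.end_bp >= c.start_bp]
            else:
                shared = []
            open_members = shared + [c]
        else:
            open_members = [c]
        chrom = c.chrom
        lo = max(m.start_bp for m in open_members)
        hi = min(m.end_bp for m in open_members)
    if open_members:
        groups.append(open_members)

    # drop groups strictly contained in another (possible at chain joins)
    keyed = [frozenset(map(id, g)) for g in groups]
    keep = [i for i, k in enumerate(keyed)
            if not any(i != j and k < keyed[j] for j in range(len(keyed)))]
    seen: set[frozenset] = set()
    out: list[CnvrRecord] = []
    pheno = sheet.df.set_index("sample_id")["phenotype"] if sheet is not None else None
    for i in keep:
        if keyed[i] in seen:
            continue
        seen.add(keyed[i])
        g = groups[i]
        carriers = {c.sample_id for c in g}
        n_case = n_ctrl = 0
        if pheno is not None:
            n_case = sum(pheno.get(s) == "case" for s in carriers)
            n_ctrl = sum(pheno.get(s) == "control" for s in carriers)
        rec = CnvrRecord(cnvr_id=f"{id_prefix}{len(out):04d}",
                         chrom=g[0].chrom,
                         start_bp=min(c.start_bp for c in g),
                         end_bp=max(c.end_bp for c in g),
                         member_calls=list(g),
                         carriers_case=n_case, carriers_control=n_ctrl,
                         frequency=len(carriers) / n_samples)
        out.append(rec)
    return out


def filter_rare_cnvrs(cnvrs: Sequence[CnvrRecord], n_samples: int,
                      call_stage_max: float = 0.05, rare_max: float = 0.01,
                      quality_min: float = 0.95,
                      max_fail_fraction: float = 0.20) -> list[CnvrRecord]:
    """Two-stage rarity plus CNVR-level quality filtering.

    Upstream, calls are retained up to ``call_stage_max`` frequency to avoid
    boundary artefacts near common variants; here member calls with quality
    below ``quality_min`` are dropped, whole CNVRs with more than
    ``max_fail_fraction`` of members failing quality are discarded, and
    CNVRs with carrier frequency above ``rare_max`` are removed.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    out = []
    for r in cnvrs:
        ok = [c for c in r.member_calls if c.quality >= quality_min]
        n_fail = len(r.member_calls) - len(ok)
        if not ok or n_fail / len(r.member_calls) > max_fail_fraction:
            continue
        carriers = {c.sample_id for c in ok}
        freq = len(carriers) / n_samples
        if freq > rare_max:
            continue
        out.append(CnvrRecord(r.cnvr_id, r.chrom,
                              min(c.start_bp for c in ok),
                              max(c.end_bp for c in ok), ok,
                              frequency=freq))
    return out  # carrier-by-phenotype counts: call recount_carriers(out, sheet)


def recount_carriers(cnvrs: Sequence[CnvrRecord], sheet: SampleSheet) -> None:
    """Refresh carrier-by-phenotype counts from member calls, in place."""
    pheno = sheet.df.set_index("sample_id")["phenotype"]
    for r in cnvrs:
        carriers = {c.sample_id for c in r.member_calls}
        r.carriers_case = sum(pheno.get(s) == "case" for s in carriers)
        r.carriers_control = sum(pheno.get(s) == "control" for s in carriers)


def annotate_overlaps(calls: Sequence[CnvCall],
                      region_sets: dict[str, RegionSet]) -> pd.DataFrame:
    """Per-call boolean overlap flags (>= 1 shared bp) and overlapped names.

    Returns a DataFrame indexed like ``calls`` with one boolean column per
    region set plus ``<label>_names`` columns listing overlapped region
    names (Table-style ``GENE +n`` reporting is built from these).
    """
    rows = []
    for c in calls:
        row = {}
        for label, rs in region_sets.items():
            hits = rs.overlapping(c.chrom, c.start_bp, c.end_bp)
            row[label] = bool(hits)
            if rs.names:
                row[f"{label}_names"] = [rs.names[i] for i in hits]
        rows.append(row)
    return pd.DataFrame(rows)


def gene_label(names: list[str]) -> str:
    """Reporting style: first gene plus ``+n`` for the remainder."""
    if not names:
        return "Intergenic"
    if len(names) == 1:
        return names[0]
    return f"{names[0]} +{len(names) - 1}"
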