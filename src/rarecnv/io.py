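"""Readers and writers for the plain-text formats the pipeline touches.

Formats: tab-delimited long intensity files, PFB files (Name/Chr/Position/PFB),
CSV sample sheets, PLINK 6-column FAM pedigrees, BED region sets, and a
PennCNV-style one-line-per-call CNV interchange format with a BED export.

Internal coordinates are 1-based inclusive; BED files (0-based half-open)
are converted at this boundary.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np
import pandas as pd

from .model import (GT_LABELS, GT_NAMES, GT_NC, CnvCall, IntensityPanel,
                    Pedigree, Region, RegionSet, SampleSheet, SnpManifest)

_NA_STRINGS = {"", "NA", "NaN", "nan", ".", "null"}


# ---------------------------------------------------------------- manifest

def read_manifest(path) -> SnpManifest:
    """Read a manifest TSV with columns snp_id, chrom, pos_bp, gc_fraction, pfb."""
    return SnpManifest(pd.read_csv(path, sep="\t"))


def write_manifest(manifest: SnpManifest, path) -> None:
    manifest.df.to_csv(path, sep="\t", index=False)


def read_pfb(path) -> pd.DataFrame:
    """Read a PennCNV-style PFB file (columns Name, Chr, Position, PFB)."""
    df = pd.read_csv(path, sep="\t")
    expected = ["Name", "Chr", "Position", "PFB"]
    if list(df.columns[:4]) != expected:
        raise ValueError(f"PFB file must have columns {expected}, got {list(df.columns)}")
    return df


def write_pfb(manifest: SnpManifest, path) -> None:
    out = pd.DataFrame({"Name": manifest.snp_ids, "Chr": manifest.chrom,
                        "Position": manifest.pos_bp, "PFB": manifest.pfb})
    out.to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------ sample sheet

def read_sample_sheet(path) -> SampleSheet:
    return SampleSheet(pd.read_csv(path, dtype={"sample_id": str, "plate_id": str,
                                                "cohort_id": str}))


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.df.to_csv(path, index=False)


# ---------------------------------------------------------------- pedigree

_AFFECTION = {"1": "unaffected", "2": "affected", "0": "unknown", "-9": "unknown"}
_AFFECTION_INV = {"unaffected": "1", "affected": "2", "unknown": "0"}
_SEX = {"1": "M", "2": "F", "0": "unknown"}
_SEX_INV = {"M": "1", "F": "2", "unknown": "0"}


def read_fam(path) -> Pedigree:
    """Read a PLINK 6-column FAM file (fid iid father mother sex affection)."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6:
                raise ValueError(f"{path}:{ln}: expected 6 columns, got {len(fields)}")
            fid, iid, fa, mo, sex, aff = fields
            rows.append((fid, iid,
                         None if fa == "0" else fa,
                         None if mo == "0" else mo,
                         _SEX.get(sex, "unknown"),
                         _AFFECTION.get(aff, "unknown")))
    return Pedigree(pd.DataFrame(rows, columns=list(Pedigree.REQUIRED)))


def write_fam(ped: Pedigree, path) -> None:
    with open(path, "w") as fh:
        for r in ped.df.itertuples():
            fa = "0" if pd.isna(r.father_id) else r.father_id
            mo = "0" if pd.isna(r.mother_id) else r.mother_id
            fh.write(f"{r.family_id} {r.individual_id} {fa} {mo} "
                     f"{_SEX_INV.get(r.sex, '0')} {_AFFECTION_INV.get(r.affection, '0')}\n")


# ---------------------------------------------------------------- regions

def read_regions_bed(path, label: str = "") -> RegionSet:
    """Read a BED file (0-based, half-open) into 1-based inclusive regions.

    A 4th column, when present, is kept as the region name (e.g. gene symbol).
    """
    regions, names = [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{ln}: BED line needs >= 3 fields")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if end < start:
                raise ValueError(f"{path}:{ln}: end < start")
            if end == start:  # zero-length half-open interval: no base covered
                raise ValueError(f"{path}:{ln}: empty interval")
            regions.append(Region(chrom, start + 1, end))
            names.append(fields[3] if len(fields) > 3 else f"{label}_{ln}")
    return RegionSet(regions, label=label, names=names)


def write_regions_bed(rs: RegionSet, path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(rs.regions):
            name = rs.names[i] if rs.names else rs.label
            fh.write(f"{r.chrom}\t{r.start_bp - 1}\t{r.end_bp}\t{name}\n")


# ------------------------------------------------------- long intensity IO

def read_intensity_long(path, manifest: SnpManifest, sheet: SampleSheet) -> IntensityPanel:
    """Read a tab-delimited long file (sample_id, snp_id, lrr, baf, genotype).

    Column order is header-driven; absent (sample, SNP) rows become missing
    cells.  Unknown sample or SNP ids are hard errors.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "snp_id": str,
                                            "lrr": str, "baf": str, "genotype": str})
    needed = {"sample_id", "snp_id", "lrr", "baf", "genotype"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"long file missing columns: {sorted(missing)}")

    snp_idx = manifest.indexer(df["snp_id"])
    samp_idx = sheet.indexer(df["sample_id"])

    n_s, n_m = len(sheet), len(manifest)
    lrr = np.full((n_s, n_m), np.nan)
    baf = np.full((n_s, n_m), np.nan)
    gt = np.full((n_s, n_m), GT_NC, dtype=np.int8)

    def parse_num(col: str) -> np.ndarray:
        raw = df[col].astype(str).str.strip()
        vals = np.full(len(raw), np.nan)
        ok = ~raw.isin(_NA_STRINGS)
        try:
            vals[ok.to_numpy()] = raw[ok].astype(float).to_numpy()
        except ValueError:
            for i, (v, good) in enumerate(zip(raw, ok)):
                if good:
                    try:
                        float(v)
                    except ValueError:
                        raise ValueError(
                            f"non-numeric {col} {v!r} at data line {i + 1}") from None
            raise
        return vals

    lrr[samp_idx, snp_idx] = parse_num("lrr")
    baf[samp_idx, snp_idx] = parse_num("baf")
    gt_codes = df["genotype"].map(lambda g: GT_LABELS.get(str(g).strip(), GT_NC))
    gt[samp_idx, snp_idx] = gt_codes.to_numpy(dtype=np.int8)

    return IntensityPanel(list(sheet.sample_ids), manifest, lrr, baf, gt)


def write_intensity_long(panel: IntensityPanel, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tsnp_id\tlrr\tbaf\tgenotype\n")
        snps = panel.manifest.snp_ids
        for i, s in enumerate(panel.samples):
            for j, m in enumerate(snps):
                l, b = panel.lrr[i, j], panel.baf[i, j]
                # str() is the shortest exact round-trip representation
                fh.write(f"{s}\t{m}\t"
                         f"{'NA' if math.isnan(l) else str(float(l))}\t"
                         f"{'NA' if math.isnan(b) else str(float(b))}\t"
                         f"{GT_NAMES[int(panel.genotype[i, j])]}\n")


# ------------------------------------------------------------- CNV call IO

def write_cnv_calls(calls: Iterable[CnvCall], path) -> None:
    """One line per call: ``chrN:start-end numsnp=K cn=C sample=S quality=Q``."""
    with open(path, "w") as fh:
        for c in calls:
            fh.write(f"{c.chrom}:{c.start_bp}-{c.end_bp} numsnp={c.n_snps} "
                     f"cn={c.copy_number} sample={c.sample_id} quality={c.quality:.6f}\n")


def read_cnv_calls(path) -> list[CnvCall]:
    calls = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                locus, *kvs = line.split()
                chrom, span = locus.split(":")
                start, end = span.split("-")
                kv = dict(item.split("=", 1) for item in kvs)
                call = CnvCall(sample_id=kv["sample"], chrom=chrom,
                               start_bp=int(start), end_bp=int(end),
                               copy_number=int(kv["cn"]), n_snps=int(kv["numsnp"]),
                               quality=float(kv["quality"]))
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}:{ln}: malformed call line: {exc}") from exc
            calls.append(call)
    return calls


def write_cnv_bed(calls: Iterable[CnvCall], path) -> None:
    """BED export: 0-based half-open, name=sample;cn=C, score=round(1000*quality)."""
    with open(path, "w") as fh:
        for c in calls:
            fh.write(f"{c.chrom}\t{c.start_bp - 1}\t{c.end_bp}\t"
                     f"{c.sample_id};cn={c.copy_number}\t{round(1000 * c.quality)}\n")
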