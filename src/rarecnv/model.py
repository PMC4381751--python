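"""Core domain types for the rare-CNV pipeline.

Conventions used throughout the package:

* Genomic coordinates are 1-based and inclusive at both ends.  BED I/O
  converts at the boundary (see :mod:`rarecnv.io`).
* CNV length is ``end_bp - start_bp + 1``.
* Missing LRR/BAF are ``NaN``, never 0 — an LRR of 0 is the diploid mean.
* Genotypes are coded 0 (AA), 1 (AB), 2 (BB) with -1 for no-calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

GT_AA, GT_AB, GT_BB, GT_NC = 0, 1, 2, -1
GT_LABELS = {"AA": GT_AA, "AB": GT_AB, "BA": GT_AB, "BB": GT_BB, "NC": GT_NC}
GT_NAMES = {GT_AA: "AA", GT_AB: "AB", GT_BB: "BB", GT_NC: "NC"}


class SnpManifest:
    """Per-SNP annotation: chromosome, position, probe GC fraction, PFB.

    Wraps a DataFrame sorted by (chrom, pos_bp); defines marker order for
    every matrix in the pipeline.
    """

    REQUIRED = ("snp_id", "chrom", "pos_bp", "gc_fraction", "pfb")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        df = df.loc[:, list(self.REQUIRED)].copy()
        df["pos_bp"] = df["pos_bp"].astype(np.int64)
        if df["snp_id"].duplicated().any():
            dup = df.loc[df["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise ValueError(f"duplicate snp_id in manifest: {dup!r}")
        if (df["pos_bp"] < 1).any():
            raise ValueError("manifest positions must be >= 1")
        for col in ("gc_fraction", "pfb"):
            v = df[col].to_numpy(float)
            if np.any((v < 0) | (v > 1)):
                raise ValueError(f"{col} outside [0, 1]")
        df = df.sort_values(["chrom", "pos_bp"], kind="stable").reset_index(drop=True)
        self.df = df
        self._index = pd.Index(df["snp_id"])

    @property
    def snp_ids(self) -> np.ndarray:
        return self.df["snp_id"].to_numpy()

    @property
    def chrom(self) -> np.ndarray:
        return self.df["chrom"].to_numpy()

    @property
    def pos_bp(self) -> np.ndarray:
        return self.df["pos_bp"].to_numpy()

    @property
    def gc_fraction(self) -> np.ndarray:
        return self.df["gc_fraction"].to_numpy(float)

    @property
    def pfb(self) -> np.ndarray:
        return self.df["pfb"].to_numpy(float)

    def __len__(self) -> int:
        return len(self.df)

    def indexer(self, snp_ids: Iterable[str]) -> np.ndarray:
        idx = self._index.get_indexer(pd.Index(snp_ids))
        if (idx < 0).any():
            bad = np.asarray(list(snp_ids))[idx < 0][:5]
            raise KeyError(f"snp_id not in manifest: {list(bad)}")
        return idx

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous slice of marker indices per chromosome (manifest order)."""
        out: dict[str, slice] = {}
        chroms = self.chrom
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                out[chroms[start]] = slice(start, i)
                start = i
        return out

    def subset(self, mask: np.ndarray) -> "SnpManifest":
        return SnpManifest(self.df.loc[np.asarray(mask)].reset_index(drop=True))

    def n_snps_in(self, chrom: str, start_bp: int, end_bp: int) -> int:
        sl = self.chrom_slices().get(chrom)
        if sl is None:
            return 0
        pos = self.pos_bp[sl]
        return int(np.searchsorted(pos, end_bp, "right") - np.searchsorted(pos, start_bp, "left"))


class SampleSheet:
    """Sample metadata: phenotype, plate, cohort (typing centre), DNA source, sex."""

    REQUIRED = ("sample_id", "phenotype", "plate_id", "cohort_id")
    OPTIONAL = {"dna_source": "unknown", "sex": "unknown"}
    PHENOTYPES = {"case", "control", "unknown"}

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        df = df.copy()
        for col, default in self.OPTIONAL.items():
            if col not in df.columns:
                df[col] = default
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample_id: {dup!r}")
        bad = set(df["phenotype"]) - self.PHENOTYPES
        if bad:
            raise ValueError(f"unknown phenotype values: {sorted(bad)}")
        if df["plate_id"].isna().any() or df["cohort_id"].isna().any():
            raise ValueError("every sample needs a plate_id and cohort_id")
        self.df = df.reset_index(drop=True)
        self._index = pd.Index(df["sample_id"])

    @property
    def sample_ids(self) -> np.ndarray:
        return self.df["sample_id"].to_numpy()

    def __len__(self) -> int:
        return len(self.df)

    def indexer(self, sample_ids: Iterable[str]) -> np.ndarray:
        idx = self._index.get_indexer(pd.Index(sample_ids))
        if (idx < 0).any():
            bad = np.asarray(list(sample_ids))[idx < 0][:5]
            raise KeyError(f"sample_id not in sample sheet: {list(bad)}")
        return idx

    def phenotype_of(self, sample_id: str) -> str:
        return self.df.loc[self._index.get_loc(sample_id), "phenotype"]

    def subset(self, sample_ids: Sequence[str]) -> "SampleSheet":
        idx = self.indexer(sample_ids)
        return SampleSheet(self.df.iloc[idx].reset_index(drop=True))


@dataclass
class IntensityPanel:
    """samples x SNPs LRR/BAF/genotype matrices aligned to a manifest."""

    samples: list[str]
    manifest: SnpManifest
    lrr: np.ndarray       # float, NaN = missing
    baf: np.ndarray       # float in [0,1], NaN = missing
    genotype: np.ndarray  # int8, codes GT_*

    def __post_init__(self):
        shape = (len(self.samples), len(self.manifest))
        for name in ("lrr", "baf", "genotype"):
            m = getattr(self, name)
            if m.shape != shape:
                raise ValueError(f"{name} shape {m.shape} != {shape}")
        with np.errstate(invalid="ignore"):
            bad = (self.baf < 0) | (self.baf > 1)
        if np.any(bad):
            raise ValueError("BAF outside [0, 1]")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.samples.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in panel") from None

    def subset_samples(self, keep: Sequence[str]) -> "IntensityPanel":
        idx = [self.sample_index(s) for s in keep]
        return IntensityPanel(list(keep), self.manifest,
                              self.lrr[idx], self.baf[idx], self.genotype[idx])

    def subset_snps(self, mask: np.ndarray) -> "IntensityPanel":
        mask = np.asarray(mask)
        return IntensityPanel(list(self.samples), self.manifest.subset(mask),
                              self.lrr[:, mask], self.baf[:, mask], self.genotype[:, mask])


@dataclass(frozen=True)
class Region:
    chrom: str
    start_bp: int
    end_bp: int

    def __post_init__(self):
        if self.start_bp < 0 or self.end_bp < self.start_bp:
            raise ValueError(f"bad region {self.chrom}:{self.start_bp}-{self.end_bp}")

    def overlaps(self, chrom: str, start_bp: int, end_bp: int) -> bool:
        return self.chrom == chrom and self.start_bp <= end_bp and start_bp <= self.end_bp


@dataclass
class RegionSet:
    """Labelled set of 1-based inclusive intervals (internal convention)."""

    regions: list[Region]
    label: str = ""
    names: list[str] | None = None  # optional per-region names (genes)

    def __len__(self) -> int:
        return len(self.regions)

    def mask_snps(self, manifest: SnpManifest) -> np.ndarray:
        """Boolean mask of manifest SNPs falling inside any region."""
        mask = np.zeros(len(manifest), dtype=bool)
        slices = manifest.chrom_slices()
        for r in self.regions:
            sl = slices.get(r.chrom)
            if sl is None:
                continue
            pos = manifest.pos_bp[sl]
            lo = np.searchsorted(pos, r.start_bp, "left")
            hi = np.searchsorted(pos, r.end_bp, "right")
            mask[sl.start + lo:sl.start + hi] = True
        return mask

    def overlapping(self, chrom: str, start_bp: int, end_bp: int) -> list[int]:
        return [i for i, r in enumerate(self.regions)
                if r.overlaps(chrom, start_bp, end_bp)]


@dataclass
class Pedigree:
    """PLINK-FAM-style pedigree."""

    df: pd.DataFrame  # family_id, individual_id, father_id, mother_id, sex, affection

    REQUIRED = ("family_id", "individual_id", "father_id", "mother_id", "sex", "affection")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"pedigree missing columns: {missing}")
        ids = set(self.df["individual_id"])
        for col in ("father_id", "mother_id"):
            known = self.df[col].isin(ids) | self.df[col].isna()
            if not known.all():
                bad = self.df.loc[~known, col].iloc[0]
                raise ValueError(f"{col} {bad!r} not in pedigree")
        self._check_no_ancestor_cycles()

    def _check_no_ancestor_cycles(self):
        parents = {r.individual_id: {p for p in (r.father_id, r.mother_id) if not pd.isna(p)}
                   for r in self.df.itertuples()}
        for start in parents:
            seen = set()
            frontier = set(parents.get(start, ()))
            while frontier:
                if start in frontier:
                    raise ValueError(f"{start!r} is its own ancestor")
                seen |= frontier
                frontier = set().union(*(parents.get(p, set()) for p in frontier)) - seen
        return None

    def children_of_trios(self) -> pd.DataFrame:
        """Rows for individuals with both parents present in the pedigree."""
        has_both = self.df["father_id"].notna() & self.df["mother_id"].notna()
        return self.df.loc[has_both]


@dataclass(frozen=True)
class CnvCall:
    """One called CNV segment for one sample."""

    sample_id: str
    chrom: str
    start_bp: int
    end_bp: int
    copy_number: int      # in {0, 1, 3, 4}
    n_snps: int
    quality: float        # in [0, 1]

    def __post_init__(self):
        if self.copy_number not in (0, 1, 3, 4):
            raise ValueError(f"copy_number must be in {{0,1,3,4}}, got {self.copy_number}")
        if self.end_bp < self.start_bp:
            raise ValueError("end_bp < start_bp")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if not (0.0 <= self.quality <= 1.0):
            raise ValueError(f"quality {self.quality} outside [0, 1]")

    @property
    def cnv_class(self) -> str:
        return "DEL" if self.copy_number < 2 else "DUP"

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


def calls_to_frame(calls: Iterable[CnvCall]) -> pd.DataFrame:
    rows = [(c.sample_id, c.chrom, c.start_bp, c.end_bp, c.copy_number,
             c.cnv_class, c.n_snps, c.quality, c.length_bp) for c in calls]
    return pd.DataFrame(rows, columns=["sample_id", "chrom", "start_bp", "end_bp",
                                       "copy_number", "cnv_class", "n_snps",
                                       "quality", "length_bp"])


@dataclass
class CnvrRecord:
    """A copy-number-variable region: overlapping calls sharing >= 1 common bp."""

    cnvr_id: str
    chrom: str
    start_bp: int
    end_bp: int
    member_calls: list[CnvCall]
    carriers_case: int = 0
    carriers_control: int = 0
    frequency: float = 0.0

    def __post_init__(self):
        if not self.member_calls:
            raise ValueError("a CNVR must have at least one member call")
        lo = max(c.start_bp for c in self.member_calls)
        hi = min(c.end_bp for c in self.member_calls)
        if lo > hi:
            raise ValueError("CNVR members share no common nucleotide")
        if self.carriers_case + self.carriers_control > len(self.member_calls):
            raise ValueError("carrier counts exceed member count")

    @property
    def carriers(self) -> set[str]:
        return {c.sample_id for c in self.member_calls}

    @property
    def cnv_class(self) -> str:
        return self.member_calls[0].cnv_class
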