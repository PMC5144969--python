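"""Shared genomic data model and readers/writers for PLINK-text and BED files.

The pipeline works on two-generation nuclear families genotyped at mapped
biallelic SNPs.  Genotypes are held as minor-allele dosages (0/1/2, -1 for
missing) in a dense individual x marker matrix; marker positions stay 1-based
(MAP convention) while every interval quantity (crossover events, hotspot and
motif tracks) is 0-based half-open, so a marker at basepair ``bp`` corresponds
to the interval ``[bp-1, bp)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

SEX_MALE = "M"
SEX_FEMALE = "F"

_SEX_FROM_PED = {"1": SEX_MALE, "2": SEX_FEMALE}
_SEX_TO_PED = {SEX_MALE: "1", SEX_FEMALE: "2", None: "0"}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def _chrom_sort_key(chrom: str):
    try:
        return (0, int(chrom), "")
    except ValueError:
        return (1, 0, chrom)


class MarkerMap:
    """Ordered SNP map: chromosome, id, genetic position (ignored), bp, alleles.

    Markers are sorted by (chromosome, bp); ids must be unique and bp strictly
    increasing within each chromosome.  ``alleles`` stores (major, minor) per
    marker; dosage counts the minor allele.
    """

    def __init__(self, df: pd.DataFrame):
        required = {"chrom", "id", "bp"}
        if not required.issubset(df.columns):
            raise FormatError(f"marker map needs columns {sorted(required)}")
        df = df.copy()
        if "cm" not in df.columns:
            df["cm"] = 0.0
        if "a1" not in df.columns:
            df["a1"] = "A"
        if "a2" not in df.columns:
            df["a2"] = "B"
        df["chrom"] = df["chrom"].astype(str)
        df["bp"] = df["bp"].astype(np.int64)
        order = sorted(range(len(df)),
                       key=lambda i: (_chrom_sort_key(df["chrom"].iat[i]), df["bp"].iat[i]))
        df = df.iloc[order].reset_index(drop=True)
        # duplicate physical positions break the switch scan: keep first
        dup = df.duplicated(subset=["chrom", "bp"])
        if dup.any():
            warnings.warn(f"dropping {int(dup.sum())} marker(s) at duplicated positions")
            df = df[~dup].reset_index(drop=True)
        if df["id"].duplicated().any():
            raise FormatError("duplicate marker ids in map")
        for chrom, sub in df.groupby("chrom", sort=False):
            if not np.all(np.diff(sub["bp"].to_numpy()) > 0):
                raise FormatError(f"positions not strictly increasing on chromosome {chrom}")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def ids(self) -> np.ndarray:
        return self.df["id"].to_numpy()

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))

    def chrom_slice(self, chrom: str) -> slice:
        idx = np.flatnonzero((self.df["chrom"] == str(chrom)).to_numpy())
        if idx.size == 0:
            return slice(0, 0)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def bp(self, chrom: str) -> np.ndarray:
        return self.df["bp"].to_numpy()[self.chrom_slice(chrom)]

    def index_of(self, marker_id: str) -> int:
        hits = np.flatnonzero(self.ids == marker_id)
        if hits.size == 0:
            raise KeyError(f"marker {marker_id!r} not in map")
        return int(hits[0])


@dataclass
class Family:
    fid: str
    father: str
    mother: str
    children: list[str]

    @property
    def parents(self) -> tuple[str, str]:
        return (self.father, self.mother)


@dataclass
class Pedigree:
    """Two-generation nuclear families; every family has 2 parents, >=2 children."""

    families: list[Family]
    sex: dict[str, str | None] = field(default_factory=dict)

    def __post_init__(self):
        seen_children: set[str] = set()
        for fam in self.families:
            if len(fam.children) < 2:
                raise FormatError(f"family {fam.fid} has fewer than 2 children")
            for c in fam.children:
                if c in seen_children:
                    raise FormatError(f"individual {c} is a child in two families")
                seen_children.add(c)

    @property
    def individuals(self) -> list[str]:
        out = []
        for fam in self.families:
            out.extend([fam.father, fam.mother, *fam.children])
        return out

    @property
    def founders(self) -> list[str]:
        out = []
        for fam in self.families:
            out.extend([fam.father, fam.mother])
        return out

    def sex_of(self, iid: str) -> str | None:
        return self.sex.get(iid)


@dataclass
class GenotypeTable:
    """Minor-allele dosages, shape (n_individuals, n_markers); -1 is missing."""

    individuals: list[str]
    marker_ids: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.individuals), len(self.marker_ids)):
            raise ValueError("genotype matrix shape does not match individuals x markers")
        bad = ~np.isin(self.values, [MISSING, 0, 1, 2])
        if bad.any():
            raise ValueError("genotype values must be in {0,1,2,-1}")
        self._row = {iid: i for i, iid in enumerate(self.individuals)}

    def row(self, iid: str) -> np.ndarray:
        return self.values[self._row[iid]]

    def has(self, iid: str) -> bool:
        return iid in self._row

    def subset_rows(self, iids: list[str]) -> np.ndarray:
        return self.values[[self._row[i] for i in iids]]


class IntervalTrack:
    """Per-chromosome 0-based half-open intervals, merged and sorted at load."""

    def __init__(self, label: str, intervals: dict[str, np.ndarray] | None = None):
        self.label = label
        self.intervals: dict[str, np.ndarray] = {}
        if intervals:
            for chrom, arr in intervals.items():
                self.intervals[str(chrom)] = merge_intervals(np.asarray(arr, dtype=np.int64))

    def chrom(self, chrom: str) -> np.ndarray:
        return self.intervals.get(str(chrom), np.empty((0, 2), dtype=np.int64))

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True iff [start, end) intersects any interval on `chrom` by >=1 bp."""
        iv = self.chrom(chrom)
        if iv.size == 0 or start >= end:
            return False
        i = np.searchsorted(iv[:, 0], end, side="left")
        return i > 0 and iv[i - 1, 1] > start

    def overlaps_many(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        iv = self.chrom(chrom)
        starts = np.asarray(starts)
        ends = np.asarray(ends)
        if iv.size == 0:
            return np.zeros(starts.shape, dtype=bool)
        i = np.searchsorted(iv[:, 0], ends, side="left")
        ok = i > 0
        prev_end = np.where(ok, iv[np.maximum(i - 1, 0), 1], 0)
        return ok & (prev_end > starts) & (starts < ends)

    def total_length(self, chrom: str | None = None) -> int:
        chroms = [chrom] if chrom is not None else list(self.intervals)
        return int(sum((self.chrom(c)[:, 1] - self.chrom(c)[:, 0]).sum() for c in chroms))

    def n_intervals(self) -> int:
        return int(sum(len(v) for v in self.intervals.values()))

    def expand(self, window: int) -> "IntervalTrack":
        """Return a copy with every interval widened by `window` bp on each side."""
        if window == 0:
            return self
        out = {c: np.stack([np.maximum(iv[:, 0] - window, 0), iv[:, 1] + window], axis=1)
               for c, iv in self.intervals.items()}
        return IntervalTrack(self.label, out)


def merge_intervals(arr: np.ndarray) -> np.ndarray:
    """Merge overlapping/adjacent half-open intervals; idempotent."""
    arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
    if len(arr) == 0:
        return arr
    if np.any(arr[:, 0] >= arr[:, 1]):
        raise FormatError("interval with start >= end")
    arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
    out = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out, dtype=np.int64)


# ---------------------------------------------------------------------------
# PED / MAP (PLINK text dialect)
# ---------------------------------------------------------------------------

def read_ped_map(ped_path, map_path) -> tuple[Pedigree, MarkerMap, GenotypeTable]:
    """Read a PLINK-text cohort.

    Genotypes are recoded to minor-allele dosage with the minor allele
    determined from parental founders only (ties broken lexicographically);
    '0 0' allele pairs become missing; markers come back sorted by
    (chromosome, bp).
    """
    rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise FormatError(f"{map_path}:{lineno}: MAP needs 4 columns, got {len(parts)}")
            rows.append((parts[0], parts[1], float(parts[2]), int(parts[3])))
    if not rows:
        raise FormatError(f"{map_path}: empty MAP")
    raw_map = pd.DataFrame(rows, columns=["chrom", "id", "cm", "bp"])
    n_markers = len(raw_map)

    iids, fids, pats, mats, sexes = [], [], [], [], []
    allele_rows = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_markers:
                raise FormatError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_markers} columns "
                    f"for {n_markers} markers, got {len(parts)}")
            fid, iid, pat, mat, sex = parts[:5]
            fids.append(fid); iids.append(iid); pats.append(pat); mats.append(mat)
            sexes.append(_SEX_FROM_PED.get(sex))
            allele_rows.append(parts[6:])
    if not iids:
        raise FormatError(f"{ped_path}: empty PED")
    alleles = np.asarray(allele_rows, dtype="U8").reshape(len(iids), n_markers, 2)

    # pedigree reconstruction from PAT/MAT links
    is_founder = [(p == "0" and m == "0") for p, m in zip(pats, mats)]
    fam_children: dict[str, list[int]] = {}
    for i, founder in enumerate(is_founder):
        if not founder:
            fam_children.setdefault(fids[i], []).append(i)
    families = []
    founder_rows: list[int] = []
    iid_row = {iid: i for i, iid in enumerate(iids)}
    for fid in dict.fromkeys(fids):
        child_idx = fam_children.get(fid, [])
        if not child_idx:
            continue
        fathers = {pats[i] for i in child_idx}
        mothers = {mats[i] for i in child_idx}
        if len(fathers) != 1 or len(mothers) != 1:
            raise FormatError(f"family {fid}: children do not share exactly two parents")
        father, mother = fathers.pop(), mothers.pop()
        for pid in (father, mother):
            if pid not in iid_row:
                raise FormatError(f"family {fid}: parent {pid} missing from PED")
        families.append(Family(fid, father, mother, [iids[i] for i in child_idx]))
        founder_rows.extend([iid_row[father], iid_row[mother]])
    pedigree = Pedigree(families, {iid: s for iid, s in zip(iids, sexes)})

    genos = np.full((len(iids), n_markers), MISSING, dtype=np.int8)
    a1_col = np.empty(n_markers, dtype="U8")
    a2_col = np.empty(n_markers, dtype="U8")
    founder_rows = np.asarray(sorted(set(founder_rows)), dtype=int)
    for j in range(n_markers):
        col = alleles[:, j, :]
        observed = sorted(set(col.ravel()) - {"0"})
        if len(observed) > 2:
            raise FormatError(
                f"marker {raw_map['id'].iat[j]}: more than two alleles observed {observed}")
        if not observed:
            a1_col[j], a2_col[j] = "0", "0"
            continue
        if len(observed) == 1:
            a1_col[j] = a2_col[j] = observed[0]
            genos[:, j] = np.where((col == "0").any(axis=1), MISSING, 0)
            continue
        x, y = observed  # lexicographic order
        fcol = col[founder_rows]
        fmiss = (fcol == "0").any(axis=1)
        n_y = int((fcol[~fmiss] == y).sum())
        n_tot = int(2 * (~fmiss).sum())
        freq_y = n_y / n_tot if n_tot else 0.5
        # minor allele from founders; exact tie -> lexicographically smaller
        minor = y if freq_y < 0.5 else (x if freq_y > 0.5 else x)
        major = x if minor == y else y
        a1_col[j], a2_col[j] = major, minor
        miss = (col == "0").any(axis=1)
        dose = (col == minor).sum(axis=1).astype(np.int8)
        genos[:, j] = np.where(miss, MISSING, dose)

    raw_map["a1"], raw_map["a2"] = a1_col, a2_col
    mmap = MarkerMap(raw_map)
    # MarkerMap may have re-sorted / dropped duplicate positions: realign columns
    orig_col = {mid: j for j, mid in enumerate(raw_map["id"])}
    keep = [orig_col[mid] for mid in mmap.ids]
    genos = genos[:, keep]
    table = GenotypeTable(iids, mmap.ids, genos)
    return pedigree, mmap, table


def write_ped_map(pedigree: Pedigree, mmap: MarkerMap, genos: GenotypeTable,
                  out_prefix: str) -> tuple[str, str]:
    """Write PLINK-text PED/MAP (sex coded 1=male, 2=female)."""
    if len(mmap) == 0:
        raise FormatError("refusing to write an empty MAP")
    for fam in pedigree.families:
        for pid in fam.parents:
            if pedigree.sex_of(pid) not in (SEX_MALE, SEX_FEMALE):
                raise FormatError(f"parent {pid} has no sex; sex-stratified GWAS requires it")
    ped_path, map_path = f"{out_prefix}.ped", f"{out_prefix}.map"
    with open(map_path, "w") as fh:
        for r in mmap.df.itertuples():
            fh.write(f"{r.chrom}\t{r.id}\t{r.cm:g}\t{r.bp}\n")
    a1 = mmap.df["a1"].to_numpy()
    a2 = mmap.df["a2"].to_numpy()
    with open(ped_path, "w") as fh:
        for fam in pedigree.families:
            for iid in [fam.father, fam.mother, *fam.children]:
                pat, mat = ("0", "0") if iid in fam.parents else fam.parents
                sex = _SEX_TO_PED[pedigree.sex_of(iid)]
                dose = genos.row(iid)
                cols = [fam.fid, iid, pat, mat, sex, "-9"]
                for j, d in enumerate(dose):
                    if d == MISSING:
                        cols.extend(["0", "0"])
                    elif d == 0:
                        cols.extend([a1[j], a1[j]])
                    elif d == 1:
                        cols.extend([a1[j], a2[j]])
                    else:
                        cols.extend([a2[j], a2[j]])
                fh.write(" ".join(cols) + "\n")
    return ped_path, map_path


# ---------------------------------------------------------------------------
# BED interval tracks
# ---------------------------------------------------------------------------

def read_interval_track(bed_path, label: str) -> IntervalTrack:
    """Read a >=3-column BED file into a merged, sorted IntervalTrack."""
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or parts[0].startswith(("#", "track", "browser")):
                continue
            if len(parts) < 3:
                raise FormatError(f"{bed_path}:{lineno}: BED needs >=3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise FormatError(f"{bed_path}:{lineno}: start >= end ({start} >= {end})")
            per_chrom.setdefault(chrom, []).append((start, end))
    return IntervalTrack(label, {c: np.asarray(v) for c, v in per_chrom.items()})


def write_interval_track(track: IntervalTrack, bed_path) -> str:
    with open(bed_path, "w") as fh:
        for chrom in sorted(track.intervals, key=_chrom_sort_key):
            for s, e in track.chrom(chrom):
                fh.write(f"{chrom}\t{s}\t{e}\t{track.label}\n")
    return str(bed_path)


def write_tsv(df: pd.DataFrame, path) -> str:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return str(path)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
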