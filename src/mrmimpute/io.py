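"""Data model and text-format I/O for regional methylation matrices.

A :class:`RegionMatrix` holds one genomic region: its CpG coordinates and an
N (subjects) x I (CpGs) matrix of beta values in [0, 1] with an observation
mask.  A :class:`MethylationDataset` is an ordered collection of regions
sharing one subject roster.

Supported text formats: a CpG x subject matrix TSV plus a positions TSV
(region_id, chrom, pos), and per-subject 4-column bedGraph files.
Coordinates are stored 1-based inclusive internally; bedGraph's 0-based
half-open intervals are converted on read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, List, Optional, Sequence

import numpy as np
import pandas as pd


class MethDataError(Exception):
    """Base class for data-model errors."""


class FormatError(MethDataError):
    """Malformed input file."""


class InputDomainError(MethDataError):
    """A value violates the domain contract (e.g. beta outside [0, 1])."""


class StateError(MethDataError):
    """Operation applied to a dataset in the wrong state."""


_NA_STRINGS = {"", "na", "nan"}


@dataclass
class RegionMatrix:
    """One genomic region's methylation values across subjects.

    values[n, i] is the beta value of subject n at CpG i; mask[n, i] is True
    where the value was observed.  Unobserved cells are stored as NaN.
    """

    region_id: str
    chrom: str
    start: int
    end: int
    positions: np.ndarray        # (I,) ascending 1-based coordinates
    values: np.ndarray           # (N, I) float
    mask: np.ndarray             # (N, I) bool
    subject_ids: List[str]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.values = np.array(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise FormatError(
                f"region {self.region_id}: values shape {self.values.shape} "
                f"!= mask shape {self.mask.shape}"
            )
        n, i = self.values.shape
        if len(self.subject_ids) != n:
            raise FormatError(
                f"region {self.region_id}: {len(self.subject_ids)} subject ids "
                f"for {n} rows"
            )
        if self.positions.shape != (i,):
            raise FormatError(
                f"region {self.region_id}: {self.positions.size} positions for "
                f"{i} columns"
            )
        if i and (np.diff(self.positions) <= 0).any():
            raise FormatError(
                f"region {self.region_id}: positions not strictly increasing"
            )
        if i and (self.positions[0] < self.start or self.positions[-1] > self.end):
            raise FormatError(
                f"region {self.region_id}: positions outside [{self.start}, {self.end}]"
            )
        obs = self.values[self.mask]
        bad = ~np.isfinite(obs) | (obs < 0.0) | (obs > 1.0)
        if bad.any():
            rows, cols = np.nonzero(self.mask)
            j = int(np.nonzero(bad)[0][0])
            raise InputDomainError(
                f"region {self.region_id}: value {obs[bad][0]!r} outside [0, 1] at "
                f"subject {self.subject_ids[rows[j]]!r}, position {self.positions[cols[j]]}"
            )
        self.values[~self.mask] = np.nan

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_cpgs(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "RegionMatrix":
        return RegionMatrix(
            self.region_id, self.chrom, self.start, self.end,
            self.positions.copy(), self.values.copy(), self.mask.copy(),
            list(self.subject_ids),
        )


@dataclass
class MethylationDataset:
    """Ordered collection of regions sharing one subject roster."""

    regions: List[RegionMatrix]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.region_id for r in self.regions]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate region ids in dataset")
        if self.regions:
            roster = self.regions[0].subject_ids
            for r in self.regions[1:]:
                if r.subject_ids != roster:
                    raise FormatError(
                        f"region {r.region_id} has a different subject roster"
                    )

    @property
    def subject_ids(self) -> List[str]:
        return self.regions[0].subject_ids if self.regions else []

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def __iter__(self) -> Iterator[RegionMatrix]:
        return iter(self.regions)

    def __len__(self) -> int:
        return len(self.regions)

    def get(self, region_id: str) -> RegionMatrix:
        for r in self.regions:
            if r.region_id == region_id:
                return r
        raise KeyError(region_id)

    def copy(self) -> "MethylationDataset":
        return MethylationDataset([r.copy() for r in self.regions], self.provenance)


# ---------------------------------------------------------------------------
# matrix TSV + positions TSV
# ---------------------------------------------------------------------------

def _parse_cell(raw: str, row: int, col_name: str, path) -> float:
    s = raw.strip()
    if s.lower() in _NA_STRINGS:
        return math.nan
    try:
        v = float(s)
    except ValueError:
        raise FormatError(f"{path}: non-numeric value {raw!r} at row {row}, "
                          f"subject {col_name!r}") from None
    if not 0.0 <= v <= 1.0:
        raise InputDomainError(
            f"{path}: value {v} outside [0, 1] at row {row}, subject {col_name!r}"
        )
    return v


def read_matrix_tsv(path, positions_path) -> MethylationDataset:
    """Read a CpG x subject matrix TSV plus its positions TSV.

    The matrix file has a header row of subject ids and one row per CpG;
    missing cells are encoded as "NA" (case-insensitive) or left empty.  The
    positions file has columns (region_id, chrom, pos); with only (chrom, pos)
    each chromosome becomes one region.
    """
    pos = pd.read_csv(positions_path, sep="\t", dtype=str)
    cols = [c.lower() for c in pos.columns]
    if {"chrom", "pos"} <= set(cols):
        pos.columns = cols
    elif pos.shape[1] == 3:
        pos.columns = ["region_id", "chrom", "pos"]
    elif pos.shape[1] == 2:
        pos.columns = ["chrom", "pos"]
    else:
        raise FormatError(f"{positions_path}: expected 2 or 3 columns, got {pos.shape[1]}")
    if "region_id" not in pos.columns:
        pos["region_id"] = pos["chrom"]
    try:
        pos["pos"] = pos["pos"].astype(np.int64)
    except ValueError as exc:
        raise FormatError(f"{positions_path}: non-integer position: {exc}") from None

    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        subject_ids = [h.strip() for h in header]
        rows = []
        for irow, line in enumerate(fh):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(subject_ids):
                raise FormatError(
                    f"{path}: row {irow} has {len(fields)} fields, expected "
                    f"{len(subject_ids)}"
                )
            rows.append([_parse_cell(f, irow, subject_ids[j], path)
                         for j, f in enumerate(fields)])
    if len(rows) != len(pos):
        raise FormatError(
            f"row count mismatch: {len(rows)} matrix rows vs {len(pos)} positions"
        )
    data = np.asarray(rows, dtype=float)  # (I_total, N)

    regions: List[RegionMatrix] = []
    for rid in pos["region_id"].drop_duplicates():
        idx = np.nonzero((pos["region_id"] == rid).to_numpy())[0]
        sub = pos.iloc[idx]
        chroms = sub["chrom"].unique()
        if len(chroms) != 1:
            raise FormatError(f"region {rid!r} spans multiple chromosomes")
        order = np.argsort(sub["pos"].to_numpy(), kind="stable")
        coords = sub["pos"].to_numpy()[order]
        if (np.diff(coords) <= 0).any():
            raise FormatError(f"region {rid!r}: duplicate CpG positions")
        vals = data[idx[order]].T  # (N, I)
        regions.append(RegionMatrix(
            region_id=str(rid), chrom=str(chroms[0]),
            start=int(coords[0]), end=int(coords[-1]),
            positions=coords, values=vals, mask=~np.isnan(vals),
            subject_ids=subject_ids,
        ))
    return MethylationDataset(regions, provenance=f"matrix:{path}")


def write_matrix_tsv(dataset: MethylationDataset, path, positions_path,
                     na_rep: str = "NA") -> None:
    """Write a dataset as matrix TSV + positions TSV (missing cells allowed).

    Values are formatted with 17 significant digits so that the read->write->
    read round trip reproduces them bit for bit.  A cell is written whenever
    its value is finite (imputed datasets keep their original mask marking
    which cells were observed, while the filled values are all finite).
    """
    with open(path, "w") as fh:
        fh.write("\t".join(dataset.subject_ids) + "\n")
        for region in dataset:
            for i in range(region.n_cpgs):
                cells = [
                    f"{v:.17g}" if math.isfinite(v) else na_rep
                    for v in region.values[:, i]
                ]
                fh.write("\t".join(cells) + "\n")
    with open(positions_path, "w") as fh:
        fh.write("region_id\tchrom\tpos\n")
        for region in dataset:
            for p in region.positions:
                fh.write(f"{region.region_id}\t{region.chrom}\t{p}\n")


def write_imputed(dataset: MethylationDataset, path,
                  positions_path=None) -> None:
    """Write a fully imputed dataset; raises :class:`StateError` on gaps."""
    for region in dataset:
        if np.isnan(region.values).any():
            n, i = np.argwhere(np.isnan(region.values))[0]
            raise StateError(
                f"region {region.region_id} still has a missing cell at subject "
                f"{region.subject_ids[n]!r}, position {region.positions[i]}"
            )
    if positions_path is None:
        positions_path = str(path) + ".positions.tsv"
    complete = MethylationDataset(
        [RegionMatrix(r.region_id, r.chrom, r.start, r.end, r.positions,
                      r.values, np.ones_like(r.mask, dtype=bool), r.subject_ids)
         for r in dataset],
        dataset.provenance,
    )
    write_matrix_tsv(complete, path, positions_path)


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def _read_one_bedgraph(path, percent: Optional[bool]):
    """Returns dict chrom -> (positions array, values array), 1-based coords."""
    chroms: dict = {}
    order: List[str] = []
    last = None  # (chrom, start)
    raw: List[tuple] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith(("#", "track", "browser")):
                continue
            fields = s.split("\t") if "\t" in s else s.split()
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
            chrom = fields[0]
            try:
                start0 = int(fields[1]); int(fields[2]); val = float(fields[3])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: malformed line {s!r}") from None
            if last is not None and chrom == last[0] and start0 <= last[1]:
                raise FormatError(f"{path}:{lineno}: unsorted positions on {chrom}")
            last = (chrom, start0)
            raw.append((chrom, start0 + 1, val, lineno))

    vals = np.array([v for _, _, v, _ in raw], dtype=float)
    if percent is None:
        percent = bool(vals.size) and float(np.nanmax(vals)) > 1.0
    if percent:
        vals = vals / 100.0
    for (chrom, pos1, _, lineno), v in zip(raw, vals):
        if not 0.0 <= v <= 1.0:
            raise InputDomainError(f"{path}:{lineno}: level {v} outside [0, 1]")
        if chrom not in chroms:
            chroms[chrom] = ([], [])
            order.append(chrom)
        chroms[chrom][0].append(pos1)
        chroms[chrom][1].append(v)
    return order, {c: (np.array(p, dtype=np.int64), np.array(v, dtype=float))
                   for c, (p, v) in chroms.items()}


def read_bedgraph_set(paths: Sequence, subject_ids: Optional[Sequence[str]] = None,
                      percent: Optional[bool] = None) -> MethylationDataset:
    """Read one bedGraph file per subject; one region per chromosome.

    The union of CpG coordinates across subjects defines the positions;
    subjects lacking a site are masked there.  Levels in [0, 100] are
    auto-detected per file (max > 1) and divided by 100 unless ``percent``
    forces the interpretation.
    """
    paths = list(paths)
    if subject_ids is None:
        subject_ids = [Path(p).stem for p in paths]
    per_subject = [_read_one_bedgraph(p, percent) for p in paths]

    chrom_order: List[str] = []
    for order, _ in per_subject:
        for c in order:
            if c not in chrom_order:
                chrom_order.append(c)

    regions = []
    for chrom in chrom_order:
        union = np.unique(np.concatenate(
            [d[chrom][0] for _, d in per_subject if chrom in d]
        ))
        n, i = len(paths), union.size
        values = np.full((n, i), np.nan)
        for s, (_, d) in enumerate(per_subject):
            if chrom not in d:
                continue
            pos, val = d[chrom]
            values[s, np.searchsorted(union, pos)] = val
        regions.append(RegionMatrix(
            region_id=chrom, chrom=chrom,
            start=int(union[0]), end=int(union[-1]),
            positions=union, values=values, mask=~np.isnan(values),
            subject_ids=list(subject_ids),
        ))
    return MethylationDataset(regions, provenance=f"bedgraph:{len(paths)} subjects")
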