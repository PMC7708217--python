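"""Region definition and filtering.

Regions can be built by correlation-based agglomeration of adjacent CpGs
(merge adjacent regions while the gap is under 3000 bp and the average
pairwise Pearson correlation exceeds 0.3), by non-overlapping 50-CpG
windows, or by pruning promoters to the 25 CpGs flanking a TSS on each
side.  Candidate regions are then gated on subject availability, pooled
variance, pooled skewness, and a runs count on the dichotomized mean
profile, to keep only regions whose profiles show the spatially structured,
variable patterns the mixture model assumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .io import FormatError, InputDomainError, RegionMatrix

__all__ = ["RegionInterval", "RegionFilterReport", "cluster_adjacent",
           "sliding_windows", "prune_promoter", "filter_region",
           "map_to_promoters", "subset_region", "write_bed", "read_tss_table"]


@dataclass
class RegionInterval:
    chrom: str
    start: int          # 1-based inclusive
    end: int
    indices: np.ndarray  # indices of member CpGs in the source matrix

    @property
    def n_cpgs(self) -> int:
        return self.indices.size


@dataclass
class RegionFilterReport:
    region_id: str
    n_subjects_available: int
    variance: float
    skewness: float
    n_runs: int
    passed: bool
    failure_reasons: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.passed == (len(self.failure_reasons) == 0)


def subset_region(region: RegionMatrix, indices, region_id: str) -> RegionMatrix:
    """A new RegionMatrix restricted to the given CpG column indices."""
    indices = np.asarray(indices, dtype=np.int64)
    pos = region.positions[indices]
    return RegionMatrix(
        region_id=region_id, chrom=region.chrom,
        start=int(pos[0]), end=int(pos[-1]), positions=pos,
        values=region.values[:, indices], mask=region.mask[:, indices],
        subject_ids=region.subject_ids,
    )


# ---------------------------------------------------------------------------
# correlation-based adjacent clustering
# ---------------------------------------------------------------------------

def _site_correlations(region: RegionMatrix) -> np.ndarray:
    """Pairwise Pearson correlations between CpG columns (pairwise-complete).

    Constant or under-observed sites get correlation 0 with everything.
    """
    df = pd.DataFrame(region.values)
    corr = df.corr(min_periods=2).to_numpy()
    return np.nan_to_num(corr, nan=0.0)


def cluster_adjacent(region: RegionMatrix, max_dist: int = 3000,
                     min_corr: float = 0.3) -> List[RegionInterval]:
    """Bottom-up agglomeration of adjacent CpG sites into regions.

    At each step the adjacent pair of regions with the highest similarity
    (average pairwise correlation over all cross-region site pairs) is
    merged, provided the genomic gap between them is below ``max_dist`` and
    the similarity exceeds ``min_corr``; ties resolve to the leftmost pair.
    Iterates to a fixed point; output regions are disjoint, ordered, and
    cover every input site.
    """
    if region.n_subjects < 2:
        raise InputDomainError("cluster_adjacent needs >= 2 subjects")
    corr = _site_correlations(region)
    pos = region.positions
    blocks: List[List[int]] = [[i] for i in range(region.n_cpgs)]
    while len(blocks) > 1:
        best_sim, best_at = -np.inf, None
        for b in range(len(blocks) - 1):
            left, right = blocks[b], blocks[b + 1]
            gap = pos[right[0]] - pos[left[-1]]
            if gap >= max_dist:
                continue
            sim = float(np.mean(corr[np.ix_(left, right)]))
            if sim > best_sim:
                best_sim, best_at = sim, b
        if best_at is None or best_sim <= min_corr:
            break
        blocks[best_at] = blocks[best_at] + blocks.pop(best_at + 1)
    return [RegionInterval(region.chrom, int(pos[b[0]]), int(pos[b[-1]]),
                           np.asarray(b, dtype=np.int64))
            for b in blocks]


def sliding_windows(region: RegionMatrix, window: int = 50) -> List[RegionInterval]:
    """Consecutive non-overlapping blocks of ``window`` CpGs.

    A trailing remainder shorter than ``window`` is dropped with a warning.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    i = region.n_cpgs
    n_full = i // window
    if i % window:
        warnings.warn(f"{i % window} trailing CpGs (< window {window}) dropped")
    out = []
    for b in range(n_full):
        idx = np.arange(b * window, (b + 1) * window)
        out.append(RegionInterval(region.chrom, int(region.positions[idx[0]]),
                                  int(region.positions[idx[-1]]), idx))
    return out


def prune_promoter(region: RegionMatrix, tss: int, flank_cpgs: int = 25
                   ) -> Tuple[RegionMatrix, bool]:
    """Keep the ``flank_cpgs`` CpGs nearest the TSS on each side.

    Sites strictly upstream (pos < tss) count to one flank; sites at or
    downstream of the TSS to the other, so no CpG is counted twice.
    Returns (pruned region, short_flank_flag); the flag is set when a flank
    had fewer than ``flank_cpgs`` sites available.
    """
    if not region.start <= tss <= region.end:
        raise InputDomainError(
            f"TSS {tss} outside region [{region.start}, {region.end}]")
    split = int(np.searchsorted(region.positions, tss))
    up = np.arange(max(0, split - flank_cpgs), split)
    down = np.arange(split, min(region.n_cpgs, split + flank_cpgs))
    short = up.size < flank_cpgs or down.size < flank_cpgs
    idx = np.concatenate([up, down])
    return subset_region(region, idx, f"{region.region_id}_tss{tss}"), short


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def _runs_count(profile: np.ndarray) -> int:
    """Runs of the mean profile dichotomized at its median (>= median -> 1)."""
    finite = profile[np.isfinite(profile)]
    if finite.size == 0:
        return 0
    med = float(np.median(finite))
    sides = (finite >= med).astype(int)
    return 1 + int(np.sum(sides[1:] != sides[:-1]))


def filter_region(region: RegionMatrix, min_subjects: int = 15,
                  min_var: float = 0.1, min_skew: float = -1.0,
                  max_runs: int = 15) -> RegionFilterReport:
    """Gate a region on data availability, variance, skewness and runs.

    Variance and skewness (adjusted Fisher-Pearson) are computed on the
    pooled observed values; the runs count on the across-subject mean
    profile dichotomized at its median.  The region passes iff
    n_subjects > min_subjects AND variance > min_var AND skewness > min_skew
    AND runs < max_runs.
    """
    obs = region.values[region.mask] if region.mask.any() else np.empty(0)
    if obs.size == 0:
        return RegionFilterReport(region.region_id, 0, np.nan, np.nan, 0,
                                  passed=False, failure_reasons=["no data"])
    n_subj = int(np.sum(region.mask.any(axis=1)))
    variance = float(np.var(obs))
    with warnings.catch_warnings():
        # near-constant data legitimately triggers precision warnings here
        warnings.simplefilter("ignore", RuntimeWarning)
        skewness = float(stats.skew(obs, bias=False)) if obs.size >= 3 else np.nan
        mean_profile = np.nanmean(region.values, axis=0)
    n_runs = _runs_count(mean_profile)
    reasons = []
    if n_subj <= min_subjects:
        reasons.append(f"subjects {n_subj} <= {min_subjects}")
    if not variance > min_var:
        reasons.append(f"variance {variance:.4g} <= {min_var}")
    if not skewness > min_skew:
        reasons.append(f"skewness {skewness:.4g} <= {min_skew}")
    if not n_runs < max_runs:
        reasons.append(f"runs {n_runs} >= {max_runs}")
    return RegionFilterReport(region.region_id, n_subj, variance, skewness,
                              n_runs, passed=not reasons,
                              failure_reasons=reasons)


# ---------------------------------------------------------------------------
# promoter mapping
# ---------------------------------------------------------------------------

def read_tss_table(path) -> pd.DataFrame:
    """Read a TSS table: TSV (gene, chrom, tss[, strand]) or 6-column BED."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    first = df.iloc[0].tolist()
    if first[:3] == ["gene", "chrom", "tss"] or "gene" in first:
        df = pd.read_csv(path, sep="\t", dtype=str)
        df.columns = [c.lower() for c in df.columns]
    elif df.shape[1] >= 6:
        # BED6: chrom start0 end0 name score strand; TSS at the strand-aware end
        strand = df[5].fillna("+")
        start0 = df[1].astype(np.int64)
        end0 = df[2].astype(np.int64)
        tss = np.where(strand == "-", end0, start0 + 1)
        df = pd.DataFrame({"gene": df[3], "chrom": df[0], "tss": tss,
                           "strand": strand})
    elif df.shape[1] >= 3:
        df.columns = ["gene", "chrom", "tss"][:df.shape[1]] + \
            [f"c{j}" for j in range(max(0, df.shape[1] - 3))]
    else:
        raise FormatError(f"{path}: cannot interpret TSS table")
    if "strand" not in df.columns or df["strand"].isna().any():
        warnings.warn("TSS table missing strand; assuming '+'")
        df["strand"] = df.get("strand", pd.Series(["+"] * len(df))).fillna("+")
    df["tss"] = df["tss"].astype(np.int64)
    return df[["gene", "chrom", "tss", "strand"]]


def map_to_promoters(regions: Sequence[RegionInterval], tss_table: pd.DataFrame,
                     flank_bp: int = 5000) -> pd.DataFrame:
    """Assign each region to every gene whose TSS +/- flank overlaps it.

    Returns a DataFrame (region_index, gene, chrom, tss); multi-mapping is
    allowed.
    """
    rows = []
    for ridx, region in enumerate(regions):
        hits = tss_table[
            (tss_table["chrom"] == region.chrom)
            & (tss_table["tss"] + flank_bp >= region.start)
            & (tss_table["tss"] - flank_bp <= region.end)
        ]
        for _, hit in hits.iterrows():
            rows.append(dict(region_index=ridx, gene=hit["gene"],
                             chrom=hit["chrom"], tss=int(hit["tss"])))
    return pd.DataFrame(rows, columns=["region_index", "gene", "chrom", "tss"])


def write_bed(regions: Sequence[RegionInterval], path) -> None:
    """Write regions as BED (0-based half-open) with CpG counts as scores."""
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\tregion_{i:04d}\t"
                     f"{r.n_cpgs}\t.\n")
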