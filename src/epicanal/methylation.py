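"""Region-level methylation quantification and simplified DMR calling.

Methylation is carried as per-cytosine (methylated, total) read counts per
sample.  Region means follow a per-cytosine coverage rule: only cytosines
with at least ``min_reads`` total reads contribute, and a sample with no
qualifying cytosine in a region gets NA.  The two-group DMR caller operates
on caller-supplied candidate regions rather than de-novo segmentation: a
region is reported when it holds at least ``min_c`` cytosines of the context
and the absolute difference of the group mean methylation percentages
(computed at ``min_cov`` per-cytosine coverage) reaches ``min_diff_pct``.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CONTEXTS, check_intervals


class MethylCalls:
    """Per-cytosine methylation read counts for a set of samples.

    Parameters
    ----------
    sites
        DataFrame with columns chrom, pos (0-based), strand, context.
    meth, total
        Integer arrays of shape (n_sites, n_samples); ``meth <= total``
        everywhere.
    samples
        Sample identifiers, one per column.
    """

    def __init__(
        self,
        sites: pd.DataFrame,
        meth: np.ndarray,
        total: np.ndarray,
        samples: list[str],
    ) -> None:
        sites = sites.reset_index(drop=True)
        meth = np.asarray(meth)
        total = np.asarray(total)
        if meth.shape != total.shape or meth.shape != (len(sites), len(samples)):
            raise ValueError("meth/total shape does not match sites × samples")
        if (meth > total).any():
            raise ValueError("methylated reads exceed total reads at some site")
        if (meth < 0).any() or (total < 0).any():
            raise ValueError("negative read counts")
        unknown = set(sites["context"]) - set(CONTEXTS)
        if unknown:
            raise ValueError(f"unknown contexts: {sorted(unknown)}")
        order = np.lexsort((sites["pos"].to_numpy(), sites["chrom"].to_numpy()))
        self.sites = sites.iloc[order].reset_index(drop=True)
        self.meth = meth[order]
        self.total = total[order]
        self.samples = list(samples)

    def __len__(self) -> int:
        return len(self.sites)

    def level(self) -> np.ndarray:
        """Per-site methylation fraction; NaN where a site has no reads."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.total > 0, self.meth / np.maximum(self.total, 1), np.nan)

    # -- text round-trip (chrom, pos, strand, context, then "meth,total" per sample)

    def to_tsv(self, path) -> None:
        df = self.sites.copy()
        for j, s in enumerate(self.samples):
            df[s] = [f"{m},{t}" for m, t in zip(self.meth[:, j], self.total[:, j])]
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "MethylCalls":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        site_cols = ["chrom", "pos", "strand", "context"]
        samples = [c for c in df.columns if c not in site_cols]
        meth_cols, total_cols = [], []
        for s in samples:
            parts = df[s].str.split(",", expand=True).astype(np.int64)
            meth_cols.append(parts[0].to_numpy())
            total_cols.append(parts[1].to_numpy())
        meth = np.column_stack(meth_cols)
        total = np.column_stack(total_cols)
        return cls(df[site_cols], meth, total, samples)


@dataclass
class RegionMethylation:
    """Per-region, per-sample mean methylation percentages.

    ``mean_pct`` is regions × samples with NaN marking insufficient coverage;
    ``n_cytosines`` counts context cytosines present in each region.
    """

    regions: pd.DataFrame
    mean_pct: pd.DataFrame
    n_cytosines: pd.Series = field(repr=False)

    @property
    def na_count(self) -> pd.Series:
        return self.mean_pct.isna().sum(axis=1)


def _region_ids(regions: pd.DataFrame) -> pd.Index:
    if regions.index.is_unique and not isinstance(regions.index, pd.RangeIndex):
        return regions.index
    return pd.Index([f"region_{i}" for i in range(len(regions))])


def region_methylation_matrix(
    calls: MethylCalls,
    regions: pd.DataFrame,
    context: str = "CG",
    min_reads: int = 2,
) -> RegionMethylation:
    """Average methylation per region and sample under a coverage rule.

    For each sample, the mean of ``100 * meth / total`` is taken over
    cytosines of ``context`` inside the region with ``total >= min_reads``;
    NA when no cytosine qualifies.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    check_intervals(regions)
    known_chroms = set(calls.sites["chrom"].unique())
    bad = set(regions["chrom"]) - known_chroms
    if bad:
        raise ValueError(f"regions on unknown chromosomes: {sorted(bad)}")

    ctx_mask = (calls.sites["context"] == context).to_numpy()
    sites = calls.sites[ctx_mask]
    meth = calls.meth[ctx_mask].astype(float)
    total = calls.total[ctx_mask].astype(float)
    qualifying = total >= min_reads
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(qualifying, 100.0 * meth / np.maximum(total, 1.0), np.nan)

    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, idx in sites.groupby("chrom", sort=False).indices.items():
        pos = sites["pos"].to_numpy()[idx]
        by_chrom[str(chrom)] = (pos, idx)

    ids = _region_ids(regions)
    n_cyt = np.zeros(len(regions), dtype=int)
    means = np.full((len(regions), len(calls.samples)), np.nan)
    for i, (_, row) in enumerate(regions.iterrows()):
        chrom = str(row["chrom"])
        if chrom not in by_chrom:
            continue
        pos, idx = by_chrom[chrom]
        lo = np.searchsorted(pos, row["start"], side="left")
        hi = np.searchsorted(pos, row["end"], side="left")
        sel = idx[lo:hi]
        n_cyt[i] = len(sel)
        if len(sel):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                means[i] = np.nanmean(pct[sel], axis=0)

    empty = n_cyt == 0
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} region(s) without {context} cytosines were skipped",
            stacklevel=2,
        )
    out_regions = regions.copy()
    out_regions.index = ids
    return RegionMethylation(
        regions=out_regions,
        mean_pct=pd.DataFrame(means, index=ids, columns=calls.samples),
        n_cytosines=pd.Series(n_cyt, index=ids, name="n_cytosines"),
    )


def filter_by_missingness(region_meth: RegionMethylation, max_na: int = 7) -> RegionMethylation:
    """Retain regions with at most ``max_na`` samples lacking coverage.

    The default of 7 presumes a methylome panel of 73 samples; for panels of
    a different size a proportional value (max_na / 73 of the sample count)
    is the intended scaling and should be passed explicitly.
    """
    keep = region_meth.na_count <= max_na
    idx = region_meth.mean_pct.index[keep]
    return RegionMethylation(
        regions=region_meth.regions.loc[idx],
        mean_pct=region_meth.mean_pct.loc[idx],
        n_cytosines=region_meth.n_cytosines.loc[idx],
    )


def call_dmrs_simple(
    calls: MethylCalls,
    regions: pd.DataFrame,
    groups: dict[str, str],
    context: str = "CG",
    min_c: int = 10,
    min_cov: int = 3,
    min_diff_pct: float = 20.0,
) -> pd.DataFrame:
    """Two-group DMR caller over candidate regions.

    ``groups`` maps each sample to ``"mutant"`` or ``"WT"``.  A region is a
    DMR when it contains at least ``min_c`` cytosines of ``context``, every
    contributing cytosine has coverage >= ``min_cov`` (enforced during mean
    computation), and the absolute difference of group mean percentages is at
    least ``min_diff_pct``.  Group means average the per-sample region means
    of samples with data.
    """
    missing = set(calls.samples) - set(groups)
    if missing:
        raise ValueError(f"samples without group label: {sorted(missing)}")
    bad = set(groups.values()) - {"mutant", "WT"}
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")

    rm = region_methylation_matrix(calls, regions, context=context, min_reads=min_cov)
    mut_samples = [s for s in calls.samples if groups[s] == "mutant"]
    wt_samples = [s for s in calls.samples if groups[s] == "WT"]
    mean_mut = rm.mean_pct[mut_samples].mean(axis=1, skipna=True)
    mean_wt = rm.mean_pct[wt_samples].mean(axis=1, skipna=True)
    no_data = mean_mut.isna() | mean_wt.isna()
    if no_data.any():
        warnings.warn(
            f"{int(no_data.sum())} region(s) skipped: one group has no covered sample",
            stacklevel=2,
        )
    diff = mean_mut - mean_wt
    keep = (~no_data) & (rm.n_cytosines >= min_c) & (diff.abs() >= min_diff_pct)
    out = rm.regions.loc[keep, ["chrom", "start", "end"]].copy()
    out["context"] = context
    out["n_cytosines"] = rm.n_cytosines[keep]
    out["mean_mutant"] = mean_mut[keep]
    out["mean_wt"] = mean_wt[keep]
    out["diff"] = diff[keep]
    return out


def global_context_means(
    calls: MethylCalls, context: str, weight_by_coverage: bool = False
) -> pd.Series:
    """Per-sample mean methylation percent over covered sites of a context.

    Unweighted by default: every site with at least one read contributes
    ``100 * meth / total`` equally.  With ``weight_by_coverage`` the mean is
    read-weighted (sum meth / sum total).
    """
    mask = (calls.sites["context"] == context).to_numpy()
    if not mask.any():
        raise ValueError(f"no sites of context {context}")
    meth = calls.meth[mask].astype(float)
    total = calls.total[mask].astype(float)
    if weight_by_coverage:
        denom = total.sum(axis=0)
        out = np.where(denom > 0, 100.0 * meth.sum(axis=0) / np.maximum(denom, 1), np.nan)
    else:
        covered = total >= 1
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(covered, 100.0 * meth / np.maximum(total, 1.0), np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out = np.nanmean(pct, axis=0)
    return pd.Series(out, index=calls.samples, name=f"mean_{context}_pct")


def intersect_features(
    a: pd.DataFrame, b: pd.DataFrame, min_overlap: int = 1
) -> tuple[pd.DataFrame, pd.Series]:
    """All interval pairs overlapping by at least ``min_overlap`` bases.

    Coordinates are half-open, so touching intervals do not overlap.  Returns
    the pair table (a_index, b_index, overlap length) and a boolean flag per
    a-interval marking whether it was hit at all.  Uses a sweep over
    start-sorted intervals with an active heap keyed on end coordinates.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    check_intervals(a)
    check_intervals(b)
    pairs: list[tuple] = []
    a_groups = {str(c): g for c, g in a.groupby("chrom", sort=False)}
    b_groups = {str(c): g for c, g in b.groupby("chrom", sort=False)}
    for chrom in a_groups:
        if chrom not in b_groups:
            continue
        ga = a_groups[chrom].sort_values("start")
        gb = b_groups[chrom].sort_values("start")
        b_iter = list(gb[["start", "end"]].itertuples())
        active: list[tuple] = []  # heap of (end, start, b_index)
        j = 0
        for ai, (a_start, a_end) in zip(ga.index, ga[["start", "end"]].to_numpy()):
            while j < len(b_iter) and b_iter[j].start < a_end:
                row = b_iter[j]
                heapq.heappush(active, (row.end, row.start, row.Index))
                j += 1
            while active and active[0][0] <= a_start:
                heapq.heappop(active)
            for b_end, b_start, bi in active:
                if b_start >= a_end:
                    continue
                ov = min(a_end, b_end) - max(a_start, b_start)
                if ov >= min_overlap:
                    pairs.append((ai, bi, int(ov)))
    pair_df = pd.DataFrame(pairs, columns=["a_index", "b_index", "overlap"])
    hit = pd.Series(False, index=a.index, name="hit")
    if len(pair_df):
        hit[pair_df["a_index"].unique()] = True
    return pair_df, hit
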