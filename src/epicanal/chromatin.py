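"""Chromatin-accessibility processing: consensus peaks, TMM/CPM, ACR selection.

Replicate peak sets (narrowPeak, pre-filtered at q <= 0.001) are combined
into consensus intervals by base-pair occupancy in at least two of three
replicates per group, then union-merged across groups.  Peak counts are
normalized by trimmed-mean-of-M-values (TMM) scaling factors and expressed
as counts per million (CPM).  Differential ACRs (dACRs) are peaks whose
mutant lines agree in direction and whose mutant-vs-wild-type log2 change
reaches a magnitude threshold in at least two accessions; highly variable
dACRs (HV-dACRs) are the union of the top quartiles of two
coefficient-of-variation filters, and are subgrouped by k-means on z-scaled
profiles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .core import HOM_GENOTYPES, SampleMeta, design_frame

NARROWPEAK_COLUMNS = [
    "chrom",
    "start",
    "end",
    "name",
    "score",
    "strand",
    "signal",
    "p_neglog10",
    "q_neglog10",
    "summit",
]


def read_filtered_peaks(path, q_max: float = 0.001) -> pd.DataFrame:
    """Read a narrowPeak file, keeping peaks with q <= q_max (inclusive).

    narrowPeak stores -log10(q); the comparison is done on the linear scale
    with a small guard so that a peak written at exactly the boundary is
    retained.  Malformed lines raise with their line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise ValueError(f"{path}:{lineno}: expected 10 narrowPeak fields")
            try:
                start, end = int(fields[1]), int(fields[2])
                q_neglog10 = float(fields[8])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparsable numeric field") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end")
            q = 10.0 ** (-q_neglog10)
            if q <= q_max * (1.0 + 1e-9):
                rows.append(
                    (fields[0], start, end, fields[3], int(float(fields[4])),
                     fields[5], float(fields[6]), float(fields[7]), q, int(fields[9]))
                )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "name", "score", "strand",
                 "signal", "p_neglog10", "q", "summit"],
    )


def _merge_intervals(iv: list[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    out: list[tuple[str, int, int]] = []
    for chrom, start, end in sorted(iv):
        if out and out[-1][0] == chrom and start <= out[-1][2]:
            out[-1] = (chrom, out[-1][1], max(out[-1][2], end))
        else:
            out.append((chrom, start, end))
    return out


def _coverage_intervals(
    replicate_peaks: list[pd.DataFrame], min_replicates: int
) -> list[tuple[str, int, int]]:
    """Base positions covered by >= min_replicates replicates, as intervals."""
    events: dict[str, list[tuple[int, int]]] = {}
    for rep in replicate_peaks:
        merged = _merge_intervals(
            list(zip(rep["chrom"].astype(str), rep["start"].astype(int), rep["end"].astype(int)))
        )
        for chrom, start, end in merged:
            events.setdefault(chrom, []).append((start, 1))
            events[chrom].append((end, -1))
    out: list[tuple[str, int, int]] = []
    for chrom, evs in events.items():
        # aggregate deltas at identical positions so threshold crossings are clean
        agg: dict[int, int] = {}
        for p, delta in evs:
            agg[p] = agg.get(p, 0) + delta
        cov = 0
        open_start: int | None = None
        for p in sorted(agg):
            cov_before = cov
            cov += agg[p]
            if cov_before < min_replicates <= cov:
                open_start = p
            elif cov_before >= min_replicates > cov:
                out.append((chrom, open_start, p))
                open_start = None
    return sorted(out)


def consensus_peaks(
    grouped_peaks: dict[str, list[pd.DataFrame]], min_replicates: int = 2
) -> pd.DataFrame:
    """Occupancy-based consensus intervals across replicate groups.

    ``grouped_peaks`` maps a group key (accession/genotype/line) to that
    group's replicate peak frames.  Within each group, positions covered by
    peaks in at least ``min_replicates`` replicates become group peaks; a
    single-replicate group is warned about and contributes its peaks as its
    own evidence.  Group peaks are union-merged into the consensus set.
    """
    all_group_peaks: list[tuple[str, int, int]] = []
    for group, reps in grouped_peaks.items():
        if not reps:
            continue
        if len(reps) < min_replicates:
            warnings.warn(
                f"group {group!r} has {len(reps)} replicate(s); "
                "treating its peaks as their own evidence",
                stacklevel=2,
            )
            threshold = len(reps)
        else:
            threshold = min_replicates
        all_group_peaks.extend(_coverage_intervals(reps, threshold))
    merged = _merge_intervals(all_group_peaks)
    df = pd.DataFrame(merged, columns=["chrom", "start", "end"])
    df.index = pd.Index([f"peak_{i + 1:05d}" for i in range(len(df))])
    return df


# ---------------------------------------------------------------------------
# TMM / CPM


@dataclass
class AccessibilityMatrix:
    """Raw peak counts with TMM factors, library sizes and derived CPM."""

    counts: pd.DataFrame
    lib_sizes: pd.Series
    tmm_factors: pd.Series
    cpm: pd.DataFrame


def _tmm_pair(
    obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
    trim_m: float, trim_a: float,
) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / n_obs) / (ref / n_ref))
        abs_e = 0.5 * (np.log2(obs / n_obs) + np.log2(ref / n_ref))
        v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    ok = np.isfinite(log_r) & np.isfinite(abs_e) & (abs_e > -1e10)
    log_r, abs_e, v = log_r[ok], abs_e[ok], v[ok]
    if len(log_r) == 0 or np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = len(log_r)
    lo_l = math.floor(n * trim_m) + 1
    hi_l = n + 1 - lo_l
    lo_s = math.floor(n * trim_a) + 1
    hi_s = n + 1 - lo_s
    rank_m = stats.rankdata(log_r)
    rank_a = stats.rankdata(abs_e)
    keep = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
    if not keep.any():
        return 1.0
    w = 1.0 / v[keep]
    f = float(np.sum(w * log_r[keep]) / np.sum(w))
    return 2.0**f


def tmm_cpm(
    counts: pd.DataFrame, trim_m: float = 0.3, trim_a: float = 0.05
) -> AccessibilityMatrix:
    """TMM scaling factors and CPM for a peak × sample count matrix.

    The reference sample is the one whose upper-quartile count fraction is
    closest to the mean across samples.  For every other sample a doubly
    trimmed (on M and A) weighted mean of log-ratios gives the log2 factor;
    factors are rescaled to geometric mean 1 and CPM divides counts by
    ``lib_size * factor / 1e6``.
    """
    arr = counts.to_numpy(dtype=float)
    lib = arr.sum(axis=0)
    if (lib <= 0).any():
        bad = counts.columns[lib <= 0].tolist()
        raise ValueError(f"all-zero sample(s): {bad}")
    with np.errstate(invalid="ignore"):
        f75 = np.array([
            np.quantile(arr[arr[:, j] > 0, j] if (arr[:, j] > 0).any() else np.zeros(1), 0.75)
            / lib[j]
            for j in range(arr.shape[1])
        ])
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.ones(arr.shape[1])
    for j in range(arr.shape[1]):
        factors[j] = _tmm_pair(
            arr[:, j], arr[:, ref_idx], lib[j], lib[ref_idx], trim_m, trim_a
        )
    factors = factors / np.exp(np.mean(np.log(factors)))
    lib_sizes = pd.Series(lib, index=counts.columns, name="lib_size")
    tmm = pd.Series(factors, index=counts.columns, name="tmm_factor")
    cpm = counts / (lib_sizes * tmm) * 1e6
    return AccessibilityMatrix(counts=counts, lib_sizes=lib_sizes, tmm_factors=tmm, cpm=cpm)


def frip(in_peak_reads: pd.Series, total_mapped_reads: pd.Series) -> pd.Series:
    """Fraction of mapped reads inside peaks, per sample."""
    totals = total_mapped_reads.reindex(in_peak_reads.index)
    if (totals < in_peak_reads).any():
        bad = in_peak_reads.index[totals < in_peak_reads].tolist()
        raise ValueError(f"total mapped reads < in-peak reads for: {bad}")
    return (in_peak_reads / totals).rename("frip")


# ---------------------------------------------------------------------------
# dACR / HV-dACR selection


def select_dacrs(
    matrix: AccessibilityMatrix,
    design: list[SampleMeta] | pd.DataFrame,
    min_accessions: int = 2,
    delta_log2: float = 1.0,
    consistency_tol: float = 0.25,
) -> pd.Index:
    """Differential ACRs: line-consistent peaks changed in >= min_accessions.

    Stage 1 drops peaks where, in any accession with two mutant lines, the
    two line-vs-wild-type log2(CPM+1) differences conflict in sign beyond
    ``consistency_tol``.  Stage 2 keeps peaks whose overall
    |mutant − wild-type| log2(CPM+1) difference reaches ``delta_log2`` in at
    least ``min_accessions`` accessions.
    """
    design_df = design if isinstance(design, pd.DataFrame) else design_frame(design)
    design_df = design_df.loc[matrix.cpm.columns]
    log_cpm = np.log2(matrix.cpm + 1.0)

    consistent = pd.Series(True, index=matrix.cpm.index)
    n_changed = pd.Series(0, index=matrix.cpm.index)
    for acc, sub in design_df.groupby("accession", sort=True):
        wt = sub.index[sub["genotype"] == "WT"]
        if len(wt) == 0:
            raise ValueError(f"accession {acc!r} has no wild-type samples")
        wt_mean = log_cpm[wt].mean(axis=1)
        mut = sub[sub["genotype"] != "WT"]
        line_deltas = []
        for _, line_sub in mut.groupby("line", sort=True):
            line_deltas.append(log_cpm[line_sub.index].mean(axis=1) - wt_mean)
        if len(line_deltas) >= 2:
            d1, d2 = line_deltas[0], line_deltas[1]
            conflict = (np.sign(d1) * np.sign(d2) < 0) & ~(
                (d1.abs() <= consistency_tol) & (d2.abs() <= consistency_tol)
            )
            consistent &= ~conflict
        if len(mut):
            overall = log_cpm[mut.index].mean(axis=1) - wt_mean
            n_changed += (overall.abs() >= delta_log2).astype(int)
    keep = consistent & (n_changed >= min_accessions)
    return matrix.cpm.index[keep]


def _two_point_cv(a: pd.Series, b: pd.Series) -> pd.Series:
    """CV of two group means with sample SD: |a-b| / (sqrt(2) * mean)."""
    mean = (a + b) / 2.0
    sd = (a - b).abs() / np.sqrt(2.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = sd / mean
    cv[mean <= 0] = np.nan
    return cv


def select_hv_dacrs(
    matrix: AccessibilityMatrix,
    design: list[SampleMeta] | pd.DataFrame,
    dacr_ids: pd.Index,
    quantile: float = 0.25,
) -> tuple[pd.Index, pd.DataFrame]:
    """Highly variable dACRs: union of two top-quartile CV filters.

    Filter A ranks each dACR by the CV of the two group means (homozygous
    mutants vs wild types); filter B by the CV over accession × genotype
    group mean CPM.  Each filter keeps the top ``ceil(quantile * n)`` peaks;
    the union is returned together with the per-filter CV values.
    """
    if len(dacr_ids) < 4:
        raise ValueError("need at least 4 dACRs for quantile selection")
    design_df = design if isinstance(design, pd.DataFrame) else design_frame(design)
    design_df = design_df.loc[matrix.cpm.columns]
    cpm = matrix.cpm.loc[dacr_ids]

    hom = design_df.index[design_df["genotype"].isin(HOM_GENOTYPES)]
    wt = design_df.index[design_df["genotype"] == "WT"]
    if len(hom) == 0 or len(wt) == 0:
        raise ValueError("need both homozygous-mutant and wild-type samples")
    cv_a = _two_point_cv(cpm[hom].mean(axis=1), cpm[wt].mean(axis=1))

    group = design_df["accession"] + ":" + design_df["genotype"]
    if group.nunique() < 2:
        raise ValueError("need at least 2 accession×genotype groups")
    group_means = cpm.T.groupby(group.to_numpy()).mean().T
    mean_b = group_means.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv_b = group_means.std(axis=1, ddof=1) / mean_b
    cv_b[mean_b <= 0] = np.nan

    n_keep = math.ceil(quantile * len(dacr_ids))

    def _top(cv: pd.Series) -> pd.Index:
        return cv.fillna(-np.inf).sort_values(ascending=False, kind="mergesort").index[:n_keep]

    hv = _top(cv_a).union(_top(cv_b))
    cvs = pd.DataFrame({"cv_group_diff": cv_a, "cv_samples": cv_b})
    return pd.Index(sorted(hv)), cvs


def cluster_hv_dacrs(
    matrix: AccessibilityMatrix,
    hv_ids: pd.Index,
    k: int = 3,
    seed: int = 0,
) -> tuple[pd.Series, pd.Series]:
    """Z-scale HV-dACR profiles and partition them with k-means.

    Rows are scaled to mean 0 / SD 1 across samples (zero-variance rows are
    excluded with a warning), then clustered with k-means++ and 10 restarts
    under a fixed seed.  Returns labels (1..k) and per-cluster mean raw CPM.
    """
    cpm = matrix.cpm.loc[hv_ids]
    mu = cpm.mean(axis=1)
    sd = cpm.std(axis=1, ddof=0)
    usable = sd > 0
    if (~usable).any():
        warnings.warn(
            f"{int((~usable).sum())} zero-variance row(s) excluded from clustering",
            stacklevel=2,
        )
    z = cpm[usable].sub(mu[usable], axis=0).div(sd[usable], axis=0)
    if k > len(z):
        raise ValueError(f"k={k} exceeds number of usable rows ({len(z)})")
    km = KMeans(n_clusters=k, n_init=10, random_state=int(seed) % (2**31))
    labels = pd.Series(km.fit_predict(z.to_numpy()) + 1, index=z.index, name="cluster")
    mean_acc = cpm[usable].mean(axis=1).groupby(labels).mean().rename("mean_cpm")
    return labels, mean_acc
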