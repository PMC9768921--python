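"""Joining expression, methylation and accessibility per gene and accession.

Each gene gets strand-aware windows: an extended body (100 bp beyond the
TSS and TTS) and 1.5 kb cis flanks beyond the extended body.  Differential
features (DMRs, HV-dACRs) overlapping a window are assigned to the gene,
keeping only the feature with the largest absolute change per accession.
Genes are then cross-tabulated by their feature pattern, binned into
wild-type expression/methylation quintiles, and classified into gene-body
methylated (gbM-like) and TE-methylation-like (teM-like) states.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .methylation import intersect_features

CATEGORIES = ("both", "dmr_only", "dacr_only", "neither")


@dataclass
class EpistateThresholds:
    """Window sizes and epigenetic-state cut-offs.

    gbM-like requires >80% wild-type CG methylation in the gene body and
    expression at or above the 40th-percentile boundary (top three
    quintiles); teM-like requires the same methylation but expression at or
    below the 20th-percentile boundary (lowest quintile).
    """

    gbm_meth_min: float = 80.0
    extended_upstream: int = 100
    extended_downstream: int = 100
    cis_flank: int = 1500
    gbm_expr_min_quantile: float = 0.4
    tem_expr_max_quantile: float = 0.2

    def __post_init__(self) -> None:
        if self.extended_upstream < 0 or self.extended_downstream < 0 or self.cis_flank < 0:
            raise ValueError("flanks must be non-negative")
        for q in (self.gbm_expr_min_quantile, self.tem_expr_max_quantile):
            if not 0.0 <= q <= 1.0:
                raise ValueError("quantiles must lie in [0, 1]")


def gene_windows(
    start: int, end: int, strand: str, thresholds: EpistateThresholds | None = None
) -> dict[str, tuple[int, int]]:
    """Extended body and cis flank intervals for one gene, clipped at 0.

    For a + strand gene the TSS is at ``start``; the extended body runs from
    ``extended_upstream`` before the TSS to ``extended_downstream`` past the
    TTS, and the cis windows are the ``cis_flank`` stretches beyond it.  On
    the − strand the upstream flank lies at higher coordinates.
    """
    t = thresholds or EpistateThresholds()
    if end <= start:
        raise ValueError("gene interval must have positive length")
    if strand == "+":
        body = (start - t.extended_upstream, end + t.extended_downstream)
    elif strand == "-":
        body = (start - t.extended_downstream, end + t.extended_upstream)
    else:
        raise ValueError(f"unknown strand {strand!r}")
    body = (max(0, body[0]), body[1])
    lower = (max(0, body[0] - t.cis_flank), body[0])
    upper = (body[1], body[1] + t.cis_flank)
    if strand == "+":
        cis_up, cis_down = lower, upper
    else:
        cis_up, cis_down = upper, lower
    return {"extended_body": body, "cis_up": cis_up, "cis_down": cis_down}


def _window_frame(
    genes: pd.DataFrame, window_kind: str, thresholds: EpistateThresholds
) -> pd.DataFrame:
    """One or two intervals per gene covering the requested window kind."""
    rows = []
    for gid, g in genes.iterrows():
        w = gene_windows(int(g["start"]), int(g["end"]), str(g["strand"]), thresholds)
        if window_kind == "body":
            spans = [w["extended_body"]]
        elif window_kind == "cis":
            spans = [w["cis_up"], w["cis_down"]]
        elif window_kind == "cis_incl_body":
            lo = min(w["cis_up"][0], w["cis_down"][0], w["extended_body"][0])
            hi = max(w["cis_up"][1], w["cis_down"][1], w["extended_body"][1])
            spans = [(lo, hi)]
        else:
            raise ValueError(f"unknown window kind {window_kind!r}")
        for s, e in spans:
            if e > s:
                rows.append((gid, g["chrom"], s, e))
    out = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])
    return out


def assign_strongest_feature(
    genes: pd.DataFrame,
    features: pd.DataFrame,
    deltas: pd.DataFrame,
    window_kind: str = "cis_incl_body",
    thresholds: EpistateThresholds | None = None,
) -> pd.DataFrame:
    """Per gene and accession, the overlapping feature with the largest |Δ|.

    ``features`` is a BED-like frame indexed by feature id; ``deltas`` holds
    the per-accession change of each feature (feature × accession).  Among
    features overlapping the requested window of a gene, the one with the
    maximal absolute change is kept for each accession, ties broken by
    leftmost feature start.  Returns a long frame (gene_id, accession,
    feature_id, delta); genes without any overlapping feature are absent.
    """
    t = thresholds or EpistateThresholds()
    windows = _window_frame(genes, window_kind, t)
    if windows.empty or features.empty:
        return pd.DataFrame(columns=["gene_id", "accession", "feature_id", "delta"])
    pairs, _ = intersect_features(windows, features[["chrom", "start", "end"]])
    rows = []
    if len(pairs):
        pairs = pairs.assign(gene_id=windows.loc[pairs["a_index"], "gene_id"].to_numpy())
        starts = features["start"]
        for gid, sub in pairs.groupby("gene_id", sort=True):
            feat_ids = pd.Index(sub["b_index"].unique())
            d = deltas.loc[feat_ids]
            order = starts.loc[feat_ids]
            for acc in deltas.columns:
                col = d[acc]
                if col.isna().all():
                    continue
                best_val = col.abs().max()
                candidates = col.index[col.abs() == best_val]
                best = candidates[np.argsort(order.loc[candidates].to_numpy(), kind="stable")][0]
                rows.append((gid, acc, best, float(col.loc[best])))
    return pd.DataFrame(rows, columns=["gene_id", "accession", "feature_id", "delta"])


def categorize_epistate(
    genes: pd.DataFrame,
    accessions: list[str],
    d_expr: pd.DataFrame,
    dmr_assignments: pd.DataFrame,
    dacr_assignments: pd.DataFrame,
) -> pd.DataFrame:
    """Four-way feature category per gene × accession.

    ``d_expr`` is gene × accession (mean transformed-count difference,
    mutant − wild type); assignment frames come from
    :func:`assign_strongest_feature`.  Category counts conserve the full
    gene-universe × accession grid.
    """
    dmr_map = dmr_assignments.set_index(["gene_id", "accession"]) if len(dmr_assignments) else None
    dacr_map = dacr_assignments.set_index(["gene_id", "accession"]) if len(dacr_assignments) else None
    rows = []
    for gid in genes.index:
        for acc in accessions:
            key = (gid, acc)
            d_meth = np.nan
            d_acc_val = np.nan
            if dmr_map is not None and key in dmr_map.index:
                d_meth = float(dmr_map.loc[key, "delta"])
            if dacr_map is not None and key in dacr_map.index:
                d_acc_val = float(dacr_map.loc[key, "delta"])
            has_dmr = not np.isnan(d_meth)
            has_dacr = not np.isnan(d_acc_val)
            category = (
                "both" if has_dmr and has_dacr
                else "dmr_only" if has_dmr
                else "dacr_only" if has_dacr
                else "neither"
            )
            expr = (
                d_expr.at[gid, acc]
                if gid in d_expr.index and acc in d_expr.columns
                else np.nan
            )
            rows.append((gid, acc, float(expr), d_meth, d_acc_val, category))
    return pd.DataFrame(
        rows, columns=["gene_id", "accession", "d_expr", "d_meth", "d_acc", "category"]
    )


def quintile_bins(values) -> tuple[pd.Series, np.ndarray]:
    """Quintile labels 1..5 with empirical 20/40/60/80 percentile boundaries.

    Boundaries use linear-interpolation percentiles; a value equal to a
    boundary falls in the lower bin.
    """
    s = pd.Series(values, dtype=float)
    finite = s.dropna()
    if len(finite) < 5:
        raise ValueError("need at least 5 finite values for quintiles")
    boundaries = np.percentile(finite, [20, 40, 60, 80])
    labels = pd.Series(
        np.searchsorted(boundaries, s.to_numpy(), side="left") + 1, index=s.index
    )
    labels[s.isna()] = np.nan
    return labels, boundaries


def classify_gbm_tem(
    wt_meth_pct: pd.Series,
    wt_expr: pd.Series,
    expr_boundaries: np.ndarray,
    thresholds: EpistateThresholds | None = None,
) -> pd.Series:
    """gbM-like / teM-like / neither labels for genes with body CG-DMRs.

    ``expr_boundaries`` are the quintile boundaries of wild-type expression
    over the full analyzed gene set (so the 40th/20th-percentile cut-offs
    are dataset quantiles, not constants).  Labels are disjoint whenever the
    two boundaries differ.
    """
    t = thresholds or EpistateThresholds()
    b20, b40 = float(expr_boundaries[0]), float(expr_boundaries[1])
    meth_ok = wt_meth_pct > t.gbm_meth_min
    labels = pd.Series("neither", index=wt_meth_pct.index)
    labels[meth_ok & (wt_expr >= b40)] = "gbM_like"
    labels[meth_ok & (wt_expr <= b20)] = "teM_like"
    return labels


def metaplot_profile(
    sites: pd.DataFrame,
    values: np.ndarray,
    features: pd.DataFrame,
    flank: int = 1000,
    bin_size: int = 10,
    body_bins: int = 100,
    sample_names: list[str] | None = None,
) -> pd.DataFrame:
    """Binned mean signal over features with flanks, strand-flipped.

    ``sites`` holds chrom/pos of signal-carrying positions and ``values``
    the per-position signal (n_sites × n_samples).  Flanks are split into
    ``flank / bin_size`` non-overlapping bins; the body is scaled to
    ``body_bins`` bins.  Bins average the positions they contain; profiles
    of − strand features are reversed before averaging across features.
    """
    if flank % bin_size != 0:
        raise ValueError("flank must be divisible by bin_size")
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] != len(sites):
        values = values.T
    n_samples = values.shape[1]
    n_flank = flank // bin_size
    n_bins = 2 * n_flank + body_bins

    by_chrom = {}
    for chrom, idx in sites.groupby("chrom", sort=False).indices.items():
        pos = sites["pos"].to_numpy()[idx]
        order = np.argsort(pos)
        by_chrom[str(chrom)] = (pos[order], idx[order])

    profiles = np.full((len(features), n_bins, n_samples), np.nan)
    short_warned = False
    for f_i, (_, feat) in enumerate(features.iterrows()):
        chrom = str(feat["chrom"])
        if chrom not in by_chrom:
            continue
        pos, idx = by_chrom[chrom]
        start, end = int(feat["start"]), int(feat["end"])
        edges = np.concatenate(
            [
                start - flank + bin_size * np.arange(n_flank + 1, dtype=float),
                start + (end - start) * (np.arange(1, body_bins + 1) / body_bins),
                end + bin_size * np.arange(1, n_flank + 1, dtype=float),
            ]
        )
        if end - start < bin_size and not short_warned:
            warnings.warn("feature(s) shorter than one bin; body collapsed", stacklevel=2)
            short_warned = True
        bounds = np.searchsorted(pos, edges)
        lo, hi = bounds[:-1], bounds[1:]
        for b in range(n_bins):
            if hi[b] > lo[b]:
                profiles[f_i, b] = np.nanmean(values[idx[lo[b]:hi[b]]], axis=0)
        if str(feat.get("strand", "+")) == "-":
            profiles[f_i] = profiles[f_i, ::-1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_profile = np.nanmean(profiles, axis=0)
    labels = (
        [f"up_{i + 1:03d}" for i in range(n_flank)]
        + [f"body_{i + 1:03d}" for i in range(body_bins)]
        + [f"down_{i + 1:03d}" for i in range(n_flank)]
    )
    columns = sample_names if sample_names is not None else list(range(n_samples))
    return pd.DataFrame(mean_profile, index=labels, columns=columns)
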