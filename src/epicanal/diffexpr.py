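"""Negative-binomial differential expression and canalization statistics.

The testing machinery is a deliberately transparent re-implementation of the
standard count-based workflow: median-of-ratios size factors, per-gene
method-of-moments dispersion with a floor, a negative-binomial GLM with log
link fitted by iteratively reweighted least squares, Wald contrasts, and
Benjamini-Hochberg adjustment.  Two designs are supported:

* ``accession_only`` — cell means per accession within one genotype group;
  the accession contrast compares one accession against the average of the
  others;
* ``genotype_x_accession`` — wild-type cell means per accession plus a
  mutant-vs-wild-type effect nested within each accession; the genotype
  contrast is either one accession's nested effect or the balanced average
  over all accessions (the "all mutants vs all wild types" contrast).

Expression variability across accessions is summarized per gene by the
coefficient of variation of per-accession mean transformed counts, compared
between genotype groups with a one-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import SampleMeta, design_frame

DISPERSION_FLOOR = 1e-4
DISPERSION_CAP = 50.0


# ---------------------------------------------------------------------------
# filtering, normalization, transformation


def filter_low_count_genes(counts: pd.DataFrame, min_total: int | None = None) -> pd.Index:
    """Genes whose total count across samples reaches ``min_total``.

    The default threshold equals the number of samples, i.e. a mean count of
    at least one read per sample.
    """
    if counts.size == 0:
        raise ValueError("empty count matrix")
    if min_total is None:
        min_total = counts.shape[1]
    totals = counts.sum(axis=1)
    return counts.index[totals >= min_total]


def median_ratio_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors against the geometric-mean pseudo-gene."""
    arr = counts.to_numpy(dtype=float)
    ref = (arr > 0).all(axis=1)
    if not ref.any():
        raise ValueError(
            "no gene has non-zero counts in every sample; supply a filtered "
            "matrix or use a pseudo-reference"
        )
    log_geo = np.log(arr[ref]).mean(axis=1)
    ratios = np.log(arr[ref]) - log_geo[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


@dataclass
class TransformedMatrix:
    """log2(count / size_factor + 1) values; monotone in counts per sample."""

    values: pd.DataFrame
    size_factors: pd.Series


def transform_counts(counts: pd.DataFrame, size_factors: pd.Series) -> TransformedMatrix:
    if (size_factors <= 0).any():
        raise ValueError("size factors must be positive")
    sf = size_factors.reindex(counts.columns)
    values = np.log2(counts.div(sf, axis=1) + 1.0)
    return TransformedMatrix(values=values, size_factors=sf)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values; NaNs are carried through."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    m = ok.sum()
    if m == 0:
        return out
    order = np.argsort(p[ok], kind="mergesort")
    ranked = p[ok][order] * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    vals = np.empty(m)
    vals[order] = np.minimum(adj, 1.0)
    out[ok] = vals
    return out


# ---------------------------------------------------------------------------
# NB GLM


def _design_matrix(
    design_df: pd.DataFrame, model: str
) -> tuple[np.ndarray, list[str], pd.Series]:
    accs = sorted(design_df["accession"].unique())
    is_mut = design_df["genotype"].ne("WT")
    cols: list[str] = []
    mats: list[np.ndarray] = []
    for a in accs:
        mats.append((design_df["accession"] == a).to_numpy(float))
        cols.append(f"acc:{a}")
    if model == "genotype_x_accession":
        for a in accs:
            mats.append(((design_df["accession"] == a) & is_mut).to_numpy(float))
            cols.append(f"mut:{a}")
    elif model != "accession_only":
        raise ValueError(f"unknown model {model!r}")
    X = np.column_stack(mats)
    return X, cols, is_mut


def _contrast_vector(
    contrast: dict, cols: list[str], model: str, design_df: pd.DataFrame
) -> np.ndarray:
    accs = sorted(design_df["accession"].unique())
    c = np.zeros(len(cols))
    kind = contrast.get("type")
    if model == "genotype_x_accession":
        if kind != "genotype":
            raise ValueError("interaction model supports genotype contrasts")
        acc = contrast.get("accession")
        targets = [acc] if acc else accs
        for a in targets:
            col = f"mut:{a}"
            if col not in cols:
                raise ValueError(f"no mutant cell for accession {a!r}")
            n_mut = int(
                ((design_df["accession"] == a) & design_df["genotype"].ne("WT")).sum()
            )
            n_wt = int(((design_df["accession"] == a) & design_df["genotype"].eq("WT")).sum())
            if n_mut == 0 or n_wt == 0:
                raise ValueError(
                    f"contrast not estimable: empty cell in accession {a!r} "
                    f"(mutant n={n_mut}, WT n={n_wt})"
                )
            c[cols.index(col)] = 1.0 / len(targets)
    elif model == "accession_only":
        if kind != "accession":
            raise ValueError("accession_only model supports accession contrasts")
        acc = contrast["accession"]
        col = f"acc:{acc}"
        if col not in cols:
            raise ValueError(f"unknown accession {acc!r} in contrast")
        others = [a for a in accs if a != acc]
        if not others:
            raise ValueError("accession contrast needs at least two accessions")
        c[cols.index(col)] = 1.0
        for a in others:
            c[cols.index(f"acc:{a}")] = -1.0 / len(others)
    else:
        raise ValueError(f"unknown model {model!r}")
    return c


def estimate_dispersions(
    counts: pd.DataFrame, size_factors: pd.Series, cells: pd.Series
) -> pd.Series:
    """Per-gene method-of-moments dispersion pooled over design cells.

    On normalized counts q = y / s, E q = mu and Var q ≈ mu * E(1/s) +
    alpha * mu^2 within a cell, so alpha is estimated by the ratio of pooled
    excess variance to pooled squared means, floored at 1e-4.
    """
    arr = counts.to_numpy(dtype=float)
    sf = size_factors.reindex(counts.columns).to_numpy()
    q = arr / sf
    num = np.zeros(arr.shape[0])
    den = np.zeros(arr.shape[0])
    cells_arr = np.asarray(cells)
    for cell in pd.unique(cells_arr):
        j = np.flatnonzero(cells_arr == cell)
        n_c = len(j)
        if n_c < 2:
            continue
        qc = q[:, j]
        mean_c = qc.mean(axis=1)
        var_c = qc.var(axis=1, ddof=1)
        r_c = float(np.mean(1.0 / sf[j]))
        num += (n_c - 1) * (var_c - mean_c * r_c)
        den += (n_c - 1) * mean_c**2
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = np.where(den > 0, num / den, DISPERSION_FLOOR)
    alpha = np.clip(alpha, DISPERSION_FLOOR, DISPERSION_CAP)
    return pd.Series(alpha, index=counts.index, name="dispersion")


def _fit_nb_glm(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    alpha: float,
    max_iter: int = 60,
    tol: float = 1e-8,
    mu_floor: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """IRLS fit of an NB GLM with log link and known dispersion.

    Returns (beta, covariance, converged); covariance is the inverse
    expected information at the final iterate.  Fitted means are floored at
    ``mu_floor`` inside the weights so that design cells with all-zero
    counts keep a finite working variance (the convention of standard NB
    differential-expression fitters).
    """
    eta = np.log(np.maximum(y, 0.5)) - offset
    beta, *_ = np.linalg.lstsq(X, eta, rcond=None)
    converged = False
    XtWX = np.eye(X.shape[1])
    eta_lo = np.log(mu_floor)
    for _ in range(max_iter):
        eta = np.clip(X @ beta + offset, eta_lo, 30.0)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha * mu)
        z = (eta - offset) + (y - mu) / mu
        Xw = X * w[:, None]
        XtWX = Xw.T @ X
        try:
            new_beta = np.linalg.solve(XtWX, Xw.T @ z)
        except np.linalg.LinAlgError:
            return beta, np.full_like(XtWX, np.nan), False
        step = np.max(np.abs(new_beta - beta))
        beta = new_beta
        if step < tol:
            converged = True
            break
    try:
        cov = np.linalg.inv(XtWX)
    except np.linalg.LinAlgError:
        cov = np.full_like(XtWX, np.nan)
    return beta, cov, converged


def nb_wald_contrasts(
    counts: pd.DataFrame,
    design: list[SampleMeta] | pd.DataFrame,
    model: str,
    contrasts: dict[str, dict],
    size_factors: pd.Series | None = None,
    dispersions: pd.Series | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-gene Wald tests of several contrasts from one model fit.

    Each result frame is indexed by gene with base_mean, log2fc, se, stat,
    p and BH-adjusted padj (adjusted within each contrast).  Non-convergent
    genes are flagged (``converged`` False) with missing p.  P-values use a
    t reference with residual degrees of freedom, which keeps the test
    calibrated when the plug-in dispersion is estimated from few samples;
    with many residual degrees of freedom it coincides with the normal
    reference.
    """
    design_df = design if isinstance(design, pd.DataFrame) else design_frame(design)
    design_df = design_df.loc[counts.columns]
    X, cols, is_mut = _design_matrix(design_df, model)
    cvecs = {
        name: _contrast_vector(spec, cols, model, design_df)
        for name, spec in contrasts.items()
    }

    if size_factors is None:
        size_factors = median_ratio_size_factors(counts)
    offset = np.log(size_factors.reindex(counts.columns).to_numpy())

    if dispersions is None:
        if model == "genotype_x_accession":
            cells = design_df["accession"] + ":" + np.where(is_mut, "mut", "wt")
            cells = pd.Series(cells, index=design_df.index)
        else:
            cells = design_df["accession"]
        dispersions = estimate_dispersions(counts, size_factors, cells)

    arr = counts.to_numpy(dtype=float)
    sf = size_factors.reindex(counts.columns).to_numpy()
    base_mean = (arr / sf).mean(axis=1)
    df_resid = max(arr.shape[1] - X.shape[1], 1)

    n_genes = arr.shape[0]
    betas = np.full((n_genes, X.shape[1]), np.nan)
    covs = np.full((n_genes, X.shape[1], X.shape[1]), np.nan)
    conv = np.zeros(n_genes, dtype=bool)
    disp = dispersions.reindex(counts.index).to_numpy()
    for g in range(n_genes):
        betas[g], covs[g], conv[g] = _fit_nb_glm(arr[g], X, offset, float(disp[g]))

    log2e = 1.0 / np.log(2.0)
    out: dict[str, pd.DataFrame] = {}
    for name, c in cvecs.items():
        est = betas @ c
        var = np.einsum("i,gij,j->g", c, covs, c)
        ok = conv & np.isfinite(var) & (var > 0)
        se = np.where(ok, np.sqrt(np.abs(var)), np.nan) * log2e
        stat = np.where(ok, est / np.sqrt(np.where(ok, var, 1.0)), np.nan)
        pvals = np.where(ok, 2.0 * stats.t.sf(np.abs(stat), df_resid), np.nan)
        res = pd.DataFrame(
            {
                "base_mean": base_mean,
                "log2fc": est * log2e,
                "se": se,
                "stat": stat,
                "p": pvals,
                "padj": bh_adjust(pvals),
                "converged": ok,
            },
            index=counts.index,
        )
        res.index.name = "gene_id"
        out[name] = res
    return out


def nb_wald_contrast(
    counts: pd.DataFrame,
    design: list[SampleMeta] | pd.DataFrame,
    model: str,
    contrast: dict,
    size_factors: pd.Series | None = None,
    dispersions: pd.Series | None = None,
) -> pd.DataFrame:
    """Single-contrast convenience wrapper around :func:`nb_wald_contrasts`."""
    return nb_wald_contrasts(
        counts, design, model, {"contrast": contrast}, size_factors, dispersions
    )["contrast"]


# ---------------------------------------------------------------------------
# DEG set logic


@dataclass
class DEGSet:
    """Genes passing the DEG thresholds for one contrast, with directions."""

    contrast_id: str
    table: pd.DataFrame  # index gene_id; columns include log2fc, direction

    @property
    def genes(self) -> frozenset:
        return frozenset(self.table.index)

    @property
    def direction(self) -> pd.Series:
        return self.table["direction"]

    def __len__(self) -> int:
        return len(self.table)


def call_degs(
    results: pd.DataFrame,
    contrast_id: str = "contrast",
    lfc_min: float = 1.0,
    alpha: float = 0.01,
    inclusive: bool = False,
) -> DEGSet:
    """Apply the DEG thresholds to a contrast result table.

    Strict inequalities by default (padj < alpha and |log2fc| > lfc_min);
    ``inclusive`` switches both to >=/<= for the alternative reading of the
    cut-offs.
    """
    padj = results["padj"]
    lfc = results["log2fc"]
    if inclusive:
        keep = (padj <= alpha) & (lfc.abs() >= lfc_min)
    else:
        keep = (padj < alpha) & (lfc.abs() > lfc_min)
    keep &= padj.notna()
    table = results.loc[keep, ["log2fc", "padj"]].copy()
    table["direction"] = np.where(table["log2fc"] > 0, "up", "down")
    return DEGSet(contrast_id=contrast_id, table=table)


def partition_te(degset: DEGSet, annotation: pd.DataFrame) -> tuple[DEGSet, DEGSet]:
    """Split a DEG set into TE-associated and non-TE genes."""
    missing = degset.table.index.difference(annotation.index)
    if len(missing):
        raise ValueError(f"DEGs missing from annotation: {list(missing[:5])}")
    is_te = annotation.loc[degset.table.index, "is_te_gene"].astype(bool)
    te = DEGSet(degset.contrast_id + ":TE", degset.table.loc[is_te.to_numpy()])
    non_te = DEGSet(degset.contrast_id + ":NonTE", degset.table.loc[~is_te.to_numpy()])
    return te, non_te


def consensus_and_universal_sets(
    deg_sets: Sequence[DEGSet], min_sets: int = 2, expected_n: int | None = 19
) -> tuple[DEGSet, DEGSet]:
    """Consensus (genes in >= min_sets contrasts) and universal (in all).

    The canonical input is the 18 per-accession contrasts plus the
    all-mutants-vs-all-wild-types contrast; pass ``expected_n=None`` to lift
    the arity check.
    """
    if expected_n is not None and len(deg_sets) != expected_n:
        raise ValueError(f"expected {expected_n} DEG sets, got {len(deg_sets)}")
    if not deg_sets:
        raise ValueError("no DEG sets supplied")
    membership: dict[str, int] = {}
    directions: dict[str, list[str]] = {}
    for ds in deg_sets:
        for gene in ds.table.index:
            membership[gene] = membership.get(gene, 0) + 1
            directions.setdefault(gene, []).append(ds.table.loc[gene, "direction"])

    def _build(genes: Iterable[str], name: str) -> DEGSet:
        genes = sorted(genes)
        dirs = []
        for g in genes:
            ups = sum(d == "up" for d in directions[g])
            dirs.append("up" if ups * 2 >= len(directions[g]) else "down")
        table = pd.DataFrame(
            {"n_contrasts": [membership[g] for g in genes], "direction": dirs},
            index=pd.Index(genes, name="gene_id"),
        )
        return DEGSet(name, table)

    consensus = _build((g for g, n in membership.items() if n >= min_sets), "consensus")
    universal = _build(
        (g for g, n in membership.items() if n == len(deg_sets)), "universal"
    )
    return consensus, universal


def sharing_spectrum(focal: DEGSet, others: Sequence[DEGSet]) -> np.ndarray:
    """Histogram over focal genes of how many other sets contain each gene."""
    bins = np.zeros(len(others) + 1, dtype=int)
    other_sets = [ds.genes for ds in others]
    for gene in focal.table.index:
        bins[sum(gene in s for s in other_sets)] += 1
    return bins


# ---------------------------------------------------------------------------
# canalization (coefficient of variation across accessions)


def expression_cv_compare(
    transformed: TransformedMatrix,
    design: list[SampleMeta] | pd.DataFrame,
    genes: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, float]:
    """Cross-accession expression variability, mutants versus wild types.

    For each gene and genotype group the coefficient of variation (sample
    standard deviation / mean) of per-accession mean transformed counts is
    computed; zero-mean genes are flagged NaN and excluded.  The two CV
    distributions are compared by a one-sided Wilcoxon rank-sum test with
    alternative CV(mutant) > CV(wild type); the returned p is NaN when
    either distribution is degenerate.
    """
    design_df = design if isinstance(design, pd.DataFrame) else design_frame(design)
    design_df = design_df.loc[transformed.values.columns]
    values = transformed.values if genes is None else transformed.values.loc[list(genes)]
    n_acc = design_df.groupby("genotype", observed=True)["accession"].nunique()
    if (n_acc < 2).any():
        raise ValueError("need >= 2 accessions in each genotype group")

    def _group_cv(samples: pd.Index) -> pd.Series:
        sub = values[samples]
        acc = design_df.loc[samples, "accession"]
        acc_means = sub.T.groupby(acc.to_numpy()).mean().T
        mean = acc_means.mean(axis=1)
        sd = acc_means.std(axis=1, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cv = sd / mean
        cv[mean <= 0] = np.nan
        return cv

    is_mut = design_df["genotype"].ne("WT")
    cv_mut = _group_cv(design_df.index[is_mut])
    cv_wt = _group_cv(design_df.index[~is_mut])
    records = pd.DataFrame({"cv_wt": cv_wt, "cv_mut": cv_mut})
    a = cv_mut.dropna().to_numpy()
    b = cv_wt.dropna().to_numpy()
    if len(a) == 0 or len(b) == 0 or (np.ptp(np.concatenate([a, b])) == 0):
        return records, float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = float(stats.mannwhitneyu(a, b, alternative="greater").pvalue)
    return records, p
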