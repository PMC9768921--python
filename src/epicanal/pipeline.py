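"""End-to-end orchestration: simulate → de → methyl → atac → integrate → genotype.

Every stage writes plain-text artifacts into the output directory and
registers them in a manifest (path, sha256, producing stage, parameters),
so two runs with identical configuration and seed produce checksum-identical
manifests.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chromatin, diffexpr, genotyping, integration, io, methylation, simulate
from .core import HOM_GENOTYPES, design_frame


@dataclass
class PipelineConfig:
    """Full parameter block for one pipeline run.

    Every threshold defaults to its quoted value; ``mode`` switches the
    optional extensions (e.g. the homozygote-deficit binomial test) on
    ("extended") or off ("strict").
    """

    outdir: str = "epicanal_out"
    seed: int = 0
    mode: str = "strict"
    # generator block
    sim: dict = field(default_factory=dict)
    # differential expression
    de_alpha: float = 0.01
    de_lfc_min: float = 1.0
    de_inclusive: bool = False
    # methylation / DMRs
    dmr_context: str = "CG"
    dmr_min_c: int = 10
    dmr_min_cov: int = 3
    dmr_min_diff_pct: float = 20.0
    dmr_mean_min_reads: int = 2
    dmr_max_na: int = 7
    # accessibility
    atac_min_accessions: int = 2
    atac_delta_log2: float = 1.0
    atac_consistency_tol: float = 0.25
    atac_hv_quantile: float = 0.25
    atac_k: int = 3
    # integration
    cis_flank: int = 1500
    extended_flank: int = 100
    gbm_meth_min: float = 80.0
    # genotyping
    geno_min_reads: int = 80
    n_progeny: int = 96

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def validate_inputs(
    design_df: pd.DataFrame,
    expression: pd.DataFrame,
    meth_samples: list[str],
    accessibility: pd.DataFrame,
) -> dict[str, list[str]]:
    """Sample-id concordance report across the input matrices (report-only)."""
    known = set(design_df["sample_id"])
    report = {
        "expression_orphans": sorted(set(expression.columns) - known),
        "accessibility_orphans": sorted(set(accessibility.columns) - known),
        "design_without_expression": sorted(known - set(expression.columns)),
    }
    # methylomes are per-line samples; match on the accession_line prefix
    lines = {f"{r.accession}_{r.line}" for r in design_df.itertuples()}
    report["methylation_orphans"] = sorted(
        s for s in meth_samples if "_".join(s.split("_")[:2]) not in lines
    )
    return report


class PipelineRun:
    """Holds intermediate results while the stages execute."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest: list[dict] = []
        self.results: dict = {}

    def register(self, path: Path, stage: str, params: dict) -> None:
        self.manifest.append(
            {
                "file": str(path.relative_to(self.outdir)),
                "sha256": io.sha256_file(path),
                "stage": stage,
                "params": {k: repr(v) for k, v in sorted(params.items())},
            }
        )


def _stage_simulate(run: PipelineRun) -> simulate.SimDataset:
    cfg = run.config
    sim_kwargs = dict(cfg.sim)
    sim_kwargs.setdefault("seed", cfg.seed)
    sconf = simulate.SimConfig(**sim_kwargs)
    data = simulate.simulate_all(sconf, n_progeny=cfg.n_progeny)
    out = run.outdir
    io.write_design_tsv(data.design, out / "design.tsv")
    io.write_counts_tsv(data.expression, out / "expression_counts.tsv")
    data.methylation.to_tsv(out / "methylation_calls.tsv")
    io.write_counts_tsv(data.accessibility, out / "peak_counts.tsv")
    io.write_bed(data.regions, out / "regions.bed", extra_cols=["kind"])
    genes = data.genes[["chrom", "start", "end", "strand", "is_te_gene", "gene_class"]]
    genes.to_csv(out / "genes.tsv", sep="\t", index_label="gene_id")
    truth = {
        "gene_class": data.truth.gene_class.to_dict(),
        "transmission_bias": data.truth.transmission_bias,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=0, sort_keys=True))
    for line, amp in data.amplicon.items():
        amp.to_csv(out / f"amplicon_{line}.csv", index=False)
    params = simulate.config_to_dict(sconf)
    for name in ["design.tsv", "expression_counts.tsv", "methylation_calls.tsv",
                 "peak_counts.tsv", "regions.bed", "genes.tsv", "truth.json"]:
        run.register(out / name, "simulate", params)
    for line in data.amplicon:
        run.register(out / f"amplicon_{line}.csv", "simulate", params)
    return data


def _stage_de(run: PipelineRun, data: simulate.SimDataset) -> None:
    cfg = run.config
    counts = data.expression
    design_df = design_frame(data.design)
    kept = diffexpr.filter_low_count_genes(counts)
    counts = counts.loc[kept]
    sf = diffexpr.median_ratio_size_factors(counts)
    transformed = diffexpr.transform_counts(counts, sf)

    accs = sorted(design_df["accession"].unique())
    contrasts = {"all": {"type": "genotype"}}
    contrasts.update({a: {"type": "genotype", "accession": a} for a in accs})
    results = diffexpr.nb_wald_contrasts(
        counts, design_df, "genotype_x_accession", contrasts, size_factors=sf
    )

    deg_sets = {}
    for name, res in results.items():
        res.to_csv(run.outdir / f"de_contrast_{name}.tsv", sep="\t")
        deg_sets[name] = diffexpr.call_degs(
            res, contrast_id=name, lfc_min=cfg.de_lfc_min, alpha=cfg.de_alpha,
            inclusive=cfg.de_inclusive,
        )
    ordered = [deg_sets[a] for a in accs] + [deg_sets["all"]]
    consensus, universal = diffexpr.consensus_and_universal_sets(
        ordered, expected_n=len(ordered)
    )
    annotation = data.genes
    cons_te, cons_nonte = diffexpr.partition_te(consensus, annotation)
    spectrum = diffexpr.sharing_spectrum(deg_sets["all"], [deg_sets[a] for a in accs])

    union_genes = sorted(set().union(*(ds.genes for ds in ordered)))
    cv_records, cv_p = diffexpr.expression_cv_compare(
        transformed, design_df, union_genes or None
    )

    # accession contrasts within each genotype group (canalization analysis):
    # genes divergent between accessions in wild types vs in mutants
    acc_contrasts = {a: {"type": "accession", "accession": a} for a in accs}
    group_deg_union: dict[str, set] = {}
    for label, mask in [("wt", design_df["genotype"].eq("WT")),
                        ("mut", design_df["genotype"].ne("WT"))]:
        samples = design_df.index[mask]
        sub = counts[samples]
        sub = sub.loc[diffexpr.filter_low_count_genes(sub)]
        sub_res = diffexpr.nb_wald_contrasts(
            sub, design_df.loc[samples], "accession_only", acc_contrasts,
            size_factors=sf.loc[samples],
        )
        union: set = set()
        for a, res in sub_res.items():
            ds = diffexpr.call_degs(
                res, contrast_id=f"{label}:{a}", lfc_min=cfg.de_lfc_min,
                alpha=cfg.de_alpha, inclusive=cfg.de_inclusive,
            )
            union |= ds.genes
        group_deg_union[label] = union
        pd.Series(sorted(union)).to_csv(
            run.outdir / f"accession_degs_{label}.tsv", sep="\t",
            index=False, header=["gene_id"],
        )

    out = run.outdir
    transformed.values.to_csv(out / "transformed_counts.tsv", sep="\t")
    sf.to_csv(out / "size_factors.tsv", sep="\t")
    consensus.table.to_csv(out / "degs_consensus.tsv", sep="\t")
    universal.table.to_csv(out / "degs_universal.tsv", sep="\t")
    pd.DataFrame({"n_other_sets": range(len(spectrum)), "n_genes": spectrum}).to_csv(
        out / "deg_sharing_spectrum.tsv", sep="\t", index=False
    )
    cv_records.assign(wilcoxon_p=cv_p).to_csv(out / "expression_cv.tsv", sep="\t")
    params = {"alpha": cfg.de_alpha, "lfc_min": cfg.de_lfc_min, "inclusive": cfg.de_inclusive}
    for name in results:
        run.register(out / f"de_contrast_{name}.tsv", "de", params)
    for name in ["transformed_counts.tsv", "size_factors.tsv", "degs_consensus.tsv",
                 "degs_universal.tsv", "deg_sharing_spectrum.tsv", "expression_cv.tsv",
                 "accession_degs_wt.tsv", "accession_degs_mut.tsv"]:
        run.register(out / name, "de", params)
    run.results["de"] = {
        "deg_sets": deg_sets,
        "consensus": consensus,
        "universal": universal,
        "consensus_te": cons_te,
        "consensus_nonte": cons_nonte,
        "transformed": transformed,
        "counts": counts,
        "cv_p": cv_p,
        "accession_deg_union": group_deg_union,
    }


def _stage_methyl(run: PipelineRun, data: simulate.SimDataset) -> None:
    cfg = run.config
    calls = data.methylation
    groups = {s.sample_id: ("WT" if s.genotype == "WT" else "mutant") for s in data.meth_design}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rm = methylation.region_methylation_matrix(
            calls, data.regions, context=cfg.dmr_context, min_reads=cfg.dmr_mean_min_reads
        )
        rm_kept = methylation.filter_by_missingness(rm, max_na=cfg.dmr_max_na)
        dmrs = methylation.call_dmrs_simple(
            calls, data.regions, groups, context=cfg.dmr_context,
            min_c=cfg.dmr_min_c, min_cov=cfg.dmr_min_cov,
            min_diff_pct=cfg.dmr_min_diff_pct,
        )
    out = run.outdir
    table = rm_kept.regions[["chrom", "start", "end"]].join(rm_kept.mean_pct)
    table.insert(3, "n_cytosines", rm_kept.n_cytosines)
    table.insert(4, "na_count", rm_kept.na_count)
    table.to_csv(out / "region_methylation.tsv", sep="\t", index_label="region_id")
    dmrs.to_csv(out / "dmrs.bed", sep="\t", index_label="region_id")
    glob = pd.DataFrame(
        {ctx: methylation.global_context_means(calls, ctx) for ctx in ("CG", "CHG", "CHH")}
    )
    glob.to_csv(out / "global_methylation.tsv", sep="\t", index_label="sample_id")
    params = {
        "context": cfg.dmr_context, "min_c": cfg.dmr_min_c, "min_cov": cfg.dmr_min_cov,
        "min_diff_pct": cfg.dmr_min_diff_pct, "max_na": cfg.dmr_max_na,
    }
    for name in ["region_methylation.tsv", "dmrs.bed", "global_methylation.tsv"]:
        run.register(out / name, "methyl", params)
    run.results["methyl"] = {"region_meth": rm, "region_meth_kept": rm_kept, "dmrs": dmrs}


def _stage_atac(run: PipelineRun, data: simulate.SimDataset) -> None:
    cfg = run.config
    design_df = design_frame(data.design)
    matrix = chromatin.tmm_cpm(data.accessibility)
    dacr_ids = chromatin.select_dacrs(
        matrix, design_df, min_accessions=cfg.atac_min_accessions,
        delta_log2=cfg.atac_delta_log2, consistency_tol=cfg.atac_consistency_tol,
    )
    hv_ids, cvs = chromatin.select_hv_dacrs(
        matrix, design_df, dacr_ids, quantile=cfg.atac_hv_quantile
    )
    # clamp k on very small runs where fewer variable peaks survive selection
    usable = int((matrix.cpm.loc[hv_ids].std(axis=1, ddof=0) > 0).sum())
    k_eff = min(cfg.atac_k, max(usable, 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        labels, cluster_means = chromatin.cluster_hv_dacrs(
            matrix, hv_ids, k=k_eff, seed=cfg.seed
        )
    totals = data.accessibility.attrs.get("total_mapped_reads")
    if totals is None:
        totals = (matrix.counts.sum(axis=0) / 0.25).round().astype(int).to_dict()
    frip_scores = chromatin.frip(
        matrix.counts.sum(axis=0), pd.Series(totals).reindex(matrix.counts.columns)
    )
    out = run.outdir
    matrix.tmm_factors.to_frame().join(matrix.lib_sizes).to_csv(
        out / "tmm_factors.tsv", sep="\t", index_label="sample_id"
    )
    dacr_bed = data.peaks.loc[dacr_ids, ["chrom", "start", "end"]].join(cvs)
    dacr_bed["is_hv"] = dacr_bed.index.isin(hv_ids)
    log_cpm = np.log2(matrix.cpm + 1.0)
    is_mut = design_df["genotype"].ne("WT")
    dacr_bed["delta_log2_mut_wt"] = (
        log_cpm.loc[dacr_ids, design_df.index[is_mut]].mean(axis=1)
        - log_cpm.loc[dacr_ids, design_df.index[~is_mut]].mean(axis=1)
    )
    dacr_bed.to_csv(out / "dacrs.bed", sep="\t", index_label="peak_id")
    labels.to_frame().join(cluster_means, on="cluster").to_csv(
        out / "hv_dacr_clusters.tsv", sep="\t", index_label="peak_id"
    )
    frip_scores.to_csv(out / "frip.tsv", sep="\t", index_label="sample_id")
    params = {
        "min_accessions": cfg.atac_min_accessions, "delta_log2": cfg.atac_delta_log2,
        "quantile": cfg.atac_hv_quantile, "k": cfg.atac_k, "seed": cfg.seed,
    }
    for name in ["tmm_factors.tsv", "dacrs.bed", "hv_dacr_clusters.tsv", "frip.tsv"]:
        run.register(out / name, "atac", params)
    run.results["atac"] = {"matrix": matrix, "dacr_ids": dacr_ids, "hv_ids": hv_ids,
                           "clusters": labels}


def _stage_integrate(run: PipelineRun, data: simulate.SimDataset) -> None:
    cfg = run.config
    thresholds = integration.EpistateThresholds(
        gbm_meth_min=cfg.gbm_meth_min,
        extended_upstream=cfg.extended_flank,
        extended_downstream=cfg.extended_flank,
        cis_flank=cfg.cis_flank,
    )
    de = run.results["de"]
    methyl = run.results["methyl"]
    atac = run.results["atac"]
    design_df = design_frame(data.design)
    meth_design_df = design_frame(data.meth_design)
    accs = sorted(design_df["accession"].unique())
    transformed = de["transformed"].values

    def _per_accession_delta(values: pd.DataFrame, df: pd.DataFrame) -> pd.DataFrame:
        cols = {}
        for a in accs:
            hom = df.index[(df["accession"] == a) & df["genotype"].isin(HOM_GENOTYPES)]
            wt = df.index[(df["accession"] == a) & (df["genotype"] == "WT")]
            hom = [s for s in hom if s in values.columns]
            wt = [s for s in wt if s in values.columns]
            if not hom or not wt:
                cols[a] = pd.Series(np.nan, index=values.index)
            else:
                cols[a] = values[hom].mean(axis=1) - values[wt].mean(axis=1)
        return pd.DataFrame(cols)

    d_expr = _per_accession_delta(transformed, design_df)
    dmr_deltas = _per_accession_delta(methyl["region_meth"].mean_pct, meth_design_df)
    dmr_features = methyl["dmrs"][["chrom", "start", "end"]]
    dmr_deltas = dmr_deltas.loc[dmr_deltas.index.intersection(dmr_features.index)]
    dacr_deltas = _per_accession_delta(atac["matrix"].cpm, design_df)
    dacr_features = data.peaks.loc[atac["hv_ids"], ["chrom", "start", "end"]]
    dacr_deltas = dacr_deltas.loc[dacr_features.index]

    genes = data.genes
    dmr_body = integration.assign_strongest_feature(
        genes, dmr_features, dmr_deltas.loc[dmr_features.index], "body", thresholds
    )
    dmr_cis = integration.assign_strongest_feature(
        genes, dmr_features, dmr_deltas.loc[dmr_features.index], "cis", thresholds
    )
    parts = [p for p in (dmr_body, dmr_cis) if len(p)]
    if parts:
        dmr_any = pd.concat(parts).drop_duplicates(
            subset=["gene_id", "accession"], keep="first"
        )
    else:
        dmr_any = pd.DataFrame(columns=["gene_id", "accession", "feature_id", "delta"])
    dacr_cis = integration.assign_strongest_feature(
        genes, dacr_features, dacr_deltas, "cis_incl_body", thresholds
    )
    epistate = integration.categorize_epistate(genes, accs, d_expr, dmr_any, dacr_cis)

    wt_cols = design_df.index[design_df["genotype"] == "WT"]
    wt_expr = transformed[[c for c in wt_cols if c in transformed.columns]].mean(axis=1)
    non_te = genes.index[~genes["is_te_gene"]].intersection(wt_expr.index)
    expr_labels, expr_bounds = integration.quintile_bins(wt_expr.loc[non_te])

    wt_meth_cols = [s.sample_id for s in data.meth_design if s.genotype == "WT"]
    body_meth = methyl["region_meth"].mean_pct[wt_meth_cols].mean(axis=1)
    body_genes = dmr_body.drop_duplicates("gene_id").set_index("gene_id")["feature_id"]
    body_genes = body_genes[body_genes.index.isin(non_te)]
    wt_meth = body_meth.reindex(body_genes.to_numpy())
    wt_meth.index = body_genes.index
    labels = integration.classify_gbm_tem(
        wt_meth, wt_expr.reindex(wt_meth.index), expr_bounds, thresholds
    )

    meth_calls = data.methylation
    cg_mask = (meth_calls.sites["context"] == "CG").to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        cg_level = np.where(
            meth_calls.total[cg_mask] > 0,
            100.0 * meth_calls.meth[cg_mask] / np.maximum(meth_calls.total[cg_mask], 1),
            np.nan,
        )
    te_genes = genes[genes["is_te_gene"]]
    metaplot = integration.metaplot_profile(
        meth_calls.sites[cg_mask].reset_index(drop=True),
        cg_level,
        te_genes,
        sample_names=meth_calls.samples,
    )

    out = run.outdir
    epistate.to_csv(out / "gene_epistate.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"label": labels, "wt_meth_pct": wt_meth, "wt_expr": wt_expr.reindex(labels.index),
         "wt_expr_quintile": expr_labels.reindex(labels.index)}
    ).to_csv(out / "gbm_tem_labels.tsv", sep="\t", index_label="gene_id")
    metaplot.to_csv(out / "metaplot_cg_te_genes.tsv", sep="\t", index_label="bin")
    params = {"cis_flank": cfg.cis_flank, "extended_flank": cfg.extended_flank,
              "gbm_meth_min": cfg.gbm_meth_min}
    for name in ["gene_epistate.tsv", "gbm_tem_labels.tsv", "metaplot_cg_te_genes.tsv"]:
        run.register(out / name, "integrate", params)
    run.results["integrate"] = {
        "epistate": epistate, "labels": labels, "d_expr": d_expr,
        "dmr_body": dmr_body, "expr_bounds": expr_bounds,
    }


def _stage_genotype(run: PipelineRun, data: simulate.SimDataset) -> None:
    cfg = run.config
    thresholds = genotyping.GenotypeThresholds(min_reads=cfg.geno_min_reads)
    summaries = []
    for line, table in sorted(data.amplicon.items()):
        calls = genotyping.call_genotypes_table(table, thresholds)
        table = table.assign(call=calls)
        table.to_csv(run.outdir / f"genotype_calls_{line}.csv", index=False)
        report = genotyping.segregation_report(
            calls, test_deficit=(cfg.mode == "extended")
        )
        summaries.append(
            {
                "line": line,
                "n_called": report["n_called"],
                "hom_fraction": report["hom_fraction"],
                "true_bias": data.truth.transmission_bias[line],
                **{f"p_{k}": v for k, v in sorted(report["proportions"].items())},
            }
        )
    summary = pd.DataFrame(summaries)
    summary.to_csv(run.outdir / "segregation_summary.csv", index=False)
    params = {"min_reads": cfg.geno_min_reads}
    for line in data.amplicon:
        run.register(run.outdir / f"genotype_calls_{line}.csv", "genotype", params)
    run.register(run.outdir / "segregation_summary.csv", "genotype", params)
    run.results["genotype"] = {"summary": summary}


STAGES = [
    ("simulate", _stage_simulate),
    ("de", _stage_de),
    ("methyl", _stage_methyl),
    ("atac", _stage_atac),
    ("integrate", _stage_integrate),
    ("genotype", _stage_genotype),
]


def run_full_pipeline(config: PipelineConfig) -> tuple[list[dict], PipelineRun]:
    """Execute every stage; returns (manifest, run handle).

    Any stage failure aborts with the stage name attached to the error.
    """
    run = PipelineRun(config)
    config.to_yaml(run.outdir / "config.yaml")
    data = None
    for name, stage in STAGES:
        try:
            if name == "simulate":
                data = stage(run)
            else:
                stage(run, data)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    io.write_manifest(run.manifest, run.outdir / "manifest.json")
    return run.manifest, run
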