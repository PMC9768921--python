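"""Synthetic multi-omics generator with planted ground truth.

The generator emulates the study conditions of a knockout of the CG
maintenance methyltransferase across a panel of natural accessions:

* a design of ``n_accessions`` accessions, each with one wild-type line and
  ``lines_per_accession`` independently derived mutant lines, sequenced in
  three biological replicates;
* gene classes planted in the expression matrix — TE-associated genes that
  are strongly and near-uniformly upregulated in mutants, canalized genes
  (identical wild-type means, accession-specific mutant effects),
  decanalized genes (the converse), gene-body-methylated (gbM) genes that
  are moderately downregulated, TE-methylation-like (teM) genes that are
  upregulated from a silenced baseline, and null genes;
* CG methylation collapsing to ~0.2% in homozygous mutants, with a modest
  relative CHG gain (stronger in second-generation homozygotes) and a
  relative CHH loss;
* chromatin accessibility gains multiplicatively coupled to methylation
  loss at TE-like regions;
* progeny amplicon read tables under biased transmission of the mutant
  allele through both gametes.

Every draw flows from a single seed through independent named streams, so
identical configurations give byte-identical outputs regardless of the
order in which the simulate_* functions are called.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import (
    HET,
    HOM_G1,
    HOM_G2,
    WT,
    SampleMeta,
    design_frame,
)
from .methylation import MethylCalls

#: Default gene-class mix.  The TE fraction mirrors a panel in which 1678 of
#: 21,657 analyzed genes (~7.7%) are TE-associated; the epigenetically
#: classified and canalization classes are modest minorities, the rest null.
DEFAULT_CLASS_FRACTIONS: dict[str, float] = {
    "TE_UP": 0.077,
    "GBM": 0.05,
    "TEM": 0.03,
    "CANALIZED": 0.10,
    "DECANALIZED": 0.05,
    "NULL": 0.693,
}

GENE_CLASSES = tuple(DEFAULT_CLASS_FRACTIONS)


@dataclass
class SimConfig:
    """All knobs of the generator; the seed fully determines the output."""

    n_accessions: int = 18
    lines_per_accession: int = 2
    replicates: int = 3
    n_genes: int = 4000
    n_regions: int = 2000
    region_width: int = 200
    nb_dispersion: float = 0.1
    coverage_mean: float = 20.0
    seed: int = 0
    class_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS)
    )
    # expression
    baseline_log_mean: float = float(np.log(50.0))
    baseline_log_sd: float = 1.2
    accession_effect_sd: float = 2.0  # canalized/decanalized divergence scale
    library_size_range: tuple[float, float] = (0.7, 1.4)
    # methylation targets
    mut_cg_level: float = 0.002
    chg_gain_g1: float = 0.068
    chg_gain_g2: float = 0.40
    chh_loss: float = 0.21
    # accessibility
    acr_baseline_log_mean: float = float(np.log(100.0))
    acr_baseline_log_sd: float = 0.8
    coupling_multiplier: float = 2.0
    acr_library_size_range: tuple[float, float] = (0.5, 2.0)
    # amplicon genotyping
    amplicon_depth_mean: float = 120.0
    transmission_bias_range: tuple[float, float] = (0.15, 0.42)

    def __post_init__(self) -> None:
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"class_fractions must sum to 1 (got {total})")
        for name, value in (
            ("n_accessions", self.n_accessions),
            ("lines_per_accession", self.lines_per_accession),
            ("replicates", self.replicates),
            ("n_genes", self.n_genes),
            ("n_regions", self.n_regions),
        ):
            if value < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.nb_dispersion <= 0 or self.coverage_mean <= 0:
            raise ValueError("nb_dispersion and coverage_mean must be positive")

    def rng(self, stream: str) -> np.random.Generator:
        """A generator for a named stream, independent of call order."""
        digest = int.from_bytes(stream.encode(), "big") % (2**31)
        return np.random.default_rng([self.seed % (2**31), digest])


@dataclass
class SimTruth:
    """Planted effects keyed by gene, region, accession, and line."""

    gene_class: pd.Series
    baseline: pd.Series  # per-gene wild-type mean count (library factor 1)
    wt_offset_log2: pd.DataFrame  # gene × accession, applied to every genotype
    effect_log2fc: pd.DataFrame  # gene × accession, applied to homozygous mutants
    region_kind: pd.Series  # te / tem / gbm / null
    region_gene: pd.Series  # gene carrying the region, or "" for intergenic
    meth_target_wt: pd.DataFrame  # region × accession CG fraction
    meth_target_mut: pd.DataFrame
    chg_target_wt: pd.Series  # per region
    chh_target_wt: pd.Series
    acr_coupled: pd.Series  # bool per region/peak
    transmission_bias: dict[str, float]


# ---------------------------------------------------------------------------
# design


def generate_design(
    n_accessions: int,
    lines_per_accession: int,
    replicates: int,
    seed: int = 0,
    g2_accessions: int = 2,
    het_accessions: int = 0,
) -> list[SampleMeta]:
    """Sample sheet for the full panel.

    Each accession contributes one wild-type line and ``lines_per_accession``
    mutant lines, all with ``replicates`` biological replicates.  Mutant
    lines are first-generation homozygotes, except that in the first
    ``g2_accessions`` accessions the last line is a second-generation
    homozygote, and in the first ``het_accessions`` accessions the first
    line is heterozygous (mirroring panels in which some backgrounds yield
    too few homozygotes).  Deterministic given the arguments; ``seed`` is
    accepted for interface symmetry.
    """
    for name, value in (
        ("n_accessions", n_accessions),
        ("lines_per_accession", lines_per_accession),
        ("replicates", replicates),
    ):
        if value < 1:
            raise ValueError(f"{name} must be >= 1")
    design: list[SampleMeta] = []
    for a in range(n_accessions):
        acc = f"Acc{a + 1:02d}"
        for rep in range(1, replicates + 1):
            design.append(SampleMeta(f"{acc}_WT_r{rep}", acc, WT, "L0", rep))
        for li in range(1, lines_per_accession + 1):
            genotype = HOM_G1
            if a < g2_accessions and li == lines_per_accession and lines_per_accession > 1:
                genotype = HOM_G2
            if a < het_accessions and li == 1:
                genotype = HET
            line = f"L{li}"
            for rep in range(1, replicates + 1):
                design.append(
                    SampleMeta(f"{acc}_{line}_{genotype}_r{rep}", acc, genotype, line, rep)
                )
    return design


def methylome_design(design: list[SampleMeta]) -> list[SampleMeta]:
    """Collapse replicates to one methylome per (accession, line).

    Bisulfite libraries pool replicate tissue, so the methylation panel has
    one sample per line rather than one per replicate.
    """
    seen: dict[tuple, SampleMeta] = {}
    for s in design:
        key = (s.accession, s.line, s.genotype)
        if key not in seen:
            seen[key] = SampleMeta(
                f"{s.accession}_{s.line}_{s.genotype}_meth", s.accession, s.genotype, s.line, 1
            )
    return list(seen.values())


# ---------------------------------------------------------------------------
# genome layout and truth


def simulate_genome(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene annotation and candidate-region/peak coordinates.

    Genes of 2 kb are laid on 5 chromosomes with 5 kb spacing, strands
    alternating.  Gene classes are assigned by deterministic interleaving to
    match ``class_fractions`` within rounding.  Each TE_UP / GBM / TEM gene
    carries one 200 bp epigenetic region centred on its body; remaining
    regions are intergenic and planted as unchanged ("stable").
    """
    rng = config.rng("genome")
    n = config.n_genes
    n_chrom = 5
    gene_len, spacing = 2000, 5000

    # deterministic class counts (largest remainder), then shuffled placement
    fracs = config.class_fractions
    counts = {c: int(np.floor(fracs.get(c, 0.0) * n)) for c in GENE_CLASSES}
    remainder = n - sum(counts.values())
    order = sorted(
        GENE_CLASSES, key=lambda c: (fracs.get(c, 0.0) * n) % 1.0, reverse=True
    )
    for c in order[:remainder]:
        counts[c] += 1
    labels = np.repeat(list(counts.keys()), list(counts.values()))
    rng.shuffle(labels)

    per_chrom = int(np.ceil(n / n_chrom))
    chroms, starts = [], []
    for i in range(n):
        chroms.append(f"chr{i // per_chrom + 1}")
        starts.append((i % per_chrom) * spacing + 1000)
    genes = pd.DataFrame(
        {
            "gene_id": [f"g{i + 1:05d}" for i in range(n)],
            "chrom": chroms,
            "start": starts,
            "end": [s + gene_len for s in starts],
            "strand": np.where(np.arange(n) % 2 == 0, "+", "-"),
            "gene_class": labels,
        }
    ).set_index("gene_id", drop=False)
    genes["is_te_gene"] = genes["gene_class"] == "TE_UP"

    epi_classes = {"TE_UP", "GBM", "TEM"}
    region_rows = []
    w = config.region_width
    for g in genes.itertuples():
        if g.gene_class in epi_classes:
            mid = (g.start + g.end) // 2
            region_rows.append(
                {
                    "chrom": g.chrom,
                    "start": mid - w // 2,
                    "end": mid + w - w // 2,
                    "kind": {"TE_UP": "te", "GBM": "gbm", "TEM": "tem"}[g.gene_class],
                    "gene_id": g.gene_id,
                }
            )
    n_null = config.n_regions - len(region_rows)
    if n_null < 0:
        raise ValueError(
            "n_regions too small for the epigenetic gene classes "
            f"({len(region_rows)} regions required)"
        )
    # intergenic null regions in the gap after each gene, cycling over genes
    gap_offset = gene_len + 1200
    for k in range(n_null):
        g = genes.iloc[k % len(genes)]
        region_rows.append(
            {
                "chrom": g["chrom"],
                "start": int(g["start"]) + gap_offset,
                "end": int(g["start"]) + gap_offset + w,
                "kind": "stable",
                "gene_id": "",
            }
        )
    regions = pd.DataFrame(region_rows)
    regions.index = pd.Index([f"r{i + 1:05d}" for i in range(len(regions))])
    return genes, regions


def make_truth(
    genes: pd.DataFrame, regions: pd.DataFrame, config: SimConfig
) -> SimTruth:
    """Draw all planted effect sizes for a genome under a configuration."""
    rng = config.rng("truth")
    accs = [f"Acc{a + 1:02d}" for a in range(config.n_accessions)]
    n, na = len(genes), len(accs)
    cls = genes["gene_class"]

    baseline = pd.Series(
        np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd, n)),
        index=genes.index,
        name="baseline",
    )
    # silenced TE-like and teM genes start low; gbM genes are well expressed
    baseline[cls == "TE_UP"] = np.exp(rng.normal(np.log(5.0), 0.8, (cls == "TE_UP").sum()))
    baseline[cls == "TEM"] = np.exp(rng.normal(np.log(4.0), 0.4, (cls == "TEM").sum()))
    baseline[cls == "GBM"] = np.exp(rng.normal(np.log(150.0), 0.5, (cls == "GBM").sum()))

    wt_offset = pd.DataFrame(0.0, index=genes.index, columns=accs)
    effect = pd.DataFrame(0.0, index=genes.index, columns=accs)

    # TE-like activation is strong everywhere but its extent varies
    # considerably between accessions (hundreds-fold in some, tens in others)
    te = cls == "TE_UP"
    effect.loc[te] = np.maximum(
        rng.uniform(3.0, 6.0, (te.sum(), 1)) + rng.normal(0.0, 1.2, (te.sum(), na)),
        1.0,
    )
    tem = cls == "TEM"
    effect.loc[tem] = np.maximum(
        rng.uniform(2.0, 4.0, (tem.sum(), 1)) + rng.normal(0.0, 0.5, (tem.sum(), na)),
        0.5,
    )
    gbm = cls == "GBM"
    effect.loc[gbm] = rng.uniform(-2.5, -1.0, (gbm.sum(), 1)) + rng.normal(
        0.0, 0.15, (gbm.sum(), na)
    )
    can = cls == "CANALIZED"
    effect.loc[can] = rng.normal(0.0, config.accession_effect_sd, (can.sum(), na))
    dec = cls == "DECANALIZED"
    dec_offsets = rng.normal(0.0, config.accession_effect_sd, (dec.sum(), na))
    wt_offset.loc[dec] = dec_offsets
    effect.loc[dec] = -dec_offsets  # mutants converge back to the common mean

    # methylation targets
    kind = regions["kind"]
    loss = kind.isin(["te", "tem", "gbm"])
    base_wt = np.where(loss, rng.uniform(0.75, 0.95, len(regions)), config.mut_cg_level)
    acc_jitter = rng.normal(0.0, 0.03, (len(regions), na))
    meth_wt = np.clip(base_wt[:, None] + np.where(loss, 1.0, 0.0)[:, None] * acc_jitter, 0.0, 1.0)
    meth_mut = np.full_like(meth_wt, config.mut_cg_level)
    meth_mut[~loss.to_numpy()] = meth_wt[~loss.to_numpy()]  # null regions unchanged

    chg_wt = pd.Series(
        np.where(loss, rng.uniform(0.2, 0.5, len(regions)), rng.uniform(0.005, 0.05, len(regions))),
        index=regions.index,
    )
    chh_wt = pd.Series(
        np.where(loss, rng.uniform(0.05, 0.2, len(regions)), rng.uniform(0.005, 0.05, len(regions))),
        index=regions.index,
    )

    lines = [f"L{li + 1}" for li in range(config.lines_per_accession)]
    bias = {
        f"{acc}_{line}": float(b)
        for (acc, line), b in zip(
            ((a, l) for a in accs for l in lines),
            rng.uniform(*config.transmission_bias_range, na * len(lines)),
        )
    }

    return SimTruth(
        gene_class=cls.copy(),
        baseline=baseline,
        wt_offset_log2=wt_offset,
        effect_log2fc=effect,
        region_kind=kind.copy(),
        region_gene=regions["gene_id"].copy(),
        meth_target_wt=pd.DataFrame(meth_wt, index=regions.index, columns=accs),
        meth_target_mut=pd.DataFrame(meth_mut, index=regions.index, columns=accs),
        chg_target_wt=chg_wt,
        chh_target_wt=chh_wt,
        acr_coupled=kind.isin(["te", "tem"]).rename("acr_coupled"),
        transmission_bias=bias,
    )


# ---------------------------------------------------------------------------
# draws


def _nb_draws(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with Var = mu + dispersion * mu^2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + np.maximum(mean, 1e-12))
    out = rng.negative_binomial(size, p)
    out[mean <= 0] = 0
    return out


def _genotype_dose(genotype: str) -> float:
    """Fraction of the planted mutant effect expressed by a genotype."""
    return {WT: 0.0, HET: 0.5, HOM_G1: 1.0, HOM_G2: 1.0}[genotype]


def simulate_expression(
    design: list[SampleMeta], truth: SimTruth, config: SimConfig
) -> pd.DataFrame:
    """Gene × sample count matrix with planted fold changes.

    Counts are negative binomial with mean
    ``baseline * 2^(wt_offset + dose * effect) * library_factor`` and the
    configured dispersion; heterozygotes express half the planted effect.
    """
    if not design:
        raise ValueError("empty design")
    missing = set()  # truth must cover every gene by construction of SimTruth
    if truth.effect_log2fc.isna().any().any():
        missing = set(truth.effect_log2fc.index[truth.effect_log2fc.isna().any(axis=1)])
    if missing:
        raise ValueError(f"genes missing planted effects: {sorted(missing)[:5]}")
    rng = config.rng("expression")
    df = design_frame(design)
    unknown = set(df["accession"]) - set(truth.effect_log2fc.columns)
    if unknown:
        raise ValueError(f"accessions missing from truth: {sorted(unknown)}")

    lib = rng.uniform(*config.library_size_range, len(df))
    base = truth.baseline.to_numpy()[:, None]
    counts = np.zeros((len(truth.baseline), len(df)), dtype=np.int64)
    for j, s in enumerate(df.itertuples()):
        log2_shift = (
            truth.wt_offset_log2[s.accession]
            + _genotype_dose(s.genotype) * truth.effect_log2fc[s.accession]
        ).to_numpy()
        mu = base[:, 0] * np.exp2(log2_shift) * lib[j]
        counts[:, j] = _nb_draws(rng, mu, config.nb_dispersion)
    return pd.DataFrame(counts, index=truth.baseline.index, columns=df["sample_id"])


def _tile_sites(regions: pd.DataFrame) -> pd.DataFrame:
    """Deterministic cytosine positions within each region.

    CG sites every 8 bp, CHG every 23 bp, CHH every 13 bp (offset so the
    contexts interleave); strands alternate.  A 200 bp region therefore
    holds 25 CG cytosines, comfortably above DMR calling minima.
    """
    rows = []
    spacing = {"CG": (2, 8), "CHG": (5, 23), "CHH": (9, 13)}
    for rid, r in regions.iterrows():
        for ctx, (offset, step) in spacing.items():
            for k, pos in enumerate(range(int(r["start"]) + offset, int(r["end"]), step)):
                rows.append((r["chrom"], pos, "+" if k % 2 == 0 else "-", ctx, rid))
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context", "region_id"])


def simulate_methylation(
    design: list[SampleMeta],
    regions: pd.DataFrame,
    truth: SimTruth,
    config: SimConfig,
) -> MethylCalls:
    """Per-cytosine methylation calls for the (replicate-pooled) panel.

    Total reads per site and sample are Poisson(coverage_mean); methylated
    reads are binomial around the planted target.  Homozygous-mutant CG
    targets default to 0.2%; CHG targets gain 6.8% relative in
    first-generation and 40% in second-generation homozygotes, CHH targets
    drop 21% relative.  Heterozygotes retain wild-type targets.
    """
    rng = config.rng("methylation")
    df = design_frame(design)
    sites = _tile_sites(regions)
    n_sites, n_samples = len(sites), len(df)

    rid = sites["region_id"].to_numpy()
    ctx = sites["context"].to_numpy()
    target = np.zeros((n_sites, n_samples))
    for j, s in enumerate(df.itertuples()):
        cg_wt = truth.meth_target_wt.loc[rid, s.accession].to_numpy()
        cg_mut = truth.meth_target_mut.loc[rid, s.accession].to_numpy()
        chg = truth.chg_target_wt.loc[rid].to_numpy()
        chh = truth.chh_target_wt.loc[rid].to_numpy()
        if s.genotype == HOM_G1:
            cg, chg, chh = cg_mut, chg * (1 + config.chg_gain_g1), chh * (1 - config.chh_loss)
        elif s.genotype == HOM_G2:
            cg, chg, chh = cg_mut, chg * (1 + config.chg_gain_g2), chh * (1 - config.chh_loss)
        else:  # WT and HET keep parental methylation
            cg = cg_wt
        col = np.where(ctx == "CG", cg, np.where(ctx == "CHG", chg, chh))
        target[:, j] = np.clip(col, 0.0, 1.0)

    total = rng.poisson(config.coverage_mean, (n_sites, n_samples))
    meth = rng.binomial(total, target)
    return MethylCalls(
        sites[["chrom", "pos", "strand", "context"]],
        meth,
        total,
        list(df["sample_id"]),
    )


def simulate_accessibility(
    design: list[SampleMeta],
    peaks: pd.DataFrame,
    truth: SimTruth,
    config: SimConfig,
) -> pd.DataFrame:
    """Peak × sample ATAC count matrix.

    Counts are negative binomial around a per-peak baseline; peaks over
    regions with planted methylation loss at TE-like sequence get their
    homozygous-mutant means multiplied by ``coupling_multiplier``.  Library
    sizes vary several-fold between samples so that normalization is
    non-trivial.
    """
    rng = config.rng("accessibility")
    df = design_frame(design)
    base = np.exp(
        rng.normal(config.acr_baseline_log_mean, config.acr_baseline_log_sd, len(peaks))
    )
    coupled = truth.acr_coupled.reindex(peaks.index, fill_value=False).to_numpy()
    lib = rng.uniform(*config.acr_library_size_range, len(df))
    counts = np.zeros((len(peaks), len(df)), dtype=np.int64)
    for j, s in enumerate(df.itertuples()):
        gain = np.where(
            coupled, config.coupling_multiplier ** _genotype_dose(s.genotype), 1.0
        )
        mu = base * gain * lib[j]
        counts[:, j] = _nb_draws(rng, mu, config.nb_dispersion)
    out = pd.DataFrame(counts, index=peaks.index, columns=df["sample_id"])
    # each library also carries off-peak reads; in-peak fractions span the
    # 0.2-0.31 range typical of good ATAC libraries
    frip_target = rng.uniform(0.2, 0.31, len(df))
    out.attrs["total_mapped_reads"] = {
        s: int(round(c / f))
        for s, c, f in zip(df["sample_id"], counts.sum(axis=0), frip_target)
    }
    return out


def simulate_amplicon(
    n_progeny: int,
    transmission_bias: float,
    depth_mean: float = 120.0,
    seed: int = 0,
    read_error: float = 0.01,
) -> pd.DataFrame:
    """Progeny amplicon read table under distorted transmission.

    A gamete carries the mutant allele with probability ``transmission_bias``
    independently through each parent, so homozygous mutants occur at
    ``bias**2`` (0.25 recovers Mendelian segregation).  Read totals are
    Poisson around ``depth_mean``; wild-type reads are binomial around the
    genotype's allele dosage, softened by a small miscall rate.
    """
    if not 0.0 <= transmission_bias <= 1.0:
        raise ValueError("transmission_bias must be in [0, 1]")
    if n_progeny < 1:
        raise ValueError("n_progeny must be >= 1")
    rng = np.random.default_rng([int(seed) % (2**31), 746_227])
    b = transmission_bias
    geno = rng.choice(
        ["HOM_MUT", "HET", "WT"],
        size=n_progeny,
        p=[b * b, 2 * b * (1 - b), (1 - b) * (1 - b)],
    )
    wt_dose = np.select([geno == "WT", geno == "HET"], [1.0, 0.5], default=0.0)
    p_wt = np.clip(wt_dose * (1 - 2 * read_error) + read_error, 0.0, 1.0)
    total = rng.poisson(depth_mean, n_progeny)
    wt_reads = rng.binomial(total, p_wt)
    return pd.DataFrame(
        {
            "sample": [f"p{i + 1:04d}" for i in range(n_progeny)],
            "wt_reads": wt_reads,
            "mut_reads": total - wt_reads,
            "true_genotype": geno,
        }
    )


# ---------------------------------------------------------------------------
# one-call bundle


@dataclass
class SimDataset:
    """Everything one run of the generator produces."""

    config: SimConfig
    design: list[SampleMeta]
    meth_design: list[SampleMeta]
    genes: pd.DataFrame
    regions: pd.DataFrame
    truth: SimTruth
    expression: pd.DataFrame
    methylation: MethylCalls
    accessibility: pd.DataFrame
    amplicon: dict[str, pd.DataFrame]

    @property
    def peaks(self) -> pd.DataFrame:
        """Accessibility peaks share coordinates with the candidate regions."""
        return self.regions


def simulate_all(config: SimConfig, n_progeny: int = 96) -> SimDataset:
    """Run every generator stage under one configuration."""
    design = generate_design(
        config.n_accessions, config.lines_per_accession, config.replicates, config.seed
    )
    mdesign = methylome_design(design)
    genes, regions = simulate_genome(config)
    truth = make_truth(genes, regions, config)
    expr = simulate_expression(design, truth, config)
    meth = simulate_methylation(mdesign, regions, truth, config)
    acc = simulate_accessibility(design, regions, truth, config)
    amplicon = {
        line: simulate_amplicon(
            n_progeny,
            bias,
            depth_mean=config.amplicon_depth_mean,
            seed=(config.seed + 13 * i + 1) % (2**31),
        )
        for i, (line, bias) in enumerate(sorted(truth.transmission_bias.items()))
    }
    return SimDataset(
        config=config,
        design=design,
        meth_design=mdesign,
        genes=genes,
        regions=regions,
        truth=truth,
        expression=expr,
        methylation=meth,
        accessibility=acc,
        amplicon=amplicon,
    )


def config_to_dict(config: SimConfig) -> dict:
    return asdict(config)
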