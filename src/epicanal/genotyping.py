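"""Amplicon-based genotype calling and segregation-distortion summaries.

Progeny of heterozygous parents are genotyped from the ratio of wild-type
to mutant amplicon reads: with r = wild-type reads / total,

* fewer than 80 total reads → no call;
* r <= 0.15 → homozygous mutant;
* 0.42 <= r <= 0.58 → heterozygous;
* r >= 0.90 → wild type;
* anything between those bands → skewed heterozygous.

Lines segregating a second mutant allele get mirrored multi-allele
categories (see :func:`call_genotype`).  Segregation distortion is
summarized as per-line genotype proportions over callable samples, with an
optional one-sided exact binomial test of the homozygote deficit against
the Mendelian expectation of 1/4.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

CALLS = (
    "HOM_MUT", "HET", "WT", "SKEWED_HET",
    "HOM_MUT2", "HET2", "SKEWED_HET2",
    "BIALLELIC", "SKEWED_BIALLELIC", "TRIALLELIC",
    "NO_CALL",
)


@dataclass
class GenotypeThresholds:
    """Read-ratio bands for genotype classification.

    ``wt_min`` wins at its boundary: r = 0.90 is called wild type, so the
    skewed band is half-open at the top.  ``minor_floor`` is the read
    fraction above which a second mutant allele counts as present, and
    ``multi_min`` the per-allele floor for the tri-allelic category.
    """

    min_reads: int = 80
    hom_max: float = 0.15
    het_lo: float = 0.42
    het_hi: float = 0.58
    wt_min: float = 0.90
    minor_floor: float = 0.10
    multi_min: float = 0.15

    def __post_init__(self) -> None:
        if not 0.0 <= self.hom_max < self.het_lo < self.het_hi < self.wt_min <= 1.0:
            raise ValueError("require 0 <= hom_max < het_lo < het_hi < wt_min <= 1")


def _single_allele_call(r: float, t: GenotypeThresholds, suffix: str = "") -> str:
    if r <= t.hom_max:
        return "HOM_MUT" + suffix
    if t.het_lo <= r <= t.het_hi:
        return "HET" + suffix
    if r >= t.wt_min:
        return "WT"
    return "SKEWED_HET" + suffix


def call_genotype(
    allele_reads: dict[str, int], thresholds: GenotypeThresholds | None = None
) -> str:
    """Classify one sample from its per-allele read counts.

    ``allele_reads`` maps allele names to read counts; the wild-type allele
    must be keyed ``"WT"``, mutant alleles in their ranking order (e.g.
    ``"mut1"``, ``"mut2"``).  With a single mutant allele the read-ratio
    bands apply directly.  When a second mutant allele exceeds the
    minor-allele floor: all three alleles >= ``multi_min`` is tri-allelic;
    wild-type <= ``hom_max`` with both mutant alleles in the heterozygous
    band is bi-allelic (otherwise skewed bi-allelic, or homozygous for the
    dominant second allele); a heterozygous-range wild-type fraction paired
    with a dominant second allele gives the allele-2 heterozygous calls.
    """
    t = thresholds or GenotypeThresholds()
    if any(v < 0 for v in allele_reads.values()):
        raise ValueError("negative read counts")
    total = sum(allele_reads.values())
    if total < t.min_reads:
        return "NO_CALL"
    wt = allele_reads.get("WT", 0)
    muts = sorted(
        ((k, v) for k, v in allele_reads.items() if k != "WT"),
        key=lambda kv: kv[0],
    )
    r = wt / total
    if len(muts) < 2:
        return _single_allele_call(r, t)
    frac = {k: v / total for k, v in muts}
    f1 = frac[muts[0][0]]
    f2 = frac[muts[1][0]]
    if f2 < t.minor_floor:
        return _single_allele_call(r, t)
    if r >= t.multi_min and f1 >= t.multi_min and f2 >= t.multi_min:
        return "TRIALLELIC"
    if r <= t.hom_max:
        if f1 < t.minor_floor:
            return _single_allele_call(1.0 - f2, t, suffix="2") if f2 >= 1 - t.hom_max else "SKEWED_BIALLELIC"
        if t.het_lo <= f1 <= t.het_hi and t.het_lo <= f2 <= t.het_hi:
            return "BIALLELIC"
        if f2 >= 1.0 - t.hom_max:
            return "HOM_MUT2"
        return "SKEWED_BIALLELIC"
    # wild-type allele present beyond the homozygous band: a het with allele 2
    if f2 >= f1:
        if t.het_lo <= r <= t.het_hi:
            return "HET2"
        if r >= t.wt_min:
            return "WT"
        return "SKEWED_HET2"
    return _single_allele_call(r, t)


def call_genotypes_table(
    reads: pd.DataFrame, thresholds: GenotypeThresholds | None = None
) -> pd.Series:
    """Vector version over a table with wt_reads/mut_reads (+ mut2_reads)."""
    t = thresholds or GenotypeThresholds()
    calls = []
    for row in reads.itertuples():
        allele_reads = {"WT": int(row.wt_reads), "mut1": int(row.mut_reads)}
        if hasattr(row, "mut2_reads"):
            allele_reads["mut2"] = int(row.mut2_reads)
        calls.append(call_genotype(allele_reads, t))
    return pd.Series(calls, index=reads.index, name="call")


HOM_CALLS = {"HOM_MUT", "HOM_MUT2", "BIALLELIC", "SKEWED_BIALLELIC"}


def segregation_report(
    calls: pd.Series,
    expected_hom: float = 0.25,
    test_deficit: bool = False,
) -> dict:
    """Genotype proportions over callable samples for one line.

    NO_CALL samples are excluded.  With ``test_deficit`` a one-sided exact
    binomial test of the homozygote count against ``expected_hom`` is added
    (an extension beyond the descriptive proportions; off by default).
    """
    called = calls[calls != "NO_CALL"]
    if len(called) == 0:
        raise ValueError("no callable samples")
    counts = called.value_counts().to_dict()
    n = int(len(called))
    proportions = {k: v / n for k, v in counts.items()}
    n_hom = int(sum(v for k, v in counts.items() if k in HOM_CALLS))
    report = {
        "n_called": n,
        "counts": counts,
        "proportions": proportions,
        "hom_fraction": n_hom / n,
    }
    if test_deficit:
        report["binom_p_deficit"] = float(
            stats.binomtest(n_hom, n, expected_hom, alternative="less").pvalue
        )
    return report
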