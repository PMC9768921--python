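"""Shared domain types: sample metadata, genotype codes, interval frames.

All genomic coordinates in this package are 0-based half-open; conversion to
1-based happens only in readers/writers of formats that require it.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

#: Genotype codes used throughout the package.
WT = "WT"
HET = "HET"
HOM_G1 = "HOM_G1"
HOM_G2 = "HOM_G2"
GENOTYPES = (WT, HET, HOM_G1, HOM_G2)

#: Genotypes counted as mutant (carrying at least one knockout allele).
MUTANT_GENOTYPES = frozenset({HET, HOM_G1, HOM_G2})
#: Homozygous-mutant genotypes (used e.g. for methylation collapse and
#: the first HV-ACR variability filter).
HOM_GENOTYPES = frozenset({HOM_G1, HOM_G2})

CONTEXTS = ("CG", "CHG", "CHH")


@dataclass(frozen=True)
class SampleMeta:
    """Identity of one sequencing sample.

    Parameters
    ----------
    sample_id
        Unique identifier within a design.
    accession
        Natural accession (genetic background) the plant derives from.
    genotype
        One of :data:`GENOTYPES`.
    line
        Mutant line of origin ("L0" for wild type).
    replicate
        Biological replicate number, >= 1.
    """

    sample_id: str
    accession: str
    genotype: str
    line: str
    replicate: int

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")

    @property
    def is_mutant(self) -> bool:
        return self.genotype in MUTANT_GENOTYPES

    @property
    def is_hom(self) -> bool:
        return self.genotype in HOM_GENOTYPES


def design_frame(design: list[SampleMeta]) -> pd.DataFrame:
    """Tabulate a design as a DataFrame indexed by sample_id."""
    if not design:
        raise ValueError("empty design")
    df = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in design],
            "accession": [s.accession for s in design],
            "genotype": [s.genotype for s in design],
            "line": [s.line for s in design],
            "replicate": [s.replicate for s in design],
        }
    ).set_index("sample_id", drop=False)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicate sample ids: {dups}")
    return df


def design_from_frame(df: pd.DataFrame) -> list[SampleMeta]:
    return [
        SampleMeta(
            sample_id=str(r.sample_id),
            accession=str(r.accession),
            genotype=str(r.genotype),
            line=str(r.line),
            replicate=int(r.replicate),
        )
        for r in df.itertuples(index=False)
    ]


def check_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a BED-like frame (chrom/start/end); returns it unchanged."""
    required = {"chrom", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"interval frame missing columns: {sorted(missing)}")
    bad = df["start"] >= df["end"]
    if bad.any():
        i = df.index[bad][0]
        raise ValueError(
            f"malformed interval at {i}: start >= end "
            f"({df.loc[i, 'start']} >= {df.loc[i, 'end']})"
        )
    return df
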