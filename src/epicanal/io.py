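"""Plain-text readers and writers for the pipeline's tabular formats.

All interval files are BED-like with 0-based half-open coordinates; count
matrices are TSV with features on rows and sample ids as the header.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .core import SampleMeta, design_frame, design_from_frame


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="feature_id")


def read_counts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="feature_id")


def write_design_tsv(design: list[SampleMeta], path) -> None:
    design_frame(design).to_csv(path, sep="\t", index=False)


def read_design_tsv(path) -> list[SampleMeta]:
    return design_from_frame(pd.read_csv(path, sep="\t"))


def write_bed(intervals: pd.DataFrame, path, extra_cols: list[str] | None = None) -> None:
    cols = ["chrom", "start", "end"] + (extra_cols or [])
    df = intervals.reset_index().rename(columns={"index": "name"})
    keep = ["chrom", "start", "end", "name"] + [c for c in (extra_cols or []) if c in df.columns]
    df[keep].to_csv(path, sep="\t", index=False, header=False)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    extra = [f"col{i}" for i in range(len(names), df.shape[1])]
    df.columns = names + extra
    if "name" in df.columns:
        df = df.set_index("name")
    return df


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(entries: list[dict], path) -> None:
    Path(path).write_text(json.dumps(entries, indent=2, sort_keys=True) + "\n")
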