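"""Readers and writers for the pipeline's plain-text contracts.

Counts and metadata travel as TSV, annotations as GMT (term, description,
then gene ids, tab-separated), alignments and loci as 6-column BED,
ground truth and summaries as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .quantify import CountMatrix, GenomicInterval


def write_counts(counts: CountMatrix, counts_path, meta_path) -> None:
    counts.values.rename_axis("feature").to_csv(counts_path, sep="\t")
    counts.samples.rename_axis("sample").to_csv(meta_path, sep="\t")


def read_counts(counts_path, meta_path, lengths_path=None) -> CountMatrix:
    values = pd.read_csv(counts_path, sep="\t", index_col=0)
    values.index.name = None
    samples = pd.read_csv(meta_path, sep="\t", index_col=0)
    lengths = None
    if lengths_path is not None:
        lengths = pd.read_csv(lengths_path, sep="\t", index_col=0).iloc[:, 0]
    return CountMatrix(values=values, samples=samples, feature_lengths=lengths)


def write_interactions(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_interactions(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    required = {"mirna", "gene"}
    if not required <= set(table.columns):
        raise ValueError(f"interaction table needs columns {sorted(required)}")
    return table


def write_gmt(annotations: dict, path, description: str = "synthetic") -> None:
    with open(path, "w") as fh:
        for term in sorted(annotations):
            genes = "\t".join(sorted(annotations[term]))
            fh.write(f"{term}\t{description}\t{genes}\n")


def read_gmt(path) -> dict:
    annotations: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            annotations[parts[0]] = set(g for g in parts[2:] if g)
    return annotations


def read_bed(path) -> list[GenomicInterval]:
    """Read intervals from a BED file (3-6 columns)."""
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            strand = parts[5] if len(parts) > 5 else "."
            intervals.append(
                GenomicInterval(parts[0], int(parts[1]), int(parts[2]), strand)
            )
    return intervals


def read_bed_named(path) -> dict:
    """Read named loci (BED with a name column) as id -> interval."""
    loci = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError("named BED needs at least 4 columns")
            strand = parts[5] if len(parts) > 5 else "."
            loci[parts[3]] = GenomicInterval(parts[0], int(parts[1]), int(parts[2]), strand)
    return loci


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))


def read_term_hallmarks(path) -> dict:
    """term -> hallmark mapping from a two-column TSV (header optional)."""
    table = pd.read_csv(path, sep="\t", header=None, comment="#")
    if str(table.iloc[0, 0]).lower() in ("term", "term_id"):
        table = table.iloc[1:]
    return dict(zip(table.iloc[:, 0], table.iloc[:, 1]))
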