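"""TSV readers and writers for count tables, truth tables and reports.

Count tables are plain TSV, UTF-8, Unix newlines: ``#``-prefixed metadata
lines first (``#totals`` carries the declared library totals), then a header
row (``gene`` plus one column per library), then one row per transcript.
A table without a ``#totals`` line gets totals equal to its column sums.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import pandas as pd
import yaml

from .concordance import AnnotatedTranscript
from .simulate import SimConfig, SimTruth, TagCountTable

__all__ = [
    "read_count_table",
    "write_count_table",
    "write_truth_table",
    "load_sim_config",
    "load_table1_fixture",
    "table1_fixture_path",
]


def write_count_table(table: TagCountTable, path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        totals = "\t".join(str(table.totals[lib]) for lib in table.libraries)
        fh.write(f"#totals\t{totals}\n")
        fh.write("gene\t" + "\t".join(table.libraries) + "\n")
        for gene, row in table.counts.iterrows():
            fh.write(gene + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def read_count_table(path) -> TagCountTable:
    """Read and validate a TSV count table.

    Rejects duplicate gene ids and negative or non-integer counts with an
    error naming the offending row and column.
    """
    path = Path(path)
    totals_line = None
    skip = 0
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("#totals"):
                totals_line = line.rstrip("\n").split("\t")[1:]
            skip += 1
    df = pd.read_csv(path, sep="\t", skiprows=skip, dtype={0: str})
    if df.columns[0] != "gene":
        raise ValueError(f"{path}: first column must be 'gene', got {df.columns[0]!r}")
    df = df.set_index("gene")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene id {dup!r}")
    for col in df.columns:
        vals = df[col]
        bad = vals[(vals < 0) | (vals != vals.astype(int))]
        if len(bad):
            raise ValueError(
                f"{path}: invalid count {bad.iloc[0]!r} at row {bad.index[0]!r}, "
                f"column {col!r} (counts must be non-negative integers)"
            )
    df = df.astype(int)
    if totals_line is not None:
        if len(totals_line) != len(df.columns):
            raise ValueError(f"{path}: #totals has {len(totals_line)} values for {len(df.columns)} libraries")
        totals = {lib: int(t) for lib, t in zip(df.columns, totals_line)}
    else:
        totals = {lib: int(df[lib].sum()) for lib in df.columns}
    return TagCountTable(counts=df, totals=totals)


def write_truth_table(truth: SimTruth, path) -> None:
    truth.to_frame().to_csv(path, sep="\t")


def load_sim_config(path) -> SimConfig:
    """Build a :class:`SimConfig` from a JSON or YAML document.

    YAML is a superset of JSON, so one loader covers both.
    """
    with Path(path).open("r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: expected a mapping of SimConfig fields")
    return SimConfig(**doc)


def table1_fixture_path() -> Path:
    return Path(importlib.resources.files("dgescreen") / "data" / "table1.tsv")


def load_table1_fixture(path=None) -> list[AnnotatedTranscript]:
    """Load the characterised-transcript fixture.

    Guards against silent drift: exactly 46 records, 25 with negative and 21
    with positive wnt3 z-scores, are required.
    """
    path = table1_fixture_path() if path is None else Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    records = [
        AnnotatedTranscript(
            name=row["name"],
            z_wnt3=float(row["wnt3_z"]),
            dge_class=int(row["dge_class"]),
            pattern=row["pattern"],
            restricted_flag=bool(row["restricted"]),
            orf_complete_flag=bool(row["orf_complete"]),
        )
        for _, row in df.iterrows()
    ]
    n_under = sum(r.z_wnt3 < 0 for r in records)
    n_over = sum(r.z_wnt3 > 0 for r in records)
    if len(records) != 46 or n_under != 25 or n_over != 21:
        raise ValueError(
            f"fixture drift: {len(records)} records ({n_under} under-, "
            f"{n_over} over-expressed); expected 46 (25 + 21)"
        )
    return records
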