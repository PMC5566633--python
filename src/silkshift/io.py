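"""Plain-text readers and writers for the pipeline's tabular formats.

All tables are tab-separated.  Counts: rows = transcripts, columns =
libraries.  Sample sheet: (library, species, tissue, replicate).  Family
map: (cluster_id, species, transcript).  Trees: one NHX string per line.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .families import FamilyMap
from .normalize import CountMatrix
from .phyloexpr.trees import GeneTree, read_gene_tree, write_gene_tree

__all__ = [
    "read_counts",
    "write_counts",
    "read_effective_lengths",
    "write_effective_lengths",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_count_matrix",
    "write_count_matrix",
    "read_family_map",
    "write_family_map",
    "read_trees",
    "write_trees",
    "read_tissue_profiles",
    "write_tissue_profiles",
    "read_json",
    "write_json",
]


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(int)


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="transcript")


def read_effective_lengths(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0].astype(float)


def write_effective_lengths(lengths: pd.Series, path) -> None:
    lengths.rename("effective_length").to_csv(path, sep="\t", index_label="transcript")


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return df[["species", "tissue", "replicate"]]


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, sep="\t", index_label="library")


def read_count_matrix(counts_path, lengths_path, sheet_path) -> CountMatrix:
    return CountMatrix(
        counts=read_counts(counts_path),
        effective_length=read_effective_lengths(lengths_path),
        sample_sheet=read_sample_sheet(sheet_path),
    )


def write_count_matrix(cm: CountMatrix, outdir) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "effective_lengths": outdir / "effective_lengths.tsv",
        "samples": outdir / "samples.tsv",
    }
    write_counts(cm.counts, paths["counts"])
    write_effective_lengths(cm.effective_length, paths["effective_lengths"])
    write_sample_sheet(cm.sample_sheet, paths["samples"])
    return paths


def read_family_map(path) -> FamilyMap:
    return FamilyMap(pd.read_csv(path, sep="\t", dtype=str))


def write_family_map(fmap: FamilyMap, path) -> None:
    fmap.table.to_csv(path, sep="\t", index=False)


def read_trees(path) -> dict[str, GeneTree]:
    """Read one tree per line; optional leading ``name<TAB>`` per line."""
    out: dict[str, GeneTree] = {}
    for i, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line:
            continue
        if "\t" in line:
            name, newick = line.split("\t", 1)
        else:
            name, newick = f"tree{i}", line
        tree = read_gene_tree(newick)
        tree.name = name
        out[name] = tree
    return out


def write_trees(trees: dict[str, GeneTree], path) -> None:
    lines = [f"{name}\t{write_gene_tree(tree)}" for name, tree in trees.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_tissue_profiles(path) -> pd.DataFrame:
    """Transcript x (species, tissue) mean-FPKM table."""
    df = pd.read_csv(path, sep="\t", header=[0, 1], index_col=0)
    df.columns = df.columns.set_names(["species", "tissue"])
    return df


def write_tissue_profiles(profiles: pd.DataFrame, path) -> None:
    profiles.to_csv(path, sep="\t", index_label="transcript")


def read_json(path):
    return json.loads(Path(path).read_text())


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")
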