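"""Reading and writing cohort data: MatrixMarket counts, TSV metadata, GMT gene sets."""

from __future__ import annotations

import os
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .simulate import CohortDataset


class MatrixFormatError(ValueError):
    """Raised for a malformed MatrixMarket file."""


class MetadataMismatchError(ValueError):
    """Raised when cell metadata references samples absent from sample metadata."""


class DuplicateGeneError(ValueError):
    """Raised when gene names are not unique."""


class GMTFormatError(ValueError):
    """Raised for malformed GMT gene-set lines; carries the offending line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


def write_cohort(dataset: CohortDataset, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    coo = sparse.coo_matrix(dataset.counts)
    spio.mmwrite(os.path.join(out_dir, "matrix.mtx"), coo, field="integer")
    pd.Series(dataset.gene_names).to_csv(
        os.path.join(out_dir, "genes.tsv"), sep="\t", index=False, header=False
    )
    pd.Series(dataset.cell_ids).to_csv(
        os.path.join(out_dir, "barcodes.tsv"), sep="\t", index=False, header=False
    )
    dataset.cell_meta.to_csv(os.path.join(out_dir, "cell_meta.tsv"), sep="\t")
    dataset.sample_meta.to_csv(os.path.join(out_dir, "sample_meta.tsv"), sep="\t")
    if dataset.parent_map:
        pd.Series(dataset.parent_map, name="cell_type").rename_axis("subtype").to_csv(
            os.path.join(out_dir, "parent_map.tsv"), sep="\t"
        )


def read_cohort(in_dir: str) -> CohortDataset:
    try:
        mat = spio.mmread(os.path.join(in_dir, "matrix.mtx"))
    except ValueError as exc:
        raise MatrixFormatError(str(exc)) from exc
    counts = np.asarray(sparse.coo_matrix(mat).todense()).astype(np.int64)
    genes = pd.Index(
        pd.read_csv(os.path.join(in_dir, "genes.tsv"), sep="\t", header=None)[0],
        name="gene",
    )
    if genes.has_duplicates:
        dups = genes[genes.duplicated()].unique().tolist()
        raise DuplicateGeneError(f"duplicate gene names: {dups}")
    barcodes = pd.Index(
        pd.read_csv(os.path.join(in_dir, "barcodes.tsv"), sep="\t", header=None)[0],
        name="cell_id",
    )
    cell_meta = pd.read_csv(os.path.join(in_dir, "cell_meta.tsv"), sep="\t", index_col=0)
    sample_meta = pd.read_csv(os.path.join(in_dir, "sample_meta.tsv"), sep="\t", index_col=0)
    unknown = set(cell_meta["sample_id"]) - set(sample_meta.index)
    if unknown:
        raise MetadataMismatchError(
            f"cell_meta references sample id(s) missing from sample_meta: {sorted(unknown)}"
        )
    parent_map: dict[str, str] = {}
    pm_path = os.path.join(in_dir, "parent_map.tsv")
    if os.path.exists(pm_path):
        pm = pd.read_csv(pm_path, sep="\t", index_col=0)
        parent_map = pm["cell_type"].to_dict()
    dataset = CohortDataset(
        counts=counts,
        gene_names=genes,
        cell_ids=barcodes,
        cell_meta=cell_meta,
        sample_meta=sample_meta,
        parent_map=parent_map,
    )
    dataset.validate()
    return dataset


def read_gmt(path: str) -> dict[str, list[str]]:
    """Parse a GMT file (name, description, then >=1 gene per line)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTFormatError(
                    f"expected at least 3 tab-separated fields, got {len(fields)}", lineno
                )
            name = fields[0]
            genes = [g for g in fields[2:] if g]
            if not genes:
                raise GMTFormatError(f"gene set {name!r} is empty", lineno)
            if name in sets:
                raise GMTFormatError(f"duplicate gene set name {name!r}", lineno)
            sets[name] = genes
    return sets


def write_gmt(sets: Mapping[str, list[str]], path: str) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def read_lr_catalog(path: str) -> pd.DataFrame:
    """Ligand-receptor catalog TSV: (interaction_id, ligand, receptor) or (ligand, receptor)."""
    df = pd.read_csv(path, sep="\t")
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    if "interaction_id" not in cols:
        if not {"ligand", "receptor"}.issubset(cols):
            raise ValueError("LR catalog needs columns (ligand, receptor)")
        df["interaction_id"] = df["ligand"] + "_" + df["receptor"]
    df = df[["interaction_id", "ligand", "receptor"]]
    if df.duplicated(["ligand", "receptor"]).any():
        raise ValueError("duplicate (ligand, receptor) pairs in catalog")
    return df
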