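"""Meta-program assignment for malignant cells.

Each cell is scored against a catalog of published expression programs and
assigned to its maximal-scoring program, subject to a minimum score and a
minimum number of expressed program genes; cells failing both gates are NA.
The score of a program in a cell is the mean gene-centred log-normalized
expression over the program's genes present in the matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import read_gmt

SCORE_MIN = 0.03
MIN_GENES = 25


@dataclass
class MPCatalog:
    sets: dict[str, list[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"meta-program {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"meta-program {name!r} has duplicate genes")

    @classmethod
    def from_gmt(cls, path: str) -> "MPCatalog":
        return cls(sets=read_gmt(path), source=path)


@dataclass
class MPAssignment:
    assignments: pd.DataFrame  # per cell: program (or NA), score, n_genes, tie
    assigned_fraction: float
    score_min: float
    min_genes: int


def lognormalize(counts: np.ndarray, scale: float = 1e4) -> np.ndarray:
    """log1p counts-per-``scale`` normalization (column-wise)."""
    counts = np.asarray(counts, dtype=float)
    colsum = counts.sum(axis=0)
    colsum[colsum == 0] = 1.0
    return np.log1p(scale * counts / colsum[None, :])


def score_metaprograms(
    counts: np.ndarray,
    gene_names: pd.Index,
    catalog: MPCatalog,
    min_genes: int = MIN_GENES,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every program in every cell.

    Returns (scores, n_expressed): programs x cells DataFrames; scores are NA
    where the cell expresses fewer than ``min_genes`` of the program's genes
    (expressed = raw count > 0).  Programs with no genes in the matrix are
    dropped with a warning.  Centering is computed within the scored cells.
    """
    counts = np.asarray(counts)
    norm = lognormalize(counts)
    centered = norm - norm.mean(axis=1, keepdims=True)
    gene_pos = {g: i for i, g in enumerate(gene_names)}
    scores = {}
    n_expr = {}
    for name, genes in catalog.sets.items():
        idx = [gene_pos[g] for g in genes if g in gene_pos]
        if not idx:
            warnings.warn(f"meta-program {name!r} has no genes in the matrix; dropped")
            continue
        expressed = (counts[idx] > 0).sum(axis=0)
        s = centered[idx].mean(axis=0)
        s = np.where(expressed >= min_genes, s, np.nan)
        scores[name] = s
        n_expr[name] = expressed
    if not scores:
        raise ValueError("no meta-program has any gene present in the matrix")
    return (
        pd.DataFrame(scores).T,
        pd.DataFrame(n_expr).T,
    )


def assign_metaprograms(scores: pd.DataFrame, score_min: float = SCORE_MIN) -> MPAssignment:
    """Argmax assignment with the minimum-score gate.

    Ties at the maximum go to the lexicographically first program name and
    are flagged.
    """
    programs = sorted(scores.index)
    S = scores.loc[programs].to_numpy(dtype=float)
    n_cells = S.shape[1]
    out_prog: list[object] = []
    out_score = np.full(n_cells, np.nan)
    out_tie = np.zeros(n_cells, dtype=bool)
    for c in range(n_cells):
        col = S[:, c]
        if np.all(np.isnan(col)):
            out_prog.append(pd.NA)
            continue
        best = np.nanmax(col)
        if best < score_min:
            out_prog.append(pd.NA)
            continue
        winners = [programs[i] for i in np.flatnonzero(col == best)]
        out_prog.append(winners[0])
        out_score[c] = best
        out_tie[c] = len(winners) > 1
    assignments = pd.DataFrame(
        {"program": out_prog, "score": out_score, "tie": out_tie},
        index=scores.columns if scores.columns is not None else range(n_cells),
    )
    frac = float(assignments["program"].notna().mean())
    return MPAssignment(assignments=assignments, assigned_fraction=frac,
                        score_min=score_min, min_genes=-1)


class MetaProgramAssigner(BaseEstimator):
    """Classifier-style wrapper: ``fit`` scores, ``predict`` returns labels.

    Parameters mirror the operative thresholds: ``score_min`` (minimum best
    score, default 0.03) and ``min_genes`` (minimum expressed program genes
    per cell, default 25).
    """

    def __init__(self, catalog: MPCatalog | None = None, score_min: float = SCORE_MIN,
                 min_genes: int = MIN_GENES):
        self.catalog = catalog
        self.score_min = score_min
        self.min_genes = min_genes

    def fit(self, counts, gene_names):
        if self.catalog is None:
            raise ValueError("catalog is required")
        scores, n_expr = score_metaprograms(counts, gene_names, self.catalog,
                                            min_genes=self.min_genes)
        assignment = assign_metaprograms(scores, score_min=self.score_min)
        assignment.min_genes = self.min_genes
        self.scores_ = scores
        self.n_expressed_ = n_expr
        self.assignment_ = assignment
        self.labels_ = assignment.assignments["program"]
        self.assigned_fraction_ = assignment.assigned_fraction
        return self

    def fit_predict(self, counts, gene_names):
        return self.fit(counts, gene_names).labels_
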