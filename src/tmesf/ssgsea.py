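"""Single-sample gene-set enrichment (ssGSEA).

Per sample, genes are ranked by expression; the score is the sum over the
ranking of the difference between the rank-weighted (rank^alpha) in-set
ECDF and the unweighted out-of-set ECDF.  Rank-based, hence invariant to
monotone transforms of a sample's expression.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

DEFAULT_ALPHA = 0.25


def ssgsea_score(
    bulk_expr: pd.DataFrame,
    gene_set: list[str],
    alpha: float = DEFAULT_ALPHA,
    normalize: bool = False,
) -> pd.Series:
    """Scores per sample for one gene set on a genes x samples matrix.

    ``normalize=True`` divides all scores by their range across samples
    (recorded in ``attrs``).
    """
    genes = bulk_expr.index
    in_set = np.asarray(genes.isin(set(gene_set)))
    if not in_set.any():
        raise ValueError("no gene of the set is present in the expression matrix")
    N = len(genes)
    n_in = int(in_set.sum())
    n_out = N - n_in
    scores = {}
    for sample in bulk_expr.columns:
        x = bulk_expr[sample].to_numpy(dtype=float)
        # descending expression; stable order for ties
        order = np.argsort(-x, kind="stable")
        ranks = np.arange(N, 0, -1, dtype=float)  # top gene gets rank N
        member = in_set[order]
        w = np.where(member, ranks**alpha, 0.0)
        p_in = np.cumsum(w) / w.sum()
        if n_out == 0:
            p_out = np.zeros(N)
        else:
            p_out = np.cumsum(~member) / n_out
        scores[sample] = float(np.sum(p_in - p_out))
    out = pd.Series(scores, name="ssgsea")
    out.attrs["alpha"] = alpha
    out.attrs["normalized"] = normalize
    if normalize:
        rng = out.max() - out.min()
        if rng > 0:
            out = out / rng
            out.attrs["alpha"] = alpha
            out.attrs["normalized"] = True
    return out


def quartile_split(scores: pd.Series) -> pd.Series:
    """Deterministic quartile labels Q1 (lowest) .. Q4 (highest)."""
    return pd.Series(
        pd.qcut(scores.rank(method="first"), 4, labels=["Q1", "Q2", "Q3", "Q4"]),
        index=scores.index,
    ).astype(str)


class SSGSEAScorer(BaseEstimator, TransformerMixin):
    """Transformer: genes x samples expression -> samples x sets score matrix."""

    def __init__(self, gene_sets: dict[str, list[str]] | None = None,
                 alpha: float = DEFAULT_ALPHA, normalize: bool = False):
        self.gene_sets = gene_sets
        self.alpha = alpha
        self.normalize = normalize

    def fit(self, X: pd.DataFrame, y=None):
        if not self.gene_sets:
            raise ValueError("gene_sets is required")
        self.gene_sets_ = dict(self.gene_sets)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(
            {
                name: ssgsea_score(X, genes, alpha=self.alpha, normalize=self.normalize)
                for name, genes in self.gene_sets_.items()
            }
        )
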