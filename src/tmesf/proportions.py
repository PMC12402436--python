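"""Relative subtype proportions, their cross-sample correlation and modules.

The relative proportion of a subtype in a sample is its cell count divided
by the cell count of its parent cell type; samples where the parent type is
absent get a missing value (never 0).  Pairwise-complete Pearson correlation
across samples, hierarchical clustering on d = 1 - r, and a flat cut yield
co-varying subtype "modules"; responder-vs-non-responder differences use the
two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy import stats
from sklearn.base import BaseEstimator, ClusterMixin

from .simulate import CohortDataset

GROUP_FILTERS: dict[str, tuple[str, ...] | None] = {
    "all": None,
    "with-ici": ("with ICI", "ICI only", "anti-PD1"),
    "ici-only": ("ICI only", "anti-PD1"),
    "anti-pd1": ("anti-PD1",),
}


@dataclass
class ProportionTable:
    """samples x subtypes relative proportions with missing-parent handling."""

    table: pd.DataFrame
    parent_map: dict[str, str]

    def validate(self) -> None:
        vals = self.table.to_numpy(dtype=float)
        defined = ~np.isnan(vals)
        if ((vals < 0) | (vals > 1))[defined].any():
            raise ValueError("defined proportions must lie in [0, 1]")


@dataclass
class ModuleResult:
    corr: pd.DataFrame
    n_pairs: pd.DataFrame
    undefined_reason: pd.DataFrame  # "" where defined
    linkage: np.ndarray | None = None
    cut: float | None = None
    labels: pd.Series | None = None
    imputed_pairs: list[tuple[str, str]] = field(default_factory=list)


def compute_relative_proportions(dataset: CohortDataset) -> ProportionTable:
    cm = dataset.cell_meta
    parent_map = dict(dataset.parent_map)
    if not parent_map:
        pairs = cm[["subtype", "cell_type"]].drop_duplicates()
        if pairs["subtype"].duplicated().any():
            raise ValueError("subtype mapped to multiple parent cell types")
        parent_map = dict(zip(pairs["subtype"], pairs["cell_type"]))
    missing = set(cm["subtype"].unique()) - set(parent_map)
    if missing:
        raise ValueError(f"subtype(s) without parent mapping: {sorted(missing)}")

    samples = pd.Index(sorted(dataset.sample_meta.index), name="sample_id")
    sub_counts = (
        cm.groupby(["sample_id", "subtype"]).size().unstack(fill_value=0)
        .reindex(index=samples, fill_value=0)
    )
    type_counts = (
        cm.groupby(["sample_id", "cell_type"]).size().unstack(fill_value=0)
        .reindex(index=samples, fill_value=0)
    )
    subtypes = sorted(parent_map)
    out = pd.DataFrame(index=samples, columns=subtypes, dtype=float)
    for sub in subtypes:
        parent = parent_map[sub]
        denom = type_counts.get(parent, pd.Series(0, index=samples)).astype(float)
        num = sub_counts.get(sub, pd.Series(0, index=samples)).astype(float)
        out[sub] = num / denom.replace(0, np.nan)
    table = ProportionTable(table=out, parent_map=parent_map)
    table.validate()
    return table


def correlate_proportions(table: ProportionTable, min_pairs: int = 3) -> ModuleResult:
    """Pairwise-complete Pearson r per subtype pair with per-pair sample counts."""
    df = table.table
    if df.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    cols = list(df.columns)
    k = len(cols)
    corr = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    n_pairs = pd.DataFrame(0, index=cols, columns=cols, dtype=int)
    reason = pd.DataFrame("", index=cols, columns=cols, dtype=object)
    vals = df.to_numpy(dtype=float)
    for i in range(k):
        n_pairs.iloc[i, i] = int(np.isfinite(vals[:, i]).sum())
    for i in range(k):
        for j in range(i + 1, k):
            ok = np.isfinite(vals[:, i]) & np.isfinite(vals[:, j])
            n = int(ok.sum())
            n_pairs.iloc[i, j] = n_pairs.iloc[j, i] = n
            if n < min_pairs:
                corr.iloc[i, j] = corr.iloc[j, i] = np.nan
                reason.iloc[i, j] = reason.iloc[j, i] = "insufficient_pairs"
                continue
            x, y = vals[ok, i], vals[ok, j]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                corr.iloc[i, j] = corr.iloc[j, i] = np.nan
                reason.iloc[i, j] = reason.iloc[j, i] = "constant"
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            corr.iloc[i, j] = corr.iloc[j, i] = r
    return ModuleResult(corr=corr, n_pairs=n_pairs, undefined_reason=reason)


def cluster_modules(
    result: ModuleResult, linkage_method: str = "complete", cut: float = 0.9
) -> ModuleResult:
    """Agglomerative clustering on d = 1 - r; flat modules cut at ``cut``.

    Undefined correlations are imputed to r = 0 inside the clustering only
    (recorded in ``imputed_pairs``); modules are numbered by the column index
    of their first subtype.
    """
    if linkage_method not in ("single", "complete", "average", "weighted",
                              "centroid", "median", "ward"):
        raise ValueError(f"invalid linkage method {linkage_method!r}")
    corr = result.corr
    cols = list(corr.columns)
    cmat = corr.to_numpy(dtype=float).copy()
    imputed = [
        (cols[i], cols[j])
        for i in range(len(cols))
        for j in range(i + 1, len(cols))
        if np.isnan(cmat[i, j])
    ]
    cmat[np.isnan(cmat)] = 0.0
    dist = 1.0 - cmat
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage_method)
    raw = hierarchy.fcluster(Z, t=cut, criterion="distance")
    # deterministic renumbering by first-occurrence column order
    relabel: dict[int, int] = {}
    labels = np.empty(len(cols), dtype=int)
    for i, r in enumerate(raw):
        if r not in relabel:
            relabel[r] = len(relabel) + 1
        labels[i] = relabel[r]
    return replace(
        result,
        linkage=Z,
        cut=cut,
        labels=pd.Series(labels, index=cols, name="module"),
        imputed_pairs=imputed,
    )


class SubtypeModuleClustering(BaseEstimator, ClusterMixin):
    """Correlation + hierarchical module calling as one estimator.

    ``fit`` accepts a :class:`ProportionTable` (or a raw samples x subtypes
    DataFrame) and exposes ``labels_``, ``corr_`` and ``linkage_``.
    """

    def __init__(self, linkage_method: str = "complete", cut: float = 0.9,
                 min_pairs: int = 3):
        self.linkage_method = linkage_method
        self.cut = cut
        self.min_pairs = min_pairs

    def fit(self, X, y=None):
        table = X if isinstance(X, ProportionTable) else ProportionTable(pd.DataFrame(X), {})
        res = correlate_proportions(table, min_pairs=self.min_pairs)
        res = cluster_modules(res, linkage_method=self.linkage_method, cut=self.cut)
        self.result_ = res
        self.corr_ = res.corr
        self.linkage_ = res.linkage
        self.labels_ = res.labels.to_numpy()
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def compare_by_response(
    table: ProportionTable,
    sample_meta: pd.DataFrame,
    group_filter: str = "all",
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum of proportions between R and NR samples.

    ``group_filter`` restricts by treatment group (keys of GROUP_FILTERS).
    Returns one row per subtype: W statistic, p, the flags the study judges
    at (p < 0.1 labelled, p < 0.05 significant), or a skip reason.
    """
    if group_filter not in GROUP_FILTERS:
        raise ValueError(f"unknown group filter {group_filter!r}")
    allowed = GROUP_FILTERS[group_filter]
    sm = sample_meta
    keep = sm.index if allowed is None else sm.index[sm["treatment_group"].isin(allowed)]
    rows = []
    for sub in table.table.columns:
        vals = table.table.loc[table.table.index.intersection(keep), sub].dropna()
        resp = sm.loc[vals.index, "response"]
        x = vals[resp == "NR"].to_numpy()
        y = vals[resp == "R"].to_numpy()
        if len(x) == 0 or len(y) == 0:
            rows.append({"subtype": sub, "W": np.nan, "p": np.nan,
                         "n_NR": len(x), "n_R": len(y),
                         "skipped": "empty response arm"})
            continue
        res = stats.mannwhitneyu(x, y, alternative="two-sided")
        rows.append({"subtype": sub, "W": float(res.statistic), "p": float(res.pvalue),
                     "n_NR": len(x), "n_R": len(y), "skipped": "",
                     "labelled_p_lt_0.1": res.pvalue < 0.1,
                     "significant_p_lt_0.05": res.pvalue < 0.05})
    return pd.DataFrame(rows).set_index("subtype")
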