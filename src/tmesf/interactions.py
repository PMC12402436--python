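"""Ligand-receptor interaction calling between cell subtypes.

Per sample, the mean of an interaction from source subtype A to target B is
half the sum of the ligand's mean log-normalized expression in A and the
receptor's in B; significance comes from a permutation null built by
shuffling subtype labels over the sample's cells.  The "significant mean"
is the observed mean when p < 0.05 and exactly 0 otherwise.  Cross-sample
aggregation yields exclusive calls (significant for the focal subtype in at
least ``min_samples`` samples and never for the comparison subtypes) and
differential calls (two-sided rank-sum p < alpha plus presence in strictly
more than half of the samples of each group).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MIN_EXPR_FRACTION = 0.1
SIG_ALPHA = 0.05


@dataclass
class InteractionCallSet:
    """Per-sample significance-gated interaction means."""

    calls: pd.DataFrame  # source, target, interaction_id, mean, p, significant_mean, masked
    n_permutations: int
    seed: int
    skipped_interactions: list[str]

    def __post_init__(self) -> None:
        ok = self.calls["p"].notna()
        p = self.calls.loc[ok, "p"]
        if ((p <= 0) | (p > 1)).any():
            raise ValueError("p-values must lie in (0, 1]")
        gated = self.calls.loc[ok]
        bad = (gated["significant_mean"] == 0) != (gated["p"] >= SIG_ALPHA)
        # masked interactions are gated to 0 regardless of p
        if (bad & ~gated["masked"]).any():
            raise ValueError("significant_mean must be 0 exactly when p >= 0.05")


def _subtype_stats(expr: np.ndarray, labels: np.ndarray, subtypes: list[str]):
    """Per-subtype mean expression and detection fraction (genes x subtypes)."""
    means = np.empty((expr.shape[0], len(subtypes)))
    fracs = np.empty_like(means)
    for j, s in enumerate(subtypes):
        cols = labels == s
        means[:, j] = expr[:, cols].mean(axis=1)
        fracs[:, j] = (expr[:, cols] > 0).mean(axis=1)
    return means, fracs


def interaction_means(
    expr: np.ndarray,
    gene_names: pd.Index,
    labels: np.ndarray,
    catalog: pd.DataFrame,
    min_fraction: float = MIN_EXPR_FRACTION,
) -> tuple[pd.DataFrame, list[str]]:
    """Observed means for every ordered subtype pair and catalog interaction.

    ``expr`` is log-normalized genes x cells.  Interactions whose ligand or
    receptor is absent from the matrix are skipped and listed.  Pairs where
    either gene is detected in < ``min_fraction`` of the relevant subtype's
    cells are masked (flagged, mean retained).  Subtypes absent from the
    sample simply do not appear (missing, not zero).
    """
    labels = np.asarray(labels, dtype=object)
    subtypes = sorted(pd.unique(labels))
    gene_pos = {g: i for i, g in enumerate(gene_names)}
    skipped = [
        row.interaction_id
        for row in catalog.itertuples()
        if row.ligand not in gene_pos or row.receptor not in gene_pos
    ]
    usable = catalog[~catalog["interaction_id"].isin(skipped)]
    means, fracs = _subtype_stats(np.asarray(expr, dtype=float), labels, subtypes)
    rows = []
    for row in usable.itertuples():
        li, ri = gene_pos[row.ligand], gene_pos[row.receptor]
        for a, src in enumerate(subtypes):
            for b, tgt in enumerate(subtypes):
                rows.append({
                    "source": src, "target": tgt,
                    "interaction_id": row.interaction_id,
                    "mean": 0.5 * (means[li, a] + means[ri, b]),
                    "masked": (fracs[li, a] < min_fraction) or (fracs[ri, b] < min_fraction),
                })
    return pd.DataFrame(rows), skipped


def permutation_test(
    expr: np.ndarray,
    gene_names: pd.Index,
    labels: np.ndarray,
    catalog: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    method: str = "auto",
) -> InteractionCallSet:
    """One sample's permutation test.

    Monte-Carlo: p = (1 + #{perm mean >= obs}) / (1 + n_perm), shuffling
    subtype labels over the sample's cells.  With ``method='exhaustive'``
    (or 'auto' and <= 8 cells) every label arrangement is enumerated and
    p = #{perm mean >= obs} / n_arrangements exactly.  Masked interactions
    get significant_mean 0 and p = 1.
    """
    expr = np.asarray(expr, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if method not in ("auto", "exhaustive", "monte-carlo"):
        raise ValueError(f"unknown method {method!r}")
    exhaustive = method == "exhaustive" or (method == "auto" and expr.shape[1] <= 8)
    if not exhaustive and n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is low; p-value resolution is poor")
    obs, skipped = interaction_means(expr, gene_names, labels, catalog)
    subtypes = sorted(pd.unique(labels))
    gene_pos = {g: i for i, g in enumerate(gene_names)}
    usable = catalog[~catalog["interaction_id"].isin(skipped)]
    lig_idx = np.array([gene_pos[g] for g in usable["ligand"]])
    rec_idx = np.array([gene_pos[g] for g in usable["receptor"]])
    need = np.unique(np.concatenate([lig_idx, rec_idx]))
    remap = {g: i for i, g in enumerate(need)}
    sub_expr = expr[need]
    li = np.array([remap[g] for g in lig_idx])
    ri = np.array([remap[g] for g in rec_idx])

    rng = np.random.default_rng(seed)
    k, n = len(subtypes), expr.shape[1]
    obs_mat = obs.pivot_table(index=["source", "target"], columns="interaction_id",
                              values="mean")
    ge = np.zeros_like(obs_mat.to_numpy())
    code = pd.Categorical(labels, categories=subtypes).codes
    pair_index = obs_mat.index
    inter_order = list(obs_mat.columns)
    col_of = {iid: j for j, iid in enumerate(inter_order)}
    sel = np.array([col_of[iid] for iid in usable["interaction_id"]])
    def _accumulate(perm_labels):
        pm = np.zeros((sub_expr.shape[0], k))
        counts = np.bincount(perm_labels, minlength=k).astype(float)
        for j in range(k):
            pm[:, j] = sub_expr[:, perm_labels == j].sum(axis=1)
        pm /= counts[None, :]
        # means for every ordered pair x usable interaction
        for p_idx, (src, tgt) in enumerate(pair_index):
            a, b = subtypes.index(src), subtypes.index(tgt)
            vals = 0.5 * (pm[li, a] + pm[ri, b])
            row_obs = obs_mat.to_numpy()[p_idx, sel]
            ge[p_idx, sel] += vals >= row_obs - 1e-12

    if exhaustive:
        import itertools

        n_total = 0
        for perm in itertools.permutations(code):
            _accumulate(np.array(perm))
            n_total += 1
        pvals = ge / n_total
        n_perm = n_total
    else:
        perm_labels = code.copy()
        for _ in range(n_perm):
            rng.shuffle(perm_labels)
            _accumulate(perm_labels)
        pvals = (1.0 + ge) / (1.0 + n_perm)
    pl = pd.DataFrame(pvals, index=pair_index, columns=inter_order).stack()
    pl.name = "p"
    calls = obs.merge(pl.rename_axis(["source", "target", "interaction_id"]).reset_index(),
                      on=["source", "target", "interaction_id"])
    calls.loc[calls["masked"], "p"] = 1.0
    calls["significant_mean"] = np.where(
        (calls["p"] < SIG_ALPHA) & ~calls["masked"], calls["mean"], 0.0
    )
    return InteractionCallSet(calls=calls, n_permutations=n_perm, seed=seed,
                              skipped_interactions=skipped)


def _gated_table(callsets: dict[str, InteractionCallSet]) -> pd.DataFrame:
    """Long table over samples: sample, source, target, interaction, gated mean."""
    frames = []
    for sid in sorted(callsets):
        df = callsets[sid].calls[["source", "target", "interaction_id",
                                  "significant_mean"]].copy()
        df.insert(0, "sample_id", sid)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def exclusive_interactions(
    callsets: dict[str, InteractionCallSet],
    focal: str = "mregDC",
    others: tuple[str, ...] = ("cDC1", "cDC2"),
    min_samples: int = 3,
) -> pd.DataFrame:
    """Interactions significant for the focal subtype in >= min_samples samples
    and never significant for any comparison subtype with the same partner."""
    if len(callsets) < min_samples:
        raise ValueError("need callsets from at least min_samples samples")
    tab = _gated_table(callsets)
    rows = []
    for role, own_col, partner_col in (("source", "source", "target"),
                                       ("target", "target", "source")):
        focal_tab = tab[tab[own_col] == focal]
        other_tab = tab[tab[own_col].isin(others)]
        grp = focal_tab.groupby([partner_col, "interaction_id"])["significant_mean"]
        n_sig = grp.apply(lambda v: int((v > 0).sum()))
        other_sig = other_tab.groupby([partner_col, "interaction_id"])[
            "significant_mean"].apply(lambda v: bool((v > 0).any()))
        for (partner, iid), n in n_sig.items():
            if partner == focal or partner in others:
                continue
            ever_other = bool(other_sig.get((partner, iid), False))
            if n >= min_samples and not ever_other:
                rows.append({"role": role, "partner": partner, "interaction_id": iid,
                             "n_significant_samples": n})
    return pd.DataFrame(rows, columns=["role", "partner", "interaction_id",
                                       "n_significant_samples"])


def differential_interactions(
    callsets: dict[str, InteractionCallSet],
    group_assignment: pd.Series | None = None,
    subtype_contrast: tuple[str, str] | None = None,
    alpha: float = SIG_ALPHA,
) -> pd.DataFrame:
    """Differential interaction calls across two groups of gated means.

    Either ``group_assignment`` (sample -> group label, two levels; the
    contrast is the same source/target pair across sample groups) or
    ``subtype_contrast`` (two source subtypes compared on the same partner
    across all samples).  A call requires two-sided rank-sum p < alpha and
    presence (nonzero gated mean) in strictly more than half of the samples
    of each group.
    """
    if (group_assignment is None) == (subtype_contrast is None):
        raise ValueError("give exactly one of group_assignment or subtype_contrast")
    tab = _gated_table(callsets)
    rows = []
    if group_assignment is not None:
        levels = sorted(pd.unique(group_assignment.dropna()))
        if len(levels) != 2:
            raise ValueError("group_assignment must have exactly 2 levels")
        g1, g2 = levels
        s1 = set(group_assignment.index[group_assignment == g1])
        s2 = set(group_assignment.index[group_assignment == g2])
        if len(s1) < 2 or len(s2) < 2:
            raise ValueError("each group needs at least 2 samples")
        for (src, tgt, iid), sub in tab.groupby(["source", "target", "interaction_id"]):
            v1 = sub.loc[sub["sample_id"].isin(s1), "significant_mean"]
            v1 = v1.reindex_like(v1).to_numpy()
            v2 = sub.loc[sub["sample_id"].isin(s2), "significant_mean"].to_numpy()
            v1 = np.concatenate([v1, np.zeros(len(s1) - len(v1))])  # absent -> 0
            v2 = np.concatenate([v2, np.zeros(len(s2) - len(v2))])
            rows.append(_diff_row({"source": src, "target": tgt, "interaction_id": iid},
                                  v1, v2, g1, g2, alpha))
    else:
        a, b = subtype_contrast
        samples = sorted(callsets)
        for (tgt, iid), sub in tab[tab["source"].isin([a, b])].groupby(
                ["target", "interaction_id"]):
            va = sub[sub["source"] == a].set_index("sample_id")["significant_mean"]
            vb = sub[sub["source"] == b].set_index("sample_id")["significant_mean"]
            v1 = va.reindex(samples, fill_value=0.0).to_numpy()
            v2 = vb.reindex(samples, fill_value=0.0).to_numpy()
            rows.append(_diff_row({"target": tgt, "interaction_id": iid,
                                   "contrast": f"{a} vs {b}"}, v1, v2, a, b, alpha))
    return pd.DataFrame(rows)


def _diff_row(key: dict, v1: np.ndarray, v2: np.ndarray, g1: str, g2: str,
              alpha: float) -> dict:
    present1 = int((v1 > 0).sum())
    present2 = int((v2 > 0).sum())
    if np.ptp(np.concatenate([v1, v2])) == 0:
        p = 1.0
    else:
        p = float(stats.mannwhitneyu(v1, v2, alternative="two-sided").pvalue)
    presence_ok = present1 * 2 > len(v1) and present2 * 2 > len(v2)
    called = bool(p < alpha and presence_ok)
    direction = ""
    if called:
        direction = f"up in {g2}" if v2.mean() > v1.mean() else f"up in {g1}"
    return {**key, "p": p, f"n_present_{g1}": present1, f"n_present_{g2}": present2,
            "n_group1": len(v1), "n_group2": len(v2),
            "called": called, "direction": direction}
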