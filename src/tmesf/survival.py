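"""Biomarker binarization, Kaplan-Meier / log-rank / Cox survival analysis.

Biomarkers: the mregDC share of conventional dendritic cells per sample
(survival splits at > 0.20; model grouping elsewhere uses > 0.185) and the
TCF7+/TCF7- CD8 T-cell ratio (default split at the cohort median).  The
combined stratification emits the 4-level cross and the "both-high vs rest"
contrast.  Survival machinery (product-limit curves, log-rank tests, Cox
partial likelihood with Efron ties) is delegated to lifelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .simulate import CohortDataset

MREGDC_SURVIVAL_THRESHOLD = 0.20   # survival splits
MREGDC_GROUP_THRESHOLD = 0.185     # model grouping


@dataclass
class BiomarkerTable:
    values: pd.DataFrame         # per sample: mregdc_cdc_proportion, tcf7_ratio
    labels: pd.DataFrame         # mregdc_group, tcf7_group, combined labels
    thresholds: dict[str, float]
    excluded: pd.DataFrame       # samples excluded from combined analyses + reason


@dataclass
class SurvivalResult:
    curves: dict[str, pd.DataFrame]   # per group: time, at_risk, survival
    statistic: float
    p: float
    n_events: int
    groups: list[str]
    dropped_groups: list[str] = field(default_factory=list)
    note: str = ""


def binarize_biomarker(
    values: pd.Series, threshold: float, direction: str = "greater"
) -> pd.Series:
    """'high' iff value > threshold ('less': high iff value < threshold);
    missing values propagate."""
    if values.dropna().empty:
        raise ValueError("all biomarker values missing")
    v = values.astype(float)
    if direction == "greater":
        hi = v > threshold
    elif direction == "less":
        hi = v < threshold
    else:
        raise ValueError("direction must be 'greater' or 'less'")
    out = pd.Series(np.where(hi, "high", "low"), index=values.index, dtype=object)
    out[v.isna()] = pd.NA
    return out


def compute_biomarkers(
    dataset: CohortDataset,
    mregdc_threshold: float = MREGDC_SURVIVAL_THRESHOLD,
    tcf7_threshold: float | None = None,
    tcf7_positive: str = "CD8 TCF7+",
    tcf7_negative: str = "CD8 TCF7-",
) -> BiomarkerTable:
    """mregDC/cDC proportion and TCF7+/- CD8 ratio per sample, binarized.

    Samples lacking CD8 T cells get a missing ratio and are excluded from
    combined analyses.  The TCF7 threshold defaults to the cohort median.
    """
    sm = dataset.sample_meta
    cm = dataset.cell_meta
    by_sample = cm.groupby("sample_id")
    n_pos = by_sample["subtype"].apply(lambda s: int((s == tcf7_positive).sum()))
    n_neg = by_sample["subtype"].apply(lambda s: int((s == tcf7_negative).sum()))
    n_pos = n_pos.reindex(sm.index, fill_value=0)
    n_neg = n_neg.reindex(sm.index, fill_value=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(
            (n_pos + n_neg) == 0, np.nan,
            np.where(n_neg == 0, np.inf, n_pos / n_neg.replace(0, np.nan)),
        )
    values = pd.DataFrame(
        {
            "mregdc_cdc_proportion": sm["mregdc_cdc_proportion"].astype(float),
            "tcf7_ratio": ratio,
        },
        index=sm.index,
    )
    if tcf7_threshold is None:
        finite = values["tcf7_ratio"].replace(np.inf, np.nan).dropna()
        tcf7_threshold = float(finite.median()) if len(finite) else np.nan
    labels = pd.DataFrame(index=sm.index)
    labels["mregdc_group"] = binarize_biomarker(
        values["mregdc_cdc_proportion"], mregdc_threshold
    )
    labels["tcf7_group"] = binarize_biomarker(values["tcf7_ratio"], tcf7_threshold)
    excluded = pd.DataFrame(
        {"reason": "no CD8 T cells"},
        index=values.index[values["tcf7_ratio"].isna()],
    )
    return BiomarkerTable(
        values=values,
        labels=labels,
        thresholds={"mregdc": mregdc_threshold, "tcf7": tcf7_threshold},
        excluded=excluded,
    )


def combine_biomarkers(biomarkers: BiomarkerTable) -> pd.DataFrame:
    """4-level cross and 2-level both-high-vs-rest labels per sample.

    Samples with either label missing are excluded (listed in
    ``biomarkers.excluded``); empty cross-cells are reported in ``attrs``.
    """
    lab = biomarkers.labels
    ok = lab["mregdc_group"].notna() & lab["tcf7_group"].notna()
    out = pd.DataFrame(index=lab.index[ok])
    out["four_level"] = (
        "mregDC-" + lab.loc[ok, "mregdc_group"].astype(str)
        + "/TCF7-" + lab.loc[ok, "tcf7_group"].astype(str)
    )
    out["high_high"] = np.where(
        (lab.loc[ok, "mregdc_group"] == "high") & (lab.loc[ok, "tcf7_group"] == "high"),
        "both-high", "rest",
    )
    all_cells = [
        f"mregDC-{a}/TCF7-{b}" for a in ("high", "low") for b in ("high", "low")
    ]
    empty = [c for c in all_cells if c not in set(out["four_level"])]
    out.attrs["empty_cells"] = empty
    out.attrs["n_excluded"] = int((~ok).sum())
    return out


def km_logrank(time, event, labels) -> SurvivalResult:
    """Product-limit curves per group and the k-group log-rank test."""
    df = pd.DataFrame({"time": np.asarray(time, dtype=float),
                       "event": np.asarray(event, dtype=int),
                       "label": np.asarray(labels, dtype=object)})
    if (df["time"] <= 0).any():
        raise ValueError("times must be positive")
    if not set(df["event"]) <= {0, 1}:
        raise ValueError("events must be 0/1")
    sizes = df.groupby("label").size()
    dropped = [str(g) for g in sizes.index[sizes == 0]]
    groups = [str(g) for g in sizes.index[sizes > 0]]
    if len(groups) < 2:
        raise ValueError("need at least 2 non-empty groups")
    curves = {}
    for g in groups:
        sub = df[df["label"] == g]
        km = KaplanMeierFitter()
        km.fit(sub["time"], sub["event"])
        tab = km.event_table
        curves[g] = pd.DataFrame({
            "time": tab.index.to_numpy(dtype=float),
            "at_risk": tab["at_risk"].to_numpy(dtype=int),
            "survival": km.survival_function_["KM_estimate"].to_numpy(dtype=float),
        })
    n_events = int(df["event"].sum())
    if n_events == 0:
        return SurvivalResult(curves=curves, statistic=np.nan, p=np.nan,
                              n_events=0, groups=groups, dropped_groups=dropped,
                              note="no events; test undefined")
    res = multivariate_logrank_test(df["time"], df["label"], df["event"])
    return SurvivalResult(curves=curves, statistic=float(res.test_statistic),
                          p=float(res.p_value), n_events=n_events, groups=groups,
                          dropped_groups=dropped)


def cox_fit(time, event, design: pd.DataFrame) -> pd.DataFrame:
    """Cox proportional hazards (Efron ties, two-sided Wald p-values).

    Constant columns are dropped with a note; rank deficiency raises an
    error naming the offending columns; non-convergence is reported.
    """
    design = design.copy().astype(float)
    constant = [c for c in design.columns if design[c].nunique() <= 1]
    design = design.drop(columns=constant)
    if design.shape[1] == 0:
        raise ValueError("design has no non-constant columns")
    X = design.to_numpy()
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad: list[str] = []
        kept: list[str] = []
        mat = None
        for c in design.columns:
            v = design[c].to_numpy()
            cand = v[:, None] if mat is None else np.column_stack([mat, v])
            if np.linalg.matrix_rank(cand) > (0 if mat is None else np.linalg.matrix_rank(mat)):
                kept.append(c)
                mat = cand
            else:
                bad.append(c)
        raise ValueError(f"rank-deficient design; column(s) {bad} are collinear with {kept}")
    df = design.copy()
    df["time"] = np.asarray(time, dtype=float)
    df["event"] = np.asarray(event, dtype=int)
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # lifelines raises ConvergenceError on separation
        raise RuntimeError(f"Cox fit failed: {exc}") from exc
    out = cph.summary[["coef", "se(coef)", "z", "p"]].copy()
    out.columns = ["log_hr", "se", "z", "p"]
    out.attrs["dropped_constant"] = constant
    return out


def latest_timepoint_filter(sample_meta: pd.DataFrame) -> tuple[pd.Index, pd.DataFrame]:
    """Keep one sample per patient — the latest collection timepoint.

    Ordering uses a ``timepoint`` column if present, else the treatment
    state (pre < on < post).  Ties go to the lexicographically last sample
    id and are flagged in the report.
    """
    if "patient_id" not in sample_meta.columns:
        raise ValueError("sample_meta must have a patient_id column")
    sm = sample_meta.copy()
    if "timepoint" in sm.columns:
        order = sm["timepoint"].astype(float)
    else:
        order = sm["treatment_state"].map({"pre": 0, "on": 1, "post": 2}).astype(float)
    sm["_order"] = order
    keep = []
    ties = []
    for pid, grp in sm.groupby("patient_id", sort=True):
        best = grp[grp["_order"] == grp["_order"].max()]
        chosen = sorted(best.index)[-1]
        keep.append(chosen)
        if len(best) > 1:
            ties.append({"patient_id": pid, "chosen": chosen,
                         "tied": sorted(best.index)})
    report = pd.DataFrame(ties, columns=["patient_id", "chosen", "tied"])
    return pd.Index(sorted(keep)), report
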