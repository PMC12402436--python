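"""Synthetic multi-sample single-cell cohorts with known ground truth.

The generator emulates the statistical structure assumed by the downstream
pipeline stages: negative-binomial counts with a log library-size offset,
per-sample Gaussian random intercepts (variance ``sigma2``) and cell-level
overdispersion ``phi`` (Var = mu + mu^2/phi); a per-cell binary latent state
``z`` whose prevalence differs between biomarker-high and biomarker-low
samples and which shifts a block of state genes by ``gamma`` on the
natural-log scale; subtype compositions whose per-sample Dirichlet
concentrations are driven by shared latent factors, producing correlated
proportion modules; and proportional-hazards survival times whose hazard
depends on the sample-level biomarkers.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

TISSUES = ("lymph", "other", "skin")
TREATMENT_STATES = ("on", "post", "pre")
TREATMENT_GROUPS = ("ICI only", "anti-PD1", "other", "with ICI")
SEXES = ("F", "M")


def _default_subtype_catalog() -> dict[str, list[str]]:
    # each parent keeps a neutral subtype so the sum-to-one constraint does
    # not force loaded subtypes of the same parent into perfect anticorrelation
    return {
        "cDC": ["cDC1", "cDC2", "mregDC"],
        "CD8 T": ["CD8 TCF7+", "CD8 TCF7-", "CD8 Tex"],
        "CD4 T": ["CD4 Tn", "CD4 Tm", "CD4 Treg"],
        "B": ["B naive", "B memory", "B plasma"],
        "Tumor": ["Tumor stress", "Tumor pigmentation", "Tumor respiration"],
    }


def _default_module_structure() -> dict[str, tuple[float, ...]]:
    # Two planted proportion-covariance modules: a naive/immune-recruitment
    # axis (factor 1) and a suppression/exhaustion axis (factor 2).
    return {
        "mregDC": (0.9, 0.0),
        "CD8 TCF7+": (0.9, 0.0),
        "CD4 Tn": (0.9, 0.0),
        "B naive": (0.9, 0.0),
        "CD8 Tex": (0.0, 0.9),
        "CD4 Treg": (0.0, 0.9),
        "B plasma": (0.0, 0.9),
        "Tumor stress": (0.0, 0.9),
    }


@dataclass
class SurvivalParams:
    """Exponential proportional-hazards generator settings.

    ``baseline_hazard`` is in events per month; ``log_hr`` maps sample-level
    covariate columns (binary or numeric) to log hazard ratios;
    ``censoring_rate`` is the expected fraction of censored subjects.
    """

    baseline_hazard: float = 0.08
    log_hr: dict[str, float] = field(
        default_factory=lambda: {"mregdc_high": -0.7, "tcf7_high": -0.5}
    )
    censoring_rate: float = 0.3

    def validate(self) -> None:
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if not 0.0 <= self.censoring_rate <= 1.0:
            raise ValueError("censoring_rate must be in [0, 1]")


@dataclass
class SimulationConfig:
    """All knobs of the cohort generator; defaults define the study conditions."""

    n_samples: int = 8
    cells_per_sample: int | tuple[int, int] = 150
    n_genes: int = 300
    n_state_genes: int = 60
    gamma_scale: float = 1.0
    pi_low: float = 0.1
    pi_high: float = 0.6
    sigma2: float = 0.25
    phi: float = 5.0
    libsize_logmean: float = float(np.log(2500.0))
    libsize_logsd: float = 0.4
    subtype_catalog: dict[str, list[str]] = field(default_factory=_default_subtype_catalog)
    module_structure: dict[str, tuple[float, ...]] = field(
        default_factory=_default_module_structure
    )
    survival_params: SurvivalParams = field(default_factory=SurvivalParams)
    covariate_frequencies: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "sex": {"F": 0.5, "M": 0.5},
            "tissue": {"skin": 0.5, "lymph": 0.3, "other": 0.2},
            "treatment_state": {"pre": 0.4, "on": 0.3, "post": 0.3},
            "treatment_group": {
                "other": 0.2,
                "with ICI": 0.3,
                "ICI only": 0.3,
                "anti-PD1": 0.2,
            },
        }
    )
    age_mean: float = 60.0
    age_sd: float = 10.0
    p_biomarker_high: float = 0.3
    beta_covariate_sd: float = 0.1
    mito_beta: tuple[float, float] = (2.0, 38.0)
    ribo_beta: tuple[float, float] = (4.0, 16.0)
    confound_mito_with_state: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("pi_low", "pi_high", "p_biomarker_high"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must be a probability in [0, 1]")
        if self.phi <= 0:
            raise ValueError("phi must be > 0")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")
        if self.n_state_genes > self.n_genes:
            raise ValueError("n_state_genes cannot exceed n_genes")
        subtypes = self.all_subtypes()
        if len(set(subtypes)) != len(subtypes):
            raise ValueError("subtype names must be unique across parent types")
        for subtype in self.module_structure:
            if subtype not in subtypes:
                raise ValueError(f"module_structure subtype {subtype!r} has no parent type")
        self.survival_params.validate()

    def all_subtypes(self) -> list[str]:
        return [s for subs in self.subtype_catalog.values() for s in subs]

    def parent_map(self) -> dict[str, str]:
        return {s: parent for parent, subs in self.subtype_catalog.items() for s in subs}

    def n_factors(self) -> int:
        lengths = {len(v) for v in self.module_structure.values()}
        if not lengths:
            return 0
        if len(lengths) != 1:
            raise ValueError("module_structure loadings must all have the same length")
        return lengths.pop()

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "survival_params" in raw:
            raw["survival_params"] = SurvivalParams(**raw["survival_params"])
        return cls(**raw)

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class GroundTruth:
    """Oracle for recovery tests; dimensions match the emitted dataset."""

    z: np.ndarray  # (n_cells,) in {0, 1}
    beta0: np.ndarray  # (n_genes,) baseline log-abundance
    beta_cov: np.ndarray  # (n_covariates, n_genes)
    gamma: np.ndarray  # (n_genes,) state log-fold effect; 0 outside state genes
    state_genes: np.ndarray  # boolean mask, gamma != 0
    sample_group: pd.Series  # per sample, 1 = biomarker high (intended)
    tcf7_group: pd.Series
    sample_effects: np.ndarray  # (n_genes, n_samples) random intercepts u_{g,s}
    module_labels: dict[str, int]  # planted partition of subtypes
    sample_factors: np.ndarray  # (n_samples, n_factors)
    survival_log_hr: dict[str, float]
    library_size: np.ndarray | None = None  # latent N_i before sampling noise

    def __post_init__(self) -> None:
        if not np.array_equal(self.state_genes, self.gamma != 0):
            raise ValueError("state_genes must be exactly the genes with gamma != 0")


@dataclass
class CohortDataset:
    """Counts plus cell- and sample-level metadata; the universal pipeline input."""

    counts: np.ndarray  # genes x cells, non-negative integers
    gene_names: pd.Index
    cell_ids: pd.Index
    cell_meta: pd.DataFrame  # index: cell id
    sample_meta: pd.DataFrame  # index: sample id
    parent_map: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        if self.counts.shape != (len(self.gene_names), len(self.cell_ids)):
            raise ValueError("counts shape does not match gene/cell names")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        colsums = np.asarray(self.counts.sum(axis=0)).ravel()
        if not np.array_equal(colsums, self.cell_meta["total_counts"].to_numpy()):
            raise ValueError("total_counts must equal column sums of counts")
        unknown = set(self.cell_meta["sample_id"]) - set(self.sample_meta.index)
        if unknown:
            raise ValueError(f"cell_meta references unknown sample id(s): {sorted(unknown)}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def subset_cells(self, mask: np.ndarray) -> "CohortDataset":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CohortDataset(
            counts=self.counts[:, idx],
            gene_names=self.gene_names,
            cell_ids=self.cell_ids[idx],
            cell_meta=self.cell_meta.iloc[idx],
            sample_meta=self.sample_meta,
            parent_map=self.parent_map,
        )


def _draw_categorical(rng, levels_freq: Mapping[str, float], n: int) -> np.ndarray:
    levels = sorted(levels_freq)
    p = np.array([levels_freq[k] for k in levels], dtype=float)
    p = p / p.sum()
    return rng.choice(levels, size=n, p=p)


def _simulate_sample_meta(config: SimulationConfig, rng) -> pd.DataFrame:
    n = config.n_samples
    ids = pd.Index([f"S{i + 1:02d}" for i in range(n)], name="sample_id")
    freq = config.covariate_frequencies
    meta = pd.DataFrame(
        {
            "age": np.round(rng.normal(config.age_mean, config.age_sd, n), 1),
            "sex": _draw_categorical(rng, freq["sex"], n),
            "tissue": _draw_categorical(rng, freq["tissue"], n),
            "treatment_state": _draw_categorical(rng, freq["treatment_state"], n),
            "treatment_group": _draw_categorical(rng, freq["treatment_group"], n),
        },
        index=ids,
    )
    meta["patient_id"] = [f"P{i + 1:02d}" for i in range(n)]
    return meta


def _composition_concentrations(
    config: SimulationConfig,
    sample_ids: pd.Index,
    factors: np.ndarray,
) -> pd.DataFrame:
    """Per-sample Dirichlet concentrations for every subtype.

    The latent module factors multiply the baselines; the mregDC baseline is
    set so that the realized mregDC/cDC share exceeds the 0.185 grouping
    threshold in roughly ``p_biomarker_high`` of samples (the biomarker group
    is then defined downstream from the realized composition).
    """
    subtypes = config.all_subtypes()
    base = pd.Series(5.0, index=subtypes)
    for other in ("cDC1", "cDC2"):
        if other in base.index:
            base[other] = 6.0
    if "mregDC" in base.index:
        lam_mreg = np.asarray(
            config.module_structure.get("mregDC", (0.0,)), dtype=float
        )
        lam = float(np.max(np.abs(lam_mreg))) if lam_mreg.size else 0.0
        t = 0.185
        c_other = float(sum(base[o] for o in ("cDC1", "cDC2") if o in base.index))
        from scipy.stats import norm as _norm

        zq = _norm.ppf(1.0 - config.p_biomarker_high)
        base["mregDC"] = (t / (1.0 - t)) * c_other / np.exp(lam * zq)
    conc = pd.DataFrame(
        np.tile(base.to_numpy(), (config.n_samples, 1)),
        index=sample_ids,
        columns=subtypes,
    )
    loadings = config.module_structure
    for subtype in subtypes:
        lam = np.asarray(loadings.get(subtype, (0.0,) * factors.shape[1]), dtype=float)
        conc[subtype] = conc[subtype].to_numpy() * np.exp(factors @ lam)
    return conc


def simulate_cohort(config: SimulationConfig) -> tuple[CohortDataset, GroundTruth]:
    """Draw a full cohort.  Identical config (incl. seed) gives identical output."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    sample_meta = _simulate_sample_meta(config, rng)
    sample_ids = sample_meta.index
    n_samples = config.n_samples
    parent_map = config.parent_map()
    subtypes = config.all_subtypes()
    parents = sorted(config.subtype_catalog)

    n_factors = max(config.n_factors(), 1)
    factors = rng.normal(0.0, 1.0, size=(n_samples, n_factors))
    conc = _composition_concentrations(config, sample_ids, factors)

    # parent-type shares: mild Dirichlet noise around fixed bases
    parent_base = {p: 10.0 for p in parents}
    if "Tumor" in parent_base:
        parent_base["Tumor"] = 25.0
    if "cDC" in parent_base:
        parent_base["cDC"] = 10.0

    cell_rows: list[dict] = []
    cells_per_sample: dict[str, int] = {}
    for s_idx, sid in enumerate(sample_ids):
        if isinstance(config.cells_per_sample, tuple):
            lo, hi = config.cells_per_sample
            n_cells_s = int(rng.integers(lo, hi + 1))
        else:
            n_cells_s = int(config.cells_per_sample)
        cells_per_sample[sid] = n_cells_s
        parent_props = rng.dirichlet([parent_base[p] for p in parents])
        parent_counts = rng.multinomial(n_cells_s, parent_props)
        for parent, n_p in zip(parents, parent_counts):
            subs = config.subtype_catalog[parent]
            alpha = conc.loc[sid, subs].to_numpy(dtype=float)
            sub_props = rng.dirichlet(alpha)
            sub_counts = rng.multinomial(n_p, sub_props)
            for sub, n_sub in zip(subs, sub_counts):
                for _ in range(n_sub):
                    cell_rows.append(
                        {"sample_id": sid, "cell_type": parent, "subtype": sub}
                    )

    cell_meta = pd.DataFrame(cell_rows)
    n_cells = len(cell_meta)
    cell_meta.index = pd.Index([f"C{i + 1:06d}" for i in range(n_cells)], name="cell_id")

    # the biomarker group is DEFINED by the realized composition (0.185 rule),
    # so downstream thresholding reproduces the generative labels exactly;
    # state prevalence, response and survival are then driven by this group
    mreg = _realized_proportion(cell_meta, parent_map, "mregDC", "cDC")
    mreg = mreg.reindex(sample_ids)
    group = pd.Series(np.where(mreg > 0.185, 1, 0), index=sample_ids)
    z_all: list[np.ndarray] = []
    for sid in sample_ids:
        pi = config.pi_high if group.loc[sid] == 1 else config.pi_low
        z_all.append((rng.random(cells_per_sample[sid]) < pi).astype(int))
    z = np.concatenate(z_all)
    resp_p = np.where(group.to_numpy() == 1, 0.6, 0.25)
    sample_meta["response"] = np.where(rng.random(n_samples) < resp_p, "R", "NR")

    a_m, b_m = config.mito_beta
    pm = rng.beta(a_m + config.confound_mito_with_state * z, b_m)
    cell_meta["percent_mito"] = 100.0 * pm
    a_r, b_r = config.ribo_beta
    cell_meta["percent_ribo"] = 100.0 * rng.beta(a_r, b_r, n_cells)

    # --- gene-level parameters -------------------------------------------
    G = config.n_genes
    rel = rng.lognormal(0.0, 1.5, G)
    beta0 = np.log(rel / rel.sum())
    state_idx = rng.choice(G, size=config.n_state_genes, replace=False)
    gamma = np.zeros(G)
    signs = rng.choice([-1.0, 1.0], size=config.n_state_genes)
    gamma[state_idx] = signs * config.gamma_scale * rng.uniform(0.8, 1.2, config.n_state_genes)
    if config.gamma_scale == 0:
        gamma[:] = 0.0
    state_mask = gamma != 0

    x_cell = _simulation_covariates(cell_meta, sample_meta, config)
    beta_cov = rng.normal(0.0, config.beta_covariate_sd, size=(x_cell.shape[1], G))
    u = rng.normal(0.0, np.sqrt(config.sigma2), size=(G, n_samples))
    s_codes = sample_ids.get_indexer(cell_meta["sample_id"])
    libsize = rng.lognormal(config.libsize_logmean, config.libsize_logsd, n_cells)

    log_mu = (
        beta0[:, None]
        + (x_cell @ beta_cov).T
        + gamma[:, None] * z[None, :]
        + u[:, s_codes]
        + np.log(libsize)[None, :]
    )
    mu = np.exp(log_mu)
    # gamma-Poisson mixture == NB with Var = mu + mu^2/phi
    lam = rng.gamma(shape=config.phi, scale=mu / config.phi)
    counts = rng.poisson(lam).astype(np.int64)
    cell_meta["total_counts"] = counts.sum(axis=0)

    gene_names = pd.Index([f"G{i + 1:04d}" for i in range(G)], name="gene")

    sample_meta["mregdc_cdc_proportion"] = mreg
    sample_meta["mregdc_high"] = group.to_numpy()
    # TCF7 ratio rides on the same module factor as mregDC, so the two
    # biomarkers co-occur; the binary label is the cohort-median split
    n_pos = cell_meta.groupby("sample_id")["subtype"].apply(
        lambda s: int((s == "CD8 TCF7+").sum())).reindex(sample_ids, fill_value=0)
    n_neg = cell_meta.groupby("sample_id")["subtype"].apply(
        lambda s: int((s == "CD8 TCF7-").sum())).reindex(sample_ids, fill_value=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where((n_pos + n_neg) == 0, np.nan, n_pos / n_neg.replace(0, np.nan))
    med = np.nanmedian(ratio) if np.isfinite(ratio).any() else np.nan
    tcf7 = pd.Series(np.where(np.isnan(ratio), 0, (ratio > med).astype(int)),
                     index=sample_ids)
    sample_meta["tcf7_high"] = tcf7.to_numpy()

    sp = config.survival_params
    sample_meta = simulate_survival(sample_meta, sp, seed=int(rng.integers(2**31 - 1)))

    dataset = CohortDataset(
        counts=counts,
        gene_names=gene_names,
        cell_ids=cell_meta.index,
        cell_meta=cell_meta,
        sample_meta=sample_meta,
        parent_map=parent_map,
    )
    dataset.validate()

    module_labels: dict[str, int] = {}
    for subtype in subtypes:
        lam_vec = np.asarray(config.module_structure.get(subtype, ()), dtype=float)
        if lam_vec.size and np.any(lam_vec != 0):
            module_labels[subtype] = int(np.argmax(np.abs(lam_vec))) + 1
        else:
            module_labels[subtype] = 0

    truth = GroundTruth(
        z=z,
        beta0=beta0,
        beta_cov=beta_cov,
        gamma=gamma,
        state_genes=state_mask,
        sample_group=group,
        tcf7_group=tcf7,
        sample_effects=u,
        module_labels=module_labels,
        sample_factors=factors,
        survival_log_hr=dict(sp.log_hr),
        library_size=libsize,
    )
    return dataset, truth


def _realized_proportion(
    cell_meta: pd.DataFrame, parent_map: Mapping[str, str], subtype: str, parent: str
) -> pd.Series:
    by_sample = cell_meta.groupby("sample_id", sort=True)
    parent_n = by_sample["cell_type"].apply(lambda s: int((s == parent).sum()))
    sub_n = by_sample["subtype"].apply(lambda s: int((s == subtype).sum()))
    out = sub_n / parent_n.replace(0, np.nan)
    return out


def _simulation_covariates(
    cell_meta: pd.DataFrame, sample_meta: pd.DataFrame, config: SimulationConfig
) -> np.ndarray:
    """Numeric covariate encoding used by the generative model (no intercept)."""
    per_cell = sample_meta.loc[cell_meta["sample_id"]]
    cols = [((per_cell["age"].to_numpy() - config.age_mean) / config.age_sd)]
    for col, levels in (
        ("sex", SEXES),
        ("tissue", TISSUES),
        ("treatment_state", TREATMENT_STATES),
        ("treatment_group", TREATMENT_GROUPS),
    ):
        for lev in levels[1:]:  # drop first level alphabetically
            cols.append((per_cell[col].to_numpy() == lev).astype(float))
    cols.append(cell_meta["percent_mito"].to_numpy() / 100.0)
    cols.append(cell_meta["percent_ribo"].to_numpy() / 100.0)
    return np.column_stack(cols)


def simulate_survival(
    sample_meta: pd.DataFrame, survival_params: SurvivalParams, seed: int
) -> pd.DataFrame:
    """Attach pfs/os time and event columns drawn from an exponential PH model."""
    survival_params.validate()
    rng = np.random.default_rng(seed)
    meta = sample_meta.copy()
    for col in survival_params.log_hr:
        if col not in meta.columns:
            raise ValueError(f"biomarker column {col!r} missing from sample_meta")
    lp = np.zeros(len(meta))
    for col, coef in survival_params.log_hr.items():
        lp = lp + coef * meta[col].to_numpy(dtype=float)
    for prefix, scale in (("pfs", 1.0), ("os", 0.6)):
        hazard = survival_params.baseline_hazard * scale * np.exp(lp)
        t_event = rng.exponential(1.0 / hazard)
        c = survival_params.censoring_rate
        if c >= 1.0:
            time, event = t_event, np.zeros(len(meta), dtype=int)
        elif c <= 0.0:
            time, event = t_event, np.ones(len(meta), dtype=int)
        else:
            cens_rate = hazard * c / (1.0 - c)
            t_cens = rng.exponential(1.0 / cens_rate)
            event = (t_event <= t_cens).astype(int)
            time = np.minimum(t_event, t_cens)
        meta[f"{prefix}_time"] = np.round(time, 4)
        meta[f"{prefix}_event"] = event
    return meta
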