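import itertools

import numpy as np
import pandas as pd
import pytest

from tmesf.interactions import (
    differential_interactions,
    exclusive_interactions,
    interaction_means,
    permutation_test,
)
from tmesf.metaprograms import lognormalize


def _catalog(pairs):
    return pd.DataFrame(
        [{"interaction_id": f"{l}_{r}", "ligand": l, "receptor": r} for l, r in pairs]
    )


@pytest.fixture()
def two_subtype_sample():
    """4 genes x 10 cells, two subtypes, hand-controllable expression."""
    genes = pd.Index(["LIG1", "REC1", "LIG2", "REC2"])
    expr = np.zeros((4, 10))
    labels = np.array(["A"] * 5 + ["B"] * 5, dtype=object)
    return genes, expr, labels


def test_interaction_mean_is_half_sum(two_subtype_sample):
    genes, expr, labels = two_subtype_sample
    expr[0, :5] = 2.0  # LIG1 in A
    expr[1, 5:] = 4.0  # REC1 in B
    out, skipped = interaction_means(expr, genes, labels, _catalog([("LIG1", "REC1")]))
    row = out[(out["source"] == "A") & (out["target"] == "B")].iloc[0]
    assert row["mean"] == pytest.approx(3.0)
    assert not skipped


def test_low_expression_fraction_masked(two_subtype_sample):
    genes, expr, labels = two_subtype_sample
    expr[0, 0] = 5.0   # LIG1 in 1/5 = 20% of A cells -> not masked at 10%
    expr[1, 5:] = 1.0
    out, _ = interaction_means(expr, genes, labels, _catalog([("LIG1", "REC1")]),
                               min_fraction=0.3)
    row = out[(out["source"] == "A") & (out["target"] == "B")].iloc[0]
    assert bool(row["masked"])
    out2, _ = interaction_means(expr, genes, labels, _catalog([("LIG1", "REC1")]),
                                min_fraction=0.1)
    row2 = out2[(out2["source"] == "A") & (out2["target"] == "B")].iloc[0]
    assert not bool(row2["masked"])


def test_absent_gene_skipped_and_listed(two_subtype_sample):
    genes, expr, labels = two_subtype_sample
    out, skipped = interaction_means(expr, genes, labels,
                                     _catalog([("LIG1", "REC1"), ("GHOST", "REC1")]))
    assert skipped == ["GHOST_REC1"]
    assert set(out["interaction_id"]) == {"LIG1_REC1"}


def test_absent_subtype_missing_not_zero(two_subtype_sample):
    genes, expr, labels = two_subtype_sample
    out, _ = interaction_means(expr, genes, labels, _catalog([("LIG1", "REC1")]))
    assert "C" not in set(out["source"]) | set(out["target"])


class TestPermutation:
    def test_identical_cells_give_p_one(self, two_subtype_sample):
        genes, expr, labels = two_subtype_sample
        expr[:] = 1.0
        cs = permutation_test(expr, genes, labels, _catalog([("LIG1", "REC1")]),
                              n_perm=200, seed=0)
        assert (cs.calls["p"] == 1.0).all()
        assert (cs.calls["significant_mean"] == 0.0).all()

    def test_determinism_same_seed(self, two_subtype_sample):
        genes, expr, labels = two_subtype_sample
        rng = np.random.default_rng(3)
        expr[:] = rng.lognormal(0, 1, expr.shape)
        a = permutation_test(expr, genes, labels, _catalog([("LIG1", "REC1")]),
                             n_perm=300, seed=5)
        b = permutation_test(expr, genes, labels, _catalog([("LIG1", "REC1")]),
                             n_perm=300, seed=5)
        pd.testing.assert_frame_equal(a.calls, b.calls)

    def test_matches_exhaustive_enumeration_on_six_cells(self):
        """6 cells, labels 3+3: the add-one Monte-Carlo p converges to the
        exhaustive permutation distribution over all 6! label orderings."""
        genes = pd.Index(["L", "R"])
        rng = np.random.default_rng(1)
        expr = rng.lognormal(0, 1, size=(2, 6))
        labels = np.array(["A", "A", "A", "B", "B", "B"], dtype=object)
        cat = _catalog([("L", "R")])

        def pair_mean(lab):
            a = lab == "A"
            b = ~a
            return 0.5 * (expr[0, a].mean() + expr[1, b].mean())

        obs = pair_mean(labels)
        null = [pair_mean(np.array(perm, dtype=object))
                for perm in itertools.permutations(labels)]
        p_exact = np.mean([v >= obs - 1e-12 for v in null])
        cs = permutation_test(expr, genes, labels, cat, n_perm=20000, seed=2)
        row = cs.calls[(cs.calls["source"] == "A") & (cs.calls["target"] == "B")].iloc[0]
        # add-one estimator converges to the exhaustive value
        assert row["p"] == pytest.approx(p_exact, abs=0.02)

    def test_low_n_perm_warns(self, two_subtype_sample):
        genes, expr, labels = two_subtype_sample
        expr[:] = 1.0
        with pytest.warns(UserWarning, match="n_perm"):
            permutation_test(expr, genes, labels, _catalog([("LIG1", "REC1")]),
                             n_perm=50, seed=0)

    def test_pvalues_uniform_under_exchangeability(self):
        """Exchangeable labels: P(p <= x) <= x (discretized uniform)."""
        genes = pd.Index(["L", "R"])
        cat = _catalog([("L", "R")])
        pvals = []
        for rep in range(60):
            rng = np.random.default_rng(rep)
            expr = rng.lognormal(0, 1, size=(2, 20))
            labels = np.array(["A"] * 10 + ["B"] * 10, dtype=object)
            cs = permutation_test(expr, genes, labels, cat, n_perm=199, seed=rep)
            row = cs.calls[(cs.calls["source"] == "A") & (cs.calls["target"] == "B")]
            pvals.append(float(row["p"].iloc[0]))
        pvals = np.array(pvals)
        assert (pvals <= 0.1).mean() < 0.25
        assert (pvals <= 0.5).mean() < 0.75


def _mk_callset(entries, sample, n_perm=1000, seed=0):
    """entries: (source, target, iid, mean, p)."""
    from tmesf.interactions import InteractionCallSet

    df = pd.DataFrame(entries, columns=["source", "target", "interaction_id", "mean", "p"])
    df["masked"] = False
    df["significant_mean"] = np.where(df["p"] < 0.05, df["mean"], 0.0)
    return InteractionCallSet(calls=df, n_permutations=n_perm, seed=seed,
                              skipped_interactions=[])


class TestAggregation:
    def test_exclusive_rule(self):
        sig = ("mregDC", "CD8 T", "I1", 2.0, 0.01)
        notsig = ("mregDC", "CD8 T", "I1", 2.0, 0.5)
        other_sig = ("cDC1", "CD8 T", "I1", 1.0, 0.01)
        other_not = ("cDC1", "CD8 T", "I1", 1.0, 0.9)
        # significant in 3 samples, never for cDC1 -> exclusive
        cs = {f"S{i}": _mk_callset([sig, other_not], f"S{i}") for i in range(3)}
        out = exclusive_interactions(cs, min_samples=3)
        assert len(out[out["role"] == "source"]) == 1
        # only 2 significant samples -> not exclusive
        cs2 = {"S0": _mk_callset([sig, other_not], "S0"),
               "S1": _mk_callset([sig, other_not], "S1"),
               "S2": _mk_callset([notsig, other_not], "S2")}
        assert exclusive_interactions(cs2, min_samples=3).empty
        # one cDC1 significance anywhere kills exclusivity
        cs3 = {f"S{i}": _mk_callset([sig, other_sig if i == 0 else other_not], f"S{i}")
               for i in range(3)}
        assert exclusive_interactions(cs3, min_samples=3).empty

    def test_differential_group_contrast(self):
        lo = [("mregDC", "CD8 T", "I1", 0.0, 0.9)]
        hi = [("mregDC", "CD8 T", "I1", 2.0, 0.01)]
        cs = {}
        groups = {}
        for i in range(4):
            cs[f"L{i}"] = _mk_callset(lo, f"L{i}")
            groups[f"L{i}"] = "low"
        for i in range(4):
            cs[f"H{i}"] = _mk_callset(hi, f"H{i}")
            groups[f"H{i}"] = "high"
        out = differential_interactions(cs, group_assignment=pd.Series(groups))
        row = out.iloc[0]
        # full presence in high, zero in low: presence rule fails for low
        assert not row["called"]
        # give the low group presence in 3/4 samples
        lo_present = [("mregDC", "CD8 T", "I1", 0.3, 0.01)]
        for i in range(3):
            cs[f"L{i}"] = _mk_callset(lo_present, f"L{i}")
        out2 = differential_interactions(cs, group_assignment=pd.Series(groups))
        assert bool(out2.iloc[0]["called"])
        assert "up in high" in out2.iloc[0]["direction"]

    def test_presence_exactly_half_not_called(self):
        hi = [("mregDC", "CD8 T", "I1", 2.0, 0.01)]
        absent = [("mregDC", "CD8 T", "I1", 0.0, 0.9)]
        cs = {}
        groups = {}
        for i in range(4):
            cs[f"H{i}"] = _mk_callset(hi, f"H{i}")
            groups[f"H{i}"] = "high"
        for i in range(4):
            cs[f"L{i}"] = _mk_callset(hi if i < 2 else absent, f"L{i}")
            groups[f"L{i}"] = "low"
        out = differential_interactions(cs, group_assignment=pd.Series(groups))
        assert not bool(out.iloc[0]["called"])  # 2/4 is not more than half

    def test_identical_distributions_not_called(self):
        same = [("mregDC", "CD8 T", "I1", 1.0, 0.01)]
        cs = {}
        groups = {}
        for i in range(6):
            cs[f"S{i}"] = _mk_callset(same, f"S{i}")
            groups[f"S{i}"] = "high" if i < 3 else "low"
        out = differential_interactions(cs, group_assignment=pd.Series(groups))
        assert out.iloc[0]["p"] == pytest.approx(1.0)
        assert not bool(out.iloc[0]["called"])

    def test_aggregation_invariant_to_sample_order(self):
        sig = ("mregDC", "CD8 T", "I1", 2.0, 0.01)
        other = ("cDC1", "CD8 T", "I1", 1.0, 0.9)
        cs = {f"S{i}": _mk_callset([sig, other], f"S{i}") for i in range(4)}
        reordered = dict(reversed(list(cs.items())))
        pd.testing.assert_frame_equal(
            exclusive_interactions(cs), exclusive_interactions(reordered)
        )


def test_planted_exclusive_and_differential_recovered_no_false_calls():
    """3-sample fixture: one mregDC-exclusive pair and one differential
    pair planted; default rules recover both with specificity 1."""
    rng = np.random.default_rng(10)
    genes = pd.Index(["CCL19", "CCR7", "CD274", "PDCD1", "NOISE1", "NOISE2"])
    cat = _catalog([("CCL19", "CCR7"), ("CD274", "PDCD1"), ("NOISE1", "NOISE2")])
    subtypes = ["CD8 T", "cDC1", "cDC2", "mregDC"]
    callsets = {}
    for s in range(3):
        cells = []
        labels = []
        for st in subtypes:
            n = 30
            # sparse background: most genes drop out in most cells
            block = rng.lognormal(0.0, 0.3, size=(6, n)) * (rng.random((6, n)) < 0.01)
            if st == "mregDC":
                block[0] += 5.0   # CCL19 ligand only in mregDC
            if st == "CD8 T":
                block[1] += 5.0   # CCR7 receptor on CD8 T
            cells.append(block)
            labels += [st] * n
        expr = lognormalize(np.concatenate(cells, axis=1))
        callsets[f"S{s}"] = permutation_test(expr, genes, np.array(labels, dtype=object),
                                             cat, n_perm=300, seed=100 + s)
    out = exclusive_interactions(callsets, focal="mregDC", others=("cDC1", "cDC2"),
                                 min_samples=3)
    src = out[out["role"] == "source"]
    assert {"CCL19_CCR7"} == set(src["interaction_id"])
    assert set(src["partner"]) == {"CD8 T"}
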