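"""Negative-binomial differential testing and the selection logic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from terminseq import (
    ContrastSpec,
    CountMatrix,
    bh_fdr,
    cross_reference_wt_response,
    estimate_dispersions,
    nb_wald_test,
    select_3prime_specific,
)


def brute_force_bh(p):
    """Independent BH oracle: adj_k = min over i >= rank(k) of p_(i) * n / i."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = np.inf
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = min(running, 1.0)
    return adj


def make_cm(counts, genotypes, condition="cold_12h_4C"):
    counts = np.asarray(counts)
    n = counts.shape[1]
    reps = {}
    rows = []
    for j, g in enumerate(genotypes):
        reps[g] = reps.get(g, 0) + 1
        rows.append({"sample_id": f"s{j}", "genotype": g, "condition": condition,
                     "replicate": reps[g]})
    samples = pd.DataFrame(rows)
    return CountMatrix([f"r{i}" for i in range(counts.shape[0])], samples, counts,
                       counts.sum(0))


class TestBhFdr:
    def test_single_p(self):
        assert bh_fdr([0.04]) == pytest.approx([0.04])

    def test_equally_spaced_ps_all_collapse(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_all_ones(self):
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(200):
            p = rng.random(int(rng.integers(1, 40)))
            assert np.allclose(bh_fdr(p), brute_force_bh(p))


class TestEstimateDispersions:
    def test_poisson_null_mean_small(self, rng):
        mu = rng.uniform(50, 500, 50)
        counts = rng.poisson(mu[:, None], (50, 6))
        cm = make_cm(counts, ["WT"] * 3 + ["hen2"] * 3)
        alpha = estimate_dispersions(cm)
        assert alpha.mean() <= 0.05

    def test_constant_counts_shrunk_toward_trend(self):
        counts = np.full((10, 4), 100)
        cm = make_cm(counts, ["WT"] * 2 + ["hen2"] * 2)
        alpha = estimate_dispersions(cm)
        assert (alpha >= 0).all()
        # raw moment estimate is 0 (s2 = 0); result is the shrunk trend share
        assert (alpha < 0.1).all()

    def test_recovers_true_dispersion(self, rng):
        true_alpha, mu, n = 0.2, 500.0, 40
        lam = rng.gamma(1 / true_alpha, mu * true_alpha, (300, n))
        counts = rng.poisson(lam)
        cm = make_cm(counts, ["WT"] * 20 + ["hen2"] * 20)
        alpha = estimate_dispersions(cm)
        assert 0.1 <= np.median(alpha) <= 0.3


class TestNbWaldTest:
    def test_all_zero_region(self):
        counts = np.array([[0, 0, 0, 0, 0, 0], [100, 110, 90, 100, 95, 105]])
        cm = make_cm(counts, ["hen2"] * 3 + ["WT"] * 3)
        res = nb_wald_test(cm, ContrastSpec("hen2", "WT", "cold_12h_4C"))
        row = res.set_index("region_id").loc["r0"]
        assert row["pvalue"] == 1.0 and row["log2FC"] == 0.0 and row["call"] == "NS"

    def test_swap_negates_lfc_preserves_p(self, rng):
        counts = rng.poisson(rng.uniform(10, 500, 100)[:, None] * rng.uniform(0.5, 2, (100, 6)))
        cm = make_cm(counts, ["hen2"] * 3 + ["WT"] * 3)
        fwd = nb_wald_test(cm, ContrastSpec("hen2", "WT", "cold_12h_4C"))
        rev = nb_wald_test(cm, ContrastSpec("WT", "hen2", "cold_12h_4C"))
        assert np.allclose(fwd["log2FC"], -rev["log2FC"])
        assert np.allclose(fwd["pvalue"], rev["pvalue"])

    def test_power_fourfold_depletion(self, rng):
        """4-fold depleted regions (mu 200 -> 50, NB alpha 0.1, 3v3) are
        called DOWN in at least 90% of 500 simulated regions."""
        n_sim = 500
        lam_ref = rng.gamma(10.0, 20.0, (n_sim, 3))   # NB mean 200, alpha 0.1
        lam_test = rng.gamma(10.0, 5.0, (n_sim, 3))   # NB mean 50
        counts = np.hstack([rng.poisson(lam_test), rng.poisson(lam_ref)])
        cm = make_cm(counts, ["hen2"] * 3 + ["WT"] * 3)
        res = nb_wald_test(cm, ContrastSpec("hen2", "WT", "cold_12h_4C"),
                           dispersions=np.full(n_sim, 0.1),
                           factors=np.ones(6))
        assert (res["call"] == "DOWN").mean() >= 0.9

    def test_missing_group_raises(self):
        counts = np.array([[1, 2]])
        cm = make_cm(counts, ["WT", "WT"])
        with pytest.raises(ValueError, match="both groups"):
            nb_wald_test(cm, ContrastSpec("hen2", "WT", "cold_12h_4C"))

    def test_contrast_spec_validation(self):
        with pytest.raises(ValueError):
            ContrastSpec("hen2", "WT", "c", alpha=1.5)
        with pytest.raises(ValueError):
            ContrastSpec("hen2", "WT", "c", lfc_min=-1)


def de_table(calls):
    return pd.DataFrame({
        "region_id": [f"{g}:three_prime" for g in calls],
        "baseMean": 100.0, "log2FC": 0.0, "dispersion": 0.1,
        "pvalue": 0.5, "fdr": 0.5, "call": list(calls.values()),
    })


class TestSelection:
    def test_toy_table(self):
        cold = de_table({"gA": "DOWN", "gB": "DOWN", "gC": "NS"})
        ctrl = de_table({"gA": "NS", "gB": "DOWN", "gC": "NS"})
        assert select_3prime_specific(cold, ctrl) == {"gA"}

    def test_empty_tables(self):
        empty = de_table({})
        assert select_3prime_specific(empty, empty) == set()

    def test_region_mismatch_raises(self):
        cold = de_table({"gA": "DOWN"})
        ctrl = de_table({"gB": "NS"})
        with pytest.raises(ValueError, match="differ"):
            select_3prime_specific(cold, ctrl)

    def test_definition_by_brute_force_on_random_tables(self, rng):
        """Selection equals the literal definition (cold DOWN and control NS)
        re-evaluated per gene, for random call tables."""
        calls = np.array(["UP", "DOWN", "NS"])
        for _ in range(50):
            genes = [f"g{i}" for i in range(20)]
            cold = de_table({g: rng.choice(calls) for g in genes})
            ctrl = de_table({g: rng.choice(calls) for g in genes})
            expected = {
                g for g in genes
                if cold.set_index("region_id").loc[f"{g}:three_prime", "call"] == "DOWN"
                and ctrl.set_index("region_id").loc[f"{g}:three_prime", "call"] == "NS"
            }
            assert select_3prime_specific(cold, ctrl) == expected


class TestCrossReference:
    def test_toy_partition(self):
        wt = pd.DataFrame({"region_id": ["gA", "gB", "gC"],
                           "call": ["UP", "NS", "DOWN"]})
        table, counts = cross_reference_wt_response({"gA", "gB", "gC"}, wt)
        assert counts == {"UP": 1, "DOWN": 1, "NS": 1}

    def test_empty_selection(self):
        wt = pd.DataFrame({"region_id": ["gA"], "call": ["UP"]})
        _, counts = cross_reference_wt_response(set(), wt)
        assert counts == {"UP": 0, "DOWN": 0, "NS": 0}

    def test_missing_gene_labelled_ns_with_warning(self):
        wt = pd.DataFrame({"region_id": ["gA"], "call": ["UP"]})
        with pytest.warns(UserWarning, match="missing"):
            table, counts = cross_reference_wt_response({"gA", "gZ"}, wt)
        assert counts == {"UP": 1, "DOWN": 0, "NS": 1}


@given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_bh_fdr_properties(p):
    adj = bh_fdr(p)
    assert ((0 <= adj) & (adj <= 1)).all()
    # order preservation: sorting by p sorts adj the same way
    order = np.argsort(p, kind="stable")
    assert (np.diff(adj[order]) >= -1e-12).all()
    assert np.allclose(adj, brute_force_bh(p))
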