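"""The premature-termination simulator and its closed-form companion."""

import filecmp

import numpy as np
import pandas as pd
import pytest

from terminseq import (
    ConditionParams,
    GeneModel,
    TerminationModel,
    coverage_track,
    expected_half_counts,
    make_benchmark,
    sample_library,
)
from terminseq.simulate_termination import CONTROL, _solve_hazard_fold
from terminseq.validation import simulator_oracle_zscores


def one_sample_sheet(n=1):
    return pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)], "genotype": "WT",
        "condition": CONTROL, "replicate": range(1, n + 1),
    })


class TestExpectedHalfCounts:
    def test_no_hazard_no_degradation_flat_coverage(self):
        p = ConditionParams(initiation_rate=100, hazard=0.0, degrade_pt=0.0, degrade_fl=0.0)
        exp = expected_half_counts(p, 2000, 1000)
        assert np.allclose(exp.coverage, 100.0)
        assert exp.cov5 == pytest.approx(exp.cov3)
        assert exp.e5_anchor == pytest.approx(100.0)
        assert exp.e3_anchor == 0.0

    def test_full_degradation_zero_coverage(self):
        p = ConditionParams(initiation_rate=100, hazard=0.0, degrade_fl=1.0)
        exp = expected_half_counts(p, 2000, 1000)
        assert np.allclose(exp.coverage, 0.0)

    def test_coverage_decays_with_hazard(self):
        p = ConditionParams(initiation_rate=100, hazard=1e-3, degrade_pt=0.0, degrade_fl=0.0)
        exp = expected_half_counts(p, 2000, 1000)
        assert (np.diff(exp.coverage) < 0).all()
        assert exp.coverage[0] / exp.coverage[-1] == pytest.approx(
            1.0 / (1 - 1e-3) ** 1999, rel=1e-9)

    def test_invalid_boundary_rejected(self):
        p = ConditionParams()
        for m in (0, 2000, -1):
            with pytest.raises(ValueError):
                expected_half_counts(p, 2000, m)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ConditionParams(hazard=1.0)
        with pytest.raises(ValueError):
            ConditionParams(degrade_pt=1.5)


class TestSampleLibrary:
    def test_zero_initiation_gives_no_fragments(self):
        model = TerminationModel({("WT", CONTROL): ConditionParams(initiation_rate=0.0)})
        genes = [GeneModel("g", "chr1", 0, 1000, "+")]
        frags, _ = sample_library(model, genes, one_sample_sheet(), seed=1)
        assert len(frags) == 0

    def test_poisson_event_counts_without_hazard(self):
        """phi=0, h=0, no degradation: per-gene fragment counts are
        Poisson(lambda); empirical mean within 3 SE over 1000 genes."""
        lam = 30.0
        p = ConditionParams(initiation_rate=lam, hazard=0.0, degrade_pt=0.0,
                            degrade_fl=0.0, dispersion=0.0)
        model = TerminationModel({("WT", CONTROL): p})
        genes = [GeneModel(f"g{i}", "chr1", i * 2000, i * 2000 + 1000, "+")
                 for i in range(1000)]
        frags, _ = sample_library(model, genes, one_sample_sheet(), shear_length=None, seed=3)
        counts = frags.groupby(frags["start"] // 2000).size().reindex(range(1000), fill_value=0)
        se = np.sqrt(lam / 1000)
        assert abs(counts.mean() - lam) <= 3 * se
        # variance should be Poisson-like, not overdispersed
        assert counts.var() == pytest.approx(lam, rel=0.2)

    def test_seed_determinism(self):
        model = TerminationModel.preset()
        genes = [GeneModel("g", "chr1", 0, 2000, "+")]
        a, _ = sample_library(model, genes, one_sample_sheet(3), seed=9)
        b, _ = sample_library(model, genes, one_sample_sheet(3), seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_minus_strand_fragments_anchor_at_gene_end(self):
        p = ConditionParams(initiation_rate=200, hazard=5e-3, degrade_pt=0.0, degrade_fl=0.0)
        model = TerminationModel({("WT", CONTROL): p})
        gene = GeneModel("g", "chr1", 1000, 3000, "-")
        frags, _ = sample_library(model, [gene], one_sample_sheet(), shear_length=None, seed=4)
        # every unsheared RNA starts at the biological TSS = gene end on -
        assert (frags["end"] == 3000).all()
        assert (frags["strand"] == "-").all()
        assert (frags["start"] >= 1000).all()

    def test_sampler_matches_closed_form(self):
        z = simulator_oracle_zscores(seed=777, n_genes=5, n_positions=8, n_replicates=80)
        assert (np.abs(z) > 3).sum() <= 1
        assert np.abs(z).max() <= 4.0


class TestPresets:
    def test_preset_cells_cover_design(self):
        model = TerminationModel.preset()
        for geno in ("WT", "hen2", "exosome_core", "zcchc8ab"):
            for cond in (CONTROL, "cold_12h_4C"):
                assert isinstance(model.get(geno, cond), ConditionParams)

    def test_hen2_cold_hazard_elevated(self):
        model = TerminationModel.preset()
        assert model.get("hen2", "cold_12h_4C").hazard > model.get("hen2", CONTROL).hazard
        assert model.get("hen2", CONTROL).degrade_pt < model.get("WT", CONTROL).degrade_pt
        # exosome core: degradation lost, hazard unchanged
        exo = model.get("exosome_core", "cold_12h_4C")
        assert exo.hazard == model.get("WT", "cold_12h_4C").hazard
        assert exo.degrade_pt < 0.5

    def test_yaml_round_trip(self, tmp_path):
        model = TerminationModel.preset(seed=5)
        p = tmp_path / "model.yaml"
        model.to_yaml(p)
        back = TerminationModel.from_yaml(p)
        assert back.params == model.params and back.seed == 5


class TestSolveHazardFold:
    def test_expected_depletion_hits_target(self):
        wt = ConditionParams()
        fold = _solve_hazard_fold(wt, wt, 2000, 4.0)
        assert fold > 1.0
        mut = ConditionParams(hazard=wt.hazard * fold)
        m = (2000 + 1) // 2
        ratio = (expected_half_counts(mut, 2000, m).cov3
                 / expected_half_counts(wt, 2000, m).cov3)
        assert ratio == pytest.approx(0.25, rel=1e-3)


class TestMakeBenchmark:
    def test_empty_benchmark_valid_files(self, tmp_path):
        bench = make_benchmark(n_genes=0, n_true_positive=0, seed=1, outdir=tmp_path)
        assert len(bench.genes) == 0 and len(bench.fragments) == 0
        assert (tmp_path / "genes.gff3").read_text().startswith("##gff-version 3")
        assert (tmp_path / "fragments.bed").read_text() == ""

    def test_fixed_seed_byte_identical_outputs(self, tmp_path):
        d1, d2 = tmp_path / "run1", tmp_path / "run2"
        make_benchmark(n_genes=20, n_true_positive=4, seed=13, outdir=d1)
        make_benchmark(n_genes=20, n_true_positive=4, seed=13, outdir=d2)
        for name in ("genes.gff3", "fragments.bed", "samples.tsv", "truth.tsv", "model.yaml"):
            assert filecmp.cmp(d1 / name, d2 / name, shallow=False), name

    def test_truth_structure(self, small_benchmark):
        truth = small_benchmark.truth
        assert truth["is_positive"].sum() == 10
        # positives are cold-induced and carry an elevated cold hazard in hen2
        pos = truth[truth["is_positive"]]
        assert pos["cold_induced"].all()
        assert (pos["hazard_fold_hen2_cold"] > 1).all()
        neg = truth[~truth["is_positive"]]
        assert (neg["hazard_fold_hen2_cold"] == 1).all()

    def test_too_many_positives_rejected(self):
        with pytest.raises(ValueError):
            make_benchmark(n_genes=5, n_true_positive=6, seed=1)


def test_hazard_recovery_from_coverage_decay():
    """With degradation known and full-length output suppressed, the hazard is
    recoverable from the exponential coverage decay within 20%."""
    h_true = 2e-3
    p = ConditionParams(initiation_rate=150, hazard=h_true, degrade_pt=0.0,
                        degrade_fl=1.0, dispersion=0.0)
    model = TerminationModel({("WT", CONTROL): p})
    gene = GeneModel("g", "chr1", 0, 2000, "+")
    sheet = one_sample_sheet(50)
    frags, _ = sample_library(model, [gene], sheet, shear_length=None, seed=21)
    cov = np.stack([coverage_track(frags, gene, sample_id=s) for s in sheet["sample_id"]]).mean(0)
    use = cov > 0
    x = np.arange(2000)[use][:1500]
    slope = np.polyfit(x, np.log(cov[use][:1500]), 1)[0]
    h_hat = 1.0 - np.exp(slope)
    assert abs(h_hat - h_true) / h_true <= 0.2
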