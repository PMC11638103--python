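"""Self-validation routines: calibration, recovery and phenotype checks.

These functions run the pipeline end to end on simulated data with known
truth and summarize how well it performs: detection sensitivity and FDR on
the default benchmark, empirical type-I error of the NB Wald test under the
null, Monte-Carlo agreement of the sampler with its closed-form
expectations, the qualitative genotype-preset contrasts, and the null
calibration of the EC50 F-test. They back both the test suite and the
reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .assays import LeakageCurve, compare_ec50_ftest, _logistic
from .gene_models import GeneModel, bisect_all
from .metaprofile import group_metaprofiles
from .positional_de import (
    ContrastSpec,
    cross_reference_wt_response,
    nb_wald_test,
    nb_wald_test_groups,
    select_3prime_specific,
)
from .quantify import CountMatrix, count_fragments, coverage_track
from .simulate_termination import (
    COLD,
    CONTROL,
    BenchmarkData,
    ConditionParams,
    TerminationModel,
    expected_half_counts,
    make_benchmark,
    sample_library,
)

__all__ = [
    "run_benchmark_pipeline",
    "wt_cold_response_partition",
    "null_type_i_error",
    "simulator_oracle_zscores",
    "preset_contrasts",
    "metaprofile_ratio_trend",
    "ftest_null_rejection_rate",
]


def run_benchmark_pipeline(bench: BenchmarkData, alpha: float = 0.05) -> dict:
    """Run bisection -> counting -> DE -> selection on a benchmark dataset
    and score the selected genes against the simulator truth."""
    halves = bisect_all(bench.genes)
    cm = count_fragments(bench.fragments, halves, bench.samples, stranded="yes")
    de_cold = nb_wald_test(cm, ContrastSpec("hen2", "WT", COLD, alpha=alpha))
    de_ctrl = nb_wald_test(cm, ContrastSpec("hen2", "WT", CONTROL, alpha=alpha))
    is_3p = de_cold["region_id"].str.endswith(":three_prime")
    selected = select_3prime_specific(de_cold[is_3p], de_ctrl[is_3p])

    truth = bench.truth.set_index("gene_id")
    positives = set(truth.index[truth["is_positive"].astype(bool)])
    tp = len(selected & positives)
    fp = len(selected - positives)
    sensitivity = tp / len(positives) if positives else float("nan")
    fdr = fp / len(selected) if selected else 0.0
    return {
        "count_matrix": cm,
        "de_cold": de_cold,
        "de_control": de_ctrl,
        "selected": selected,
        "n_selected": len(selected),
        "sensitivity": sensitivity,
        "fdr": fdr,
    }


def wt_cold_response_partition(bench: BenchmarkData, selected: set[str],
                               alpha: float = 0.05) -> dict[str, int]:
    """Label selected genes by the WT whole-gene cold response (UP/DOWN/NS).

    Runs the cold-vs-control contrast on whole-gene counts of the wild-type
    samples and partitions the selected gene set by its calls.
    """
    cm_genes = count_fragments(bench.fragments, bench.genes, bench.samples, stranded="yes")
    wt = cm_genes.subset_samples((cm_genes.samples["genotype"] == "WT").to_numpy())
    is_cold = (wt.samples["condition"] == COLD).to_numpy()
    de_wt = nb_wald_test_groups(wt, is_cold, alpha=alpha, label="WT cold vs control")
    _, counts = cross_reference_wt_response(selected, de_wt)
    return counts


def null_type_i_error(
    seed: int,
    n_regions: int = 2000,
    n_per_group: int = 15,
    dispersion: float = 0.1,
    nominal: float = 0.05,
) -> float:
    """Empirical type-I error of the NB Wald test on a null NB count matrix.

    Both groups share the same NB distribution per region (means uniform on
    [100, 400]); dispersions are estimated and shrunk exactly as in a real
    run. Returns the fraction of raw p-values below ``nominal``.
    """
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    mu = rng.uniform(100, 400, n_regions)
    lam = rng.gamma(1.0 / dispersion, mu[:, None] * dispersion, (n_regions, n))
    counts = rng.poisson(lam)
    samples = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "genotype": ["hen2"] * n_per_group + ["WT"] * n_per_group,
        "condition": COLD,
        "replicate": list(range(1, n_per_group + 1)) * 2,
    })
    cm = CountMatrix([f"r{i}" for i in range(n_regions)], samples, counts, counts.sum(0))
    res = nb_wald_test(cm, ContrastSpec("hen2", "WT", COLD))
    return float((res["pvalue"] < nominal).mean())


def simulator_oracle_zscores(
    seed: int,
    n_genes: int = 20,
    n_positions: int = 10,
    n_replicates: int = 100,
    params: ConditionParams | None = None,
) -> np.ndarray:
    """Z-scores of Monte-Carlo mean coverage against the closed form.

    Each gene (random length, hazard-model parameters ``params``) is
    simulated unsheared across ``n_replicates`` libraries; at
    ``n_positions`` evenly spaced bases the empirical mean coverage is
    compared with :func:`expected_half_counts` using the empirical standard
    error of the mean. Returns the flat array of z-scores
    (``n_genes * n_positions``).
    """
    if params is None:
        params = ConditionParams(initiation_rate=100.0, hazard=1e-3,
                                 degrade_pt=0.3, degrade_fl=0.1, dispersion=0.05)
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    model = TerminationModel({("WT", CONTROL): params}, seed=seed)
    samples = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n_replicates)],
        "genotype": "WT", "condition": CONTROL,
        "replicate": range(1, n_replicates + 1),
    })
    zs = []
    for gi in range(n_genes):
        L = int(rng.integers(800, 4000))
        gene = GeneModel(f"g{gi}", "chr1", 0, L, "+")
        lib_seed = int(ss.generate_state(1)[0] % 2**31) + gi
        frags, _ = sample_library(model, [gene], samples, shear_length=None, seed=lib_seed)
        cov = np.stack([coverage_track(frags, gene, sample_id=s) for s in samples["sample_id"]])
        exp = expected_half_counts(params, L, L // 2)
        pos = np.linspace(0, L - 1, n_positions).astype(int)
        emp = cov[:, pos].mean(axis=0)
        se = cov[:, pos].std(axis=0, ddof=1) / np.sqrt(n_replicates)
        zs.append((emp - exp.coverage[pos]) / np.where(se > 0, se, np.inf))
    return np.concatenate(zs)


def _random_genes(rng: np.random.Generator, n: int, genes_per_chrom: int = 30) -> list[GeneModel]:
    genes = []
    pos = 1000
    for i in range(n):
        L = int(np.clip(np.rint(rng.lognormal(np.log(2000.0), 0.4)), 500, 8000))
        if i and i % genes_per_chrom == 0:
            pos = 1000
        genes.append(GeneModel(f"g{i:03d}", f"chr{i // genes_per_chrom + 1}", pos, pos + L,
                               rng.choice(["+", "-"])))
        pos += L + 10000
    return genes


def preset_contrasts(seed: int, n_genes: int = 200, n_replicates: int = 3) -> dict:
    """Half-count contrasts of the genotype presets on cold-induced genes.

    Simulates WT, hen2 and exosome_core libraries in cold over ``n_genes``
    cold-induced genes, counts gene halves, and returns per genotype and
    half the mean mutant/WT count ratio and one-sided Wilcoxon p-values for
    elevation / depletion, plus the shared data for further profiling.
    """
    model = TerminationModel.preset(seed=seed)
    rng = np.random.default_rng(seed)
    genes = _random_genes(rng, n_genes)
    eff = pd.DataFrame({"gene_id": [g.gene_id for g in genes], "cold_induced": True})
    samples = pd.DataFrame([
        {"sample_id": f"{g}_r{r}", "genotype": g, "condition": COLD, "replicate": r}
        for g in ("WT", "hen2", "exosome_core") for r in range(1, n_replicates + 1)
    ])
    frags, _ = sample_library(model, genes, samples, gene_effects=eff, seed=seed)
    cm = count_fragments(frags, bisect_all(genes), samples, stranded="yes")
    frame = cm.to_frame()
    geno = cm.samples.set_index("sample_id")["genotype"]
    means = {g: frame.loc[:, geno[geno == g].index].mean(axis=1)
             for g in ("WT", "hen2", "exosome_core")}
    out = {"genes": genes, "fragments": frags, "count_matrix": cm}
    for g in ("hen2", "exosome_core"):
        for half in ("five_prime", "three_prime"):
            idx = [r for r in frame.index if r.endswith(half)]
            wt, mut = means["WT"][idx], means[g][idx]
            out[(g, half)] = {
                "mean_ratio": float((mut / wt).mean()),
                "p_up": float(stats.wilcoxon(mut, wt, alternative="greater")[1]),
                "p_down": float(stats.wilcoxon(mut, wt, alternative="less")[1]),
            }
    return out


def metaprofile_ratio_trend(
    contrast_data: dict,
    n_profile_genes: int = 60,
    first_bin: int = 10,
) -> tuple[float, float, np.ndarray]:
    """Spearman trend of the hen2/WT metaprofile ratio along the gene body.

    Returns (rho, p, ratio) for bins ``first_bin``..99 of the cold
    metaprofiles computed on the preset-contrast data.
    """
    genes = contrast_data["genes"][:n_profile_genes]
    cm = contrast_data["count_matrix"]
    keep = cm.samples["genotype"].isin(["WT", "hen2"]).to_numpy()
    profiles = group_metaprofiles(contrast_data["fragments"], genes, cm.subset_samples(keep))
    ratio = profiles[("hen2", COLD)].values / profiles[("WT", COLD)].values
    bins = np.arange(first_bin, len(ratio))
    rho, p = stats.spearmanr(bins, ratio[bins])
    return float(rho), float(p), ratio


def ftest_null_rejection_rate(
    seed: int,
    n_sims: int = 1000,
    noise_sd: float = 0.02,
    nominal: float = 0.05,
) -> float:
    """Rejection rate of the EC50 F-test when both curves share parameters.

    Both curves are drawn from the same four-parameter logistic (the
    leakage transition around -6 C) with Gaussian noise at 9 temperatures;
    under this null the extra sum-of-squares F-test should reject at about
    the nominal rate.
    """
    rng = np.random.default_rng(seed)
    temps = np.linspace(-12.0, 0.0, 9)
    true = dict(bottom=0.05, top=0.95, log_ec50=-6.0, slope=0.8)
    clean = _logistic(temps, **true)
    n_reject = 0
    for _ in range(n_sims):
        ya = np.clip(clean + rng.normal(0, noise_sd, temps.size), 0, 1)
        yb = np.clip(clean + rng.normal(0, noise_sd, temps.size), 0, 1)
        ca = LeakageCurve("A", "non", temps, ya)
        cb = LeakageCurve("B", "non", temps, yb)
        _, p = compare_ec50_ftest(ca, cb)
        n_reject += p < nominal
    return n_reject / n_sims
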