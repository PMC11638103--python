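"""Generative simulator of premature RNAPII termination and exosome degradation.

The working model: transcription initiates on a gene at rate ``lambda``
(events per gene per library); at every transcribed base RNAPII terminates
prematurely with probability ``h`` (a geometric hazard), otherwise it runs
to the annotated 3' end. A prematurely terminated RNA is degraded by the
nuclear exosome with probability ``delta_pt`` before it can be sampled; a
full-length mRNA is lost with probability ``delta_fl``. Genotype presets
move these knobs: the wild type degrades premature fragments efficiently
(high ``delta_pt``); exosome-pathway mutants let 5'-end fragments survive
(low ``delta_pt``); the HEN2 helicase mutant additionally suffers an
elevated termination hazard in cold, depleting full-length (3'-end)
signal. Replicate noise is gamma-Poisson (negative binomial) with shared
dispersion ``phi``.

All magnitudes are module defaults chosen to reproduce the qualitative
genotype x condition contrasts; they are not measured rates.

Surviving RNAs are optionally sheared into fixed-length subfragments
(default 100 bases, uniform placement) so the emitted fragments resemble an
RNA-seq library; unsheared mode emits one fragment per RNA, which is what
the closed-form expectations describe. Everything is driven by one seed
with deterministic per-sample substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .gene_models import GeneModel, write_bed
from .quantify import FRAGMENT_COLUMNS, write_fragments_bed

__all__ = [
    "ConditionParams",
    "TerminationModel",
    "ExpectedCounts",
    "expected_half_counts",
    "sample_library",
    "make_benchmark",
    "BenchmarkData",
]

#: baseline per-base premature-termination hazard (all genotypes, 22 C)
BASE_HAZARD = 5e-4
#: hazard elevation factor for the hen2 preset in cold; at 2x the surviving
#: premature fragments outweigh the full-length loss over the 5' half while
#: the 3' half is depleted (both signs flip if the elevation is much larger,
#: because full-length loss then dominates everywhere)
HEN2_COLD_HAZARD_FOLD = 2.0
#: default expected initiation events per gene per library
BASE_INITIATION = 50.0
#: default gamma-Poisson replicate dispersion
BASE_DISPERSION = 0.05
#: default cold-induction factor for cold-responsive genes
BASE_COLD_INDUCTION = 4.0

COLD = "cold_12h_4C"
CONTROL = "control_22C"


@dataclass(frozen=True)
class ConditionParams:
    """Generative parameters for one (genotype, condition) cell."""

    initiation_rate: float = BASE_INITIATION
    hazard: float = BASE_HAZARD
    degrade_pt: float = 0.9
    degrade_fl: float = 0.05
    cold_induction: float = BASE_COLD_INDUCTION
    dispersion: float = BASE_DISPERSION

    def __post_init__(self) -> None:
        if self.initiation_rate < 0:
            raise ValueError("initiation_rate must be >= 0")
        if not 0 <= self.hazard < 1:
            raise ValueError("hazard must lie in [0, 1)")
        for name in ("degrade_pt", "degrade_fl"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.cold_induction < 0 or self.dispersion < 0:
            raise ValueError("cold_induction and dispersion must be >= 0")


@dataclass
class TerminationModel:
    """Per-(genotype, condition) generative parameters plus the master seed."""

    params: dict[tuple[str, str], ConditionParams]
    seed: int = 0

    def get(self, genotype: str, condition: str) -> ConditionParams:
        try:
            return self.params[(genotype, condition)]
        except KeyError:
            raise KeyError(f"no parameters for genotype={genotype!r}, condition={condition!r}")

    def with_params(self, genotype: str, condition: str, **kwargs) -> "TerminationModel":
        new = dict(self.params)
        new[(genotype, condition)] = replace(new[(genotype, condition)], **kwargs)
        return TerminationModel(new, self.seed)

    @classmethod
    def preset(cls, seed: int = 0) -> "TerminationModel":
        """Default genotype presets.

        WT: efficient premature-fragment degradation. hen2: degradation
        lost at both temperatures plus an elevated termination hazard in
        cold. exosome_core: degradation lost, hazard unchanged. zcchc8ab:
        full-length level modifier only.
        """
        wt = ConditionParams()
        hen2 = replace(wt, degrade_pt=0.2)
        hen2_cold = replace(hen2, hazard=BASE_HAZARD * HEN2_COLD_HAZARD_FOLD)
        exo = replace(wt, degrade_pt=0.2)
        zc = replace(wt, degrade_fl=0.15)
        params = {
            ("WT", CONTROL): wt, ("WT", COLD): wt,
            ("hen2", CONTROL): hen2, ("hen2", COLD): hen2_cold,
            ("exosome_core", CONTROL): exo, ("exosome_core", COLD): exo,
            ("zcchc8ab", CONTROL): zc, ("zcchc8ab", COLD): zc,
        }
        return cls(params, seed)

    def to_yaml(self, path) -> None:
        data = {"seed": self.seed, "params": {
            f"{g}/{c}": asdict(p) for (g, c), p in sorted(self.params.items())
        }}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "TerminationModel":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        params = {}
        for key, fields_ in data["params"].items():
            g, _, c = key.partition("/")
            params[(g, c)] = ConditionParams(**fields_)
        return cls(params, int(data.get("seed", 0)))


@dataclass
class ExpectedCounts:
    """Closed-form expectations of the hazard model for one gene.

    ``e5_anchor``/``e3_anchor`` count surviving RNAs by their 5'-most base
    (every unsheared RNA starts at the TSS, so the 3' half expectation is
    exactly zero). ``coverage`` is the expected per-base RNA coverage in
    5'->3' gene coordinates; ``cov5``/``cov3`` are its sums over the two
    halves, i.e. half-level expectations under coverage-proportional
    counting.
    """

    e5_anchor: float
    e3_anchor: float
    coverage: np.ndarray
    cov5: float
    cov3: float


def expected_half_counts(params: ConditionParams, gene_length: int, boundary: int,
                         cold_induced_in_cold: bool = False) -> ExpectedCounts:
    """Expected fragment counts and per-base coverage for one gene.

    A premature event terminating at base ``x`` (1-indexed, probability
    ``h (1-h)**(x-1)``) survives degradation with probability
    ``1 - delta_pt`` and covers bases ``[0, x)``; a full-length event
    (probability ``(1-h)**L``) survives with ``1 - delta_fl`` and covers
    ``[0, L)``. Hence ``cov(x) = lam * ((1-delta_pt) * ((1-h)**x - (1-h)**L)
    + (1-delta_fl) * (1-h)**L)``.
    """
    L, m = int(gene_length), int(boundary)
    if not 0 < m < L:
        raise ValueError(f"boundary must satisfy 0 < m < L, got m={m}, L={L}")
    lam = params.initiation_rate * (params.cold_induction if cold_induced_in_cold else 1.0)
    h = params.hazard
    x = np.arange(L, dtype=float)
    q = (1.0 - h) ** L  # P(full length)
    surv_pt = 1.0 - params.degrade_pt
    surv_fl = 1.0 - params.degrade_fl
    coverage = lam * (surv_pt * ((1.0 - h) ** x - q) + surv_fl * q)
    e5 = lam * (surv_pt * (1.0 - q) + surv_fl * q)
    return ExpectedCounts(
        e5_anchor=float(e5),
        e3_anchor=0.0,
        coverage=coverage,
        cov5=float(coverage[:m].sum()),
        cov3=float(coverage[m:].sum()),
    )


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """Gamma-Poisson draws with var = mean + phi * mean**2 (phi=0 -> Poisson)."""
    mean = np.asarray(mean, dtype=float)
    if phi <= 0:
        return rng.poisson(mean)
    shape = 1.0 / phi
    lam = rng.gamma(shape, mean * phi)
    return rng.poisson(lam)


def _default_gene_effects(genes: list[GeneModel]) -> pd.DataFrame:
    return pd.DataFrame({
        "gene_id": [g.gene_id for g in genes],
        "cold_induced": False,
        "hazard_fold_hen2_cold": 1.0,
        "expression": 1.0,
    })


def sample_library(
    model: TerminationModel,
    genes: list[GeneModel],
    samples: pd.DataFrame,
    gene_effects: pd.DataFrame | None = None,
    shear_length: int | None = 100,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one fragment library per sample; returns (fragments, truth).

    ``gene_effects`` may carry per-gene modifiers: ``cold_induced`` (bool,
    initiation boosted by the preset's cold_induction factor in cold),
    ``hazard_fold_hen2_cold`` (multiplies the hazard for the hen2 genotype
    in cold only — a gene-specific cold effect), and ``expression``
    (multiplies the initiation rate everywhere). The returned truth table
    is ``gene_effects`` with defaults filled in.
    """
    if seed is None:
        seed = model.seed
    eff = _default_gene_effects(genes)
    if gene_effects is not None:
        eff = eff.set_index("gene_id")
        ge = gene_effects.set_index("gene_id")
        for col in ge.columns:
            eff.loc[ge.index, col] = ge[col]
        eff = eff.reset_index()
    eff_idx = eff.set_index("gene_id")

    n_genes = len(genes)
    g_len = np.array([g.length for g in genes])
    g_start = np.array([g.start for g in genes])
    g_end = np.array([g.end for g in genes])
    g_plus = np.array([g.strand == "+" for g in genes])
    cold_induced = eff_idx.loc[[g.gene_id for g in genes], "cold_induced"].to_numpy(dtype=bool)
    hz_fold = eff_idx.loc[[g.gene_id for g in genes], "hazard_fold_hen2_cold"].to_numpy(dtype=float)
    expr = eff_idx.loc[[g.gene_id for g in genes], "expression"].to_numpy(dtype=float)

    streams = np.random.SeedSequence(seed).spawn(len(samples))
    pieces = []
    for (row, ss) in zip(samples.itertuples(index=False), streams):
        rng = np.random.default_rng(ss)
        p = model.get(row.genotype, row.condition)
        is_cold = row.condition == COLD
        lam = p.initiation_rate * expr * np.where(is_cold & cold_induced, p.cold_induction, 1.0)
        hazard = np.full(n_genes, p.hazard)
        if is_cold and row.genotype == "hen2":
            hazard = np.minimum(hazard * hz_fold, 0.999)

        n_events = _nb_counts(rng, lam, p.dispersion)
        gi = np.repeat(np.arange(n_genes), n_events)
        if len(gi) == 0:
            continue
        h_e = hazard[gi]
        L_e = g_len[gi]
        # geometric termination position (1-indexed base of termination)
        u = rng.random(len(gi))
        with np.errstate(divide="ignore"):
            x = np.where(h_e > 0,
                         np.floor(np.log1p(-u) / np.log1p(-h_e)) + 1,
                         np.inf)
        rna_len = np.minimum(x, L_e).astype(np.int64)
        is_fl = x > L_e
        p_survive = np.where(is_fl, 1.0 - p.degrade_fl, 1.0 - p.degrade_pt)
        keep = rng.random(len(gi)) < p_survive
        gi, rna_len = gi[keep], rna_len[keep]
        rna_len = np.maximum(rna_len, 1)
        if len(gi) == 0:
            continue

        if shear_length is None:
            frag_gi = gi
            s_rna = np.zeros(len(gi), dtype=np.int64)
            f_len = rna_len
        else:
            f_len_rna = np.minimum(shear_length, rna_len)
            n_sub = np.maximum(1, np.rint(rna_len / f_len_rna).astype(np.int64))
            frag_gi = np.repeat(gi, n_sub)
            f_len = np.repeat(f_len_rna, n_sub)
            span = np.repeat(rna_len - f_len_rna, n_sub) + 1
            s_rna = np.floor(rng.random(len(frag_gi)) * span).astype(np.int64)

        plus = g_plus[frag_gi]
        gstart = np.where(plus, g_start[frag_gi] + s_rna, g_end[frag_gi] - s_rna - f_len)
        gend = gstart + f_len
        pieces.append(pd.DataFrame({
            "chrom": pd.Series([genes[i].chrom for i in frag_gi], dtype=str),
            "start": gstart,
            "end": gend,
            "strand": np.where(plus, "+", "-"),
            "sample_id": row.sample_id,
        }))

    if pieces:
        fragments = pd.concat(pieces, ignore_index=True)
    else:
        fragments = pd.DataFrame(columns=FRAGMENT_COLUMNS)
    return fragments, eff


def _solve_hazard_fold(params_mut: ConditionParams, params_wt: ConditionParams,
                       L: int, effect_fold: float) -> float:
    """Hazard multiplier for the mutant so that the expected 3'-half coverage
    ratio mutant/WT equals 1/effect_fold (closed-form, gene-length aware)."""
    m = (L + 1) // 2
    cov3_wt = expected_half_counts(params_wt, L, m).cov3
    if cov3_wt <= 0:
        return 1.0

    def f(fold):
        p = replace(params_mut, hazard=min(params_mut.hazard * fold, 0.99))
        return expected_half_counts(p, L, m).cov3 / cov3_wt - 1.0 / effect_fold

    if f(1.0) <= 0:  # already at/below target without elevation
        return 1.0
    hi = 2.0
    while f(hi) > 0 and hi < 1e6:
        hi *= 2.0
    return float(brentq(f, 1.0, hi, xtol=1e-6))


@dataclass
class BenchmarkData:
    """A full synthetic dataset: annotation, fragments, samples, truth, model."""

    genes: list[GeneModel]
    fragments: pd.DataFrame
    samples: pd.DataFrame
    truth: pd.DataFrame
    model: TerminationModel
    paths: dict = field(default_factory=dict)


def _write_gff3(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(f"{g.chrom}\tterminseq\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n")


def make_benchmark(
    n_genes: int = 600,
    n_true_positive: int = 60,
    effect_fold: float = 4.0,
    n_replicates: int = 3,
    seed: int = 17,
    outdir=None,
    shear_length: int | None = 100,
    frac_null_cold_induced: float = 0.15,
    genes_per_chrom: int = 30,
) -> BenchmarkData:
    """Generate the default end-to-end benchmark dataset.

    ``n_true_positive`` genes carry a *cold-specific* elevated termination
    hazard in the hen2 genotype, sized per gene (via the closed-form
    expectations) so their expected 3'-half coverage drops ``effect_fold``-
    fold versus wild type in cold. All positives are cold-induced (their
    initiation rises in cold in every genotype); a fraction of the null
    genes is cold-induced too. The two genotypes otherwise share identical
    baseline parameters, so null genes are exact nulls, normalization is
    stable, and the empirical FDR against truth is well defined; the full
    genotype presets (with their genome-wide 5'-fragment stabilization) are
    exercised by the preset-contrast properties instead. Genes are long and variable (log-normal
    lengths around 2 kb), spaced far apart on synthetic chromosomes.
    WT and hen2 are simulated at 22 C and after 12 h at 4 C with
    ``n_replicates`` libraries each.
    """
    if n_true_positive > n_genes:
        raise ValueError("n_true_positive must be <= n_genes")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])

    lengths = np.clip(np.rint(rng.lognormal(np.log(2000.0), 0.4, n_genes)), 500, 8000).astype(int)
    strands = rng.choice(["+", "-"], n_genes)
    genes = []
    pos = 1000
    for i in range(n_genes):
        if i and i % genes_per_chrom == 0:
            pos = 1000
        chrom = f"chr{i // genes_per_chrom + 1}"
        genes.append(GeneModel(f"g{i:04d}", chrom, pos, pos + int(lengths[i]), strands[i]))
        pos += int(lengths[i]) + 10000

    idx = rng.permutation(n_genes)
    positives = set(idx[:n_true_positive])
    n_null_cold = int(round(frac_null_cold_induced * (n_genes - n_true_positive)))
    null_cold = set(idx[n_true_positive:n_true_positive + n_null_cold])

    # benchmark model: both genotypes share baseline parameters and the
    # mutant differs only at the truth genes (gene-specific cold hazard
    # elevation), so null genes are exact nulls and the empirical FDR
    # against truth is well defined
    wt_params = TerminationModel.preset(seed=seed).get("WT", CONTROL)
    model = TerminationModel(
        {(g, c): wt_params for g in ("WT", "hen2") for c in (CONTROL, COLD)},
        seed=seed,
    )
    p_hen2_cold = model.get("hen2", COLD)
    p_wt_cold = model.get("WT", COLD)

    fold_by_len: dict[int, float] = {}
    records = []
    for i, g in enumerate(genes):
        is_pos = i in positives
        fold = 1.0
        if is_pos:
            if g.length not in fold_by_len:
                fold_by_len[g.length] = _solve_hazard_fold(p_hen2_cold, p_wt_cold, g.length, effect_fold)
            fold = fold_by_len[g.length]
        records.append({
            "gene_id": g.gene_id,
            "cold_induced": bool(is_pos or i in null_cold),
            "hazard_fold_hen2_cold": fold,
            "expression": float(np.round(rng.lognormal(0.0, 0.3), 6)),
            "is_positive": bool(is_pos),
        })
    effects = pd.DataFrame(records, columns=[
        "gene_id", "cold_induced", "hazard_fold_hen2_cold", "expression", "is_positive",
    ])

    samples = pd.DataFrame([
        {"sample_id": f"{geno}_{'cold' if cond == COLD else 'ctrl'}_r{r}",
         "genotype": geno, "condition": cond, "replicate": r}
        for geno in ("WT", "hen2")
        for cond in (CONTROL, COLD)
        for r in range(1, n_replicates + 1)
    ])

    lib_seed = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31))
    fragments, truth = sample_library(
        model, genes, samples,
        gene_effects=effects.drop(columns="is_positive"),
        shear_length=shear_length, seed=lib_seed,
    )
    if len(truth):
        truth = truth.merge(effects[["gene_id", "is_positive"]], on="gene_id")
    else:
        truth = effects.copy()

    paths = {}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "annotation": outdir / "genes.gff3",
            "fragments": outdir / "fragments.bed",
            "samples": outdir / "samples.tsv",
            "truth": outdir / "truth.tsv",
            "model": outdir / "model.yaml",
        }
        _write_gff3(genes, paths["annotation"])
        write_fragments_bed(fragments, paths["fragments"])
        samples.to_csv(paths["samples"], sep="\t", index=False)
        truth.to_csv(paths["truth"], sep="\t", index=False)
        model.to_yaml(paths["model"])
        paths = {k: str(v) for k, v in paths.items()}

    return BenchmarkData(genes, fragments, samples, truth, model, paths)
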