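"""Half-specific differential abundance testing and cold-specific selection.

The half-gene counts are modelled as negative binomial with variance
``mu + alpha * mu**2``. Per-region dispersions are method-of-moments
estimates shrunk toward a fitted mean-dispersion trend; group differences
are tested with a Wald statistic on the log2 fold change (delta method for
the standard error), and Benjamini-Hochberg correction is applied across
all tested regions within one contrast.

The selection step reproduces the discovery logic for cold-specific 3'-end
depletion: a gene is selected when its 3' half is called DOWN in the
mutant-vs-WT contrast in cold but not differentially expressed in the
control condition, and each selected gene is then cross-referenced against
the wild-type whole-gene cold response (induced / repressed / unchanged).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .quantify import CountMatrix, size_factors

__all__ = [
    "ContrastSpec",
    "DE_COLUMNS",
    "bh_fdr",
    "estimate_dispersions",
    "nb_wald_test",
    "nb_wald_test_groups",
    "select_3prime_specific",
    "cross_reference_wt_response",
]

DE_COLUMNS = ["region_id", "baseMean", "log2FC", "dispersion", "pvalue", "fdr", "call"]

#: pseudocount added to group mean normalized counts for fold-change stability
PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class ContrastSpec:
    """One two-group comparison within a condition.

    ``alpha`` is the FDR threshold and ``lfc_min`` the minimum absolute
    log2 fold change for a region to be called UP or DOWN.
    """

    genotype_test: str
    genotype_ref: str
    condition: str
    alpha: float = 0.05
    lfc_min: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.lfc_min < 0:
            raise ValueError(f"lfc_min must be >= 0, got {self.lfc_min}")


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _group_labels(cm: CountMatrix, groups=None) -> np.ndarray:
    if groups is not None:
        groups = np.asarray(groups)
        if len(groups) != len(cm.samples):
            raise ValueError("groups length must match number of samples")
        return groups
    return (cm.samples["genotype"].astype(str) + "/" + cm.samples["condition"].astype(str)).to_numpy()


def _fit_dispersion_trend(mu: np.ndarray, alpha_raw: np.ndarray) -> tuple[float, float]:
    """Fit alpha_trend(mu) = a0 + a1/mu by least squares on the log scale."""
    ok = (mu > 0) & (alpha_raw > 0)
    if ok.sum() < 2:
        return 0.01, 1.0  # flat fallback trend for degenerate inputs
    mu_f, a_f = mu[ok], alpha_raw[ok]

    def resid(theta):
        a0, a1 = np.exp(theta)
        return np.log(a0 + a1 / mu_f) - np.log(a_f)

    start = np.log([max(np.median(a_f), 1e-4), 1.0])
    sol = optimize.least_squares(resid, start, method="lm", max_nfev=200)
    a0, a1 = np.exp(sol.x)
    return float(a0), float(a1)


def estimate_dispersions(cm: CountMatrix, groups=None, factors=None) -> np.ndarray:
    """Per-region NB dispersion estimates, shrunk toward a 1/mu trend.

    The raw estimate is the method of moments ``max(0, (s2 - mu) / mu**2)``
    on size-factor-normalized counts, with the variance pooled within groups
    (residual from group means). Raw values are shrunk toward the fitted
    trend with weight ``n / (n + 4)`` where ``n`` is the number of samples.
    All-zero regions receive the trend value at the smallest positive
    region mean.
    """
    groups = _group_labels(cm, groups)
    if factors is None:
        factors = size_factors(cm)
    norm = cm.counts / factors
    n = norm.shape[1]
    uniq = np.unique(groups)
    if n < 2 or not any((groups == g).sum() >= 2 for g in uniq):
        warnings.warn("no group with >= 2 replicates; returning flat trend dispersions",
                      stacklevel=2)

    mu = norm.mean(axis=1)
    # pooled within-group residual variance
    ss = np.zeros(len(mu))
    df = 0
    for g in uniq:
        cols = groups == g
        k = int(cols.sum())
        if k >= 2:
            gm = norm[:, cols].mean(axis=1, keepdims=True)
            ss += ((norm[:, cols] - gm) ** 2).sum(axis=1)
            df += k - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        s2 = ss / df if df > 0 else np.zeros_like(ss)
        alpha_raw = np.where(mu > 0, np.maximum(0.0, (s2 - mu) / mu**2), 0.0)

    a0, a1 = _fit_dispersion_trend(mu, alpha_raw)
    mu_floor = mu[mu > 0].min() if (mu > 0).any() else 1.0
    trend = a0 + a1 / np.maximum(mu, mu_floor)
    w = n / (n + 4)
    alpha = np.where(mu > 0, w * alpha_raw + (1 - w) * trend, trend)
    if df == 0:
        alpha = trend.copy()
    return np.maximum(alpha, 0.0)


def nb_wald_test(
    cm: CountMatrix,
    contrast: ContrastSpec,
    dispersions=None,
    factors=None,
) -> pd.DataFrame:
    """Wald test of each region's log2 fold change (test vs reference genotype).

    Group means of normalized counts are compared with a pseudocount of
    0.5; the standard error of the log2 fold change comes from the NB
    variance ``mu + alpha*mu**2`` by the delta method, and two-sided
    p-values from the standard normal. Returns a DataFrame with
    :data:`DE_COLUMNS`, FDR-adjusted across all tested regions.
    """
    sel = (cm.samples["condition"] == contrast.condition) & (
        cm.samples["genotype"].isin([contrast.genotype_test, contrast.genotype_ref])
    )
    sub = cm.subset_samples(sel.to_numpy())
    is_test = (sub.samples["genotype"] == contrast.genotype_test).to_numpy()
    label = f"{contrast.genotype_test} vs {contrast.genotype_ref} in {contrast.condition}"
    return nb_wald_test_groups(sub, is_test, alpha=contrast.alpha,
                               lfc_min=contrast.lfc_min, dispersions=dispersions,
                               factors=factors, label=label)


def nb_wald_test_groups(
    sub: CountMatrix,
    is_test,
    alpha: float = 0.05,
    lfc_min: float = 0.0,
    dispersions=None,
    factors=None,
    label: str = "contrast",
) -> pd.DataFrame:
    """General two-group NB Wald test on an arbitrary sample split.

    ``is_test`` is a boolean mask over the samples of ``sub``; the remaining
    samples form the reference group. Used directly for condition contrasts
    (e.g. the wild-type cold response) where the groups are not genotypes.
    """
    is_test = np.asarray(is_test, dtype=bool)
    n_test, n_ref = int(is_test.sum()), int((~is_test).sum())
    if n_test == 0 or n_ref == 0 or n_test + n_ref < 2:
        raise ValueError(
            f"contrast {label}: both groups must be present with >= 2 samples total"
        )
    if factors is None:
        factors = size_factors(sub)
    if dispersions is None:
        dispersions = estimate_dispersions(sub, is_test, factors=factors)
    disp = np.asarray(dispersions, dtype=float)
    if len(disp) != len(sub.region_ids):
        raise ValueError("dispersions length must match number of regions")

    norm = sub.counts / factors
    mu_t = norm[:, is_test].mean(axis=1)
    mu_r = norm[:, ~is_test].mean(axis=1)
    base_mean = norm.mean(axis=1)

    log2fc = np.log2((mu_t + PSEUDOCOUNT) / (mu_r + PSEUDOCOUNT))
    # delta method: var(log2 mu_hat) ~= var(mu_hat) / ((mu + pc) ln2)^2
    var_t = (mu_t + disp * mu_t**2) / n_test
    var_r = (mu_r + disp * mu_r**2) / n_ref
    se2 = (var_t / (mu_t + PSEUDOCOUNT) ** 2 + var_r / (mu_r + PSEUDOCOUNT) ** 2) / np.log(2) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se2 > 0, log2fc / np.sqrt(se2), 0.0)
    pval = 2 * stats.norm.sf(np.abs(z))

    both_zero = (mu_t == 0) & (mu_r == 0)
    pval = np.where(both_zero, 1.0, pval)
    log2fc = np.where(both_zero, 0.0, log2fc)

    fdr = bh_fdr(pval)
    call = np.full(len(pval), "NS", dtype=object)
    sig = (fdr <= alpha) & (np.abs(log2fc) >= lfc_min) & (log2fc != 0)
    call[sig & (log2fc > 0)] = "UP"
    call[sig & (log2fc < 0)] = "DOWN"

    return pd.DataFrame({
        "region_id": sub.region_ids,
        "baseMean": base_mean,
        "log2FC": log2fc,
        "dispersion": disp,
        "pvalue": pval,
        "fdr": fdr,
        "call": call,
    })


def _gene_of_region(region_id: str) -> str:
    gene, _, half = region_id.rpartition(":")
    return gene if gene else region_id


def select_3prime_specific(de_3p_cold: pd.DataFrame, de_3p_control: pd.DataFrame) -> set[str]:
    """Genes whose 3' half is DOWN in cold but NS in the control condition.

    Both tables must cover exactly the same 3'-half regions (same bisection).
    Returns the set of parent gene ids.
    """
    cold = de_3p_cold.set_index("region_id")
    ctrl = de_3p_control.set_index("region_id")
    if set(cold.index) != set(ctrl.index):
        diff = sorted(set(cold.index) ^ set(ctrl.index))
        raise ValueError(f"region sets differ between contrasts: {diff[:20]}"
                         + ("..." if len(diff) > 20 else ""))
    mask = (cold["call"] == "DOWN") & (ctrl.loc[cold.index, "call"] == "NS")
    return {_gene_of_region(rid) for rid in cold.index[mask]}


def cross_reference_wt_response(
    selected: set[str],
    de_wt_wholegene: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Label each selected gene by its wild-type whole-gene cold-response call.

    Returns the per-gene label table and counts per label
    ({'UP': ..., 'DOWN': ..., 'NS': ...}). Genes missing from the WT table
    are labelled NS with a warning.
    """
    wt = de_wt_wholegene.set_index("region_id")["call"]
    labels = {}
    n_missing = 0
    for g in sorted(selected):
        if g in wt.index:
            labels[g] = wt[g]
        else:
            labels[g] = "NS"
            n_missing += 1
    if n_missing:
        warnings.warn(f"{n_missing} selected gene(s) missing from the WT whole-gene table; "
                      "labelled NS", stacklevel=2)
    table = pd.DataFrame({"gene_id": list(labels), "wt_response": list(labels.values())})
    counts = {lab: int((table["wt_response"] == lab).sum()) for lab in ("UP", "DOWN", "NS")}
    return table, counts
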