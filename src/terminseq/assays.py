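"""Small-data quantitative assays: ddCt qPCR and electrolyte-leakage EC50.

Relative expression follows the comparative Ct method: dCt = Ct(target) -
mean Ct(reference genes); ddCt = dCt(test) - dCt(reference sample); fold
change = 2**(-ddCt). Multiple reference genes are combined by the
arithmetic mean of their Ct values (the geometric mean of the linear
quantities).

Freezing tolerance is summarized by fitting relative electrolyte leakage
against treatment temperature with a four-parameter logistic curve

    leakage(T) = bottom + (top - bottom) / (1 + 10**((LogEC50 - T) * slope))

and genotypes are compared with the extra sum-of-squares F-test between a
full model (separate LogEC50 per curve, other parameters shared) and a
nested null model (one shared LogEC50).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "QpcrRecord",
    "LeakageCurve",
    "SigmoidFit",
    "ddct_fold_change",
    "relative_leakage",
    "fit_sigmoid",
    "compare_ec50_ftest",
    "qpcr_table_fold_changes",
]


@dataclass(frozen=True)
class QpcrRecord:
    """One qPCR measurement: target Ct plus one or more reference-gene Cts."""

    sample_id: str
    genotype: str
    condition: str
    target: str
    ct_target: float
    ct_refs: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.ct_refs) < 1:
            raise ValueError("at least one reference-gene Ct is required")
        vals = (self.ct_target, *self.ct_refs)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("Ct values must be finite")

    @property
    def delta_ct(self) -> float:
        return self.ct_target - float(np.mean(self.ct_refs))


def ddct_fold_change(rec_test: QpcrRecord, rec_ref: QpcrRecord) -> float:
    """Fold change 2**(-ddCt) of the test record relative to the reference."""
    if rec_test.target != rec_ref.target:
        raise ValueError(
            f"records target different genes: {rec_test.target!r} vs {rec_ref.target!r}"
        )
    ddct = rec_test.delta_ct - rec_ref.delta_ct
    return float(2.0 ** (-ddct))


def qpcr_table_fold_changes(table: pd.DataFrame, ref_genotype: str = "WT") -> pd.DataFrame:
    """Per-replicate fold changes of each genotype vs the reference genotype.

    ``table`` columns: sample_id, genotype, condition, target, ct_target and
    one or more ct_ref* columns. Test replicate i is paired with reference
    replicate i within each (condition, target); fold-change mean and SEM
    over replicate pairs are computed on the 2**(-ddCt) scale.
    """
    ref_cols = [c for c in table.columns if c.startswith("ct_ref")]
    if not ref_cols:
        raise ValueError("no ct_ref* columns in qPCR table")

    def records(df):
        return [
            QpcrRecord(r["sample_id"], r["genotype"], r["condition"], r["target"],
                       float(r["ct_target"]), tuple(float(r[c]) for c in ref_cols))
            for _, r in df.iterrows()
        ]

    rows = []
    for (cond, target), grp in table.groupby(["condition", "target"], sort=True):
        refs = records(grp[grp["genotype"] == ref_genotype])
        if not refs:
            raise ValueError(f"no {ref_genotype!r} records for {target} / {cond}")
        for geno, sub in grp[grp["genotype"] != ref_genotype].groupby("genotype", sort=True):
            fcs = [ddct_fold_change(t, r) for t, r in zip(records(sub), itertools.cycle(refs))]
            rows.append({
                "genotype": geno, "condition": cond, "target": target,
                "fold_change": float(np.mean(fcs)),
                "sem": float(np.std(fcs, ddof=1) / np.sqrt(len(fcs))) if len(fcs) > 1 else np.nan,
                "n": len(fcs),
            })
    return pd.DataFrame(rows)


def relative_leakage(cond_initial: float, cond_total_after_kill: float) -> float:
    """Relative electrolyte leakage: conductivity before / after total kill."""
    if cond_total_after_kill <= 0:
        raise ValueError("total conductivity after kill must be positive")
    if cond_initial < 0:
        raise ValueError("initial conductivity must be non-negative")
    if cond_initial > cond_total_after_kill:
        warnings.warn("initial conductivity exceeds total; clipping to 1.0", stacklevel=2)
        return 1.0
    return cond_initial / cond_total_after_kill


@dataclass
class LeakageCurve:
    """Leakage fractions vs treatment temperature for one genotype."""

    genotype: str
    acclimation: str
    temperatures: np.ndarray
    leakage: np.ndarray
    sem: np.ndarray | None = None

    def __post_init__(self) -> None:
        order = np.argsort(self.temperatures)
        self.temperatures = np.asarray(self.temperatures, dtype=float)[order]
        self.leakage = np.asarray(self.leakage, dtype=float)[order]
        if self.sem is not None:
            self.sem = np.asarray(self.sem, dtype=float)[order]
        if len(self.temperatures) != len(self.leakage):
            raise ValueError("temperatures and leakage must have equal length")
        if ((self.leakage < 0) | (self.leakage > 1)).any():
            raise ValueError("leakage fractions must lie in [0, 1]")


@dataclass
class SigmoidFit:
    """Four-parameter logistic fit of one leakage curve."""

    bottom: float
    top: float
    log_ec50: float
    slope: float
    rss: float
    df: int
    degenerate: bool = False


def _logistic(T, bottom, top, log_ec50, slope):
    expo = np.clip((log_ec50 - T) * slope, -300.0, 300.0)
    return bottom + (top - bottom) / (1.0 + 10.0 ** expo)


def _multistart_grid(temps: np.ndarray, leakage: np.ndarray):
    lo, hi = float(leakage.min()), float(leakage.max())
    ec50s = np.quantile(temps, [0.25, 0.5, 0.75])
    for slope in (-2.0, -0.5, 0.5, 2.0):
        for ec in ec50s:
            yield np.array([lo, hi, ec, slope])


def fit_sigmoid(curve: LeakageCurve) -> SigmoidFit:
    """Least-squares four-parameter logistic fit with a fixed multi-start grid.

    Deterministic given the data. The best of the converged starts is
    returned; ``bottom > top`` solutions are re-expressed with the
    asymptotes swapped and the slope negated (an equivalent curve). A fit
    whose dynamic range ``top - bottom`` is below 1e-3 is flagged
    degenerate.
    """
    t, y = curve.temperatures, curve.leakage
    if len(t) < 5:
        raise ValueError("need at least 5 points spanning the transition")

    def resid(p):
        return _logistic(t, *p) - y

    best = None
    for start in _multistart_grid(t, y):
        try:
            sol = optimize.least_squares(resid, start, method="lm", max_nfev=2000)
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0] - 1e-15:
            best = (rss, sol.x)
    if best is None:
        raise RuntimeError("sigmoid fit failed to converge from every start")
    rss, p = best
    bottom, top, ec50, slope = (float(v) for v in p)
    if bottom > top:
        bottom, top, slope = top, bottom, -slope
    return SigmoidFit(bottom, top, ec50, slope, rss, df=len(t) - 4,
                      degenerate=(top - bottom) < 1e-3)


def _fit_shared(curves: list[LeakageCurve], share_ec50: bool,
                start: np.ndarray | None = None) -> tuple[float, np.ndarray, int]:
    """Fit curves jointly with shared bottom/top/slope.

    Full model: one LogEC50 per curve. Null model: a single shared LogEC50.
    Returns (rss, params, n_free_params).
    """
    n_ec = 1 if share_ec50 else len(curves)
    t_all = [c.temperatures for c in curves]
    y_all = [c.leakage for c in curves]

    def resid(p):
        bottom, top, slope = p[:3]
        ecs = p[3:]
        out = []
        for i, (t, y) in enumerate(zip(t_all, y_all)):
            ec = ecs[0] if share_ec50 else ecs[i]
            out.append(_logistic(t, bottom, top, ec, slope) - y)
        return np.concatenate(out)

    starts = []
    if start is not None:
        starts.append(start)
    y_cat = np.concatenate(y_all)
    t_cat = np.concatenate(t_all)
    for base in _multistart_grid(t_cat, y_cat):
        starts.append(np.concatenate([base[:2], [base[3]], np.repeat(base[2], n_ec)]))
    best = None
    for s in starts:
        try:
            sol = optimize.least_squares(resid, s, method="lm", max_nfev=4000)
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0] - 1e-15:
            best = (rss, sol.x)
    if best is None:
        raise RuntimeError("joint sigmoid fit failed to converge from every start")
    return best[0], best[1], 3 + n_ec


def compare_ec50_ftest(curve_a: LeakageCurve, curve_b: LeakageCurve) -> tuple[float, float]:
    """Extra sum-of-squares F-test for a LogEC50 difference between two curves.

    Full model: shared bottom/top/slope, separate LogEC50 per curve (5 free
    parameters); null model: everything shared (4). F = ((RSS0 - RSS1) /
    (df0 - df1)) / (RSS1 / df1), p from F(df0 - df1, df1).
    """
    curves = [curve_a, curve_b]
    n_points = sum(len(c.temperatures) for c in curves)
    rss_full, p_full, k_full = _fit_shared(curves, share_ec50=False)
    null_start = np.concatenate([p_full[:3], [float(np.mean(p_full[3:]))]])
    rss_null, _, k_null = _fit_shared(curves, share_ec50=True, start=null_start)
    if rss_full > rss_null + 1e-12:
        # optimizer failure on the full model: refit from the null solution
        refit_start = np.concatenate([p_full[:3], np.repeat(null_start[3], 2)])
        rss_retry, _, _ = _fit_shared(curves, share_ec50=False, start=refit_start)
        rss_full = min(rss_full, rss_retry)
        if rss_full > rss_null + 1e-9:
            raise RuntimeError("nested fits inconsistent: RSS(full) > RSS(null)")
    df_full = n_points - k_full
    df_null = n_points - k_null
    rss_full = max(rss_full, 0.0)
    num = max(rss_null - rss_full, 0.0) / (df_null - df_full)
    den = rss_full / df_full if rss_full > 0 else np.finfo(float).tiny
    F = num / den
    p = float(stats.f.sf(F, df_null - df_full, df_full))
    return float(F), p


def read_leakage_table(path) -> pd.DataFrame:
    """TSV with genotype, acclimation, temperature_C, conductivity_initial,
    conductivity_total; returns the table with a relative_leakage column."""
    df = pd.read_csv(path, sep="\t")
    required = {"genotype", "acclimation", "temperature_C",
                "conductivity_initial", "conductivity_total"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df["relative_leakage"] = [
        relative_leakage(a, b)
        for a, b in zip(df["conductivity_initial"], df["conductivity_total"])
    ]
    return df


def leakage_curves_from_table(df: pd.DataFrame) -> dict[tuple[str, str], LeakageCurve]:
    """Collapse a per-replicate leakage table to one mean curve per
    (genotype, acclimation)."""
    out = {}
    for (geno, acc), grp in df.groupby(["genotype", "acclimation"], sort=True):
        agg = grp.groupby("temperature_C")["relative_leakage"].agg(["mean", "sem", "count"])
        out[(geno, acc)] = LeakageCurve(
            genotype=geno, acclimation=acc,
            temperatures=agg.index.to_numpy(dtype=float),
            leakage=agg["mean"].to_numpy(),
            sem=agg["sem"].to_numpy(),
        )
    return out
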