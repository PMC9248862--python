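"""Heterogeneity, pleiotropy, outlier and influence diagnostics.

* Cochran's Q — weighted sum of squared deviations of per-SNP Wald ratios
  from a pooled estimate; chi-square with L-1 df under homogeneity.  Excess
  Q signals heterogeneity, often caused by horizontal pleiotropy.
* MR-PRESSO-style global/outlier test — compares the observed sum of
  squared leave-one-out standardized residuals against a parametric
  simulation of the no-pleiotropy null; per-SNP residuals against their own
  simulated distributions flag individual outliers.
* Influence table — leave-one-out random-effects IVW estimates and
  single-SNP Wald ratios, plot-ready.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MREstimate, _arrays, _ivw_core, ivw, wald_ratio
from .harmonize import HarmonizedSet


@dataclass(frozen=True)
class HeterogeneityResult:
    q: float
    df: int
    p: float

    @property
    def scale(self) -> float:
        """Multiplicative residual scale sqrt(Q/df) used by random-effects IVW."""
        return float(np.sqrt(self.q / self.df))


@dataclass(frozen=True)
class PressoResult:
    rss_obs: float
    global_p: float
    n_sim: int
    seed: int
    per_snp_p: dict[str, float]
    outliers: list[str]

    @property
    def has_outliers(self) -> bool:
        return bool(self.outliers)


@dataclass
class DiagnosticsReport:
    """All diagnostics for one harmonized instrument set."""

    heterogeneity: HeterogeneityResult
    egger_intercept: MREstimate
    presso: PressoResult | None = None
    influence: pd.DataFrame | None = None
    notes: list[str] = field(default_factory=list)

    def to_flat_dict(self) -> dict:
        flat = {
            "cochran_q": self.heterogeneity.q,
            "cochran_q_df": self.heterogeneity.df,
            "cochran_q_p": self.heterogeneity.p,
            "egger_intercept": self.egger_intercept.theta,
            "egger_intercept_se": self.egger_intercept.se,
            "egger_intercept_p": self.egger_intercept.p,
        }
        if self.presso is not None:
            flat.update(
                presso_rss_obs=self.presso.rss_obs,
                presso_global_p=self.presso.global_p,
                presso_n_sim=self.presso.n_sim,
                presso_outliers=",".join(self.presso.outliers) or "none",
            )
        return flat


def cochran_q(harmonized: HarmonizedSet, theta: float | None = None) -> HeterogeneityResult:
    """Cochran's Q about ``theta`` (default: the fixed-effect IVW estimate).

    Q = sum_j w_j (ratio_j - theta)^2 with w_j = beta_exp_j^2 / se_out_j^2,
    referred to chi-square(L-1).
    """
    L = len(harmonized)
    if L < 2:
        raise ValueError("Cochran's Q needs at least 2 instruments")
    bx, _, by, sy = _arrays(harmonized)
    theta_ivw, _, q_at_ivw = _ivw_core(bx, by, sy)
    if theta is None:
        q = q_at_ivw
    else:
        w = bx**2 / sy**2
        q = float(np.sum(w * (by / bx - theta) ** 2))
    return HeterogeneityResult(q=q, df=L - 1, p=float(stats.chi2.sf(q, L - 1)))


def _loo_slopes(bx, by, sy):
    """Leave-one-out fixed-effect IVW slope for each SNP, vectorized."""
    num = np.sum(bx * by / sy**2)
    den = np.sum(bx**2 / sy**2)
    return (num - bx * by / sy**2) / (den - bx**2 / sy**2)


def presso(
    harmonized: HarmonizedSet,
    n_sim: int = 5000,
    seed: int | None = None,
    outlier_alpha: float = 0.05,
) -> PressoResult:
    """Simulation-based global pleiotropy and per-SNP outlier test.

    The observed statistic is the residual sum of squares of standardized
    leave-one-out residuals r_j = (beta_out_j - b_{-j} beta_exp_j)/se_out_j,
    where b_{-j} is the fixed-effect IVW slope without SNP j.  The null
    distribution is built by redrawing, per simulation, beta_exp* from
    normal(beta_exp, se_exp) and beta_out* from normal(b_{-j} beta_exp*,
    se_out) and recomputing the statistic identically.  The global p uses
    the add-one empirical formula (1 + #{RSS* >= RSS_obs})/(n_sim + 1), so
    it is never exactly zero.  Per-SNP outlier p-values are the empirical
    tails of r_j^2, Bonferroni-multiplied by L.
    """
    L = len(harmonized)
    if L < 3:
        raise ValueError("the pleiotropy outlier test needs at least 3 instruments")
    if n_sim < 100:
        raise ValueError(f"n_sim must be at least 100, got {n_sim}")
    if seed is None:
        raise ValueError("seed is mandatory for the simulation-based test")

    bx, sx, by, sy = _arrays(harmonized)
    if not np.all(np.isfinite(sx)):
        raise ValueError("exposure SEs are required for the null simulation")

    b_loo = _loo_slopes(bx, by, sy)
    r_obs = (by - b_loo * bx) / sy
    rss_obs = float(np.sum(r_obs**2))

    rng = np.random.default_rng(seed)
    bx_sim = rng.normal(bx, sx, size=(n_sim, L))
    by_sim = rng.normal(b_loo * bx_sim, sy)
    # recompute LOO slopes within each simulated dataset (vectorized rows)
    num = np.sum(bx_sim * by_sim / sy**2, axis=1, keepdims=True)
    den = np.sum(bx_sim**2 / sy**2, axis=1, keepdims=True)
    b_loo_sim = (num - bx_sim * by_sim / sy**2) / (den - bx_sim**2 / sy**2)
    r_sim = (by_sim - b_loo_sim * bx_sim) / sy
    rss_sim = np.sum(r_sim**2, axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))

    per_snp_p = {}
    outliers = []
    for j, inst in enumerate(harmonized):
        tail = float((1 + np.sum(r_sim[:, j] ** 2 >= r_obs[j] ** 2)) / (n_sim + 1))
        p_adj = min(1.0, tail * L)
        per_snp_p[inst.rsid] = p_adj
        if p_adj < outlier_alpha:
            outliers.append(inst.rsid)

    return PressoResult(
        rss_obs=rss_obs,
        global_p=global_p,
        n_sim=n_sim,
        seed=seed,
        per_snp_p=per_snp_p,
        outliers=outliers,
    )


def influence(harmonized: HarmonizedSet) -> pd.DataFrame:
    """Leave-one-out random-effects IVW and single-SNP Wald estimates.

    One row per SNP; ``loo_*`` columns are the pooled estimate with that
    SNP removed, ``snp_*`` columns its own Wald ratio.  Ready for forest
    plotting.
    """
    if len(harmonized) < 3:
        raise ValueError("influence analysis needs at least 3 instruments")
    rows = []
    for inst in harmonized:
        loo = ivw(harmonized.without(inst.rsid), effects_model="random")
        single = wald_ratio(inst)
        rows.append(
            {
                "rsid": inst.rsid,
                "loo_theta": loo.theta,
                "loo_se": loo.se,
                "loo_or": loo.or_point,
                "loo_or_low": loo.or_low,
                "loo_or_high": loo.or_high,
                "loo_p": loo.p,
                "snp_theta": single.theta,
                "snp_se": single.se,
                "snp_or": single.or_point,
                "snp_or_low": single.or_low,
                "snp_or_high": single.or_high,
                "snp_p": single.p,
            }
        )
    return pd.DataFrame(rows)


def diagnose(
    harmonized: HarmonizedSet,
    n_sim: int = 5000,
    seed: int | None = None,
    outlier_alpha: float = 0.05,
) -> DiagnosticsReport:
    """Run the full diagnostic battery on a harmonized set."""
    from .estimators import egger

    het = cochran_q(harmonized)
    _, intercept = egger(harmonized)
    report = DiagnosticsReport(heterogeneity=het, egger_intercept=intercept)
    if seed is not None:
        report.presso = presso(harmonized, n_sim=n_sim, seed=seed, outlier_alpha=outlier_alpha)
        if report.presso.has_outliers:
            report.notes.append(
                "outlier SNPs detected: "
                + ", ".join(report.presso.outliers)
                + "; remove them and re-run to obtain outlier-corrected estimates"
            )
    report.influence = influence(harmonized)
    return report
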