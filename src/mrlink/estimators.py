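"""Causal-effect estimators for two-sample Mendelian randomization.

Given L harmonized instruments with exposure effects beta_exp (SE se_exp)
and outcome effects beta_out (SE se_out), every method combines the per-SNP
Wald ratios theta_j = beta_out,j / beta_exp,j into one causal log-odds
ratio per unit of exposure:

* **IVW** — inverse-variance weighted average of the ratios, identical to a
  weighted regression of beta_out on beta_exp through the origin with
  weights 1/se_out².  The fixed-effect SE assumes homogeneity; the
  multiplicative random-effects SE inflates it by sqrt(Q/(L-1)), floored at
  1, where Q is Cochran's heterogeneity statistic.
* **MR-Egger** — the same regression with an unconstrained intercept.  The
  slope is robust to *directional* pleiotropy under the InSIDE assumption;
  the intercept estimates the average direct (pleiotropic) effect, and its
  departure from zero is the pleiotropy test.  P-values use t(L-2).
* **Simple / weighted / penalized weighted median** — the (weighted) median
  of the ratios, consistent while instruments carrying up to half the
  weight are invalid.  The penalized variant down-weights SNPs with large
  heterogeneity contributions.  SEs come from a parametric bootstrap.

All standard errors for Wald ratios are first-order (exposure-side noise
neglected); a second-order option is available on :func:`wald_ratio`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .harmonize import HarmonizedInstrument, HarmonizedSet

Z95 = 1.959963984540054  # normal 97.5% quantile, used for every CI

METHOD_LABELS = {
    "wald_ratio": "Wald ratio",
    "ivw_fe": "IVW (fixed-effect)",
    "ivw_re": "IVW (random-effects)",
    "egger_slope": "MR-Egger",
    "egger_intercept": "MR-Egger intercept",
    "simple_median": "Simple median",
    "weighted_median": "Weighted median",
    "penalized_weighted_median": "Penalized weighted median",
}

ALL_METHODS = (
    "ivw_fe",
    "ivw_re",
    "egger_slope",
    "egger_intercept",
    "simple_median",
    "weighted_median",
    "penalized_weighted_median",
)


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate on the log-OR scale from one MR method."""

    method: str
    theta: float
    se: float
    p: float
    n_snps: int
    df: int | None = None  # t degrees of freedom for p; None => normal
    extra: dict = field(default_factory=dict, compare=False)

    @property
    def ci_low(self) -> float:
        return self.theta - Z95 * self.se

    @property
    def ci_high(self) -> float:
        return self.theta + Z95 * self.se

    @property
    def or_point(self) -> float:
        return math.exp(self.theta)

    @property
    def or_low(self) -> float:
        return math.exp(self.ci_low)

    @property
    def or_high(self) -> float:
        return math.exp(self.ci_high)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "theta": self.theta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "or": self.or_point,
            "or_low": self.or_low,
            "or_high": self.or_high,
            "p": self.p,
            "n_snps": self.n_snps,
        }


def _arrays(harmonized: HarmonizedSet):
    bx = np.array([i.beta_exp for i in harmonized], dtype=float)
    sx = np.array([i.se_exp for i in harmonized], dtype=float)
    by = np.array([i.beta_out for i in harmonized], dtype=float)
    sy = np.array([i.se_out for i in harmonized], dtype=float)
    return bx, sx, by, sy


def _two_sided_p(z: float, df: int | None = None) -> float:
    if df is None:
        return float(2.0 * stats.norm.sf(abs(z)))
    return float(2.0 * stats.t.sf(abs(z), df))


def wald_ratio(inst: HarmonizedInstrument, second_order: bool = False) -> MREstimate:
    """Single-SNP causal estimate beta_out / beta_exp.

    The default first-order SE is se_out/|beta_exp|.  With
    ``second_order=True`` the delta-method term for exposure-side noise is
    added: se² = se_out²/beta_exp² + beta_out²·se_exp²/beta_exp⁴.
    """
    if inst.beta_exp == 0:
        raise ValueError(f"{inst.rsid}: zero exposure beta; Wald ratio undefined")
    theta = inst.beta_out / inst.beta_exp
    se = inst.se_out / abs(inst.beta_exp)
    if second_order:
        se = math.sqrt(se**2 + inst.beta_out**2 * inst.se_exp**2 / inst.beta_exp**4)
    return MREstimate(
        method="wald_ratio",
        theta=theta,
        se=se,
        p=_two_sided_p(theta / se),
        n_snps=1,
        extra={"rsid": inst.rsid},
    )


def ivw_weights(bx: np.ndarray, sy: np.ndarray) -> np.ndarray:
    """Per-SNP IVW weights on the ratio scale: beta_exp² / se_out²."""
    return bx**2 / sy**2


def _ivw_core(bx: np.ndarray, by: np.ndarray, sy: np.ndarray):
    """Closed-form IVW slope, fixed-effect SE and Cochran Q in one pass."""
    w = ivw_weights(bx, sy)
    theta = float(np.sum(bx * by / sy**2) / np.sum(bx**2 / sy**2))
    se_fixed = float(1.0 / np.sqrt(np.sum(bx**2 / sy**2)))
    q = float(np.sum(w * (by / bx - theta) ** 2))
    return theta, se_fixed, q


def ivw(harmonized: HarmonizedSet, effects_model: str = "random") -> MREstimate:
    """Inverse-variance weighted estimate (fixed or multiplicative random effects)."""
    if effects_model not in ("fixed", "random"):
        raise ValueError(f"effects_model must be 'fixed' or 'random', got {effects_model!r}")
    L = len(harmonized)
    if L < 2:
        raise ValueError("IVW needs at least 2 instruments; use wald_ratio for a single SNP")
    bx, _, by, sy = _arrays(harmonized)
    theta, se_fixed, q = _ivw_core(bx, by, sy)
    scale = max(1.0, math.sqrt(q / (L - 1)))
    se = se_fixed if effects_model == "fixed" else se_fixed * scale
    return MREstimate(
        method="ivw_fe" if effects_model == "fixed" else "ivw_re",
        theta=theta,
        se=se,
        p=_two_sided_p(theta / se),
        n_snps=L,
        extra={"cochran_q": q, "residual_scale": scale},
    )


def egger(harmonized: HarmonizedSet) -> tuple[MREstimate, MREstimate]:
    """MR-Egger regression; returns (slope, intercept) estimates.

    Each SNP is first oriented so its exposure beta is positive (both betas
    negated where needed) — the intercept is only meaningful in that
    orientation.  The weighted least-squares SEs are inflated by the
    residual scale when it exceeds 1, and p-values use t(L-2).  The 95% CIs
    use the normal 1.96 quantile.
    """
    L = len(harmonized)
    if L < 3:
        raise ValueError("MR-Egger needs at least 3 instruments")
    bx, _, by, sy = _arrays(harmonized)
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign

    w = 1.0 / sy**2
    if np.allclose(bx, bx[0]):
        raise ValueError("exposure betas are collinear after orientation; Egger slope undefined")

    import statsmodels.api as sm

    design = sm.add_constant(bx)
    fit = sm.WLS(by, design, weights=w).fit()
    # fit.bse embeds the estimated residual scale; re-floor it at 1 so a
    # better-than-chance fit cannot shrink the SEs below the fixed-effect ones
    sigma = math.sqrt(float(fit.scale))
    se_unscaled = fit.bse / sigma
    se = se_unscaled * max(1.0, sigma)

    intercept, slope = float(fit.params[0]), float(fit.params[1])
    se_int, se_slope = float(se[0]), float(se[1])
    df = L - 2
    slope_est = MREstimate(
        method="egger_slope",
        theta=slope,
        se=se_slope,
        p=_two_sided_p(slope / se_slope, df),
        n_snps=L,
        df=df,
        extra={"residual_scale": max(1.0, sigma)},
    )
    intercept_est = MREstimate(
        method="egger_intercept",
        theta=intercept,
        se=se_int,
        p=_two_sided_p(intercept / se_int, df),
        n_snps=L,
        df=df,
    )
    return slope_est, intercept_est


def weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median of per-SNP ratios.

    Ratios are sorted (ties broken by input order), weights standardized to
    cumulative positions p_j = (cum_j - w_j/2) / sum(w), and the ratio at
    p = 0.5 obtained by linear interpolation; outside [p_1, p_L] the end
    ratio is returned.
    """
    order = np.argsort(ratios, kind="stable")
    r = np.asarray(ratios, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    p = (np.cumsum(w) - w / 2.0) / w.sum()
    return float(np.interp(0.5, p, r))


def _median_weights(bx, sy, variant: str, L: int):
    if variant == "simple":
        return np.full(L, 1.0 / L)
    return ivw_weights(bx, sy)


def _penalize(ratios, weights, penalty: float):
    theta_wm = weighted_median_point(ratios, weights)
    q_contrib = weights * (ratios - theta_wm) ** 2
    q_tail = stats.chi2.sf(q_contrib, df=1)
    return weights * np.minimum(1.0, penalty * q_tail)


def _median_point(bx, by, sy, variant: str, penalty: float) -> float:
    L = len(bx)
    ratios = by / bx
    w = _median_weights(bx, sy, variant, L)
    if variant == "penalized":
        w = _penalize(ratios, w, penalty)
    return weighted_median_point(ratios, w)


def median_estimator(
    harmonized: HarmonizedSet,
    variant: str = "weighted",
    n_boot: int = 1000,
    seed: int | None = None,
    penalty: float = 20.0,
) -> MREstimate:
    """Simple, weighted, or penalized weighted median estimate.

    The SE is the standard deviation of the point estimate over ``n_boot``
    parametric-bootstrap replicates in which both studies' betas are
    redrawn from normal(beta, se); weights (and penalties) are recomputed
    within each replicate.  ``seed`` is required: median bootstrap results
    must be reproducible.
    """
    if variant not in ("simple", "weighted", "penalized"):
        raise ValueError(f"unknown median variant {variant!r}")
    L = len(harmonized)
    if variant == "simple":
        if L < 1:
            raise ValueError("simple median needs at least 1 instrument")
    elif L < 3:
        raise ValueError(f"{variant} median needs at least 3 instruments")
    if n_boot < 2:
        raise ValueError(f"n_boot must be at least 2, got {n_boot}")
    if seed is None:
        raise ValueError("seed is mandatory for the median bootstrap")

    bx, sx, by, sy = _arrays(harmonized)
    point = _median_point(bx, by, sy, variant, penalty)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = rng.normal(bx, sx)
        by_b = rng.normal(by, sy)
        boots[b] = _median_point(bx_b, by_b, sy, variant, penalty)
    se = float(np.std(boots, ddof=1))

    method = {"simple": "simple_median", "weighted": "weighted_median", "penalized": "penalized_weighted_median"}[variant]
    return MREstimate(
        method=method,
        theta=point,
        se=se,
        p=_two_sided_p(point / se),
        n_snps=L,
        extra={"n_boot": n_boot, "seed": seed},
    )
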