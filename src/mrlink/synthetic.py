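"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the data-generating process assumed by two-sample
MR: independent SNPs each raise a standardized exposure by a true
per-allele effect; the binary outcome's true per-allele log-odds effect is
``theta`` (the causal effect) times the exposure effect, plus an optional
direct pleiotropic effect alpha_j.  Observed betas are the true effects
plus sampling noise at the analytic SE for an additive GWAS:
se_exp = 1/sqrt(2 p (1-p) N_exp) for a standardized quantitative trait and
se_out = 1/sqrt(2 p (1-p) N_out K (1-K)) for a binary trait with case
fraction K.  ``scramble_alleles`` re-codes outcome records onto random
alleles/strands so that harmonization has real work to do.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .summary_io import AssociationTable, SNPAssociation

#: non-palindromic allele pairs; strand/order scrambling stays unambiguous
_ALLELE_PAIRS = [("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"), ("C", "A"), ("G", "A"), ("C", "T"), ("G", "T")]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class SimulationScenario:
    """Parameters of one simulated two-sample MR study.

    Defaults mirror the vitamin D / atrial fibrillation study scale:
    exposure GWAS of 79,366, outcome GWAS of 1,030,836 with case fraction
    0.0588, per-SNP variance explained drawn uniformly from
    ``r2_range`` (default 0.02%-0.32%, the span of the six instruments).
    """

    l: int = 50
    theta: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    n_exp: int = 79_366
    n_out: int = 1_030_836
    case_fraction: float = 0.0588
    eaf_range: tuple[float, float] = (0.1, 0.9)
    r2_range: tuple[float, float] = (0.0002, 0.0032)
    scramble_alleles: bool = False
    allow_palindromic: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.l < 1:
            raise ValueError("need at least one SNP")
        if self.n_exp <= 2 or self.n_out <= 2:
            raise ValueError("study sizes must exceed 2")
        lo, hi = self.eaf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError(f"eaf_range must lie inside (0, 1), got {self.eaf_range}")
        if not (0.0 < self.case_fraction < 1.0):
            raise ValueError("case fraction must be in (0, 1)")
        if self.pleiotropy_sd < 0:
            raise ValueError("pleiotropy_sd must be non-negative")


@dataclass(frozen=True)
class SimulationTruth:
    theta: float
    beta_exp_true: np.ndarray
    alpha: np.ndarray  # per-SNP direct (pleiotropic) outcome effects
    scrambled: np.ndarray = field(default=None)  # bool per SNP: outcome record re-coded


def _p_from_z(z):
    return 2.0 * stats.norm.sf(np.abs(z))


def simulate_two_sample(scenario: SimulationScenario) -> tuple[AssociationTable, AssociationTable, SimulationTruth]:
    """Generate (exposure table, outcome table, truth) for one scenario.

    Bit-reproducible given ``scenario.seed``.  Exposure effects are drawn
    so each SNP explains a realistic share of exposure variance
    (``r2_range``); observed betas add normal noise at the analytic SEs.
    With ``scramble_alleles`` each outcome record independently swaps its
    allele order (negating beta, complementing EAF) and/or relabels both
    alleles onto the opposite strand, each with probability 1/2.
    """
    rng = np.random.default_rng(scenario.seed)
    L = scenario.l
    eaf = rng.uniform(*scenario.eaf_range, size=L)
    r2 = rng.uniform(*scenario.r2_range, size=L)
    sign = rng.choice([-1.0, 1.0], size=L)
    beta_exp_true = sign * np.sqrt(r2 / (2.0 * eaf * (1.0 - eaf)))

    se_exp = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * scenario.n_exp)
    k = scenario.case_fraction
    se_out = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * scenario.n_out * k * (1.0 - k))

    alpha = (
        rng.normal(scenario.pleiotropy_mean, scenario.pleiotropy_sd, size=L)
        if (scenario.pleiotropy_mean != 0 or scenario.pleiotropy_sd > 0)
        else np.zeros(L)
    )
    # directional pleiotropy is defined relative to the exposure-raising
    # allele; otherwise random allele orientations would cancel it out
    beta_out_true = scenario.theta * beta_exp_true + np.sign(beta_exp_true) * alpha

    beta_exp_obs = rng.normal(beta_exp_true, se_exp)
    beta_out_obs = rng.normal(beta_out_true, se_out)

    pairs = _ALLELE_PAIRS + (_PALINDROMIC_PAIRS if scenario.allow_palindromic else [])
    pair_idx = rng.integers(0, len(pairs), size=L)
    swap = rng.random(size=L) < 0.5 if scenario.scramble_alleles else np.zeros(L, dtype=bool)
    strand = rng.random(size=L) < 0.5 if scenario.scramble_alleles else np.zeros(L, dtype=bool)

    exp_records, out_records = [], []
    for j in range(L):
        ea, nea = pairs[pair_idx[j]]
        rsid = f"rs{j + 1:06d}"
        exp_records.append(
            SNPAssociation(
                rsid=rsid,
                position=f"{(j % 22) + 1}:{1_000_000 + j}",
                effect_allele=ea,
                other_allele=nea,
                eaf=float(eaf[j]),
                beta=float(beta_exp_obs[j]),
                se=float(se_exp[j]),
                pvalue=float(max(_p_from_z(beta_exp_obs[j] / se_exp[j]), 1e-300)),
                n=scenario.n_exp,
            )
        )
        o_ea, o_nea, o_beta, o_eaf = ea, nea, beta_out_obs[j], eaf[j]
        if swap[j]:
            o_ea, o_nea, o_beta, o_eaf = o_nea, o_ea, -o_beta, 1.0 - o_eaf
        if strand[j]:
            o_ea, o_nea = _COMPLEMENT[o_ea], _COMPLEMENT[o_nea]
        out_records.append(
            SNPAssociation(
                rsid=rsid,
                position=f"{(j % 22) + 1}:{1_000_000 + j}",
                effect_allele=o_ea,
                other_allele=o_nea,
                eaf=float(o_eaf),
                beta=float(o_beta),
                se=float(se_out[j]),
                pvalue=float(max(_p_from_z(o_beta / se_out[j]), 1e-300)),
                n=scenario.n_out,
            )
        )

    exposure = AssociationTable("simulated_exposure", "exposure", exp_records)
    outcome = AssociationTable("simulated_outcome", "outcome", out_records)
    truth = SimulationTruth(
        theta=scenario.theta,
        beta_exp_true=beta_exp_true,
        alpha=alpha,
        scrambled=swap | strand,
    )
    return exposure, outcome, truth
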