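"""Instrument strength (R², F) and per-SNP outcome-association screening.

For a biallelic SNP with effect-allele frequency ``p`` and per-allele
effect ``beta`` on a standardized trait (SD = 1), the variance explained is

    R² = 2 p (1 − p) beta²

and the strength of the instrument in a study of ``N`` individuals is

    F = R² (N − 2) / (1 − R²).

F > 10 is the conventional bar for a "strong" instrument with low risk of
weak-instrument bias.  The outcome screen checks that no instrument is
directly associated with the outcome at a Bonferroni-corrected level — a
direct association would hint at a pathway bypassing the exposure.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .harmonize import HarmonizedSet

F_STRONG_THRESHOLD = 10.0


@dataclass(frozen=True)
class InstrumentStrength:
    rsid: str
    r2: float
    f_stat: float

    @property
    def strong(self) -> bool:
        return self.f_stat > F_STRONG_THRESHOLD


def variance_explained(eaf: float, beta: float, trait_sd: float = 1.0) -> float:
    """Proportion of exposure variance explained by one SNP.

    ``beta`` is the per-allele effect; ``trait_sd`` rescales a beta reported
    in raw units to SD units (defaults to 1, i.e. beta already standardized).
    """
    if not (0.0 < eaf < 1.0):
        raise ValueError(f"degenerate allele frequency {eaf}; need 0 < eaf < 1")
    return 2.0 * eaf * (1.0 - eaf) * (beta / trait_sd) ** 2


def f_statistic(r2: float, n: int) -> float:
    """Single-instrument F-statistic from variance explained and sample size."""
    if not (0.0 <= r2 < 1.0):
        raise ValueError(f"r2 must lie in [0, 1), got {r2}")
    if n <= 2:
        raise ValueError(f"sample size must exceed 2, got {n}")
    return r2 * (n - 2) / (1.0 - r2)


def strength_table(harmonized: HarmonizedSet, n_exposure: int, trait_sd: float = 1.0) -> pd.DataFrame:
    """Per-SNP R², F and strength verdict for a harmonized instrument set."""
    rows = []
    for inst in harmonized:
        if inst.eaf_exp is None:
            rows.append({"rsid": inst.rsid, "r2": None, "f_stat": None, "strong": None})
            continue
        r2 = variance_explained(inst.eaf_exp, inst.beta_exp, trait_sd)
        f = f_statistic(r2, n_exposure)
        rows.append({"rsid": inst.rsid, "r2": r2, "f_stat": f, "strong": f > F_STRONG_THRESHOLD})
    return pd.DataFrame(rows)


def outcome_association_screen(harmonized: HarmonizedSet, alpha: float = 0.05) -> pd.DataFrame:
    """Bonferroni screen of each instrument's direct outcome association.

    P-values are recomputed from beta_out/se_out (two-sided normal) rather
    than trusted from the input table; the threshold is ``alpha / L`` for L
    instruments.  "pass" means *not* associated — the desired outcome.
    """
    L = len(harmonized)
    threshold = alpha / L
    rows = []
    for inst in harmonized:
        p = float(2.0 * stats.norm.sf(abs(inst.beta_out / inst.se_out)))
        rows.append(
            {
                "rsid": inst.rsid,
                "beta_out": inst.beta_out,
                "se_out": inst.se_out,
                "pvalue": p,
                "threshold": threshold,
                "passed": p >= threshold,
            }
        )
    return pd.DataFrame(rows)
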