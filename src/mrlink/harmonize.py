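"""Allele harmonization between exposure and outcome summary statistics.

Two GWAS may report the same SNP on different effect alleles or opposite
DNA strands.  Before any two-sample analysis, each SNP's outcome effect
must be re-expressed on the exposure study's effect allele: swapped allele
order negates the beta and complements the EAF; strand complementation
(A<->T, C<->G) changes the allele letters only.  Palindromic SNPs (A/T or
C/G pairs) are strand-ambiguous and their orientation is inferred from
allele-frequency agreement, provided both frequencies are far enough from
0.5 to be informative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .summary_io import AssociationTable, SNPAssociation

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: default: EAF must lie outside [0.42, 0.58] before strand is inferred
DEFAULT_PALINDROMIC_MAF_LIMIT = 0.08
#: default: warn when the two studies' EAFs differ by more than this
DEFAULT_EAF_TOLERANCE = 0.2


class HarmonizationError(ValueError):
    pass


@dataclass(frozen=True)
class HarmonizedInstrument:
    """Exposure and outcome effects of one SNP on a common effect allele.

    ``ratio`` is the Wald ratio beta_out/beta_exp — the per-SNP causal
    estimate — with first-order SE se_out/|beta_exp| (exposure-side
    uncertainty neglected, appropriate for strong instruments).
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: float | None
    eaf_out: float | None
    flipped: bool = False
    palindromic: bool = False
    eaf_discordant: bool = False

    def __post_init__(self):
        if self.beta_exp == 0:
            raise HarmonizationError(f"{self.rsid}: zero exposure beta; no Wald ratio exists")
        if self.se_out <= 0 or self.se_exp <= 0:
            raise HarmonizationError(f"{self.rsid}: non-positive standard error")

    @property
    def ratio(self) -> float:
        return self.beta_out / self.beta_exp

    @property
    def ratio_se(self) -> float:
        return self.se_out / abs(self.beta_exp)


@dataclass
class HarmonizedSet:
    """Harmonized instruments plus a log of dropped SNPs with reasons."""

    instruments: list[HarmonizedInstrument]
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        if not self.instruments:
            raise HarmonizationError(
                "harmonization produced no usable instruments; "
                f"dropped: {self.dropped}"
            )
        ids = [i.rsid for i in self.instruments]
        if len(set(ids)) != len(ids):
            raise HarmonizationError("duplicate rsids after harmonization")

    def __len__(self) -> int:
        return len(self.instruments)

    def __iter__(self):
        return iter(self.instruments)

    @property
    def rsids(self) -> list[str]:
        return [i.rsid for i in self.instruments]

    def without(self, rsid: str) -> "HarmonizedSet":
        return HarmonizedSet(
            [i for i in self.instruments if i.rsid != rsid], list(self.dropped)
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "rsid": i.rsid,
                    "ea": i.effect_allele,
                    "nea": i.other_allele,
                    "beta_exp": i.beta_exp,
                    "se_exp": i.se_exp,
                    "beta_out": i.beta_out,
                    "se_out": i.se_out,
                    "eaf_exp": i.eaf_exp,
                    "eaf_out": i.eaf_out,
                    "ratio": i.ratio,
                    "ratio_se": i.ratio_se,
                    "flipped": i.flipped,
                    "palindromic": i.palindromic,
                    "eaf_discordant": i.eaf_discordant,
                }
                for i in self.instruments
            ]
        )


def _flip(rec: SNPAssociation) -> tuple[float, float | None]:
    """Outcome beta and EAF re-expressed on the opposite allele."""
    eaf = None if rec.eaf is None else 1.0 - rec.eaf
    return -rec.beta, eaf


def harmonize(
    exposure: AssociationTable,
    outcome: AssociationTable,
    eaf_tolerance: float = DEFAULT_EAF_TOLERANCE,
    palindromic_maf_limit: float = DEFAULT_PALINDROMIC_MAF_LIMIT,
) -> HarmonizedSet:
    """Align outcome effects to the exposure study's effect alleles.

    For each SNP present in both tables the outcome record is matched to the
    exposure alleles directly, after allele swap, or after strand
    complementation (plus swap); swapping negates the outcome beta and
    complements its EAF.  Palindromic SNPs are oriented by EAF agreement and
    dropped when either EAF lies within ``palindromic_maf_limit`` of 0.5 (or
    is missing).  SNPs whose harmonized EAFs still differ by more than
    ``eaf_tolerance`` are kept but flagged, with a warning.

    Raises
    ------
    HarmonizationError
        If the tables share no rsids, or nothing survives harmonization.
    """
    out_by_id = {r.rsid: r for r in outcome.records}
    shared = [r for r in exposure.records if r.rsid in out_by_id]
    if not shared:
        raise HarmonizationError(
            f"no shared rsids between {exposure.study_label!r} and {outcome.study_label!r}"
        )

    instruments: list[HarmonizedInstrument] = []
    dropped: list[tuple[str, str]] = []
    for exp in exposure.records:
        if exp.rsid not in out_by_id:
            dropped.append((exp.rsid, "absent from outcome table"))
            continue
        out = out_by_id[exp.rsid]
        try:
            inst = _harmonize_one(exp, out, eaf_tolerance, palindromic_maf_limit)
        except _Drop as d:
            dropped.append((exp.rsid, str(d)))
            continue
        instruments.append(inst)
    for rec in outcome.records:
        if rec.rsid not in {r.rsid for r in exposure.records}:
            dropped.append((rec.rsid, "absent from exposure table"))

    return HarmonizedSet(instruments, dropped)


class _Drop(Exception):
    """Internal: per-record drop with reason."""


def _harmonize_one(
    exp: SNPAssociation,
    out: SNPAssociation,
    eaf_tolerance: float,
    palindromic_maf_limit: float,
) -> HarmonizedInstrument:
    if exp.beta == 0:
        raise _Drop("zero exposure beta")

    pair_exp = (exp.effect_allele, exp.other_allele)
    pair_out = (out.effect_allele, out.other_allele)
    pair_out_comp = (COMPLEMENT[out.effect_allele], COMPLEMENT[out.other_allele])

    palindromic = exp.is_palindromic
    if pair_out == pair_exp or (not palindromic and pair_out_comp == pair_exp):
        beta_out, eaf_out, flipped = out.beta, out.eaf, False
    elif pair_out == pair_exp[::-1] or (not palindromic and pair_out_comp == pair_exp[::-1]):
        (beta_out, eaf_out), flipped = _flip(out), True
    else:
        raise _Drop(
            f"allele mismatch: exposure {'/'.join(pair_exp)} vs outcome {'/'.join(pair_out)}"
        )

    if palindromic:
        # letters cannot resolve strand for A/T and C/G pairs; use EAF
        if exp.eaf is None or eaf_out is None:
            raise _Drop("palindromic SNP with missing EAF; strand unresolvable")
        if (
            abs(exp.eaf - 0.5) <= palindromic_maf_limit
            or abs(eaf_out - 0.5) <= palindromic_maf_limit
        ):
            raise _Drop(
                "palindromic SNP with EAF too close to 0.5 "
                f"(exposure {exp.eaf:.2f}, outcome {eaf_out:.2f})"
            )
        if (exp.eaf - 0.5) * (eaf_out - 0.5) < 0:
            # frequencies disagree in direction: outcome is on the other strand
            beta_out, eaf_out = -beta_out, 1.0 - eaf_out
            flipped = not flipped

    discordant = False
    if exp.eaf is not None and eaf_out is not None and abs(exp.eaf - eaf_out) > eaf_tolerance:
        discordant = True
        warnings.warn(
            f"{exp.rsid}: harmonized EAFs differ by more than {eaf_tolerance:.2f} "
            f"(exposure {exp.eaf:.2f}, outcome {eaf_out:.2f}); kept but flagged",
            stacklevel=4,
        )

    return HarmonizedInstrument(
        rsid=exp.rsid,
        effect_allele=exp.effect_allele,
        other_allele=exp.other_allele,
        beta_exp=exp.beta,
        se_exp=exp.se,
        beta_out=beta_out,
        se_out=out.se,
        eaf_exp=exp.eaf,
        eaf_out=eaf_out,
        flipped=flipped,
        palindromic=palindromic,
        eaf_discordant=discordant,
    )
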