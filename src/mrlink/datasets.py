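"""Packaged example data: the vitamin D / atrial fibrillation instrument set.

Six SNPs associated with circulating 25-hydroxyvitamin D at genome-wide
significance in the SUNLIGHT meta-GWAS (N = 79,366, effects per unit
natural-log 25(OH)D), with their effects on atrial fibrillation from the
Nielsen et al. meta-GWAS (N = 1,030,836; 60,620 cases / 970,216 controls,
log-odds scale).  The outcome records for rs10741657 and rs17216707 are
coded on the opposite allele to the exposure study, as their published
allele frequencies imply, so harmonization is exercised for real.
"""

from __future__ import annotations

from importlib import resources

from .summary_io import AssociationTable, read_summary_table

EXPOSURE_N = 79_366
OUTCOME_N = 1_030_836
OUTCOME_CASES = 60_620
OUTCOME_CASE_FRACTION = OUTCOME_CASES / OUTCOME_N


def _load(name: str, label: str, trait: str) -> AssociationTable:
    with resources.as_file(resources.files("mrlink.data").joinpath(name)) as path:
        return read_summary_table(path, study_label=label, trait=trait)


def vitamin_d_exposure() -> AssociationTable:
    """SNP effects on natural-log 25(OH)D (SUNLIGHT meta-GWAS)."""
    return _load("vitamin_d_exposure.tsv", "SUNLIGHT", "ln 25(OH)D")


def atrial_fibrillation_outcome() -> AssociationTable:
    """SNP effects on atrial fibrillation log-odds (Nielsen et al. meta-GWAS)."""
    return _load("atrial_fibrillation_outcome.tsv", "Nielsen-AF", "atrial fibrillation")


def vitamin_d_af() -> tuple[AssociationTable, AssociationTable]:
    """The packaged (exposure, outcome) table pair."""
    return vitamin_d_exposure(), atrial_fibrillation_outcome()


FIXTURES = {"vitamin-d-af": vitamin_d_af}
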