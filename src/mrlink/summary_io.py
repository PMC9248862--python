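"""Reading, validating and writing per-SNP GWAS summary-statistic tables.

A summary-statistic table holds one row per SNP with the additive per-allele
effect of that SNP on a trait, as estimated by a GWAS: effect allele, other
allele, effect-allele frequency (EAF), beta, its standard error, p-value and
sample size.  Exposure effects here are per unit natural-log 25(OH)D;
outcome effects are log-odds of atrial fibrillation — but nothing in this
module is trait-specific.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

VALID_ALLELES = frozenset("ACGT")

#: default column names; override with ``column_map`` on read
DEFAULT_COLUMNS = {
    "rsid": "rsid",
    "chr_pos": "chr_pos",
    "ea": "ea",
    "nea": "nea",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pval": "pval",
    "n": "n",
}


class SummaryFormatError(ValueError):
    """The file as a whole does not conform to the expected layout."""


class RecordValidationError(ValueError):
    """A single SNP row violates an invariant; carries the offending rsid."""

    def __init__(self, rsid: str, message: str):
        self.rsid = rsid
        super().__init__(f"{rsid}: {message}")


@dataclass(frozen=True)
class SNPAssociation:
    """One SNP's association record from a single GWAS.

    Parameters
    ----------
    rsid : str
        Variant identifier.
    position : str
        1-based "chrom:pos" string; informational only.
    effect_allele, other_allele : str
        Single-base alleles (A/C/G/T); the beta refers to each extra copy
        of the effect allele.
    eaf : float or None
        Effect-allele frequency in [0, 1].  May be missing (None); strand
        inference for palindromic SNPs then becomes impossible.
    beta : float
        Additive per-allele effect.
    se : float
        Standard error of beta, > 0.
    pvalue : float or None
        Two-sided p-value in (0, 1].
    n : int or None
        Study sample size.
    """

    rsid: str
    position: str
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pvalue: float | None = None
    n: int | None = None

    def __post_init__(self):
        if self.effect_allele not in VALID_ALLELES:
            raise RecordValidationError(self.rsid, f"invalid effect allele {self.effect_allele!r}")
        if self.other_allele not in VALID_ALLELES:
            raise RecordValidationError(self.rsid, f"invalid other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise RecordValidationError(self.rsid, "effect and other allele are identical")
        if not np.isfinite(self.beta):
            raise RecordValidationError(self.rsid, "beta is not finite")
        if not (np.isfinite(self.se) and self.se > 0):
            raise RecordValidationError(self.rsid, f"se must be > 0, got {self.se}")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise RecordValidationError(self.rsid, f"eaf outside [0, 1]: {self.eaf}")
        if self.pvalue is not None:
            if not (0.0 < self.pvalue <= 1.0):
                raise RecordValidationError(self.rsid, f"p-value outside (0, 1]: {self.pvalue}")
            self._check_pvalue_consistency()
        if self.n is not None and self.n <= 0:
            raise RecordValidationError(self.rsid, f"sample size must be positive, got {self.n}")

    def _check_pvalue_consistency(self):
        # loose check only: published betas/SEs are rounded, so tiny p-values
        # can shift by orders of magnitude; compare on the log10 scale
        implied = 2.0 * stats.norm.sf(abs(self.beta / self.se))
        if implied < np.finfo(float).tiny:
            return  # far beyond printable precision either way
        log_diff = abs(np.log10(self.pvalue) - np.log10(implied))
        if log_diff > max(1.5, 0.2 * abs(np.log10(implied))):
            warnings.warn(
                f"{self.rsid}: stated p-value {self.pvalue:g} disagrees with "
                f"|beta/se| (implies {implied:.3g})",
                stacklevel=3,
            )

    @property
    def is_palindromic(self) -> bool:
        """True for A/T or C/G pairs, where strand cannot be read off the alleles."""
        return {self.effect_allele, self.other_allele} in ({"A", "T"}, {"C", "G"})

    def zscore(self) -> float:
        return self.beta / self.se

    def pvalue_from_z(self) -> float:
        """Two-sided normal p recomputed from beta/se (ignores the stored column)."""
        return float(2.0 * stats.norm.sf(abs(self.zscore())))


@dataclass
class AssociationTable:
    """An ordered collection of :class:`SNPAssociation`, unique by rsid."""

    study_label: str
    trait: str
    records: list[SNPAssociation] = field(default_factory=list)

    def __post_init__(self):
        if not self.records:
            raise SummaryFormatError(f"{self.study_label}: association table is empty")
        ids = [r.rsid for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SummaryFormatError(f"{self.study_label}: duplicate rsids {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, rsid: str) -> SNPAssociation:
        for r in self.records:
            if r.rsid == rsid:
                return r
        raise KeyError(rsid)

    @property
    def rsids(self) -> list[str]:
        return [r.rsid for r in self.records]

    def subset(self, rsids: Iterable[str]) -> "AssociationTable":
        keep = set(rsids)
        return replace(self, records=[r for r in self.records if r.rsid in keep])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rsid": [r.rsid for r in self.records],
                "chr_pos": [r.position for r in self.records],
                "ea": [r.effect_allele for r in self.records],
                "nea": [r.other_allele for r in self.records],
                "eaf": [r.eaf for r in self.records],
                "beta": [r.beta for r in self.records],
                "se": [r.se for r in self.records],
                "pval": [r.pvalue for r in self.records],
                "n": [r.n for r in self.records],
            }
        )


def _sniff_sep(path: Path) -> str:
    with path.open("r") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_summary_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    study_label: str | None = None,
    trait: str = "",
) -> AssociationTable:
    """Read a delimited (TSV/CSV) GWAS summary-statistic table.

    ``column_map`` maps canonical field names (keys of
    :data:`DEFAULT_COLUMNS`) to the column names actually present in the
    file.  ``eaf``, ``pval``, ``n`` and ``chr_pos`` are optional columns;
    ``rsid``, ``ea``, ``nea``, ``beta`` and ``se`` are mandatory.
    """
    path = Path(path)
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype={cols["rsid"]: str})
    for key in ("rsid", "ea", "nea", "beta", "se"):
        if cols[key] not in df.columns:
            raise SummaryFormatError(
                f"{path}: mandatory column {cols[key]!r} (field {key!r}) not found; "
                f"available: {list(df.columns)}"
            )
    if df.empty:
        raise SummaryFormatError(f"{path}: table has a header but no rows")

    def _opt(row, key, cast=float):
        name = cols[key]
        if name not in df.columns or pd.isna(row[name]):
            return None
        return cast(row[name])

    def _pval(row):
        p = _opt(row, "pval")
        # published p-values below ~5e-324 underflow float64; clamp to the
        # smallest positive subnormal rather than rejecting the record
        if p == 0.0:
            p = float(np.nextafter(0.0, 1.0))
        return p

    records = []
    for _, row in df.iterrows():
        records.append(
            SNPAssociation(
                rsid=str(row[cols["rsid"]]),
                position=str(row[cols["chr_pos"]]) if cols["chr_pos"] in df.columns else "",
                effect_allele=str(row[cols["ea"]]).upper(),
                other_allele=str(row[cols["nea"]]).upper(),
                eaf=_opt(row, "eaf"),
                beta=float(row[cols["beta"]]),
                se=float(row[cols["se"]]),
                pvalue=_pval(row),
                n=_opt(row, "n", cast=lambda v: int(float(v))),
            )
        )
    return AssociationTable(study_label=study_label or path.stem, trait=trait, records=records)


def write_association_table(table: AssociationTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def write_results(estimates, path: str | Path, diagnostics=None, settings: dict | None = None) -> None:
    """Write causal-effect estimates (and optional diagnostics) as TSV.

    One row per method with point estimate, SE, 95% CI on both the log-OR
    and OR scales, p-value and instrument count.  Diagnostic blocks
    (heterogeneity, pleiotropy tests) follow as commented key-value lines so
    the file round-trips through :func:`read_results`.  A sibling ``.json``
    run summary is written alongside when ``settings`` is given.
    """
    estimates = list(estimates)
    if not estimates:
        raise ValueError("no estimates to write")
    path = Path(path)
    frame = pd.DataFrame([e.to_dict() for e in estimates])
    with path.open("w") as fh:
        frame.to_csv(fh, sep="\t", index=False, float_format="%.6f")
        if diagnostics is not None:
            for key, value in diagnostics.to_flat_dict().items():
                fh.write(f"# {key}\t{value}\n")
    if settings is not None:
        summary = {"settings": settings, "methods": [e.method for e in estimates]}
        path.with_suffix(".json").write_text(json.dumps(summary, indent=2, default=str) + "\n")


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back the estimate rows written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t", comment="#")
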