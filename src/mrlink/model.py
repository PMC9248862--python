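"""Model/Results surface tying the estimators and diagnostics together.

Typical use::

    from mrlink import MRModel, datasets

    exposure, outcome = datasets.vitamin_d_af()
    model = MRModel.from_tables(exposure, outcome)
    results = model.fit(seed=7)
    print(results.summary())
    diag = results.diagnostics(n_sim=5000, seed=7)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import estimators as est
from .diagnostics import DiagnosticsReport, diagnose
from .harmonize import HarmonizedInstrument, HarmonizedSet, harmonize
from .summary_io import AssociationTable


class MRModel:
    """Two-sample Mendelian randomization model over harmonized instruments.

    Construct from a :class:`~mrlink.harmonize.HarmonizedSet`, from raw
    exposure/outcome tables (:meth:`from_tables`, which harmonizes), or
    from a DataFrame of per-SNP betas and SEs (:meth:`from_dataframe`).
    """

    def __init__(self, harmonized: HarmonizedSet):
        self.harmonized = harmonized

    @classmethod
    def from_tables(
        cls,
        exposure: AssociationTable,
        outcome: AssociationTable,
        **harmonize_kwargs,
    ) -> "MRModel":
        return cls(harmonize(exposure, outcome, **harmonize_kwargs))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "MRModel":
        """Build from a frame with columns rsid, beta_exp, se_exp, beta_out, se_out.

        Optional columns eaf_exp, eaf_out, ea, nea are carried through;
        effects are assumed already harmonized.
        """
        instruments = [
            HarmonizedInstrument(
                rsid=str(row["rsid"]),
                effect_allele=str(row.get("ea", "A")),
                other_allele=str(row.get("nea", "G")),
                beta_exp=float(row["beta_exp"]),
                se_exp=float(row["se_exp"]),
                beta_out=float(row["beta_out"]),
                se_out=float(row["se_out"]),
                eaf_exp=float(row["eaf_exp"]) if "eaf_exp" in row and pd.notna(row["eaf_exp"]) else None,
                eaf_out=float(row["eaf_out"]) if "eaf_out" in row and pd.notna(row["eaf_out"]) else None,
            )
            for _, row in df.iterrows()
        ]
        return cls(HarmonizedSet(instruments))

    @property
    def n_instruments(self) -> int:
        return len(self.harmonized)

    def fit(
        self,
        methods: tuple[str, ...] = est.ALL_METHODS,
        n_boot: int = 1000,
        seed: int | None = None,
    ) -> "MRResults":
        """Compute the requested causal-effect estimates.

        ``seed`` drives the median bootstrap and is mandatory when any
        median method is requested.
        """
        estimates: dict[str, est.MREstimate] = {}
        for method in methods:
            if method == "ivw_fe":
                estimates[method] = est.ivw(self.harmonized, "fixed")
            elif method == "ivw_re":
                estimates[method] = est.ivw(self.harmonized, "random")
            elif method in ("egger_slope", "egger_intercept"):
                if "egger_slope" in estimates or "egger_intercept" in estimates:
                    continue
                slope, intercept = est.egger(self.harmonized)
                estimates["egger_slope"] = slope
                estimates["egger_intercept"] = intercept
            elif method in ("simple_median", "weighted_median", "penalized_weighted_median"):
                variant = {"simple_median": "simple", "weighted_median": "weighted", "penalized_weighted_median": "penalized"}[method]
                estimates[method] = est.median_estimator(
                    self.harmonized, variant=variant, n_boot=n_boot, seed=seed
                )
            else:
                raise ValueError(f"unknown method {method!r}")
        return MRResults(self, estimates)


@dataclass
class MRResults:
    """Fitted estimates plus access to diagnostics and exports."""

    model: MRModel
    estimates: dict[str, est.MREstimate]

    def __getitem__(self, method: str) -> est.MREstimate:
        return self.estimates[method]

    def __contains__(self, method: str) -> bool:
        return method in self.estimates

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([e.to_dict() for e in self.estimates.values()])

    def diagnostics(self, n_sim: int = 5000, seed: int | None = None, outlier_alpha: float = 0.05) -> DiagnosticsReport:
        return diagnose(self.model.harmonized, n_sim=n_sim, seed=seed, outlier_alpha=outlier_alpha)

    def summary(self) -> str:
        """Plain-text summary table in the style of a forest-plot legend."""
        lines = [
            "Two-sample Mendelian randomization",
            f"Instruments: {self.model.n_instruments} SNPs",
            "",
            f"{'Method':<28}{'OR':>8}{'95% CI':>18}{'P':>9}",
        ]
        for e in self.estimates.values():
            if e.method == "egger_intercept":
                lines.append(
                    f"{est.METHOD_LABELS[e.method]:<28}"
                    f"{e.theta:>8.3f}{'(se ' + format(e.se, '.3f') + ')':>18}{e.p:>9.3f}"
                )
            else:
                ci = f"({e.or_low:.3f}-{e.or_high:.3f})"
                lines.append(f"{est.METHOD_LABELS[e.method]:<28}{e.or_point:>8.3f}{ci:>18}{e.p:>9.3f}")
        return "\n".join(lines)

    def scatter_data(self) -> pd.DataFrame:
        """Per-SNP betas and fitted lines, ready for a scatter/forest plot."""
        h = self.model.harmonized
        df = h.to_frame()[["rsid", "beta_exp", "se_exp", "beta_out", "se_out", "ratio", "ratio_se"]]
        for name in ("ivw_fe", "ivw_re", "egger_slope"):
            if name in self.estimates:
                df[f"fit_{name}"] = np.abs(df["beta_exp"]) * self.estimates[name].theta
        return df
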