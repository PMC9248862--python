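"""End-to-end analysis runs: read, harmonize, QC, estimate, diagnose, power.

:class:`RunConfig` captures every knob of a run; :func:`run_full_analysis`
executes the whole pipeline into an output directory with a log, so two
runs with the same config and seed produce byte-identical tables.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .datasets import FIXTURES
from .diagnostics import diagnose
from .estimators import ALL_METHODS
from .harmonize import DEFAULT_EAF_TOLERANCE, DEFAULT_PALINDROMIC_MAF_LIMIT, harmonize
from .instrument_qc import outcome_association_screen, strength_table
from .model import MRModel
from .power import PowerSpec, detectable_or
from .summary_io import read_summary_table, write_results


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Configuration of one full analysis run.

    ``seed`` is mandatory: the median bootstrap and the pleiotropy
    simulation are stochastic and must be reproducible.
    """

    exposure: str | None = None
    outcome: str | None = None
    fixture: str | None = None
    out_dir: str = "mr_results"
    methods: tuple[str, ...] = ALL_METHODS
    n_boot: int = 1000
    n_sim: int = 5000
    seed: int | None = None
    alpha: float = 0.05
    eaf_tolerance: float = DEFAULT_EAF_TOLERANCE
    palindromic_maf_limit: float = DEFAULT_PALINDROMIC_MAF_LIMIT
    n_exposure: int | None = None
    power_r2: float | None = None
    power_case_fraction: float | None = None
    power_target: float = 0.80
    extra: dict = field(default_factory=dict)

    def validate(self):
        if self.seed is None:
            raise ConfigError("seed is required (stochastic steps must be reproducible)")
        if self.fixture is None and (self.exposure is None or self.outcome is None):
            raise ConfigError("provide either a fixture name or both exposure and outcome paths")
        if self.fixture is not None and self.fixture not in FIXTURES:
            raise ConfigError(f"unknown fixture {self.fixture!r}; available: {sorted(FIXTURES)}")


def _load_tables(config: RunConfig):
    if config.fixture is not None:
        return FIXTURES[config.fixture]()
    return (
        read_summary_table(config.exposure, trait="exposure"),
        read_summary_table(config.outcome, trait="outcome"),
    )


def run_full_analysis(config: RunConfig) -> Path:
    """Run the complete pipeline; returns the output directory.

    Writes: ``harmonized.tsv`` (+ drop log), ``qc.tsv``, ``screen.tsv``,
    ``estimates.tsv`` (+ JSON run summary), ``influence.tsv``,
    ``diagnostics.json``, optional ``power.json``, and ``run.log``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"mrlink {__version__}", f"config: {json.dumps(asdict(config), default=str, sort_keys=True)}"]

    def stage(name):
        log_lines.append(f"stage: {name}")

    try:
        stage("read")
        exposure, outcome = _load_tables(config)
        log_lines.append(f"exposure: {exposure.study_label} ({len(exposure)} SNPs)")
        log_lines.append(f"outcome: {outcome.study_label} ({len(outcome)} SNPs)")

        stage("harmonize")
        harmonized = harmonize(
            exposure,
            outcome,
            eaf_tolerance=config.eaf_tolerance,
            palindromic_maf_limit=config.palindromic_maf_limit,
        )
        harmonized.to_frame().to_csv(out / "harmonized.tsv", sep="\t", index=False)
        for rsid, reason in harmonized.dropped:
            log_lines.append(f"dropped {rsid}: {reason}")

        stage("qc")
        n_exp = config.n_exposure or next((r.n for r in exposure.records if r.n), None)
        if n_exp:
            strength_table(harmonized, n_exposure=n_exp).to_csv(out / "qc.tsv", sep="\t", index=False)
        screen = outcome_association_screen(harmonized, alpha=config.alpha)
        screen.to_csv(out / "screen.tsv", sep="\t", index=False)
        if not screen["passed"].all():
            log_lines.append(
                "warning: instruments directly associated with outcome: "
                + ", ".join(screen.loc[~screen["passed"], "rsid"])
            )

        stage("estimate")
        results = MRModel(harmonized).fit(methods=config.methods, n_boot=config.n_boot, seed=config.seed)

        stage("diagnose")
        report = diagnose(harmonized, n_sim=config.n_sim, seed=config.seed, outlier_alpha=config.alpha)
        write_results(
            results.estimates.values(),
            out / "estimates.tsv",
            diagnostics=report,
            settings=asdict(config),
        )
        report.influence.to_csv(out / "influence.tsv", sep="\t", index=False)
        (out / "diagnostics.json").write_text(json.dumps(report.to_flat_dict(), indent=2) + "\n")
        log_lines.extend(report.notes)

        if config.power_r2 is not None:
            stage("power")
            n_out = next((r.n for r in outcome.records if r.n), None)
            spec = PowerSpec(
                n=n_out,
                case_fraction=config.power_case_fraction or 0.5,
                r2=config.power_r2,
                alpha=config.alpha,
                target_power=config.power_target,
            )
            res = detectable_or(spec)
            (out / "power.json").write_text(
                json.dumps({"target_power": config.power_target, "detectable_or": res.detectable_or}, indent=2) + "\n"
            )
    except Exception as exc:
        log_lines.append(f"FAILED at {log_lines[-1]}: {exc}")
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
        raise

    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out
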