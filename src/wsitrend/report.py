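"""End-to-end pipeline runner and run report.

``run_pipeline`` composes the whole analysis: load tables -> build treatment
episodes -> apply the eligibility cascade -> extract time-anchored
measurements -> summarize trends.  The resulting :class:`RunReport` bundles
the attrition ledger, the summary table, warnings (degenerate SDs,
missing-data counts) and provenance (input hashes, seed, timestamp), and can
write itself out as CSV/text artifacts.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .cohort import AnchorSet, AttritionLedger, cohort_frame, render_flowchart, run_cascade
from .io_tables import (
    DrugDictionary,
    StudyConfig,
    load_config,
    load_labs,
    load_prescriptions,
)
from .outcomes import extract_measurements, plot_trends, summarize
from .simulate import GeneratorConfig, load_generator_config, write_dataset

__all__ = ["RunReport", "run_pipeline", "make_dataset"]

logger = logging.getLogger("wsitrend")


@dataclass
class RunReport:
    config: StudyConfig
    ledger: AttritionLedger
    cohort: list[AnchorSet]
    measurements: pd.DataFrame
    summary: pd.DataFrame
    warnings: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    @property
    def cohort_size(self) -> int:
        return len(self.cohort)

    def write(self, out_dir: str | Path, plots: bool = False) -> dict[str, str]:
        """Write ledger, flow chart, cohort, measurement and summary tables."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written = {}
        self.ledger.export(out_dir / "attrition_ledger.csv")
        written["ledger"] = str(out_dir / "attrition_ledger.csv")
        (out_dir / "flowchart.txt").write_text(render_flowchart(self.ledger) + "\n")
        written["flowchart"] = str(out_dir / "flowchart.txt")
        cohort_frame(self.cohort).to_csv(out_dir / "cohort.csv", index=False)
        written["cohort"] = str(out_dir / "cohort.csv")
        if not self.measurements.empty:
            self.measurements.to_csv(out_dir / "measurements.csv", index=False)
            written["measurements"] = str(out_dir / "measurements.csv")
            self.summary.to_csv(out_dir / "summary.csv", index=False)
            written["summary"] = str(out_dir / "summary.csv")
            if plots:
                for p in plot_trends(self.summary, out_dir):
                    written.setdefault("plots", []).append(p)  # type: ignore[union-attr]
        report_lines = [
            f"run at: {self.provenance.get('timestamp', '')}",
            f"inputs: {self.provenance.get('inputs', {})}",
            f"config: {dataclasses.asdict(self.config)}",
            f"cohort size: {self.cohort_size}",
            *(f"warning: {w}" for w in self.warnings),
        ]
        (out_dir / "report.txt").write_text("\n".join(str(x) for x in report_lines) + "\n")
        written["report"] = str(out_dir / "report.txt")
        return written


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


def run_pipeline(
    prescriptions_path: str | Path,
    labs_path: str | Path,
    config_path: str | Path,
    out_dir: str | Path | None = None,
    plots: bool = False,
    config_overrides: dict | None = None,
) -> RunReport:
    """Execute load -> episodes -> cascade -> extract -> summarize.

    ``config_overrides`` replaces individual :class:`StudyConfig` fields
    (CLI threshold flags).  When ``out_dir`` is given the report artifacts
    are written there.
    """
    config, dictionary = load_config(config_path)
    if config_overrides:
        config = dataclasses.replace(config, **config_overrides)

    logger.info("stage=load prescriptions=%s labs=%s", prescriptions_path, labs_path)
    prescriptions = load_prescriptions(prescriptions_path, dictionary, config)
    labs = load_labs(labs_path)
    n_patients = len({r.patient_id for r in prescriptions})
    logger.info(
        "stage=loaded rx_rows=%d lab_rows=%d patients=%d",
        len(prescriptions), len(labs), n_patients,
    )

    cohort, ledger = run_cascade(prescriptions, labs, config, dictionary)
    for step in ledger:
        logger.info(
            "stage=cascade step=%r remaining=%d excluded=%d",
            step.step_label, step.patients_remaining, step.patients_excluded,
        )

    warnings: list[str] = []
    if cohort:
        measurements = extract_measurements(cohort, labs, prescriptions, config)
        summary = summarize(measurements)
        n_missing = int(measurements["value"].isna().sum())
        if n_missing:
            warnings.append(f"{n_missing} measurement slots missing (non-PT-INR tests)")
        degen = summary[summary["sd_degenerate"]]
        if not degen.empty:
            warnings.append(
                f"sample SD degenerate (n=1) for {len(degen)} summary cells"
            )
    else:
        measurements = pd.DataFrame()
        summary = pd.DataFrame()
        warnings.append("empty cohort: no summaries produced")
    logger.info("stage=summarize cohort=%d", len(cohort))

    report = RunReport(
        config=config,
        ledger=ledger,
        cohort=cohort,
        measurements=measurements,
        summary=summary,
        warnings=warnings,
        provenance={
            "timestamp": datetime.datetime.now().isoformat(timespec="seconds"),
            "seed": config.random_seed,
            "inputs": {
                "prescriptions": _sha256(prescriptions_path),
                "labs": _sha256(labs_path),
                "config": _sha256(config_path),
            },
        },
    )
    if out_dir is not None:
        report.write(out_dir, plots=plots)
    return report


def make_dataset(
    generator_config: str | Path | GeneratorConfig, out_dir: str | Path
) -> dict[str, Path]:
    """Generate and write a synthetic dataset directory (deterministic per seed)."""
    if not isinstance(generator_config, GeneratorConfig):
        generator_config = load_generator_config(generator_config)
    logger.info("stage=simulate n_patients=%d seed=%d",
                generator_config.n_patients, generator_config.seed)
    return write_dataset(generator_config, out_dir)
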