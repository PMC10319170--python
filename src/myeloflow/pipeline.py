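"""End-to-end orchestration: simulate → gate → indices → compare → report.

A :class:`RunConfig` collects the seed, cohort layout, generator sizes,
gating/positivity constants and QC minima.  :func:`run_all` executes
the full pipeline deterministically: a single run seed fans out to
per-case child seeds by stable hashing of the case id, every tabular
output embeds the configuration hash and seed, and rerunning with the
same configuration is byte-identical for CSV outputs.

QC follows the acquisition rules: at least 100,000 relevant events per
sample (below → fail warning), ideally 500,000 (below → info note),
at least 100 positive cells per index and at least 1000 events per
population for merged analysis.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .fcs_io import SpilloverMatrix, apply_compensation, write_events
from .gating import GatingConfig, count_relevant_events, gate_all, population_fractions
from .merge_tubes import MERGE_MIN_EVENTS
from .panels import default_panel
from .positivity import GatedSample, PositivityConfig, compute_all_indices, indices_to_frame
from .stats_report import compare_indices, render_report
from .synthetic_data import (
    CohortConfig,
    case_seed,
    generate_cohort,
    generate_combined,
)

__all__ = ["RunConfig", "QCVerdict", "qc_sample", "run_all",
           "MIN_RELEVANT_EVENTS", "IDEAL_RELEVANT_EVENTS"]

log = logging.getLogger("myeloflow")

MIN_RELEVANT_EVENTS = 100_000
IDEAL_RELEVANT_EVENTS = 500_000


@dataclass
class QCVerdict:
    level: str                    # "pass" | "below_ideal" | "below_minimum"
    relevant_count: int
    messages: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return self.level != "below_minimum"


def qc_sample(
    relevant_count: int,
    minimum: int = MIN_RELEVANT_EVENTS,
    ideal: int = IDEAL_RELEVANT_EVENTS,
) -> QCVerdict:
    """Relevant-event QC: fail warning < 100,000, info note < 500,000."""
    if relevant_count < 0:
        raise ValueError("relevant_count must be >= 0")
    if relevant_count < minimum:
        return QCVerdict(
            "below_minimum", relevant_count,
            [f"{relevant_count} relevant events below the {minimum} minimum"],
        )
    if relevant_count < ideal:
        return QCVerdict(
            "below_ideal", relevant_count,
            [f"{relevant_count} relevant events below the ideal {ideal}"],
        )
    return QCVerdict("pass", relevant_count)


@dataclass
class RunConfig:
    """Everything a pipeline run depends on."""

    seed: int = 0
    out: str = "results"
    cohorts: tuple[str, ...] = ("non_malignant", "MDS", "AML")
    cases_per_cohort: int | None = None    # None → every fixture row
    n_events: int = 100_000
    strategy: str = "all"                  # or one of the four strategies
    use_merge: bool = False
    spillover_file: str | None = None
    write_fcs: bool = False
    min_relevant: int = MIN_RELEVANT_EVENTS
    ideal_relevant: int = IDEAL_RELEVANT_EVENTS
    min_positives: int = 100
    merge_min_events: int = MERGE_MIN_EVENTS
    gating: GatingConfig = field(default_factory=GatingConfig)
    positivity: PositivityConfig = field(default_factory=PositivityConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        gating = GatingConfig(**raw.pop("gating", {}))
        positivity = PositivityConfig(**raw.pop("positivity", {}))
        cfg = cls(gating=gating, positivity=positivity, **raw)
        if "cohorts" in raw:
            cfg.cohorts = tuple(raw["cohorts"])
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohorts"] = list(self.cohorts)
        return d

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out", None)  # the destination is not part of the analysis
        blob = yaml.safe_dump(d, sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


def _stamped_csv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config.config_hash()} seed={config.seed}\n")
        df.to_csv(fh, index=False)


def read_stamped_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def run_all(config: RunConfig) -> Path:
    """Run the full pipeline; returns the artifact directory.

    Stages: synthesize the configured cohorts → gate each case →
    compute all Ki-67/Bcl-2 indices → pairwise cohort comparisons →
    figures and CSV exports.  Any stage error aborts with a
    stage-tagged message.
    """
    outdir = Path(config.out)
    outdir.mkdir(parents=True, exist_ok=True)
    panel = default_panel()
    stage = "configure"
    try:
        stage = "simulate"
        t0 = time.time()
        cohort_cfg = CohortConfig(n_events=config.n_events)
        if config.cases_per_cohort is not None:
            cohort_cfg.sizes = {
                c: min(cohort_cfg.sizes[c], config.cases_per_cohort)
                for c in config.cohorts
            }
        profiles, metadata = generate_cohort(
            cohort_cfg, panel, seed=config.seed, cohorts=config.cohorts
        )
        log.info("simulate: %d cases configured (%.1fs)", len(profiles), time.time() - t0)

        spill = (
            SpilloverMatrix.from_csv(config.spillover_file)
            if config.spillover_file
            else None
        )

        frac_rows, all_indices, qc_rows = [], [], []
        cohort_by_sample = {}
        for prof in profiles:
            child = case_seed(config.seed, prof.case_id)
            stage = f"simulate:{prof.case_id}"
            table, gt = generate_combined(prof, seed=child)
            if spill is not None:
                table = apply_compensation(table, spill)
            if config.write_fcs:
                fcs_dir = outdir / "fcs"
                fcs_dir.mkdir(exist_ok=True)
                write_events(table, fcs_dir / f"{prof.case_id}.fcs")

            stage = f"gate:{prof.case_id}"
            t0 = time.time()
            relevant = count_relevant_events(table, config.gating)
            verdict = qc_sample(relevant, config.min_relevant, config.ideal_relevant)
            masks = gate_all(table, config.gating)
            fracs = population_fractions(masks, relevant)
            log.info(
                "gate %s: %d relevant events, QC=%s (%.1fs)",
                prof.case_id, relevant, verdict.level, time.time() - t0,
            )
            frac_rows.append(
                {"case_id": prof.case_id, "cohort": prof.cohort,
                 "relevant_events": relevant, "qc": verdict.level,
                 **{f"{p}_pct": round(v, 1) for p, v in fracs.fractions.items()}}
            )
            qc_rows.append(
                {"case_id": prof.case_id, "relevant_events": relevant,
                 "qc": verdict.level, "notes": "; ".join(verdict.messages)}
            )

            stage = f"indices:{prof.case_id}"
            sample = GatedSample(table=table, masks=masks, cohort=prof.cohort)
            results = compute_all_indices(sample, cfg=config.positivity)
            if config.strategy != "all":
                results = [r for r in results if r.strategy == config.strategy]
            all_indices.extend(results)
            cohort_by_sample[prof.case_id] = prof.cohort

        stage = "export"
        indices_df = indices_to_frame(all_indices, cohort_by_sample)
        _stamped_csv(metadata, outdir / "metadata.csv", config)
        _stamped_csv(pd.DataFrame(frac_rows), outdir / "population_fractions.csv", config)
        _stamped_csv(pd.DataFrame(qc_rows), outdir / "qc.csv", config)
        _stamped_csv(indices_df, outdir / "indices.csv", config)

        stage = "compare"
        comparisons = []
        if indices_df["cohort"].nunique() >= 2:
            comparisons = compare_indices(indices_df)

        stage = "report"
        render_report(comparisons, indices_df, outdir / "report")
        with open(outdir / "run.yaml", "w") as fh:
            yaml.safe_dump(
                {"config": config.to_dict(), "config_hash": config.config_hash()},
                fh, sort_keys=True,
            )
        return outdir
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
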