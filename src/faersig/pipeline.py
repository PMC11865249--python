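"""End-to-end orchestration: generate → ingest → describe → screen →
stratify → correlate, as one reproducible run.

A run is parameterized by a :class:`RunConfig` (constructed programmatically
or loaded from a YAML file), executes the stages in flow-chart order, writes
every module's tidy TSV outputs plus a JSON manifest (config echo, seed,
per-stage row counts, exclusion tallies, output checksums), and is
byte-identical under an identical config and seed. One seed governs the whole
run; stage sub-seeds are derived by seed-sequence splitting.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .descriptive import outcome_distribution, summarize_demographics, summary_to_frames
from .disproportionality import results_to_frame, screen_all
from .errors import ConfigurationError, DataError
from .ingest import (
    CohortFilter,
    apply_cohort_filter,
    assemble_reports,
    deduplicate,
    identity_mapping,
    read_mapping,
    read_quarterly_files,
    standardize_drug_names,
)
from .subgroups import (
    StratumSpec,
    correlations_to_frame,
    default_strata,
    matrix_to_long_frame,
    pairwise_drug_correlation,
    rank_negative_pairs,
    stratified_metrics,
    top_k_per_stratum,
    yearly_metric_matrix,
)
from .synthetic import (
    GeneratorConfig,
    PlantedSignal,
    default_config,
    generate_reports,
    inject_duplicates,
    write_quarterly_files,
)

log = logging.getLogger("faersig")


@dataclass
class RunConfig:
    """Everything one pipeline run needs; exactly one input mode is set."""

    mode: str = "synthetic"  # "synthetic" | "directory"
    generator: GeneratorConfig | None = None
    data_dir: str | None = None
    mapping_path: str | None = None
    cohort: CohortFilter = field(default_factory=lambda: CohortFilter(
        min_age_years=18.0, required_role="primary_suspect"))
    event: str = "DIZZINESS"
    drugs: list[str] | None = None  # None = all observed
    background: str = "cohort"  # "cohort" | "all"
    strata: list[StratumSpec] = field(default_factory=default_strata)
    ic_method: str = "gamma"
    correlation_axis: str = "strata"  # "strata" | "years"
    top_k: int = 5
    n_negative_pairs: int = 10
    output_dir: str = "faersig-out"
    seed: int = 0

    def validate(self) -> None:
        if self.mode not in ("synthetic", "directory"):
            raise ConfigurationError(
                f"mode must be 'synthetic' or 'directory', got {self.mode!r}")
        if self.mode == "directory" and not self.data_dir:
            raise ConfigurationError("directory mode requires data_dir")
        if self.mode == "directory" and Path(self.data_dir) == Path(self.output_dir):
            raise ConfigurationError("output_dir must differ from data_dir")
        if self.background not in ("cohort", "all"):
            raise ConfigurationError(
                f"background must be 'cohort' or 'all', got {self.background!r}")
        if self.correlation_axis not in ("strata", "years"):
            raise ConfigurationError(
                f"correlation_axis must be 'strata' or 'years', "
                f"got {self.correlation_axis!r}")


def _stratum_from_dict(d: dict) -> StratumSpec:
    return StratumSpec(
        label=d["label"], sex=d["sex"], age_min=float(d["age_min"]),
        age_max=None if d.get("age_max") is None else float(d["age_max"]),
        min_inclusive=bool(d.get("min_inclusive", True)),
        max_inclusive=bool(d.get("max_inclusive", True)),
    )


def _generator_from_dict(d: dict) -> GeneratorConfig:
    base = default_config(
        n_reports=int(d.get("n_reports", 10_000)),
        seed=int(d.get("seed", 0)),
        duplicate_rate=float(d.get("duplicate_rate", 0.05)),
    )
    simple = {"indication_term", "indication_rate"}
    for key, value in d.items():
        if key in ("n_reports", "seed", "duplicate_rate"):
            continue
        if key in simple:
            setattr(base, key, value)
        elif key in ("drug_vocabulary", "event_vocabulary"):
            setattr(base, key, [tuple(item) for item in value])
        elif key == "planted_signals":
            base.planted_signals = [
                PlantedSignal(s["drug"], s["event"], float(s["effect"]),
                              restrict_to=(_stratum_from_dict(s["restrict_to"])
                                           if s.get("restrict_to") else None))
                for s in value]
        elif key in ("sex_proportions", "age_band_proportions",
                     "reporter_proportions", "outcome_proportions"):
            setattr(base, key, {str(k): float(v) for k, v in value.items()})
        elif key == "year_range":
            base.year_range = (int(value[0]), int(value[1]))
        elif key == "year_weights":
            base.year_weights = {int(k): float(v) for k, v in value.items()}
        elif key == "drugs_per_report":
            base.drugs_per_report = (int(value[0]), int(value[1]))
        else:
            raise ConfigurationError(f"generator: unknown key {key!r}")
    return base


def load_run_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML file (flat key-value with nested
    sections; unspecified keys keep their defaults)."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config file {path} is not a mapping")
    cfg = RunConfig()
    for key, value in raw.items():
        if key == "generator":
            cfg.generator = _generator_from_dict(value or {})
        elif key == "cohort":
            cfg.cohort = CohortFilter(
                min_age_years=(None if value.get("min_age_years") is None
                               else float(value["min_age_years"])),
                required_role=value.get("required_role"),
                required_event=value.get("required_event"),
                required_indication=value.get("required_indication"),
                keep_missing_age=bool(value.get("keep_missing_age", False)),
            )
        elif key == "strata":
            cfg.strata = [_stratum_from_dict(s) for s in value]
        elif hasattr(cfg, key):
            setattr(cfg, key, value)
        else:
            raise ConfigurationError(f"unknown config key {key!r}")
    return cfg


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_echo(cfg: RunConfig) -> dict[str, Any]:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: enc(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)}
        if isinstance(obj, dict):
            return {str(k): enc(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        return obj

    return enc(cfg)


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute every stage and return the run manifest.

    Any stage failure aborts with the stage name; the partial manifest written
    so far is still saved to the output directory.
    """
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "config": _config_echo(config),
        "stages": {},
        "outputs": {},
    }
    written: list[Path] = []

    def save_frame(name: str, frame) -> None:
        path = out_dir / name
        frame.to_csv(path, sep="\t", index=False)
        written.append(path)

    stage = "setup"
    try:
        # --- generate ----------------------------------------------------
        if config.mode == "synthetic":
            stage = "generate"
            gen_cfg = config.generator or default_config()
            seeds = np.random.SeedSequence(config.seed).generate_state(2)
            gen_cfg = dataclasses.replace(gen_cfg, seed=int(seeds[0] % 2**31))
            reports = generate_reports(gen_cfg)
            reports = inject_duplicates(reports, gen_cfg.duplicate_rate,
                                        seed=int(seeds[1] % 2**31))
            data_dir = out_dir / "data"
            write_quarterly_files(reports, data_dir,
                                  year_range=gen_cfg.year_range)
            manifest["stages"]["generate"] = {
                "n_reports": gen_cfg.n_reports,
                "n_with_duplicates": len(reports),
            }
            log.info("generated %d reports (incl. duplicates)", len(reports))
            vocab_names = [d for d, _ in gen_cfg.drug_vocabulary]
            mapping = identity_mapping(vocab_names)
        else:
            data_dir = Path(config.data_dir)
            if config.mapping_path:
                mapping = read_mapping(config.mapping_path)
            else:
                mapping = None  # identity over observed verbatims

        # --- ingest ------------------------------------------------------
        stage = "ingest"
        tables = read_quarterly_files(data_dir)
        assembly = assemble_reports(tables)
        if mapping is None:
            mapping = identity_mapping(
                m.verbatim_name for r in assembly.reports for m in r.drugs)
        standardized = standardize_drug_names(assembly.reports, mapping)
        deduped = deduplicate(standardized.reports)
        manifest["stages"]["ingest"] = {
            "raw_demo_rows": len(tables.demo),
            "read_rejects": len(tables.rejects),
            "assembly_rejects": len(assembly.rejects),
            "incomplete_no_drug": assembly.n_incomplete_no_drug,
            "incomplete_no_event": assembly.n_incomplete_no_event,
            "collapsed_identical": assembly.n_collapsed_identical,
            "assembled": len(assembly.reports),
            "duplicates_removed": len(assembly.reports) - len(deduped),
            "deduplicated": len(deduped),
            "name_coverage": standardized.coverage,
        }

        # --- cohort filter -----------------------------------------------
        stage = "cohort"
        filtered = apply_cohort_filter(deduped, config.cohort)
        cohort = filtered.kept
        manifest["stages"]["cohort"] = {
            "input": len(deduped),
            "kept": len(cohort),
            "excluded": dict(filtered.tally),
        }
        if not cohort:
            raise DataError("cohort is empty after filtering")

        # --- describe ----------------------------------------------------
        stage = "describe"
        summary = summarize_demographics(cohort)
        for name, frame in summary_to_frames(summary).items():
            save_frame(f"summary_{name}.tsv", frame)
        save_frame("outcome_by_year.tsv", outcome_distribution(cohort, by_year=True))
        manifest["stages"]["describe"] = {"total_reports": summary.total_reports}

        # --- screen ------------------------------------------------------
        stage = "screen"
        background = cohort if config.background == "cohort" else deduped
        results = screen_all(background, config.event, drugs=config.drugs,
                             role=config.cohort.required_role,
                             ic_method=config.ic_method)
        forest = results_to_frame(results)
        save_frame("forest.tsv", forest)
        manifest["stages"]["screen"] = {
            "background": config.background,
            "n_background": len(background),
            "n_drugs": len(results),
            "n_flag_ror": int(forest["flag_ror"].sum()),
            "n_flag_aersmine": int(forest["flag_aersmine"].sum()),
            "n_flag_bcpnn": int(forest["flag_bcpnn"].sum()),
        }

        # --- subgroups ---------------------------------------------------
        stage = "subgroups"
        drug_list = list(forest["drug"])
        matrices = stratified_metrics(background, config.event, drug_list,
                                      strata=config.strata,
                                      role=config.cohort.required_role)
        save_frame("stratified_metrics.tsv", matrix_to_long_frame(matrices))
        top_rows = []
        for stratum, ranked in top_k_per_stratum(
                matrices["relative_reporting_ratio"], config.top_k).items():
            for rank, (drug, value) in enumerate(ranked, start=1):
                top_rows.append({"stratum": stratum, "rank": rank,
                                 "drug": drug, "relative_reporting_ratio": value})
        save_frame("top_per_stratum.tsv", pd.DataFrame(top_rows))
        manifest["stages"]["subgroups"] = {
            "strata": [s.label for s in config.strata],
            "n_drugs": len(drug_list),
        }

        # --- correlate ---------------------------------------------------
        stage = "correlate"
        corr_stats = {}
        for metric in ("absolute_count", "relative_reporting_ratio"):
            if config.correlation_axis == "strata":
                matrix = matrices[metric]
            else:
                matrix = yearly_metric_matrix(background, config.event,
                                              drug_list, metric,
                                              role=config.cohort.required_role)
            pairs, excluded = pairwise_drug_correlation(matrix)
            save_frame(f"correlations_{metric}.tsv", correlations_to_frame(pairs))
            negative = rank_negative_pairs(pairs, config.n_negative_pairs) \
                if pairs else []
            save_frame(f"negative_pairs_{metric}.tsv",
                       correlations_to_frame(negative))
            corr_stats[metric] = {"pairs": len(pairs), "excluded": len(excluded)}
        manifest["stages"]["correlate"] = {
            "axis": config.correlation_axis, **corr_stats}
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        _write_manifest(out_dir, manifest, written)
        raise DataError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    _write_manifest(out_dir, manifest, written)
    return manifest


def _write_manifest(out_dir: Path, manifest: dict[str, Any],
                    written: list[Path]) -> None:
    manifest["outputs"] = {p.name: {"sha256": _checksum(p)} for p in written}
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")
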