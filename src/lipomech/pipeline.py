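"""End-to-end orchestration: synth -> lipidomics -> vld -> md.

A :class:`RunConfig` (YAML-serializable) selects stages and carries every
module default; :func:`run_pipeline` executes the requested stages in order,
writes per-stage CSV outputs and a machine-readable JSON report with the
per-condition summary statistics.  Re-running with the same config and seed
is bit-identical in all outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import lipidomics as lip
from . import md as mdmod
from . import synth
from . import vld as vldmod

__all__ = ["RunConfig", "ConfigError", "run_pipeline", "analyze_cohort", "count_vlds"]

log = logging.getLogger("lipomech")


class ConfigError(ValueError):
    """Raised when a config value violates the schema; names the key."""


@dataclass
class RunConfig:
    """Declarative run description; defaults mirror the module defaults."""

    stages: list[str] = field(default_factory=lambda: ["synth", "lipidomics", "vld", "md"])
    seed: int = 0
    out_dir: str = "lipomech_out"
    conditions: list[str] = field(
        default_factory=lambda: ["NT", "NT_VLD", "NT_cracked", "AA", "DHA"]
    )
    species_presets: list[str] = field(default_factory=lambda: ["NT", "AA", "DHA"])
    # vld analysis
    breakage_threshold: float = vldmod.BREAKAGE_THRESHOLD
    smooth_window: int = 5
    smooth_order: int = 2
    baseline_noise_k: float = 3.0
    run_length: int = 3
    plateau_fraction: float = 0.1
    # lipidomics
    annotation_ppm: float = 5.0
    # md
    angle_bin_width: float = mdmod.DEFAULT_ANGLE_BIN_WIDTH
    fold_angles: bool = False
    extension_step_pct: float = 5.0
    extension_max_pct: float = 25.0
    target_gamma: float = 5.0
    gamma_blocks: int = 5
    # input paths for analysis without the synth stage
    traces_path: str | None = None
    areas_path: str | None = None
    species_path: str | None = None
    pressure_path: str | None = None
    shock_time_s: float = float(synth.SHOCK_FRAME) * synth.FRAME_INTERVAL_S

    def validate(self) -> None:
        known = {"synth", "lipidomics", "vld", "md"}
        for s in self.stages:
            if s not in known:
                raise ConfigError(f"stages: unknown stage {s!r}")
        if self.breakage_threshold <= 0:
            raise ConfigError("breakage_threshold: must be positive")
        if self.annotation_ppm < 0:
            raise ConfigError("annotation_ppm: must be >= 0")
        if self.smooth_window < 3 or self.smooth_window % 2 == 0:
            raise ConfigError("smooth_window: must be odd and >= 3")
        if self.angle_bin_width <= 0:
            raise ConfigError("angle_bin_width: must be positive")
        if self.extension_step_pct <= 0:
            raise ConfigError("extension_step_pct: must be positive")
        if self.extension_max_pct < self.extension_step_pct:
            raise ConfigError("extension_max_pct: must be >= extension_step_pct")
        if self.gamma_blocks < 2:
            raise ConfigError("gamma_blocks: must be >= 2")
        for c in self.conditions:
            if c not in synth.condition_presets():
                raise ConfigError(f"conditions: unknown condition {c!r}")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ConfigError(f"unknown config keys {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def kinetics_params(self) -> vldmod.KineticsParams:
        return vldmod.KineticsParams(
            smooth_window=self.smooth_window,
            smooth_order=self.smooth_order,
            baseline_noise_k=self.baseline_noise_k,
            run_length=self.run_length,
            plateau_fraction=self.plateau_fraction,
        )


def count_vlds(traces515: dict, cell_ids, params: vldmod.KineticsParams | None = None) -> dict[str, int]:
    """Count VLDs per cell as the number of 515 nm ROI traces with a
    detected formation event."""
    params = params or vldmod.KineticsParams()
    counts = {str(c): 0 for c in cell_ids}
    for (cell, _roi, _ch), trace in traces515.items():
        res = vldmod.extract_kinetics(trace, params)
        if res.event_detected:
            counts[cell] = counts.get(cell, 0) + 1
    return counts


def analyze_cohort(
    cohort: synth.Cohort,
    params: vldmod.KineticsParams | None = None,
    breakage_threshold: float = vldmod.BREAKAGE_THRESHOLD,
) -> list[vldmod.CellRecord]:
    """Run the full trace analysis over a cohort: per-VLD kinetics, VLD
    counting by event detection, breakage calls and surface metrics."""
    params = params or vldmod.KineticsParams()
    by_cell: dict[str, list[vldmod.KineticsResult]] = {
        str(c): [] for c in cohort.truth["cell_id"]
    }
    for (cell, _roi, _ch), trace in cohort.traces515.items():
        res = vldmod.extract_kinetics(trace, params)
        if res.event_detected:
            by_cell[cell].append(res)
    records = []
    areas = cohort.areas.groupby("cell_id", sort=False)
    for cell in cohort.truth["cell_id"]:
        cell = str(cell)
        grp = areas.get_group(cell)
        surf = vldmod.surface_metrics(
            grp["time_s"].to_numpy(), grp["area_um2"].to_numpy(), cohort.shock_time
        )
        brk = None
        key = (cell, "cyto", 543)
        if key in cohort.traces543:
            brk = vldmod.classify_breakage(cohort.traces543[key], threshold=breakage_threshold)
        kin = by_cell[cell]
        records.append(
            vldmod.CellRecord(
                cell_id=cell,
                vld_count=len(kin),
                kinetics=kin,
                surface=surf,
                breakage=brk,
            )
        )
    return records


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages; returns the report dict (also written
    to <out_dir>/report.json)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}, "conditions": {}}
    rng_base = np.random.SeedSequence(config.seed)
    stage_seeds = {s: int(c.generate_state(1)[0] % (2**31)) for s, c in
                   zip(["synth", "lipidomics", "vld", "md"], rng_base.spawn(4))}

    cohorts: dict[str, synth.Cohort] = {}
    tables: list[lip.SpeciesTable] = []

    for stage in ["synth", "lipidomics", "vld", "md"]:
        if stage not in config.stages:
            continue
        t_start = time.perf_counter()
        log.info("stage %s starting", stage)
        if stage == "synth":
            presets = synth.condition_presets()
            for j, cond in enumerate(config.conditions):
                cohorts[cond] = synth.gen_cell_cohort(
                    presets[cond], seed=stage_seeds["synth"] + j
                )
                vldmod.write_traces(cohorts[cond].traces515, out / f"traces515_{cond}.csv")
                vldmod.write_traces(cohorts[cond].traces543, out / f"traces543_{cond}.csv")
                cohorts[cond].areas.to_csv(out / f"areas_{cond}.csv", index=False)
                cohorts[cond].truth.to_csv(out / f"truth_{cond}.csv", index=False)
            for j, preset in enumerate(config.species_presets):
                tables.append(
                    synth.gen_species_table(preset, seed=stage_seeds["synth"] + 100 + j)
                )
            lip.write_species_table(tables, out / "species.csv")

        elif stage == "lipidomics":
            if not tables:
                if config.species_path is None:
                    raise ConfigError("species_path: required when synth stage is disabled")
                tables = lip.read_species_table(config.species_path)
            rows, ratio_rows, indexes = [], [], []
            for t in tables:
                tn = t if t.is_normalized() else t.normalize()
                ix = lip.db_index(tn)
                indexes.append((t.sample_label, ix))
                rows.append({"sample": t.sample_label, "DB0": ix.db0, "DB1": ix.db1,
                             "DB2": ix.db2, "DBgt2": ix.dbgt2})
                ratio_rows.append({"sample": t.sample_label, "dha_aa_ratio": lip.dha_aa_ratio(tn)})
            pd.DataFrame(rows).to_csv(out / "db_index.csv", index=False)
            pd.DataFrame(ratio_rows).to_csv(out / "ratios.csv", index=False)
            if len(indexes) >= 2:
                pca = lip.pca_db(indexes)
                pca.scores.to_csv(out / "pca_scores.csv")
                pd.DataFrame({"component": pca.scores.columns,
                              "explained_pct": pca.explained_pct}).to_csv(
                    out / "pca.csv", index=False)
                report["stages"]["lipidomics"] = {
                    "explained_pct": [float(v) for v in pca.explained_pct]
                }

        elif stage == "vld":
            if not cohorts:
                raise ConfigError(
                    "stages: vld stage without synth requires traces via the library API"
                )
            summary_frames = []
            for cond, cohort in cohorts.items():
                records = analyze_cohort(
                    cohort, config.kinetics_params(), config.breakage_threshold
                )
                summary = vldmod.summarize_condition(records, cond)
                summary_frames.append(summary)
                counts = [r.vld_count for r in records]
                dist = vldmod.bin_vld_counts(counts)
                report["conditions"][cond] = {
                    "summary": {
                        r.quantity: {"mean": r.mean, "sem": r.sem, "n": int(r.n)}
                        for r in summary.itertuples()
                    },
                    "count_distribution_pct": dist,
                }
                pd.DataFrame([dist]).to_csv(out / f"counts_{cond}.csv", index=False)
            pd.concat(summary_frames, ignore_index=True).to_csv(
                out / "condition_summary.csv", index=False
            )

        elif stage == "md":
            plan = mdmod.plan_extensions(
                (30.0, 30.0), config.extension_step_pct, config.extension_max_pct
            )
            pd.DataFrame(
                {"level_pct": plan.levels,
                 "Lx_nm": [t[0] for t in plan.targets],
                 "Ly_nm": [t[1] for t in plan.targets],
                 "area_ratio": [plan.area_ratio(e) for e in plan.levels]}
            ).to_csv(out / "extension_plan.csv", index=False)
            if config.pressure_path is not None:
                series = mdmod.PressureSeries.from_csv(config.pressure_path)
            else:
                series = synth.gen_pressure_series(
                    config.target_gamma, seed=stage_seeds["md"]
                )
            gamma = mdmod.surface_tension(series, n_blocks=config.gamma_blocks)
            report["stages"]["md"] = {
                "gamma_mN_per_m": gamma.gamma,
                "gamma_stderr": gamma.stderr,
                "convention": gamma.convention,
            }
            frames, topo = synth.gen_trajectory(
                angle_law=("normal", 30.0, 8.0), seed=stage_seeds["md"]
            )
            dist = mdmod.angle_distribution(
                frames, topo, bin_width=config.angle_bin_width, fold=config.fold_angles
            )
            pd.DataFrame(
                {"angle_deg": dist.bin_centers(), "probability": dist.probabilities}
            ).to_csv(out / "angle_distribution.csv", index=False)

        report["stages"].setdefault(stage, {})
        report["stages"][stage]["elapsed_s"] = round(time.perf_counter() - t_start, 3)
        log.info("stage %s done in %.2fs", stage, report["stages"][stage]["elapsed_s"])

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
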