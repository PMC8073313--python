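"""Condition-statistic recovery: regenerate a packaged condition and measure
it back through the analysis pipeline.

This is the round-trip the synthetic cohorts are calibrated for: generate a
cohort at the packaged condition defaults, run the trace/area analysis, and
report the cohort-level statistics (mean VLD count, kinetic means, surface
means, count-bin fractions) that a study of the corresponding condition
would tabulate.
"""

from __future__ import annotations

import numpy as np

from .pipeline import analyze_cohort
from .synth import condition_presets, gen_cell_cohort
from .vld import bin_vld_counts

__all__ = ["recover_condition", "child_seed"]


def child_seed(master_seed: int, label: str, n_cells: int | None) -> int:
    """Deterministic per-cohort child seed derived from a master seed.

    Each (condition, cohort size) pair gets an independent stream so that
    cohorts generated in the same session do not share raw draws.
    """
    key = [int(master_seed)] + [ord(ch) for ch in label] + [0 if n_cells is None else int(n_cells)]
    return int(np.random.SeedSequence(key).generate_state(1)[0] % (2**31))


def recover_condition(label: str, seed: int, n_cells: int | None = None) -> dict[str, float]:
    """Generate the labelled condition at its packaged defaults and recover
    its cohort statistics with the analysis pipeline.

    Returns a dict with the recovered means (vld_count, t_vmax_s, vmax_per_s,
    t0_s, plateau, surface_increase_pct, t_surface_max_s, breakage_fraction),
    the count-bin percentages, and the cohort size ``n``.
    """
    params = condition_presets()[label]
    cohort = gen_cell_cohort(params, seed=seed, n_cells=n_cells)
    records = analyze_cohort(cohort)

    counts = np.array([r.vld_count for r in records])
    kin = [k for r in records for k in r.kinetics if k.event_detected]
    bins = bin_vld_counts(counts)
    out = {
        "n": len(records),
        "n_vld_traces": len(kin),
        "vld_count": float(counts.mean()),
        "surface_increase_pct": float(
            np.mean([r.surface.surface_increase_pct for r in records])
        ),
        "t_surface_max_s": float(np.mean([r.surface.t_surface_max for r in records])),
        "breakage_fraction": float(
            np.mean([1.0 if (r.breakage and r.breakage.broken) else 0.0 for r in records])
        ),
        "pct_zero": bins["0"],
        "pct_1_5": bins["1-5"],
        "pct_6_10": bins["6-10"],
        "pct_gt10": bins[">10"],
    }
    for name, attr in (
        ("t0_s", "t0"),
        ("vmax_per_s", "vmax"),
        ("t_vmax_s", "t_vmax"),
        ("plateau", "plateau"),
    ):
        out[name] = float(np.mean([getattr(k, attr) for k in kin])) if kin else float("nan")
    return out
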