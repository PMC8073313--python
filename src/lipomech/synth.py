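"""Synthetic inputs with known ground truth.

Every input the analysis modules consume can be generated here, with the
generating parameters attached, so each downstream operation has an oracle.
Condition presets are calibrated to the published osmotic-downshock
statistics of C2C12 myoblasts grown untreated (NT) or supplemented with
arachidonic acid (AA) or docosahexaenoic acid (DHA):

=============  ======  ==============  =============  ==============
condition      n       VLDs/cell       tVmax (s)      Vmax (1/s)
=============  ======  ==============  =============  ==============
NT             152     3.8 +- 0.3      622 +- 21      0.016 +- 0.001
AA             103     4.2 +- 0.4      423 +- 25      0.018 +- 0.002
DHA            148     11.4 +- 0.7     301 +- 10      0.024 +- 0.002
=============  ======  ==============  =============  ==============

plus the surface assay (NT VLD-forming: t_surface_max 227.3 +- 14.0 s,
n=47; NT cracked: surface increase 19.5 +- 4.0 %, n=58; AA: 12.6 +- 2.8 %,
n=96; DHA: t_surface_max 137.7 +- 6.6 s, n=88), a 34 % zero-VLD fraction in
NT cells, a 48 % 1-5-VLD fraction in AA cells and a ~50 % >10-VLD fraction
in DHA cells.  The quoted uncertainties are SEMs; per-cell spreads are
SEM*sqrt(n), capped at a coefficient of variation of 0.6 (see
docs/methods.md for why), and positive quantities are drawn from lognormals
with exactly the target mean.

VLD counts follow a hurdle (zero-truncated negative binomial) law whose
zero mass is the zero-cell fraction itself and whose dispersion was
calibrated once against the published count-bin fractions.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .imaging import ImageStack
from .lipidomics import SpeciesID, SpeciesTable, PeakList, adduct_mz, parse_species_name, pc_monoisotopic_mass
from .md import ChainTopology, PressureSeries, TrajectoryFrame
from .vld import FluorescenceTrace

__all__ = [
    "ConditionParams",
    "Cohort",
    "condition_presets",
    "species_presets",
    "gen_species_table",
    "gen_cell_cohort",
    "gen_image_stack",
    "gen_trajectory",
    "gen_pressure_series",
    "sample_law",
]

N_FRAMES = 300
FRAME_INTERVAL_S = 5.0
SHOCK_FRAME = 10  # shock onset after 10 baseline frames (50 s)
TRACE_NOISE_SD = 0.02  # relative fluorescence units on the 515 nm ROI mean
AREA_NOISE_FRAC = 0.003  # fractional noise on manual-outline cross sections
BASELINE_F = 100.0  # arbitrary raw-fluorescence baseline


@dataclass(frozen=True)
class ConditionParams:
    """Per-condition generative parameters (means/SDs of the per-cell laws).

    Times are seconds after shock onset; Vmax is 1/s; surface increase is %.
    ``vld_count_zero_inflation`` is the total zero-count mass of the hurdle
    count law and ``vld_count_dispersion`` the NB shape r of its positive
    branch.  ``t0_mean/sd`` describe the emergent fluorescence-appearance
    time (the trace model ties t0 to tVmax and Vmax; these fields document
    the expected scale and are validated against tVmax).
    """

    label: str
    n_cells: int
    vld_count_mean: float
    vld_count_zero_inflation: float
    vld_count_dispersion: float
    t0_mean: float
    t0_sd: float
    tvmax_mean: float
    tvmax_sd: float
    vmax_mean: float
    vmax_sd: float
    plateau_mean: float
    plateau_sd: float
    surface_increase_mean: float
    surface_increase_sd: float
    t_surface_max_mean: float
    t_surface_max_sd: float
    breakage_prob: float
    t_breakage_mean: float
    t_breakage_sd: float

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not 0.0 <= self.vld_count_zero_inflation <= 1.0:
            raise ValueError("vld_count_zero_inflation must be in [0, 1]")
        if not 0.0 <= self.breakage_prob <= 1.0:
            raise ValueError("breakage_prob must be in [0, 1]")
        for name in ("tvmax_mean", "vmax_mean", "plateau_mean", "t_surface_max_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.t0_mean >= self.tvmax_mean:
            raise ValueError(
                f"inconsistent params: t0_mean {self.t0_mean} >= tvmax_mean {self.tvmax_mean}"
            )


def _preset(label, n, count_mean, zero, r, t0, tvmax, tvmax_sem, vmax, vmax_sem,
            surf, surf_sem, tsurf, tsurf_sem, brk, tbrk, tbrk_sd, n_sem=None):
    """SDs are SEM*sqrt(n) capped at CV 0.6; unprinted SDs passed directly."""
    n_sem = n_sem or n

    def sd(mean, sem):
        return min(sem * math.sqrt(n_sem), 0.6 * mean)

    return ConditionParams(
        label=label,
        n_cells=n,
        vld_count_mean=count_mean,
        vld_count_zero_inflation=zero,
        vld_count_dispersion=r,
        t0_mean=t0,
        t0_sd=0.4 * t0,
        tvmax_mean=tvmax,
        tvmax_sd=sd(tvmax, tvmax_sem),
        vmax_mean=vmax,
        vmax_sd=sd(vmax, vmax_sem),
        plateau_mean=2.0,
        plateau_sd=0.6,
        surface_increase_mean=surf,
        surface_increase_sd=sd(surf, surf_sem),
        t_surface_max_mean=tsurf,
        t_surface_max_sd=sd(tsurf, tsurf_sem),
        breakage_prob=brk,
        t_breakage_mean=tbrk,
        t_breakage_sd=tbrk_sd,
    )


def condition_presets() -> dict[str, ConditionParams]:
    """Packaged condition defaults (see the module docstring for the sources).

    "NT" is the whole non-treated population (counts and kinetics assays);
    "NT_VLD" / "NT_cracked" are its VLD-forming and breaking subpopulations
    used in the surface assay.  Unprinted quantities (surface increase for
    NT_VLD/DHA, t_surface_max for AA/NT_cracked, breakage rates and times,
    plateau) are fixed at plausible values inside the printed 12.6-19.5 %
    surface bracket and the published event ordering.
    """
    return {
        "NT": _preset("NT", 152, 3.8, 0.34, 2.0, 420.0, 622.0, 21.0, 0.016, 0.001,
                      15.0, 2.0, 227.3, 14.0, 0.55, 680.0, 150.0, n_sem=152),
        "NT_VLD": _preset("NT_VLD", 47, 5.8, 0.0, 2.0, 420.0, 622.0, 21.0, 0.016, 0.001,
                          15.0, 2.0, 227.3, 14.0, 0.0, 680.0, 150.0, n_sem=47),
        "NT_cracked": _preset("NT_cracked", 58, 0.0, 1.0, 2.0, 420.0, 622.0, 21.0,
                              0.016, 0.001, 19.5, 4.0, 180.0, 12.0, 1.0, 680.0, 150.0,
                              n_sem=58),
        "AA": _preset("AA", 103, 4.2, 0.20, 4.0, 290.0, 423.0, 25.0, 0.018, 0.002,
                      12.6, 2.8, 180.0, 10.0, 0.15, 600.0, 140.0, n_sem=103),
        "DHA": _preset("DHA", 148, 11.4, 0.03, 5.0, 200.0, 301.0, 10.0, 0.024, 0.002,
                       17.5, 2.0, 137.7, 6.6, 0.08, 550.0, 130.0, n_sem=148),
    }


# ---------------------------------------------------------------------------
# elementary samplers


def _lognormal(rng: np.random.Generator, mean: float, sd: float, size=None):
    """Lognormal draws with the requested arithmetic mean and SD."""
    if mean <= 0:
        raise ValueError("lognormal mean must be positive")
    if sd <= 0:
        return np.full(size, mean) if size is not None else mean
    s2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - s2 / 2.0
    return rng.lognormal(mu, math.sqrt(s2), size=size)


def _ztnb_mu(r: float, mean_positive: float) -> float:
    """NB mean mu such that the zero-truncated NB has the given mean."""

    def f(mu):
        p0 = stats.nbinom.pmf(0, r, r / (r + mu))
        return mu / (1.0 - p0) - mean_positive

    return optimize.brentq(f, 1e-9, max(10.0 * mean_positive, 1.0))


def _sample_counts(rng: np.random.Generator, params: ConditionParams, n: int) -> np.ndarray:
    """Hurdle counts: zero with the stated mass, else zero-truncated NB."""
    pi0 = params.vld_count_zero_inflation
    counts = np.zeros(n, dtype=int)
    if pi0 >= 1.0 or params.vld_count_mean <= 0:
        return counts
    positive = rng.random(n) >= pi0
    n_pos = int(positive.sum())
    if n_pos == 0:
        return counts
    r = params.vld_count_dispersion
    mu = _ztnb_mu(r, params.vld_count_mean / (1.0 - pi0))
    p = r / (r + mu)
    draws = np.empty(n_pos, dtype=int)
    remaining = np.arange(n_pos)
    while remaining.size:  # rejection-sample the truncation
        d = rng.negative_binomial(r, p, size=remaining.size)
        draws[remaining] = d
        remaining = remaining[d == 0]
    counts[positive] = draws
    return counts


def sample_law(law, rng: np.random.Generator, size: int) -> np.ndarray:
    """Sample an imposed law: a callable(rng, size), or one of
    ("delta", v), ("uniform", lo, hi), ("normal", mean, sd),
    ("mixture", [(weight, law), ...])."""
    if callable(law):
        return np.asarray(law(rng, size), dtype=float)
    kind = law[0]
    if kind == "delta":
        return np.full(size, float(law[1]))
    if kind == "uniform":
        return rng.uniform(law[1], law[2], size)
    if kind == "normal":
        return rng.normal(law[1], law[2], size)
    if kind == "mixture":
        comps = law[1]
        weights = np.array([w for w, _ in comps], dtype=float)
        weights /= weights.sum()
        which = rng.choice(len(comps), size=size, p=weights)
        out = np.empty(size)
        for i, (_, sub) in enumerate(comps):
            sel = which == i
            if sel.any():
                out[sel] = sample_law(sub, rng, int(sel.sum()))
        return out
    raise ValueError(f"unknown law {law!r}")


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def _shifted_logistic(t_rel, amp: float, k: float, tm: float) -> np.ndarray:
    """Logistic fluorescence rise pinned to zero at shock onset.

    A plain logistic A*sigma(k(t-tm)) is already above zero at t=0 when k*tm
    is small, which would put an unphysical step at the shock; shifting and
    rescaling, A*(sigma(k(t-tm)) - sigma(-k*tm))/(1 - sigma(-k*tm)), starts
    at exactly 0, keeps the inflection at tm and still plateaus at A.
    """
    s0 = float(_sigmoid(np.array(-k * tm)))
    rel = amp * (_sigmoid(k * (t_rel - tm)) - s0) / (1.0 - s0)
    rel[t_rel < 0] = 0.0
    return rel


def _solve_logistic_rate(amp: float, vmax: float, tm: float) -> float:
    """Rate k such that the shifted logistic's peak slope equals vmax.

    The shifted logistic's maximal slope is A*k/4/(1 - sigma(-k*tm)), so the
    naive k = 4*vmax/A overshoots when k*tm is small; solve the monotone
    scalar equation instead.
    """
    def realized(k):
        s0 = float(_sigmoid(np.array(-k * tm)))
        return amp * k / 4.0 / (1.0 - s0)

    k_hi = 4.0 * vmax / amp
    if realized(k_hi) <= vmax * (1.0 + 1e-12):
        return k_hi  # sigma(-k*tm) ~ 0: the plain logistic is already exact
    return float(optimize.brentq(lambda k: realized(k) - vmax, 1e-12, k_hi))


def _logistic_crossing(amp: float, k: float, tm: float, thr: float) -> float:
    """Time at which the noiseless shifted logistic first exceeds thr."""
    s0 = float(_sigmoid(np.array(-k * tm)))
    s = s0 + thr * (1.0 - s0) / amp
    return tm + math.log(s / (1.0 - s)) / k


# ---------------------------------------------------------------------------
# cell cohorts


@dataclass
class Cohort:
    """A generated cohort: traces, area series and the generating truth.

    ``traces515``/``traces543`` are keyed (cell_id, roi_id, channel) as the
    trace reader returns them; ``truth`` has one row per cell (count,
    breakage, surface parameters) and ``truth_vlds`` one row per VLD (tm,
    vmax, plateau, t0).
    """

    label: str
    shock_time: float
    traces515: dict
    traces543: dict
    areas: pd.DataFrame  # cell_id, time_s, area_um2
    truth: pd.DataFrame
    truth_vlds: pd.DataFrame
    params: ConditionParams


def gen_cell_cohort(
    params: ConditionParams,
    seed: int,
    n_cells: int | None = None,
    n_frames: int = N_FRAMES,
    frame_interval: float = FRAME_INTERVAL_S,
    shock_frame: int = SHOCK_FRAME,
    noise_sd: float = TRACE_NOISE_SD,
    area_noise_frac: float = AREA_NOISE_FRAC,
) -> Cohort:
    """Generate one condition's cohort of cells.

    Per cell: a VLD count from the hurdle law; per VLD a 515 nm logistic
    trace A/(1+exp(-k(t-tm))) with tm and Vmax drawn from the condition laws
    and k = 4*Vmax/A; a 543 nm trace that steps above the breakage threshold
    at the drawn t_breakage for breaking cells and stays low otherwise; and a
    cross-section area series rising to the drawn maximum at the drawn
    t_surface_max and relaxing after it.
    """
    rng = np.random.default_rng(seed)
    n = n_cells if n_cells is not None else params.n_cells
    times = np.arange(n_frames) * frame_interval
    shock_time = shock_frame * frame_interval
    t_rel = times - shock_time

    counts = _sample_counts(rng, params, n)
    broken = rng.random(n) < params.breakage_prob

    traces515: dict = {}
    traces543: dict = {}
    area_frames = []
    truth_rows = []
    vld_rows = []

    for i in range(n):
        cell = f"{params.label}_c{i:04d}"
        # --- 515 nm: one logistic trace per VLD -------------------------
        for v in range(counts[i]):
            tm = float(_lognormal(rng, params.tvmax_mean, params.tvmax_sd))
            vmax = float(_lognormal(rng, params.vmax_mean, params.vmax_sd))
            amp = float(_lognormal(rng, params.plateau_mean, params.plateau_sd))
            k = _solve_logistic_rate(amp, vmax, tm)
            rel = _shifted_logistic(t_rel, amp, k, tm)
            raw = BASELINE_F * (1.0 + rel) + rng.normal(0.0, noise_sd * BASELINE_F, n_frames)
            raw = np.clip(raw, 0.0, None)
            roi = f"v{v:02d}"
            traces515[(cell, roi, 515)] = FluorescenceTrace(
                times=times, values=raw, channel=515, shock_time=shock_time
            )
            # analytic threshold-crossing time of the noiseless trace
            # (undefined when the generator adds no noise: no noise floor)
            thr = 3.0 * noise_sd
            t0_true = _logistic_crossing(amp, k, tm, thr) if 0.0 < thr < amp else math.nan
            vld_rows.append(
                {"cell_id": cell, "roi_id": roi, "tm": tm, "vmax": vmax,
                 "plateau": amp, "t0": t0_true}
            )

        # --- 543 nm: breakage step or low-level entry -------------------
        if broken[i]:
            tb = float(_lognormal(rng, params.t_breakage_mean, params.t_breakage_sd))
            step = max(float(rng.normal(12.0, 1.0)), 10.5)
            rel543 = np.zeros(n_frames)
            after = t_rel >= tb
            rel543[after] = step + 3.0 * (1.0 - np.exp(-(t_rel[after] - tb) / 15.0))
        else:
            tb = math.nan
            level = float(rng.uniform(0.5, 4.0))  # sub-threshold dye entry
            rel543 = np.where(t_rel >= 0, level * (1.0 - np.exp(-np.clip(t_rel, 0, None) / 300.0)), 0.0)
        raw543 = BASELINE_F * (1.0 + rel543) + rng.normal(0.0, noise_sd * BASELINE_F, n_frames)
        traces543[(cell, "cyto", 543)] = FluorescenceTrace(
            times=times, values=np.clip(raw543, 0.0, None), channel=543, shock_time=shock_time
        )

        # --- cross-section area series ----------------------------------
        p = float(_lognormal(rng, params.surface_increase_mean, params.surface_increase_sd)) / 100.0
        t_peak = float(_lognormal(rng, params.t_surface_max_mean, params.t_surface_max_sd))
        a0 = float(_lognormal(rng, 500.0, 100.0))  # um^2 cross section
        s = np.where(t_rel > 0, (t_rel / t_peak) * np.exp(1.0 - t_rel / t_peak), 0.0)
        area = a0 * (1.0 + p * s) * (1.0 + rng.normal(0.0, area_noise_frac, n_frames))
        area_frames.append(pd.DataFrame({"cell_id": cell, "time_s": times, "area_um2": area}))

        truth_rows.append(
            {
                "cell_id": cell,
                "vld_count": int(counts[i]),
                "broken": bool(broken[i]),
                "t_breakage": tb,
                "surface_increase_pct": p * 100.0,
                "t_surface_max": t_peak,
                "area0_um2": a0,
            }
        )

    return Cohort(
        label=params.label,
        shock_time=shock_time,
        traces515=traces515,
        traces543=traces543,
        areas=pd.concat(area_frames, ignore_index=True),
        truth=pd.DataFrame(truth_rows),
        truth_vlds=pd.DataFrame(
            vld_rows, columns=["cell_id", "roi_id", "tm", "vmax", "plateau", "t0"]
        ),
        params=params,
    )


# ---------------------------------------------------------------------------
# species tables


def species_presets() -> dict[str, dict[str, float]]:
    """PC species profiles (percent of class) emulating organ and culture
    signatures: DHA-supplemented cells and muscle/heart are dominated by
    PC 38:6, the brain by PC 34:1, the lung by PC 32:0, the pancreas by
    DB=2 species; untreated myoblasts carry almost no polyunsaturated PC."""
    presets = {
        "muscle": {"PC 32:0": 4, "PC 32:1": 5, "PC 34:1": 8, "PC 34:2": 9, "PC 36:1": 3,
                   "PC 36:2": 7, "PC 36:4": 9, "PC 38:4": 7, "PC 38:6": 32, "PC 40:6": 16},
        "heart": {"PC 32:0": 5, "PC 32:1": 4, "PC 34:1": 9, "PC 34:2": 10, "PC 36:1": 4,
                  "PC 36:2": 9, "PC 36:4": 10, "PC 38:4": 10, "PC 38:6": 27, "PC 40:6": 12},
        "brain": {"PC 32:0": 15, "PC 32:1": 10, "PC 34:1": 32, "PC 34:2": 7, "PC 36:1": 12,
                  "PC 36:2": 6, "PC 36:4": 8, "PC 38:4": 6, "PC 38:6": 3, "PC 40:6": 1},
        "lung": {"PC 32:0": 38, "PC 30:0": 8, "PC 32:1": 12, "PC 34:1": 14, "PC 34:2": 9,
                 "PC 36:2": 6, "PC 36:4": 7, "PC 38:4": 5, "PC 38:6": 1},
        "pancreas": {"PC 32:0": 8, "PC 32:1": 6, "PC 34:1": 12, "PC 34:2": 22, "PC 36:2": 24,
                     "PC 36:4": 12, "PC 38:4": 10, "PC 38:6": 4, "PC 40:6": 2},
        "liver": {"PC 32:0": 7, "PC 32:1": 5, "PC 34:1": 11, "PC 34:2": 16, "PC 36:2": 18,
                  "PC 36:4": 12, "PC 38:4": 16, "PC 38:6": 11, "PC 40:6": 4},
        "NT": {"PC 32:0": 10, "PC 32:1": 18, "PC 34:1": 30, "PC 34:2": 16, "PC 36:1": 8,
               "PC 36:2": 14, "PC 36:4": 1.5, "PC 38:4": 1.5, "PC 38:6": 1},
        "AA": {"PC 32:0": 8, "PC 32:1": 8, "PC 34:1": 16, "PC 34:2": 12, "PC 36:1": 5,
               "PC 36:2": 10, "PC 36:4": 18, "PC 38:4": 20, "PC 40:4": 1, "PC 38:6": 2},
        "DHA": {"PC 32:0": 8, "PC 32:1": 8, "PC 34:1": 14, "PC 34:2": 10, "PC 36:1": 4,
                "PC 36:2": 8, "PC 36:4": 4, "PC 38:4": 4, "PC 36:6": 4, "PC 38:6": 28,
                "PC 40:6": 8},
    }
    return presets


def gen_species_table(
    preset: str,
    jitter: float = 0.05,
    seed: int = 0,
    with_peaks: bool = False,
    mz_jitter_ppm: float = 0.5,
):
    """Generate a normalized PC species table for one organ/condition preset.

    ``jitter`` applies multiplicative lognormal noise to the abundances
    before renormalization.  With ``with_peaks`` a matching [M+H]+ peak list
    (m/z perturbed by ``mz_jitter_ppm``) is returned as well.
    """
    presets = species_presets()
    if preset not in presets:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(presets)}")
    rng = np.random.default_rng(seed)
    names = list(presets[preset])
    ids = [parse_species_name(nm) for nm in names]
    pct = np.array([presets[preset][nm] for nm in names], dtype=float)
    if jitter > 0:
        pct = pct * rng.lognormal(0.0, jitter, pct.size)
    pct = pct / pct.sum() * 100.0
    entries = pd.DataFrame(
        {
            "lipid_class": [s.lipid_class for s in ids],
            "total_carbons": [s.total_carbons for s in ids],
            "double_bonds": [s.double_bonds for s in ids],
            "abundance_pct": pct,
        }
    )
    table = SpeciesTable(preset, entries)
    if not with_peaks:
        return table
    mz = np.array([adduct_mz(pc_monoisotopic_mass(s)) for s in ids])
    mz = mz * (1.0 + rng.normal(0.0, mz_jitter_ppm * 1e-6, mz.size))
    peaks = PeakList(
        pd.DataFrame({"mz": mz, "intensity": pct * 1e4}), ion_mode="positive"
    )
    return table, peaks


# ---------------------------------------------------------------------------
# image stacks


def gen_image_stack(
    vld_counts,
    seed: int,
    tile_px: int = 128,
    cell_radius_px: int = 56,
    n_frames: int = 12,
    pixel_size: float = 0.13,
    frame_interval: float = FRAME_INTERVAL_S,
    snr: float = 10.0,
    noise_sd: float = 2.0,
    background: float = 20.0,
    spot_d_min_um: float = 1.2,
    spot_d_max_um: float = 2.0,
):
    """Render cells as disks on a tile grid with Gaussian VLD spots.

    Spot amplitude = snr * the background noise floor (Gaussian read noise
    plus the Poisson shot noise of the cell background); apparent spot
    diameters are drawn from [spot_d_min_um, spot_d_max_um], inside the 1-3
    um band the detector expects.  Returns (stack, label mask, truth
    DataFrame of spot centers).  Raises when a cell's spots cannot be placed
    without overlap.
    """
    rng = np.random.default_rng(seed)
    vld_counts = list(int(c) for c in vld_counts)
    n_cells = len(vld_counts)
    side = math.ceil(math.sqrt(n_cells))
    h = w = side * tile_px
    frames = np.zeros((n_frames, h, w))
    labels = np.zeros((h, w), dtype=int)
    yy, xx = np.mgrid[0:h, 0:w]
    amp = snr * math.sqrt(noise_sd**2 + background)
    sig_min = spot_d_min_um / 2.0 / math.sqrt(2.0) / pixel_size
    sig_max = spot_d_max_um / 2.0 / math.sqrt(2.0) / pixel_size
    truth_rows = []
    for i, count in enumerate(vld_counts):
        cy = (i // side) * tile_px + tile_px // 2
        cx = (i % side) * tile_px + tile_px // 2
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= cell_radius_px**2
        labels[disk] = i + 1
        frames[:, disk] += background
        centers: list[tuple[float, float, float]] = []  # (row, col, sigma)
        for s in range(count):
            sigma = rng.uniform(sig_min, sig_max)
            placed = False
            for _ in range(500):
                r_pos = rng.uniform(0, cell_radius_px - 2.5 * sigma)
                theta = rng.uniform(0, 2 * math.pi)
                py = cy + r_pos * math.sin(theta)
                px = cx + r_pos * math.cos(theta)
                if all(
                    (py - q[0]) ** 2 + (px - q[1]) ** 2 > (2.2 * (sigma + q[2])) ** 2
                    for q in centers
                ):
                    placed = True
                    break
            if not placed:
                raise ValueError(
                    f"cannot place {count} non-overlapping spots in cell {i}"
                )
            centers.append((py, px, sigma))
            spot = amp * np.exp(-((yy - py) ** 2 + (xx - px) ** 2) / (2 * sigma**2))
            frames += spot[None, :, :]
            truth_rows.append(
                {"cell": i + 1, "row": py, "col": px, "sigma_px": sigma}
            )
    # Poisson-Gaussian pixel noise
    frames = rng.poisson(np.clip(frames, 0, None)).astype(float)
    frames += rng.normal(0.0, noise_sd, frames.shape)
    stack = ImageStack(
        frames=frames, pixel_size=pixel_size, frame_interval=frame_interval, channel=515
    )
    truth = pd.DataFrame(truth_rows, columns=["cell", "row", "col", "sigma_px"])
    return stack, labels, truth


# ---------------------------------------------------------------------------
# trajectories and pressure series


def gen_trajectory(
    n_lipids: int = 64,
    n_beads: int = 6,
    angle_law=("delta", 30.0),
    dist_law=("delta", 1.5),
    box: tuple[float, float, float] = (30.0, 30.0, 10.0),
    n_frames: int = 5,
    seed: int = 0,
) -> tuple[list[TrajectoryFrame], ChainTopology]:
    """Two mirrored leaflets of single-chain lipids whose first-to-last
    vectors follow the imposed angle law (upper leaflet; the lower leaflet is
    mirrored through the membrane plane) and distance law."""
    if n_lipids % 2:
        raise ValueError("n_lipids must be even (two equal leaflets)")
    if n_beads < 2:
        raise ValueError("need >= 2 beads per chain")
    rng = np.random.default_rng(seed)
    per_leaflet = n_lipids // 2
    side = math.ceil(math.sqrt(per_leaflet))
    lx, ly, lz = box
    margin = 2.0
    gx = np.linspace(margin, lx - margin, side)
    gy = np.linspace(margin, ly - margin, side)

    topo_rows = []
    bead = 0
    for lip in range(n_lipids):
        leaflet = "upper" if lip < per_leaflet else "lower"
        for order in range(n_beads):
            topo_rows.append(
                {
                    "lipid_id": lip,
                    "chain_id": 0,
                    "sn_position": "sn2",
                    "leaflet": leaflet,
                    "bead_order": order,
                    "bead_index": bead,
                }
            )
            bead += 1
    topology = ChainTopology(pd.DataFrame(topo_rows))

    frames = []
    for f in range(n_frames):
        coords = np.zeros((n_lipids * n_beads, 3))
        angles = sample_law(angle_law, rng, per_leaflet)
        dists_u = sample_law(dist_law, rng, per_leaflet)
        dists_l = sample_law(dist_law, rng, per_leaflet)
        if np.any(np.concatenate([dists_u, dists_l]) > min(box) / 2.0):
            raise ValueError("imposed chain length exceeds half the box")
        for lip in range(n_lipids):
            upper = lip < per_leaflet
            j = lip if upper else lip - per_leaflet
            alpha = angles[j] if upper else 180.0 - angles[j]
            d = dists_u[j] if upper else dists_l[j]
            phi = rng.uniform(0.0, 2.0 * math.pi)
            a = math.radians(alpha)
            v = d * np.array(
                [math.sin(a) * math.cos(phi), math.sin(a) * math.sin(phi), math.cos(a)]
            )
            z0 = 0.3 * lz if upper else 0.7 * lz
            first = np.array([gx[j % side], gy[j // side], z0])
            for order in range(n_beads):
                coords[lip * n_beads + order] = first + v * (order / (n_beads - 1))
        frames.append(TrajectoryFrame(coordinates=coords, box=box, time=float(f)))
    return frames, topology


def gen_pressure_series(
    target_gamma: float,
    lz: float = 10.0,
    noise_sd: float = 50.0,
    n: int = 2000,
    seed: int = 0,
    p0: float = 1.0,
    dt_ns: float = 0.1,
) -> PressureSeries:
    """Pressure-tensor series whose expected Kirkwood-Irving surface tension
    (per interface, mN/m) equals ``target_gamma``; Gaussian fluctuations of
    ``noise_sd`` bar on each diagonal component."""
    if n < 2:
        raise ValueError("need n >= 2")
    rng = np.random.default_rng(seed)
    # gamma = 0.1 * (lz/2) * dP  =>  dP = gamma / (0.05 * lz)
    dp = target_gamma / (0.05 * lz)
    times = np.arange(n) * dt_ns
    pzz = p0 + rng.normal(0.0, noise_sd, n)
    pxx = p0 - dp + rng.normal(0.0, noise_sd, n)
    pyy = p0 - dp + rng.normal(0.0, noise_sd, n)
    return PressureSeries(times=times, pxx=pxx, pyy=pyy, pzz=pzz, lz=np.full(n, lz))
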