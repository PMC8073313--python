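"""Vacuole-like dilation (VLD) kinetics and cell-breakage analysis.

Under an osmotic downshock, muscle cells labelled with the styryl dye FM1-43
(fluorescent at 515 nm in the outer membrane leaflet) form vacuole-like
dilations — passive membrane invaginations that buffer excess membrane area.
Per-ROI fluorescence traces are normalized to their pre-shock baseline; from
each normalized trace the module extracts the formation kinetics (t0: time to
fluorescence appearance, Vmax: maximal rate of relative-fluorescence
increase, tVmax: the time of Vmax, and the plateau amplitude).  When the
membrane ruptures the dye floods the cytoplasm and the 543 nm signal jumps:
a relative intensity of 10 or more is called cell breakage.  Cross-section
area series yield the percent surface increase and its time, valid because
adherent myoblasts approximate hemispheres whose surface scales with the
cross-section area.

All kinetic times are reported relative to shock onset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

__all__ = [
    "FluorescenceTrace",
    "KineticsParams",
    "KineticsResult",
    "BreakageCall",
    "SurfaceMetrics",
    "CellRecord",
    "TraceError",
    "normalize_trace",
    "extract_kinetics",
    "classify_breakage",
    "bin_vld_counts",
    "surface_metrics",
    "summarize_condition",
    "read_traces",
    "write_traces",
    "VLD_COUNT_BINS",
]

BREAKAGE_THRESHOLD = 10.0  # relative fluorescence calling bona fide breakage


class TraceError(ValueError):
    """Raised for invalid traces or parameters."""


@dataclass
class FluorescenceTrace:
    """A per-ROI fluorescence time series.

    times are seconds on the acquisition clock; ``shock_time`` marks the
    osmotic-downshock onset on the same clock.  ``normalized`` marks values
    already expressed as relative fluorescence.
    """

    times: np.ndarray
    values: np.ndarray
    channel: int = 515
    shock_time: float = 0.0
    normalized: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise TraceError("times and values must be 1-D arrays of equal length")
        if np.any(np.diff(self.times) <= 0):
            raise TraceError("times must be strictly increasing")
        if not self.normalized and np.any(self.values < 0):
            raise TraceError("raw fluorescence values must be >= 0")

    @property
    def pre_shock(self) -> np.ndarray:
        return self.values[self.times < self.shock_time]

    def n_pre_shock(self) -> int:
        return int(np.sum(self.times < self.shock_time))


def normalize_trace(trace: FluorescenceTrace, mode: str = "delta_f_over_f0") -> FluorescenceTrace:
    """Express a trace as relative fluorescence.

    ``delta_f_over_f0`` (default, (F-F0)/F0) matches the maximal-relative-
    fluorescence convention; ``f_over_f0`` is provided because some displays
    plot F/F0.  F0 is the mean of the pre-shock samples (>= 3 required).
    """
    if trace.normalized:
        return trace
    if trace.n_pre_shock() < 3:
        raise TraceError("need >= 3 pre-shock samples to estimate the baseline")
    f0 = float(trace.pre_shock.mean())
    if f0 <= 0:
        raise TraceError(f"degenerate baseline F0={f0}; cannot normalize")
    if mode == "delta_f_over_f0":
        rel = (trace.values - f0) / f0
    elif mode == "f_over_f0":
        rel = trace.values / f0
    else:
        raise TraceError(f"unknown normalization mode {mode!r}")
    return replace(trace, values=rel, normalized=True)


@dataclass
class KineticsParams:
    """Tunables for kinetics extraction.

    smooth_window/smooth_order: Savitzky-Golay smoothing before finite
    differences (5 s sampling is noisy); deriv_smooth_window applies a second
    Savitzky-Golay pass to the derivative itself before its maximum is taken,
    suppressing the upward bias of maximizing over correlated noise (set to 0
    to disable).  t0 is the first post-shock time at
    which the smoothed trace stays above baseline_noise_k * sigma_baseline for
    run_length consecutive samples.  The plateau is the mean of the final
    plateau_fraction of samples ("tail"), or a logistic-fit asymptote.
    """

    smooth_window: int = 5
    smooth_order: int = 2
    deriv_smooth_window: int = 9
    baseline_noise_k: float = 3.0
    run_length: int = 3
    plateau_fraction: float = 0.1
    plateau_mode: str = "tail"  # "tail" | "logistic"

    def __post_init__(self) -> None:
        if self.smooth_window < 3 or self.smooth_window % 2 == 0:
            raise TraceError("smooth_window must be odd and >= 3")
        if self.smooth_order >= self.smooth_window:
            raise TraceError("smooth_order must be < smooth_window")
        if self.deriv_smooth_window and (
            self.deriv_smooth_window < 3 or self.deriv_smooth_window % 2 == 0
        ):
            raise TraceError("deriv_smooth_window must be 0 or odd and >= 3")
        if not 0 < self.plateau_fraction <= 1:
            raise TraceError("plateau_fraction must be in (0, 1]")


@dataclass
class KineticsResult:
    """VLD-formation kinetics for one ROI; times relative to shock onset."""

    event_detected: bool
    t0: float | None = None  # s
    vmax: float | None = None  # 1/s
    t_vmax: float | None = None  # s
    plateau: float | None = None  # relative fluorescence


def _smooth(values: np.ndarray, params: KineticsParams) -> np.ndarray:
    w = min(params.smooth_window, len(values) if len(values) % 2 else len(values) - 1)
    if len(values) < params.smooth_window:
        raise TraceError(
            f"trace of {len(values)} samples shorter than smoothing window "
            f"{params.smooth_window}"
        )
    return savgol_filter(values, w, params.smooth_order)


def extract_kinetics(
    trace: FluorescenceTrace, params: KineticsParams | None = None
) -> KineticsResult:
    """Extract t0, Vmax, tVmax and plateau from a normalized trace."""
    params = params or KineticsParams()
    if not trace.normalized:
        trace = normalize_trace(trace)
    smoothed = _smooth(trace.values, params)
    pre = trace.times < trace.shock_time
    if pre.sum() < 3:
        raise TraceError("need >= 3 pre-shock samples for the noise floor")
    sigma = float(np.std(trace.values[pre], ddof=1))
    threshold = params.baseline_noise_k * max(sigma, 1e-12)

    post = np.flatnonzero(trace.times >= trace.shock_time)
    above = smoothed[post] > threshold
    t0_idx = _first_run(above, params.run_length)
    if t0_idx is None:
        return KineticsResult(event_detected=False)
    t0_abs = trace.times[post[t0_idx]]

    deriv = np.gradient(smoothed, trace.times)
    if params.deriv_smooth_window and len(deriv) >= params.deriv_smooth_window:
        deriv = savgol_filter(deriv, params.deriv_smooth_window, params.smooth_order)
    region = post[t0_idx:]
    j = int(np.argmax(deriv[region]))
    vmax, t_vmax_abs = _refine_peak(trace.times[region], deriv[region], j)

    if params.plateau_mode == "tail":
        n_tail = max(1, int(round(params.plateau_fraction * len(trace.values))))
        plateau = float(trace.values[-n_tail:].mean())
    elif params.plateau_mode == "logistic":
        plateau = _logistic_plateau(trace, t_vmax_abs, vmax)
    else:
        raise TraceError(f"unknown plateau_mode {params.plateau_mode!r}")

    return KineticsResult(
        event_detected=True,
        t0=float(t0_abs - trace.shock_time),
        vmax=vmax,
        t_vmax=float(t_vmax_abs - trace.shock_time),
        plateau=plateau,
    )


def _refine_peak(times: np.ndarray, deriv: np.ndarray, j: int) -> tuple[float, float]:
    """Vertex of a parabola least-squares fitted around the derivative argmax.

    Taking the raw maximum of a noisy derivative selects upward noise
    excursions; the local parabola vertex averages the neighbourhood instead
    and is exact for the (locally quadratic) peak of a noiseless logistic
    derivative.
    """
    lo, hi = max(0, j - 2), min(len(deriv), j + 3)
    t, d = times[lo:hi], deriv[lo:hi]
    if len(t) < 3:
        return float(deriv[j]), float(times[j])
    tc = t - times[j]
    a, b, c = np.polyfit(tc, d, 2)
    if a >= 0:  # no concave vertex: fall back to the grid maximum
        return float(deriv[j]), float(times[j])
    tv = -b / (2.0 * a)
    tv = float(np.clip(tv, tc[0], tc[-1]))
    return float(a * tv**2 + b * tv + c), float(times[j] + tv)


def _first_run(mask: np.ndarray, run_length: int) -> int | None:
    """Index of the first element starting a run of run_length True values."""
    if len(mask) < run_length:
        return None
    run = 0
    for i, m in enumerate(mask):
        run = run + 1 if m else 0
        if run >= run_length:
            return i - run_length + 1
    return None


def _logistic_plateau(trace: FluorescenceTrace, t_vmax_abs: float, vmax: float) -> float:
    from scipy.optimize import curve_fit

    def logistic(t, a, k, tm):
        return a / (1.0 + np.exp(-np.clip(k * (t - tm), -500, 500)))

    a0 = max(float(trace.values.max()), 1e-6)
    k0 = max(4.0 * vmax / a0, 1e-6)
    try:
        popt, _ = curve_fit(
            logistic, trace.times, trace.values, p0=(a0, k0, t_vmax_abs), maxfev=2000
        )
        return float(popt[0])
    except RuntimeError:
        return a0


@dataclass
class BreakageCall:
    """Breakage classification of one cell from its 543 nm trace."""

    broken: bool
    relative_intensity_max: float
    t_breakage: float | None = None  # s after shock, present iff broken


def classify_breakage(
    trace543: FluorescenceTrace,
    threshold: float = BREAKAGE_THRESHOLD,
    mode: str = "delta_f_over_f0",
) -> BreakageCall:
    """Call cell breakage from the cytoplasmic 543 nm signal.

    Broken iff the maximal relative intensity reaches ``threshold`` (default
    10); the crossing time is linearly interpolated between samples.
    """
    rel = trace543 if trace543.normalized else normalize_trace(trace543, mode=mode)
    post = rel.times >= rel.shock_time
    values, times = rel.values[post], rel.times[post]
    rmax = float(values.max())
    if rmax < threshold:
        return BreakageCall(broken=False, relative_intensity_max=rmax)
    i = int(np.argmax(values >= threshold))
    if i == 0:
        t_cross = times[0]
    else:
        f0, f1 = values[i - 1], values[i]
        t_cross = times[i - 1] + (threshold - f0) / (f1 - f0) * (times[i] - times[i - 1])
    return BreakageCall(
        broken=True,
        relative_intensity_max=rmax,
        t_breakage=float(t_cross - rel.shock_time),
    )


VLD_COUNT_BINS = ("0", "1-5", "6-10", ">10")


def bin_vld_counts(counts) -> dict[str, float]:
    """Percent distribution of cells over VLD-count bins {0}, [1,5], [6,10], >10."""
    counts = np.asarray(counts, dtype=int)
    if counts.size == 0:
        raise TraceError("empty count list")
    if (counts < 0).any():
        raise TraceError("VLD counts must be >= 0")
    n = counts.size
    return {
        "0": float((counts == 0).sum()) / n * 100.0,
        "1-5": float(((counts >= 1) & (counts <= 5)).sum()) / n * 100.0,
        "6-10": float(((counts >= 6) & (counts <= 10)).sum()) / n * 100.0,
        ">10": float((counts > 10).sum()) / n * 100.0,
    }


@dataclass
class SurfaceMetrics:
    """Cell-surface expansion metrics from a cross-section area series."""

    surface_increase_pct: float
    t_surface_max: float  # s after shock
    degenerate: bool = False  # flagged when no post-shock increase was seen


def surface_metrics(
    times, areas, shock_time: float = 0.0, smooth_window: int = 5
) -> SurfaceMetrics:
    """Percent surface increase and its time from a cross-section area series.

    Initial surface = mean pre-shock area; increase = (max post-shock area -
    initial)/initial x 100.  Scale-free in the areas.  The maximum is located
    on a centered moving average of ``smooth_window`` samples (1 disables
    smoothing): taking the raw maximum of a noisy, flat-topped series both
    overestimates the peak and scatters its time.
    """
    times = np.asarray(times, dtype=float)
    areas = np.asarray(areas, dtype=float)
    if np.any(areas <= 0):
        raise TraceError("areas must be positive")
    if smooth_window < 1:
        raise TraceError("smooth_window must be >= 1")
    pre = times < shock_time
    post = times >= shock_time
    if pre.sum() < 1:
        raise TraceError("need >= 1 pre-shock area sample")
    if post.sum() < 1:
        raise TraceError("need >= 1 post-shock area sample")
    initial = float(areas[pre].mean())
    if smooth_window > 1 and areas.size >= smooth_window:
        from scipy.ndimage import uniform_filter1d

        smoothed = uniform_filter1d(areas, size=smooth_window, mode="nearest")
    else:
        smoothed = areas
    j = int(np.argmax(smoothed[post]))
    amax = float(smoothed[post][j])
    pct = (amax - initial) / initial * 100.0
    degenerate = pct <= 0.0
    return SurfaceMetrics(
        surface_increase_pct=max(pct, 0.0),
        t_surface_max=float(times[post][j] - shock_time),
        degenerate=degenerate,
    )


@dataclass
class CellRecord:
    """Everything measured on one cell."""

    cell_id: str
    vld_count: int
    kinetics: list[KineticsResult] = field(default_factory=list)
    vld_rois: list[tuple[tuple[float, float], float]] = field(default_factory=list)
    surface: SurfaceMetrics | None = None
    breakage: BreakageCall | None = None


_SUMMARY_FIELDS = (
    "vld_count",
    "t0",
    "vmax",
    "t_vmax",
    "plateau",
    "surface_increase_pct",
    "t_surface_max",
    "breakage_fraction",
)


def summarize_condition(records: list[CellRecord], condition: str) -> pd.DataFrame:
    """Per-condition mean +- SEM table (SEM = SD/sqrt(n); absent when n < 2).

    Kinetic quantities pool every detected VLD event across cells; count,
    surface and breakage quantities are per cell.
    """
    if len(records) < 2:
        raise TraceError("need >= 2 records to summarize a condition")
    pools: dict[str, list[float]] = {f: [] for f in _SUMMARY_FIELDS}
    for rec in records:
        pools["vld_count"].append(float(rec.vld_count))
        for k in rec.kinetics:
            if k.event_detected:
                pools["t0"].append(k.t0)
                pools["vmax"].append(k.vmax)
                pools["t_vmax"].append(k.t_vmax)
                pools["plateau"].append(k.plateau)
        if rec.surface is not None:
            pools["surface_increase_pct"].append(rec.surface.surface_increase_pct)
            pools["t_surface_max"].append(rec.surface.t_surface_max)
        if rec.breakage is not None:
            pools["breakage_fraction"].append(1.0 if rec.breakage.broken else 0.0)
    rows = []
    for name, vals in pools.items():
        arr = np.asarray(vals, dtype=float)
        n = arr.size
        mean = float(arr.mean()) if n else math.nan
        sem = float(arr.std(ddof=1) / math.sqrt(n)) if n >= 2 else math.nan
        rows.append({"condition": condition, "quantity": name, "mean": mean, "sem": sem, "n": n})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# trace I/O: CSV/TSV with columns cell_id, roi_id, channel, time_s, intensity


def read_traces(path, shock_time: float = 0.0) -> dict[tuple[str, str, int], FluorescenceTrace]:
    """Read per-ROI traces keyed by (cell_id, roi_id, channel)."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"cell_id", "roi_id", "channel", "time_s", "intensity"}
    if not required.issubset(df.columns):
        raise TraceError(f"trace file must have columns {sorted(required)}")
    out = {}
    for (cell, roi, ch), grp in df.groupby(["cell_id", "roi_id", "channel"], sort=False):
        grp = grp.sort_values("time_s")
        out[(str(cell), str(roi), int(ch))] = FluorescenceTrace(
            times=grp["time_s"].to_numpy(),
            values=grp["intensity"].to_numpy(),
            channel=int(ch),
            shock_time=shock_time,
        )
    return out


def write_traces(traces: dict[tuple[str, str, int], FluorescenceTrace], path) -> None:
    frames = []
    for (cell, roi, ch), tr in traces.items():
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": cell,
                    "roi_id": roi,
                    "channel": ch,
                    "time_s": tr.times,
                    "intensity": tr.values,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
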