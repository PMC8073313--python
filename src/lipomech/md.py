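"""Coarse-grained membrane post-processing under imposed surface extension.

A bilayer is stretched by scaling the membrane-plane box axes (X, Y) in
steps of a few percent while the normal axis stays pressure-coupled.  The
module plans such extension series, measures how the acyl chains respond —
the tilt angle between each chain's first-to-last-bead vector and the
membrane normal, the first-to-last bead distance, and their joint
distribution — and computes the surface tension from the pressure-tensor
anisotropy (Kirkwood-Irving):

    gamma = (Lz / 2) * (Pzz - (Pxx + Pyy) / 2)

with the factor 1/2 sharing the tension between the bilayer's two
interfaces.  In bar*nm, 1 bar*nm = 0.1 mN/m.  A chain angle near 0 deg (or
180 deg in the opposite leaflet) means the chain stands perpendicular to the
membrane plane; 90 deg means it lies in the plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ChainTopology",
    "TrajectoryFrame",
    "PressureSeries",
    "ExtensionPlan",
    "AngleDistribution",
    "AngleDistanceHistogram",
    "GammaResult",
    "plan_extensions",
    "chain_angle",
    "chain_extension_distance",
    "angle_distribution",
    "angle_distance_histogram",
    "surface_tension",
    "area_per_lipid",
    "load_trajectory",
    "write_trajectory",
]

BAR_NM_TO_MN_PER_M = 0.1
DEFAULT_ANGLE_BIN_WIDTH = 2.5  # degrees


@dataclass
class ChainTopology:
    """Chain topology table.

    ``table`` columns: lipid_id, chain_id, sn_position (sn1|sn2), leaflet
    (upper|lower), bead_order (0 = glycerol-proximal), bead_index (global
    bead index into the coordinate array).
    """

    table: pd.DataFrame

    REQUIRED = ("lipid_id", "chain_id", "sn_position", "leaflet", "bead_order", "bead_index")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"topology missing columns {missing}")
        sizes = self.table.groupby(["lipid_id", "chain_id"]).size()
        if (sizes < 2).any():
            raise ValueError("every chain needs >= 2 beads")
        dup = self.table.groupby("lipid_id")["bead_index"].apply(lambda s: s.duplicated().any())
        if dup.any():
            raise ValueError("bead indices must be unique within a lipid")

    def chain_endpoints(self, selection: pd.Series | None = None) -> pd.DataFrame:
        """First/last bead index per chain (columns first, last, leaflet, ...)."""
        df = self.table if selection is None else self.table[selection]
        if df.empty:
            raise ValueError("empty chain selection")
        df = df.sort_values("bead_order")
        grouped = df.groupby(["lipid_id", "chain_id"], sort=True)
        out = grouped.agg(
            first=("bead_index", "first"),
            last=("bead_index", "last"),
            leaflet=("leaflet", "first"),
            sn_position=("sn_position", "first"),
        ).reset_index()
        return out

    @classmethod
    def from_csv(cls, path) -> "ChainTopology":
        return cls(pd.read_csv(path, sep=None, engine="python"))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class TrajectoryFrame:
    """One frame: bead coordinates (nm) and box lengths (nm)."""

    coordinates: np.ndarray  # N x 3
    box: tuple[float, float, float]
    time: float = 0.0  # ns

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be N x 3")
        if any(b <= 0 for b in self.box):
            raise ValueError("box lengths must be positive")


@dataclass
class PressureSeries:
    """Diagonal pressure-tensor time series (bar) with box height Lz (nm)."""

    times: np.ndarray  # ns
    pxx: np.ndarray
    pyy: np.ndarray
    pzz: np.ndarray
    lz: np.ndarray  # nm, per frame (a scalar is broadcast)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.pxx = np.asarray(self.pxx, dtype=float)
        self.pyy = np.asarray(self.pyy, dtype=float)
        self.pzz = np.asarray(self.pzz, dtype=float)
        self.lz = np.broadcast_to(np.asarray(self.lz, dtype=float), self.times.shape).copy()
        n = self.times.size
        for name in ("pxx", "pyy", "pzz", "lz"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} length does not match times")
        if np.any(self.lz <= 0):
            raise ValueError("Lz must be positive")

    @classmethod
    def from_csv(cls, path) -> "PressureSeries":
        df = pd.read_csv(path, sep=None, engine="python")
        required = {"time_ns", "Pxx_bar", "Pyy_bar", "Pzz_bar", "Lz_nm"}
        if not required.issubset(df.columns):
            raise ValueError(f"pressure file must have columns {sorted(required)}")
        return cls(
            times=df["time_ns"].to_numpy(),
            pxx=df["Pxx_bar"].to_numpy(),
            pyy=df["Pyy_bar"].to_numpy(),
            pzz=df["Pzz_bar"].to_numpy(),
            lz=df["Lz_nm"].to_numpy(),
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "time_ns": self.times,
                "Pxx_bar": self.pxx,
                "Pyy_bar": self.pyy,
                "Pzz_bar": self.pzz,
                "Lz_nm": self.lz,
            }
        ).to_csv(path, index=False)


@dataclass
class ExtensionPlan:
    """Stepwise in-plane extension series: level e scales Lx and Ly by 1+e/100."""

    levels: list[float]  # %
    targets: list[tuple[float, float]]  # (Lx', Ly') nm per level
    eq_box: tuple[float, float]

    def area_ratio(self, level: float) -> float:
        return (1.0 + level / 100.0) ** 2


def plan_extensions(
    eq_box: tuple[float, float], step_pct: float = 5.0, max_pct: float = 25.0
) -> ExtensionPlan:
    """Plan an extension series from step_pct up to max_pct (inclusive)."""
    lx, ly = eq_box
    if lx <= 0 or ly <= 0:
        raise ValueError("equilibrium box lengths must be positive")
    if step_pct <= 0:
        raise ValueError("step_pct must be > 0")
    if max_pct < step_pct:
        raise ValueError("max_pct must be >= step_pct")
    levels = list(np.arange(step_pct, max_pct + 1e-9, step_pct))
    targets = [(lx * (1 + e / 100.0), ly * (1 + e / 100.0)) for e in levels]
    return ExtensionPlan(levels=levels, targets=targets, eq_box=(lx, ly))


def chain_angle(first_bead, last_bead) -> float | np.ndarray:
    """Tilt angle (deg, in [0, 180]) of the first->last bead vector vs +z.

    Accepts single points or (N, 3) arrays.
    """
    v = np.asarray(last_bead, dtype=float) - np.asarray(first_bead, dtype=float)
    single = v.ndim == 1
    v = np.atleast_2d(v)
    norm = np.linalg.norm(v, axis=1)
    if np.any(norm == 0):
        raise ValueError("zero-length chain vector")
    cos = np.clip(v[:, 2] / norm, -1.0, 1.0)
    ang = np.degrees(np.arccos(cos))
    return float(ang[0]) if single else ang


def chain_extension_distance(first_bead, last_bead) -> float | np.ndarray:
    """Euclidean first-to-last bead distance (nm)."""
    v = np.asarray(last_bead, dtype=float) - np.asarray(first_bead, dtype=float)
    single = v.ndim == 1
    v = np.atleast_2d(v)
    d = np.linalg.norm(v, axis=1)
    return float(d[0]) if single else d


@dataclass
class AngleDistribution:
    """Per-bin probability mass of chain tilt angles."""

    bin_edges: np.ndarray  # degrees
    probabilities: np.ndarray  # sums to 1
    extension_level: float | None = None  # %

    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def _collect_chain_vectors(
    frames: list[TrajectoryFrame],
    topology: ChainTopology,
    selection: pd.Series | None = None,
    check_pbc: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Angles (deg) and distances (nm) for all selected chains x frames."""
    if not frames:
        raise ValueError("need >= 1 trajectory frame")
    ends = topology.chain_endpoints(selection)
    angles, dists = [], []
    for fr in frames:
        first = fr.coordinates[ends["first"].to_numpy()]
        last = fr.coordinates[ends["last"].to_numpy()]
        d = chain_extension_distance(first, last)
        if check_pbc:
            half = min(fr.box) / 2.0
            if np.any(d > half):
                raise ValueError(
                    "chain vector longer than half the box: coordinates look "
                    "wrapped across the periodic boundary; unwrap first"
                )
        angles.append(chain_angle(first, last))
        dists.append(d)
    return np.concatenate(angles), np.concatenate(dists)


def angle_distribution(
    frames: list[TrajectoryFrame],
    topology: ChainTopology,
    selection: pd.Series | None = None,
    bin_width: float = DEFAULT_ANGLE_BIN_WIDTH,
    fold: bool = False,
    extension_level: float | None = None,
) -> AngleDistribution:
    """Probability mass of chain tilt angles over all selected chains x frames.

    ``fold=True`` maps each angle a to min(a, 180 - a), pooling the two
    leaflet lobes onto [0, 90].
    """
    angles, _ = _collect_chain_vectors(frames, topology, selection)
    hi = 90.0 if fold else 180.0
    if fold:
        angles = np.minimum(angles, 180.0 - angles)
    edges = np.arange(0.0, hi + bin_width / 2, bin_width)
    if edges[-1] < hi:
        edges = np.append(edges, hi)
    counts, edges = np.histogram(angles, bins=edges)
    return AngleDistribution(
        bin_edges=edges,
        probabilities=counts / counts.sum(),
        extension_level=extension_level,
    )


@dataclass
class AngleDistanceHistogram:
    """Joint probability mass over (tilt angle, chain extension distance)."""

    angle_edges: np.ndarray
    dist_edges: np.ndarray
    probabilities: np.ndarray  # (n_angle_bins, n_dist_bins), sums to 1

    def angle_marginal(self) -> AngleDistribution:
        return AngleDistribution(
            bin_edges=self.angle_edges, probabilities=self.probabilities.sum(axis=1)
        )

    def distance_marginal(self) -> np.ndarray:
        return self.probabilities.sum(axis=0)


def angle_distance_histogram(
    frames: list[TrajectoryFrame],
    topology: ChainTopology,
    selection: pd.Series | None = None,
    angle_bins: np.ndarray | None = None,
    dist_bins: np.ndarray | None = None,
) -> AngleDistanceHistogram:
    """Joint (angle, first-last distance) probability grid; marginals match
    the 1-D distributions on the same binning."""
    angles, dists = _collect_chain_vectors(frames, topology, selection)
    if angle_bins is None:
        angle_bins = np.arange(0.0, 180.0 + DEFAULT_ANGLE_BIN_WIDTH / 2, DEFAULT_ANGLE_BIN_WIDTH)
    if dist_bins is None:
        dist_bins = np.linspace(0.0, max(float(dists.max()) * 1.05, 1e-6), 41)
    h, ae, de = np.histogram2d(angles, dists, bins=[angle_bins, dist_bins])
    return AngleDistanceHistogram(angle_edges=ae, dist_edges=de, probabilities=h / h.sum())


@dataclass
class GammaResult:
    """Surface tension estimate with block-averaged standard error."""

    gamma: float  # mN/m (per interface)
    stderr: float
    n_frames: int
    convention: dict = field(
        default_factory=lambda: {
            "formula": "gamma = (Lz/2) * (Pzz - (Pxx+Pyy)/2)",
            "per_interface": True,
            "units": "mN/m",
            "bar_nm_to_mN_per_m": BAR_NM_TO_MN_PER_M,
        }
    )


def surface_tension(series: PressureSeries, n_blocks: int = 5) -> GammaResult:
    """Kirkwood-Irving surface tension from a pressure-tensor series.

    Per-frame gamma = (Lz/2)(Pzz - (Pxx+Pyy)/2) in bar*nm, converted to mN/m
    (x 0.1); the 1/2 assigns the tension to each of the bilayer's two
    interfaces.  The value is the time average; the error is the SD of
    n_blocks contiguous block means / sqrt(n_blocks).
    """
    n = series.times.size
    if n < 2:
        raise ValueError("need >= 2 pressure samples")
    if n < n_blocks:
        raise ValueError(f"need >= {n_blocks} samples for {n_blocks}-block error estimate")
    anisotropy = series.pzz - 0.5 * (series.pxx + series.pyy)
    gamma_t = BAR_NM_TO_MN_PER_M * 0.5 * series.lz * anisotropy
    blocks = np.array_split(gamma_t, n_blocks)
    block_means = np.array([b.mean() for b in blocks])
    stderr = float(block_means.std(ddof=1) / np.sqrt(n_blocks))
    return GammaResult(gamma=float(gamma_t.mean()), stderr=stderr, n_frames=n)


def area_per_lipid(box: tuple[float, float], n_lipids_per_leaflet: int) -> float:
    """Membrane-plane area / lipids per leaflet (nm^2)."""
    if n_lipids_per_leaflet <= 0:
        raise ValueError("n_lipids_per_leaflet must be > 0")
    lx, ly = box
    return lx * ly / n_lipids_per_leaflet


# ---------------------------------------------------------------------------
# trajectory I/O


def load_trajectory(path, topology_path=None) -> list[TrajectoryFrame]:
    """Load frames from a tabular file (frame, bead_id, x, y, z, Lx, Ly, Lz)
    or, for .gro/.xtc/.trr files, through MDAnalysis."""
    p = str(path)
    if p.endswith((".gro", ".xtc", ".trr")):
        return _load_mdanalysis(path, topology_path)
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"frame", "bead_id", "x", "y", "z", "Lx", "Ly", "Lz"}
    if not required.issubset(df.columns):
        raise ValueError(f"tabular trajectory must have columns {sorted(required)}")
    frames = []
    for fidx, grp in df.groupby("frame", sort=True):
        grp = grp.sort_values("bead_id")
        frames.append(
            TrajectoryFrame(
                coordinates=grp[["x", "y", "z"]].to_numpy(),
                box=(float(grp["Lx"].iloc[0]), float(grp["Ly"].iloc[0]), float(grp["Lz"].iloc[0])),
                time=float(fidx),
            )
        )
    return frames


def _load_mdanalysis(path, topology_path) -> list[TrajectoryFrame]:
    try:
        import MDAnalysis as mda
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "reading GRO/XTC/TRR requires MDAnalysis (pip install lipomech[md])"
        ) from exc
    if topology_path is not None and str(path).endswith((".xtc", ".trr")):
        u = mda.Universe(str(topology_path), str(path))
    else:
        u = mda.Universe(str(path))
    frames = []
    for ts in u.trajectory:
        frames.append(
            TrajectoryFrame(
                coordinates=ts.positions / 10.0,  # A -> nm
                box=tuple(ts.dimensions[:3] / 10.0),
                time=float(ts.time) / 1000.0,  # ps -> ns
            )
        )
    return frames


def write_trajectory(frames: list[TrajectoryFrame], path) -> None:
    rows = []
    for i, fr in enumerate(frames):
        n = fr.coordinates.shape[0]
        rows.append(
            pd.DataFrame(
                {
                    "frame": i,
                    "bead_id": np.arange(n),
                    "x": fr.coordinates[:, 0],
                    "y": fr.coordinates[:, 1],
                    "z": fr.coordinates[:, 2],
                    "Lx": fr.box[0],
                    "Ly": fr.box[1],
                    "Lz": fr.box[2],
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
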