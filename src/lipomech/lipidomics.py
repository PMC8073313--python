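"""Phospholipid species profiling.

Shotgun lipidomics reports each phospholipid as ``<class> x:y`` where *x* is
the total number of acyl-chain carbons and *y* the total number of C=C double
bonds (e.g. ``PC 38:4`` is a phosphatidylcholine whose two fatty-acyl chains
carry 38 carbons and 4 double bonds between them).  Per-class species
distributions condense into the double-bond (DB) index — the percentage of a
class carried by saturated (DB=0), monounsaturated (DB=1), diunsaturated
(DB=2) and polyunsaturated (DB>2) species — and into the DHA/AA ratio, the
relative weight of docosahexaenoate- versus arachidonate-containing PC.
Cross-sample structure is summarised by a PCA over the DB indexes.

Only PC masses are computed from elemental composition; PE/PS/PI tables are
accepted pre-annotated.  Isotopologue overlap (the M+2 peak of an x:y+1
species falling on the M peak of x:y) is ignored — a documented limitation.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LIPID_CLASSES",
    "SpeciesID",
    "SpeciesTable",
    "DBIndex",
    "PeakList",
    "PCAResult",
    "LipidomicsError",
    "parse_species_name",
    "pc_monoisotopic_mass",
    "adduct_mz",
    "annotate_peaks",
    "db_index",
    "dha_aa_ratio",
    "pca_db",
    "read_species_table",
    "write_species_table",
    "read_peak_list",
]

LIPID_CLASSES = ("PC", "PE", "PS", "PI")

# monoisotopic atomic masses, Da (CODATA/IUPAC)
_MASS = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
}
PROTON_MASS = 1.007276466  # Da

MZ_SCAN_RANGE = (500.0, 1200.0)  # m/z window of the phospholipid scan


class LipidomicsError(ValueError):
    """Raised for malformed species names, classes or tables."""


@dataclass(frozen=True, order=True)
class SpeciesID:
    """A phospholipid species: class + total acyl carbons x + double bonds y."""

    lipid_class: str
    total_carbons: int
    double_bonds: int

    def __post_init__(self) -> None:
        if self.lipid_class not in LIPID_CLASSES:
            raise LipidomicsError(
                f"unknown lipid class {self.lipid_class!r}; expected one of {LIPID_CLASSES}"
            )
        if self.total_carbons < 2:
            raise LipidomicsError(f"total_carbons must be >= 2, got {self.total_carbons}")
        if self.double_bonds < 0:
            raise LipidomicsError(f"double_bonds must be >= 0, got {self.double_bonds}")

    def __str__(self) -> str:
        return f"{self.lipid_class} {self.total_carbons}:{self.double_bonds}"


_NAME_RE = re.compile(r"^\s*([A-Za-z]+)\s+(\d+)\s*:\s*(\d+)\s*$")


def parse_species_name(name: str) -> SpeciesID:
    """Parse ``"PC 38:4"`` (whitespace-tolerant) into a :class:`SpeciesID`."""
    m = _NAME_RE.match(name)
    if m is None:
        raise LipidomicsError(f"malformed species name {name!r}; expected '<class> <x>:<y>'")
    cls, x, y = m.group(1).upper(), int(m.group(2)), int(m.group(3))
    if cls not in LIPID_CLASSES:
        raise LipidomicsError(f"unknown lipid class token {m.group(1)!r} in {name!r}")
    return SpeciesID(cls, x, y)


def pc_monoisotopic_mass(species: SpeciesID) -> float:
    """Monoisotopic mass (Da) of a diacyl-PC with composition C(x+8) H(2x+16-2y) N O8 P.

    Each extra double bond removes one H2 (2.0156500638 Da); each extra pair
    of chain carbons adds C2H4 (28.0313 Da).
    """
    if species.lipid_class != "PC":
        raise LipidomicsError(
            f"mass computation only supported for PC, got {species.lipid_class}"
        )
    x, y = species.total_carbons, species.double_bonds
    n_h = 2 * x + 16 - 2 * y
    if n_h <= 0:
        raise LipidomicsError(f"unphysical composition for {species}: H count {n_h}")
    return (x + 8) * _MASS["C"] + n_h * _MASS["H"] + _MASS["N"] + 8 * _MASS["O"] + _MASS["P"]


def adduct_mz(mass: float, adduct: str = "[M+H]+") -> float:
    """m/z of the given adduct of a neutral monoisotopic mass (singly charged)."""
    if adduct == "[M+H]+":
        return mass + PROTON_MASS
    if adduct == "[M-H]-":
        return mass - PROTON_MASS
    raise LipidomicsError(f"unsupported adduct {adduct!r}; use '[M+H]+' or '[M-H]-'")


@dataclass
class SpeciesTable:
    """One sample's phospholipid species with per-class relative abundances (%).

    ``entries`` columns: lipid_class, total_carbons, double_bonds, abundance_pct.
    Within each lipid class the abundances sum to 100.
    """

    sample_label: str
    entries: pd.DataFrame

    REQUIRED_COLUMNS = ("lipid_class", "total_carbons", "double_bonds", "abundance_pct")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED_COLUMNS if c not in self.entries.columns]
        if missing:
            raise LipidomicsError(f"species table missing columns {missing}")
        key = self.entries[["lipid_class", "total_carbons", "double_bonds"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise LipidomicsError(
                f"duplicate species {dup.lipid_class} {dup.total_carbons}:{dup.double_bonds}"
            )

    def species(self) -> list[SpeciesID]:
        return [
            SpeciesID(r.lipid_class, int(r.total_carbons), int(r.double_bonds))
            for r in self.entries.itertuples()
        ]

    def is_normalized(self, tol: float = 1e-6) -> bool:
        sums = self.entries.groupby("lipid_class")["abundance_pct"].sum()
        return bool(np.all(np.abs(sums.to_numpy() - 100.0) <= tol))

    def normalize(self) -> "SpeciesTable":
        """Return a copy with per-class abundances rescaled to sum to 100."""
        df = self.entries.copy()
        totals = df.groupby("lipid_class")["abundance_pct"].transform("sum")
        if (totals <= 0).any():
            raise LipidomicsError("cannot normalize: a lipid class has non-positive total")
        df["abundance_pct"] = df["abundance_pct"] / totals * 100.0
        return SpeciesTable(self.sample_label, df)

    def abundance(self, species: SpeciesID) -> float:
        df = self.entries
        sel = (
            (df.lipid_class == species.lipid_class)
            & (df.total_carbons == species.total_carbons)
            & (df.double_bonds == species.double_bonds)
        )
        return float(df.loc[sel, "abundance_pct"].sum())


@dataclass
class PeakList:
    """Raw MS peak list: (m/z, intensity) pairs plus ion mode."""

    peaks: pd.DataFrame  # columns mz, intensity
    ion_mode: str = "positive"

    def __post_init__(self) -> None:
        for c in ("mz", "intensity"):
            if c not in self.peaks.columns:
                raise LipidomicsError(f"peak list missing column {c!r}")
        if self.ion_mode not in ("positive", "negative"):
            raise LipidomicsError(f"ion_mode must be positive|negative, got {self.ion_mode!r}")
        if (self.peaks["intensity"] < 0).any():
            raise LipidomicsError("peak intensities must be >= 0")
        lo, hi = MZ_SCAN_RANGE
        outside = (self.peaks["mz"] < lo) | (self.peaks["mz"] > hi)
        if outside.any():
            warnings.warn(
                f"{int(outside.sum())} peak(s) outside the {lo:.0f}-{hi:.0f} m/z "
                "phospholipid scan range"
            )


@dataclass
class DBIndex:
    """Per-class double-bond index: % saturated / mono- / di- / poly-unsaturated."""

    db0: float
    db1: float
    db2: float
    dbgt2: float

    def as_array(self) -> np.ndarray:
        return np.array([self.db0, self.db1, self.db2, self.dbgt2], dtype=float)

    COLUMNS = ("DB=0", "DB=1", "DB=2", "DB>2")


def db_index(table: SpeciesTable, lipid_class: str = "PC", tol: float = 1e-6) -> DBIndex:
    """Bin one class's species abundances by total double bonds {0},{1},{2},{>2}."""
    df = table.entries[table.entries.lipid_class == lipid_class]
    if df.empty:
        raise LipidomicsError(f"no {lipid_class} species in table {table.sample_label!r}")
    total = df["abundance_pct"].sum()
    if abs(total - 100.0) > tol:
        raise LipidomicsError(
            f"{lipid_class} abundances sum to {total:.6f}, not 100; normalize first"
        )
    y = df["double_bonds"].to_numpy()
    a = df["abundance_pct"].to_numpy(dtype=float)
    return DBIndex(
        db0=float(a[y == 0].sum()),
        db1=float(a[y == 1].sum()),
        db2=float(a[y == 2].sum()),
        dbgt2=float(a[y > 2].sum()),
    )


_DHA_SPECIES = [SpeciesID("PC", x, 6) for x in (36, 38, 40)]
_AA_SPECIES = [SpeciesID("PC", x, 4) for x in (36, 38, 40)]


def dha_aa_ratio(table: SpeciesTable, tol: float = 1e-6) -> float:
    """Ratio of DHA-containing (PC 36:6, 38:6, 40:6) to AA-containing
    (PC 36:4, 38:4, 40:4) PC abundance.

    Returns ``inf`` (with a warning) when DHA species are present but no AA
    species, and ``nan`` when both sums are zero.
    """
    pc = table.entries[table.entries.lipid_class == "PC"]
    if abs(pc["abundance_pct"].sum() - 100.0) > tol:
        raise LipidomicsError("PC abundances not normalized to 100; normalize first")
    dha = sum(table.abundance(s) for s in _DHA_SPECIES)
    aa = sum(table.abundance(s) for s in _AA_SPECIES)
    if aa == 0.0:
        if dha == 0.0:
            warnings.warn("DHA/AA ratio undefined: no DHA- or AA-containing PC species")
            return math.nan
        warnings.warn("DHA/AA ratio infinite: AA-containing PC species absent")
        return math.inf
    return dha / aa


def annotate_peaks(
    peaks: PeakList,
    candidates: list[SpeciesID],
    tolerance_ppm: float = 5.0,
    adduct: str = "[M+H]+",
    sample_label: str = "sample",
) -> SpeciesTable:
    """Assign peaks to candidate PC species by exact-mass adduct matching.

    Each peak is assigned to the candidate whose adduct m/z is nearest in ppm
    and within ``tolerance_ppm``; peaks equidistant (in ppm) from two
    candidates are left unassigned with a warning.  Intensities of assigned
    peaks are renormalized to % of the class total.  Candidates with no
    matching peak appear with 0 %.
    """
    if not candidates:
        raise LipidomicsError("empty candidate list")
    if tolerance_ppm < 0:
        raise LipidomicsError("tolerance_ppm must be >= 0")
    expected_adduct = "[M+H]+" if peaks.ion_mode == "positive" else "[M-H]-"
    if adduct != expected_adduct:
        raise LipidomicsError(
            f"adduct {adduct} inconsistent with {peaks.ion_mode} ion mode"
        )
    cand_mz = np.array([adduct_mz(pc_monoisotopic_mass(s)) for s in candidates])
    # accumulate intensity per candidate; order-invariant because each peak is
    # treated independently
    intensity = np.zeros(len(candidates))
    for row in peaks.peaks.sort_values("mz").itertuples():
        ppm = np.abs(row.mz - cand_mz) / cand_mz * 1e6
        order = np.argsort(ppm)
        best = order[0]
        if ppm[best] > tolerance_ppm:
            continue
        if len(candidates) > 1 and math.isclose(
            ppm[best], ppm[order[1]], rel_tol=0.0, abs_tol=1e-9
        ):
            warnings.warn(
                f"peak m/z {row.mz:.4f} equidistant (ppm) from {candidates[best]} "
                f"and {candidates[order[1]]}; left unassigned"
            )
            continue
        intensity[best] += row.intensity
    total = intensity.sum()
    pct = intensity / total * 100.0 if total > 0 else intensity
    df = pd.DataFrame(
        {
            "lipid_class": [s.lipid_class for s in candidates],
            "total_carbons": [s.total_carbons for s in candidates],
            "double_bonds": [s.double_bonds for s in candidates],
            "abundance_pct": pct,
        }
    )
    return SpeciesTable(sample_label, df)


@dataclass
class PCAResult:
    """Mean-centered PCA of DB indexes across samples."""

    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # variables x components
    explained_pct: np.ndarray  # one entry per component, sums to 100
    rank_deficient: bool = field(default=False)


def pca_db(indexes: list[tuple[str, DBIndex]]) -> PCAResult:
    """PCA of the (samples x 4) DB-index matrix.

    Mean-centered, unscaled.  Explained variances sum to 100 % over all
    components; the sign of each component is fixed by making its
    largest-magnitude loading positive.  Identical rows (zero total variance)
    are reported as rank deficiency, not an exception.
    """
    if len(indexes) < 2:
        raise LipidomicsError("PCA requires at least 2 samples")
    labels = [lbl for lbl, _ in indexes]
    X = np.vstack([ix.as_array() for _, ix in indexes])
    Xc = X - X.mean(axis=0)
    n, p = Xc.shape
    k = min(n - 1, p)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    s, Vt = s[:k], Vt[:k]
    var = s**2 / (n - 1)
    total = var.sum()
    rank_deficient = total <= 1e-12
    if rank_deficient:
        warnings.warn("all DB indexes identical: PCA is rank deficient")
        explained = np.zeros(k)
    else:
        explained = var / total * 100.0
    # deterministic sign: largest |loading| of each component made positive
    for j in range(k):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    scores = U[:, :k] * s
    comp_names = [f"PC{j + 1}" for j in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=labels, columns=comp_names),
        loadings=pd.DataFrame(Vt.T, index=list(DBIndex.COLUMNS), columns=comp_names),
        explained_pct=explained,
        rank_deficient=rank_deficient,
    )


# ---------------------------------------------------------------------------
# file I/O — CSV/TSV with columns sample, class, species ("38:6"), abundance_pct


def _read_delimited(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python")


def read_species_table(path) -> list[SpeciesTable]:
    """Read species tables (columns sample, class, species, abundance_pct);
    one :class:`SpeciesTable` per distinct sample."""
    df = _read_delimited(path)
    required = {"sample", "class", "species", "abundance_pct"}
    if not required.issubset(df.columns):
        raise LipidomicsError(f"species file must have columns {sorted(required)}")
    tables = []
    for sample, grp in df.groupby("sample", sort=False):
        ids = [parse_species_name(f"{c} {sp}") for c, sp in zip(grp["class"], grp["species"])]
        entries = pd.DataFrame(
            {
                "lipid_class": [s.lipid_class for s in ids],
                "total_carbons": [s.total_carbons for s in ids],
                "double_bonds": [s.double_bonds for s in ids],
                "abundance_pct": grp["abundance_pct"].to_numpy(dtype=float),
            }
        )
        tables.append(SpeciesTable(str(sample), entries))
    return tables


def write_species_table(tables: list[SpeciesTable], path) -> None:
    rows = []
    for t in tables:
        for r in t.entries.itertuples():
            rows.append(
                {
                    "sample": t.sample_label,
                    "class": r.lipid_class,
                    "species": f"{r.total_carbons}:{r.double_bonds}",
                    "abundance_pct": r.abundance_pct,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_peak_list(path, ion_mode: str = "positive") -> PeakList:
    """Read a peak list (columns mz, intensity)."""
    df = _read_delimited(path)
    return PeakList(df[["mz", "intensity"]], ion_mode=ion_mode)
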