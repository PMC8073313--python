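"""Species parsing, exact masses, peak annotation, DB index, ratios, PCA."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lipomech.lipidomics import (
    DBIndex,
    LipidomicsError,
    PeakList,
    SpeciesID,
    SpeciesTable,
    adduct_mz,
    annotate_peaks,
    db_index,
    dha_aa_ratio,
    parse_species_name,
    pc_monoisotopic_mass,
    pca_db,
)


def make_table(entries, label="s"):
    """entries: list of (class, x, y, pct)."""
    return SpeciesTable(
        label,
        pd.DataFrame(
            entries, columns=["lipid_class", "total_carbons", "double_bonds", "abundance_pct"]
        ),
    )


class TestParsing:
    @pytest.mark.parametrize(
        "name,expected",
        [
            ("PC 38:4", ("PC", 38, 4)),
            ("PC 32:0", ("PC", 32, 0)),
            ("  pe  40 : 6 ", ("PE", 40, 6)),
        ],
    )
    def test_parses_class_carbons_double_bonds(self, name, expected):
        sp = parse_species_name(name)
        assert (sp.lipid_class, sp.total_carbons, sp.double_bonds) == expected

    def test_round_trips_through_canonical_form(self):
        sp = parse_species_name("PC 38:4")
        assert parse_species_name(str(sp)) == sp

    @pytest.mark.parametrize("bad", ["XX 10:1", "PC 38", "PC x:y", "38:4"])
    def test_rejects_malformed_names(self, bad):
        with pytest.raises(LipidomicsError):
            parse_species_name(bad)


# independent elemental-sum oracle with its own atomic-mass constants
_ORACLE_MASSES = {"C": 12.0, "H": 1.00782503207, "N": 14.0030740048,
                  "O": 15.9949146196, "P": 30.97376163}


def oracle_pc_mass(x: int, y: int) -> float:
    formula = {"C": x + 8, "H": 2 * x + 16 - 2 * y, "N": 1, "O": 8, "P": 1}
    return sum(_ORACLE_MASSES[el] * n for el, n in formula.items())


class TestMonoisotopicMass:
    @pytest.mark.parametrize("x,y,expected", [(32, 0, 733.5622), (34, 1, 759.5778)])
    def test_reference_species_masses(self, x, y, expected):
        assert pc_monoisotopic_mass(SpeciesID("PC", x, y)) == pytest.approx(expected, abs=1e-4)

    @pytest.mark.parametrize("x,y", [(32, 0), (34, 1), (36, 4), (38, 6), (40, 6)])
    def test_matches_elemental_sum_oracle(self, x, y):
        assert pc_monoisotopic_mass(SpeciesID("PC", x, y)) == pytest.approx(
            oracle_pc_mass(x, y), abs=1e-4
        )

    def test_double_bond_removes_exactly_h2(self):
        h2 = 2 * 1.0078250319
        for x in (32, 36, 40):
            for y in (0, 2, 5):
                delta = pc_monoisotopic_mass(SpeciesID("PC", x, y)) - pc_monoisotopic_mass(
                    SpeciesID("PC", x, y + 1)
                )
                assert delta == pytest.approx(h2, abs=1e-12)

    def test_monotone_in_carbons_and_double_bonds(self):
        ch2_pair = 28.0313
        m = pc_monoisotopic_mass
        assert m(SpeciesID("PC", 36, 2)) - m(SpeciesID("PC", 34, 2)) == pytest.approx(
            ch2_pair, abs=1e-4
        )
        assert m(SpeciesID("PC", 34, 1)) < m(SpeciesID("PC", 34, 0))

    def test_non_pc_class_unsupported(self):
        with pytest.raises(LipidomicsError, match="PC"):
            pc_monoisotopic_mass(SpeciesID("PE", 34, 1))


class TestAnnotatePeaks:
    def test_assigns_peak_to_nearest_candidate_within_tolerance(self):
        # [M+H]+ of PC 32:0 = 733.5622 + 1.007276
        peaks = PeakList(pd.DataFrame({"mz": [734.5695], "intensity": [1000.0]}))
        table = annotate_peaks(peaks, [SpeciesID("PC", 32, 0), SpeciesID("PC", 32, 1)])
        assert table.abundance(SpeciesID("PC", 32, 0)) == pytest.approx(100.0)
        assert table.abundance(SpeciesID("PC", 32, 1)) == 0.0

    def test_peak_outside_tolerance_leaves_species_at_zero(self):
        peaks = PeakList(pd.DataFrame({"mz": [740.0], "intensity": [1000.0]}))
        table = annotate_peaks(peaks, [SpeciesID("PC", 32, 0)])
        assert table.abundance(SpeciesID("PC", 32, 0)) == 0.0

    def test_equidistant_peak_unassigned_with_warning(self):
        a, b = SpeciesID("PC", 32, 0), SpeciesID("PC", 32, 1)
        mza, mzb = (adduct_mz(pc_monoisotopic_mass(s)) for s in (a, b))
        # the harmonic mean is exactly equidistant in ppm from both masses
        mid = 2.0 * mza * mzb / (mza + mzb)
        peaks = PeakList(pd.DataFrame({"mz": [mid], "intensity": [500.0]}))
        with pytest.warns(UserWarning, match="equidistant"):
            table = annotate_peaks(peaks, [a, b], tolerance_ppm=2000.0)
        assert table.entries["abundance_pct"].sum() == 0.0

    def test_assignment_invariant_to_peak_order(self):
        cands = [SpeciesID("PC", x, y) for x in (32, 34, 36) for y in (0, 1, 2)]
        mzs = [adduct_mz(pc_monoisotopic_mass(s)) for s in cands]
        intens = np.linspace(100, 900, len(mzs))
        fwd = PeakList(pd.DataFrame({"mz": mzs, "intensity": intens}))
        rev = PeakList(pd.DataFrame({"mz": mzs[::-1], "intensity": intens[::-1]}))
        t1 = annotate_peaks(fwd, cands)
        t2 = annotate_peaks(rev, cands)
        pd.testing.assert_frame_equal(t1.entries, t2.entries)

    def test_empty_candidates_and_negative_tolerance_rejected(self):
        peaks = PeakList(pd.DataFrame({"mz": [700.0], "intensity": [1.0]}))
        with pytest.raises(LipidomicsError):
            annotate_peaks(peaks, [])
        with pytest.raises(LipidomicsError):
            annotate_peaks(peaks, [SpeciesID("PC", 32, 0)], tolerance_ppm=-1)


class TestDBIndex:
    @pytest.mark.parametrize(
        "entries,expected",
        [
            ([("PC", 34, 1, 100.0)], (0, 100, 0, 0)),
            ([("PC", 32, 0, 50.0), ("PC", 38, 6, 50.0)], (50, 0, 0, 50)),
            (
                [("PC", 32, 0, 25.0), ("PC", 34, 1, 25.0), ("PC", 34, 2, 25.0), ("PC", 38, 6, 25.0)],
                (25, 25, 25, 25),
            ),
        ],
    )
    def test_bins_by_double_bond_count(self, entries, expected):
        ix = db_index(make_table(entries))
        assert (ix.db0, ix.db1, ix.db2, ix.dbgt2) == expected

    def test_unnormalized_table_rejected(self):
        with pytest.raises(LipidomicsError, match="normalize"):
            db_index(make_table([("PC", 34, 1, 50.0)]))

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.lists(st.floats(0.01, 100.0), min_size=1, max_size=12))
    def test_sums_to_100_for_any_normalized_table(self, weights):
        entries = [("PC", 30 + 2 * (i % 7), i, w) for i, w in enumerate(weights)]
        table = make_table(entries).normalize()
        ix = db_index(table)
        assert ix.db0 + ix.db1 + ix.db2 + ix.dbgt2 == pytest.approx(100.0, abs=1e-6)
        assert min(ix.db0, ix.db1, ix.db2, ix.dbgt2) >= 0.0


class TestDhaAaRatio:
    def test_equal_dha_and_aa_gives_unity(self):
        t = make_table([("PC", 38, 6, 10.0), ("PC", 38, 4, 10.0), ("PC", 34, 1, 80.0)])
        assert dha_aa_ratio(t) == pytest.approx(1.0)

    def test_hand_summed_ratio(self):
        t = make_table(
            [("PC", 38, 6, 20.0), ("PC", 40, 6, 5.0), ("PC", 38, 4, 12.5), ("PC", 34, 1, 62.5)]
        )
        assert dha_aa_ratio(t) == pytest.approx(2.0)

    def test_no_dha_gives_zero(self):
        t = make_table([("PC", 38, 4, 10.0), ("PC", 34, 1, 90.0)])
        assert dha_aa_ratio(t) == 0.0

    def test_zero_aa_denominator_signalled(self):
        t = make_table([("PC", 38, 6, 10.0), ("PC", 34, 1, 90.0)])
        with pytest.warns(UserWarning, match="infinite"):
            assert math.isinf(dha_aa_ratio(t))


class TestPCA:
    def _indexes(self, X):
        return [(f"s{i}", DBIndex(*row)) for i, row in enumerate(X)]

    def test_two_samples_single_component_explains_all(self):
        X = [[10, 20, 30, 40], [40, 30, 20, 10]]
        res = pca_db(self._indexes(X))
        assert res.explained_pct[0] == pytest.approx(100.0)

    def test_collinear_samples_put_everything_on_pc1(self):
        base = np.array([10.0, 20.0, 30.0, 40.0])
        d = np.array([1.0, -1.0, 2.0, -2.0])
        X = [base + t * d for t in (0.0, 1.0, 2.0, 3.0)]
        res = pca_db(self._indexes(X))
        assert res.explained_pct[0] == pytest.approx(100.0, abs=1e-9)
        assert res.explained_pct[1:] == pytest.approx(0.0, abs=1e-9)

    def test_explained_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(42)
        X = rng.uniform(0, 100, size=(7, 4))
        res = pca_db(self._indexes(X))
        # independent oracle: eigenvalues of the sample covariance matrix
        eig = np.linalg.eigvalsh(np.cov(np.asarray(X).T))[::-1]
        expected = eig[: len(res.explained_pct)] / eig.sum() * 100.0
        assert res.explained_pct == pytest.approx(expected, abs=1e-8)
        assert res.explained_pct.sum() == pytest.approx(100.0, abs=1e-8)
        assert np.all(np.diff(res.explained_pct) <= 1e-9)

    def test_sign_convention_largest_loading_positive(self):
        rng = np.random.default_rng(7)
        X = rng.uniform(0, 100, size=(6, 4))
        res = pca_db(self._indexes(X))
        for comp in res.loadings.columns:
            col = res.loadings[comp].to_numpy()
            assert col[np.argmax(np.abs(col))] > 0

    def test_identical_rows_report_rank_deficiency(self):
        X = [[25.0, 25.0, 25.0, 25.0]] * 3
        with pytest.warns(UserWarning, match="rank deficient"):
            res = pca_db(self._indexes(X))
        assert res.rank_deficient

    def test_fewer_than_two_samples_rejected(self):
        with pytest.raises(LipidomicsError):
            pca_db(self._indexes([[25, 25, 25, 25]]))


class TestSpeciesTable:
    def test_duplicate_species_rejected(self):
        with pytest.raises(LipidomicsError, match="duplicate"):
            make_table([("PC", 34, 1, 50.0), ("PC", 34, 1, 50.0)])

    def test_normalize_per_class(self):
        t = make_table([("PC", 34, 1, 3.0), ("PC", 32, 0, 1.0), ("PE", 38, 6, 5.0)])
        tn = t.normalize()
        assert tn.is_normalized()
        assert tn.abundance(SpeciesID("PC", 34, 1)) == pytest.approx(75.0)
        assert tn.abundance(SpeciesID("PE", 38, 6)) == pytest.approx(100.0)
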