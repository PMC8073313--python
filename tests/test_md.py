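"""Extension planning, chain geometry, distributions and surface tension."""

import numpy as np
import pandas as pd
import pytest

from lipomech.md import (
    ChainTopology,
    PressureSeries,
    TrajectoryFrame,
    angle_distance_histogram,
    angle_distribution,
    area_per_lipid,
    chain_angle,
    chain_extension_distance,
    load_trajectory,
    plan_extensions,
    surface_tension,
    write_trajectory,
)
from lipomech.synth import gen_pressure_series, gen_trajectory


class TestExtensionPlan:
    def test_five_percent_steps_to_25(self):
        plan = plan_extensions((30.0, 30.0), 5.0, 25.0)
        assert plan.levels == [5.0, 10.0, 15.0, 20.0, 25.0]
        assert plan.targets[0] == pytest.approx((31.5, 31.5))

    def test_single_level(self):
        plan = plan_extensions((20.0, 25.0), 5.0, 5.0)
        assert plan.levels == [5.0]

    def test_area_ratio_is_square_of_linear_scaling(self):
        plan = plan_extensions((30.0, 30.0))
        assert plan.area_ratio(25.0) == pytest.approx(1.5625)
        for e in plan.levels:
            assert plan.area_ratio(e) == pytest.approx((1 + e / 100.0) ** 2)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            plan_extensions((0.0, 30.0))
        with pytest.raises(ValueError):
            plan_extensions((30.0, 30.0), step_pct=-5.0)
        with pytest.raises(ValueError):
            plan_extensions((30.0, 30.0), step_pct=10.0, max_pct=5.0)


class TestChainGeometry:
    @pytest.mark.parametrize(
        "last,expected",
        [((0, 0, 1), 0.0), ((0, 0, -1), 180.0), ((1, 0, 0), 90.0), ((1, 0, 1), 45.0)],
    )
    def test_angle_oracle_cases(self, last, expected):
        assert chain_angle((0, 0, 0), last) == pytest.approx(expected, abs=1e-9)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            chain_angle((1.0, 1.0, 1.0), (1.0, 1.0, 1.0))

    @pytest.mark.parametrize("last,expected", [((0, 0, 1), 1.0), ((3, 4, 0), 5.0)])
    def test_distance(self, last, expected):
        assert chain_extension_distance((0, 0, 0), last) == pytest.approx(expected)

    def test_distance_invariant_under_rotation(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=3)
        theta = 0.7
        rot = np.array(
            [[np.cos(theta), -np.sin(theta), 0], [np.sin(theta), np.cos(theta), 0], [0, 0, 1]]
        )
        assert chain_extension_distance(np.zeros(3), rot @ v) == pytest.approx(
            chain_extension_distance(np.zeros(3), v)
        )


def _uniform_traj(lo, hi, seed=0, n_frames=4, n_lipids=200):
    return gen_trajectory(
        n_lipids=n_lipids, angle_law=("uniform", lo, hi), n_frames=n_frames, seed=seed
    )


class TestAngleDistribution:
    def test_delta_law_concentrates_in_mirrored_bins(self):
        frames, topo = gen_trajectory(angle_law=("delta", 45.0), seed=1)
        dist = angle_distribution(frames, topo)
        c = dist.bin_centers()
        assert dist.probabilities[(c > 43) & (c < 48)].sum() == pytest.approx(0.5)
        assert dist.probabilities[(c > 133) & (c < 138)].sum() == pytest.approx(0.5)
        assert dist.probabilities.sum() == pytest.approx(1.0)

    def test_vertical_chains_single_bin(self):
        frames, topo = gen_trajectory(angle_law=("delta", 0.0), seed=0)
        upper = topo.table["leaflet"] == "upper"
        dist = angle_distribution(frames, topo, selection=upper)
        assert dist.probabilities[0] == pytest.approx(1.0)

    def test_uniform_law_mass_recovered_in_band(self):
        frames, topo = _uniform_traj(80.0, 100.0, seed=2)
        dist = angle_distribution(frames, topo)
        c = dist.bin_centers()
        assert dist.probabilities[(c >= 80.0) & (c <= 100.0)].sum() >= 0.99

    def test_pooled_leaflets_symmetric_about_90(self):
        frames, topo = _uniform_traj(20.0, 60.0, seed=3, n_frames=8, n_lipids=400)
        dist = angle_distribution(frames, topo, bin_width=10.0)
        p = dist.probabilities
        # mirrored leaflets: bin at alpha matches bin at 180-alpha within
        # binomial sampling error
        n = 8 * 400
        for i in range(len(p) // 2):
            se = np.sqrt(max(p[i] * (1 - p[i]), 1e-12) / n)
            assert abs(p[i] - p[-1 - i]) <= 5 * se + 5e-3

    def test_fold_maps_to_quarter_circle(self):
        frames, topo = gen_trajectory(angle_law=("delta", 45.0), seed=1)
        dist = angle_distribution(frames, topo, fold=True)
        c = dist.bin_centers()
        assert dist.bin_edges[-1] == pytest.approx(90.0)
        assert dist.probabilities[(c > 43) & (c < 48)].sum() == pytest.approx(1.0)

    def test_invariant_to_frame_order(self):
        frames, topo = _uniform_traj(30.0, 150.0, seed=4)
        d1 = angle_distribution(frames, topo)
        d2 = angle_distribution(frames[::-1], topo)
        assert d1.probabilities == pytest.approx(d2.probabilities)

    def test_empty_selection_rejected(self):
        frames, topo = gen_trajectory(seed=0)
        with pytest.raises(ValueError, match="empty"):
            angle_distribution(frames, topo, selection=topo.table["leaflet"] == "nope")


class TestAngleDistanceHistogram:
    def test_single_conformation_single_cell(self):
        frames, topo = gen_trajectory(
            n_lipids=2, angle_law=("delta", 90.0), dist_law=("delta", 1.0), n_frames=1, seed=0
        )
        h = angle_distance_histogram(frames, topo)
        assert np.count_nonzero(h.probabilities) == 1
        assert h.probabilities.sum() == pytest.approx(1.0)

    def test_marginal_equals_1d_distribution(self):
        frames, topo = _uniform_traj(10.0, 170.0, seed=5)
        bins = np.arange(0.0, 180.0 + 1.25, 2.5)
        h = angle_distance_histogram(frames, topo, angle_bins=bins)
        d1 = angle_distribution(frames, topo, bin_width=2.5)
        assert h.angle_marginal().probabilities == pytest.approx(d1.probabilities)

    def test_bimodal_distances_recovered(self):
        law = ("mixture", [(0.5, ("normal", 0.55, 0.02)), (0.5, ("normal", 0.95, 0.02))])
        frames, topo = gen_trajectory(
            n_lipids=400, angle_law=("delta", 90.0), dist_law=law, n_frames=4, seed=6
        )
        h = angle_distance_histogram(
            frames, topo, dist_bins=np.linspace(0.3, 1.3, 51)
        )
        dmarg = h.distance_marginal()
        centers = 0.5 * (h.dist_edges[:-1] + h.dist_edges[1:])
        lo = dmarg[(centers > 0.45) & (centers < 0.65)].sum()
        hi = dmarg[(centers > 0.85) & (centers < 1.05)].sum()
        mid = dmarg[(centers > 0.70) & (centers < 0.80)].sum()
        assert lo > 0.4 and hi > 0.4 and mid < 0.05


class TestSurfaceTension:
    def test_isotropic_pressure_gives_zero(self):
        n = 100
        s = PressureSeries(np.arange(n) * 0.1, np.ones(n), np.ones(n), np.ones(n), np.full(n, 10.0))
        assert surface_tension(s).gamma == pytest.approx(0.0)

    def test_unit_conversion_reference_case(self):
        # Lz=10 nm, anisotropy 100 bar -> (10/2)*100 bar*nm = 500 bar*nm
        # = 50 mN/m per interface
        n = 50
        s = PressureSeries(
            np.arange(n) * 0.1, np.full(n, -99.0), np.full(n, -99.0), np.ones(n), np.full(n, 10.0)
        )
        res = surface_tension(s)
        assert res.gamma == pytest.approx(50.0)
        assert res.stderr == pytest.approx(0.0, abs=1e-12)

    def test_linear_in_anisotropy_and_lz(self):
        def gamma(dp, lz):
            n = 20
            return surface_tension(
                PressureSeries(
                    np.arange(n) * 0.1,
                    np.full(n, 1.0 - dp),
                    np.full(n, 1.0 - dp),
                    np.full(n, 1.0),
                    np.full(n, lz),
                )
            ).gamma

        assert gamma(40.0, 10.0) == pytest.approx(2 * gamma(20.0, 10.0))
        assert gamma(20.0, 20.0) == pytest.approx(2 * gamma(20.0, 10.0))
        # stretched membranes (Pzz above lateral) carry positive tension
        assert gamma(20.0, 10.0) > 0

    def test_recovers_target_from_noisy_series(self):
        series = gen_pressure_series(5.0, noise_sd=50.0, n=10000, seed=9)
        res = surface_tension(series)
        assert abs(res.gamma - 5.0) <= 2 * res.stderr

    def test_too_few_samples_for_blocks(self):
        s = PressureSeries([0.0, 1.0], [1.0, 1.0], [1.0, 1.0], [1.0, 1.0], [10.0, 10.0])
        with pytest.raises(ValueError, match="block"):
            surface_tension(s, n_blocks=5)


class TestAreaPerLipid:
    def test_reference_value(self):
        assert area_per_lipid((30.0, 30.0), 1500) == pytest.approx(0.6)

    def test_scaling(self):
        base = area_per_lipid((30.0, 30.0), 1500)
        assert area_per_lipid((60.0, 60.0), 1500) == pytest.approx(4 * base)
        assert area_per_lipid((30.0 * 1.25, 30.0 * 1.25), 1500) == pytest.approx(1.5625 * base)

    def test_zero_lipids_rejected(self):
        with pytest.raises(ValueError):
            area_per_lipid((30.0, 30.0), 0)


class TestTopologyAndIO:
    def test_topology_requires_two_beads_per_chain(self):
        df = pd.DataFrame(
            {
                "lipid_id": [0], "chain_id": [0], "sn_position": ["sn1"],
                "leaflet": ["upper"], "bead_order": [0], "bead_index": [0],
            }
        )
        with pytest.raises(ValueError, match="2 beads"):
            ChainTopology(df)

    def test_wrapped_chain_flagged(self):
        frames, topo = gen_trajectory(n_lipids=2, dist_law=("delta", 1.0), n_frames=1, seed=0)
        coords = frames[0].coordinates.copy()
        # teleport one terminal bead across the box
        coords[5] = coords[0] + np.array([20.0, 0.0, 0.0])
        bad = TrajectoryFrame(coords, frames[0].box)
        with pytest.raises(ValueError, match="wrapped|unwrap"):
            angle_distribution([bad], topo)

    def test_tabular_round_trip(self, tmp_path):
        frames, topo = gen_trajectory(n_lipids=4, n_frames=3, seed=2)
        path = tmp_path / "traj.csv"
        write_trajectory(frames, path)
        loaded = load_trajectory(path)
        assert len(loaded) == 3
        np.testing.assert_allclose(loaded[1].coordinates, frames[1].coordinates, atol=1e-12)
        assert loaded[1].box == pytest.approx(frames[1].box)
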