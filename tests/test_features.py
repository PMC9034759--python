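"""Morphology/connectivity features and feature-matrix assembly."""

import numpy as np
import pandas as pd
import pytest

from lobtype import features as ft
from lobtype.exceptions import DegenerateFeatureError, InvalidArgumentError
from lobtype.geometry import frame_points


class TestSynapseSpread:
    def test_single_synapse_is_zero_by_convention(self):
        assert np.all(ft.synapse_spread([[1.0, 2.0, 3.0]]) == 0.0)

    def test_two_points_sample_sd(self):
        pts = np.array([[1.0, 0.0, 0.0], [-1.0, 0.0, 0.0]])
        spread = ft.synapse_spread(pts)
        assert spread[0] == pytest.approx(np.sqrt(2.0))
        assert spread[1] == spread[2] == 0.0

    def test_estimator_consistency(self, rng):
        pts = rng.normal(0, 1, (10_000, 3)) * [2.5, 1.5, 1.5]
        spread = ft.synapse_spread(pts)
        assert np.all(np.abs(spread / [2.5, 1.5, 1.5] - 1) < 0.05)

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ft.synapse_spread(np.empty((0, 3)))


class TestDepthHistogram:
    def test_default_binning_yields_14_features(self):
        assert len(ft.innervation_depth_hist([])) == 14

    def test_no_synapses_gives_zero_vector(self):
        h = ft.innervation_depth_hist([])
        assert h.sum() == 0 and len(h) == 14

    def test_half_open_bins_and_boundary_handling(self):
        h = ft.innervation_depth_hist([-20.0, -0.1, 0.0, 49.9, 50.0])
        expect = np.zeros(14, dtype=int)
        expect[0] = 1   # -20.0 in [-20, -15)
        expect[3] = 1   # -0.1 in [-5, 0)
        expect[4] = 1   # 0.0 in [0, 5)
        expect[13] = 1  # 49.9 in [45, 50); 50.0 dropped
        assert np.array_equal(h, expect)
        assert h.sum() == 4

    def test_out_of_range_dropped_not_clipped(self):
        h = ft.innervation_depth_hist([-100.0, 100.0])
        assert h.sum() == 0

    def test_conservation_of_in_range_counts(self, rng):
        depths = rng.uniform(-40, 80, 5000)
        h = ft.innervation_depth_hist(depths)
        assert h.sum() == np.sum((depths >= -20) & (depths < 50))

    def test_non_divisible_range_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ft.innervation_depth_hist([], lo=0.0, hi=10.0, width=3.0)


class TestSmoothing:
    def test_identity_kernel_is_noop(self, rng):
        h = rng.integers(0, 10, 14)
        assert np.allclose(ft.smooth_depth_hist(h, (1.0,)), h)

    def test_hand_convolution_of_interior_spike(self):
        h = np.zeros(14)
        h[6] = 4.0
        out = ft.smooth_depth_hist(h, (0.25, 0.5, 0.25))
        assert np.allclose(out[5:8], [1.0, 2.0, 1.0])
        assert out.sum() == pytest.approx(4.0, abs=1e-9)

    def test_constant_signal_fixed_point(self):
        h = np.full(14, 3.0)
        assert np.allclose(ft.smooth_depth_hist(h, (0.2, 0.2, 0.2, 0.2, 0.2)), h)

    def test_mass_conserved_with_reflect_boundary(self, rng):
        h = rng.uniform(0, 5, 14)
        out = ft.smooth_depth_hist(h, (0.25, 0.5, 0.25))
        assert out.sum() == pytest.approx(h.sum(), abs=1e-9)

    @pytest.mark.parametrize("kernel", [(0.5, 0.5), (0.2, 0.5, 0.2), (-0.5, 2.0, -0.5)])
    def test_bad_kernels_rejected(self, kernel):
        with pytest.raises(InvalidArgumentError):
            ft.smooth_depth_hist(np.zeros(14), kernel)


class TestConnectivity:
    def _edges(self):
        return pd.DataFrame(
            {
                "source_id": [1, 1, 1, 2],
                "target_id": [101, 102, 201, 101],
                "target_type": ["LC4", "LC4", "LT1", "LC4"],
                "weight": [3, 2, 1, 7],
            }
        )

    def test_counts_summed_over_cells_of_a_type(self):
        v = ft.connectivity_vector(1, self._edges(), ["LC4", "LT1"])
        assert list(v) == [5, 1]

    def test_cell_with_no_labeled_targets_is_zero(self):
        v = ft.connectivity_vector(99, self._edges(), ["LC4", "LT1"])
        assert list(v) == [0, 0]

    def test_matrix_panel_is_union_of_downstream_types(self):
        m = ft.connectivity_matrix([1, 2], self._edges())
        assert list(m.columns) == ["LC4", "LT1"]
        assert m.loc[1, "LC4"] == 5 and m.loc[2, "LT1"] == 0

    def test_fixture_panel_covers_all_signature_types(self, fixture_sc):
        coi = sorted(fixture_sc.ground_truth)
        m = ft.connectivity_matrix(coi, fixture_sc.edges)
        assert set(m.columns) == set(fixture_sc.edges["target_type"].unique())
        assert m.to_numpy().sum() == fixture_sc.edges["weight"].sum()


def _blocks(rng, n=40):
    idx = pd.Index(range(n), name="cell_id")
    conn = pd.DataFrame(rng.poisson(5, (n, 4)), index=idx, columns=list("abcd"))
    spread = pd.DataFrame(rng.normal(3, 1, (n, 3)), index=idx, columns=["e1", "e2", "e3"])
    depth = pd.DataFrame(rng.uniform(0, 10, (n, 14)), index=idx,
                         columns=[f"bin{i:02d}" for i in range(1, 15)])
    return conn, spread, depth


class TestAssembly:
    def test_unit_dispersion_block_with_unit_weight_unchanged(self, rng):
        conn, spread, depth = _blocks(rng)
        fm = ft.assemble_feature_matrix(conn, spread, depth, weights=(1.0, 1.0, 1.0))
        d = fm.normalization_record["spread"]
        assert np.allclose(fm.block("spread"), spread.to_numpy() / np.sqrt(d))

    def test_variance_scaling_arithmetic(self):
        # 2-feature block with variances (3, 1): total dispersion 4 -> divide by 2
        rng = np.random.default_rng(0)
        idx = pd.Index(range(500), name="cell_id")
        b = pd.DataFrame(
            {"u": rng.normal(0, np.sqrt(3), 500), "v": rng.normal(0, 1, 500)}, index=idx
        )
        disp = b.var(ddof=1).sum()
        fm = ft.assemble_feature_matrix(b, b, b, weights=(3.0, 1.0, 1.0))
        scaled = fm.block("connectivity")
        assert np.allclose(scaled, b.to_numpy() / np.sqrt(disp) * 3.0)
        assert scaled.var(axis=0, ddof=1).sum() == pytest.approx(9.0)

    def test_assembled_block_dispersion_equals_weight_squared(self, rng):
        conn, spread, depth = _blocks(rng)
        fm = ft.assemble_feature_matrix(conn, spread, depth)
        for name, w in zip(("connectivity", "spread", "depth"), (5.0, 1.0, 3.0)):
            disp = fm.block(name).var(axis=0, ddof=1).sum()
            assert disp == pytest.approx(w**2, abs=1e-9)

    def test_linear_mode_divides_by_dispersion(self, rng):
        conn, spread, depth = _blocks(rng)
        fm = ft.assemble_feature_matrix(conn, spread, depth, mode="linear")
        d = fm.normalization_record["connectivity"]
        assert np.allclose(fm.block("connectivity"), conn.to_numpy() / d * 5.0)

    def test_zero_dispersion_block_named_in_error(self, rng):
        conn, spread, depth = _blocks(rng)
        spread.iloc[:, :] = 7.0
        with pytest.raises(DegenerateFeatureError, match="spread"):
            ft.assemble_feature_matrix(conn, spread, depth)

    def test_row_permutation_equivariance(self, rng):
        conn, spread, depth = _blocks(rng)
        fm = ft.assemble_feature_matrix(conn, spread, depth)
        perm = rng.permutation(len(conn))
        fm_p = ft.assemble_feature_matrix(
            conn.iloc[perm], spread.iloc[perm], depth.iloc[perm]
        )
        assert np.allclose(fm_p.array, fm.array[perm])

    def test_scale_equivariance_of_morphology_blocks(self, rng):
        """Multiplying coordinates by c scales spreads by c but not assembled blocks."""
        conn, spread, depth = _blocks(rng)
        c = 3.7
        fm = ft.assemble_feature_matrix(conn, spread, depth)
        fm_scaled = ft.assemble_feature_matrix(conn, spread * c, depth)
        assert np.allclose(fm_scaled.block("spread"), fm.block("spread"), atol=1e-9)


class TestBruteForceOracle:
    def test_batch_equals_per_synapse_computation(self, fixture_sc, fitted_frame, rng):
        """Spread + histogram computed one synapse at a time match the batch path."""
        coi = rng.choice(sorted(fixture_sc.ground_truth), size=100, replace=False)
        syn = fixture_sc.synapses
        pre = syn[(syn["polarity"] == "pre") & syn["cell_id"].isin(coi)]
        framed_all = frame_points(pre[["x", "y", "z"]].to_numpy(), fitted_frame)
        framed_all["cell_id"] = pre["cell_id"].to_numpy()
        for cid in coi:
            g = framed_all[framed_all["cell_id"] == cid]
            batch_spread = ft.synapse_spread(g)
            batch_hist = ft.innervation_depth_hist(g["depth"].to_numpy())
            # oracle: accumulate one synapse at a time
            hist = np.zeros(14, dtype=int)
            for d in g["depth"]:
                hist += ft.innervation_depth_hist([d])
            coords = g[["x", "y", "z"]].to_numpy()
            mean = coords.mean(axis=0)
            sq = sum((row - mean) ** 2 for row in coords)
            oracle_spread = np.sqrt(sq / (len(coords) - 1))
            assert np.array_equal(hist, batch_hist)
            assert np.allclose(oracle_spread, batch_spread, atol=1e-9)


class TestTypeProfile:
    def _framed(self, depths):
        n = len(depths)
        return pd.DataFrame({"x": np.zeros(n), "y": np.zeros(n), "z": np.zeros(n), "depth": depths})

    def test_single_cell_profile_is_peak_normalized_histogram(self):
        tp = ft.type_profile([self._framed([1.0, 1.5, 22.0])])
        assert tp.depth_profile.max() == 1.0
        assert tp.n_cells == 1
        assert np.all(tp.sem_spread == 0.0)

    def test_bistratified_type_shows_two_local_maxima(self, rng):
        cells = []
        for _ in range(20):
            d = np.concatenate([rng.normal(5, 1.5, 60), rng.normal(30, 1.5, 40)])
            cells.append(self._framed(d))
        tp = ft.type_profile(cells)
        p = tp.depth_profile
        peaks = [i for i in range(1, 13) if p[i] > p[i - 1] and p[i] >= p[i + 1] and p[i] > 0.2]
        assert len(peaks) >= 2
        # the 5 um mode straddles bins [0,5) and [5,10); the peak sits there
        assert max(p[4], p[5]) == 1.0
        # the 30 um mode straddles bins [25,30) and [30,35)
        assert max(p[9], p[10]) > 0.4

    def test_all_zero_histograms_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ft.type_profile([self._framed([200.0, 300.0])])

    def test_empty_type_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ft.type_profile([])
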