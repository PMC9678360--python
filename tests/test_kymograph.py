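"""Kymograph gridding, averaging, and pole snapshots."""

import numpy as np
import pytest

import polegrowth as pg
from polegrowth.profiles import NEW_TO_OLD
from _oracle import bilinear_track_oracle


def make_track(profile_arrays, cell_id=1):
    profs = [
        pg.AxialProfile(cell_id, f, np.asarray(a, float), orientation=NEW_TO_OLD)
        for f, a in enumerate(profile_arrays)
    ]
    return pg.CellCycleTrack(cell_id, profs)


class TestGridNormalize:
    def test_hand_bilinear_example(self):
        kymo = pg.grid_normalize_track(make_track([[0, 2], [2, 4]]), T=3, L=3)
        assert np.allclose(kymo.values, [[0, 1, 2], [1, 2, 3], [2, 3, 4]])

    def test_interpolation_identity_on_matching_grid(self):
        rows = [np.full(7, 3.5) for _ in range(5)]
        kymo = pg.grid_normalize_track(make_track(rows), T=5, L=7)
        assert np.allclose(kymo.values, 3.5)

    def test_unknown_orientation_rejected(self):
        profs = [pg.AxialProfile(1, f, np.arange(5.0)) for f in range(3)]
        track = pg.CellCycleTrack(1, profs)
        with pytest.raises(pg.OrientationError):
            pg.grid_normalize_track(track)

    def test_tiny_grid_rejected(self):
        with pytest.raises(ValueError):
            pg.grid_normalize_track(make_track([[0, 1], [1, 2]]), T=1, L=5)

    def test_matches_bruteforce_oracle_on_random_tracks(self, rng):
        worst = 0.0
        for _ in range(100):
            F = int(rng.integers(2, 21))
            arrays = [
                rng.uniform(0, 100, size=int(rng.integers(5, 201))) for _ in range(F)
            ]
            T = int(rng.integers(2, 12))
            L = int(rng.integers(2, 12))
            got = pg.grid_normalize_track(make_track(arrays), T=T, L=L).values
            want = bilinear_track_oracle(arrays, T, L)
            worst = max(worst, float(np.max(np.abs(got - want))))
        assert worst < 1e-9


class TestAveraging:
    def test_single_kymograph_mode_none_is_identity(self, rng):
        k = pg.Kymograph(rng.uniform(1, 2, (4, 6)), 1)
        avg = pg.average_kymographs([k], "none")
        assert np.allclose(avg.values, k.values)
        assert avg.n_cells == 1

    def test_two_constant_kymographs_average_to_midpoint(self):
        a = pg.Kymograph(np.full((3, 4), 2.0), 1)
        b = pg.Kymograph(np.full((3, 4), 4.0), 2)
        avg = pg.average_kymographs([a, b], "none")
        assert np.allclose(avg.values, 3.0)

    def test_row_sum_rows_sum_to_one(self, rng):
        k = pg.Kymograph(rng.uniform(0.1, 5, (6, 9)), 1)
        out = pg.normalize_kymograph(k, "row_sum")
        assert np.allclose(out.values.sum(axis=1), 1.0, atol=1e-9)

    def test_global_max_normalization(self, rng):
        k = pg.Kymograph(rng.uniform(0.1, 5, (6, 9)), 1)
        assert pg.normalize_kymograph(k, "global_max").values.max() == pytest.approx(1.0)

    def test_mixed_shapes_rejected(self):
        with pytest.raises(ValueError):
            pg.average_kymographs(
                [pg.Kymograph(np.ones((3, 4)), 1), pg.Kymograph(np.ones((3, 5)), 2)]
            )

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            pg.average_kymographs([])

    def test_mirror_equivariance(self, rng):
        tracks = [
            make_track([rng.uniform(0, 9, rng.integers(4, 9)) for _ in range(5)], i)
            for i in range(4)
        ]
        avg = pg.average_kymographs(
            [pg.grid_normalize_track(t, 6, 8) for t in tracks], "row_sum"
        )
        flipped_tracks = [
            make_track([p.samples[::-1] for p in t.profiles], t.cell_id) for t in tracks
        ]
        avg_f = pg.average_kymographs(
            [pg.grid_normalize_track(t, 6, 8) for t in flipped_tracks], "row_sum"
        )
        assert np.allclose(avg_f.values, avg.values[:, ::-1], atol=1e-12)

    def test_average_within_pointwise_envelope(self, rng):
        kymos = [pg.Kymograph(rng.uniform(0, 5, (4, 6)), i) for i in range(5)]
        avg = pg.average_kymographs(kymos, "none")
        stack = np.stack([k.values for k in kymos])
        assert np.all(avg.values >= stack.min(axis=0) - 1e-12)
        assert np.all(avg.values <= stack.max(axis=0) + 1e-12)

    def test_uniform_cohort_yields_flat_average(self):
        cfg = pg.SimulationConfig(localization_mode="uniform", noise_sd=0.0, seed=4)
        cohort = pg.simulate_cohort(cfg, 10)
        kymos = [
            pg.grid_normalize_track(pg.render_localization_track(r, cfg))
            for r in cohort
        ]
        avg = pg.average_kymographs(kymos, "none")
        assert avg.values.std() / avg.values.mean() < 1e-9


class TestPoleSnapshot:
    def test_old_pole_block(self):
        v = np.zeros((5, 20))
        v[:, -2:] = 1.0
        snap = pg.pole_intensity_snapshot([pg.Kymograph(v, 7)], 0.5, pole_window=0.1)
        row = snap.iloc[0]
        assert row.old_pole_intensity == 1.0 and row.new_pole_intensity == 0.0

    def test_uniform_kymograph(self):
        snap = pg.pole_intensity_snapshot([pg.Kymograph(np.full((4, 9), 2.5), 1)], 0.0)
        assert snap.iloc[0].old_pole_intensity == snap.iloc[0].new_pole_intensity == 2.5

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            pg.pole_intensity_snapshot([], 0.5)

    def test_old_pole_cohort_ratio_exceeds_two(self):
        """An old-pole-localized cohort shows a strong old/new contrast early."""
        cfg = pg.SimulationConfig(
            localization_mode="old_pole", noise_sd=5.0, background=5.0, seed=6
        )
        cohort = pg.simulate_cohort(cfg, 25)
        kymos = [
            pg.grid_normalize_track(pg.render_localization_track(r, cfg))
            for r in cohort
        ]
        snap = pg.pole_intensity_snapshot(kymos, 0.25, pole_window=0.1)
        ratio = (snap.old_pole_intensity / snap.new_pole_intensity).median()
        assert ratio > 2
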