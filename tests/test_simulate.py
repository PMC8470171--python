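"""Synthetic transient generator: curve shape, dose response, dataset design."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ojiptox.simulate import (
    ContaminantProfile,
    ControlTemplate,
    DatasetConfig,
    SimulationError,
    TABLE1_CONCENTRATIONS,
    TABLE2_IC50,
    TimeGrid,
    control_curve,
    curve_space_gain,
    dose_effect,
    generate_curve,
    generate_dataset,
    scaled_profiles,
    table1_profiles,
    well_separated_profiles,
)
from ojiptox.transforms import vt_matrix

from conftest import make_profile


class TestTimeGrid:
    def test_default_matches_instrument_protocol(self):
        grid = TimeGrid()
        assert grid.n_points == 458
        assert grid.dt == 0.010
        t = grid.times
        assert t[0] == pytest.approx(0.010)
        assert np.allclose(np.diff(t), 0.010)

    @pytest.mark.parametrize("kwargs", [{"n_points": 1}, {"dt": 0.0}, {"dt": -1.0}])
    def test_invalid_grids_rejected(self, kwargs):
        with pytest.raises(SimulationError):
            TimeGrid(**kwargs)


class TestControlCurve:
    def test_length_matches_default_grid(self):
        curve = control_curve()
        assert len(curve.fluorescence) == 458

    def test_zero_amplitude_limit_is_flat_at_f0(self):
        # amplitudes must be > 0; in the limit A -> 0 the curve tends to f0
        tpl = ControlTemplate(f0=500.0, amplitudes=(1e-12, 1e-12, 1e-12))
        curve = control_curve(tpl)
        assert np.allclose(curve.fluorescence, 500.0)

    def test_bounds_against_direct_evaluation(self):
        # closed form evaluated on a dense grid brackets the sampled curve
        tpl = ControlTemplate()
        dense = control_curve(tpl, TimeGrid(n_points=5000, dt=0.001)).fluorescence
        coarse = control_curve(tpl, TimeGrid()).fluorescence
        upper = tpl.f0 * (1 + sum(tpl.amplitudes))
        assert coarse.min() >= tpl.f0
        assert coarse.max() <= upper
        assert dense.max() <= upper
        assert coarse.max() <= dense.max() + 1e-9

    def test_step_time_outside_window_rejected(self):
        tpl = ControlTemplate(step_times=(0.03, 0.3, 10.0))
        with pytest.raises(SimulationError):
            control_curve(tpl, TimeGrid(n_points=100, dt=0.01))  # window ends at 1 s

    @given(
        f0=st.floats(10.0, 5000.0),
        a=st.tuples(*[st.floats(0.05, 2.0)] * 3),
        taus=st.tuples(st.floats(0.02, 0.05), st.floats(0.1, 0.5), st.floats(0.8, 3.0)),
        widths=st.tuples(*[st.floats(0.05, 0.5)] * 3),
    )
    @settings(max_examples=50, deadline=None)
    def test_noise_free_curves_nondecreasing(self, f0, a, taus, widths):
        tpl = ControlTemplate(f0=f0, amplitudes=a, step_times=taus, step_widths=widths)
        f = control_curve(tpl).fluorescence
        assert np.all(np.diff(f) >= -1e-9)


class TestDoseEffect:
    def test_zero_dose_gives_zero_effect(self):
        assert dose_effect(0.0, ec50=10.0, hill=2.0) == 0.0

    def test_half_maximal_at_ec50(self):
        assert dose_effect(10.0, ec50=10.0, hill=1.7) == pytest.approx(0.5)

    def test_monotone_over_diclofenac_dose_list(self):
        doses = TABLE1_CONCENTRATIONS["dcf"]
        assert doses == (0, 0.8, 3, 40, 100, 300)
        effects = [dose_effect(d, ec50=TABLE2_IC50["dcf"], hill=1.5) for d in doses]
        # brute-force pairwise comparison over the full enumeration
        for i in range(len(effects)):
            for j in range(i + 1, len(effects)):
                assert effects[i] < effects[j]

    def test_negative_dose_rejected(self):
        with pytest.raises(SimulationError):
            dose_effect(-1.0, 10.0, 1.5)

    def test_bounded_below_one(self):
        assert dose_effect(1e9, 1.0, 1.5) < 1.0


class TestGenerateCurve:
    def test_zero_dose_zero_noise_equals_control(self, small_grid):
        profile = make_profile()
        tpl = ControlTemplate()
        curve = generate_curve(profile, tpl, small_grid, 0.0, rng_seed=1, noise_cv=0.0)
        ref = control_curve(tpl, small_grid)
        assert np.array_equal(curve.fluorescence, ref.fluorescence)
        assert curve.ec_label == "ecA"

    def test_same_seed_bit_identical(self, small_grid):
        profile = make_profile()
        tpl = ControlTemplate()
        a = generate_curve(profile, tpl, small_grid, 10.0, rng_seed=42, rep_cv=0.01)
        b = generate_curve(profile, tpl, small_grid, 10.0, rng_seed=42, rep_cv=0.01)
        assert np.array_equal(a.fluorescence, b.fluorescence)

    def test_dose_not_in_list_rejected(self, small_grid):
        with pytest.raises(SimulationError):
            generate_curve(make_profile(), ControlTemplate(), small_grid, 3.3, rng_seed=0)

    def test_overlarge_direction_rejected_at_construction(self):
        with pytest.raises(SimulationError):
            make_profile(direction=np.array([1.2, 0, 0, 0, 0, 0, 0]))

    def test_delta_vt_of_replicate_mean_grows_with_dose(self, small_grid):
        """Monte-Carlo: the systematic dVt displacement increases along the
        dose grid (replicate-averaged so measurement noise cancels)."""
        profile = make_profile(ec50=10.0)
        tpl = ControlTemplate()
        # control reference estimated from replicates, as the pipeline pairs
        # it, so the peak-extraction bias of noisy Vt cancels in the delta
        ctrl_vt = np.mean(
            [
                vt_matrix(
                    generate_curve(
                        profile, tpl, small_grid, 0.0,
                        rng_seed=(500 + r), noise_cv=0.02,
                    ).fluorescence[None, :]
                )[0]
                for r in range(100)
            ],
            axis=0,
        )
        dist = []
        for conc in profile.concentrations:
            vts = [
                vt_matrix(
                    generate_curve(
                        profile, tpl, small_grid, conc,
                        rng_seed=(1000 + r), noise_cv=0.02,
                    ).fluorescence[None, :]
                )[0]
                for r in range(100)
            ]
            dist.append(np.linalg.norm(np.mean(vts, axis=0) - ctrl_vt))
        assert all(a < b for a, b in zip(dist, dist[1:]))


class TestGenerateDataset:
    def test_table1_design_totals(self):
        cfg = DatasetConfig(profiles=table1_profiles(), master_seed=3)
        assert cfg.n_samples == 1950
        ds = generate_dataset(cfg)
        assert len(ds) == 1950
        assert ds.values.shape == (1950, 458)
        sizes = ds.meta.groupby("ec_label").size()
        assert len(sizes) == 13
        assert sizes["sds"] == 150
        assert set(sizes) <= {120, 150, 180}
        per_cell = ds.meta.groupby(["ec_label", "concentration"]).size()
        assert (per_cell == 30).all()

    def test_single_cell_dataset(self, small_grid):
        cfg = DatasetConfig(
            profiles=(make_profile(concentrations=(0.0,)),),
            replicates_per_cell=1,
            grid=small_grid,
        )
        assert len(generate_dataset(cfg)) == 1

    def test_master_seed_reproducibility(self, small_grid):
        cfg = dict(
            profiles=(make_profile(),), replicates_per_cell=3, master_seed=9,
            grid=small_grid,
        )
        a = generate_dataset(DatasetConfig(**cfg))
        b = generate_dataset(DatasetConfig(**cfg))
        assert np.array_equal(a.values, b.values)
        assert a.meta.equals(b.meta)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(SimulationError):
            DatasetConfig(profiles=(make_profile("x"), make_profile("x")))

    @given(
        n_profiles=st.integers(1, 3),
        n_conc=st.integers(1, 4),
        reps=st.integers(1, 5),
    )
    @settings(max_examples=10, deadline=None)
    def test_sample_count_conservation(self, n_profiles, n_conc, reps):
        concs = tuple(float(i) for i in range(n_conc))
        profiles = tuple(
            make_profile(f"ec{i}", concentrations=concs) for i in range(n_profiles)
        )
        cfg = DatasetConfig(
            profiles=profiles, replicates_per_cell=reps,
            grid=TimeGrid(n_points=16, dt=0.3), noise_cv=0.0, rep_cv=0.0,
        )
        assert len(generate_dataset(cfg)) == n_profiles * n_conc * reps


class TestProfileRosters:
    def test_ec50_anchored_to_measured_ic50(self):
        for p in table1_profiles():
            assert p.ec50 == TABLE2_IC50[p.ec_label]

    def test_well_separated_midpoints_span_dose_lists(self):
        for p in well_separated_profiles():
            doses = [c for c in p.concentrations if c > 0]
            assert min(doses) < p.ec50 < max(doses)

    def test_curve_space_gain_normalization(self):
        # all class directions displace the control curve by a comparable
        # fraction of its norm (unless the positivity cap bit)
        for p in well_separated_profiles(effect_scale=0.2, batch_scale=0.05):
            gain = curve_space_gain(p.direction)
            rel = gain * 1.0  # direction applied at full effect
            assert 0.0 < rel <= 0.25

    def test_scaled_profiles_zero_separation_collapses_classes(self, small_grid):
        profiles = scaled_profiles(well_separated_profiles(), 0.0)
        tpl = ControlTemplate()
        curves = [
            generate_curve(p, tpl, small_grid, 0.0, rng_seed=5, noise_cv=0.0)
            for p in profiles
        ]
        ref = curves[0].fluorescence
        for c in curves[1:]:
            assert np.array_equal(c.fluorescence, ref)
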