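"""Glide selection, compression-weighted MSE, DRAV/tissue/drag estimation."""

import numpy as np
import pandas as pd
import pytest

from gliderav import (EstimationError, ModelParams, Morphometry,
                      SelectionCriteria, estimate_cd, estimate_drav,
                      estimate_tissue_density, select_descent_glides,
                      sensitivity_over_cd, weighted_mse)
from gliderav.synthetic_data import TruthParams, make_glide_segment

SINP75 = abs(np.sin(np.radians(-75.0)))


def scripted_dive(glide_pitch=-75.0, glide_roll=0.0, glide_start_s=11.0,
                  glide_dur=20.0, u=1.8):
    """1 Hz arrays for a scripted descent plus a phases table and one glide."""
    n = 240
    rate = u * SINP75
    depth = rate * np.arange(n, dtype=float)
    pitch = np.full(n, -75.0)
    roll = np.zeros(n)
    g0, g1 = glide_start_s, glide_start_s + glide_dur
    sl = slice(int(g0), int(g1))
    pitch[sl] = glide_pitch if np.isscalar(glide_pitch) else glide_pitch
    if not np.isscalar(glide_roll):
        roll[sl] = np.resize(glide_roll, int(g1) - int(g0))
    speed = np.full(n, u)
    phases = pd.DataFrame([{"dive_id": 0, "start": 0, "end": n,
                            "max_depth": depth[-1], "descent_end": n,
                            "ascent_start": n, "flag": ""}])
    return phases, [(g0, g1)], depth, pitch, roll, speed


class TestGlideSelection:
    def test_compliant_glide_accepted(self):
        args = scripted_dive()
        selected, rejects = select_descent_glides(*args)
        assert len(selected) == 1 and rejects.empty
        g = selected[0]
        assert g.start_depth < 30.0 and g.duration > 10.0

    def test_deep_start_fails_criterion_1(self):
        args = scripted_dive(glide_start_s=21.0)  # starts ~36 m
        selected, rejects = select_descent_glides(*args)
        assert not selected
        assert rejects.iloc[0].reason == "criterion_1"

    def test_short_glide_fails_criterion_2(self):
        args = scripted_dive(glide_dur=8.0)
        selected, rejects = select_descent_glides(*args)
        assert not selected
        assert rejects.iloc[0].reason == "criterion_2"

    def test_shallow_pitch_fails_criterion_3(self):
        args = scripted_dive(glide_pitch=-55.0)
        selected, rejects = select_descent_glides(*args)
        assert not selected
        assert rejects.iloc[0].reason == "criterion_3"

    def test_unstable_roll_fails_criterion_4(self):
        wobble = np.tile([35.0, -35.0], 20)  # circular variance ~0.18
        args = scripted_dive(glide_roll=wobble)
        selected, rejects = select_descent_glides(*args)
        assert not selected
        assert rejects.iloc[0].reason == "criterion_4"

    def test_truncated_at_fifty_metres(self):
        args = scripted_dive(glide_dur=30.0)  # would reach ~71 m
        selected, _ = select_descent_glides(*args)
        assert selected[0].depth.max() <= 50.0 + 1.8

    def test_dive_without_glide_logged(self):
        phases, _, depth, pitch, roll, speed = scripted_dive()
        selected, rejects = select_descent_glides(phases, [], depth, pitch,
                                                  roll, speed)
        assert not selected
        assert rejects.iloc[0].reason == "no_glide"


class TestWeightedMse:
    def test_identical_series_scores_zero(self):
        u = np.array([1.0, 2.0, 3.0])
        assert weighted_mse(u, u, np.array([0.0, 10.0, 20.0])) == 0.0

    def test_surface_sample_has_unit_weight(self):
        assert weighted_mse([1.0], [2.0], [0.0]) == pytest.approx(1.0)

    def test_ten_metre_sample_has_half_weight(self):
        assert weighted_mse([1.0], [2.0], [10.0]) == pytest.approx(0.5)

    def test_candidate_matrix_column_wise(self):
        u = np.array([1.0, 1.0])
        sims = np.array([[1.0, 2.0], [1.0, 2.0]])
        out = weighted_mse(u, sims, np.array([0.0, 0.0]))
        assert out == pytest.approx([0.0, 1.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            weighted_mse([1.0, 2.0], [1.0], [0.0, 1.0])


class TestDravEstimation:
    def test_recovers_worked_example_volume(self, env_const, morph300, params):
        # truth: 0.0149 m^3 of surface air on a 313 kg animal
        morph = Morphometry(mass=313.0, girth=1.70)
        truth = TruthParams(mass=313.0, drav=0.0149e6 / 313.0, cd=0.03,
                            rho_tissue=1037.0, seed=1)
        glide = make_glide_segment(truth, env_const)
        est = estimate_drav(glide, params, morph, env_const)
        assert est.v_air0 == pytest.approx(0.0149, abs=0.0001)
        assert est.mse_curve.shape[0] == 301
        assert est.drav_ml_kg == pytest.approx(est.v_air0 / 313.0 * 1e6)

    def test_zero_truth_recovers_zero_with_flag(self, env_const, params):
        morph = Morphometry(mass=300.0, girth=1.70)
        truth = TruthParams(mass=300.0, drav=1e-9, cd=0.03, rho_tissue=1037.0,
                            seed=2)
        glide = make_glide_segment(truth, env_const)
        est = estimate_drav(glide, params, morph, env_const)
        assert est.v_air0 == 0.0
        assert "zero_estimate" in est.qc_flags

    def test_truth_beyond_grid_is_boundary_flagged(self, env_const, params,
                                                   morph300):
        truth = TruthParams(mass=300.0, drav=30.0, cd=0.03, rho_tissue=1037.0,
                            seed=3)
        glide = make_glide_segment(truth, env_const)
        est = estimate_drav(glide, params, morph300, env_const,
                            grid=(0.0, 0.005, 0.0001))
        assert est.v_air0 == 0.005
        assert "grid_boundary" in est.qc_flags

    def test_curve_minimum_is_reported_estimate(self, env_const, params,
                                                morph300):
        truth = TruthParams(mass=300.0, drav=20.0, seed=4)
        est = estimate_drav(make_glide_segment(truth, env_const), params,
                            morph300, env_const)
        curve = est.mse_curve
        assert curve.loc[curve.weighted_mse.idxmin(), "v_air0_m3"] == est.v_air0

    def test_estimate_nondecreasing_in_truth(self, env_const, params, morph300):
        estimates = []
        for drav in [5.0, 12.0, 20.0, 33.0, 45.0]:
            truth = TruthParams(mass=300.0, drav=drav, seed=5)
            est = estimate_drav(make_glide_segment(truth, env_const), params,
                                morph300, env_const)
            estimates.append(est.drav_ml_kg)
        assert np.all(np.diff(estimates) > 0)


class TestTissueDensityEstimation:
    def _deep_glides(self, env, rho_tissue=1037.0, drav=0.0):
        out = []
        for i, end in enumerate([300.0, 450.0]):
            t = TruthParams(mass=300.0, cd=0.03, rho_tissue=rho_tissue,
                            drav=drav, seed=i)
            out.append(make_glide_segment(t, env, start_depth=120.0, u0=2.0,
                                          end_depth=end, dive_id=i))
        return out

    def test_noise_free_recovery(self, env_profile, params, morph300):
        glides = self._deep_glides(env_profile)
        est = estimate_tissue_density(glides, params, morph300, env_profile)
        assert est.rho_tissue == pytest.approx(1037.0, abs=0.5)
        assert est.n_glides_used == 2

    def test_shallow_spanning_glide_excluded(self, env_profile, params,
                                             morph300):
        glides = self._deep_glides(env_profile)
        t = TruthParams(mass=300.0, drav=0.0, seed=9)
        straddler = make_glide_segment(t, env_profile, start_depth=80.0,
                                       u0=2.0, end_depth=120.0, dive_id=9)
        est = estimate_tissue_density(glides + [straddler], params, morph300,
                                      env_profile)
        assert est.n_glides_used == 2

    def test_no_qualifying_glides_is_estimation_error(self, env_profile,
                                                      params, morph300):
        t = TruthParams(mass=300.0, drav=0.0, seed=9)
        shallow = make_glide_segment(t, env_profile, start_depth=20.0,
                                     end_depth=45.0)
        with pytest.raises(EstimationError):
            estimate_tissue_density([shallow], params, morph300, env_profile)

    def test_residual_air_biases_density_low(self, env_profile, params,
                                             morph300):
        """With air aboard, ignoring it attributes extra lift to the tissue."""
        est0 = estimate_tissue_density(self._deep_glides(env_profile),
                                       params, morph300, env_profile)
        est1 = estimate_tissue_density(
            self._deep_glides(env_profile, drav=21.1), params, morph300,
            env_profile)
        assert est1.rho_tissue < est0.rho_tissue


class TestCdEstimation:
    def _terminal_glides(self, env, cd, girth=1.70, mass=300.0):
        out = []
        for i, end in enumerate([250.0, 380.0, 520.0, 650.0]):
            t = TruthParams(mass=mass, girth=girth, cd=cd, rho_tissue=1037.0,
                            drav=0.0, seed=i)
            out.append(make_glide_segment(t, env, start_depth=120.0, u0=2.0,
                                          end_depth=end, dive_id=i))
        return out

    def test_recovery_within_one_grid_step(self, env_profile, morph300):
        est = estimate_cd(self._terminal_glides(env_profile, 0.03), morph300,
                          env_profile)
        grid_ratio = (1.0 / 0.01) ** (1 / 99)  # adjacent-candidate ratio
        assert abs(np.log(est.pooled_median / 0.03)) < np.log(grid_ratio)

    def test_doubling_frontal_area_halves_cd(self, env_profile):
        # speeds regenerated with doubled area: the product A_f * C_d is what
        # terminal speed constrains
        girth2 = 1.70 * np.sqrt(2.0)
        glides = self._terminal_glides(env_profile, 0.03, girth=girth2)
        est = estimate_cd(glides, Morphometry(mass=300.0, girth=1.70),
                          env_profile)
        assert est.pooled_median == pytest.approx(0.06, rel=0.05)

    def test_pooled_median_across_individuals(self, env_profile, morph300):
        per = {name: self._terminal_glides(env_profile, cd)
               for name, cd in [("a", 0.02), ("b", 0.03), ("c", 0.05)]}
        est = estimate_cd(per, morph300, env_profile)
        assert est.pooled_median == pytest.approx(0.03, rel=0.05)
        assert set(est.per_individual) == {"a", "b", "c"}

    def test_no_plateau_is_estimation_error(self, env_profile, morph300):
        # a short accelerating glide never reaches terminal speed
        t = TruthParams(mass=300.0, drav=0.0, seed=1)
        g = make_glide_segment(t, env_profile, start_depth=110.0, u0=0.5,
                               end_depth=140.0)
        with pytest.raises(EstimationError):
            estimate_cd([g], morph300, env_profile)


class TestCdSensitivity:
    def test_misspecified_cd_bias_direction(self, env_const, morph300):
        """Overestimating drag lowers DRAV; underestimating raises it."""
        truth = TruthParams(mass=300.0, drav=25.0, cd=0.03, seed=6)
        glide = make_glide_segment(truth, env_const)
        table = sensitivity_over_cd([glide], ModelParams(rho_tissue=1037.0),
                                    morph300, env_const,
                                    cd_values=(0.02, 0.03, 0.04, 0.05))
        dravs = table.mean_drav_ml_kg.values
        assert np.all(np.diff(dravs) < 0)
        i = list(table.cd).index(0.03)
        assert dravs[i] == pytest.approx(25.0, abs=0.5)

    def test_single_glide_single_cd_one_row(self, env_const, params, morph300):
        truth = TruthParams(mass=300.0, drav=20.0, seed=7)
        glide = make_glide_segment(truth, env_const)
        table = sensitivity_over_cd([glide], params, morph300, env_const,
                                    cd_values=(0.03,))
        assert len(table) == 1 and table.iloc[0].n_dives == 1

    def test_empty_glide_set_gives_empty_means(self, env_const, params,
                                               morph300):
        table = sensitivity_over_cd([], params, morph300, env_const)
        assert table.n_dives.sum() == 0
        assert table.mean_drav_ml_kg.isna().all()
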