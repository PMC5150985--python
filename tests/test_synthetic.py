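"""Synthetic video-trace generation and parameter recovery."""

import numpy as np
import pytest

from striderjump import (
    DEFAULT_TEMPLATES,
    DomainError,
    InsectMorphology,
    SpeciesTemplate,
    generate_jump_trace,
    generate_morphology,
    recover_parameters,
    recovery_experiment,
    sample_omega,
)

MEDIUM = DEFAULT_TEMPLATES["medium"]


class TestMorphologyGeneration:
    def test_deterministic_per_seed(self):
        assert generate_morphology(MEDIUM, 7) == generate_morphology(MEDIUM, 7)
        assert generate_morphology(MEDIUM, 7) != generate_morphology(MEDIUM, 8)

    def test_degenerate_ranges_return_template_values(self):
        tmpl = SpeciesTemplate("point", (30e-6, 30e-6), (15e-3, 15e-3),
                               (7.5e-3, 7.5e-3), (50e-6, 50e-6), (0.4, 0.4),
                               (50.0, 50.0))
        m = generate_morphology(tmpl, 0)
        assert m.body_mass == pytest.approx(30e-6)
        assert m.support_length == pytest.approx(7.5e-3)
        assert m.rest_height == pytest.approx(0.4 * 15e-3)

    @pytest.mark.parametrize("name", list(DEFAULT_TEMPLATES))
    def test_sampled_morphologies_satisfy_invariants(self, name):
        tmpl = DEFAULT_TEMPLATES[name]
        for seed in range(200):
            m = generate_morphology(tmpl, seed)  # constructor validates
            assert 0 < m.support_length <= m.leg_length
            assert m.max_reach > 0

    def test_inconsistent_template_rejected(self):
        with pytest.raises(DomainError):
            SpeciesTemplate("bad", (30e-6, 10e-6), (15e-3, 15e-3),
                            (7.5e-3, 7.5e-3), (50e-6, 50e-6), (0.4, 0.4),
                            (50.0, 50.0))


class TestTraceGeneration:
    def test_noiseless_trace_peaks_at_maximum_dimple_time(self, water):
        morph = generate_morphology(MEDIUM, 1)
        tr = generate_jump_trace(morph, water, omega=43.0, fps=1000, noise=0.0)
        pf = tr.per_frame()
        gt = tr.ground_truth
        t_peak = pf.t_s.iloc[int(np.argmax(pf.h_m))]
        assert abs(t_peak - gt["t_m"]) <= 1.0 / tr.frame_rate
        # the dimple growth rate v_s - v changes sign at the same moment
        v_body = np.gradient(pf.y_m.to_numpy(), 1e-3)
        growth = pf.v_s_mps.to_numpy() - v_body
        i_peak = int(np.argmax(pf.h_m))
        assert growth[max(i_peak - 3, 0)] > 0
        assert growth[min(i_peak + 3, len(growth) - 1)] < 0

    def test_large_individual_trace_shapes(self, water):
        # emulates the large filmed individual: 37.2 mg, 22.1 mm legs
        morph = InsectMorphology(body_mass=37.2e-6, leg_length=22.1e-3,
                                 support_length=10.5e-3, leg_radius=60e-6,
                                 rest_height=9e-3)
        tr = generate_jump_trace(morph, water, omega=36.0, fps=1000, noise=0.0)
        pf = tr.per_frame()
        vs = pf.v_s_mps.to_numpy()
        interior = int(np.argmax(vs))
        assert 0 < interior < len(vs) - 1  # bell-shaped leg speed
        assert np.all(np.diff(pf.y_m.to_numpy()) > -1e-6)  # body rises

    def test_same_seed_reproducible_different_seed_same_signal(self, water):
        morph = generate_morphology(MEDIUM, 3)
        a = generate_jump_trace(morph, water, 48.0, noise=0.02, seed=11)
        b = generate_jump_trace(morph, water, 48.0, noise=0.02, seed=11)
        c = generate_jump_trace(morph, water, 48.0, noise=0.02, seed=12)
        assert np.array_equal(a.frames.h_m, b.frames.h_m)
        assert not np.array_equal(a.frames.h_m, c.frames.h_m)
        # underlying noiseless signal identical: noise averages away
        clean = generate_jump_trace(morph, water, 48.0, noise=0.0)
        assert a.ground_truth["v_t"] == clean.ground_truth["v_t"]

    def test_per_leg_replicates_present(self, water):
        morph = generate_morphology(MEDIUM, 5)
        tr = generate_jump_trace(morph, water, 48.0, noise=0.01, seed=0)
        assert set(tr.frames.leg_id) == {"mid_L", "mid_R", "hind_L", "hind_R"}
        spread = tr.frames.groupby("t_s")["h_m"].std()
        assert spread.median() > 0

    def test_negative_noise_rejected(self, water):
        with pytest.raises(DomainError):
            generate_jump_trace(generate_morphology(MEDIUM, 0), water, 48.0, noise=-0.1)


class TestRecovery:
    def test_noiseless_round_trip_within_discretization(self, water):
        morph = generate_morphology(MEDIUM, 1)
        omega = sample_omega(MEDIUM, 2)
        tr = generate_jump_trace(morph, water, omega, fps=1000, noise=0.0)
        est = recover_parameters(tr)
        gt = tr.ground_truth
        frame = 1.0 / tr.frame_rate
        assert abs(est.omega - omega) / omega < 0.01
        assert abs(est.delta_l - gt["delta_l"]) / gt["delta_l"] < 0.01
        assert abs(est.t_m - gt["t_m"]) <= frame
        assert abs(est.takeoff_time - gt["t_t"]) <= frame
        assert abs(est.h_m - gt["h_m"]) / gt["h_m"] < 0.01
        assert abs(est.v_t - gt["v_t"]) / gt["v_t"] < 0.01

    def test_raw_peak_estimator_bias_is_exposed(self, water):
        # max of a finite-differenced noisy series overshoots: bias > 0
        biases = []
        ss = np.random.SeedSequence(99)
        for child in ss.spawn(30):
            rng = np.random.default_rng(int(child.generate_state(1)[0] % 2**31))
            m = generate_morphology(MEDIUM, rng)
            w = sample_omega(MEDIUM, rng)
            tr = generate_jump_trace(m, water, w, fps=1000, noise=0.02, seed=rng)
            est = recover_parameters(tr)
            biases.append((est.omega_peak_raw - w) / w)
        assert np.median(biases) > 0.05

    def test_lower_frame_rate_recovers_worse(self, water):
        errs = {500: [], 1000: []}
        ss = np.random.SeedSequence(7)
        for child in ss.spawn(40):
            seed = int(child.generate_state(1)[0] % 2**31)
            for fps in (500, 1000):
                rng = np.random.default_rng(seed)
                m = generate_morphology(MEDIUM, rng)
                w = sample_omega(MEDIUM, rng)
                tr = generate_jump_trace(m, water, w, fps=fps, noise=0.02, seed=rng)
                est = recover_parameters(tr)
                errs[fps].append(abs(est.omega - w) / w)
        assert np.median(errs[500]) >= np.median(errs[1000])

    def test_short_trace_rejected(self, water):
        morph = generate_morphology(MEDIUM, 1)
        tr = generate_jump_trace(morph, water, 48.0, fps=200, noise=0.0)
        pruned = tr.frames[tr.frames.t_s < 0.004]
        short = type(tr)(frame_rate=200.0, noise=0.0, frames=pruned,
                         ground_truth=tr.ground_truth)
        with pytest.raises(DomainError):
            recover_parameters(short)


class TestRecoveryExperiment:
    def test_single_noiseless_row_has_near_zero_errors(self):
        df = recovery_experiment([MEDIUM], n_per_template=1, noise_levels=(0.0,),
                                 seed=3)
        assert len(df) == 1
        assert df.omega_rel_err.iloc[0] < 0.01

    def test_error_medians_increase_with_noise(self):
        df = recovery_experiment([MEDIUM], n_per_template=12,
                                 noise_levels=(0.0, 0.01, 0.04), seed=5)
        med = df.groupby("noise")["omega_rel_err"].median()
        assert med.loc[0.0] < med.loc[0.01] < med.loc[0.04]

    def test_rows_record_reproducible_seeds(self):
        df1 = recovery_experiment([MEDIUM], n_per_template=3, noise_levels=(0.02,),
                                  seed=11)
        df2 = recovery_experiment([MEDIUM], n_per_template=3, noise_levels=(0.02,),
                                  seed=11)
        assert df1.equals(df2)
        assert df1.seed.nunique() == 3
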