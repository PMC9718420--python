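"""Simulation experiments against the closed-form theory they should realise."""

import numpy as np
import pytest
from dataclasses import replace

from inhplast import (
    DriveSpec,
    FeedforwardParams,
    PlasticityParams,
    ei_induction_experiment,
    ei_ratios,
    feedback_motif_stability_map,
    line_attractor,
    perturbation_experiment,
    run_feedforward,
    stability_condition,
    varying_drive_experiment,
)


class TestRunFeedforward:
    def test_converges_onto_line_attractor(self, motif_params, nonlinear_plasticity):
        """From [1.5, 0.5] the weights settle on the attractor at the target rate."""
        traj = run_feedforward(
            motif_params,
            nonlinear_plasticity,
            nonlinear_plasticity.initial_weights(1.5, 0.5),
            T=100.0,
            stop_when_converged=True,
        )
        assert traj.converged and not traj.diverged
        assert traj.final_rates.nu_E == pytest.approx(1.0, abs=1e-3)
        line = line_attractor(motif_params, c_post=1.0)
        assert abs(line.side(traj.final.w_EE, traj.final.w_EI)) < 1e-3
        # realized weight ratio matches the analytic prediction at the final w_EI
        rep = ei_ratios(motif_params, nonlinear_plasticity, traj.final.w_EI)
        assert traj.final.w_EE / traj.final.w_EI == pytest.approx(rep.R, abs=1e-3)

    def test_excitation_dominant_init_still_converges(self, sim_params, nonlinear_plasticity):
        """The nonlinear rule has no unstable region: [2.5, 1] also converges."""
        traj = run_feedforward(
            sim_params,
            nonlinear_plasticity,
            nonlinear_plasticity.initial_weights(2.5, 1.0),
            T=200.0,
            stop_when_converged=True,
        )
        assert traj.converged and not traj.diverged
        assert traj.final_rates.nu_E == pytest.approx(1.0, abs=1e-3)

    def test_linear_rule_diverges_from_excitation_dominant_init(
        self, motif_params, linear_plasticity
    ):
        traj = run_feedforward(
            motif_params, linear_plasticity, linear_plasticity.initial_weights(2.5, 1.0), T=100.0
        )
        assert traj.diverged and traj.t_diverged is not None

    def test_linear_rule_converges_from_inhibition_dominant_init(
        self, motif_params, linear_plasticity
    ):
        traj = run_feedforward(
            motif_params,
            linear_plasticity,
            linear_plasticity.initial_weights(1.5, 0.5),
            T=200.0,
            stop_when_converged=True,
        )
        assert traj.converged and not traj.diverged

    def test_trajectory_invariants(self, sim_params, nonlinear_plasticity):
        traj = run_feedforward(
            sim_params, nonlinear_plasticity, nonlinear_plasticity.initial_weights(1.5, 1.8), T=20.0
        )
        assert np.all(np.diff(traj.t) > 0)
        assert np.all(traj.nu_E >= 0) and np.all(traj.nu_I >= 0)
        assert np.all(traj.w_EE >= nonlinear_plasticity.weight_floor)
        assert np.all(traj.w_EI >= nonlinear_plasticity.weight_floor)


class TestDynamicThresholds:
    @pytest.mark.parametrize("c_init", [(0.7, 1.3), (1.3, 0.7)])
    def test_thresholds_match_and_rates_stabilise(self, c_init):
        """Sliding thresholds converge onto a common value from either ordering.

        Requires an inhibitory rate above the presynaptic rate for the
        matched state to be attracting; the default threshold-matching
        regime uses rho_I = 2 (nu_I = 3).
        """
        p = FeedforwardParams(rho_I=2.0, dt=1e-3)
        pl = PlasticityParams(
            dynamic_thresholds=True, tau_c=2.0, c_post_E_init=c_init[0], c_post_I_init=c_init[1]
        )
        traj = run_feedforward(p, pl, pl.initial_weights(1.5, 0.5), T=20.0, record_every=200)
        final = traj.final
        assert abs(final.c_post_E - final.c_post_I) < 1e-3
        assert final.w_EE > 0 and final.w_EI > 0
        # the stabilised rate equals the common threshold
        assert traj.final_rates.nu_E == pytest.approx(final.c_post_I, abs=1e-2)


class TestPerturbation:
    def test_rate_recovers_and_weights_follow_perturbation_sign(
        self, motif_params, nonlinear_plasticity
    ):
        for rho_disr in (2.5, 1.5):
            res = perturbation_experiment(
                motif_params, nonlinear_plasticity, rho_base=2.0, rho_disr=rho_disr
            )
            s = res["summary"]
            assert s["nu_E_post"] == pytest.approx(1.0, abs=1e-3)
            sign = np.sign(rho_disr - 2.0)
            assert np.sign(s["delta_w_EE"]) == sign
            assert np.sign(s["delta_w_EI"]) == sign

    def test_null_perturbation_changes_nothing(self, motif_params, nonlinear_plasticity):
        res = perturbation_experiment(
            motif_params, nonlinear_plasticity, rho_base=2.0, rho_disr=2.0
        )
        s = res["summary"]
        assert s["delta_w_EE"] == pytest.approx(0.0, abs=1e-9)
        assert s["delta_w_EI"] == pytest.approx(0.0, abs=1e-9)
        assert s["c_pre_E_after"] == pytest.approx(s["c_pre_E_before"], abs=1e-9)

    def test_upward_perturbation_raises_presynaptic_threshold(
        self, motif_params, nonlinear_plasticity
    ):
        res = perturbation_experiment(
            motif_params, nonlinear_plasticity, rho_base=2.0, rho_disr=2.5
        )
        s = res["summary"]
        assert s["c_pre_E_after"] > s["c_pre_E_before"]


class TestEIInduction:
    def test_draw_on_attractor_is_a_fixed_point(self, sim_params, nonlinear_plasticity):
        line = line_attractor(sim_params, c_post=1.0)
        w_EE = 1.5
        w_EI = float(line.w_EI_at(w_EE))
        traj = run_feedforward(
            sim_params,
            nonlinear_plasticity,
            nonlinear_plasticity.initial_weights(w_EE, w_EI),
            T=0.5,
        )
        assert traj.final.w_EE / traj.final.w_EI == pytest.approx(w_EE / w_EI, abs=1e-9)

    def test_inhibitory_weights_change_more(self, sim_params, nonlinear_plasticity):
        tab = ei_induction_experiment(
            sim_params, nonlinear_plasticity, n_draws=100, seed=3
        )
        ok = tab[~tab.diverged]
        assert len(ok) > 50
        assert ok.dw_EI_pct.abs().mean() > ok.dw_EE_pct.abs().mean()
        assert (ok.R_before <= 12.0).all()

    def test_long_induction_reaches_analytic_ratio(self, sim_params, nonlinear_plasticity):
        tab = ei_induction_experiment(
            sim_params, nonlinear_plasticity, n_draws=8, induction_time=100.0, seed=5, dt=0.01
        )
        ok = tab[~tab.diverged]
        active = ok[(ok.dw_EE_pct != 0) | (ok.dw_EI_pct != 0)]
        assert len(active) >= len(ok) // 2
        for _, row in active.iterrows():
            # draws that stay active end on the attractor, where the weight
            # ratio is R = R_inf + c/(rho_E * w_EI) >= R_inf
            assert row.R_after >= 0.75 - 1e-6
        # draws starting in the silent region freeze there (no plasticity)
        frozen = ok[(ok.dw_EE_pct == 0) & (ok.dw_EI_pct == 0)]
        assert (frozen.R_after == frozen.R_before).all()

    def test_rejects_empty_ensemble(self, sim_params, nonlinear_plasticity):
        with pytest.raises(ValueError):
            ei_induction_experiment(sim_params, nonlinear_plasticity, n_draws=0)


class TestVaryingDrive:
    def test_zero_amplitude_matches_constant_drive(self, sim_params, nonlinear_plasticity):
        flat = DriveSpec(target="rho_add", kind="sinusoid", amplitude=0.0, omega=0.01)
        res = varying_drive_experiment(sim_params, nonlinear_plasticity, flat, T=50.0)
        ref = run_feedforward(
            sim_params,
            nonlinear_plasticity,
            nonlinear_plasticity.initial_weights(1.5, 0.5),
            T=50.0,
        )
        np.testing.assert_allclose(res["trajectory"].w_EE, ref.w_EE, rtol=0, atol=0)
        np.testing.assert_allclose(res["trajectory"].w_EI, ref.w_EI, rtol=0, atol=0)

    def test_postsynaptic_noise_keeps_weights_bounded(self, sim_params, nonlinear_plasticity):
        drv = DriveSpec(target="rho_add", kind="gaussian_noise", std=0.01)
        res = varying_drive_experiment(
            sim_params, nonlinear_plasticity, drv, T=500.0, seed=21, record_every=5
        )
        s = res["summary"]
        assert not s["diverged"]
        assert abs(s["drift_slope_w_EE"]) < 1e-5
        assert abs(s["drift_slope_w_EI"]) < 1e-5
        traj = res["trajectory"]
        half = len(traj.t) // 2
        assert traj.w_EE[half:].max() - traj.w_EE[half:].min() < 0.1

    def test_presynaptic_sinusoid_drives_slow_weight_growth(
        self, sim_params, nonlinear_plasticity
    ):
        drv = DriveSpec(target="rho_E", kind="sinusoid", offset=2.0, amplitude=0.5, omega=0.01)
        res = varying_drive_experiment(
            sim_params, nonlinear_plasticity, drv, T=3000.0, record_every=20
        )
        s = res["summary"]
        assert s["drift_slope_w_EE"] > 0
        assert s["drift_slope_w_EI"] > 0
        assert s["nu_E_mean"] == pytest.approx(1.0, abs=0.05)

    def test_postsynaptic_sinusoid_shuttles_between_shifted_attractors(
        self, sim_params, nonlinear_plasticity
    ):
        """At each drive extremum the weights sit on the shifted attractor.

        The additive drive moves only the attractor intercept, so the
        trajectory oscillates between two parallel lines whose slope is
        the unperturbed attractor slope.
        """
        omega = 0.1
        drv = DriveSpec(target="rho_add", kind="sinusoid", amplitude=0.25, omega=omega)
        res = varying_drive_experiment(
            sim_params, nonlinear_plasticity, drv, T=2000.0, record_every=1
        )
        traj = res["trajectory"]
        period = 2 * np.pi / omega
        base_slope = line_attractor(sim_params, c_post=1.0).slope
        for phase, rho_add in ((period / 4, 0.25), (3 * period / 4, -0.25)):
            t_ext = np.arange(phase, 2000.0, period)
            idx = np.searchsorted(traj.t, t_ext)
            idx = idx[idx < len(traj.t)][5:]  # discard the initial transient
            line = line_attractor(sim_params, c_post=1.0, rho_add=rho_add)
            assert line.slope == pytest.approx(base_slope, rel=0.02)
            dist = np.abs(traj.w_EI[idx] - line.w_EI_at(traj.w_EE[idx]))
            assert dist.max() < 1e-3


class TestFeedbackMotif:
    @pytest.fixture
    def e_driven_params(self):
        # inhibition driven purely by (feedforward + feedback) excitation
        return FeedforwardParams(rho_I=0.0, dt=0.01)

    def test_zero_feedback_matches_closed_form(self, e_driven_params, nonlinear_plasticity):
        grid = np.array([0.0, 0.3, 0.6, 0.9])
        m = feedback_motif_stability_map(grid, [0.0], e_driven_params, nonlinear_plasticity, T=150.0)
        for i, wff in enumerate(grid):
            p = replace(e_driven_params, w_IE=float(wff))
            assert m[i, 0] == stability_condition(p, nonlinear_plasticity).stable

    def test_map_is_monotone_and_origin_unstable(self, e_driven_params, nonlinear_plasticity):
        grid = np.linspace(0.0, 1.0, 5)
        m = feedback_motif_stability_map(grid, grid, e_driven_params, nonlinear_plasticity, T=150.0)
        assert not m[0, 0]  # no inhibition at all: runaway
        # increasing either weight never destabilises
        assert np.all(m[1:, :] >= m[:-1, :])
        assert np.all(m[:, 1:] >= m[:, :-1])


class TestStabilitySweep:
    def test_simulation_agrees_with_dominance_condition(self):
        """Seeded random parameter sets >=10% off the boundary: full agreement."""
        rng = np.random.default_rng(42)
        n_checked = 0
        while n_checked < 50:
            p_kw = dict(
                rho_E=rng.uniform(0.5, 3.0),
                rho_I=rng.uniform(0.0, 1.5),
                w_IE=rng.uniform(0.2, 1.0),
            )
            pl = PlasticityParams(
                tau_w_E=rng.uniform(0.5, 2.0), tau_w_I=rng.uniform(0.1, 0.5)
            )
            rep = stability_condition(FeedforwardParams(**p_kw), pl)
            if abs(rep.lhs - rep.rhs) < 0.1 * rep.rhs:
                continue
            n_checked += 1
            dt = min(0.05, 0.5 / (rep.lhs + rep.rhs))
            params = FeedforwardParams(**p_kw, dt=dt)
            # start on the potentiation side (nu_E = 2*c) so an unstable
            # flow blows up instead of freezing in the silent region
            w_EE0 = 1.5
            w_EI0 = max((params.rho_E * w_EE0 - 2.0) / params.nu_I_steady(), 0.01)
            traj = run_feedforward(
                params, pl, pl.initial_weights(w_EE0, w_EI0), T=2000.0, stop_when_converged=True
            )
            assert traj.diverged != rep.stable, f"disagreement at {p_kw}, {pl}"
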