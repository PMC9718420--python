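"""Single-postsynaptic-neuron simulation experiments.

Each experiment integrates the feedforward motif with one of the
plasticity rules and summarises the outcome: convergence to the line
attractor, recovery of the target rate after an input perturbation,
the distribution of E/I ratios after brief plasticity induction from
random initial weights, weight drift under fluctuating drive, and the
stability map of the feedback inhibitory motif.

Integration runs the rates in the instantaneous limit by default
(rates at their steady state given the current weights and drive),
which matches the quasi-static separation of timescales assumed by the
closed-form theory; per step the order is: evaluate drive, update
rates, compute weight derivatives from the updated rates, update
weights (and thresholds when sliding thresholds are enabled).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    CONSTANT_DRIVE,
    DriveSpec,
    FeedforwardParams,
    RateState,
    WeightState,
    rectify,
    steady_state_rates,
    step_rates,
)
from .plasticity import PlasticityParams, dw_ee, dw_ei, step_thresholds, step_weights
from . import analysis

logger = logging.getLogger(__name__)

__all__ = [
    "Trajectory",
    "FeedbackMotifParams",
    "run_feedforward",
    "perturbation_experiment",
    "ei_induction_experiment",
    "varying_drive_experiment",
    "feedback_motif_stability_map",
]

#: weights above this are classified as runaway dynamics
DIVERGENCE_GUARD = 1e6

#: run-in convergence criterion: max |dw| per unit time
CONVERGENCE_TOL = 1e-8

_LOG_EVERY = 1000  # steps between progress log lines


@dataclass
class Trajectory:
    """Recorded time course of rates, weights and thresholds.

    ``diverged`` is set (with ``t_diverged``) when any weight exceeded
    the divergence guard or turned non-finite; integration stops there.
    ``converged`` is set when the run ended because the weight
    derivatives fell below the convergence tolerance.
    """

    t: np.ndarray
    nu_E: np.ndarray
    nu_I: np.ndarray
    w_EE: np.ndarray
    w_EI: np.ndarray
    c_post_E: np.ndarray
    c_post_I: np.ndarray
    diverged: bool = False
    t_diverged: float | None = None
    converged: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("trajectory time grid must be strictly increasing")

    @property
    def final(self) -> WeightState:
        return WeightState(
            w_EE=float(self.w_EE[-1]),
            w_EI=float(self.w_EI[-1]),
            c_post_E=float(self.c_post_E[-1]),
            c_post_I=float(self.c_post_I[-1]),
            t=float(self.t[-1]),
        )

    @property
    def final_rates(self) -> RateState:
        return RateState(nu_E=float(self.nu_E[-1]), nu_I=float(self.nu_I[-1]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "nu_E": self.nu_E,
                "nu_I": self.nu_I,
                "w_EE": self.w_EE,
                "w_EI": self.w_EI,
                "c_post_E": self.c_post_E,
                "c_post_I": self.c_post_I,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _rates_for(
    params: FeedforwardParams,
    state: WeightState,
    drive: DriveSpec,
    t: float,
    rng,
    mode: str,
    prev: RateState,
) -> RateState:
    if mode == "euler":
        return step_rates(prev, state, params, drive, t, rng)
    rho_E, rho_I, rho_add = drive.resolve(params, t, rng)
    return steady_state_rates(params, state, rho_add=rho_add, rho_E=rho_E, rho_I=rho_I)


def run_feedforward(
    params: FeedforwardParams,
    plasticity: PlasticityParams,
    initial: WeightState,
    drive: DriveSpec = CONSTANT_DRIVE,
    T: float = 100.0,
    seed: int | None = None,
    record_every: int = 1,
    rate_mode: str = "instantaneous",
    stop_when_converged: bool = False,
    divergence_guard: float = DIVERGENCE_GUARD,
) -> Trajectory:
    """Integrate rates and the selected plasticity rule for duration ``T``.

    ``rate_mode`` is ``"instantaneous"`` (rates at steady state each
    step; default) or ``"euler"`` (explicit rate dynamics; requires
    ``dt <= tau_FR``).  With ``stop_when_converged`` the run ends early
    once ``max(|dw_EE|, |dw_EI|) < CONVERGENCE_TOL`` per unit time.

    Divergence (a weight beyond ``divergence_guard``, or a non-finite
    value) sets the trajectory's ``diverged`` flag with the time of
    blow-up instead of raising.
    """
    if rate_mode not in ("instantaneous", "euler"):
        raise ValueError(f"unknown rate mode {rate_mode!r}")
    rng = np.random.default_rng(seed)
    dt = params.dt
    n_steps = int(round(T / dt))
    state = initial
    rates = RateState()

    rec_t, rec = [], []
    diverged, t_div, converged = False, None, False

    def record(t: float) -> None:
        if rec_t and rec_t[-1] >= t:
            return
        rec_t.append(t)
        rec.append(
            (rates.nu_E, rates.nu_I, state.w_EE, state.w_EI, state.c_post_E, state.c_post_I)
        )

    for i in range(n_steps):
        t = initial.t + i * dt
        rates = _rates_for(params, state, drive, t, rng, rate_mode, rates)
        dwee = dw_ee(params.rho_E, rates.nu_E, state.c_post_E, plasticity.tau_w_E)
        dwei = dw_ei(plasticity, rates.nu_I, rates.nu_E, state.c_post_I)
        state = step_weights(state, dwee, dwei, dt, plasticity.weight_floor)
        if plasticity.dynamic_thresholds:
            state = step_thresholds(state, dwee, dwei, plasticity.tau_c, dt)
        state = replace(state, t=t + dt)

        bad = not (math.isfinite(state.w_EE) and math.isfinite(state.w_EI))
        if bad or max(state.w_EE, state.w_EI) > divergence_guard:
            diverged, t_div = True, t + dt
            record(t + dt)
            break
        if i % record_every == 0:
            record(t + dt)
        if i % _LOG_EVERY == 0 and i:
            logger.info("t=%.3f w_EE=%.4f w_EI=%.4f nu_E=%.4f", t, state.w_EE, state.w_EI, rates.nu_E)
        if stop_when_converged and max(abs(dwee), abs(dwei)) < CONVERGENCE_TOL:
            converged = True
            record(t + dt)
            break

    if not rec_t or rec_t[-1] < state.t:
        rates = _rates_for(params, state, drive, state.t, rng, rate_mode, rates)
        record(state.t)

    arr = np.asarray(rec)
    return Trajectory(
        t=np.asarray(rec_t),
        nu_E=arr[:, 0],
        nu_I=arr[:, 1],
        w_EE=arr[:, 2],
        w_EI=arr[:, 3],
        c_post_E=arr[:, 4],
        c_post_I=arr[:, 5],
        diverged=diverged,
        t_diverged=t_div,
        converged=converged,
        meta={"rate_mode": rate_mode, "T": T, "seed": seed},
    )


def perturbation_experiment(
    params: FeedforwardParams,
    plasticity: PlasticityParams,
    rho_base: float = 2.0,
    rho_disr: float = 2.5,
    t_runin: float = 400.0,
    T: float = 400.0,
    initial: WeightState | None = None,
) -> dict:
    """Step the presynaptic rate after a converged run-in (input perturbation).

    The system is first run at ``rho_base`` until the weight derivatives
    vanish (``CONVERGENCE_TOL``); the presynaptic rate then steps
    instantaneously and permanently to ``rho_disr``.  Returns the two
    trajectories plus a summary of pre/post steady rates and weights,
    the shifted presynaptic LTD/LTP threshold and the shifted line
    attractor.
    """
    if initial is None:
        initial = plasticity.initial_weights(1.0, 1.0)
    base_params = replace(params, rho_E=rho_base)
    pre = run_feedforward(
        base_params, plasticity, initial, T=t_runin, stop_when_converged=True
    )
    if not pre.converged:
        raise RuntimeError("run-in did not converge before the perturbation")
    state0 = pre.final

    disr_params = replace(params, rho_E=rho_disr)
    post = run_feedforward(
        disr_params, plasticity, state0, T=T, stop_when_converged=True
    )

    c_post = initial.c_post_I
    pre_rates, post_rates = pre.final_rates, post.final_rates
    thr_pre = analysis.presynaptic_threshold(
        state0.w_EE, state0.w_EI, pre_rates.nu_I, c_post, params.N_E, params.N_I
    )
    final = post.final
    thr_post = analysis.presynaptic_threshold(
        final.w_EE, final.w_EI, post_rates.nu_I, c_post, params.N_E, params.N_I
    )
    return {
        "pre": pre,
        "post": post,
        "summary": {
            "rho_base": rho_base,
            "rho_disr": rho_disr,
            "nu_E_pre": pre_rates.nu_E,
            "nu_E_post": post_rates.nu_E,
            "nu_I_pre": pre_rates.nu_I,
            "nu_I_post": post_rates.nu_I,
            "w_EE_pre": state0.w_EE,
            "w_EE_post": final.w_EE,
            "w_EI_pre": state0.w_EI,
            "w_EI_post": final.w_EI,
            "delta_w_EE": final.w_EE - state0.w_EE,
            "delta_w_EI": final.w_EI - state0.w_EI,
            "c_pre_E_before": thr_pre.c_pre_E,
            "c_pre_E_after": thr_post.c_pre_E,
            "attractor_before": analysis.line_attractor(base_params, c_post).to_dict(),
            "attractor_after": analysis.line_attractor(disr_params, c_post).to_dict(),
        },
    }


def ei_induction_experiment(
    params: FeedforwardParams,
    plasticity: PlasticityParams,
    n_draws: int = 100,
    induction_time: float = 0.1,
    weight_range: tuple[float, float] = (0.0, 3.0),
    exclusion_ratio: float = 12.0,
    seed: int = 0,
    dt: float = 1e-3,
) -> pd.DataFrame:
    """Brief plasticity induction from random initial weights.

    Initial ``(w_EE, w_EI)`` pairs are drawn uniformly from
    ``weight_range``; draws whose initial E/I ratio exceeds
    ``exclusion_ratio`` (including inhibitory weights so small the
    ratio is effectively unbounded) are dropped before induction.
    Plasticity then runs for ``induction_time`` and the table reports,
    per retained draw, the E/I ratio before and after induction and
    the percent change of each weight.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    sim_params = replace(params, dt=dt)
    rows = []
    for _ in range(n_draws):
        w0 = rng.uniform(weight_range[0], weight_range[1], size=2)
        if w0[1] <= 0 or w0[0] / w0[1] > exclusion_ratio:
            continue
        initial = plasticity.initial_weights(float(w0[0]), float(w0[1]))
        traj = run_feedforward(sim_params, plasticity, initial, T=induction_time)
        final = traj.final
        if traj.diverged or final.w_EI <= 0:
            rows.append(
                {
                    "R_before": w0[0] / w0[1],
                    "R_after": np.nan,
                    "dw_EE_pct": np.nan,
                    "dw_EI_pct": np.nan,
                    "diverged": True,
                }
            )
            continue
        rows.append(
            {
                "R_before": w0[0] / w0[1],
                "R_after": final.w_EE / final.w_EI,
                "dw_EE_pct": 100.0 * (final.w_EE - w0[0]) / w0[0] if w0[0] > 0 else np.nan,
                "dw_EI_pct": 100.0 * (final.w_EI - w0[1]) / w0[1],
                "diverged": False,
            }
        )
    return pd.DataFrame(rows)


def varying_drive_experiment(
    params: FeedforwardParams,
    plasticity: PlasticityParams,
    drive: DriveSpec,
    T: float = 2000.0,
    initial: WeightState | None = None,
    seed: int | None = None,
    record_every: int = 1,
) -> dict:
    """Simulate under fluctuating drive and summarise weight drift.

    The drift summary is the ordinary-least-squares slope of each
    weight against time over the final half of the run, together with
    the mean and variance of the postsynaptic rate over that window.
    """
    if drive.kind not in ("gaussian_noise", "sinusoid", "constant"):
        raise ValueError("varying-drive experiment expects noise, sinusoid or constant drive")
    if initial is None:
        initial = plasticity.initial_weights(1.5, 0.5)
    traj = run_feedforward(
        params,
        plasticity,
        initial,
        drive=drive,
        T=T,
        seed=seed if seed is not None else drive.seed,
        record_every=record_every,
    )
    half = len(traj.t) // 2
    tt = traj.t[half:]
    slope_ee = float(stats.linregress(tt, traj.w_EE[half:]).slope)
    slope_ei = float(stats.linregress(tt, traj.w_EI[half:]).slope)
    return {
        "trajectory": traj,
        "summary": {
            "drift_slope_w_EE": slope_ee,
            "drift_slope_w_EI": slope_ei,
            "nu_E_mean": float(np.mean(traj.nu_E[half:])),
            "nu_E_var": float(np.var(traj.nu_E[half:])),
            "diverged": traj.diverged,
        },
    }


@dataclass(frozen=True)
class FeedbackMotifParams:
    """Feedforward motif extended with postsynaptic feedback onto inhibition.

    The inhibitory population receives the presynaptic excitatory input
    through ``w_FF_IE`` and the postsynaptic excitatory neuron's own
    rate through ``w_FB_IE``:

        nu_I = [N_E*rho_E*w_FF_IE + w_FB_IE*nu_E + rho_I]_+

    (inferred minimal form of the feedback inhibitory motif).
    """

    w_FF_IE: float = 0.5
    w_FB_IE: float = 0.5
    base: FeedforwardParams = field(default_factory=FeedforwardParams)

    def __post_init__(self) -> None:
        if self.w_FF_IE < 0 or self.w_FB_IE < 0:
            raise ValueError("E-to-I weights must be nonnegative")


def _feedback_rates(p: FeedbackMotifParams, w: WeightState) -> RateState:
    """Self-consistent instantaneous rates of the feedback motif.

    Solves the coupled rectified-linear fixed point case by case:
    both populations active, inhibition silencing excitation, or
    inhibition itself rectified to zero.
    """
    b = p.base
    ff = b.N_E * b.rho_E * p.w_FF_IE + b.rho_I
    exc = b.N_E * b.rho_E * w.w_EE
    # try: both rates positive
    denom = 1.0 + p.w_FB_IE * b.N_I * w.w_EI
    nu_E = (exc - b.N_I * w.w_EI * ff) / denom
    if nu_E > 0:
        nu_I = ff + p.w_FB_IE * nu_E
        if nu_I >= 0:
            return RateState(nu_E=nu_E, nu_I=nu_I)
    # postsynaptic neuron silenced
    nu_I = rectify(ff)
    nu_E = rectify(exc - b.N_I * nu_I * w.w_EI)
    return RateState(nu_E=nu_E, nu_I=nu_I)


def run_feedback_motif(
    params: FeedbackMotifParams,
    plasticity: PlasticityParams,
    initial: WeightState,
    T: float = 200.0,
    divergence_guard: float = DIVERGENCE_GUARD,
) -> Trajectory:
    """Integrate the feedback motif with instantaneous rates."""
    dt = params.base.dt
    n = int(round(T / dt))
    state = initial
    rec_t, rec = [], []
    diverged, t_div = False, None
    rates = _feedback_rates(params, state)
    for i in range(n):
        rates = _feedback_rates(params, state)
        dwee = dw_ee(params.base.rho_E, rates.nu_E, state.c_post_E, plasticity.tau_w_E)
        dwei = dw_ei(plasticity, rates.nu_I, rates.nu_E, state.c_post_I)
        state = step_weights(state, dwee, dwei, dt, plasticity.weight_floor)
        state = replace(state, t=initial.t + (i + 1) * dt)
        rec_t.append(state.t)
        rec.append((rates.nu_E, rates.nu_I, state.w_EE, state.w_EI, state.c_post_E, state.c_post_I))
        if not (math.isfinite(state.w_EE) and math.isfinite(state.w_EI)) or max(
            state.w_EE, state.w_EI
        ) > divergence_guard:
            diverged, t_div = True, state.t
            break
    arr = np.asarray(rec)
    return Trajectory(
        t=np.asarray(rec_t),
        nu_E=arr[:, 0],
        nu_I=arr[:, 1],
        w_EE=arr[:, 2],
        w_EI=arr[:, 3],
        c_post_E=arr[:, 4],
        c_post_I=arr[:, 5],
        diverged=diverged,
        t_diverged=t_div,
    )


def feedback_motif_stability_map(
    w_ff_grid,
    w_fb_grid,
    params: FeedforwardParams,
    plasticity: PlasticityParams,
    initial: WeightState | None = None,
    T: float = 200.0,
) -> np.ndarray:
    """Boolean stability matrix over a grid of (feedforward, feedback) E-to-I weights.

    Entry ``[i, j]`` is True when the simulation from the shared initial
    condition stays below the divergence guard for feedforward weight
    ``w_ff_grid[i]`` and feedback weight ``w_fb_grid[j]``.
    """
    if initial is None:
        initial = plasticity.initial_weights(1.5, 0.5)
    out = np.zeros((len(w_ff_grid), len(w_fb_grid)), dtype=bool)
    for i, wff in enumerate(w_ff_grid):
        for j, wfb in enumerate(w_fb_grid):
            p = FeedbackMotifParams(w_FF_IE=float(wff), w_FB_IE=float(wfb), base=params)
            traj = run_feedback_motif(p, plasticity, initial, T=T)
            out[i, j] = not traj.diverged
    return out
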