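"""Synaptic plasticity rules and the sliding LTD/LTP-threshold mechanism.

Three rate-based rules are implemented, all switching sign at a
postsynaptic LTD/LTP threshold ``c_post``:

- excitatory (Hebbian, nonlinear in the postsynaptic rate)::

      tau_w_E * dw_EE/dt = rho_E * nu_E * (nu_E - c_post_E)

- linear inhibitory (the classical homeostatic rule)::

      tau_w_I * dw_EI/dt = nu_I * (nu_E - c_post_I)

- nonlinear inhibitory (same sign structure as the excitatory rule)::

      tau_w_I * dw_EI/dt = nu_I * nu_E * (nu_E - c_post_I)

The nonlinear inhibitory rule is the stabilising mechanism studied
throughout this package: because the inhibitory weight change carries
the same factor ``nu_E * (nu_E - c_post)`` as the excitatory one,
inhibition potentiates whenever excitation does, and neither synapse
changes when the postsynaptic neuron is silent.

The sliding-threshold (metaplasticity) variant lets the two thresholds
move in opposite directions in proportion to the induced plasticity::

    tau_c * dc_post_E/dt = +dw_EE/dt
    tau_c * dc_post_I/dt = -dw_EI/dt

so a postsynaptic rate above ``c_post_E`` raises the excitatory
threshold while a rate above ``c_post_I`` lowers the inhibitory one;
the two thresholds converge onto a common value and the firing rate
settles there.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .model import WeightState

__all__ = [
    "PlasticityParams",
    "dw_ee",
    "dw_ei_linear",
    "dw_ei_nonlinear",
    "dw_ei",
    "step_weights",
    "step_thresholds",
]

#: smallest admissible LTD/LTP threshold; keeps the target rate meaningful
THRESHOLD_EPS = 1e-6


@dataclass(frozen=True)
class PlasticityParams:
    """Constants of the plasticity rules.

    ``tau_w_E`` and ``tau_w_I`` are the plasticity timescales (inverse
    learning rates; units Hz^2, or Hz for the linear inhibitory rule).
    ``inhibitory_rule`` selects ``"linear"`` or ``"nonlinear"``.
    ``tau_c`` is the threshold-adaptation timescale used when
    ``dynamic_thresholds`` is on; its default of 2 time units is slower
    than the weight-mediated rate feedback, which is required for the
    two thresholds to attract each other rather than run away.
    """

    tau_w_E: float = 1.0
    tau_w_I: float = 0.2
    c_post_E_init: float = 1.0
    c_post_I_init: float = 1.0
    inhibitory_rule: str = "nonlinear"
    dynamic_thresholds: bool = False
    tau_c: float = 2.0
    weight_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.tau_w_E <= 0:
            raise ValueError("tau_w_E must be positive")
        if self.tau_w_I <= 0:
            raise ValueError("tau_w_I must be positive")
        if self.tau_c <= 0:
            raise ValueError("tau_c must be positive")
        if self.weight_floor < 0:
            raise ValueError("weight_floor must be nonnegative")
        if self.inhibitory_rule not in ("linear", "nonlinear"):
            raise ValueError(f"unknown inhibitory rule {self.inhibitory_rule!r}")
        if self.c_post_E_init <= 0 or self.c_post_I_init <= 0:
            raise ValueError("initial LTD/LTP thresholds must be positive")

    def initial_weights(self, w_EE: float, w_EI: float, t: float = 0.0) -> WeightState:
        """Build a :class:`WeightState` carrying the initial thresholds."""
        return WeightState(
            w_EE=w_EE,
            w_EI=w_EI,
            c_post_E=self.c_post_E_init,
            c_post_I=self.c_post_I_init,
            t=t,
        )


def dw_ee(rho_E, nu_E, c_post_E, tau_w_E):
    """Excitatory weight-change rate ``rho_E*nu_E*(nu_E - c_post_E)/tau_w_E``."""
    return rho_E * nu_E * (nu_E - c_post_E) / tau_w_E


def dw_ei_linear(nu_I, nu_E, c_post_I, tau_w_I):
    """Linear inhibitory rule ``nu_I*(nu_E - c_post_I)/tau_w_I``.

    Note the nonzero depression at ``nu_E = 0`` — the feature that lets
    this rule destabilise strongly excitation-dominated initial weights.
    """
    return nu_I * (nu_E - c_post_I) / tau_w_I


def dw_ei_nonlinear(nu_I, nu_E, c_post_I, tau_w_I):
    """Nonlinear inhibitory rule ``nu_I*nu_E*(nu_E - c_post_I)/tau_w_I``.

    Vanishes whenever the postsynaptic neuron is silent, and changes
    with the same sign as the excitatory rule for matched thresholds.
    """
    return nu_I * nu_E * (nu_E - c_post_I) / tau_w_I


def dw_ei(params: PlasticityParams, nu_I, nu_E, c_post_I):
    """Inhibitory weight-change rate under the configured rule."""
    if params.inhibitory_rule == "linear":
        return dw_ei_linear(nu_I, nu_E, c_post_I, params.tau_w_I)
    return dw_ei_nonlinear(nu_I, nu_E, c_post_I, params.tau_w_I)


def step_weights(
    state: WeightState,
    dwee: float,
    dwei: float,
    dt: float,
    weight_floor: float = 0.0,
) -> WeightState:
    """One Euler step of both weights, clipped at the weight floor."""
    return replace(
        state,
        w_EE=max(state.w_EE + dwee * dt, weight_floor),
        w_EI=max(state.w_EI + dwei * dt, weight_floor),
    )


def step_thresholds(
    state: WeightState,
    dwee: float,
    dwei: float,
    tau_c: float,
    dt: float,
) -> WeightState:
    """One Euler step of the sliding LTD/LTP thresholds.

    The excitatory threshold moves with the excitatory weight-change
    rate and the inhibitory threshold against the inhibitory one; both
    are clamped strictly positive.
    """
    return replace(
        state,
        c_post_E=max(state.c_post_E + dwee * dt / tau_c, THRESHOLD_EPS),
        c_post_I=max(state.c_post_I - dwei * dt / tau_c, THRESHOLD_EPS),
    )
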