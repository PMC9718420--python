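"""Threshold-linear rate dynamics of the feedforward inhibitory motif.

A single postsynaptic excitatory neuron receives input from ``N_E``
presynaptic excitatory neurons (rate ``rho_E``, plastic weight ``w_EE``)
and from ``N_I`` inhibitory neurons (rate ``nu_I``, plastic weight
``w_EI``).  The inhibitory neurons are driven by the same presynaptic
excitatory population through a fixed weight ``w_IE`` plus an external
drive ``rho_I``:

    tau_FR_E * dnu_E/dt = -nu_E + [N_E*rho_E*w_EE - N_I*nu_I*w_EI + rho_add]_+
    tau_FR_I * dnu_I/dt = -nu_I + [N_E*rho_E*w_IE + rho_I]_+

where ``[x]_+ = max(x, 0)`` is the threshold-linear rectifier.  All
quantities are treated as population means, so ``N_E = N_I = 1``
reproduces the mean-field collapse; the counts are kept explicit so that
parameter sweeps over synapse numbers remain possible.

Time units
----------
All time constants and the Euler step ``dt`` are numbers in a single
consistent, arbitrary simulation time unit; parameter-table values are
taken verbatim.  Because the rate dynamics are orders of magnitude
faster than the plasticity dynamics, most experiments run the rates in
the instantaneous-integrator limit (``tau_FR = dt``), in which one Euler
step lands exactly on the steady state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "FeedforwardParams",
    "RateState",
    "WeightState",
    "DriveSpec",
    "rectify",
    "steady_state_rates",
    "step_rates",
]


def rectify(x):
    """Threshold-linear rectifier ``[x]_+``: negative values clamp to zero.

    Works on scalars and numpy arrays alike.
    """
    if isinstance(x, np.ndarray):
        return np.maximum(x, 0.0)
    return x if x > 0.0 else 0.0


@dataclass(frozen=True)
class FeedforwardParams:
    """Circuit constants of the feedforward inhibitory motif.

    Attributes
    ----------
    N_E, N_I:
        Number of presynaptic excitatory / inhibitory neurons.
    rho_E:
        Presynaptic excitatory firing rate (Hz).
    rho_I:
        External excitatory rate onto the inhibitory neurons (Hz).  May
        be negative to model inhibition of the inhibitory neurons
        (disinhibition).
    w_IE:
        Fixed excitatory-to-inhibitory weight.
    tau_FR_E, tau_FR_I:
        Time constants of the rate dynamics.
    dt:
        Euler integration step.
    """

    N_E: int = 1
    N_I: int = 1
    rho_E: float = 2.0
    rho_I: float = 0.5
    w_IE: float = 0.5
    tau_FR_E: float = 0.01
    tau_FR_I: float = 0.01
    dt: float = 0.1

    def __post_init__(self) -> None:
        if self.N_E < 1 or self.N_I < 1:
            raise ValueError("N_E and N_I must be >= 1")
        if self.rho_E < 0:
            raise ValueError("rho_E must be nonnegative")
        if self.w_IE < 0:
            raise ValueError("w_IE must be nonnegative")
        if self.tau_FR_E <= 0:
            raise ValueError("tau_FR_E must be positive")
        if self.tau_FR_I <= 0:
            raise ValueError("tau_FR_I must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def nu_I_steady(self, rho_E: float | None = None, rho_I: float | None = None) -> float:
        """Steady-state inhibitory rate ``[N_E*rho_E*w_IE + rho_I]_+``."""
        rE = self.rho_E if rho_E is None else rho_E
        rI = self.rho_I if rho_I is None else rho_I
        return rectify(self.N_E * rE * self.w_IE + rI)


@dataclass(frozen=True)
class RateState:
    """Instantaneous population rates (Hz); rectification keeps both >= 0."""

    nu_E: float = 0.0
    nu_I: float = 0.0

    def __post_init__(self) -> None:
        if self.nu_E < 0 or self.nu_I < 0:
            raise ValueError("rates must be nonnegative")


@dataclass(frozen=True)
class WeightState:
    """Plastic weights plus the (possibly sliding) LTD/LTP thresholds.

    ``c_post_E`` and ``c_post_I`` are the postsynaptic rates at which
    excitatory and inhibitory plasticity switch sign from depression to
    potentiation.  ``t`` tracks simulation time for trajectory
    bookkeeping.
    """

    w_EE: float
    w_EI: float
    c_post_E: float = 1.0
    c_post_I: float = 1.0
    t: float = 0.0

    def __post_init__(self) -> None:
        if self.w_EE < 0 or self.w_EI < 0:
            raise ValueError("weights must be nonnegative")
        if self.c_post_E <= 0 or self.c_post_I <= 0:
            raise ValueError("LTD/LTP thresholds must be positive")


@dataclass(frozen=True)
class DriveSpec:
    """Time-varying modulation of one input quantity.

    ``target`` selects what is modulated: the presynaptic rate
    ``"rho_E"``, an additive term on the postsynaptic neuron
    ``"rho_add"``, or the external inhibitory drive ``"rho_I"``.
    ``kind`` selects the waveform:

    - ``constant``: value ``base`` at all times
    - ``step``: ``base`` before ``t_switch``, ``disrupted`` after
    - ``gaussian_noise``: ``mean + std * N(0,1)`` drawn i.i.d. per Euler
      step (no sqrt(dt) scaling; the noise is specified per step)
    - ``sinusoid``: ``offset + amplitude * sin(omega * t)``
    """

    target: str = "rho_add"
    kind: str = "constant"
    base: float = 0.0
    disrupted: float = 0.0
    t_switch: float = 0.0
    mean: float = 0.0
    std: float = 0.0
    amplitude: float = 0.0
    omega: float = 0.0
    offset: float = 0.0
    seed: int | None = None

    _TARGETS = ("rho_E", "rho_add", "rho_I")
    _KINDS = ("constant", "step", "gaussian_noise", "sinusoid")

    def __post_init__(self) -> None:
        if self.target not in self._TARGETS:
            raise ValueError(f"unknown drive target {self.target!r}")
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown drive kind {self.kind!r}")
        if self.std < 0:
            raise ValueError("noise std must be nonnegative")
        if self.kind == "step" and self.t_switch < 0:
            raise ValueError("step switch time must be nonnegative")

    def value(self, t: float, rng: np.random.Generator | None = None) -> float:
        """Waveform value at time ``t`` (noise drawn from ``rng``)."""
        if self.kind == "constant":
            return self.base
        if self.kind == "step":
            return self.base if t < self.t_switch else self.disrupted
        if self.kind == "sinusoid":
            return self.offset + self.amplitude * math.sin(self.omega * t)
        if rng is None:
            raise ValueError("gaussian_noise drive requires a random generator")
        return self.mean + self.std * float(rng.standard_normal())

    def resolve(
        self, params: FeedforwardParams, t: float, rng: np.random.Generator | None = None
    ) -> tuple[float, float, float]:
        """Return the effective ``(rho_E, rho_I, rho_add)`` at time ``t``."""
        v = self.value(t, rng)
        if self.target == "rho_E":
            return v, params.rho_I, 0.0
        if self.target == "rho_I":
            return params.rho_E, v, 0.0
        return params.rho_E, params.rho_I, v


#: drive leaving every input at its parameter-table baseline
CONSTANT_DRIVE = DriveSpec(target="rho_add", kind="constant", base=0.0)


def steady_state_rates(
    params: FeedforwardParams,
    weights: WeightState,
    rho_add: float = 0.0,
    rho_E: float | None = None,
    rho_I: float | None = None,
) -> RateState:
    """Fixed point of the rate equations for frozen weights.

    The inhibitory population settles first (it receives no plastic
    input), then the postsynaptic excitatory neuron:

        nu_I = [N_E*rho_E*w_IE + rho_I]_+
        nu_E = [N_E*rho_E*w_EE - N_I*nu_I*w_EI + rho_add]_+
    """
    rE = params.rho_E if rho_E is None else rho_E
    nu_I = params.nu_I_steady(rho_E=rE, rho_I=rho_I)
    nu_E = rectify(params.N_E * rE * weights.w_EE - params.N_I * nu_I * weights.w_EI + rho_add)
    return RateState(nu_E=nu_E, nu_I=nu_I)


def step_rates(
    rates: RateState,
    weights: WeightState,
    params: FeedforwardParams,
    drive: DriveSpec = CONSTANT_DRIVE,
    t: float = 0.0,
    rng: np.random.Generator | None = None,
) -> RateState:
    """One explicit Euler step of both rate equations.

    Requires ``dt <= tau_FR`` for both populations (explicit-Euler
    stability).  At ``tau_FR = dt`` the update degenerates to the
    instantaneous steady state, which is the integration mode used for
    the multi-input circuits.
    """
    if params.dt > params.tau_FR_E or params.dt > params.tau_FR_I:
        raise ValueError(
            f"dt={params.dt} exceeds a rate time constant "
            f"(tau_FR_E={params.tau_FR_E}, tau_FR_I={params.tau_FR_I}); "
            "explicit Euler integration of the rate equations is unstable"
        )
    rho_E, rho_I, rho_add = drive.resolve(params, t, rng)
    target_I = rectify(params.N_E * rho_E * params.w_IE + rho_I)
    nu_I = rates.nu_I + (-rates.nu_I + target_I) * params.dt / params.tau_FR_I
    target_E = rectify(
        params.N_E * rho_E * weights.w_EE - params.N_I * rates.nu_I * weights.w_EI + rho_add
    )
    nu_E = rates.nu_E + (-rates.nu_E + target_E) * params.dt / params.tau_FR_E
    return RateState(nu_E=rectify(nu_E), nu_I=rectify(nu_I))


def with_time(weights: WeightState, t: float) -> WeightState:
    """Return a copy of ``weights`` stamped with simulation time ``t``."""
    return replace(weights, t=t)
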