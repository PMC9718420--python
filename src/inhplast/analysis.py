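"""Closed-form theory of the coupled weight dynamics.

For frozen input rates, the excitatory and nonlinear inhibitory rules
share the factor ``nu_E * (nu_E - c_post)``; their nullclines in the
``(w_EE, w_EI)`` plane therefore coincide whenever the two thresholds
are matched, producing a line attractor

    w_EI = (N_E*rho_E)/(N_I*nu_I) * w_EE - c_post/(N_I*nu_I)

whose slope equals the large-weight E/I ratio.  Linearising the coupled
weight system about any point of the line gives a rank-one Jacobian
with eigenvalues {Tr(J*), 0}; the attractor is stable exactly when

    N_I*nu_I**2 / tau_w_I  >  N_E*rho_E**2 / tau_w_E

i.e. when inhibitory plasticity is dominant.  For the *linear*
inhibitory rule the attractor coexists with a separatrix below which
initial weights diverge.  All of these objects are computed here in
closed form; :func:`jacobian_numeric` provides a finite-difference
cross-check that is independent of the algebra.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model import FeedforwardParams, WeightState, rectify, steady_state_rates
from .plasticity import PlasticityParams, dw_ee, dw_ei

__all__ = [
    "PhaseLines",
    "StabilityReport",
    "EIRatioReport",
    "AnalyticReport",
    "presynaptic_threshold",
    "presynaptic_threshold_selfconsistent",
    "line_attractor",
    "zero_rate_boundary",
    "separatrix_linear_rule",
    "stability_condition",
    "jacobian_numeric",
    "ei_ratios",
]


@dataclass(frozen=True)
class PhaseLines:
    """A straight line in the ``(w_EE, w_EI)`` phase plane.

    ``kind`` is one of ``attractor``, ``zero_rate`` or ``separatrix``.
    ``abscissa_intercept`` is the ``w_EE`` value at which the line
    crosses ``w_EI = 0`` (``None`` for a line through the origin with
    zero intercept handled explicitly).
    """

    kind: str
    slope: float
    intercept: float
    abscissa_intercept: float | None = None

    def w_EI_at(self, w_EE):
        """Evaluate the line at ``w_EE`` (scalar or array)."""
        return self.slope * np.asarray(w_EE) + self.intercept

    def side(self, w_EE: float, w_EI: float) -> float:
        """Signed vertical distance of a point from the line (>0 above)."""
        return w_EI - (self.slope * w_EE + self.intercept)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "slope": self.slope,
            "intercept": self.intercept,
            "abscissa_intercept": self.abscissa_intercept,
        }


@dataclass(frozen=True)
class StabilityReport:
    """Stability of the line attractor under the nonlinear rules.

    ``lhs``/``rhs`` are the inhibitory and excitatory dominance terms;
    the attractor is stable iff ``lhs > rhs``, equivalently iff the
    Jacobian trace is negative.  The determinant is identically zero,
    so the eigenvalues are ``{trace, 0}``.
    """

    lhs: float
    rhs: float
    stable: bool
    trace: float
    det: float
    eigenvalues: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "lhs": self.lhs,
            "rhs": self.rhs,
            "stable": self.stable,
            "trace": self.trace,
            "det": self.det,
            "eigenvalues": list(self.eigenvalues),
        }


@dataclass(frozen=True)
class EIRatioReport:
    """Excitatory-to-inhibitory ratios at the stable weight configuration.

    ``R`` is the weight ratio ``w_EE/w_EI`` on the attractor at the
    given ``w_EI``; ``R_inf`` its large-weight limit (the attractor
    slope); ``R_large_rhoE`` the limit of ``R_inf`` for large
    presynaptic rate; ``R_tot`` the total-input ratio.
    """

    R: float
    R_inf: float
    R_large_rhoE: float
    R_tot: float

    def to_dict(self) -> dict:
        return {
            "R": self.R,
            "R_inf": self.R_inf,
            "R_large_rhoE": self.R_large_rhoE,
            "R_tot": self.R_tot,
        }


@dataclass(frozen=True)
class AnalyticReport:
    """Presynaptic LTD/LTP threshold and the context it was computed in."""

    c_pre_E: float
    w_EE: float
    w_EI: float
    nu_I: float
    c_post: float

    def to_dict(self) -> dict:
        return {
            "c_pre_E": self.c_pre_E,
            "w_EE": self.w_EE,
            "w_EI": self.w_EI,
            "nu_I": self.nu_I,
            "c_post": self.c_post,
        }


def presynaptic_threshold(
    w_EE: float,
    w_EI: float,
    nu_I: float,
    c_post: float,
    N_E: int = 1,
    N_I: int = 1,
) -> AnalyticReport:
    """Presynaptic rate at which excitatory plasticity changes sign.

    With the postsynaptic rate at steady state, excitatory plasticity
    vanishes when ``nu_E = c_post``; solving for the presynaptic rate
    gives ``c_pre_E = (c_post + N_I*nu_I*w_EI) / (N_E*w_EE)``.  The
    inhibitory rate ``nu_I`` is treated as given, so the threshold can
    be evaluated for any hypothetical level of inhibition.
    """
    if w_EE <= 0:
        raise ValueError("presynaptic threshold undefined for w_EE = 0")
    c_pre = (c_post + N_I * nu_I * w_EI) / (N_E * w_EE)
    return AnalyticReport(c_pre_E=c_pre, w_EE=w_EE, w_EI=w_EI, nu_I=nu_I, c_post=c_post)


def presynaptic_threshold_selfconsistent(
    params: FeedforwardParams,
    w_EE: float,
    w_EI: float,
    c_post: float,
) -> AnalyticReport:
    """Presynaptic threshold with ``nu_I`` tied to the presynaptic rate.

    Convenience variant that closes the loop ``nu_I = N_E*rho_E*w_IE +
    rho_I``: it finds the presynaptic rate ``rho_E`` at which plasticity
    vanishes, i.e. solves

        N_E*rho_E*w_EE - N_I*(N_E*rho_E*w_IE + rho_I)*w_EI = c_post

    for ``rho_E``.  This is the threshold one reads off a plasticity
    curve plotted against the presynaptic rate.
    """
    if w_EE <= 0:
        raise ValueError("presynaptic threshold undefined for w_EE = 0")
    denom = params.N_E * w_EE - params.N_I * params.N_E * params.w_IE * w_EI
    if denom <= 0:
        raise ValueError(
            "no positive presynaptic rate induces LTP for these weights "
            "(inhibition grows at least as fast as excitation)"
        )
    rho_star = (c_post + params.N_I * params.rho_I * w_EI) / denom
    nu_I = params.nu_I_steady(rho_E=rho_star)
    return AnalyticReport(c_pre_E=rho_star, w_EE=w_EE, w_EI=w_EI, nu_I=nu_I, c_post=c_post)


def _steady_nu_I(params: FeedforwardParams) -> float:
    nu_I = params.nu_I_steady()
    if nu_I <= 0:
        raise ValueError("degenerate phase-plane geometry: steady-state nu_I = 0")
    return nu_I


def line_attractor(
    params: FeedforwardParams,
    c_post: float = 1.0,
    rho_add: float = 0.0,
) -> PhaseLines:
    """Line of fixed points of the coupled weight dynamics.

    An additive postsynaptic input ``rho_add`` shifts the intercept but
    never the slope, which is why fluctuating postsynaptic drive keeps
    the weights confined to a narrow band between shifted attractors.
    """
    nu_I = _steady_nu_I(params)
    slope = params.N_E * params.rho_E / (params.N_I * nu_I)
    intercept = -(c_post - rho_add) / (params.N_I * nu_I)
    abscissa = (c_post - rho_add) / (params.N_E * params.rho_E)
    return PhaseLines(kind="attractor", slope=slope, intercept=intercept, abscissa_intercept=abscissa)


def zero_rate_boundary(params: FeedforwardParams, c_post: float = 1.0) -> PhaseLines:
    """Boundary above which total inhibition silences the postsynaptic neuron.

    ``c_post`` is accepted for interface symmetry; the boundary itself
    does not depend on it.
    """
    nu_I = _steady_nu_I(params)
    slope = params.N_E * params.rho_E / (params.N_I * nu_I)
    return PhaseLines(kind="zero_rate", slope=slope, intercept=0.0, abscissa_intercept=0.0)


def separatrix_linear_rule(
    params: FeedforwardParams,
    plasticity: PlasticityParams,
) -> PhaseLines:
    """Line separating stable from unstable initial weights (linear rule).

    Initial weights *above* this line converge to the line attractor;
    weights below it run away.  Only meaningful for the linear
    inhibitory rule — the nonlinear rule removes the unstable region.
    """
    nu_I = _steady_nu_I(params)
    slope = params.N_E * params.rho_E / (params.N_I * nu_I)
    offset = nu_I * plasticity.tau_w_E / (params.N_E * params.rho_E**2 * plasticity.tau_w_I)
    return PhaseLines(
        kind="separatrix",
        slope=slope,
        intercept=-offset,
        abscissa_intercept=offset / slope,
    )


def stability_condition(
    params: FeedforwardParams,
    plasticity: PlasticityParams,
    c_post: float = 1.0,
) -> StabilityReport:
    """Dominance condition for stability of the line attractor.

    Inhibition must dominate: more inhibitory synapses, higher
    inhibitory rates or faster inhibitory plasticity all contribute to
    ``lhs = N_I*nu_I^2/tau_w_I`` exceeding ``rhs = N_E*rho_E^2/tau_w_E``.
    """
    nu_I = params.nu_I_steady()
    lhs = params.N_I * nu_I**2 / plasticity.tau_w_I
    rhs = params.N_E * params.rho_E**2 / plasticity.tau_w_E
    trace = (rhs - lhs) * c_post
    return StabilityReport(
        lhs=lhs,
        rhs=rhs,
        stable=lhs > rhs,
        trace=trace,
        det=0.0,
        eigenvalues=(trace, 0.0),
    )


#: absolute tolerance (weight units) for attractor membership checks
ATTRACTOR_TOL = 1e-6


def _weight_field(
    params: FeedforwardParams,
    plasticity: PlasticityParams,
    w_EE: float,
    w_EI: float,
    c_post: float,
) -> tuple[float, float]:
    """Weight-derivative field with rates at steady state."""
    ws = WeightState(w_EE=max(w_EE, 0.0), w_EI=max(w_EI, 0.0), c_post_E=c_post, c_post_I=c_post)
    rates = steady_state_rates(params, ws)
    f = dw_ee(params.rho_E, rates.nu_E, c_post, plasticity.tau_w_E)
    g = dw_ei(plasticity, rates.nu_I, rates.nu_E, c_post)
    return f, g


def jacobian_numeric(
    params: FeedforwardParams,
    plasticity: PlasticityParams,
    fixed_point: WeightState,
    h: float = 1e-6,
) -> np.ndarray:
    """Central-difference Jacobian of the weight dynamics at a fixed point.

    Serves as the independent oracle for :func:`stability_condition`:
    at any point of the line attractor the determinant vanishes and the
    eigenvalues are {Tr(J*), 0} to finite-difference accuracy.  Points
    off the attractor (beyond ``ATTRACTOR_TOL``) produce a warning but
    still return the local Jacobian, which phase-portrait tooling needs.
    """
    c_post = fixed_point.c_post_E
    if abs(fixed_point.c_post_E - fixed_point.c_post_I) > ATTRACTOR_TOL:
        warnings.warn("thresholds are not matched; no line attractor exists", stacklevel=2)
    line = line_attractor(params, c_post=c_post)
    if abs(line.side(fixed_point.w_EE, fixed_point.w_EI)) > ATTRACTOR_TOL:
        warnings.warn(
            "fixed point lies off the line attractor; Jacobian is local, "
            "not an attractor linearisation",
            stacklevel=2,
        )

    J = np.empty((2, 2))
    w0 = np.array([fixed_point.w_EE, fixed_point.w_EI])
    for j in range(2):
        wp, wm = w0.copy(), w0.copy()
        wp[j] += h
        wm[j] -= h
        fp = _weight_field(params, plasticity, wp[0], wp[1], c_post)
        fm = _weight_field(params, plasticity, wm[0], wm[1], c_post)
        J[0, j] = (fp[0] - fm[0]) / (2 * h)
        J[1, j] = (fp[1] - fm[1]) / (2 * h)
    return J


def ei_ratios(
    params: FeedforwardParams,
    plasticity: PlasticityParams,
    w_EI: float,
    c_post: float = 1.0,
) -> EIRatioReport:
    """E/I ratios at the stable weight configuration for a given ``w_EI``.

    On the line attractor the weight ratio is

        R = (N_I*nu_I*w_EI + c_post) / (N_E*rho_E*w_EI)

    which decays to the attractor slope ``R_inf = N_I*nu_I/(N_E*rho_E)``
    for strong inhibitory weights.  For large presynaptic rates
    ``R_inf`` approaches ``(N_I/N_E)*(rho_I/rho_E + w_IE)``, bounded
    below by the fixed E-to-I weight.
    """
    if w_EI <= 0:
        raise ValueError("E/I ratio undefined for w_EI = 0")
    nu_I = _steady_nu_I(params)
    num = params.N_I * nu_I * w_EI + c_post
    R = num / (params.N_E * params.rho_E * w_EI)
    R_inf = params.N_I * nu_I / (params.N_E * params.rho_E)
    R_large = (params.N_I / params.N_E) * (params.rho_I / params.rho_E + params.w_IE)
    R_tot = num / (params.N_I * nu_I * w_EI)
    return EIRatioReport(R=R, R_inf=R_inf, R_large_rhoE=R_large, R_tot=R_tot)
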