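"""Multi-input circuits: disinhibition-gated receptive fields and assemblies.

The feedforward motif is extended to ``n_inputs`` input patterns, each
defined by a subset of presynaptic excitatory neurons firing at a high
rate for one pattern window, presented in random order.  Two inhibitory
classes control plasticity: *specific* populations, one per input,
driven only by that input's presynaptic neurons, and one *unspecific*
population driven by all of them.  All feedforward E-to-E and I-to-E
weights are plastic (nonlinear inhibitory rule); rates use
instantaneous integrators.

Transiently driving an inhibitory class with a negative external rate
(disinhibition) gates plasticity on.  Disinhibiting the *specific*
populations removes the input-specific counterweight to excitatory
potentiation, so inputs compete and the postsynaptic neuron forms a
receptive field; disinhibiting the *unspecific* population leaves the
specific populations to cancel any input-specific excitatory gain, and
no selectivity emerges.  For the specific case the release of
disinhibition is ramped gradually to avoid silencing the neuron.

The recurrent variant connects 30 such feedforward circuits with
plastic recurrent E-to-E weights: each neuron forms its own receptive
field and strong bidirectional connections develop between neurons
with the same preferred input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .plasticity import PlasticityParams

logger = logging.getLogger(__name__)

__all__ = [
    "MultiInputParams",
    "RecurrentParams",
    "ReceptiveFieldReport",
    "pattern_sequence",
    "run_multi_input",
    "run_recurrent",
    "analyze_selectivity",
]

_LOG_EVERY = 1000


@dataclass(frozen=True)
class MultiInputParams:
    """Configuration of the multi-input feedforward circuit.

    Defaults are the feedforward-circuit parameter set: 10 inputs of 4
    presynaptic neurons each, patterns at 4 Hz against a 1 Hz
    background, 100-ms pattern windows (0.1 time units), 20 specific
    (two per input) and 20 unspecific inhibitory neurons, disinhibition
    of -2 for 60 time units with a 100-time-unit release ramp.
    """

    n_inputs: int = 10
    n_pre_E: int = 40
    pattern_size: int = 4
    pattern_rate_hi: float = 4.0
    rho_E_base: float = 1.0
    pattern_duration: float = 0.1
    N_spec_I: int = 20
    N_unsp_I: int = 20
    w_spec_IE: float = 0.2
    w_unsp_IE: float = 0.02
    rho_spec_I: float = 0.0
    rho_unsp_I: float = 0.0
    disinhibition: float = -2.0
    disinhibition_duration: float = 60.0
    release_ramp: float = 100.0
    w0_EE: float = 0.03
    w0_spec_EI: float = 0.01
    w0_unsp_EI: float = 0.01
    t_baseline: float = 10.0
    t_post: float = 10.0
    dt: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pre_E != self.n_inputs * self.pattern_size:
            raise ValueError("n_pre_E must equal n_inputs * pattern_size")
        for name in ("n_inputs", "n_pre_E", "pattern_size", "N_spec_I", "N_unsp_I"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("pattern_duration", "disinhibition_duration", "release_ramp", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.N_spec_I % self.n_inputs:
            raise ValueError("N_spec_I must be divisible by n_inputs (equal-sized pools)")

    @property
    def input_masks(self) -> np.ndarray:
        """(n_inputs, n_pre_E) 0/1 matrix marking each input's neurons."""
        masks = np.zeros((self.n_inputs, self.n_pre_E))
        for i in range(self.n_inputs):
            masks[i, i * self.pattern_size : (i + 1) * self.pattern_size] = 1.0
        return masks

    @property
    def pool_of_spec(self) -> np.ndarray:
        """Input index served by each specific inhibitory neuron."""
        return np.repeat(np.arange(self.n_inputs), self.N_spec_I // self.n_inputs)


@dataclass(frozen=True)
class RecurrentParams:
    """Configuration of the 30-neuron recurrent circuit.

    Recurrent E-to-E weights are drawn uniformly from
    ``w_rec_init_range`` on a sparse random graph with connection
    probability ``connection_prob`` (keeping the initial recurrent gain
    below one).  ``pattern_correlation`` is the probability per pattern
    window that a neuron's circuit sees the globally shared input
    rather than an independently drawn one; partial sharing both
    correlates similarly tuned neurons and breaks the symmetry that
    would otherwise drive every neuron to the same preferred input.
    ``display_threshold`` prunes the reported adjacency.
    """

    n_post: int = 30
    w_rec_init_range: tuple[float, float] = (0.0, 0.18)
    pattern_correlation: float = 0.5
    connection_prob: float = 0.25
    display_threshold: float = 0.03
    tau_FR: float = 0.01
    dt: float = 1e-3

    def __post_init__(self) -> None:
        if self.n_post < 2:
            raise ValueError("n_post must be >= 2")
        lo, hi = self.w_rec_init_range
        if lo < 0 or hi < lo:
            raise ValueError("w_rec_init_range must be nonnegative and ordered")
        if not 0.0 <= self.pattern_correlation <= 1.0:
            raise ValueError("pattern_correlation must lie in [0, 1]")
        if not 0.0 < self.connection_prob <= 1.0:
            raise ValueError("connection_prob must lie in (0, 1]")


@dataclass
class ReceptiveFieldReport:
    """Selectivity and connectivity readout of a finished run.

    ``mean_weight_per_input`` has shape (n_post, n_inputs);
    ``selectivity`` is (max - mean of the rest)/max per neuron, in
    [0, 1]; ``preferred_input`` is the argmax (ties to the lowest input
    index).  Recurrent fields are ``None`` for single-neuron runs; the
    bidirectionality score is the mean of ``min(w_ij, w_ji)`` over
    ordered pairs within / across preference groups.
    """

    mean_weight_per_input: np.ndarray
    preferred_input: np.ndarray
    selectivity: np.ndarray
    recurrent_weights: np.ndarray | None = None
    within_pref_mean: float | None = None
    across_pref_mean: float | None = None
    bidirectionality_within: float | None = None
    bidirectionality_across: float | None = None
    adjacency: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "mean_weight_per_input": self.mean_weight_per_input.tolist(),
            "preferred_input": self.preferred_input.tolist(),
            "selectivity": self.selectivity.tolist(),
            "within_pref_mean": self.within_pref_mean,
            "across_pref_mean": self.across_pref_mean,
            "bidirectionality_within": self.bidirectionality_within,
            "bidirectionality_across": self.bidirectionality_across,
            "meta": self.meta,
        }
        return d


def pattern_sequence(params: MultiInputParams, T: float, seed: int | None = None):
    """Random input-pattern schedule as a piecewise-constant rate matrix.

    Returns ``(choices, rates)`` where ``choices[k]`` is the input
    active in window ``k`` (uniform over inputs, seeded) and
    ``rates[k]`` the corresponding per-presynaptic-neuron rate vector:
    the chosen input's neurons at ``pattern_rate_hi``, the rest at
    ``rho_E_base``.  Each window lasts ``pattern_duration``.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n_windows = int(np.ceil(T / params.pattern_duration))
    choices = rng.integers(params.n_inputs, size=n_windows)
    rates = np.full((n_windows, params.n_pre_E), params.rho_E_base)
    masks = params.input_masks
    for k, c in enumerate(choices):
        rates[k] += masks[c] * (params.pattern_rate_hi - params.rho_E_base)
    return choices, rates


def _disinhibition_at(params: MultiInputParams, t: float, mode: str) -> tuple[float, float]:
    """External drives (specific, unspecific) at time ``t`` for a protocol.

    The unspecific release is instantaneous; the specific release ramps
    linearly back to baseline over ``release_ramp``.
    """
    r_spec, r_unsp = params.rho_spec_I, params.rho_unsp_I
    t0 = params.t_baseline
    t1 = t0 + params.disinhibition_duration
    if mode == "none" or t < t0:
        return r_spec, r_unsp
    if mode == "unspecific":
        return r_spec, (r_unsp + params.disinhibition if t < t1 else r_unsp)
    if mode == "specific":
        if t < t1:
            return r_spec + params.disinhibition, r_unsp
        t2 = t1 + params.release_ramp
        if t < t2:
            frac = (t - t1) / params.release_ramp
            return r_spec + params.disinhibition * (1.0 - frac), r_unsp
        return r_spec, r_unsp
    raise ValueError(f"unknown disinhibition mode {mode!r}")


def analyze_selectivity(
    ff_weights: np.ndarray,
    recurrent_weights: np.ndarray | None,
    params: MultiInputParams,
    conn_mask: np.ndarray | None = None,
    display_threshold: float = 0.03,
) -> ReceptiveFieldReport:
    """Compute the receptive-field report from final weights.

    ``ff_weights`` is (n_post, n_pre_E) or (n_pre_E,) for a single
    neuron.  Ties in the preferred input break to the lowest index
    (numpy argmax convention).  For recurrent runs the within- versus
    across-preference statistics are restricted to existing connections
    when ``conn_mask`` is given.
    """
    W = np.atleast_2d(np.asarray(ff_weights, dtype=float))
    masks = params.input_masks
    mean_w = W @ masks.T / params.pattern_size  # (n_post, n_inputs)
    pref = mean_w.argmax(axis=1)
    top = mean_w.max(axis=1)
    rest = (mean_w.sum(axis=1) - top) / (params.n_inputs - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sel = np.where(top > 0, (top - rest) / np.where(top > 0, top, 1.0), 0.0)
    sel = np.clip(sel, 0.0, 1.0)

    report = ReceptiveFieldReport(
        mean_weight_per_input=mean_w,
        preferred_input=pref,
        selectivity=sel,
    )
    if recurrent_weights is None:
        return report

    Wr = np.asarray(recurrent_weights, dtype=float)
    n = Wr.shape[0]
    off = ~np.eye(n, dtype=bool)
    exists = off if conn_mask is None else (off & conn_mask)
    same = (pref[:, None] == pref[None, :]) & exists
    diff = (~(pref[:, None] == pref[None, :])) & exists
    bid = np.minimum(Wr, Wr.T)
    report.recurrent_weights = Wr
    report.within_pref_mean = float(Wr[same].mean()) if same.any() else float("nan")
    report.across_pref_mean = float(Wr[diff].mean()) if diff.any() else float("nan")
    report.bidirectionality_within = float(bid[same].mean()) if same.any() else float("nan")
    report.bidirectionality_across = float(bid[diff].mean()) if diff.any() else float("nan")
    report.adjacency = np.where(Wr >= display_threshold, Wr, 0.0)
    return report


def run_multi_input(
    params: MultiInputParams,
    plasticity: PlasticityParams,
    disinhibit: str = "specific",
    T: float | None = None,
    seed: int | None = None,
    record_every: int = 10,
    divergence_guard: float = 1e6,
):
    """Simulate the single-postsynaptic-neuron multi-input circuit.

    ``disinhibit`` is ``"none"``, ``"specific"`` or ``"unspecific"``.
    Returns ``(history, report)`` where ``history`` is a DataFrame of
    downsampled time, postsynaptic rate and per-input mean E-to-E
    weights, and ``report`` the final :class:`ReceptiveFieldReport`.
    """
    if disinhibit not in ("none", "specific", "unspecific"):
        raise ValueError(f"unknown disinhibition mode {disinhibit!r}")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    dt = params.dt
    if T is None:
        T = params.t_baseline + params.disinhibition_duration + (
            params.release_ramp if disinhibit == "specific" else 0.0
        ) + params.t_post
    n_steps = int(round(T / dt))
    steps_per_window = max(int(round(params.pattern_duration / dt)), 1)

    masks = params.input_masks
    pool_of = params.pool_of_spec
    c = plasticity
    wee = np.full(params.n_pre_E, params.w0_EE)
    wei_s = np.full(params.N_spec_I, params.w0_spec_EI)
    wei_u = np.full(params.N_unsp_I, params.w0_unsp_EI)
    cE, cI = c.c_post_E_init, c.c_post_I_init

    rho = np.full(params.n_pre_E, params.rho_E_base)
    rec = []
    diverged, t_div = False, None
    for i in range(n_steps):
        t = i * dt
        if i % steps_per_window == 0:
            cur = int(rng.integers(params.n_inputs))
            rho = np.full(params.n_pre_E, params.rho_E_base)
            rho += masks[cur] * (params.pattern_rate_hi - params.rho_E_base)
            pat_drive = masks @ rho  # summed rate of each input's neurons
        r_spec, r_unsp = _disinhibition_at(params, t, disinhibit)
        nuI_s = np.maximum(pat_drive[pool_of] * params.w_spec_IE + r_spec, 0.0)
        nuI_u = max(rho.sum() * params.w_unsp_IE + r_unsp, 0.0) * np.ones(params.N_unsp_I)
        nu_E = max(float(rho @ wee - nuI_s @ wei_s - nuI_u @ wei_u), 0.0)

        f = nu_E * (nu_E - cE)
        g = nu_E * (nu_E - cI)
        wee = np.maximum(wee + rho * f / c.tau_w_E * dt, c.weight_floor)
        wei_s = np.maximum(wei_s + nuI_s * g / c.tau_w_I * dt, c.weight_floor)
        wei_u = np.maximum(wei_u + nuI_u * g / c.tau_w_I * dt, c.weight_floor)

        if not np.isfinite(wee).all() or wee.max() > divergence_guard:
            diverged, t_div = True, t
            break
        if i % record_every == 0:
            rec.append((t, nu_E, *(masks @ wee / params.pattern_size)))
        if i % _LOG_EVERY == 0 and i:
            logger.info("multi-input t=%.2f nu_E=%.3f", t, nu_E)

    cols = ["t", "nu_E"] + [f"mean_w_input_{k}" for k in range(params.n_inputs)]
    history = pd.DataFrame(rec, columns=cols)
    report = analyze_selectivity(wee, None, params)
    report.meta = {
        "disinhibit": disinhibit,
        "diverged": diverged,
        "t_diverged": t_div,
        "final_wei_spec_mean": float(wei_s.mean()),
        "final_wei_unsp_mean": float(wei_u.mean()),
    }
    return history, report


def run_recurrent(
    params: MultiInputParams,
    rec: RecurrentParams,
    plasticity: PlasticityParams,
    T: float | None = None,
    seed: int | None = None,
    divergence_guard: float = 1e6,
) -> ReceptiveFieldReport:
    """Simulate the recurrent circuit with specific-population disinhibition.

    Each of the ``n_post`` excitatory neurons owns a feedforward circuit
    (its own presynaptic pattern neurons); the two inhibitory classes
    are shared and pool the pattern neurons of all circuits, which is
    why the per-synapse E-to-I weights of the recurrent parameter set
    are an order of magnitude weaker than the single-circuit ones.
    Recurrent E-to-E weights are plastic under the excitatory rule with
    the presynaptic recurrent neuron's rate in place of the input rate.
    Rates integrate with time constant ``rec.tau_FR``.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n_post, dt = rec.n_post, rec.dt
    if T is None:
        T = params.t_baseline + params.disinhibition_duration + params.release_ramp + params.t_post
    n_steps = int(round(T / dt))
    steps_per_window = max(int(round(params.pattern_duration / dt)), 1)

    masks = params.input_masks
    pool_of = params.pool_of_spec
    c = plasticity
    wee = np.full((n_post, params.n_pre_E), params.w0_EE)
    wei_s = np.full((n_post, params.N_spec_I), params.w0_spec_EI)
    wei_u = np.full((n_post, params.N_unsp_I), params.w0_unsp_EI)
    conn = rng.random((n_post, n_post)) < rec.connection_prob
    np.fill_diagonal(conn, False)
    lo, hi = rec.w_rec_init_range
    wrec = np.where(conn, rng.uniform(lo, hi, (n_post, n_post)), 0.0)

    nu = np.zeros(n_post)
    nuI_s = np.zeros(params.N_spec_I)
    nuI_u = np.zeros(params.N_unsp_I)
    rho = np.full((n_post, params.n_pre_E), params.rho_E_base)
    diverged, t_div = False, None
    cE, cI = c.c_post_E_init, c.c_post_I_init

    for i in range(n_steps):
        t = i * dt
        if i % steps_per_window == 0:
            shared = int(rng.integers(params.n_inputs))
            cur = np.where(
                rng.random(n_post) < rec.pattern_correlation,
                shared,
                rng.integers(params.n_inputs, size=n_post),
            )
            rho = np.full((n_post, params.n_pre_E), params.rho_E_base)
            rho += masks[cur] * (params.pattern_rate_hi - params.rho_E_base)
            pat_drive = (rho @ masks.T).sum(axis=0)  # pooled over circuits
            ff_drive = (wee * rho).sum(axis=1)
        r_spec, r_unsp = _disinhibition_at(params, t, "specific")
        k = dt / rec.tau_FR
        nuI_s += (-nuI_s + np.maximum(pat_drive[pool_of] * params.w_spec_IE + r_spec, 0.0)) * k
        nuI_u += (-nuI_u + np.maximum(rho.sum() * params.w_unsp_IE + r_unsp, 0.0)) * k
        nu += (-nu + np.maximum(ff_drive - wei_s @ nuI_s - wei_u @ nuI_u + wrec @ nu, 0.0)) * k

        fE = nu * (nu - cE)
        fI = nu * (nu - cI)
        wee = np.maximum(wee + fE[:, None] * rho / c.tau_w_E * dt, c.weight_floor)
        ff_drive = (wee * rho).sum(axis=1)
        wei_s = np.maximum(wei_s + np.outer(fI, nuI_s) / c.tau_w_I * dt, c.weight_floor)
        wei_u = np.maximum(wei_u + np.outer(fI, nuI_u) / c.tau_w_I * dt, c.weight_floor)
        wrec = np.where(conn, np.maximum(wrec + np.outer(fE, nu) / c.tau_w_E * dt, c.weight_floor), 0.0)

        if not np.isfinite(nu).all() or wrec.max() > divergence_guard or wee.max() > divergence_guard:
            diverged, t_div = True, t
            break
        if i % (_LOG_EVERY * 10) == 0 and i:
            logger.info("recurrent t=%.2f mean rate=%.3f", t, float(nu.mean()))

    report = analyze_selectivity(wee, wrec, params, conn_mask=conn, display_threshold=rec.display_threshold)
    report.meta = {
        "diverged": diverged,
        "t_diverged": t_div,
        "pattern_correlation": rec.pattern_correlation,
        "connection_prob": rec.connection_prob,
        "n_preferred_inputs": int(len(np.unique(report.preferred_input))),
    }
    return report
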