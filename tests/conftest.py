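"""Shared fixtures: the single-neuron parameter regime used throughout.

``motif_params`` carries the parameter-table values for the
single-neuron feedforward motif (presynaptic rate 2 Hz, external
inhibitory drive 0.5 Hz, E-to-I weight 0.5, giving a steady inhibitory
rate of 1.5 Hz) with the coarse Euler step 0.1.  ``sim_params`` is the
same circuit with a finer step (0.01) for runs that start far from the
line attractor, where the coarse step overshoots.
"""

import pytest

from inhplast import FeedforwardParams, PlasticityParams


@pytest.fixture
def motif_params() -> FeedforwardParams:
    return FeedforwardParams()


@pytest.fixture
def sim_params() -> FeedforwardParams:
    return FeedforwardParams(dt=0.01)


@pytest.fixture
def nonlinear_plasticity() -> PlasticityParams:
    return PlasticityParams(inhibitory_rule="nonlinear")


@pytest.fixture
def linear_plasticity() -> PlasticityParams:
    return PlasticityParams(inhibitory_rule="linear")
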