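import numpy as np
import pytest

from autokinetics import (
    Peak,
    Reaction,
    ReactionNetwork,
    ConcentrationTrace,
    SpectralSignature,
)


@pytest.fixture
def ab_network():
    """A + B -> C, second order overall (the pseudo-first-order workhorse)."""
    def make(k=3.5e-5):
        return ReactionNetwork(
            species=["A", "B", "C"],
            reactions=[Reaction(reactants={"A": 1, "B": 1}, products={"C": 1}, k=k)],
        )
    return make


@pytest.fixture
def first_order_network():
    def make(k=0.1):
        return ReactionNetwork(
            species=["A", "B"],
            reactions=[Reaction(reactants={"A": 1}, products={"B": 1}, k=k)],
        )
    return make


@pytest.fixture
def random_trace():
    """Factory for smooth random positive traces on a dense grid."""
    def make(rng, n_points=120, n_species=1, t_end=30.0):
        times = np.linspace(0.0, t_end, n_points)
        concs = {}
        for j in range(n_species):
            # random smooth positive curve: sum of decaying exponentials
            amps = rng.uniform(0.2, 2.0, size=3)
            rates = rng.uniform(0.01, 0.2, size=3)
            concs[f"S{j}"] = (amps[:, None] * np.exp(-rates[:, None] * times)).sum(axis=0)
        return ConcentrationTrace(times=times, concentrations=concs)
    return make


@pytest.fixture
def single_peak_signature():
    def make(modality="nmr", center=2.4, width=0.003, response=3.0, species="X"):
        return SpectralSignature(
            modality=modality, peaks={species: [Peak(center, width, response)]}
        )
    return make
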