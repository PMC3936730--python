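"""Shared fixtures: small synthetic amplicons and clone sets."""

import numpy as np
import pandas as pd
import pytest

import nomeamp as na
from nomeamp.calls import Call
from nomeamp.pipeline import call_clones


@pytest.fixture(scope="session")
def reference():
    """600-bp amplicon: GpC every 20 bp, CH controls every 40 bp,
    one CpG block."""
    return na.make_reference(600, 20, [(250, 380, 0.08)], seed=1,
                             ch_spacing=40, name="amp",
                             genomic_offset=-9900)


@pytest.fixture(scope="session")
def gpc_only_reference():
    """600-bp amplicon with only GpC sites every 20 bp."""
    return na.make_reference(600, 20, seed=1)


@pytest.fixture
def open_state_model():
    """Single fully-accessible state (no protected intervals)."""
    return na.ChromatinStateModel(states=(na.CellState(weight=1.0),))


@pytest.fixture
def protected_model():
    """Single state with one nucleosome-like protected interval."""
    return na.ChromatinStateModel(states=(
        na.CellState(weight=1.0, protected_intervals=((200, 350),),
                     linker_accessibility=1.0,
                     occluded_accessibility=0.0),))


def matrix_from_calls(call_rows, positions, registry):
    """Hand-build a CloneCallMatrix from lists of Call values."""
    calls = pd.DataFrame(
        np.array(call_rows, dtype=np.int8),
        index=[f"clone_{i:03d}" for i in range(len(call_rows))],
        columns=positions)
    qc = pd.DataFrame({"conversion_efficiency": 1.0,
                       "ambiguous_fraction": 0.0,
                       "mismatch_rate": 0.0},
                      index=calls.index)
    return na.CloneCallMatrix(calls=calls, registry=registry, clone_qc=qc)


def gch_registry(positions):
    """Registry whose only sites are GCH at the given positions."""
    return na.SiteRegistry(tuple(positions), (), (), ())


@pytest.fixture
def simulated_matrix(reference, protected_model):
    """Perfect-noise clones over the protected model, called."""
    sim = na.simulate_clones(reference, protected_model,
                             noise=na.NoiseModel(seed=3), n_clones=20)
    matrix, rejected = call_clones(reference, sim.clones)
    assert not rejected
    return matrix, sim


# re-export for tests that build matrices by hand
A = int(Call.RETAINED)     # accessible / methylated
I = int(Call.CONVERTED)    # inaccessible / unmethylated  # noqa: E741
N = int(Call.AMBIGUOUS)
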