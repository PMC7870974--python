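import numpy as np
import pytest
from hypothesis import settings

from sigqbic import synthetic as syn

settings.register_profile("deterministic", derandomize=True, database=None, deadline=None)
settings.load_profile("deterministic")
from sigqbic.signature_io import Signature, uniform_signature

ALL_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


@pytest.fixture(scope="session")
def taat_table():
    """Reduced-flank table for an AT-rich (homeodomain-like) toy TF."""
    tf = syn.ToyTF("TAAT_1", syn.motif_from_consensus("TAAT"), seed=3)
    return syn.synth_qbic_table(tf, flank=2)


@pytest.fixture(scope="session")
def gccg_table():
    """Reduced-flank table for a GC-motif toy TF."""
    tf = syn.ToyTF("GCCG_1", syn.motif_from_consensus("GCCG"), seed=7)
    return syn.synth_qbic_table(tf, flank=2)


@pytest.fixture(scope="session")
def tiny_table():
    """Very small (flank 1, 16 changes/class) table for brute-force oracles."""
    tf = syn.ToyTF("TINY_1", syn.motif_from_consensus("TAAT"), p_scale=1.0, seed=11)
    return syn.synth_qbic_table(tf, flank=1)


@pytest.fixture(scope="session")
def ctot_sig():
    return syn.synth_signature(
        {"C>T": 0.99, "C>A": 0.002, "C>G": 0.002, "T>A": 0.002, "T>C": 0.002, "T>G": 0.002},
        name="ctot",
    )


@pytest.fixture(scope="session")
def ttoc_sig():
    return syn.synth_signature(
        {"T>C": 0.99, "C>A": 0.002, "C>G": 0.002, "T>A": 0.002, "C>T": 0.002, "T>G": 0.002},
        name="ttoc",
    )


@pytest.fixture(scope="session")
def flat_sig():
    """Flat signature: equal type masses, randomized within-type structure."""
    return syn.synth_signature(
        {t: 1 / 6 for t in ALL_TYPES}, within_type="random", seed=19, name="flat"
    )


@pytest.fixture(scope="session")
def uniform():
    return uniform_signature()


@pytest.fixture(scope="session")
def random_sig():
    rng = np.random.default_rng(123)
    return Signature("random123", rng.dirichlet(np.full(96, 2.0)))
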