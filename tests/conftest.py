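import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from glapred import (
    AnnotatedProtein,
    PeptideWindow,
    SynthConfig,
    extract_all_windows,
    generate,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """A small synthetic benchmark: proteins, windows, and their labels."""
    proteins, table = generate(SynthConfig(n_positive=40, n_negative=50, seed=7))
    windows = extract_all_windows(proteins)
    return proteins, table, windows


@pytest.fixture
def toy_protein():
    # positions (1-based):      123456789...
    seq = "MKEALVTWYEACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWYE"
    positives = {pos for pos in (3, 10) if seq[pos - 1] == "E"}
    return AnnotatedProtein(id="TOY1", sequence=seq, positive_sites=positives)


@pytest.fixture
def make_window():
    """Build a PeptideWindow from an arbitrary residue string."""

    def _make(residues: str, label: int = 0) -> PeptideWindow:
        return PeptideWindow(
            residues=residues, label=label, source_id="T", center_position=1
        )

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(42)
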