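import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from dolphyn import classifier, synthetic
from dolphyn.features import default_schema


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def small_model():
    """A quickly trained but well-separated epitope model for design tests."""
    data = synthetic.make_labeled_peptides(150, seed=11)
    return classifier.train(data, n_trees=50, seed=42)


class ProbByStart:
    """Stub model: windows are scored by their start offset within a protein.

    ``dolphyn_select`` passes all windows of one protein in start order
    (stride 1), so probabilities can be assigned positionally.
    """

    def __init__(self, probs):
        self.probs = list(probs)

    def predict_proba_many(self, seqs):
        if len(seqs) != len(self.probs):
            raise AssertionError(
                f"stub got {len(seqs)} windows, configured for {len(self.probs)}"
            )
        return np.asarray(self.probs, dtype=float)


@pytest.fixture
def prob_by_start():
    return ProbByStart
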