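import numpy as np
import pytest

from lfpburst import bursts as bc
from lfpburst import simulate


@pytest.fixture(scope="session")
def reference_corpus():
    """Synthetic reference burst corpus (features + generating labels)."""
    feats, labels = simulate.generate_reference_corpus(300, seed=11)
    return feats.to_numpy(), labels


@pytest.fixture(scope="session")
def som_model(reference_corpus):
    """SOM classifier trained once on the reference corpus (label mode)."""
    X, y = reference_corpus
    model = bc.SOMBurstClassifier(grid_shape=(8, 8), epochs=30,
                                  random_state=5)
    return model.fit(X, y)


@pytest.fixture(scope="session")
def small_session():
    """One quiet-plus-bursts LFS session at reduced rate/length for speed."""
    plan = simulate.make_lfs_plan(seed=21, sub_duration_s=150.0, fs=2000.0)
    return simulate.generate_session(plan)


def match_events(detected: np.ndarray, truth: np.ndarray,
                 tol_s: float = 0.025) -> tuple[float, float]:
    """(recall, precision) by nearest-neighbor matching at tolerance."""
    if truth.size == 0:
        return 1.0, float(detected.size == 0)
    if detected.size == 0:
        return 0.0, 1.0
    d = np.abs(detected[:, None] - truth[None, :])
    recall = float((d.min(axis=0) <= tol_s).mean())
    precision = float((d.min(axis=1) <= tol_s).mean())
    return recall, precision
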