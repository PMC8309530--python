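import numpy as np
import pytest

from ecgid.experiments import ExperimentConfig
from ecgid.signal_prep import SymbolSequence, default_alphabet
from ecgid.synthetic_ecg import CohortSpec, generate_cohort


def make_seq(symbols: str, alphabet_size: int = None) -> SymbolSequence:
    """Symbol sequence over A, B, C, ... (size inferred unless given)."""
    if alphabet_size is None:
        alphabet_size = max(ord(c) - ord("A") for c in symbols) + 1
    return SymbolSequence(symbols=symbols, alphabet=default_alphabet(alphabet_size))


def naive_code_length(x: str, y: str, k: int, alpha: float, alphabet_size: int) -> float:
    """Independent per-position recount oracle for relative compression.

    For every position of ``x`` the (context, symbol) counts are re-derived
    by scanning ``y`` from scratch with circular contexts; no state is shared
    with the package's vectorized coder.  An unseen context reduces to the
    uniform 1/|A| probability.
    """
    n_y, n_x = len(y), len(x)
    probs = np.empty(n_x)
    for i in range(n_x):
        ctx = "".join(x[(i - k + j) % n_x] for j in range(k))
        v = t = 0
        for p in range(n_y):
            y_ctx = "".join(y[(p - k + j) % n_y] for j in range(k))
            if y_ctx == ctx:
                t += 1
                if y[p] == x[i]:
                    v += 1
        probs[i] = 1.0 / alphabet_size if t == 0 else (v + alpha) / (t + alpha * alphabet_size)
    return float(-np.log2(probs).sum())


@pytest.fixture(scope="session")
def tiny_cohort():
    """4 subjects, short blocks: enough for structure and direction checks."""
    spec = CohortSpec(
        n_subjects=4,
        rest1_duration=60.0,
        movement_duration=10.0,
        rest2_duration=30.0,
        seed=5,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def tiny_cfg():
    return ExperimentConfig(
        train_duration=40.0,
        test_duration=15.0,
        k=10,
        duration_grid=(5.0,),
    )
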