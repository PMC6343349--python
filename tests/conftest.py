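import numpy as np
import pandas as pd
import pytest

from dsindex.variables import Group, VariableSpec


@pytest.fixture
def cont_spec():
    return VariableSpec("x", "continuous", "g")


@pytest.fixture
def toy_hierarchy():
    """Two concept groups over three factors, one perfectly separating."""
    return Group("model", [
        Group("cognition", [
            VariableSpec("mmse", "continuous", "cognition"),
            VariableSpec("spmsq", "continuous", "cognition"),
        ]),
        Group("lifestyle", [
            VariableSpec("bmi", "continuous", "lifestyle"),
        ]),
    ])


@pytest.fixture
def toy_cohort():
    """12 subjects; mmse separates classes perfectly, bmi is noise."""
    rng = np.random.default_rng(0)
    n = 12
    y = np.array([1] * 6 + [0] * 6, dtype=float)
    mmse = np.where(y == 1, rng.normal(18, 1, n), rng.normal(28, 1, n))
    spmsq = np.where(y == 1, rng.normal(4, 1.5, n), rng.normal(1, 1.5, n))
    bmi = rng.normal(25, 3, n)
    return pd.DataFrame({
        "subject_id": [f"S{i}" for i in range(n)],
        "outcome": y, "mmse": mmse, "spmsq": spmsq, "bmi": bmi,
    })


def oracle_relevance(cases, controls):
    """Brute-force max Youden index over all observed thresholds and both
    orientations (independent pure-Python oracle)."""
    best = 0.0
    n1, n0 = len(cases), len(controls)
    for t in sorted(set(cases) | set(controls)):
        sens = sum(v >= t for v in cases) / n1
        spec = sum(v < t for v in controls) / n0
        best = max(best, sens + spec - 1)
        sens = sum(v <= t for v in cases) / n1
        spec = sum(v > t for v in controls) / n0
        best = max(best, sens + spec - 1)
    return best


def oracle_auc(scores, labels):
    """Pairwise win-fraction enumeration of the AUC (ties count 1/2)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = wins = 0.0
    for p in pos:
        for q in neg:
            total += 1
            if p > q:
                wins += 1
            elif p == q:
                wins += 0.5
    return wins / total
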