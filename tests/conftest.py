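import numpy as np
import pandas as pd
import pytest

from basalscreen.synthdata import SimulationConfig


@pytest.fixture
def config():
    """Default synthetic-screen configuration at a fixed seed."""
    return SimulationConfig(seed=123)


@pytest.fixture
def cell_lines():
    """25 cell lines: 10 basal, 15 spread over the other subtypes."""
    others = ["classical", "mesenchymal", "atypical"]
    lines = {f"B{i:02d}": "basal" for i in range(10)}
    lines.update({f"N{i:02d}": others[i % 3] for i in range(15)})
    return lines


def brute_force_pearson(a, b):
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    am, bm = a - a.mean(), b - b.mean()
    return float((am * bm).sum() / np.sqrt((am**2).sum() * (bm**2).sum()))


def brute_force_roc_auc(values, labels):
    """Exhaustive pair counting: P(pos > neg) + 0.5 P(tie)."""
    values = np.asarray(values, float)
    labels = np.asarray(labels, int)
    pos = values[labels == 1]
    neg = values[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))
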