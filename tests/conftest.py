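import numpy as np
import pandas as pd
import pytest

from secretodiff import cytokines, simulate


@pytest.fixture
def small_layout() -> cytokines.ArrayLayout:
    return cytokines.ArrayLayout.grid([f"CK{i:02d}" for i in range(8)], n_duplicates=2)


@pytest.fixture
def tiny_counts() -> tuple[pd.DataFrame, pd.Series]:
    cfg = simulate.SimConfig(seed=42, n_features=300, de_fraction=0.2, nb_dispersion=0.15)
    counts, _ = simulate.generate_mirna_counts(cfg)
    counts = counts[counts.sum(axis=1) > 0]
    groups = pd.Series(["control"] * 3 + ["treated"] * 3, index=counts.columns)
    return counts, groups


def make_membrane(layout, analyte_levels, pos=1000.0, neg=50.0):
    """Raw spot table for one membrane from normalized analyte levels."""
    rows = []
    for _, spot in layout.spots.iterrows():
        if spot["role"] == "POS":
            v = pos
        elif spot["role"] in ("NEG", "BLANK"):
            v = neg
        else:
            v = neg + analyte_levels[spot["name"]] * (pos - neg)
        rows.append((spot["row"], spot["col"], v))
    return pd.DataFrame(rows, columns=["row", "col", "intensity"])


def brute_force_logrank(time_a, event_a, time_b, event_b):
    """Hand two-sample log-rank chi-square from the 2x2 table at each
    distinct event time (hypergeometric mean/variance)."""
    times = np.concatenate([time_a, time_b])
    events = np.concatenate([event_a, event_b])
    group = np.concatenate([np.zeros(len(time_a)), np.ones(len(time_b))])
    obs_minus_exp = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 0)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (group == 0)).sum()
        obs_minus_exp += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return obs_minus_exp**2 / var
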