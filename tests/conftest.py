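"""Shared fixtures: one small synthetic cohort reused across test modules."""

import numpy as np
import pytest

from musicnet import connectivity, states, synthgen


@pytest.fixture(scope="session")
def small_cohort():
    """Default small-profile cohort (12 subjects, 20 parcels) with truth."""
    spec = synthgen.small_profile(seed=11)
    runs, truth = synthgen.simulate_cohort(spec)
    return spec, runs, truth


@pytest.fixture(scope="session")
def small_windows(small_cohort):
    _, runs, _ = small_cohort
    return [connectivity.sliding_window_fc(r) for r in runs]


@pytest.fixture(scope="session")
def small_model(small_windows):
    return states.cluster_windows(small_windows, k=2, n_replicates=20, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def window_truth(series, truth):
    """Ground-truth majority regime and purity for every pooled window."""
    L = series[0].window_length_samples
    labels, purity = [], []
    for ws in series:
        sched = truth.schedules[(ws.subject_id, ws.condition)]
        for s0 in ws.window_start_index:
            frac = sched[s0 : s0 + L].mean()
            labels.append(int(round(frac)))
            purity.append(max(frac, 1 - frac))
    return np.asarray(labels), np.asarray(purity)
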