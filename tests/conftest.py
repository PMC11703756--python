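"""Shared fixtures and independent oracles for the test suite.

The expensive Langevin runs (20-replica batteries) are session-scoped so the
suppression, peripheral-shift and ground-truth tests share them.
"""

from __future__ import annotations

import numpy as np
import pytest

from leafletdyn.synthetic import (
    LangevinParams,
    PairInteraction,
    SimulationComposition,
    simulate_solute_trajectories,
)

N_REPLICAS = 20

#: study conditions for the paired-vs-free comparisons: barrier low enough
#: that spontaneous flip-flop is well sampled in 2 µs of synthetic time
PARAMS_2US = LangevinParams(
    barrier_height=4.0, n_steps=100_000, timestep=0.02, frame_stride=10
)

PAIRED_INTERACTION = PairInteraction(epsilon=6.0, kappa=4.0, sigma_r=1.0, sigma_z=0.5)


def brute_force_transitions(z, d):
    """Sign-change-of-threshold-excursions oracle, sample-by-sample.

    Returns (pre_index, post_index, sign_after) tuples; independent of the
    vectorized implementation.
    """
    events = []
    last_sign = 0
    last_idx = -1
    for i, zi in enumerate(z):
        if abs(zi) >= d:
            s = 1 if zi > 0 else -1
            if last_sign != 0 and s != last_sign:
                events.append((last_idx, i, s))
            last_sign = s
            last_idx = i
    return events


def fold_and_filter_oracle(z, bin_width):
    """Independent intensity-sensitive histogram: full histogram on
    symmetric edges, pick the half with the taller peak (ties positive),
    keep that half's samples, histogram |z|."""
    z = np.asarray(z, float)
    lim = max(np.max(np.abs(z)), bin_width)
    n = int(np.ceil(lim / bin_width + 1e-9))
    edges = np.arange(-n, n + 1) * bin_width
    counts, _ = np.histogram(z, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    pos_peak = counts[centers > 0].max()
    neg_peak = counts[centers < 0].max()
    half = z[z > 0] if pos_peak >= neg_peak else z[z < 0]
    fedges = np.arange(0, n + 1) * bin_width
    fcounts, _ = np.histogram(np.abs(half), bins=fedges)
    return fedges, fcounts / fcounts.sum(), len(half) / len(z)


def _run_battery(comp, params=PARAMS_2US, seed0=0, n=N_REPLICAS):
    return [
        simulate_solute_trajectories(params, comp, seed0 + k) for k in range(n)
    ]


@pytest.fixture(scope="session")
def paired_runs():
    """A+B solutes with ε=6 kT, κ=4 kT/nm unlike-pair coupling, 20 replicas."""
    comp = SimulationComposition(
        counts={"A": 1, "B": 1},
        interactions={("A", "B"): PAIRED_INTERACTION},
    )
    return _run_battery(comp, seed0=100)


@pytest.fixture(scope="session")
def free_runs():
    """Same composition with no coupling (ε=κ=0), 20 replicas."""
    comp = SimulationComposition(counts={"A": 1, "B": 1})
    return _run_battery(comp, seed0=100)


@pytest.fixture(scope="session")
def barrier_runs():
    """Single free solute at ΔE = 4 and 10 kT, 20 replicas each."""
    out = {}
    for de in (4.0, 10.0):
        params = LangevinParams(
            barrier_height=de, n_steps=100_000, timestep=0.02, frame_stride=10
        )
        comp = SimulationComposition(counts={"A": 1})
        out[de] = _run_battery(comp, params=params, seed0=300)
    return out


def ci95(values):
    """(low, high) normal-approximation 95% confidence interval of the mean."""
    values = np.asarray(values, float)
    m = values.mean()
    sem = values.std(ddof=1) / np.sqrt(len(values))
    return m - 1.96 * sem, m + 1.96 * sem
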