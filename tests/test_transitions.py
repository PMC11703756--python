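"""Transition detector, leaflet assignment, height histograms, orientation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leafletdyn.trajectory import Trajectory, ZTrace
from leafletdyn.transitions import (
    TransitionConfig,
    assign_leaflet,
    detect_transitions,
    height_histogram,
    orientation_profile,
    summarize_transitions,
    transition_indices,
)

from conftest import brute_force_transitions, fold_and_filter_oracle


def ztrace(z, species="A"):
    z = np.asarray(z, float)
    return ZTrace(0, species, np.arange(len(z), dtype=float), z)


class TestDetector:
    @pytest.mark.parametrize(
        "z, d, expected",
        [
            ([0.8, 0.2, -0.75, 0.1, 0.9], 0.7, [("down", 2.0), ("up", 4.0)]),
            ([0.8, 0.5, -0.5, 0.6], 0.7, []),  # far side never confirmed
            ([0.5] * 10, 0.7, []),  # constant sub-threshold
            ([0.8] * 10, 0.7, []),  # constant confirmed, no change
            ([], 0.7, []),
        ],
    )
    def test_examples(self, z, d, expected):
        events = detect_transitions(ztrace(z), d=d)
        assert [(e.direction, e.time_ns) for e in events] == expected

    def test_event_metadata(self):
        (ev,) = detect_transitions(ztrace([0.9, 0.1, -0.8]), d=0.7)
        assert ev.pre_index == 0 and ev.post_index == 2 and ev.direction == "down"

    def test_negation_flips_directions(self):
        z = np.array([0.8, 0.2, -0.75, 0.1, 0.9])
        fwd = detect_transitions(ztrace(z), d=0.7)
        neg = detect_transitions(ztrace(-z), d=0.7)
        assert len(fwd) == len(neg)
        assert [e.direction for e in neg] == [
            {"up": "down", "down": "up"}[e.direction] for e in fwd
        ]

    def test_species_threshold_lookup(self):
        cfg = TransitionConfig()
        z = [0.65, -0.65, 0.65]
        assert len(detect_transitions(ztrace(z, "A"), cfg)) == 0  # d=0.7
        assert len(detect_transitions(ztrace(z, "B"), cfg)) == 2  # d=0.6
        with pytest.raises(KeyError, match="species 'X'"):
            detect_transitions(ztrace(z, "X"), cfg)

    @settings(max_examples=300, derandomize=True)
    @given(
        z=st.lists(st.floats(-2.0, 2.0, allow_nan=False), max_size=120),
        d=st.floats(0.1, 1.5),
    )
    def test_matches_brute_force_oracle(self, z, d):
        pre, post, sign = transition_indices(np.asarray(z), d)
        oracle = brute_force_transitions(z, d)
        assert list(zip(pre.tolist(), post.tolist(), sign.astype(int).tolist())) == oracle

    @settings(max_examples=100, derandomize=True)
    @given(st.data())
    def test_subthreshold_insertion_invariance(self, data):
        d = 0.7
        z = data.draw(st.lists(st.floats(-2, 2, allow_nan=False), max_size=40))
        fillers = data.draw(
            st.lists(st.floats(-d + 1e-6, d - 1e-6), min_size=1, max_size=10)
        )
        pos = data.draw(st.integers(0, len(z)))
        z2 = z[:pos] + fillers + z[pos:]
        assert len(transition_indices(np.array(z2), d)[0]) == len(
            transition_indices(np.array(z), d)[0]
        )

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(-2, 2, allow_nan=False), max_size=80))
    def test_time_reversal_count_invariant(self, z):
        fwd = transition_indices(np.array(z), 0.7)
        rev = transition_indices(np.array(z[::-1]), 0.7)
        assert len(fwd[0]) == len(rev[0])
        # directions reverse: post-change signs of reversed trace are the
        # pre-change signs of the forward trace, negated order-wise
        assert sorted(fwd[2]) == sorted(-rev[2])

    @settings(max_examples=100, derandomize=True)
    @given(
        z=st.lists(st.floats(-2, 2, allow_nan=False), max_size=100),
        k=st.integers(1, 5),
    )
    def test_downsampling_never_increases_count(self, z, k):
        full = len(transition_indices(np.array(z), 0.7)[0])
        down = len(transition_indices(np.array(z[::k]), 0.7)[0])
        assert down <= full


class TestLeafletAssignment:
    def test_confirmed_matches_example(self):
        labels = assign_leaflet(ztrace([0.8, 0.1, -0.8]), policy="confirmed")
        assert labels.tolist() == ["upper", "upper", "lower"]

    def test_instantaneous_uses_sign(self):
        labels = assign_leaflet(ztrace([0.8, 0.1, -0.8]), policy="instantaneous")
        assert labels.tolist() == ["upper", "upper", "lower"]
        labels = assign_leaflet(ztrace([0.0, -0.2]), policy="instantaneous")
        assert labels.tolist() == ["undetermined", "lower"]

    def test_confirmed_undetermined_before_first_excursion(self):
        labels = assign_leaflet(ztrace([0.2, -0.3, 0.1]), policy="confirmed")
        assert set(labels) == {"undetermined"}


class TestSummary:
    def test_replica_average_is_fractional(self):
        a = ztrace([0.8, -0.8])  # 1 event
        b = ztrace([0.8, 0.8])  # 0 events
        summary = summarize_transitions({"rep1": [a], "rep2": [b]})
        assert summary.mean_count["A"] == pytest.approx(0.5)

    def test_single_replica_count(self):
        z = [0.8, -0.8, 0.8, -0.8, 0.8]
        summary = summarize_transitions({"r": [ztrace(z)]})
        assert summary.mean_count["A"] == pytest.approx(4.0)
        assert summary.per_molecule.n_events.tolist() == [4]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_transitions({})


class TestHeightHistogram:
    def test_single_value_mass_in_one_bin(self):
        h = height_histogram(ztrace([0.7] * 50), mode="intensity_sensitive")
        assert h.probabilities.sum() == pytest.approx(1.0)
        idx = np.flatnonzero(h.probabilities)
        assert len(idx) == 1
        lo, hi = h.edges[idx[0]], h.edges[idx[0] + 1]
        assert lo <= 0.7 <= hi

    def test_mirror_symmetric_ties_break_positive(self):
        z = np.concatenate([np.full(40, 0.9), np.full(40, -0.9)])
        h = height_histogram(ztrace(z), mode="intensity_sensitive")
        assert h.winning_half == 1
        assert h.mass_share == pytest.approx(0.5)

    def test_matches_fold_and_filter_oracle(self):
        rng = np.random.default_rng(42)
        # asymmetric two-peak data: 70% upper leaflet
        z = np.concatenate(
            [rng.normal(1.0, 0.2, 700), rng.normal(-1.0, 0.2, 300)]
        )
        h = height_histogram(ztrace(z), bin_width=0.05, mode="intensity_sensitive")
        edges, probs, share = fold_and_filter_oracle(z, 0.05)
        assert h.winning_half == 1
        assert h.mass_share == pytest.approx(share)
        n = min(len(probs), len(h.probabilities))
        np.testing.assert_allclose(h.probabilities[:n], probs[:n], atol=1e-12)

    def test_full_z_normalizes(self):
        rng = np.random.default_rng(0)
        h = height_histogram(ztrace(rng.normal(0, 1, 1000)), mode="full_z")
        assert h.probabilities.sum() == pytest.approx(1.0, abs=1e-9)

    def test_same_leaflet_conditioning(self):
        a = ztrace([0.8, 0.9, -0.7, 0.8])
        partner = ztrace([0.5, -0.5, -0.9, 0.9])
        h = height_histogram(a, conditioning="same_leaflet", partner=partner)
        # frames 0 (both up), 2 (both down), 3 (both up) survive
        assert h.n_samples == 3

    def test_conditioning_removing_everything_errors(self):
        a = ztrace([0.8, 0.9])
        partner = ztrace([-0.8, -0.9])
        with pytest.raises(ValueError, match="no samples"):
            height_histogram(a, conditioning="same_leaflet", partner=partner)


def _two_atom_trajectory(vectors, com_z):
    """Molecule 0 with atoms a1, a2 separated by `vectors`, plus a P sheet."""
    n = len(vectors)
    positions = np.zeros((n, 4, 3))
    for f, (v, zc) in enumerate(zip(vectors, com_z)):
        base = np.array([2.0, 2.0, zc])
        positions[f, 0] = base - 0.5 * np.asarray(v)
        positions[f, 1] = base + 0.5 * np.asarray(v)
        positions[f, 2] = [1.0, 1.0, 1.9]
        positions[f, 3] = [1.0, 1.0, -1.9]
    topology = pd.DataFrame(
        {
            "molecule_id": [0, 0, 1, 2],
            "species": ["A", "A", "P", "P"],
            "atom_name": ["a1", "a2", "P", "P"],
            "mass": [1.0, 1.0, 31.0, 31.0],
        }
    )
    return Trajectory(
        times=np.arange(n, dtype=float),
        positions=positions,
        box=np.array([6.0, 6.0, 8.0]),
        topology=topology,
    )


class TestOrientationProfile:
    def test_axis_along_normal_gives_one(self):
        traj = _two_atom_trajectory([(0, 0, 1.0)] * 5, np.linspace(-1, 1, 5))
        prof = orientation_profile(traj, 0, ("a1", "a2"))
        np.testing.assert_allclose(prof.mean_abs_cos, 1.0)

    def test_in_plane_axis_gives_zero(self):
        traj = _two_atom_trajectory([(1.0, 0, 0)] * 5, np.linspace(-1, 1, 5))
        prof = orientation_profile(traj, 0, ("a1", "a2"))
        np.testing.assert_allclose(prof.mean_abs_cos, 0.0, atol=1e-12)

    def test_z_dependent_orientation_recovered(self):
        # rule: parallel to the surface near the head groups (|z| > 1),
        # orthogonal in the core — recovered bin by bin
        rng = np.random.default_rng(1)
        com_z = rng.uniform(-1.6, 1.6, 400)
        vectors = [(1.0, 0, 0) if abs(z) > 1.0 else (0, 0, 1.0) for z in com_z]
        traj = _two_atom_trajectory(vectors, com_z)
        prof = orientation_profile(traj, 0, ("a1", "a2"), z_bin_width=0.4)
        for c, v in zip(prof.bin_centers, prof.mean_abs_cos):
            if abs(c) > 1.2:
                assert v < 0.2
            elif abs(c) < 0.8:
                assert v > 0.8

    def test_degenerate_axis_rejected(self):
        traj = _two_atom_trajectory([(0, 0, 0)] * 3, [0.0, 0.1, 0.2])
        with pytest.raises(ValueError, match="degenerate"):
            orientation_profile(traj, 0, ("a1", "a2"))
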