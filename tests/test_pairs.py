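"""RDF calibration and cutoff clustering against brute-force oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from leafletdyn.pairs import (
    RDFConfig,
    cluster_timeseries,
    detect_clusters,
    radial_distribution,
)
from leafletdyn.trajectory import Trajectory


def make_traj(positions, species, box=(6.0, 6.0, 6.0)):
    positions = np.asarray(positions, float)
    n = positions.shape[1]
    topology = pd.DataFrame(
        {
            "molecule_id": range(n),
            "species": species,
            "atom_name": ["X"] * n,
            "mass": np.ones(n),
        }
    )
    return Trajectory(
        times=np.arange(positions.shape[0], dtype=float),
        positions=positions,
        box=np.asarray(box, float),
        topology=topology,
    )


def poisson_traj(n_frames, n_particles, box, seed):
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0, 1, size=(n_frames, n_particles, 3)) * np.asarray(box)
    return make_traj(pos, ["A"] * n_particles, box)


class TestRDF:
    def test_poisson_gas_is_unity(self):
        """Uniform random points: g(r) = 1 within 3·SEM at every bin."""
        traj = poisson_traj(400, 40, (6.0, 6.0, 6.0), seed=3)
        cfg = RDFConfig(mode="full_3d", bin_width=0.1, r_max=2.9)
        res = radial_distribution(traj, ("A", "A"), cfg)
        # Poisson SEM per bin from the expected count
        expected = res.pair_counts / np.where(res.g > 0, res.g, np.nan)
        sem = 3.0 / np.sqrt(expected)
        ok = np.abs(res.g - 1.0) <= sem
        assert np.all(ok[np.isfinite(sem)])

    def test_poisson_lateral_mode_calibrated(self):
        # per-bin z-scores of g(r) about 1 should look standard normal:
        # nearly all within 3σ, none grossly out, mean square ≈ 1
        traj = poisson_traj(400, 30, (6.0, 6.0, 6.0), seed=5)
        cfg = RDFConfig(mode="lateral_2d", bin_width=0.1, r_max=2.9)
        res = radial_distribution(traj, ("A", "A"), cfg)
        expected = res.pair_counts / np.where(res.g > 0, res.g, np.nan)
        zscores = (res.g - 1.0) * np.sqrt(expected)
        zscores = zscores[np.isfinite(zscores)]
        assert np.mean(np.abs(zscores) <= 3.0) >= 0.95
        assert np.max(np.abs(zscores)) < 5.0
        assert 0.3 < np.mean(zscores**2) < 3.0

    def test_frozen_pair_peak_in_correct_bin(self):
        pos = np.tile(np.array([[[1.0, 1.0, 1.0], [2.22, 1.0, 1.0]]]), (50, 1, 1))
        traj = make_traj(pos, ["A", "A"])
        res = radial_distribution(
            traj, ("A", "A"), RDFConfig(mode="lateral_2d", bin_width=0.05)
        )
        assert res.peak_r() == pytest.approx(1.22, abs=0.025)
        assert res.pair_counts.sum() == 50

    def test_lateral_rdf_ignores_z(self):
        pos = np.tile(np.array([[[1.0, 1.0, 1.0], [2.2, 1.0, -1.0]]]), (10, 1, 1))
        traj = make_traj(pos, ["A", "A"])
        res = radial_distribution(
            traj, ("A", "A"), RDFConfig(mode="lateral_2d", bin_width=0.05)
        )
        assert res.peak_r() == pytest.approx(1.2, abs=0.05)

    def test_opposite_leaflet_conditioning_empties_same_leaflet_pair(self):
        pos = np.tile(
            np.array([[[1, 1, 1.0], [2.2, 1, 1.0], [0, 0, 1.9], [0, 0, -1.9]]]),
            (5, 1, 1),
        )
        traj = make_traj(pos, ["A", "A", "P", "P"])
        res = radial_distribution(
            traj,
            ("A", "A"),
            RDFConfig(mode="lateral_2d", conditioning="opposite_leaflet"),
        )
        assert res.empty

    def test_r_max_beyond_half_box_rejected(self):
        traj = poisson_traj(2, 5, (6.0, 6.0, 6.0), seed=0)
        with pytest.raises(ValueError, match="half-box"):
            radial_distribution(traj, ("A", "A"), RDFConfig(r_max=4.0))

    def test_rigid_translation_invariance(self):
        traj = poisson_traj(50, 10, (6.0, 6.0, 6.0), seed=8)
        shifted = make_traj(
            (traj.positions + np.array([1.3, -0.7, 0.0])) % 6.0, ["A"] * 10
        )
        cfg = RDFConfig(mode="lateral_2d", bin_width=0.1, r_max=2.5)
        res1 = radial_distribution(traj, ("A", "A"), cfg)
        res2 = radial_distribution(shifted, ("A", "A"), cfg)
        np.testing.assert_allclose(res1.g, res2.g, atol=1e-9)

    def test_z_displacement_leaves_lateral_rdf(self):
        traj = poisson_traj(50, 10, (6.0, 6.0, 6.0), seed=8)
        moved = make_traj(
            traj.positions + np.array([0.0, 0.0, 0.9]), ["A"] * 10
        )
        cfg = RDFConfig(mode="lateral_2d", bin_width=0.1, r_max=2.5)
        np.testing.assert_allclose(
            radial_distribution(traj, ("A", "A"), cfg).g,
            radial_distribution(moved, ("A", "A"), cfg).g,
            atol=1e-9,
        )


def brute_force_clusters(pos, box, cutoff, lateral):
    """O(N²) union-find oracle for connected components."""
    n = len(pos)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            d = pos[i] - pos[j]
            dims = 2 if lateral else 3
            for k in range(dims):
                d[k] -= box[k] * round(d[k] / box[k])
            if np.sqrt((d[:dims] ** 2).sum()) <= cutoff:
                parent[find(i)] = find(j)
    roots = [find(i) for i in range(n)]
    relabel = {r: k for k, r in enumerate(dict.fromkeys(roots))}
    return [relabel[r] for r in roots]


class TestClusters:
    def test_chain_is_one_cluster(self):
        pos = np.array([[[0.1 + 0.8 * i, 1.0, 1.0] for i in range(5)]])
        traj = make_traj(pos, ["A"] * 5)
        res = detect_clusters(traj, 0, cutoff=1.0)
        assert res.largest_per_frame[0] == 5

    def test_far_particles_are_singletons(self):
        pos = np.array([[[0.5, 0.5, 0.5], [3.0, 3.0, 3.0], [0.5, 3.0, 0.5]]])
        traj = make_traj(pos, ["A"] * 3)
        res = detect_clusters(traj, 0, cutoff=1.0)
        assert res.largest_per_frame[0] == 1
        assert len(set(res.labels[0])) == 3

    @pytest.mark.parametrize("mode", ["lateral_2d", "full_3d"])
    def test_random_configs_match_union_find_oracle(self, mode):
        rng = np.random.default_rng(13)
        for _ in range(50):
            n = rng.integers(2, 12)
            pos = rng.uniform(0, 6.0, size=(1, n, 3))
            traj = make_traj(pos, ["A"] * n)
            res = detect_clusters(traj, 0, cutoff=1.2, mode=mode)
            oracle = brute_force_clusters(
                pos[0].copy(), traj.box, 1.2, lateral=mode == "lateral_2d"
            )
            # same partition up to relabelling
            ours = res.labels[0]
            assert len(set(ours)) == len(set(oracle))
            mapping = {}
            for a, b in zip(ours, oracle):
                assert mapping.setdefault(a, b) == b

    def test_relabelling_invariance(self):
        rng = np.random.default_rng(2)
        pos = rng.uniform(0, 6, size=(1, 8, 3))
        traj = make_traj(pos, ["A"] * 8)
        perm = rng.permutation(8)
        traj_perm = make_traj(pos[:, perm, :], ["A"] * 8)
        s1 = sorted(np.bincount(detect_clusters(traj, 0, cutoff=1.5).labels[0]))
        s2 = sorted(np.bincount(detect_clusters(traj_perm, 0, cutoff=1.5).labels[0]))
        assert s1 == s2

    def test_static_frame_constant_largest(self):
        pos = np.tile(np.array([[[1, 1, 1], [1.5, 1, 1], [4, 4, 4]]], float), (6, 1, 1))
        traj = make_traj(pos, ["A"] * 3)
        res = cluster_timeseries(traj, cutoff=1.0)
        assert np.all(res.largest_per_frame == 2)
        assert res.fraction_frames_with_cluster_geq(2) == 1.0

    def test_coupling_increases_clustering(self, paired_runs, free_runs):
        largest_paired = [
            np.mean(cluster_timeseries(traj, cutoff=1.0, mode="lateral_2d").largest_per_frame)
            for traj, _ in paired_runs[:10]
        ]
        largest_free = [
            np.mean(cluster_timeseries(traj, cutoff=1.0, mode="lateral_2d").largest_per_frame)
            for traj, _ in free_runs[:10]
        ]
        assert np.mean(largest_free) < np.mean(largest_paired)

    def test_empty_subset_rejected(self):
        traj = make_traj(np.zeros((1, 2, 3)), ["A", "A"])
        with pytest.raises(ValueError, match="selects no particles"):
            cluster_timeseries(traj, species="Q")

    def test_nonpositive_cutoff_rejected(self):
        traj = make_traj(np.zeros((1, 2, 3)), ["A", "A"])
        with pytest.raises(ValueError, match="cutoff"):
            cluster_timeseries(traj, cutoff=0.0)
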