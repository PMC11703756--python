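"""Pair statistics of membrane solutes: radial distribution functions and
distance-cutoff clustering.

The RDF normalizes pair-distance histograms against the ideal uniform
expectation at the same particle numbers and geometry, so g(r) → 1 for a
structureless system.  Two distance metrics are offered: ``lateral_2d``
(in-plane separation, minimum image in x/y, z ignored — appropriate for
in-leaflet structure) and ``full_3d`` (Euclidean with minimum image in all
box dimensions — resolves features such as interleaflet edge-to-edge pairs).
The normalization counts the actually considered pairs frame by frame, which
makes it finite-N correct (each reference particle sees N−1 partners) and
consistent with leaflet conditioning.

Clusters are connected components of the contact graph with edges between
particles closer than a cutoff (default 1.0 nm, the scale at which solute
RDFs typically deviate from unity).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .trajectory import Trajectory

__all__ = [
    "RDFConfig",
    "RDFResult",
    "ClusterResult",
    "radial_distribution",
    "detect_clusters",
    "cluster_timeseries",
]

DistanceMode = Literal["lateral_2d", "full_3d"]


@dataclass(frozen=True)
class RDFConfig:
    """Distance metric, binning and leaflet conditioning for the RDF."""

    mode: DistanceMode = "full_3d"
    bin_width: float = 0.05
    r_max: float | None = None  # defaults to half the lateral box
    conditioning: Literal["none", "same_leaflet", "opposite_leaflet"] = "none"

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if self.r_max is not None and self.r_max <= 0:
            raise ValueError("r_max must be > 0")


@dataclass
class RDFResult:
    """g(r) with raw pair counts and the normalization actually used."""

    r: np.ndarray
    g: np.ndarray
    pair_counts: np.ndarray
    n_pairs_used: int
    mode: str
    conditioning: str

    @property
    def empty(self) -> bool:
        return self.n_pairs_used == 0

    def peak_r(self) -> float:
        """Location of the strongest g(r) bin."""
        if self.empty:
            raise ValueError("empty RDF has no peak")
        return float(self.r[int(np.nanargmax(self.g))])


def _minimum_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    return d - box * np.round(d / box)


def _pair_distances(
    pos_a: np.ndarray,
    pos_b: np.ndarray,
    box: np.ndarray,
    mode: DistanceMode,
) -> np.ndarray:
    """(len(a), len(b)) minimum-image distances for one frame."""
    d = pos_a[:, None, :] - pos_b[None, :, :]
    if mode == "lateral_2d":
        d = _minimum_image(d[..., :2], box[:2])
        return np.sqrt((d**2).sum(axis=-1))
    if mode == "full_3d":
        d = _minimum_image(d, box[:3])
        return np.sqrt((d**2).sum(axis=-1))
    raise ValueError(f"unknown distance mode {mode!r}")


def radial_distribution(
    traj: Trajectory,
    species_pair: tuple[str, str],
    config: RDFConfig | None = None,
    reference_species: str = "P",
) -> RDFResult:
    """Radial distribution function between two species over all frames.

    Leaflet conditioning uses the instantaneous sign of z relative to the
    per-frame reference-particle COM (membrane centre); pairs with either
    particle exactly at the centre are dropped from conditioned analyses.
    """
    config = config or RDFConfig()
    sp_a, sp_b = species_pair
    idx_a = traj.select(species=sp_a)
    idx_b = traj.select(species=sp_b)
    like = sp_a == sp_b
    if idx_a.size == 0 or idx_b.size == 0 or (like and idx_a.size < 2):
        raise ValueError(f"need particles of both species {species_pair}")

    box = traj.box
    half_box = box[:2].min() / 2 if config.mode == "lateral_2d" else box.min() / 2
    r_max = config.r_max if config.r_max is not None else half_box
    if r_max > half_box + 1e-9:
        raise ValueError(
            f"r_max {r_max:.3f} nm exceeds half-box {half_box:.3f} nm for "
            f"mode {config.mode}"
        )
    edges = np.arange(0.0, r_max + config.bin_width * 0.5, config.bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = np.zeros(len(centers))
    expected = np.zeros(len(centers))

    if config.mode == "lateral_2d":
        shell = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
        domain = box[0] * box[1]
    else:
        shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
        domain = box[0] * box[1] * box[2]

    ref = traj.select(species=reference_species)
    need_leaflet = config.conditioning != "none"
    if need_leaflet and ref.size == 0:
        raise ValueError("leaflet conditioning requires reference particles")
    masses = traj.topology["mass"].to_numpy()

    n_pairs_used = 0
    iu = np.triu_indices(idx_a.size, k=1) if like else None
    for f in range(traj.n_frames):
        pos = traj.positions[f]
        dist = _pair_distances(pos[idx_a], pos[idx_b], box, config.mode)
        if like:
            vals = dist[iu]
            pair_mask = np.ones(vals.shape, bool)
        else:
            vals = dist.ravel()
            pair_mask = np.ones(vals.shape, bool)
        if need_leaflet:
            m = masses[ref]
            z_center = np.average(pos[ref, 2], weights=m)
            za = pos[idx_a, 2] - z_center
            zb = pos[idx_b, 2] - z_center
            rel = np.sign(za)[:, None] * np.sign(zb)[None, :]
            rel_flat = rel[iu] if like else rel.ravel()
            if config.conditioning == "same_leaflet":
                pair_mask = rel_flat > 0
            else:
                pair_mask = rel_flat < 0
        vals = vals[pair_mask]
        n_used = int(pair_mask.sum())
        n_pairs_used += n_used
        if n_used:
            counts += np.histogram(vals, bins=edges)[0]
            expected += n_used * shell / domain

    if n_pairs_used == 0:
        return RDFResult(
            r=centers,
            g=np.full_like(centers, np.nan),
            pair_counts=counts,
            n_pairs_used=0,
            mode=config.mode,
            conditioning=config.conditioning,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(expected > 0, counts / expected, np.nan)
    return RDFResult(
        r=centers,
        g=g,
        pair_counts=counts,
        n_pairs_used=n_pairs_used,
        mode=config.mode,
        conditioning=config.conditioning,
    )


@dataclass
class ClusterResult:
    """Connected-component clustering over one or more frames.

    ``labels`` is (n_frames_analysed, n_selected) with component ids per
    frame; ``size_distribution`` aggregates cluster sizes over frames;
    ``largest_per_frame`` traces the largest cluster size.
    """

    frames: np.ndarray
    particle_indices: np.ndarray
    labels: np.ndarray
    size_distribution: Counter = field(default_factory=Counter)
    largest_per_frame: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    cutoff: float = 1.0

    def fraction_frames_with_cluster_geq(self, k: int) -> float:
        if self.largest_per_frame.size == 0:
            return 0.0
        return float(np.mean(self.largest_per_frame >= k))


def _cluster_frame(
    pos: np.ndarray, box: np.ndarray, cutoff: float, mode: DistanceMode
) -> np.ndarray:
    dist = _pair_distances(pos, pos, box, mode)
    adj = csr_matrix(dist <= cutoff)
    _, labels = connected_components(adj, directed=False)
    return labels


def detect_clusters(
    traj: Trajectory,
    frame: int,
    species: str | Sequence[str] | None = None,
    cutoff: float = 1.0,
    mode: DistanceMode = "full_3d",
) -> ClusterResult:
    """Cluster one frame: components of the ≤cutoff contact graph."""
    return cluster_timeseries(traj, species, cutoff, mode, frames=[frame])


def cluster_timeseries(
    traj: Trajectory,
    species: str | Sequence[str] | None = None,
    cutoff: float = 1.0,
    mode: DistanceMode = "full_3d",
    frames: Sequence[int] | None = None,
) -> ClusterResult:
    """Per-frame clustering aggregated into a size distribution.

    ``species`` may be one tag, a list of tags, or None for every
    non-reference ("P") particle.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    if species is None:
        sel = np.flatnonzero((traj.topology["species"] != "P").to_numpy())
    elif isinstance(species, str):
        sel = traj.select(species=species)
    else:
        mask = traj.topology["species"].isin(list(species)).to_numpy()
        sel = np.flatnonzero(mask)
    if sel.size == 0:
        raise ValueError("species subset selects no particles")
    frame_ids = np.arange(traj.n_frames) if frames is None else np.asarray(frames, int)
    labels = np.empty((len(frame_ids), sel.size), dtype=int)
    sizes = Counter()
    largest = np.empty(len(frame_ids), dtype=int)
    for k, f in enumerate(frame_ids):
        lab = _cluster_frame(traj.positions[f, sel, :], traj.box, cutoff, mode)
        labels[k] = lab
        counts = np.bincount(lab)
        sizes.update(counts.tolist())
        largest[k] = counts.max()
    return ClusterResult(
        frames=frame_ids,
        particle_indices=sel,
        labels=labels,
        size_distribution=sizes,
        largest_per_frame=largest,
        cutoff=cutoff,
    )
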