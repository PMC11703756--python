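"""Flip-flop (interleaflet transition) detection and leaflet-resolved statistics.

A membrane-embedded molecule is said to have flipped from one leaflet to the
other only when its membrane-normal COM position confirms residence on both
sides: before and after the event the trace must reach at least a distance
``d`` from the membrane centre, once with positive and once with negative
sign.  Excursions that cross z = 0 but never reach ``-d`` (or ``+d``) on the
far side are not counted — the dead zone (−d, d) acts as a hysteresis band
that suppresses recrossing noise.  Default confirmation distances are
0.7 nm for species "A" and 0.6 nm for species "B" (close to the typical
resting distance of those solutes from the bilayer centre); other species
must be configured explicitly.

The module also provides leaflet assignment, replica-averaged transition
summaries, the two height-distribution representations (full signed-z and the
intensity-sensitive folded |z| histogram built from the dominant leaflet
only) and molecular-orientation profiles along the membrane normal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .trajectory import Trajectory, ZTrace, com_series, extract_ztrace

__all__ = [
    "TransitionConfig",
    "TransitionEvent",
    "TransitionSummary",
    "HeightHistogram",
    "OrientationProfile",
    "transition_indices",
    "detect_transitions",
    "summarize_transitions",
    "assign_leaflet",
    "height_histogram",
    "orientation_profile",
]

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = {"A": 0.7, "B": 0.6}


@dataclass(frozen=True)
class TransitionConfig:
    """Per-species confirmation distances d (nm) for transition detection."""

    thresholds: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_THRESHOLDS)
    )

    def __post_init__(self) -> None:
        for sp, d in self.thresholds.items():
            if not d > 0:
                raise ValueError(f"threshold for species {sp!r} must be > 0, got {d}")

    def threshold_for(self, species: str) -> float:
        try:
            return float(self.thresholds[species])
        except KeyError:
            raise KeyError(
                f"no transition threshold configured for species {species!r}; "
                "pass it explicitly in TransitionConfig(thresholds=...)"
            ) from None


@dataclass(frozen=True)
class TransitionEvent:
    """One confirmed interleaflet transition.

    ``time_ns`` is the first sample confirming arrival in the new leaflet;
    ``direction`` is "up" for lower→upper (− to +) and "down" for upper→lower.
    ``pre_index``/``post_index`` are the confirming excursion samples.
    """

    time_ns: float
    direction: Literal["up", "down"]
    pre_index: int
    post_index: int


def transition_indices(
    z: np.ndarray, d: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized core of the hysteresis detector.

    Takes the subsequence of samples with |z| ≥ d; every sign change within
    that subsequence is one event.  Returns (pre_indices, post_indices,
    signs_after) as arrays of indices into ``z`` and the post-change sign.
    """
    z = np.asarray(z, dtype=float)
    if d <= 0:
        raise ValueError("threshold d must be positive")
    idx = np.flatnonzero(np.abs(z) >= d)
    if idx.size < 2:
        empty = np.empty(0, dtype=int)
        return empty, empty, np.empty(0)
    s = np.sign(z[idx])
    change = np.flatnonzero(s[1:] != s[:-1])
    return idx[change], idx[change + 1], s[change + 1]


def detect_transitions(
    ztrace: ZTrace, config: TransitionConfig | None = None, d: float | None = None
) -> list[TransitionEvent]:
    """Detect confirmed flip-flop events in a z-trace.

    The threshold is taken from ``config`` by species unless ``d`` overrides
    it.  Empty and too-short traces return an empty list.
    """
    if d is None:
        config = config or TransitionConfig()
        d = config.threshold_for(ztrace.species)
    pre, post, sign_after = transition_indices(ztrace.z, d)
    return [
        TransitionEvent(
            time_ns=float(ztrace.times[p]),
            direction="up" if s > 0 else "down",
            pre_index=int(q),
            post_index=int(p),
        )
        for q, p, s in zip(pre, post, sign_after)
    ]


@dataclass
class TransitionSummary:
    """Replica-averaged transition counts per species.

    ``per_molecule`` has one row per (replica, molecule): columns ``replica,
    molecule_id, species, n_events, observation_ns``.  ``mean_count`` is the
    arithmetic mean over replicas of the per-replica per-molecule average
    count for each species — fractional values (e.g. 0.5 over two replicas)
    are the expected convention.  ``rate_per_us`` averages per-replica rates,
    which keeps mixed observation lengths comparable.
    """

    per_molecule: pd.DataFrame
    mean_count: dict[str, float]
    rate_per_us: dict[str, float]
    observation_ns: float


def summarize_transitions(
    traces_by_replica: Mapping[object, Sequence[ZTrace]],
    config: TransitionConfig | None = None,
) -> TransitionSummary:
    """Count events per molecule and average across replicas by species."""
    if not traces_by_replica:
        raise ValueError("need at least one replica")
    config = config or TransitionConfig()
    rows = []
    for replica, traces in traces_by_replica.items():
        for tr in traces:
            events = detect_transitions(tr, config)
            obs = float(tr.times[-1] - tr.times[0]) if len(tr) > 1 else 0.0
            rows.append(
                {
                    "replica": replica,
                    "molecule_id": tr.molecule_id,
                    "species": tr.species,
                    "n_events": len(events),
                    "observation_ns": obs,
                }
            )
    per_mol = pd.DataFrame(rows)
    obs_lengths = per_mol["observation_ns"].unique()
    if len(obs_lengths) > 1:
        logger.warning(
            "mixed observation lengths %s; rates computed per replica then averaged",
            obs_lengths,
        )
    mean_count: dict[str, float] = {}
    rate_per_us: dict[str, float] = {}
    for species, grp in per_mol.groupby("species"):
        per_replica = grp.groupby("replica")["n_events"].mean()
        mean_count[str(species)] = float(per_replica.mean())
        rep_rates = grp.groupby("replica").apply(
            lambda g: (g["n_events"] / g["observation_ns"] * 1e3).mean(),
            include_groups=False,
        )
        rate_per_us[str(species)] = float(rep_rates.mean())
    return TransitionSummary(
        per_molecule=per_mol,
        mean_count=mean_count,
        rate_per_us=rate_per_us,
        observation_ns=float(per_mol["observation_ns"].max()),
    )


def assign_leaflet(
    ztrace: ZTrace,
    config: TransitionConfig | None = None,
    policy: Literal["instantaneous", "confirmed"] = "instantaneous",
    d: float | None = None,
) -> np.ndarray:
    """Per-frame leaflet labels in {"upper", "lower", "undetermined"}.

    ``instantaneous``: sign of z (undetermined only at exactly 0).
    ``confirmed``: the last leaflet in which |z| ≥ d was reached; frames
    before the first threshold excursion are undetermined.
    """
    z = ztrace.z
    labels = np.full(len(z), "undetermined", dtype=object)
    if policy == "instantaneous":
        labels[z > 0] = "upper"
        labels[z < 0] = "lower"
        return labels
    if policy != "confirmed":
        raise ValueError(f"unknown leaflet policy {policy!r}")
    if d is None:
        config = config or TransitionConfig()
        d = config.threshold_for(ztrace.species)
    confirmed = np.where(np.abs(z) >= d, np.sign(z), 0.0)
    # forward-fill the last confirmed sign
    idx = np.where(confirmed != 0, np.arange(len(z)), -1)
    idx = np.maximum.accumulate(idx)
    state = np.where(idx >= 0, confirmed[np.maximum(idx, 0)], 0.0)
    labels[state > 0] = "upper"
    labels[state < 0] = "lower"
    return labels


@dataclass
class HeightHistogram:
    """Normalized height distribution of a membrane solute.

    ``mode="full_z"`` is the plain signed-z histogram.
    ``mode="intensity_sensitive"`` keeps only the leaflet half containing the
    higher peak and re-histograms on |z| (non-negative support);
    ``mass_share`` records that half's share of the probability before
    renormalization, and ``winning_half`` which leaflet won (+1 upper, −1
    lower; exact ties break to the positive half).
    """

    edges: np.ndarray
    probabilities: np.ndarray
    mode: str
    conditioning: str
    n_samples: int
    winning_half: int | None = None
    mass_share: float | None = None

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def peak_location(self) -> float:
        """Centre of the highest-probability bin."""
        return float(self.centers[int(np.argmax(self.probabilities))])


def _symmetric_edges(z: np.ndarray, bin_width: float) -> np.ndarray:
    lim = max(np.max(np.abs(z)), bin_width)
    n = int(np.ceil(lim / bin_width + 1e-9))
    return np.arange(-n, n + 1) * bin_width


def height_histogram(
    ztraces: ZTrace | Sequence[ZTrace],
    bin_width: float = 0.05,
    mode: Literal["full_z", "intensity_sensitive"] = "full_z",
    conditioning: Literal["none", "same_leaflet"] = "none",
    partner: ZTrace | None = None,
    leaflet_policy: Literal["instantaneous", "confirmed"] = "instantaneous",
    config: TransitionConfig | None = None,
) -> HeightHistogram:
    """Height distribution of one or more z-traces.

    With ``conditioning="same_leaflet"`` only frames where the molecule and
    its ``partner`` occupy the same leaflet contribute (instantaneous sign by
    default; ``confirmed`` uses the hysteresis state).  The
    intensity-sensitive mode selects the leaflet half whose histogram peak is
    higher, keeps only those samples and re-bins them on |z|.
    """
    if isinstance(ztraces, ZTrace):
        ztraces = [ztraces]
    if conditioning not in ("none", "same_leaflet"):
        raise ValueError(f"unknown conditioning {conditioning!r}")
    samples = []
    for tr in ztraces:
        z = tr.z
        if conditioning == "same_leaflet":
            if partner is None:
                raise ValueError("same_leaflet conditioning requires a partner trace")
            if len(partner) != len(tr):
                raise ValueError("partner trace length differs from trace length")
            lab_a = assign_leaflet(tr, config, leaflet_policy)
            lab_b = assign_leaflet(partner, config, leaflet_policy)
            keep = (lab_a == lab_b) & (lab_a != "undetermined")
            z = z[keep]
        samples.append(z)
    z = np.concatenate(samples) if samples else np.empty(0)
    if z.size == 0:
        raise ValueError("no samples remain after conditioning")

    edges = _symmetric_edges(z, bin_width)
    counts, _ = np.histogram(z, bins=edges)
    probs = counts / counts.sum()
    if mode == "full_z":
        return HeightHistogram(edges, probs, mode, conditioning, int(z.size))
    if mode != "intensity_sensitive":
        raise ValueError(f"unknown histogram mode {mode!r}")

    centers = 0.5 * (edges[:-1] + edges[1:])
    pos_max = probs[centers > 0].max() if np.any(centers > 0) else 0.0
    neg_max = probs[centers < 0].max() if np.any(centers < 0) else 0.0
    winning = 1 if pos_max >= neg_max else -1  # exact tie -> positive half
    kept = z[z > 0] if winning > 0 else z[z < 0]
    if kept.size == 0:
        raise ValueError("winning half contains no samples")
    mass_share = kept.size / z.size
    n_bins = int(np.ceil(np.max(np.abs(kept)) / bin_width + 1e-9))
    fold_edges = np.arange(n_bins + 1) * bin_width
    fold_counts, _ = np.histogram(np.abs(kept), bins=fold_edges)
    fold_probs = fold_counts / fold_counts.sum()
    return HeightHistogram(
        fold_edges,
        fold_probs,
        mode,
        conditioning,
        int(z.size),
        winning_half=winning,
        mass_share=float(mass_share),
    )


@dataclass
class OrientationProfile:
    """Mean |cos θ| of a molecular axis vs membrane-normal position.

    θ is the angle between the declared axis and +z; |cos θ| = 1 means the
    axis is along the normal, 0 means in-plane.
    """

    bin_centers: np.ndarray
    mean_abs_cos: np.ndarray
    counts: np.ndarray


def orientation_profile(
    traj: Trajectory,
    molecule_id: int,
    axis: tuple[str, str],
    z_bin_width: float = 0.2,
    reference_species: str = "P",
) -> OrientationProfile:
    """Orientation of a molecule's axis binned by its membrane-normal position.

    ``axis`` names the two atoms of the molecule defining the axis vector.
    The molecule's z (COM relative to the membrane centre when reference
    particles are present, raw COM z otherwise) selects the bin.
    """
    a_sel = traj.select(molecule_id=molecule_id, atom_name=axis[0])
    b_sel = traj.select(molecule_id=molecule_id, atom_name=axis[1])
    if a_sel.size != 1 or b_sel.size != 1:
        raise ValueError(f"axis atoms {axis} not uniquely resolvable in molecule")
    vec = traj.positions[:, b_sel[0], :] - traj.positions[:, a_sel[0], :]
    norms = np.linalg.norm(vec, axis=1)
    if np.any(norms < 1e-12):
        raise ValueError("degenerate axis: coincident atoms in at least one frame")
    abs_cos = np.abs(vec[:, 2] / norms)

    ref = traj.select(species=reference_species)
    if ref.size:
        zmol = extract_ztrace(traj, molecule_id, reference_species).z
    else:
        mol_sel = traj.select(molecule_id=molecule_id)
        zmol = com_series(traj, mol_sel)[:, 2]
    edges = _symmetric_edges(zmol, z_bin_width)
    which = np.digitize(zmol, edges) - 1
    n_bins = len(edges) - 1
    counts = np.bincount(which, minlength=n_bins)
    sums = np.bincount(which, weights=abs_cos, minlength=n_bins)
    occupied = counts > 0
    mean = np.full(n_bins, np.nan)
    mean[occupied] = sums[occupied] / counts[occupied]
    centers = 0.5 * (edges[:-1] + edges[1:])
    return OrientationProfile(
        bin_centers=centers[occupied],
        mean_abs_cos=mean[occupied],
        counts=counts[occupied],
    )
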