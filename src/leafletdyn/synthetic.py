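"""Ground-truthed synthetic data generators.

This module stands in for atomistic MD and confocal microscopy: it produces
(i) solute trajectories in a bilayer-mimetic potential, (ii) per-GUV
fluorescence time series with known transport fractions, (iii) GUV area
traces with known lysis labels, and (iv) sensor readouts drawn around
fate-typical centroids.  Every generator is deterministic at fixed seed and
records the ground truth it generated, so the analysis layer can be tested
end-to-end.

Membrane model
--------------
Each solute is an overdamped Langevin particle (Euler–Maruyama integration;
units nm, ns, kT).  Along the membrane normal it moves in a quartic double
well ``U(z) = ΔE[(z/z0)² − 1]²`` whose minima at ±z0 are the two leaflet
resting positions and whose barrier ΔE (kT) sets the spontaneous flip-flop
rate.  Pairs of solutes couple through

    U_ij = w(r_ij) · [ ε(G(z_i) + G(z_j)) − κ(|z_i| + |z_j|) ]

with ``w(r) = exp(−r²/2σ_r²)`` a lateral Gaussian contact weight (minimum
image, truncated at 3σ_r) and ``G(z) = exp(−z²/2σ_z²)``.  The ε term raises
the mid-membrane barrier for a solute whose partner is laterally close
(transition suppression); the κ term biases both partners outward toward the
head groups (peripheral shift) and, through its r-dependence, makes contact
energetically favourable, so interacting solutes dwell together and cluster.
Forces are the exact gradients of the total energy, so lateral and normal
motion are consistent with a single energy surface.

Two static sheets of reference "P" particles at ±head_group_z are emitted
with every trajectory so that the analysis layer's membrane-centre
computation is exercised rather than assumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from numba import njit

from .trajectory import Trajectory, ZTrace
from .transitions import transition_indices
from .transport import GUVAreaTrace, GUVFluorescenceTrace

__all__ = [
    "LangevinParams",
    "PairInteraction",
    "SimulationComposition",
    "GroundTruth",
    "simulate_solute_trajectories",
    "ztraces_from_trajectory",
    "simulate_fluorescence_traces",
    "simulate_area_traces",
    "simulate_fate_readouts",
]

SOLUTE_MASS = 700.0  # u, ionophore-sized
PHOSPHORUS_MASS = 30.974


@dataclass(frozen=True)
class LangevinParams:
    """Integration and geometry parameters (nm, ns, energies in kT).

    ``box_xy`` defaults to 6.3 nm so that two solutes give the reference
    surface density of ~0.05 molecules/nm².  The timestep must keep the RMS
    single-step normal displacement below z0/5, checked at construction.
    """

    well_position_z0: float = 1.0
    barrier_height: float = 8.0
    lateral_diffusion: float = 0.5
    normal_diffusion: float = 0.5
    timestep: float = 0.02
    n_steps: int = 100_000
    frame_stride: int = 10
    box_xy: float = 6.3
    box_z: float = 6.0
    head_group_z: float = 1.9

    def __post_init__(self) -> None:
        if self.well_position_z0 <= 0:
            raise ValueError("well_position_z0 must be > 0")
        if self.barrier_height < 0:
            raise ValueError("barrier_height must be >= 0")
        if self.lateral_diffusion <= 0 or self.normal_diffusion <= 0:
            raise ValueError("diffusion coefficients must be > 0")
        if self.timestep <= 0 or self.n_steps < 1 or self.frame_stride < 1:
            raise ValueError("timestep, n_steps and frame_stride must be positive")
        if self.box_z <= 4 * self.well_position_z0:
            raise ValueError("box_z must exceed 4*well_position_z0")
        step_rms = np.sqrt(2 * self.normal_diffusion * self.timestep)
        if step_rms >= self.well_position_z0 / 5:
            raise ValueError(
                f"unstable integration: RMS step {step_rms:.3f} nm >= z0/5 "
                f"({self.well_position_z0 / 5:.3f} nm); reduce timestep"
            )


@dataclass(frozen=True)
class PairInteraction:
    """Coupling for one unordered species pair (ε, κ ≥ 0 attraction/shift)."""

    epsilon: float = 0.0  # barrier raise at contact, kT
    sigma_r: float = 1.0  # lateral range, nm
    sigma_z: float = 0.5  # normal range, nm
    kappa: float = 0.0  # peripheral shift strength, kT/nm

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.sigma_r <= 0 or self.sigma_z <= 0:
            raise ValueError("interaction ranges must be > 0")


@dataclass
class SimulationComposition:
    """Species counts, per-species detection thresholds and pair couplings.

    ``interactions`` is keyed by unordered species pair; lookups are
    symmetric and default to no coupling.
    """

    counts: Mapping[str, int]
    thresholds: Mapping[str, float] = field(
        default_factory=lambda: {"A": 0.7, "B": 0.6, "C": 0.7}
    )
    interactions: Mapping[tuple[str, str], PairInteraction] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("species counts must be >= 0")
        if self.total_count < 1:
            raise ValueError("composition must contain at least one particle")
        canon = {}
        for (a, b), inter in self.interactions.items():
            key = tuple(sorted((a, b)))
            if key in canon and canon[key] != inter:
                raise ValueError(f"conflicting interactions for pair {key}")
            canon[key] = inter
        self.interactions = canon

    @property
    def total_count(self) -> int:
        return int(sum(self.counts.values()))

    def species_list(self) -> list[str]:
        """Per-particle species tags, deterministic ordering."""
        out: list[str] = []
        for sp in sorted(self.counts):
            out.extend([sp] * self.counts[sp])
        return out

    def interaction_for(self, a: str, b: str) -> PairInteraction:
        return self.interactions.get(tuple(sorted((a, b))), PairInteraction())

    def threshold_for(self, species: str) -> float:
        try:
            return float(self.thresholds[species])
        except KeyError:
            raise KeyError(f"no threshold configured for species {species!r}") from None


@dataclass
class GroundTruth:
    """True per-particle transition record at full generation resolution.

    Transition times use the same confirmed-excursion criterion as the
    analysis-layer detector, applied to the unstrided z sequence.  Contact
    fraction is the fraction of steps an interacting pair spent within
    1.5σ_r (minimum image, lateral).
    """

    transition_times: dict[int, np.ndarray]
    occupancy_upper: dict[int, float]
    contact_fraction: dict[tuple[int, int], float]
    species: dict[int, str]
    dt_ns: float

    @property
    def transition_counts(self) -> dict[int, int]:
        return {k: len(v) for k, v in self.transition_times.items()}

    def to_json_dict(self) -> dict:
        return {
            "dt_ns": self.dt_ns,
            "species": {str(k): v for k, v in self.species.items()},
            "transition_times_ns": {
                str(k): np.asarray(v).tolist() for k, v in self.transition_times.items()
            },
            "occupancy_upper": {str(k): v for k, v in self.occupancy_upper.items()},
            "contact_fraction": {
                f"{i}-{j}": v for (i, j), v in self.contact_fraction.items()
            },
        }


@njit(cache=True)
def _integrate(
    xy0, z0arr, noise, dt, dlat, dz_diff, de, z0, box_xy, eps, sr, sz, kap, stride
):  # pragma: no cover - exercised through simulate_solute_trajectories
    n_steps = noise.shape[0]
    n = z0arr.shape[0]
    n_frames = n_steps // stride + 1
    zfull = np.empty((n_steps + 1, n))
    frames = np.empty((n_frames, n, 3))
    contact = np.zeros((n, n))
    xy = xy0.copy()
    z = z0arr.copy()
    sq2lat = np.sqrt(2.0 * dlat * dt)
    sq2z = np.sqrt(2.0 * dz_diff * dt)
    zfull[0] = z
    for i in range(n):
        frames[0, i, 0] = xy[i, 0]
        frames[0, i, 1] = xy[i, 1]
        frames[0, i, 2] = z[i]
    fi = 1
    z0sq = z0 * z0
    z0q = z0sq * z0sq
    for step in range(n_steps):
        fx = np.zeros(n)
        fy = np.zeros(n)
        fz = np.empty(n)
        for i in range(n):
            fz[i] = -4.0 * de * z[i] * (z[i] * z[i] - z0sq) / z0q
        for i in range(n):
            for j in range(i + 1, n):
                e = eps[i, j]
                k = kap[i, j]
                if e == 0.0 and k == 0.0:
                    continue
                srij = sr[i, j]
                dx = xy[i, 0] - xy[j, 0]
                dx -= box_xy * np.round(dx / box_xy)
                dy = xy[i, 1] - xy[j, 1]
                dy -= box_xy * np.round(dy / box_xy)
                r2 = dx * dx + dy * dy
                if r2 <= 2.25 * srij * srij:
                    contact[i, j] += 1.0
                if r2 > 9.0 * srij * srij:
                    continue
                w = np.exp(-r2 / (2.0 * srij * srij))
                szij = sz[i, j]
                gi = np.exp(-z[i] * z[i] / (2.0 * szij * szij))
                gj = np.exp(-z[j] * z[j] / (2.0 * szij * szij))
                sgn_i = 0.0
                if z[i] > 0.0:
                    sgn_i = 1.0
                elif z[i] < 0.0:
                    sgn_i = -1.0
                sgn_j = 0.0
                if z[j] > 0.0:
                    sgn_j = 1.0
                elif z[j] < 0.0:
                    sgn_j = -1.0
                fz[i] += w * (e * z[i] / (szij * szij) * gi + k * sgn_i)
                fz[j] += w * (e * z[j] / (szij * szij) * gj + k * sgn_j)
                bracket = e * (gi + gj) - k * (abs(z[i]) + abs(z[j]))
                coef = w * bracket / (srij * srij)
                fx[i] += coef * dx
                fy[i] += coef * dy
                fx[j] -= coef * dx
                fy[j] -= coef * dy
        for i in range(n):
            xy[i, 0] = (xy[i, 0] + dlat * fx[i] * dt + sq2lat * noise[step, i, 0]) % box_xy
            xy[i, 1] = (xy[i, 1] + dlat * fy[i] * dt + sq2lat * noise[step, i, 1]) % box_xy
            z[i] = z[i] + dz_diff * fz[i] * dt + sq2z * noise[step, i, 2]
            zfull[step + 1, i] = z[i]
        if (step + 1) % stride == 0 and fi < n_frames:
            for i in range(n):
                frames[fi, i, 0] = xy[i, 0]
                frames[fi, i, 1] = xy[i, 1]
                frames[fi, i, 2] = z[i]
            fi += 1
    return zfull, frames, contact


def _phosphate_sheets(params: LangevinParams, n_side: int = 3) -> np.ndarray:
    """Static reference particle positions: two (n_side²) grids at ±head_group_z."""
    ticks = (np.arange(n_side) + 0.5) * params.box_xy / n_side
    gx, gy = np.meshgrid(ticks, ticks)
    sheet = np.column_stack([gx.ravel(), gy.ravel()])
    upper = np.column_stack([sheet, np.full(len(sheet), params.head_group_z)])
    lower = np.column_stack([sheet, np.full(len(sheet), -params.head_group_z)])
    return np.vstack([upper, lower])


def simulate_solute_trajectories(
    params: LangevinParams,
    comp: SimulationComposition,
    seed: int,
) -> tuple[Trajectory, GroundTruth]:
    """Generate one replica of coupled solutes in the bilayer-mimetic potential.

    Returns the strided :class:`Trajectory` (solutes plus static "P"
    reference sheets, membrane centre at z = 0) and the full-resolution
    :class:`GroundTruth`.  Deterministic at fixed (params, comp, seed).
    """
    species = comp.species_list()
    n = len(species)
    # per-particle-pair interaction tables
    eps = np.zeros((n, n))
    sr = np.ones((n, n))
    sz = np.ones((n, n)) * 0.5
    kap = np.zeros((n, n))
    max_range = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            inter = comp.interaction_for(species[i], species[j])
            eps[i, j] = eps[j, i] = inter.epsilon
            sr[i, j] = sr[j, i] = inter.sigma_r
            sz[i, j] = sz[j, i] = inter.sigma_z
            kap[i, j] = kap[j, i] = inter.kappa
            if inter.epsilon > 0 or inter.kappa > 0:
                max_range = max(max_range, 3 * inter.sigma_r)
    if max_range >= params.box_xy / 2:
        raise ValueError(
            f"interaction range {max_range:.2f} nm exceeds half box "
            f"({params.box_xy / 2:.2f} nm)"
        )

    rng = np.random.default_rng(seed)
    xy0 = rng.uniform(0.0, params.box_xy, size=(n, 2))
    zinit = params.well_position_z0 * rng.choice(np.array([-1.0, 1.0]), size=n)
    noise = rng.standard_normal((params.n_steps, n, 3))

    zfull, frames, contact = _integrate(
        xy0,
        zinit,
        noise,
        params.timestep,
        params.lateral_diffusion,
        params.normal_diffusion,
        params.barrier_height,
        params.well_position_z0,
        params.box_xy,
        eps,
        sr,
        sz,
        kap,
        params.frame_stride,
    )

    # ground truth at full resolution, same criterion as the detector
    transition_times: dict[int, np.ndarray] = {}
    occupancy: dict[int, float] = {}
    for i in range(n):
        d = comp.threshold_for(species[i])
        _, post, _ = transition_indices(zfull[:, i], d)
        transition_times[i] = post * params.timestep
        occupancy[i] = float(np.mean(zfull[:, i] > 0))
    contact_fraction = {
        (i, j): float(contact[i, j] / params.n_steps)
        for i in range(n)
        for j in range(i + 1, n)
        if eps[i, j] > 0 or kap[i, j] > 0
    }
    truth = GroundTruth(
        transition_times=transition_times,
        occupancy_upper=occupancy,
        contact_fraction=contact_fraction,
        species=dict(enumerate(species)),
        dt_ns=params.timestep,
    )

    sheets = _phosphate_sheets(params)
    n_ref = len(sheets)
    n_frames = frames.shape[0]
    positions = np.empty((n_frames, n + n_ref, 3))
    positions[:, :n, :] = frames
    positions[:, n:, :] = sheets[None, :, :]
    topology = pd.DataFrame(
        {
            "molecule_id": list(range(n)) + list(range(n, n + n_ref)),
            "species": species + ["P"] * n_ref,
            "atom_name": ["COM"] * n + ["P"] * n_ref,
            "mass": [SOLUTE_MASS] * n + [PHOSPHORUS_MASS] * n_ref,
        }
    )
    times = np.arange(n_frames) * params.timestep * params.frame_stride
    traj = Trajectory(
        times=times,
        positions=positions,
        box=np.array([params.box_xy, params.box_xy, params.box_z]),
        topology=topology,
    )
    return traj, truth


def ztraces_from_trajectory(traj: Trajectory) -> list[ZTrace]:
    """z-traces of every non-reference molecule, via the membrane-centre frame."""
    from .trajectory import extract_ztrace

    mols = traj.topology.loc[traj.topology["species"] != "P", "molecule_id"].unique()
    return [extract_ztrace(traj, int(m)) for m in mols]


# ---------------------------------------------------------------------------
# fluorescence and area traces


def simulate_fluorescence_traces(
    n_guvs: int,
    rate_per_min: float | np.ndarray = 0.3,
    direction: Literal["quench", "gain"] = "quench",
    transport_fractions: np.ndarray | None = None,
    noise_sd: float = 0.02,
    addition_time_min: float = 20.0,
    total_time_min: float = 60.0,
    dt_min: float = 0.5,
    baseline: float = 100.0,
    channel: str = "rhod2",
    seed: int = 0,
) -> tuple[list[GUVFluorescenceTrace], np.ndarray]:
    """Per-GUV intensity traces with known transport fractions.

    Each trace is flat at ``baseline`` until the ionophore addition time,
    then approaches its plateau mono-exponentially at ``rate_per_min``:
    quench traces decay to ``baseline·(1 − f)``, gain traces rise to
    ``baseline·(1 + f)``, with f the true transport fraction (drawn uniform
    on [0, 1] unless given).  Gaussian noise with sd ``noise_sd·baseline`` is
    added.  Returns the traces and the true fractions.
    """
    if n_guvs < 1:
        raise ValueError("n_guvs must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise sd must be >= 0")
    rates = np.broadcast_to(np.asarray(rate_per_min, float), (n_guvs,))
    if np.any(rates < 0):
        raise ValueError("rates must be >= 0")
    if not (0 <= addition_time_min < total_time_min):
        raise ValueError("addition time must lie within the trace window")
    rng = np.random.default_rng(seed)
    if transport_fractions is None:
        transport_fractions = rng.uniform(0.0, 1.0, size=n_guvs)
    transport_fractions = np.asarray(transport_fractions, float)
    times = np.arange(0.0, total_time_min + 1e-9, dt_min)
    sign = -1.0 if direction == "quench" else 1.0
    traces = []
    for g in range(n_guvs):
        response = np.where(
            times >= addition_time_min,
            1.0 - np.exp(-rates[g] * np.clip(times - addition_time_min, 0, None)),
            0.0,
        )
        intensity = baseline * (1.0 + sign * transport_fractions[g] * response)
        intensity = intensity + rng.normal(0.0, noise_sd * baseline, size=times.shape)
        traces.append(
            GUVFluorescenceTrace(
                guv_id=g,
                channel=channel,
                times=times.copy(),
                intensities=intensity,
                additions={"ionophore": addition_time_min},
            )
        )
    return traces, transport_fractions


def simulate_area_traces(
    n: int,
    lysing: bool | Sequence[bool] = True,
    seed: int = 0,
    noise_sd: float = 0.02,
    onset_min: float = 10.0,
    decay_rate_per_min: float = 0.5,
    area0_um2: float = 300.0,
    total_time_min: float = 40.0,
    dt_min: float = 0.5,
) -> tuple[list[GUVAreaTrace], np.ndarray]:
    """GUV area traces: lysing ones decay to ~0 after onset, others fluctuate.

    ``noise_sd`` is relative to the initial area.  Returns traces and the
    boolean lysis labels.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    labels = np.broadcast_to(np.asarray(lysing, bool), (n,)).copy()
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, total_time_min + 1e-9, dt_min)
    traces = []
    for g in range(n):
        if labels[g]:
            area = area0_um2 * np.where(
                times < onset_min,
                1.0,
                np.exp(-decay_rate_per_min * (times - onset_min)),
            )
        else:
            area = np.full_like(times, area0_um2)
        area = np.clip(area + rng.normal(0.0, noise_sd * area0_um2, times.shape), 0, None)
        traces.append(GUVAreaTrace(guv_id=g, times=times.copy(), areas=area))
    return traces, labels


def simulate_fate_readouts(
    n_per_fate: int = 10,
    fold_sd: float = 0.3,
    leak_sd: float = 5.0,
    seed: int = 0,
):
    """Sensor readouts drawn around fate-typical centroids, with labels.

    Centroids mimic the qualitative contrasts between terminal fates: high
    urease response after first-A fates, high oxidase (GaoA) response after
    first-B fates, dye leakage marking partial lipase activation when the
    Ca-ionophore came second, and lysis for C-first.
    """
    from .fate import SensorReadout

    centroids = {
        "A-b": (5.0, 1.2, 5.0, False),
        "A-c": (5.0, 1.0, 40.0, False),
        "B-a": (1.2, 5.0, 5.0, False),
        "B-c": (1.0, 5.0, 40.0, False),
        "C": (0.0, 0.0, 100.0, True),
    }
    rng = np.random.default_rng(seed)
    readouts, labels = [], []
    for label, (ur, ga, leak, lysed) in centroids.items():
        for _ in range(n_per_fate):
            readouts.append(
                SensorReadout(
                    urease_fold=max(0.0, rng.normal(ur, fold_sd)) if not lysed else 0.0,
                    gaoa_fold=max(0.0, rng.normal(ga, fold_sd)) if not lysed else 0.0,
                    leakage_pct=float(np.clip(rng.normal(leak, leak_sd), -5, 105)),
                    lysed=lysed,
                )
            )
            labels.append(label)
    return readouts, labels
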