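"""Trajectory containers, readers/writers and membrane-frame geometry.

The in-memory model is deliberately small: a :class:`Trajectory` holds frame
times (ns), positions (nm) in a periodic box and a flat topology table
(molecule id, species tag, atom name, mass).  A :class:`ZTrace` is the derived
one-dimensional observable the leaflet analyses consume: the centre-of-mass
position of one molecule along the membrane normal, measured relative to the
membrane centre (the mass-weighted centre of the phosphate reference
particles) recomputed every frame.

File formats (GRO/XTC/DCD/PDB) are delegated to MDAnalysis; all coordinates
are converted to nm on load regardless of the source convention.  A plain TSV
dialect (``time_ns  molecule_id  species  z_nm``) serves as the text
interchange format so downstream analyses remain testable without binary
trajectories.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "ZTrace",
    "compute_com",
    "com_series",
    "extract_ztrace",
    "read_trajectory",
    "write_gro",
    "write_trajectory",
    "read_ztrace_tsv",
    "write_ztrace_tsv",
]

_ANGSTROM_PER_NM = 10.0

#: columns every topology table must carry
TOPOLOGY_COLUMNS = ("molecule_id", "species", "atom_name", "mass")


@dataclass
class Trajectory:
    """Frames of labelled particle positions in a periodic box.

    Parameters
    ----------
    times : (F,) array, ns.  Strictly increasing.
    positions : (F, N, 3) array, nm.
    box : (3,) array, nm.  Orthorhombic box lengths; x/y are periodic, z is
        treated as unwrapped by the analyses.
    topology : DataFrame with columns ``molecule_id, species, atom_name,
        mass`` and one row per particle.
    """

    times: np.ndarray
    positions: np.ndarray
    box: np.ndarray
    topology: pd.DataFrame

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (n_frames, n_atoms, 3)")
        if len(self.times) != self.positions.shape[0]:
            raise ValueError("times and positions disagree on frame count")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        missing = [c for c in TOPOLOGY_COLUMNS if c not in self.topology.columns]
        if missing:
            raise ValueError(f"topology missing columns: {missing}")
        if len(self.topology) != self.positions.shape[1]:
            raise ValueError(
                f"topology has {len(self.topology)} atoms but positions have "
                f"{self.positions.shape[1]}"
            )
        if np.any(self.topology["mass"].to_numpy() <= 0):
            raise ValueError("all masses must be positive")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[1]

    def select(
        self,
        species: str | None = None,
        molecule_id: int | None = None,
        atom_name: str | None = None,
    ) -> np.ndarray:
        """Indices of particles matching all given (species, molecule, name)."""
        mask = np.ones(self.n_atoms, dtype=bool)
        top = self.topology
        if species is not None:
            mask &= (top["species"] == species).to_numpy()
        if molecule_id is not None:
            mask &= (top["molecule_id"] == molecule_id).to_numpy()
        if atom_name is not None:
            mask &= (top["atom_name"] == atom_name).to_numpy()
        return np.flatnonzero(mask)

    def species_of(self, molecule_id: int) -> str:
        rows = self.topology[self.topology["molecule_id"] == molecule_id]
        if rows.empty:
            raise KeyError(f"molecule_id {molecule_id} not in topology")
        return str(rows["species"].iloc[0])


@dataclass
class ZTrace:
    """Membrane-normal COM position of one molecule vs time.

    ``z`` is the molecule COM z minus the membrane-centre z, in nm; positive
    values are the upper leaflet.
    """

    molecule_id: int
    species: str
    times: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.times.shape != self.z.shape:
            raise ValueError("times and z must have the same length")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("z values must be finite")

    def __len__(self) -> int:
        return len(self.z)


# ---------------------------------------------------------------------------
# geometry


def mass_weighted_com(positions: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """COM of a (..., n, 3) position block with (n,) masses."""
    m = np.asarray(masses, dtype=float)
    if m.size == 0:
        raise ValueError("empty selection has no centre of mass")
    w = m / m.sum()
    return np.tensordot(np.asarray(positions, float), w, axes=([-2], [0]))


def compute_com(traj: Trajectory, selection: np.ndarray, frame: int) -> np.ndarray:
    """Mass-weighted centre of mass of ``selection`` at one frame (nm).

    z is used unwrapped; lateral coordinates are taken as stored.
    """
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValueError("empty selection has no centre of mass")
    masses = traj.topology["mass"].to_numpy()[selection]
    return mass_weighted_com(traj.positions[frame, selection, :], masses)


def com_series(traj: Trajectory, selection: np.ndarray) -> np.ndarray:
    """(F, 3) centre-of-mass trajectory of a selection."""
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValueError("empty selection has no centre of mass")
    masses = traj.topology["mass"].to_numpy()[selection]
    return mass_weighted_com(traj.positions[:, selection, :], masses)


def extract_ztrace(
    traj: Trajectory,
    molecule_id: int,
    reference_species: str = "P",
    reference_selection: np.ndarray | None = None,
) -> ZTrace:
    """z-trace of a molecule relative to the per-frame membrane centre.

    The membrane centre is the mass-weighted COM of the reference selection
    (by default every particle of species ``"P"``, mirroring the phosphate
    convention), recomputed at every frame.
    """
    mol_sel = traj.select(molecule_id=molecule_id)
    if mol_sel.size == 0:
        raise KeyError(f"molecule_id {molecule_id} not present in topology")
    if reference_selection is None:
        reference_selection = traj.select(species=reference_species)
        if reference_selection.size == 0:
            raise ValueError(
                f"no particles of reference species {reference_species!r}; "
                "pass reference_selection explicitly"
            )
    ref_com = com_series(traj, reference_selection)
    mol_com = com_series(traj, mol_sel)
    return ZTrace(
        molecule_id=molecule_id,
        species=traj.species_of(molecule_id),
        times=traj.times.copy(),
        z=mol_com[:, 2] - ref_com[:, 2],
    )


# ---------------------------------------------------------------------------
# MDAnalysis-backed binary/structured formats

_SUPPORTED = ("gro", "xtc", "dcd", "pdb", "tsv")

_XTC_MAGIC = 1995


def _validate_xtc(path: Path) -> None:
    """Walk the XTC frame chain; raise if the file ends mid-frame.

    XTC readers commonly skip a truncated trailing frame, silently loading a
    partial trajectory; this check enforces an explicit error instead.
    Frame layout: magic, natoms, step, time, 3x3 box, natoms, then either
    3·natoms plain floats (natoms ≤ 9) or the compressed block whose byte
    count precedes it, padded to 4.
    """
    import struct

    def _take(fh, n, what):
        buf = fh.read(n)
        if len(buf) < n:
            raise IOError(f"truncated trajectory file {path}: incomplete {what}")
        return buf

    with open(path, "rb") as fh:
        while True:
            head = fh.read(4)
            if not head:
                return
            if len(head) < 4:
                raise IOError(f"truncated trajectory file {path}: incomplete magic")
            (magic,) = struct.unpack(">i", head)
            if magic != _XTC_MAGIC:
                raise IOError(f"corrupt XTC {path}: bad frame magic {magic}")
            _take(fh, 12, "frame header")
            _take(fh, 36, "box")
            (lsize,) = struct.unpack(">i", _take(fh, 4, "atom count"))
            if lsize <= 9:
                _take(fh, 12 * lsize, "coordinates")
            else:
                sub = _take(fh, 36, "compression header")
                (nbytes,) = struct.unpack(">i", sub[-4:])
                _take(fh, (nbytes + 3) // 4 * 4, "coordinate block")


def _to_universe(traj: Trajectory):
    import MDAnalysis as mda

    mol_ids = traj.topology["molecule_id"].to_numpy()
    unique_mols, resindex = np.unique(mol_ids, return_inverse=True)
    u = mda.Universe.empty(
        n_atoms=traj.n_atoms,
        n_residues=len(unique_mols),
        atom_resindex=resindex,
        trajectory=True,
    )
    u.add_TopologyAttr("names", traj.topology["atom_name"].astype(str).tolist())
    resnames = [
        str(traj.topology.loc[mol_ids == m, "species"].iloc[0])[:4] or "X"
        for m in unique_mols
    ]
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", (unique_mols + 1).tolist())
    u.add_TopologyAttr("masses", traj.topology["mass"].to_numpy())
    u.dimensions = np.array(
        [*(traj.box * _ANGSTROM_PER_NM), 90.0, 90.0, 90.0], dtype=np.float32
    )
    return u


def _write_sidecar(path: Path, **provenance) -> None:
    from . import __version__

    meta = {"writer": "leafletdyn", "version": __version__, **provenance}
    Path(str(path) + ".provenance.json").write_text(json.dumps(meta, indent=2))


def write_gro(traj: Trajectory, path: str | Path, frame: int = 0) -> None:
    """Write a single frame as GRO (topology companion for XTC/DCD)."""
    u = _to_universe(traj)
    u.atoms.positions = traj.positions[frame] * _ANGSTROM_PER_NM
    u.atoms.write(str(path))
    _write_sidecar(Path(path), format="gro", frame=frame)


def write_trajectory(traj: Trajectory, path: str | Path, fmt: str | None = None) -> None:
    """Write all frames to XTC or DCD (by extension unless ``fmt`` forces)."""
    import MDAnalysis as mda

    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt not in ("xtc", "dcd"):
        raise ValueError(f"unsupported trajectory format {fmt!r}; use xtc or dcd")
    u = _to_universe(traj)
    with mda.Writer(str(path), n_atoms=traj.n_atoms) as w:
        for i in range(traj.n_frames):
            u.atoms.positions = traj.positions[i] * _ANGSTROM_PER_NM
            u.trajectory.ts.frame = i
            u.trajectory.ts.time = traj.times[i] * 1000.0  # ps
            u.trajectory.ts.dimensions = u.dimensions
            w.write(u.atoms)
    _write_sidecar(path, format=fmt, n_frames=traj.n_frames)


def _topology_from_universe(u) -> pd.DataFrame:
    n = len(u.atoms)
    try:
        names = u.atoms.names.astype(str)
    except Exception:  # pragma: no cover - topology without names
        names = np.array(["X"] * n)
    try:
        resnames = u.atoms.resnames.astype(str)
    except Exception:  # pragma: no cover
        resnames = np.array(["X"] * n)
    try:
        masses = np.asarray(u.atoms.masses, dtype=float)
        if np.any(~np.isfinite(masses)) or np.any(masses <= 0):
            raise ValueError
    except Exception:
        masses = np.ones(n)
    return pd.DataFrame(
        {
            "molecule_id": np.asarray(u.atoms.resids, dtype=int) - 1,
            "species": resnames,
            "atom_name": names,
            "mass": masses,
        }
    )


def read_trajectory(
    topology: str | Path,
    trajectory: str | Path | None = None,
    fmt: str | None = None,
    stride_ns: float = 1.0,
):
    """Load a trajectory (GRO+XTC/DCD, PDB, GRO) or a TSV z-trace table.

    Returns a :class:`Trajectory`, or a list of :class:`ZTrace` for the TSV
    dialect.  Coordinates are converted to nm (PDB/MDAnalysis native Å are
    divided by 10).  Frame times are taken from the file when present,
    otherwise synthesized as ``frame_index * stride_ns``.
    """
    import MDAnalysis as mda

    topology = Path(topology)
    ext = (fmt or topology.suffix.lstrip(".")).lower()
    if ext == "tsv":
        return read_ztrace_tsv(topology)
    if ext not in _SUPPORTED:
        raise ValueError(
            f"unknown format {ext!r}; supported formats: {', '.join(_SUPPORTED)}"
        )
    if trajectory is not None:
        if str(trajectory).lower().endswith(".xtc"):
            _validate_xtc(Path(trajectory))
        u = mda.Universe(str(topology), str(trajectory))
    else:
        u = mda.Universe(str(topology))
    top = _topology_from_universe(u)

    positions, times = [], []
    try:
        for i, ts in enumerate(u.trajectory):
            if len(u.atoms) != len(top):
                raise IOError(f"atom count changed at frame {i}")
            positions.append(u.atoms.positions / _ANGSTROM_PER_NM)
            t = getattr(ts, "time", None)
            times.append(float(t) / 1000.0 if t is not None else np.nan)
    except EOFError as exc:  # truncated binary trajectory: no partial load
        raise IOError(f"truncated trajectory file {trajectory}: {exc}") from exc
    times_arr = np.asarray(times)
    if np.any(~np.isfinite(times_arr)) or len(times_arr) > 1 and np.any(
        np.diff(times_arr) <= 0
    ):
        times_arr = np.arange(len(positions), dtype=float) * stride_ns
    dims = u.dimensions
    box = (
        np.asarray(dims[:3], dtype=float) / _ANGSTROM_PER_NM
        if dims is not None
        else np.full(3, np.nan)
    )
    return Trajectory(
        times=times_arr,
        positions=np.asarray(positions),
        box=box,
        topology=top,
    )


# ---------------------------------------------------------------------------
# TSV z-trace dialect

_ZTRACE_COLUMNS = ["time_ns", "molecule_id", "species", "z_nm"]


def write_ztrace_tsv(traces: Iterable[ZTrace], path: str | Path) -> None:
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "time_ns": tr.times,
                    "molecule_id": tr.molecule_id,
                    "species": tr.species,
                    "z_nm": tr.z,
                }
            )
        )
    if not frames:
        raise ValueError("no traces to write")
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
    _write_sidecar(Path(path), format="ztrace_tsv", n_traces=len(frames))


def read_ztrace_tsv(path: str | Path) -> list[ZTrace]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _ZTRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"z-trace TSV missing columns {missing}")
    traces = []
    for (mol, species), grp in df.groupby(["molecule_id", "species"], sort=True):
        grp = grp.sort_values("time_ns")
        traces.append(
            ZTrace(
                molecule_id=int(mol),
                species=str(species),
                times=grp["time_ns"].to_numpy(),
                z=grp["z_nm"].to_numpy(),
            )
        )
    return traces
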