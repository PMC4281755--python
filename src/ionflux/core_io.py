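"""Topology/trajectory containers and readers for the formats used here.

Internal conventions: lengths in Å, times in ns (rates are reported in
μs⁻¹ downstream), +z points toward the extracellular side and analyses
place z = 0 at the S1 centroid. Frame times are t_k = k * frame_interval.

File I/O for PDB / DCD / XTC is delegated to MDAnalysis; the columnar
TSV frame format (header ``frame time_ns atom_id x y z``) is handled with
pandas. Atom selections use the MDAnalysis selection language, with
``chain`` accepted as an alias for ``chainID``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import MDAnalysis as mda
import numpy as np
import pandas as pd

from .errors import EmptyInputError, ParseError, StructureError

#: the sampling interval the analyses assume when a container does not carry one, ns
DEFAULT_FRAME_INTERVAL = 1.25

_FRAME_FORMATS = ("tsv", "pdb", "dcd", "xtc")


@dataclass
class Topology:
    """Per-atom identity table.

    Atom ids are dense 0..N-1 in file order; residue/chain identifiers are
    preserved verbatim from the source.
    """

    atom_names: np.ndarray
    residue_names: np.ndarray
    residue_numbers: np.ndarray
    chain_ids: np.ndarray
    _universe: mda.Universe | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        n = len(self.atom_names)
        for arr in (self.residue_names, self.residue_numbers, self.chain_ids):
            if len(arr) != n:
                raise StructureError("topology field lengths differ")
        if any(name == "" for name in self.residue_names):
            raise StructureError("empty residue_name in topology")
        if any(cid == "" for cid in self.chain_ids):
            raise StructureError("empty chain_id in topology")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def atom_ids(self) -> np.ndarray:
        return np.arange(self.n_atoms)

    @property
    def atoms(self) -> list[tuple[int, str, str, int, str]]:
        """Atom records as (atom_id, atom_name, residue_name, residue_number, chain_id)."""
        return [
            (i, self.atom_names[i], self.residue_names[i],
             int(self.residue_numbers[i]), self.chain_ids[i])
            for i in range(self.n_atoms)
        ]

    @classmethod
    def from_records(cls, records) -> "Topology":
        """Build from an iterable of (atom_name, residue_name, residue_number, chain_id)."""
        recs = list(records)
        return cls(
            atom_names=np.array([r[0] for r in recs], dtype=object),
            residue_names=np.array([r[1] for r in recs], dtype=object),
            residue_numbers=np.array([int(r[2]) for r in recs], dtype=np.int64),
            chain_ids=np.array([r[3] for r in recs], dtype=object),
        )

    def to_universe(self) -> mda.Universe:
        """In-memory MDAnalysis Universe mirroring this topology (cached)."""
        if self._universe is None:
            # residues delimited by change of (chain, resid, resname) in atom order
            keys = list(zip(self.chain_ids, self.residue_numbers, self.residue_names))
            resindex = np.zeros(self.n_atoms, dtype=np.int64)
            res_keys = []
            for i, k in enumerate(keys):
                if not res_keys or k != res_keys[-1]:
                    res_keys.append(k)
                resindex[i] = len(res_keys) - 1
            u = mda.Universe.empty(
                self.n_atoms,
                n_residues=len(res_keys),
                atom_resindex=resindex,
                residue_segindex=np.zeros(len(res_keys), dtype=np.int64),
                trajectory=True,
            )
            u.add_TopologyAttr("names", list(self.atom_names))
            u.add_TopologyAttr("resnames", [k[2] for k in res_keys])
            u.add_TopologyAttr("resids", [int(k[1]) for k in res_keys])
            u.add_TopologyAttr("chainIDs", list(self.chain_ids))
            object.__setattr__(self, "_universe", u)
        return self._universe


_CHAIN_ALIAS = re.compile(r"\bchain\b(?!ID)")


@dataclass(frozen=True)
class Selection:
    """Atom selection over (chain, residue number/name, atom name).

    Resolution is deterministic: the same expression on the same topology
    always yields the same sorted id set.
    """

    expression: str

    def resolve(self, topology: Topology) -> np.ndarray:
        expr = _CHAIN_ALIAS.sub("chainID", self.expression)
        group = topology.to_universe().select_atoms(expr)
        return np.sort(group.ix.astype(np.int64))


@dataclass
class Trajectory:
    """Coordinate frames (Å) over a fixed topology at a fixed sampling interval."""

    topology: Topology
    frames: np.ndarray          # (n_frames, n_atoms, 3), Å
    frame_interval: float       # ns
    z_convention: bool = False  # True once +z=extracellular / S1-at-origin is established

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise StructureError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise StructureError(
                f"frame atom count {self.frames.shape[1]} != topology "
                f"atom count {self.topology.n_atoms}"
            )
        if self.n_frames == 0:
            raise EmptyInputError("trajectory has zero frames")
        if self.frame_interval <= 0:
            raise StructureError("frame_interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Frame times t_k = k * frame_interval, ns."""
        return np.arange(self.n_frames) * self.frame_interval

    def positions(self, selection: Selection | np.ndarray) -> np.ndarray:
        """Per-frame centroid (n_frames, 3) of the selected atoms."""
        ids = selection.resolve(self.topology) if isinstance(selection, Selection) else np.asarray(selection)
        if len(ids) == 0:
            raise StructureError(f"selection resolves to no atoms")
        return self.frames[:, ids, :].mean(axis=1)


def _check_pdb_records(path: Path) -> None:
    """Cheap structural validation so malformed records fail with a line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                if len(line.rstrip("\n")) < 54:
                    raise ParseError(f"{path}: line {lineno}: truncated coordinate record")
                try:
                    float(line[30:38]), float(line[38:46]), float(line[46:54])
                except ValueError as exc:
                    raise ParseError(
                        f"{path}: line {lineno}: non-numeric coordinate field"
                    ) from exc


def load_topology(path, format: str = "pdb") -> Topology:
    """Read a topology from a PDB file (one atom per ATOM/HETATM record)."""
    path = Path(path)
    if format != "pdb":
        raise ParseError(f"unsupported topology format {format!r}")
    if not path.is_file():
        raise IOError(f"topology file not found: {path}")
    _check_pdb_records(path)
    try:
        u = mda.Universe(str(path))
    except Exception as exc:  # pragma: no cover - MDA error text varies
        raise ParseError(f"{path}: {exc}") from exc
    chains = (
        u.atoms.chainIDs if hasattr(u.atoms, "chainIDs") else np.full(len(u.atoms), "A")
    )
    return Topology(
        atom_names=np.array(u.atoms.names, dtype=object),
        residue_names=np.array(u.atoms.resnames, dtype=object),
        residue_numbers=np.array(u.atoms.resids, dtype=np.int64),
        chain_ids=np.array([c if c.strip() else "A" for c in chains], dtype=object),
    )


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in _FRAME_FORMATS:
        return suffix
    raise ParseError(f"cannot infer frame format from suffix of {path}")


def load_frames(path, topology: Topology, format: str | None = None,
                frame_interval: float = DEFAULT_FRAME_INTERVAL) -> Trajectory:
    """Read coordinate frames and attach them to *topology*.

    Supported formats: ``tsv`` (columnar ``frame time_ns atom_id x y z``),
    multi-model ``pdb``, ``dcd``, ``xtc``.
    """
    path = Path(path)
    if not path.is_file():
        raise IOError(f"frames file not found: {path}")
    fmt = format or _infer_format(path)
    if fmt == "tsv":
        frames = _read_tsv_frames(path, topology)
    elif fmt in ("pdb", "dcd", "xtc"):
        if fmt == "pdb":
            _check_pdb_records(path)
        u = mda.Universe.empty(topology.n_atoms, trajectory=True)
        try:
            u.load_new(str(path), format=fmt.upper() if fmt != "pdb" else "PDB")
        except (ValueError, OSError) as exc:
            raise StructureError(f"{path}: {exc}") from exc
        frames = np.array([ts.positions.copy() for ts in u.trajectory], dtype=np.float64)
    else:
        raise ParseError(f"unsupported frame format {fmt!r}")
    if frames.shape[0] == 0:
        raise EmptyInputError(f"{path}: zero frames")
    if frames.shape[1] != topology.n_atoms:
        raise StructureError(
            f"{path}: frame atom count {frames.shape[1]} != topology {topology.n_atoms}"
        )
    return Trajectory(topology=topology, frames=frames, frame_interval=frame_interval)


def _read_tsv_frames(path: Path, topology: Topology) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"frame", "atom_id", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: TSV frames need columns {sorted(required)}")
    if len(df) == 0:
        raise EmptyInputError(f"{path}: zero frames")
    df = df.sort_values(["frame", "atom_id"], kind="stable")
    n_frames = df["frame"].nunique()
    counts = df.groupby("frame").size()
    if counts.nunique() != 1 or counts.iloc[0] != topology.n_atoms:
        raise StructureError(f"{path}: rows per frame do not match topology atom count")
    xyz = df[["x", "y", "z"]].to_numpy(dtype=np.float64)
    return xyz.reshape(n_frames, topology.n_atoms, 3)


def write_frames(traj: Trajectory, path, format: str | None = None) -> None:
    """Write frames; formats mirror :func:`load_frames` (round-trip safe)."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "tsv":
        n_f, n_a = traj.n_frames, traj.topology.n_atoms
        df = pd.DataFrame({
            "frame": np.repeat(np.arange(n_f), n_a),
            "time_ns": np.repeat(traj.times, n_a),
            "atom_id": np.tile(np.arange(n_a), n_f),
        })
        xyz = traj.frames.reshape(-1, 3)
        df["x"], df["y"], df["z"] = xyz[:, 0], xyz[:, 1], xyz[:, 2]
        df.to_csv(path, sep="\t", index=False, float_format="%.4f")
        return
    u = traj.topology.to_universe()
    u.load_new(traj.frames, order="fac")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MDA warns about absent elements/occupancies
        with mda.Writer(str(path), n_atoms=traj.topology.n_atoms, multiframe=True) as w:
            for _ in u.trajectory:
                w.write(u.atoms)


def center_on(traj: Trajectory, selection: Selection | np.ndarray) -> Trajectory:
    """Rigid translation placing the selection centroid of frame 0 at the origin.

    Used to establish the z-convention: after centering on the S1
    coordinating shell, S1 sits at z = 0 and +z points extracellularly
    (assuming the input was built in a membrane-normal frame).
    """
    ref = traj.positions(selection)[0]
    out = Trajectory(
        topology=traj.topology,
        frames=traj.frames - ref[None, None, :],
        frame_interval=traj.frame_interval,
        z_convention=True,
    )
    return out


def validate_continuity(traj: Trajectory, max_jump: float = 5.0) -> int:
    """Warn if any atom moves more than *max_jump* Å between consecutive frames.

    A frame-to-frame jump above a bond-length-scale threshold usually means
    the input was not re-imaged/whole-molecule wrapped. Returns the number
    of offending frame pairs.
    """
    if traj.n_frames < 2:
        return 0
    jumps = np.linalg.norm(np.diff(traj.frames, axis=0), axis=2)
    bad = int((jumps.max(axis=1) > max_jump).sum())
    if bad:
        warnings.warn(
            f"{bad} frame pair(s) contain atom displacements > {max_jump} Å; "
            "input may not be imaged/whole",
            stacklevel=2,
        )
    return bad
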