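"""Trajectory and topology I/O, periodic boundaries, and atom selection.

Conventions (used package-wide): coordinates in Angstrom, time in fs,
0-based atom indices.  Only orthorhombic boxes are supported; triclinic
lattices are rejected.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence
import warnings

import numpy as np
import yaml

__all__ = [
    "Topology",
    "Frame",
    "Trajectory",
    "XYZParseError",
    "read_xyz",
    "write_xyz",
    "minimum_image",
    "select_group",
    "load_topology",
]


class XYZParseError(ValueError):
    """Raised on malformed multi-frame XYZ input."""


@dataclass
class Topology:
    """Static description of the system: atoms, bonds and named groups.

    ``groups`` maps a name (e.g. ``"C2=O2"``, ``"water"``) to a tuple of
    atom indices.  Deuteration is expressed as a mass override (polar H set
    to 2 amu) and never as element relabelling, so geometric analysis is
    mass-agnostic.
    """

    labels: list[str]
    elements: list[str]
    masses: np.ndarray
    bonds: set[tuple[int, int]] = field(default_factory=set)
    groups: dict[str, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        n = self.n_atoms
        if len(self.elements) != n or len(self.masses) != n:
            raise ValueError("labels, elements and masses must have equal length")
        if np.any(self.masses <= 0):
            raise ValueError("all masses must be positive")
        self.bonds = {tuple(sorted(b)) for b in self.bonds}
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i}, {j}) references atom outside 0..{n - 1}")
        for name, idx in self.groups.items():
            idx = tuple(int(k) for k in idx)
            if any(k < 0 or k >= n for k in idx):
                raise ValueError(f"group {name!r} references atom outside 0..{n - 1}")
            self.groups[name] = idx

    @property
    def n_atoms(self) -> int:
        return len(self.labels)

    def bonded_to(self, i: int) -> list[int]:
        return sorted(j if a == i else a for a, j in self.bonds if i in (a, j))

    def set_deuterium_masses(self, indices: Sequence[int], mass: float = 2.0141) -> None:
        """Override masses of polar hydrogens (deuteration); labels unchanged."""
        self.masses = self.masses.copy()
        self.masses[list(indices)] = mass


@dataclass
class Frame:
    """One snapshot: positions (n_atoms, 3) in Angstrom, optional box, time in fs."""

    positions: np.ndarray
    box: np.ndarray | None = None
    time: float = 0.0
    topology: Topology | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (n_atoms, 3)")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,) or np.any(self.box <= 0):
                raise ValueError("box must be three positive edge lengths")
        if self.topology is not None and len(self.positions) != self.topology.n_atoms:
            raise ValueError("position count does not match topology atom count")


class Trajectory:
    """Ordered frames with uniform time spacing ``dt`` (fs).

    Positions are stored as one contiguous array of shape
    (n_frames, n_atoms, 3).
    """

    def __init__(
        self,
        topology: Topology,
        positions: np.ndarray,
        dt: float,
        box: np.ndarray | None = None,
        t0: float = 0.0,
    ) -> None:
        positions = np.asarray(positions, dtype=float)
        if positions.ndim != 3 or positions.shape[2] != 3:
            raise ValueError("positions must have shape (n_frames, n_atoms, 3)")
        if positions.shape[1] != topology.n_atoms:
            raise ValueError("atom count of positions does not match topology")
        if dt <= 0:
            raise ValueError("dt must be positive")
        self.topology = topology
        self.positions = positions
        self.dt = float(dt)
        self.t0 = float(t0)
        self.box = None if box is None else np.asarray(box, dtype=float)
        if self.box is not None and (self.box.shape != (3,) or np.any(self.box <= 0)):
            raise ValueError("box must be three positive edge lengths")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_frames)

    def frame(self, i: int) -> Frame:
        return Frame(
            positions=self.positions[i],
            box=self.box,
            time=float(self.times[i]),
            topology=self.topology,
        )

    def __len__(self) -> int:
        return self.n_frames

    def __iter__(self) -> Iterator[Frame]:
        for i in range(self.n_frames):
            yield self.frame(i)

    def window(self, start_fs: float, end_fs: float) -> np.ndarray:
        """Frame-index array for times in [start_fs, end_fs)."""
        t = self.times
        idx = np.nonzero((t >= start_fs - 1e-9) & (t < end_fs - 1e-9))[0]
        if idx.size == 0:
            raise ValueError(f"empty window [{start_fs}, {end_fs}) fs")
        return idx


_LATTICE_RE = re.compile(r'Lattice="([^"]+)"')


def _parse_box(comment: str) -> np.ndarray | None:
    """Extract an orthorhombic box from an XYZ comment line, if present."""
    m = _LATTICE_RE.search(comment)
    if m:
        vals = np.array([float(x) for x in m.group(1).split()])
        if vals.size != 9:
            raise XYZParseError("Lattice entry must contain 9 numbers")
        cell = vals.reshape(3, 3)
        off = cell - np.diag(np.diag(cell))
        if np.any(np.abs(off) > 1e-8):
            raise ValueError("only orthorhombic boxes are supported (triclinic lattice found)")
        return np.diag(cell).copy()
    toks = comment.split()
    if len(toks) == 3:
        try:
            box = np.array([float(t) for t in toks])
        except ValueError:
            return None
        if np.all(box > 0):
            return box
    return None


def read_xyz(path: str | Path, dt: float, topology: Topology | None = None) -> Trajectory:
    """Read a multi-frame XYZ file into a Trajectory with time step ``dt`` fs.

    The comment line may carry an orthorhombic box either as an extended-XYZ
    ``Lattice="..."`` entry or as three bare floats.  If no topology is
    given, a minimal one is built from the element column with unit masses.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    frames: list[np.ndarray] = []
    elements: list[str] = []
    box: np.ndarray | None = None
    ln = 0
    nframe = 0
    while ln < len(lines):
        if not lines[ln].strip():
            ln += 1
            continue
        nframe += 1
        try:
            natoms = int(lines[ln].strip())
        except ValueError:
            raise XYZParseError(
                f"frame {nframe}: expected atom count on line {ln + 1}, got {lines[ln]!r}"
            )
        if ln + 1 + natoms >= len(lines) + 1:
            raise XYZParseError(f"frame {nframe}: truncated (expected {natoms} atoms)")
        comment = lines[ln + 1] if ln + 1 < len(lines) else ""
        fbox = _parse_box(comment)
        if fbox is not None:
            box = fbox
        coords = np.empty((natoms, 3))
        els: list[str] = []
        for k in range(natoms):
            lno = ln + 2 + k
            if lno >= len(lines):
                raise XYZParseError(f"frame {nframe}: truncated (expected {natoms} atoms)")
            toks = lines[lno].split()
            if len(toks) < 4:
                raise XYZParseError(
                    f"frame {nframe}, line {lno + 1}: expected element and 3 coordinates"
                )
            try:
                coords[k] = [float(t) for t in toks[1:4]]
            except ValueError:
                raise XYZParseError(f"frame {nframe}, line {lno + 1}: non-numeric coordinate")
            els.append(toks[0])
        if frames and natoms != frames[0].shape[0]:
            raise XYZParseError(
                f"frame {nframe}: atom count {natoms} differs from frame 1 "
                f"({frames[0].shape[0]})"
            )
        if not frames:
            elements = els
        frames.append(coords)
        ln += 2 + natoms
    if not frames:
        raise XYZParseError(f"{path}: no frames found")
    if topology is None:
        topology = Topology(
            labels=list(elements),
            elements=list(elements),
            masses=np.ones(len(elements)),
        )
    return Trajectory(topology, np.stack(frames), dt=dt, box=box)


def write_xyz(path: str | Path, traj: Trajectory, precision: int = 6) -> None:
    """Write a Trajectory as multi-frame XYZ (box on the comment line if set)."""
    path = Path(path)
    els = traj.topology.elements
    with path.open("w") as fh:
        for i in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n")
            if traj.box is not None:
                a, b, c = traj.box
                fh.write(
                    f'Lattice="{a:.6f} 0.0 0.0 0.0 {b:.6f} 0.0 0.0 0.0 {c:.6f}" '
                    f"time={traj.times[i]:.4f}\n"
                )
            else:
                fh.write(f"time={traj.times[i]:.4f}\n")
            for el, (x, y, z) in zip(els, traj.positions[i]):
                fh.write(f"{el} {x:.{precision}f} {y:.{precision}f} {z:.{precision}f}\n")


def minimum_image(delta: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Wrap displacement vector(s) into the primary cell, per component in
    [-edge/2, edge/2).  With no box the input is returned with a warning."""
    delta = np.asarray(delta, dtype=float)
    if box is None:
        warnings.warn("minimum_image called without a box; returning input unchanged")
        return delta
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise ValueError("box edges must be positive")
    return delta - box * np.floor(delta / box + 0.5)


def select_group(topology: Topology, name: str) -> tuple[int, ...]:
    """Return the atom-index tuple registered under ``name``."""
    try:
        return topology.groups[name]
    except KeyError:
        avail = ", ".join(sorted(topology.groups)) or "<none>"
        raise KeyError(f"unknown group {name!r}; available groups: {avail}") from None


def load_topology(path: str | Path) -> Topology:
    """Load a topology from a YAML config.

    Expected layout::

        atoms:
          - {label: C2, element: C, mass: 12.011}
          - ...
        bonds: [[0, 1], [1, 2]]
        groups:
          "C2=O2": [1, 2]
          water: [6, 7, 8]
        deuterate: [4]        # optional mass-override indices
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    atoms = cfg["atoms"]
    top = Topology(
        labels=[a["label"] for a in atoms],
        elements=[a["element"] for a in atoms],
        masses=np.array([float(a["mass"]) for a in atoms]),
        bonds={tuple(b) for b in cfg.get("bonds", [])},
        groups={k: tuple(v) for k, v in cfg.get("groups", {}).items()},
    )
    if cfg.get("deuterate"):
        top.set_deuterium_masses(cfg["deuterate"])
    return top
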