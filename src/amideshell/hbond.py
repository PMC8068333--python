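"""Geometric hydrogen-bond analysis.

A hydrogen bond is counted when the hydrogen-acceptor distance is at most
``r_max`` (default 2.5 A) and the donor-hydrogen-acceptor arrangement
deviates from linearity by at most ``ang_max`` (default 45 deg).  Both
cutoffs are inclusive.  Angles are reported as deviation from linearity
(0 deg = perfectly linear), not as the D-H-A angle itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from amideshell.trajectory_io import Frame, Topology, Trajectory, minimum_image, select_group

__all__ = [
    "HBondCriteria",
    "HBondSeries",
    "DistAngleHistogram",
    "WaterBridge",
    "WaterRanking",
    "is_hbonded",
    "hbond_count_series",
    "hbond_state_distribution",
    "dist_angle_histogram",
    "running_integral",
    "rank_waters",
    "find_water_bridges",
    "water_molecules",
    "group_acceptors",
    "group_donors",
]


@dataclass(frozen=True)
class HBondCriteria:
    r_max: float = 2.5
    ang_max: float = 45.0

    def __post_init__(self) -> None:
        if self.r_max <= 0:
            raise ValueError("r_max must be positive")
        if not (0 < self.ang_max <= 180):
            raise ValueError("ang_max must lie in (0, 180]")


def water_molecules(topology: Topology, water_group: str = "water") -> np.ndarray:
    """(n_waters, 3) index array of O, H, H per molecule from the water group."""
    idx = select_group(topology, water_group)
    if len(idx) % 3 != 0:
        raise ValueError("water group size must be divisible by 3 (O, H, H per molecule)")
    mols = np.asarray(idx, dtype=int).reshape(-1, 3)
    for o, h1, h2 in mols:
        els = (topology.elements[o], topology.elements[h1], topology.elements[h2])
        if els != ("O", "H", "H"):
            raise ValueError(f"water molecule {o},{h1},{h2} is not O,H,H (got {els})")
    return mols


def group_acceptors(topology: Topology, name: str) -> list[int]:
    """Oxygen (and hydrogen-free nitrogen) atoms of a polar group."""
    out = []
    for i in select_group(topology, name):
        el = topology.elements[i]
        if el == "O":
            out.append(i)
        elif el == "N" and not any(
            topology.elements[j] == "H" for j in topology.bonded_to(i)
        ):
            out.append(i)
    return out


def group_donors(topology: Topology, name: str) -> list[tuple[int, int]]:
    """(donor, hydrogen) pairs of a polar group, from N-H / O-H bonds."""
    members = set(select_group(topology, name))
    pairs = []
    for i in sorted(members):
        if topology.elements[i] in ("N", "O"):
            for j in topology.bonded_to(i):
                if j in members and topology.elements[j] == "H":
                    pairs.append((i, j))
    return pairs


def _deviation_deg(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """180 deg minus the angle between u = D - H and v = A - H."""
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    cosang = np.einsum("...i,...i->...", u, v) / np.where(nu * nv == 0, np.nan, nu * nv)
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return 180.0 - ang


def is_hbonded(
    donor: np.ndarray,
    hydrogen: np.ndarray,
    acceptor: np.ndarray,
    criteria: HBondCriteria | None = None,
    box: np.ndarray | None = None,
) -> bool:
    """Geometric test for one D-H...A triple (boundary inclusive)."""
    c = criteria or HBondCriteria()
    donor = np.asarray(donor, dtype=float)
    hydrogen = np.asarray(hydrogen, dtype=float)
    acceptor = np.asarray(acceptor, dtype=float)
    ha = acceptor - hydrogen
    if box is not None:
        ha = minimum_image(ha, box)
    r = float(np.linalg.norm(ha))
    if r == 0.0:
        raise ValueError("hydrogen and acceptor coincide; angle undefined")
    dh = donor - hydrogen
    if box is not None:
        dh = minimum_image(dh, box)
    dev = float(_deviation_deg(dh, ha))
    return r <= c.r_max and dev <= c.ang_max


@dataclass
class HBondSeries:
    """Per-frame hydrogen-bond counts and water identities for one group."""

    counts: np.ndarray
    identities: list[frozenset[int]]
    dt: float
    group: str

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if len(self.identities) != len(self.counts):
            raise ValueError("identities and counts must have equal length")

    @property
    def times(self) -> np.ndarray:
        return self.dt * np.arange(len(self.counts))

    def window_stats(self, start_fs: float | None = None, end_fs: float | None = None):
        """(mean, sd) of the count over [start_fs, end_fs)."""
        t = self.times
        m = np.ones(len(t), dtype=bool)
        if start_fs is not None:
            m &= t >= start_fs - 1e-9
        if end_fs is not None:
            m &= t < end_fs - 1e-9
        if not m.any():
            raise ValueError("empty window")
        c = self.counts[m]
        return float(c.mean()), float(c.std())


def _water_group_bond_mask(
    positions: np.ndarray,
    box: np.ndarray | None,
    waters: np.ndarray,
    acceptors: list[int],
    donors: list[tuple[int, int]],
    criteria: HBondCriteria,
) -> np.ndarray:
    """(n_frames, n_waters) boolean: water i H-bonded to the group at frame f.

    Both directions are tested: each water hydrogen against each group
    acceptor, and each group donor hydrogen against each water oxygen.
    """
    squeeze = positions.ndim == 2
    if squeeze:
        positions = positions[None]
    F = positions.shape[0]
    nw = len(waters)
    bonded = np.zeros((F, nw), dtype=bool)
    if nw == 0:
        return bonded[0] if squeeze else bonded
    o_w = positions[:, waters[:, 0]]          # (F, nw, 3)
    h_w = positions[:, waters[:, 1:3]]        # (F, nw, 2, 3)
    for a in acceptors:
        apos = positions[:, a][:, None, None, :]
        ha = apos - h_w
        if box is not None:
            ha = minimum_image(ha, box)
        r = np.linalg.norm(ha, axis=-1)       # (F, nw, 2)
        dh = o_w[:, :, None, :] - h_w
        if box is not None:
            dh = minimum_image(dh, box)
        dev = _deviation_deg(dh, ha)
        bonded |= ((r <= criteria.r_max) & (dev <= criteria.ang_max)).any(axis=2)
    for d, h in donors:
        hpos = positions[:, h][:, None, :]
        ha = o_w - hpos
        if box is not None:
            ha = minimum_image(ha, box)
        r = np.linalg.norm(ha, axis=-1)       # (F, nw)
        dh = (positions[:, d] - positions[:, h])[:, None, :]
        if box is not None:
            dh = minimum_image(dh, box)
        dev = _deviation_deg(np.broadcast_to(dh, ha.shape), ha)
        bonded |= (r <= criteria.r_max) & (dev <= criteria.ang_max)
    return bonded[0] if squeeze else bonded


def hbond_count_series(
    traj: Trajectory,
    group: str,
    criteria: HBondCriteria | None = None,
    water_group: str = "water",
) -> HBondSeries:
    """Per-frame number (and identities) of waters H-bonded to ``group``."""
    c = criteria or HBondCriteria()
    top = traj.topology
    waters = water_molecules(top, water_group)
    acceptors = group_acceptors(top, group)
    donors = group_donors(top, group)
    if not acceptors and not donors:
        raise ValueError(f"group {group!r} has no acceptor or donor atoms")
    bonded = _water_group_bond_mask(traj.positions, traj.box, waters, acceptors, donors, c)
    counts = bonded.sum(axis=1)
    oxy = waters[:, 0]
    identities = [frozenset(oxy[row]) for row in bonded]
    return HBondSeries(counts=counts, identities=identities, dt=traj.dt, group=group)


def hbond_state_distribution(series: HBondSeries) -> dict[int, float]:
    """Probability of each hydrogen-bond count; probabilities sum to 1."""
    if len(series.counts) == 0:
        raise ValueError("empty series")
    vals, n = np.unique(series.counts, return_counts=True)
    total = n.sum()
    return {int(v): float(k) / total for v, k in zip(vals, n)}


@dataclass
class DistAngleHistogram:
    """2D density over (closest-H...acceptor distance, D-H...A deviation).

    The grid is normalized per frame and per bin area, so
    grid * dr * dtheta summed over all bins is the mean number of waters
    per frame inside the histogram ranges.
    """

    r_edges: np.ndarray
    theta_edges: np.ndarray
    grid: np.ndarray
    n_frames: int
    criteria: HBondCriteria = field(default_factory=HBondCriteria)

    @property
    def dr(self) -> float:
        return float(self.r_edges[1] - self.r_edges[0])

    @property
    def dtheta(self) -> float:
        return float(self.theta_edges[1] - self.theta_edges[0])

    @property
    def g_r(self) -> np.ndarray:
        """Distance marginal: row sums times the angular bin width."""
        return self.grid.sum(axis=1) * self.dtheta

    @property
    def g_theta(self) -> np.ndarray:
        """Angle marginal: column sums times the radial bin width."""
        return self.grid.sum(axis=0) * self.dr

    @property
    def r_centers(self) -> np.ndarray:
        return 0.5 * (self.r_edges[:-1] + self.r_edges[1:])

    @property
    def theta_centers(self) -> np.ndarray:
        return 0.5 * (self.theta_edges[:-1] + self.theta_edges[1:])


def _water_distance_angle(
    positions: np.ndarray,
    box: np.ndarray | None,
    waters: np.ndarray,
    acceptors: list[int],
) -> tuple[np.ndarray, np.ndarray]:
    """Closest-hydrogen distance and deviation angle per (frame, water).

    For each water the hydrogen closest to the nearest acceptor defines
    both the distance and the angle.
    """
    squeeze = positions.ndim == 2
    if squeeze:
        positions = positions[None]
    o_w = positions[:, waters[:, 0]]
    h_w = positions[:, waters[:, 1:3]]
    r_best = np.full(o_w.shape[:2], np.inf)
    th_best = np.full(o_w.shape[:2], np.nan)
    for a in acceptors:
        apos = positions[:, a][:, None, None, :]
        ha = apos - h_w
        if box is not None:
            ha = minimum_image(ha, box)
        r = np.linalg.norm(ha, axis=-1)       # (F, nw, 2)
        dh = o_w[:, :, None, :] - h_w
        if box is not None:
            dh = minimum_image(dh, box)
        dev = _deviation_deg(dh, ha)
        pick = np.argmin(r, axis=2)
        r_a = np.take_along_axis(r, pick[:, :, None], axis=2)[:, :, 0]
        th_a = np.take_along_axis(dev, pick[:, :, None], axis=2)[:, :, 0]
        upd = r_a < r_best
        r_best[upd] = r_a[upd]
        th_best[upd] = th_a[upd]
    if squeeze:
        return r_best[0], th_best[0]
    return r_best, th_best


def dist_angle_histogram(
    traj: Trajectory,
    group: str,
    r_range: tuple[float, float] = (0.0, 5.0),
    theta_range: tuple[float, float] = (0.0, 180.0),
    bin_widths: tuple[float, float] = (0.05, 1.0),
    criteria: HBondCriteria | None = None,
    water_group: str = "water",
) -> DistAngleHistogram:
    """Combined distance-angle density of waters around a group's acceptor."""
    c = criteria or HBondCriteria()
    top = traj.topology
    waters = water_molecules(top, water_group)
    acceptors = group_acceptors(top, group)
    if not acceptors:
        raise ValueError(f"group {group!r} has no acceptor atoms")
    dr, dth = bin_widths
    if dr <= 0 or dth <= 0:
        raise ValueError("bin widths must be positive")
    r_edges = np.arange(r_range[0], r_range[1] + dr / 2, dr)
    th_edges = np.arange(theta_range[0], theta_range[1] + dth / 2, dth)
    nf = traj.n_frames
    if len(waters) == 0:
        grid = np.zeros((len(r_edges) - 1, len(th_edges) - 1))
        return DistAngleHistogram(r_edges, th_edges, grid, nf, c)
    r, th = _water_distance_angle(traj.positions, traj.box, waters, acceptors)
    H, _, _ = np.histogram2d(r.ravel(), th.ravel(), bins=[r_edges, th_edges])
    grid = H / (nf * dr * dth)
    return DistAngleHistogram(r_edges, th_edges, grid, nf, c)


def running_integral(hist: DistAngleHistogram, r: float, restrict: str = "all") -> float:
    """Cumulative mean number of waters per frame with distance <= r.

    ``restrict='hbond'`` additionally requires the angle criterion of the
    histogram's stored criteria.  Non-decreasing in r by construction.
    """
    if not (hist.r_edges[0] <= r <= hist.r_edges[-1] + 1e-9):
        raise ValueError("r outside histogram range")
    if restrict not in ("all", "hbond"):
        raise ValueError("restrict must be 'all' or 'hbond'")
    rmask = hist.r_centers <= r
    grid = hist.grid
    if restrict == "hbond":
        tmask = hist.theta_centers <= hist.criteria.ang_max
        grid = grid[:, tmask]
    return float(grid[rmask].sum() * hist.dr * hist.dtheta)


@dataclass(frozen=True)
class RankedWater:
    oxygen: int        # water O atom index
    r: float           # closest water H to acceptor distance (A)
    theta: float       # deviation from linearity for that H (deg)
    oo_distance: float # water O to acceptor O distance used for ranking (A)


@dataclass
class WaterRanking:
    entries: list[RankedWater]
    short: bool = False

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, i: int) -> RankedWater:
        return self.entries[i]


def rank_waters(frame: Frame, group: str, n: int = 4, water_group: str = "water") -> WaterRanking:
    """Rank waters by water-O to acceptor-O distance, ascending.

    Ranks are recomputed per frame, so the same rank label (W1..Wn) can map
    to different water identities over time.  Ties break on lower atom
    index.  If fewer than n waters exist, all are returned with
    ``short=True``.
    """
    if frame.topology is None:
        raise ValueError("frame carries no topology")
    top = frame.topology
    waters = water_molecules(top, water_group)
    acceptors = group_acceptors(top, group)
    if not acceptors:
        raise ValueError(f"group {group!r} has no acceptor atoms")
    pos = frame.positions
    d_oo = np.full(len(waters), np.inf)
    for a in acceptors:
        delta = pos[waters[:, 0]] - pos[a]
        if frame.box is not None:
            delta = minimum_image(delta, frame.box)
        d_oo = np.minimum(d_oo, np.linalg.norm(delta, axis=-1))
    order = np.lexsort((waters[:, 0], d_oo))
    r, th = _water_distance_angle(pos, frame.box, waters, acceptors)
    entries = [
        RankedWater(oxygen=int(waters[i, 0]), r=float(r[i]), theta=float(th[i]),
                    oo_distance=float(d_oo[i]))
        for i in order[:n]
    ]
    return WaterRanking(entries=entries, short=len(waters) < n)


@dataclass(frozen=True)
class WaterBridge:
    """Chain of H-bonded waters connecting two polar groups; ``order`` is
    the number of intermediate waters."""

    endpoints: tuple[str, str]
    path: tuple[int, ...]  # water O atom indices, ordered from endpoint A to B

    @property
    def order(self) -> int:
        return len(self.path)


def _water_water_edges(
    pos: np.ndarray, box: np.ndarray | None, waters: np.ndarray, criteria: HBondCriteria
) -> list[tuple[int, int]]:
    edges = []
    nw = len(waters)
    for i in range(nw):
        for j in range(i + 1, nw):
            bonded = False
            for don, acc in ((i, j), (j, i)):
                o_d = pos[waters[don, 0]]
                o_a = pos[waters[acc, 0]]
                for h in waters[don, 1:3]:
                    try:
                        if is_hbonded(o_d, pos[h], o_a, criteria, box):
                            bonded = True
                            break
                    except ValueError:
                        continue
                if bonded:
                    break
            if bonded:
                edges.append((i, j))
    return edges


def find_water_bridges(
    frame: Frame,
    group_a: str,
    group_b: str,
    criteria: HBondCriteria | None = None,
    max_order: int = 7,
    water_group: str = "water",
) -> list[WaterBridge]:
    """All minimal-length chains of H-bonded waters linking two groups.

    The hydrogen-bond graph over waters and the two groups is searched
    breadth-first; only paths at the minimal chain length are returned, and
    none longer than ``max_order`` intermediate waters.
    """
    if frame.topology is None:
        raise ValueError("frame carries no topology")
    c = criteria or HBondCriteria()
    top = frame.topology
    waters = water_molecules(top, water_group)
    pos = frame.positions
    g = nx.Graph()
    g.add_nodes_from(["__A__", "__B__"])
    g.add_nodes_from(range(len(waters)))
    for node, name in (("__A__", group_a), ("__B__", group_b)):
        mask = _water_group_bond_mask(
            pos, frame.box, waters, group_acceptors(top, name), group_donors(top, name), c
        )
        for w in np.nonzero(mask)[0]:
            g.add_edge(node, int(w))
    g.add_edges_from(_water_water_edges(pos, frame.box, waters, c))
    if not nx.has_path(g, "__A__", "__B__"):
        return []
    length = nx.shortest_path_length(g, "__A__", "__B__")
    order = length - 1
    if order < 1 or order > max_order:
        return []
    bridges = []
    for path in nx.all_shortest_paths(g, "__A__", "__B__"):
        chain = tuple(int(waters[w, 0]) for w in path[1:-1])
        bridges.append(WaterBridge(endpoints=(group_a, group_b), path=chain))
    return bridges
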