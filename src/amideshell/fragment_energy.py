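"""Capped amide fragments, supermolecular interaction energies and
interaction-zone clustering.

The energy backend is a contract: ``evaluate(geometry) -> kcal/mol``.  The
built-in toy backend (fixed point charges + Lennard-Jones) reproduces the
qualitative physics — sign, distance/angle dependence, zone separation —
not quantum-chemical magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
from sklearn.cluster import KMeans

from amideshell.trajectory_io import Frame, Topology, minimum_image

__all__ = [
    "FragmentGeometry",
    "InteractionRecord",
    "ZoneModel",
    "EnergyBackend",
    "ToyEnergyBackend",
    "extract_capped_fragment",
    "water_geometry",
    "attach_water",
    "interaction_energy",
    "toy_energy_backend",
    "kmeans_zones",
    "zone_occupancy",
    "correlate_energy_frequency",
]

COULOMB_KCAL = 332.0637  # kcal*A/(mol*e^2)

CAP_CH = 1.09  # A, hydrogen cap replacing a cut C-C bond
CAP_NH = 1.01  # A, hydrogen cap replacing a cut N-C bond


@dataclass
class FragmentGeometry:
    """A small molecular geometry with per-atom roles for the toy backend.

    Roles: C, O, N, HN (amide H), HCAP_C / HCAP_N (caps), OW / HW (water).
    """

    elements: list[str]
    roles: list[str]
    positions: np.ndarray
    source_frame: int | None = None
    cut_bonds: list[tuple[int, int]] = field(default_factory=list)
    overlap: bool = False

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.elements) != len(self.roles) or len(self.elements) != len(self.positions):
            raise ValueError("elements, roles and positions must have equal length")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)


@dataclass(frozen=True)
class InteractionRecord:
    """One (frame, ranked water) interaction sample."""

    frame: int
    rank: int               # 1-based: W1 is the closest water
    water_id: int           # persistent identity (water O atom index)
    r: float                # closest water H to carbonyl O distance (A)
    theta: float            # deviation from linearity (deg)
    e_int: float            # kcal/mol
    nd_distance: float      # closest water H to the fragment N-H distance (A)

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("r must be positive")
        if not np.isfinite(self.e_int):
            raise ValueError("e_int must be finite")


class EnergyBackend(Protocol):
    """Contract for supermolecular energy engines."""

    name: str
    deterministic: bool

    def evaluate(self, geometry: FragmentGeometry) -> float: ...


# Frozen toy parameters: TIP3P-like water, amide-like fragment charges
# (net neutral), Lennard-Jones on heavy atoms only.
TOY_CHARGES = {
    "C": 0.51,
    "O": -0.51,
    "N": -0.47,
    "HN": 0.31,
    "HCAP_C": 0.08,
    "HCAP_N": 0.08,
    "OW": -0.834,
    "HW": 0.417,
}
TOY_LJ = {  # (sigma A, epsilon kcal/mol)
    "C": (3.40, 0.086),
    "O": (2.96, 0.210),
    "N": (3.25, 0.170),
    "HN": (0.40, 0.046),
    "HCAP_C": (0.40, 0.046),
    "HCAP_N": (0.40, 0.046),
    "OW": (3.1507, 0.1521),
    "HW": (0.40, 0.046),
}


class ToyEnergyBackend:
    """Pairwise fixed-point-charge Coulomb + Lennard-Jones energy.

    Deterministic, rotation/translation invariant.  Lorentz-Berthelot
    combining rules; parameters are frozen package constants."""

    name = "toy-coulomb-lj"
    deterministic = True

    def evaluate(self, geometry: FragmentGeometry) -> float:
        q = np.array([TOY_CHARGES[r] for r in geometry.roles])
        sig = np.array([TOY_LJ[r][0] for r in geometry.roles])
        eps = np.array([TOY_LJ[r][1] for r in geometry.roles])
        pos = geometry.positions
        n = len(q)
        e = 0.0
        for i in range(n):
            d = pos[i + 1 :] - pos[i]
            r = np.linalg.norm(d, axis=1)
            e += COULOMB_KCAL * q[i] * np.sum(q[i + 1 :] / r)
            s = 0.5 * (sig[i] + sig[i + 1 :])
            ep = np.sqrt(eps[i] * eps[i + 1 :])
            sr6 = (s / r) ** 6
            e += np.sum(4.0 * ep * (sr6**2 - sr6))
        return float(e)


def toy_energy_backend() -> ToyEnergyBackend:
    """The built-in deterministic desk-scale energy backend."""
    return ToyEnergyBackend()


def extract_capped_fragment(
    frame: Frame, topology: Topology, peptide_bond: tuple[int, int], frame_index: int = 0
) -> FragmentGeometry:
    """Cut out the amide unit around a C-N peptide bond and cap it.

    The flanking C(alpha)-C and N-C(alpha) bonds are cut and each replaced
    by a hydrogen placed along the former bond vector (1.09 A at C, 1.01 A
    at N), giving a 6-atom H-capped CONH fragment."""
    c_idx, n_idx = peptide_bond
    if tuple(sorted((c_idx, n_idx))) not in topology.bonds:
        raise ValueError(f"no peptide bond between atoms {c_idx} and {n_idx}")
    if topology.elements[c_idx] != "C" or topology.elements[n_idx] != "N":
        raise ValueError(f"bond ({c_idx}, {n_idx}) is not a C-N bond")
    pos = frame.positions

    def _neighbor(center: int, element: str, exclude: set[int]) -> int:
        cands = [j for j in topology.bonded_to(center)
                 if topology.elements[j] == element and j not in exclude]
        if not cands:
            raise ValueError(
                f"atom {center} ({topology.labels[center]}) has no bonded "
                f"{element} outside {sorted(exclude)}"
            )
        return cands[0]

    o_idx = _neighbor(c_idx, "O", {n_idx})
    h_idx = _neighbor(n_idx, "H", {c_idx})
    ca_c = _neighbor(c_idx, "C", {n_idx, o_idx})
    ca_n = _neighbor(n_idx, "C", {c_idx, h_idx})

    def _cap(center: int, toward: int, length: float) -> np.ndarray:
        v = pos[toward] - pos[center]
        if frame.box is not None:
            v = minimum_image(v, frame.box)
        return pos[center] + length * v / np.linalg.norm(v)

    return FragmentGeometry(
        elements=["C", "O", "N", "H", "H", "H"],
        roles=["C", "O", "N", "HN", "HCAP_C", "HCAP_N"],
        positions=np.vstack(
            [pos[c_idx], pos[o_idx], pos[n_idx], pos[h_idx],
             _cap(c_idx, ca_c, CAP_CH), _cap(n_idx, ca_n, CAP_NH)]
        ),
        source_frame=frame_index,
        cut_bonds=[(ca_c, c_idx), (ca_n, n_idx)],
    )


def water_geometry(
    frame: Frame, water_oxygen: int, reference: np.ndarray | None = None
) -> FragmentGeometry:
    """Extract one water molecule; with a periodic box and a reference
    point, the molecule is shifted to its minimum image relative to it."""
    top = frame.topology
    if top is None:
        raise ValueError("frame carries no topology")
    hyd = [j for j in top.bonded_to(water_oxygen) if top.elements[j] == "H"]
    if len(hyd) != 2:
        raise ValueError(f"atom {water_oxygen} is not a water oxygen with two hydrogens")
    idx = [water_oxygen] + hyd
    pos = frame.positions[idx].copy()
    if frame.box is not None and reference is not None:
        shift = minimum_image(pos[0] - reference, frame.box) - (pos[0] - reference)
        pos += shift
    return FragmentGeometry(elements=["O", "H", "H"], roles=["OW", "HW", "HW"], positions=pos)


def attach_water(fragment: FragmentGeometry, water: FragmentGeometry,
                 min_separation: float = 0.8) -> FragmentGeometry:
    """Combine fragment and water into one geometry.

    Any fragment-water atom pair closer than ``min_separation`` sets the
    ``overlap`` flag (kept, not silently accepted)."""
    d = np.linalg.norm(
        fragment.positions[:, None, :] - water.positions[None, :, :], axis=-1
    )
    return FragmentGeometry(
        elements=fragment.elements + water.elements,
        roles=fragment.roles + water.roles,
        positions=np.vstack([fragment.positions, water.positions]),
        source_frame=fragment.source_frame,
        cut_bonds=list(fragment.cut_bonds),
        overlap=bool((d < min_separation).any()),
    )


def interaction_energy(
    fragment: FragmentGeometry, water: FragmentGeometry, backend: EnergyBackend | None = None
) -> float:
    """Supermolecular interaction energy E(AB) - E(A) - E(B), kcal/mol."""
    be = backend or toy_energy_backend()
    combined = attach_water(fragment, water)
    try:
        return be.evaluate(combined) - be.evaluate(fragment) - be.evaluate(water)
    except Exception as exc:  # propagate with geometry context
        raise RuntimeError(
            f"backend {be.name!r} failed on geometry with atoms "
            f"{combined.elements} at\n{combined.positions}"
        ) from exc


_ZONE_NAMES = {
    2: ["strong", "weak"],
    3: ["strong", "moderate", "weak"],
    4: ["very_strong", "strong", "moderate", "weak"],
}


@dataclass
class ZoneModel:
    """k-means interaction zones ordered by ascending mean energy
    (most negative = strongest)."""

    k: int
    centers: np.ndarray           # mean energy per zone, ascending
    names: list[str]
    record_labels: np.ndarray     # zone index per fitted record
    features: str = "energy"

    def label_names(self) -> list[str]:
        return [self.names[i] for i in self.record_labels]


def kmeans_zones(
    records: Sequence[InteractionRecord],
    k: int = 3,
    seed: int = 0,
    restarts: int = 50,
    features: str = "energy",
) -> ZoneModel:
    """Cluster interaction records into k zones.

    Default clustering is 1D on the interaction energy; ``features='joint'``
    clusters standardized (E, r, theta).  Labels are ordered by ascending
    mean energy within cluster."""
    if len(records) < k:
        raise ValueError(f"need at least k={k} records, got {len(records)}")
    e = np.array([rec.e_int for rec in records])
    if features == "energy":
        X = e[:, None]
    elif features == "joint":
        X = np.column_stack([e, [r.r for r in records], [r.theta for r in records]])
        sd = X.std(axis=0)
        if np.any(sd == 0):
            raise ValueError("degenerate records: zero variance in a feature")
        X = (X - X.mean(axis=0)) / sd
    else:
        raise ValueError("features must be 'energy' or 'joint'")
    if np.allclose(X.std(axis=0), 0):
        raise ValueError("degenerate records: all identical")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    raw = km.fit_predict(X)
    mean_e = np.array([e[raw == i].mean() for i in range(k)])
    order = np.argsort(mean_e)
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    names = _ZONE_NAMES.get(k, [f"zone_{i}" for i in range(k)])
    return ZoneModel(
        k=k,
        centers=mean_e[order],
        names=names,
        record_labels=remap[raw],
        features=features,
    )


def zone_occupancy(
    records: Sequence[InteractionRecord], zones: ZoneModel
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-frame counts of records in the strongest and moderate zones.

    Returns (frames, strong_counts, moderate_counts); for k=2 the second
    zone counts are reported as 'moderate'."""
    names = zones.label_names()
    frames = np.array(sorted({rec.frame for rec in records}))
    pos = {f: i for i, f in enumerate(frames)}
    strong = np.zeros(len(frames), dtype=int)
    moderate = np.zeros(len(frames), dtype=int)
    strong_names = {"strong", "very_strong"}
    for rec, name in zip(records, names):
        if name in strong_names:
            strong[pos[rec.frame]] += 1
        elif name == "moderate" or (zones.k == 2 and name == "weak"):
            moderate[pos[rec.frame]] += 1
    return frames, strong, moderate


def correlate_energy_frequency(energy: np.ndarray, freq) -> float:
    """Pearson correlation over frames where both series are valid."""
    e = np.asarray(energy, dtype=float)
    if hasattr(freq, "frequency"):
        f = np.asarray(freq.frequency, dtype=float)
        valid = np.asarray(freq.valid, dtype=bool)
    else:
        f = np.asarray(freq, dtype=float)
        valid = np.ones(len(f), dtype=bool)
    if len(e) != len(f):
        raise ValueError("series must have equal length")
    m = valid & np.isfinite(e) & np.isfinite(f)
    if m.sum() < 10:
        raise ValueError("fewer than 10 valid overlapping frames")
    e, f = e[m], f[m]
    if e.std() == 0 or f.std() == 0:
        raise ValueError("zero-variance input")
    return float(np.corrcoef(e, f)[0, 1])
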