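"""Backbone torsions, histogram free-energy surfaces and state assignment."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KB_KCAL",
    "TorsionSeries",
    "FreeEnergySurface",
    "dihedral",
    "free_energy_2d",
    "assign_backbone_state",
    "state_probabilities",
    "STATE_CENTERS",
]

KB_KCAL = 0.0019872  # kcal/(mol*K)

# (phi, psi) centers of the backbone states; windows are +-width rectangles
STATE_CENTERS = {
    "alpha": (-57.0, -47.0),
    "beta": (-130.0, 140.0),
    "L": (80.0, 70.0),
}


def _wrap(angle: np.ndarray | float) -> np.ndarray | float:
    """Wrap degrees into (-180, 180]."""
    a = ((np.asarray(angle, dtype=float) + 180.0) % 360.0) - 180.0
    a = np.where(a == -180.0, 180.0, a)
    return float(a) if np.isscalar(angle) or np.ndim(angle) == 0 else a


@dataclass
class TorsionSeries:
    """Named per-frame torsion angles in degrees, wrapped to (-180, 180]."""

    name: str
    angles: np.ndarray

    def __post_init__(self) -> None:
        self.angles = np.asarray(_wrap(self.angles), dtype=float)


def dihedral(p1, p2, p3, p4) -> float:
    """Signed IUPAC torsion angle p1-p2-p3-p4 in degrees, in (-180, 180]."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-12 * nb2 or np.linalg.norm(n2) < 1e-12 * nb2:
        raise ValueError("three consecutive points are collinear; torsion undefined")
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2) / nb2
    ang = np.degrees(np.arctan2(y, x))
    return float(_wrap(ang))


@dataclass
class FreeEnergySurface:
    """F = -kB T ln(H / H_max) over a 2D torsion histogram.

    ``F`` is a masked array (kcal/mol); empty bins are masked (undefined),
    the most populated bin has F = 0."""

    phi_edges: np.ndarray
    psi_edges: np.ndarray
    F: np.ma.MaskedArray
    temperature: float
    counts: np.ndarray = field(repr=False, default=None)


def free_energy_2d(
    phi: np.ndarray,
    psi: np.ndarray,
    bins: int | tuple[int, int] = 72,
    temperature: float = 300.0,
) -> FreeEnergySurface:
    """Free-energy surface from the 2D histogram of two torsion series."""
    phi = np.asarray(_wrap(phi), dtype=float)
    psi = np.asarray(_wrap(psi), dtype=float)
    if phi.size == 0 or phi.shape != psi.shape:
        raise ValueError("phi and psi must be equal-length, non-empty series")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if isinstance(bins, int):
        bins = (bins, bins)
    edges = (np.linspace(-180.0, 180.0, bins[0] + 1), np.linspace(-180.0, 180.0, bins[1] + 1))
    # samples at exactly +180 belong to the last bin already (inclusive edge)
    H, pe, se = np.histogram2d(phi, psi, bins=edges)
    hmax = H.max()
    with np.errstate(divide="ignore"):
        F = -KB_KCAL * temperature * np.log(np.where(H > 0, H / hmax, np.nan))
    return FreeEnergySurface(
        phi_edges=pe,
        psi_edges=se,
        F=np.ma.masked_invalid(F),
        temperature=temperature,
        counts=H,
    )


def assign_backbone_state(phi: float, psi: float, width: float = 30.0) -> str:
    """Label (phi, psi) as 'alpha', 'beta', 'L' or 'other'.

    States are rectangular +-``width`` degree windows around the canonical
    centers, with periodic distance in each angle."""
    for name, (pc, sc) in STATE_CENTERS.items():
        dphi = abs(_wrap(phi - pc))
        dpsi = abs(_wrap(psi - sc))
        if dphi <= width and dpsi <= width:
            return name
    return "other"


def assign_backbone_states(phi: np.ndarray, psi: np.ndarray, width: float = 30.0) -> np.ndarray:
    """Vectorized :func:`assign_backbone_state`."""
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    out = np.full(phi.shape, "other", dtype=object)
    for name, (pc, sc) in STATE_CENTERS.items():
        m = (np.abs(_wrap(phi - pc)) <= width) & (np.abs(_wrap(psi - sc)) <= width)
        out[m & (out == "other")] = name
    return out


def state_probabilities(
    labels_1: np.ndarray, labels_2: np.ndarray
) -> dict[tuple[str, str], float]:
    """Joint probability of (state, state) label pairs; sums to 1."""
    l1 = np.asarray(labels_1)
    l2 = np.asarray(labels_2)
    if l1.shape != l2.shape or l1.size == 0:
        raise ValueError("label series must be equal-length and non-empty")
    pairs, counts = np.unique(
        np.array([f"{a}|{b}" for a, b in zip(l1, l2)]), return_counts=True
    )
    total = counts.sum()
    out = {}
    for p, c in zip(pairs, counts):
        a, b = p.split("|")
        out[(a, b)] = float(c) / total
    return out
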