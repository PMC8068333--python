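"""Synthetic trajectories, signals and records with known ground truth.

Every generator is deterministic given its parameters and seed, and emits
its ground truth next to the data so downstream recovery tests need no
re-derivation.  The default acceptance seed used across the package is
``DEFAULT_SEED``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from amideshell.fragment_energy import InteractionRecord
from amideshell.spectra import C_CM_PER_FS
from amideshell.trajectory_io import Topology, Trajectory

__all__ = [
    "DEFAULT_SEED",
    "FrequencySchedule",
    "HydrationSchedule",
    "SyntheticRecords",
    "make_peptide_fixture",
    "gen_oscillator_trajectory",
    "gen_hydration_trajectory",
    "gen_correlated_series",
    "gen_interaction_records",
    "gen_torsion_series",
]

DEFAULT_SEED = 2148


@dataclass
class FrequencySchedule:
    """Piecewise-constant bond-stretch frequency schedule.

    ``segments``: list of (start_fs, end_fs, frequency_cm) covering a
    contiguous, non-overlapping span.  The oscillator phase resets at each
    segment boundary.
    """

    segments: list[tuple[float, float, float]]
    amplitude: float = 0.03
    noise_sd: float = 0.0
    r0: float = 1.23

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("schedule needs at least one segment")
        for t0, t1, nu in self.segments:
            if t1 <= t0:
                raise ValueError(f"segment ({t0}, {t1}) is empty")
            if nu <= 0:
                raise ValueError("frequencies must be positive")
        for (_, e0, _), (s1, _, _) in zip(self.segments, self.segments[1:]):
            if abs(e0 - s1) > 1e-9:
                raise ValueError("segments must be contiguous and non-overlapping")

    @property
    def total_fs(self) -> float:
        return self.segments[-1][1] - self.segments[0][0]

    def bond_length_series(self, dt: float, rng: np.random.Generator | None = None) -> np.ndarray:
        """Evaluate r0 + A cos(2 pi c nu t_local) + noise on the dt grid."""
        nmax = max(nu for _, _, nu in self.segments)
        period = 1.0 / (nmax * C_CM_PER_FS)
        if dt > period / 10:
            raise ValueError(
                f"dt={dt} fs undersamples {nmax} cm^-1; need dt <= {period / 10:.4f} fs"
            )
        t0 = self.segments[0][0]
        n = int(round(self.total_fs / dt))
        t = t0 + dt * np.arange(n)
        b = np.full(n, self.r0)
        for s0, s1, nu in self.segments:
            m = (t >= s0 - 1e-9) & (t < s1 - 1e-9)
            tloc = t[m] - s0
            b[m] += self.amplitude * np.cos(2 * np.pi * C_CM_PER_FS * nu * tloc)
        if self.noise_sd > 0:
            if rng is None:
                rng = np.random.default_rng(0)
            b += rng.normal(0.0, self.noise_sd, n)
        return b


@dataclass
class HydrationSchedule:
    """Per-segment target H-bond count and identity-exchange rate.

    ``segments``: list of (start_fs, end_fs, target_count, exchange_per_fs).
    Bound-water geometry is Gaussian in (r, theta) with uniform azimuth.
    """

    segments: list[tuple[float, float, float, float]]
    mean_r: float = 1.9
    mean_theta: float = 10.0
    jitter_r: float = 0.05
    jitter_theta: float = 3.0

    def __post_init__(self) -> None:
        for t0, t1, target, rate in self.segments:
            if t1 <= t0:
                raise ValueError(f"segment ({t0}, {t1}) is empty")
            if target < 0 or rate < 0:
                raise ValueError("target counts and exchange rates must be >= 0")
        if self.mean_r <= 0 or not (0 <= self.mean_theta <= 180):
            raise ValueError("invalid bound-water geometry")

    @property
    def max_bound(self) -> int:
        return int(max(np.ceil(t) for _, _, t, _ in self.segments))

    @property
    def total_fs(self) -> float:
        return self.segments[-1][1] - self.segments[0][0]


def make_peptide_fixture() -> tuple[Topology, np.ndarray]:
    """Minimal peptide-like fixture: one central amide unit plus a second
    carbonyl, with polar groups registered.  Returns (topology, positions)."""
    labels = ["CA1", "C2", "O2", "N2", "D2", "CA2", "C3", "O3"]
    elements = ["C", "C", "O", "N", "H", "C", "C", "O"]
    masses = np.array([12.011, 12.011, 15.999, 14.007, 2.0141, 12.011, 12.011, 15.999])
    positions = np.array(
        [
            [-0.76, -1.32, 0.00],   # CA1
            [0.00, 0.00, 0.00],     # C2
            [1.23, 0.00, 0.00],     # O2
            [-0.67, 1.15, 0.00],    # N2
            [-0.17, 2.02, 0.00],    # D2
            [-2.12, 1.20, 0.00],    # CA2
            [-2.80, 1.20, 1.33],    # C3
            [-2.80, 1.20, 2.56],    # O3
        ]
    )
    top = Topology(
        labels=labels,
        elements=elements,
        masses=masses,
        bonds={(0, 1), (1, 2), (1, 3), (3, 4), (3, 5), (5, 6), (6, 7)},
        groups={
            "C2=O2": (1, 2),
            "N2-D2": (3, 4),
            "C3=O3": (6, 7),
            "peptide": tuple(range(8)),
        },
    )
    return top, positions


def _perp(v: np.ndarray) -> np.ndarray:
    """A unit vector perpendicular to v."""
    a = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    p = np.cross(v, a)
    return p / np.linalg.norm(p)


def gen_oscillator_trajectory(
    schedule: FrequencySchedule, dt: float, seed: int = DEFAULT_SEED
) -> Trajectory:
    """Two-atom C=O oscillator following a piecewise-constant frequency
    schedule; the ground-truth schedule is stored as ``traj.ground_truth``."""
    rng = np.random.default_rng(seed)
    b = schedule.bond_length_series(dt, rng)
    n = len(b)
    pos = np.zeros((n, 2, 3))
    pos[:, 1, 0] = b
    top = Topology(
        labels=["C2", "O2"],
        elements=["C", "O"],
        masses=np.array([12.011, 15.999]),
        bonds={(0, 1)},
        groups={"C2=O2": (0, 1)},
    )
    traj = Trajectory(top, pos, dt=dt, t0=schedule.segments[0][0])
    traj.ground_truth = {"frequency_schedule": schedule}
    return traj


def _duty_cycle_counts(n: int, target: float, period: int = 400) -> np.ndarray:
    """Integer count series with mean equal to target (within rounding)."""
    lo = int(np.floor(target))
    frac = target - lo
    counts = np.full(n, lo, dtype=int)
    if frac > 0:
        hi_len = int(round(frac * period))
        phase = np.arange(n) % period
        counts[phase < hi_len] += 1
    return counts


def gen_hydration_trajectory(
    schedule: HydrationSchedule,
    dt: float,
    seed: int = DEFAULT_SEED,
    freq_schedule: FrequencySchedule | None = None,
    n_background: int = 4,
    peptide: tuple[Topology, np.ndarray] | None = None,
) -> Trajectory:
    """Peptide fixture plus waters scheduled to hit per-segment mean H-bond
    counts at the carbonyl acceptor.

    Bound waters sit at hydrogen-bond geometry around the O2 atom with
    persistent identities; exchanges swap which water occupies a binding
    site (at least one exchange per segment when the rate is positive).
    Background waters are parked 6-9 A away, outside the 4.5 A shell.
    Optionally the C2=O2 bond length oscillates per ``freq_schedule``.
    """
    rng = np.random.default_rng(seed)
    top_p, pos_p = peptide if peptide is not None else make_peptide_fixture()
    n_pep = top_p.n_atoms
    max_bound = schedule.max_bound
    n_wat = max_bound + n_background
    if n_wat == 0:
        raise ValueError("schedule implies zero waters")

    n = int(round(schedule.total_fs / dt))
    t0 = schedule.segments[0][0]
    t = t0 + dt * np.arange(n)

    # target bound count per frame (deterministic duty cycle per segment)
    counts = np.zeros(n, dtype=int)
    seg_of = np.zeros(n, dtype=int)
    for k, (s0, s1, target, _rate) in enumerate(schedule.segments):
        m = (t >= s0 - 1e-9) & (t < s1 - 1e-9)
        counts[m] = _duty_cycle_counts(int(m.sum()), target)
        seg_of[m] = k

    # binding-site occupancy: which water id occupies site j at frame i
    site_water = np.full((n, max_bound), -1, dtype=int)
    current = list(range(max_bound))
    free = list(range(max_bound, n_wat))
    exchanges_in_seg = np.zeros(len(schedule.segments), dtype=int)
    for i in range(n):
        rate = schedule.segments[seg_of[i]][3]
        if rate > 0 and free and rng.random() < rate * dt:
            site = int(rng.integers(max_bound))
            incoming = free.pop(int(rng.integers(len(free))))
            free.append(current[site])
            current[site] = incoming
            exchanges_in_seg[seg_of[i]] += 1
        site_water[i] = current
    # guarantee one exchange per positive-rate segment
    for k, (s0, s1, _tg, rate) in enumerate(schedule.segments):
        if rate > 0 and exchanges_in_seg[k] == 0 and free:
            mid = int(np.searchsorted(t, 0.5 * (s0 + s1)))
            incoming = free.pop()
            site_water[mid:, 0] = incoming
            free.append(int(site_water[mid - 1, 0]) if mid > 0 else 0)

    # geometry scaffold around the acceptor oxygen
    c_idx, o_idx = top_p.groups["C2=O2"]
    axis = pos_p[o_idx] - pos_p[c_idx]
    axis = axis / np.linalg.norm(axis)
    e1 = _perp(axis)
    e2 = np.cross(axis, e1)
    o2_ref = pos_p[o_idx]

    positions = np.empty((n, n_pep + 3 * n_wat, 3))
    positions[:, :n_pep] = pos_p

    if freq_schedule is not None:
        b = freq_schedule.bond_length_series(dt, rng)
        positions[:, o_idx] = pos_p[c_idx] + b[:, None] * axis

    # background parking spots: ring 6-9 A from O2, non-overlapping by construction
    park = np.empty((n_wat, 3))
    for w in range(n_wat):
        ang = 2 * np.pi * w / n_wat
        rad = 6.5 + 2.0 * (w % 3) / 3.0
        park[w] = o2_ref + rad * (
            np.cos(ang) * e1 + np.sin(ang) * e2 + 0.3 * axis
        )

    # per-frame bound-water geometry, vectorized over frames per site
    oh = 0.9572
    beta = np.radians(30.0)  # polar offset of the H...A direction from the C=O axis
    for site in range(max_bound):
        bound = counts > site
        nb = int(bound.sum())
        r = rng.normal(schedule.mean_r, schedule.jitter_r, nb).clip(0.8)
        thd = rng.normal(schedule.mean_theta, schedule.jitter_theta, nb).clip(0.0, 179.0)
        phi = 2 * np.pi * site / max(max_bound, 1) + rng.normal(0.0, 0.15, nb)
        # direction from acceptor to the bonded hydrogen
        v = (
            np.cos(beta) * axis[None, :]
            + np.sin(beta) * (np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2)
        )
        h1 = o2_ref + r[:, None] * v
        # donor direction: rotate the continuation of A->H by theta
        axis_rot = np.cos(phi)[:, None] * e2 - np.sin(phi)[:, None] * e1
        thr = np.radians(thd)[:, None]
        d_dir = np.cos(thr) * v + np.sin(thr) * np.cross(axis_rot, v)
        o_w = h1 + oh * d_dir
        # second hydrogen at ~104.5 deg from the first O-H bond
        b1 = h1 - o_w
        b1 /= np.linalg.norm(b1, axis=1, keepdims=True)
        perp = np.cross(b1, axis_rot)
        perp /= np.linalg.norm(perp, axis=1, keepdims=True)
        ang2 = np.radians(104.5)
        h2 = o_w + oh * (np.cos(ang2) * b1 + np.sin(ang2) * perp)

        wid_bound = site_water[bound, site]
        frames_bound = np.nonzero(bound)[0]
        for w in range(n_wat):
            sel = wid_bound == w
            if not sel.any():
                continue
            fr = frames_bound[sel]
            base = n_pep + 3 * w
            positions[fr, base] = o_w[sel]
            positions[fr, base + 1] = h1[sel]
            positions[fr, base + 2] = h2[sel]

    # park every water that is not bound at its spot
    bound_mask = np.zeros((n, n_wat), dtype=bool)
    for site in range(max_bound):
        bound = counts > site
        bound_mask[np.nonzero(bound)[0], site_water[bound, site]] = True
    for w in range(n_wat):
        fr = np.nonzero(~bound_mask[:, w])[0]
        base = n_pep + 3 * w
        positions[fr, base] = park[w]
        positions[fr, base + 1] = park[w] + np.array([oh, 0.0, 0.0])
        positions[fr, base + 2] = park[w] + oh * np.array(
            [np.cos(np.radians(104.5)), np.sin(np.radians(104.5)), 0.0]
        )

    labels = list(top_p.labels)
    elements = list(top_p.elements)
    masses = list(top_p.masses)
    for w in range(n_wat):
        labels += [f"OW{w}", f"HW{w}a", f"HW{w}b"]
        elements += ["O", "H", "H"]
        masses += [15.999, 2.0141, 2.0141]
    bonds = set(top_p.bonds)
    groups = {k: v for k, v in top_p.groups.items()}
    water_idx = tuple(range(n_pep, n_pep + 3 * n_wat))
    groups["water"] = water_idx
    for w in range(n_wat):
        base = n_pep + 3 * w
        bonds |= {(base, base + 1), (base, base + 2)}
    top = Topology(labels=labels, elements=elements, masses=np.array(masses),
                   bonds=bonds, groups=groups)
    traj = Trajectory(top, positions, dt=dt, t0=t0)
    traj.ground_truth = {
        "hydration_schedule": schedule,
        "frequency_schedule": freq_schedule,
        "bound_counts": counts,
        "site_water": site_water,
        "water_oxygen_indices": np.array([n_pep + 3 * w for w in range(n_wat)]),
    }
    return traj


def gen_correlated_series(
    n: int, target_r: float, seed: int = DEFAULT_SEED
) -> tuple[np.ndarray, np.ndarray]:
    """Two Gaussian series with population Pearson correlation ``target_r``."""
    if abs(target_r) > 1:
        raise ValueError("|target_r| must be <= 1")
    if n < 3:
        raise ValueError("need n >= 3")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    z = rng.standard_normal(n)
    y = target_r * x + np.sqrt(1.0 - target_r**2) * z
    return x, y


@dataclass
class SyntheticRecords:
    """Interaction records with planted zone labels."""

    records: list[InteractionRecord]
    labels: np.ndarray
    degenerate: bool = False
    zone_means: np.ndarray = field(default_factory=lambda: np.array([]))


def gen_interaction_records(
    zone_params: list[tuple[float, float, float, float, int]],
    seed: int = DEFAULT_SEED,
) -> SyntheticRecords:
    """Draw labeled interaction records from energy zones.

    ``zone_params``: per zone (mean_E kcal/mol, sd_E, mean_r A, mean_theta
    deg, count).  Zones whose means are closer than 3 pooled sd are flagged
    degenerate (clustering may not recover them)."""
    rng = np.random.default_rng(seed)
    means = np.array([z[0] for z in zone_params])
    sds = np.array([z[1] for z in zone_params])
    degenerate = False
    for i in range(len(zone_params)):
        for j in range(i + 1, len(zone_params)):
            pooled = np.sqrt(0.5 * (sds[i] ** 2 + sds[j] ** 2))
            if abs(means[i] - means[j]) <= 3 * pooled:
                degenerate = True
    records: list[InteractionRecord] = []
    labels: list[int] = []
    for zi, (me, sd, mr, mth, count) in enumerate(zone_params):
        for k in range(count):
            records.append(
                InteractionRecord(
                    frame=k,
                    rank=zi + 1,
                    water_id=zi,
                    r=float(max(rng.normal(mr, 0.1), 0.5)),
                    theta=float(np.clip(rng.normal(mth, 5.0), 0.0, 180.0)),
                    e_int=float(rng.normal(me, sd)),
                    nd_distance=float(max(rng.normal(4.5, 0.3), 1.0)),
                )
            )
            labels.append(zi)
    return SyntheticRecords(
        records=records, labels=np.array(labels), degenerate=degenerate, zone_means=means
    )


def gen_torsion_series(
    states: list[tuple[float, float, float, float]],
    n: int,
    transition_prob: float = 0.02,
    seed: int = DEFAULT_SEED,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Markov-switching wrapped-normal (phi, psi) samples.

    ``states``: list of (phi_deg, psi_deg, weight, concentration); weights
    must sum to 1.  At each step the state is resampled from the weights
    with probability ``transition_prob`` (stationary distribution equals
    the weights).  Infinite concentration gives zero-variance angles.
    Returns (phi, psi, state_index)."""
    weights = np.array([s[2] for s in states])
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("state weights must sum to 1")
    rng = np.random.default_rng(seed)
    state = np.empty(n, dtype=int)
    state[0] = rng.choice(len(states), p=weights)
    jumps = rng.random(n) < transition_prob
    draws = rng.choice(len(states), size=n, p=weights)
    for i in range(1, n):
        state[i] = draws[i] if jumps[i] else state[i - 1]
    phi = np.empty(n)
    psi = np.empty(n)
    for si, (p0, s0, _w, kappa) in enumerate(states):
        m = state == si
        k = int(m.sum())
        if k == 0:
            continue
        if np.isinf(kappa):
            phi[m] = p0
            psi[m] = s0
        else:
            phi[m] = np.degrees(rng.vonmises(np.radians(p0), kappa, k))
            psi[m] = np.degrees(rng.vonmises(np.radians(s0), kappa, k))
    wrap = lambda a: ((a + 180.0) % 360.0) - 180.0  # noqa: E731
    phi, psi = wrap(phi), wrap(psi)
    phi[phi == -180.0] = 180.0
    psi[psi == -180.0] = 180.0
    return phi, psi, state
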