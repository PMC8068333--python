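import numpy as np
import pytest

from amideshell import synthetic as syn
from amideshell.trajectory_io import Frame, Topology, Trajectory


@pytest.fixture(scope="session")
def peptide_fixture():
    return syn.make_peptide_fixture()


@pytest.fixture(scope="session")
def three_window_traj():
    """Combined oscillator + hydration scenario with three 2-ps windows."""
    fs = syn.FrequencySchedule(
        [(0.0, 2000.0, 1600.0), (2000.0, 4000.0, 1594.0), (4000.0, 6000.0, 1584.0)],
        amplitude=0.03,
        noise_sd=0.003,
    )
    hs = syn.HydrationSchedule(
        [(0.0, 2000.0, 1.0, 0.003), (2000.0, 4000.0, 1.5, 0.003), (4000.0, 6000.0, 2.0, 0.003)]
    )
    return syn.gen_hydration_trajectory(hs, dt=0.5, seed=syn.DEFAULT_SEED, freq_schedule=fs)


def _water_triplet(center, seed=0):
    """A water molecule (O,H,H positions) near `center`."""
    rng = np.random.default_rng(seed)
    o = np.asarray(center, dtype=float)
    h1 = o + np.array([0.9572, 0.0, 0.0])
    h2 = o + 0.9572 * np.array([np.cos(np.radians(104.5)), np.sin(np.radians(104.5)), 0.0])
    return np.vstack([o, h1, h2]) + rng.normal(0, 1e-3, (3, 3))


@pytest.fixture()
def water_chain_frame(peptide_fixture):
    """Frame with a hand-built 3-water chain linking C2=O2 to C3=O3.

    The C3=O3 group is moved 8.5 A from O2 so that a zig-zag chain with
    2.86 A O-O spacing spans the gap.  Each chain water donates one H to
    the previous member (deviation 0), the last water additionally donates
    to O3; second hydrogens point out of the chain plane.  Two far-away
    spectator waters are added.
    """
    top_p, pos_p = peptide_fixture
    pos_p = pos_p.copy()
    o2 = pos_p[2]
    pos_p[7] = o2 + np.array([8.5, 0.0, 0.0])   # O3
    pos_p[6] = o2 + np.array([9.73, 0.0, 0.0])  # C3 (points away)
    o3 = pos_p[7]
    # zig-zag anchors: 4 steps of 2.86 A spanning 8.5 A
    step = 2.86
    cos_a = 8.5 / (4 * step)
    sin_a = np.sqrt(1.0 - cos_a**2)
    e = np.array([1.0, 0.0, 0.0])
    p = np.array([0.0, 1.0, 0.0])
    anchors = []
    cur = o2.copy()
    for k in range(3):
        cur = cur + step * (cos_a * e + (sin_a if k % 2 == 0 else -sin_a) * p)
        anchors.append(cur.copy())
    waters = []
    prev = o2
    for a in anchors:
        d = prev - a
        d = d / np.linalg.norm(d)
        o = np.asarray(a, dtype=float)
        h1 = o + 0.9572 * d  # points at the previous member: H-bond donor
        perp = np.array([0.0, 0.0, 1.0])
        h2 = o + 0.9572 * (np.cos(np.radians(104.5)) * d + np.sin(np.radians(104.5)) * perp)
        waters.append(np.vstack([o, h1, h2]))
        prev = o
    # last chain water must donate to O3: point its second H toward O3
    d3 = o3 - waters[-1][0]
    d3 /= np.linalg.norm(d3)
    waters[-1][2] = waters[-1][0] + 0.9572 * d3
    waters.append(_water_triplet(o2 + np.array([8.0, 8.0, 0.0]), 1))
    waters.append(_water_triplet(o2 + np.array([-8.0, 8.0, 4.0]), 2))

    labels = list(top_p.labels)
    elements = list(top_p.elements)
    masses = list(top_p.masses)
    positions = [pos_p]
    for w, wpos in enumerate(waters):
        labels += [f"OW{w}", f"HW{w}a", f"HW{w}b"]
        elements += ["O", "H", "H"]
        masses += [15.999, 1.008, 1.008]
        positions.append(wpos)
    n_pep = top_p.n_atoms
    bonds = set(top_p.bonds)
    for w in range(len(waters)):
        base = n_pep + 3 * w
        bonds |= {(base, base + 1), (base, base + 2)}
    groups = dict(top_p.groups)
    groups["water"] = tuple(range(n_pep, n_pep + 3 * len(waters)))
    top = Topology(labels=labels, elements=elements, masses=np.array(masses),
                   bonds=bonds, groups=groups)
    return Frame(np.vstack(positions), topology=top)


def make_water_box_frame(n_waters, seed, box=None, spread=6.0):
    """Random small frame of the peptide + n scattered waters (oracle tests)."""
    top_p, pos_p = syn.make_peptide_fixture()
    rng = np.random.default_rng(seed)
    labels = list(top_p.labels)
    elements = list(top_p.elements)
    masses = list(top_p.masses)
    positions = [pos_p]
    for w in range(n_waters):
        center = pos_p[2] + rng.uniform(-spread, spread, 3)
        o = center
        v1 = rng.normal(size=3)
        v1 /= np.linalg.norm(v1)
        perp = np.cross(v1, rng.normal(size=3))
        perp /= np.linalg.norm(perp)
        h1 = o + 0.9572 * v1
        h2 = o + 0.9572 * (np.cos(np.radians(104.5)) * v1 + np.sin(np.radians(104.5)) * perp)
        positions.append(np.vstack([o, h1, h2]))
        labels += [f"OW{w}", f"HW{w}a", f"HW{w}b"]
        elements += ["O", "H", "H"]
        masses += [15.999, 1.008, 1.008]
    n_pep = top_p.n_atoms
    bonds = set(top_p.bonds)
    for w in range(n_waters):
        base = n_pep + 3 * w
        bonds |= {(base, base + 1), (base, base + 2)}
    groups = dict(top_p.groups)
    groups["water"] = tuple(range(n_pep, n_pep + 3 * n_waters))
    top = Topology(labels=labels, elements=elements, masses=np.array(masses),
                   bonds=bonds, groups=groups)
    return Frame(np.vstack(positions), box=box, topology=top)


@pytest.fixture()
def small_trajectory(peptide_fixture):
    """Tiny 3-frame trajectory of the bare peptide for I/O tests."""
    top, pos = peptide_fixture
    rng = np.random.default_rng(5)
    frames = np.stack([pos + rng.normal(0, 0.01, pos.shape) for _ in range(3)])
    return Trajectory(top, frames, dt=0.5, box=np.array([22.2, 22.2, 22.2]))
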