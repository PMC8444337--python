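"""Synthetic geometries and tracks with known structure.

Every fixture is deterministic (seeded where random), emits valid extended
XYZ via :mod:`cectrack.trajectory_io`, and records its parameters in the
frame comment line. Internal geometries are idealized (0.97 Angstrom O-H
bonds, cone-distributed hydrogen bonds): the CEC depends only on the
distances entering the transfer coordinate and on the species positions, so
idealization does not weaken what the fixtures test.
"""

from __future__ import annotations

import numpy as np

from .errors import GeometryError
from .trajectory_io import Frame, FrameSeries

__all__ = [
    "make_ideal_network",
    "make_zundel_scan",
    "make_oscillating_track",
    "make_shuttle_trajectory",
    "SPEED_OF_LIGHT_CM_PER_FS",
]

OH_BOND = 0.97  # Angstrom, idealized covalent O-H
SPEED_OF_LIGHT_CM_PER_FS = 2.99792458e-5  # cm per fs


def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def _orthonormal_pair(u):
    """Two unit vectors completing ``u`` to a right-handed frame."""
    ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    a = _unit(np.cross(u, ref))
    b = np.cross(u, a)
    return a, b


def _cone_directions(axis, n, cone_deg, twist=0.0):
    """``n`` unit vectors on a cone of half-angle ``cone_deg`` about ``axis``."""
    u = _unit(axis)
    a, b = _orthonormal_pair(u)
    th = np.deg2rad(cone_deg)
    out = []
    for j in range(n):
        phi = twist + 2 * np.pi * j / max(n, 1)
        out.append(np.cos(th) * u + np.sin(th) * (np.cos(phi) * a + np.sin(phi) * b))
    return out


def make_ideal_network(
    branching: tuple[int, ...] = (3, 2, 2),
    hbond_len: float = 1.6,
) -> Frame:
    """Ring-free idealized hydrogen-bond network around a central hydronium.

    The hydronium donates ``branching[0]`` hydrogen bonds; every shell-k
    water donates ``branching[k]`` onward. All donated H...O acceptor
    distances equal ``hbond_len``. With the defaults the three-shell state
    enumeration resolves 1 + 3 + 6 + 12 = 22 states.
    """
    if any(b < 0 for b in branching) or not branching:
        raise ValueError("branching must be non-negative integers")
    elements: list[str] = ["O"]
    positions: list[np.ndarray] = [np.zeros(3)]
    hbond_pairs: list[tuple[int, int]] = []  # (H index, acceptor O index)
    covalent: set[tuple[int, int]] = set()

    # root hydronium: up to 3 donated bonds in the xy-plane
    n_root_h = 3
    root_dirs = [
        np.array([np.cos(p), np.sin(p), 0.0]) for p in (0.0, 2 * np.pi / 3, 4 * np.pi / 3)
    ]
    # (parent O idx, direction, depth) for each H-bond to extend
    frontier: list[tuple[int, np.ndarray, int]] = []
    counter = 0
    for j in range(n_root_h):
        h_idx = len(elements)
        elements.append("H")
        positions.append(positions[0] + OH_BOND * root_dirs[j])
        covalent.add((0, h_idx))
        if j < branching[0]:
            frontier.append((h_idx, root_dirs[j], 1))

    # out-of-plane then horizontal spreading keeps branches from touching
    cone_by_depth = {1: (52.0, np.pi / 2), 2: (46.0, 0.0), 3: (40.0, np.pi / 2)}
    while frontier:
        h_idx, direction, depth = frontier.pop(0)
        o_idx = len(elements)
        elements.append("O")
        positions.append(positions[h_idx] + hbond_len * direction)
        hbond_pairs.append((h_idx, o_idx))
        counter += 1
        b_next = branching[depth] if depth < len(branching) else 0
        cone, twist = cone_by_depth.get(depth, (40.0, 0.0))
        dirs = _cone_directions(direction, 2, cone, twist=twist)
        for j in range(2):
            new_h = len(elements)
            elements.append("H")
            positions.append(positions[o_idx] + OH_BOND * dirs[j])
            covalent.add((o_idx, new_h))
            if j < b_next and depth < len(branching):
                frontier.append((new_h, dirs[j], depth + 1))

    frame = Frame(
        elements=elements,
        positions=np.array(positions),
        comment=f"ideal-network branching={branching} hbond_len={hbond_len}",
    )
    _validate_network(frame, covalent, hbond_pairs, hbond_len)
    return frame


def _validate_network(frame, covalent, hbond_pairs, hbond_len):
    """Reject clashes and unintended hydrogen-bond contacts."""
    n = frame.n_atoms
    pos = frame.positions
    intended = set(hbond_pairs)
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in covalent or (j, i) in covalent:
                continue
            d = np.linalg.norm(pos[i] - pos[j])
            if d < 0.8:
                raise GeometryError(f"clash: atoms {i} and {j} at {d:.3f} A")
            ei, ej = frame.elements[i], frame.elements[j]
            if {ei, ej} == {"H", "O"} and hbond_len <= 2.5:
                pair = (i, j) if ei == "H" else (j, i)
                if pair not in intended and d <= 2.55:
                    raise GeometryError(
                        f"unintended H...O contact {pair} at {d:.3f} A would add states"
                    )


def make_zundel_scan(r_oo: float = 2.6, n_frames: int = 11, dt: float = 0.5) -> FrameSeries:
    """Shared proton moving linearly from donor-bound (0.9 A) to the midpoint.

    A gas-phase pair of one hydronium and one water along x; spectator
    hydrogens idealized. The last frame is the symmetric Zundel geometry
    (delta = 0).
    """
    if r_oo < 2.2:
        raise ValueError("r_oo must be at least 2.2 A")
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    frames = []
    r_oh_values = np.linspace(0.9, r_oo / 2, n_frames)
    for k, r_oh in enumerate(r_oh_values):
        frames.append(
            _proton_pair_frame(
                r_oo,
                float(r_oh),
                index=k,
                time=k * dt,
                comment=f"zundel-scan r_oo={r_oo} r_oh={r_oh:.6f}",
            )
        )
    return FrameSeries(frames=frames, dt=dt)


def _proton_pair_frame(r_oo, r_oh, index=0, time=0.0, comment=""):
    """Collinear O-H-O hydronium-water pair used by scans and training grids.

    Spectator hydrogens are mirror images through the O-O bisecting plane,
    so the r_oh = r_oo/2 geometry is exactly symmetric.
    """
    th = np.deg2rad(115.0)
    donor_h = [
        np.array([np.cos(th), 0.0, s * np.sin(th)]) * OH_BOND for s in (+1, -1)
    ]
    water_h = [
        np.array([r_oo, 0, 0]) + OH_BOND * np.array([-np.cos(th), 0.0, s * np.sin(th)])
        for s in (+1, -1)
    ]
    elements = ["O", "H", "H", "H", "O", "H", "H"]
    positions = np.array(
        [
            [0.0, 0.0, 0.0],
            [r_oh, 0.0, 0.0],
            donor_h[0],
            donor_h[1],
            [r_oo, 0.0, 0.0],
            water_h[0],
            water_h[1],
        ]
    )
    return Frame(elements=elements, positions=positions, index=index, time=time, comment=comment)


def make_oscillating_track(
    freq_cm: float,
    dt_fs: float = 0.5,
    n: int = 4096,
    noise: float = 0.0,
    seed: int = 0,
    amplitude: float = 0.05,
) -> np.ndarray:
    """Sinusoidal 1-D CEC track (along x) with optional seeded Gaussian noise.

    ``freq_cm`` is the oscillation wavenumber; the sampling must satisfy the
    Nyquist criterion for it.
    """
    freq_fs = freq_cm * SPEED_OF_LIGHT_CM_PER_FS  # cycles per fs
    if freq_fs >= 0.5 / dt_fs:
        raise ValueError(
            f"{freq_cm} cm^-1 violates Nyquist at dt = {dt_fs} fs"
        )
    t = np.arange(n) * dt_fs
    track = np.zeros((n, 3))
    track[:, 0] = amplitude * np.sin(2 * np.pi * freq_fs * t)
    if noise > 0:
        rng = np.random.default_rng(seed)
        track += rng.normal(scale=noise, size=(n, 3))
    return track


def _minimum_jerk(u: np.ndarray) -> np.ndarray:
    """Smooth 0->1 profile with zero velocity and acceleration at both ends."""
    return 10 * u**3 - 15 * u**4 + 6 * u**5


def make_shuttle_trajectory(
    n_waters_in_wire: int = 4,
    hops: int = 2,
    frames_per_hop: int = 20,
    r_oo: float = 2.6,
    dt: float = 0.5,
) -> FrameSeries:
    """Grotthuss shuttling along a linear water wire.

    The excess proton starts as a hydronium on the first wire molecule and is
    handed off molecule-to-molecule ``hops`` times; during each hop the
    shared H follows a minimum-jerk profile from its donor (O-H = 0.97 A) to
    its acceptor, so every intermediate O-H distance stays in [0.9, 1.8] A
    and the CEC moves continuously.
    """
    if n_waters_in_wire < hops + 1:
        raise ValueError("wire must contain at least hops + 1 molecules")
    elements: list[str] = []
    base: list[np.ndarray] = []
    forward_h: list[int] = []  # index of the +x hydrogen of each wire O
    for k in range(n_waters_in_wire):
        o = np.array([k * r_oo, 0.0, 0.0])
        elements.append("O")
        base.append(o)
        elements.append("H")  # perpendicular H, alternating +-y
        base.append(o + OH_BOND * np.array([0.0, (-1.0) ** k, 0.0]))
        elements.append("H")  # forward H along the wire
        forward_h.append(len(base))
        base.append(o + OH_BOND * np.array([1.0, 0.0, 0.0]))
    elements.append("H")  # the extra proton, initially on molecule 0
    base.append(np.array([-OH_BOND, 0.0, 0.0]))

    travel = r_oo - 2 * OH_BOND
    frames = [
        Frame(
            elements=list(elements),
            positions=np.array(base),
            index=0,
            time=0.0,
            comment=f"shuttle wire={n_waters_in_wire} hops={hops} r_oo={r_oo}",
        )
    ]
    pos = np.array(base)
    for j in range(hops):
        mover = forward_h[j]
        start_x = j * r_oo + OH_BOND
        for m in range(1, frames_per_hop + 1):
            s = float(_minimum_jerk(np.array([m / frames_per_hop]))[0])
            pos = pos.copy()
            pos[mover, 0] = start_x + s * travel
            idx = len(frames)
            frames.append(
                Frame(
                    elements=list(elements),
                    positions=pos,
                    index=idx,
                    time=idx * dt,
                    comment=f"shuttle hop={j} progress={s:.4f}",
                )
            )
    return FrameSeries(frames=frames, dt=dt)
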