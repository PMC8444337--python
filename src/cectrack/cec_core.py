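"""Center-of-excess-charge evaluation.

The excess-proton charge defect is represented as a weighted average over
diabatic states. Each state |i> carries the charge on one protonated
species, whose center of charge (COC) is

    COC_i = sum_I q_I^i r_I / sum_I q_I^i ,

with fixed per-atom *excess* charges q_I^i summing to +1 e. The weight of a
state is built from charge-transfer factors, one per proton hop on its path,

    f_CT(delta) = exp(k (delta - delta_0)),
    delta = |r_H - r_donorO| - |r_H - r_acceptorO|,

and normalized so that sum_i c_i^2 = 1; the root state's unnormalized weight
is the empty product 1, giving c_1^2 = 1 / (1 + sum over paths of the path
product). The adiabatic CEC is then

    r_CEC = sum_i c_i^2 COC_i ,

equivalently the dipole of the per-atom excess charges sum_i c_i^2 q_I^i
divided by the total (+1 e). Analytic gradients of the CEC with respect to
all atomic positions are provided for biasing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, GeometryError
from .topology_states import AcidSpec, DiabaticState, Hop, StateSet, assign_topology, enumerate_states
from .trajectory_io import Frame, minimum_image

__all__ = [
    "CTParams",
    "ParamSet",
    "DEFAULT_CT_PARAMS",
    "DEFAULT_CHARGES",
    "load_ct_params",
    "load_charge_table",
    "CECResult",
    "hop_delta",
    "charge_transfer_factor",
    "state_weights",
    "center_of_charge",
    "compute_cec",
    "excess_charge_dipole",
    "cec_gradient",
    "cec_for_frame",
]

EXPONENT_CLIP = 50.0  # |k (delta - delta0)| cap before exponentiation


@dataclass(frozen=True)
class CTParams:
    """Fitted exponential charge-transfer parameters for one donor-acceptor pair."""

    pair_kind: str
    k: float  # 1/Angstrom
    delta0: float  # Angstrom
    functional: str = "BLYP"

    def __post_init__(self):
        if self.k <= 0:
            raise ConfigurationError(f"k must be positive, got {self.k}")
        if not np.isfinite(self.delta0):
            raise ConfigurationError("delta0 must be finite")


# Gas-phase CDFT-CI calibrated parameters per donor-acceptor pair kind.
_TABLE = [
    CTParams("h3o-water", k=4.234, delta0=0.0, functional="BLYP"),
    CTParams("h3o-water", k=4.898, delta0=0.0, functional="wB97X"),
    CTParams("glu-water", k=2.946, delta0=0.5361, functional="BLYP"),
]

ParamSet = dict[str, CTParams]


def default_ct_params(functional: str = "BLYP") -> ParamSet:
    """Shipped (k, delta0) per pair kind for the requested functional."""
    out: ParamSet = {}
    for p in _TABLE:
        if p.functional.lower() == functional.lower():
            out[p.pair_kind] = p
    if not out:
        raise ConfigurationError(f"no parameters shipped for functional {functional!r}")
    return out


DEFAULT_CT_PARAMS: ParamSet = default_ct_params("BLYP")

# Stand-in excess charges (protonated-species charge minus deprotonated-parent
# charge, summing to +1 e per species); override via a JSON charge table.
DEFAULT_CHARGES: dict[str, dict[str, float]] = {
    "hydronium": {"O": 0.334, "H": 0.222},
    "glu": {"C": 0.10, "OH": 0.35, "O": 0.11, "H": 0.44},
}


def load_ct_params(path: str | Path, functional: str = "BLYP") -> ParamSet:
    """Load CT parameters from a JSON list of {pair_kind, k, delta0, functional}."""
    entries = json.loads(Path(path).read_text())
    out: ParamSet = {}
    for e in entries:
        p = CTParams(
            pair_kind=e["pair_kind"],
            k=float(e["k"]),
            delta0=float(e["delta0"]),
            functional=e.get("functional", "BLYP"),
        )
        if p.functional.lower() == functional.lower():
            out[p.pair_kind] = p
    if not out:
        raise ConfigurationError(
            f"parameter file {path} has no entries for functional {functional!r}"
        )
    return out


def save_ct_params(params: ParamSet | list[CTParams], path: str | Path) -> None:
    entries = params.values() if isinstance(params, dict) else params
    payload = [
        {"pair_kind": p.pair_kind, "k": p.k, "delta0": p.delta0, "functional": p.functional}
        for p in entries
    ]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_charge_table(path: str | Path) -> dict[str, dict[str, float]]:
    """Load excess charges from JSON {species: [{role, q}]} or {species: {role: q}}."""
    raw = json.loads(Path(path).read_text())
    table: dict[str, dict[str, float]] = {}
    for label, entries in raw.items():
        if isinstance(entries, dict):
            table[label] = {r: float(q) for r, q in entries.items()}
        else:
            table[label] = {e["role"]: float(e["q"]) for e in entries}
    return table


@dataclass
class CECResult:
    """CEC position plus the per-state and per-atom decomposition for one frame."""

    cec: np.ndarray  # (3,) Angstrom
    weights: np.ndarray  # c_i^2 per state, sums to 1
    per_atom_excess: dict[int, float]  # atom index -> excess charge (e)
    dipole: np.ndarray  # (3,) e * Angstrom
    n_states: int
    xi: float | None = None


# --------------------------------------------------------------------------
# elementary quantities


def hop_delta(frame: Frame, hop: Hop) -> float:
    """Proton-transfer coordinate of a hop (minimum-image distances).

    delta = |r_H - r_donorO| - |r_H - r_acceptorO|; negative while the proton
    is bound to the donor, zero at equal sharing, increasing as it moves
    toward the acceptor.
    """
    d_don = frame.distance(hop.shared_h, hop.donor_o)
    d_acc = frame.distance(hop.shared_h, hop.acceptor_o)
    if d_don < 1e-8 or d_acc < 1e-8:
        raise GeometryError(
            f"shared H {hop.shared_h} coincides with an oxygen; delta undefined"
        )
    return d_don - d_acc


def charge_transfer_factor(delta: float, params: CTParams, reverse: bool = False) -> float:
    """Exponential charge-transfer factor f_CT = exp(k (delta - delta0)).

    ``reverse`` evaluates the mirrored donor/acceptor role (1 / f(-delta),
    i.e. exp(k (delta + delta0))). The exponent is clipped to +-50 so the
    factor stays finite for any geometry.
    """
    d0 = -params.delta0 if reverse else params.delta0
    expo = float(np.clip(params.k * (delta - d0), -EXPONENT_CLIP, EXPONENT_CLIP))
    return float(np.exp(expo))


def _hop_factor(frame: Frame, hop: Hop, params_by_kind: ParamSet) -> tuple[float, CTParams]:
    try:
        p = params_by_kind[hop.pair_kind]
    except KeyError:
        raise ConfigurationError(
            f"no charge-transfer parameters for pair kind {hop.pair_kind!r}"
        ) from None
    return charge_transfer_factor(hop_delta(frame, hop), p, reverse=hop.reverse), p


def state_weights(stateset: StateSet, frame: Frame, params_by_kind: ParamSet) -> np.ndarray:
    """Normalized state populations c_i^2 (path products of f_CT, summed to 1)."""
    raw = np.empty(len(stateset))
    cache: dict[tuple[int, int, int], float] = {}
    for i, state in enumerate(stateset):
        prod = 1.0
        for hop in state.path:
            key = hop.key()
            if key not in cache:
                cache[key], _ = _hop_factor(frame, hop, params_by_kind)
            prod *= cache[key]
        raw[i] = prod
    return raw / raw.sum()


# --------------------------------------------------------------------------
# centers of charge and the CEC


def _species_charges(species, charges: dict[str, dict[str, float]]) -> np.ndarray:
    try:
        entry = charges[species.label]
    except KeyError:
        raise ConfigurationError(
            f"no charge-table entry for species {species.label!r}"
        ) from None
    q = np.empty(len(species.atoms))
    for j, role in enumerate(species.roles):
        if role not in entry:
            raise ConfigurationError(
                f"charge table for {species.label!r} lacks role {role!r}"
            )
        q[j] = entry[role]
    total = q.sum()
    if abs(total - 1.0) > 1e-9:
        raise ConfigurationError(
            f"excess charges of {species.label!r} sum to {total}, expected +1 e"
        )
    return q


def _unwrap_molecule(frame: Frame, atoms: tuple[int, ...]) -> np.ndarray:
    """Molecule coordinates made whole by minimum image about the first atom."""
    ref = frame.positions[atoms[0]]
    coords = np.empty((len(atoms), 3))
    for j, a in enumerate(atoms):
        coords[j] = ref + minimum_image(frame.positions[a] - ref, frame.box)
    return coords


def center_of_charge(frame: Frame, state: DiabaticState, charges) -> np.ndarray:
    """Excess-charge-weighted position of a state's protonated species."""
    q = _species_charges(state.species, charges)
    coords = _unwrap_molecule(frame, state.species.atoms)
    return (q[:, None] * coords).sum(axis=0) / q.sum()


def _network_unwrapped(frame: Frame, stateset: StateSet) -> np.ndarray:
    """Positions with every molecule of the state network made image-consistent.

    Anchored at the root species' first atom; each acceptor molecule is
    placed by minimum image relative to its donor oxygen as the hop network
    is walked, so all COCs and the dipole share one common set of images.
    """
    pos = frame.positions.copy()
    if frame.box is None:
        return pos
    placed: set[int] = set()

    def place(atom: int, ref: np.ndarray):
        if atom not in placed:
            pos[atom] = ref + minimum_image(pos[atom] - ref, frame.box)
            placed.add(atom)

    root = stateset.root.species
    anchor = root.atoms[0]
    placed.add(anchor)
    for a in root.atoms:
        place(a, pos[anchor])
    for state in stateset:
        for hop in state.path:
            place(hop.acceptor_o, pos[hop.donor_o])
            ref = pos[hop.acceptor_o]
            for a in state.species.atoms:
                place(a, ref)
    return pos


def compute_cec(frame: Frame, stateset: StateSet, weights: np.ndarray, charges) -> CECResult:
    """Adiabatic CEC: the c_i^2-weighted average of the diabatic COCs.

    Also populates the per-atom excess charges sum_i c_i^2 q_I^i and their
    dipole (equal to +1 e times the CEC under the common unwrapped origin).
    """
    weights = np.asarray(weights, dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("state weights must be normalized")
    pos = _network_unwrapped(frame, stateset)
    cec = np.zeros(3)
    per_atom: dict[int, float] = {}
    for w, state in zip(weights, stateset):
        q = _species_charges(state.species, charges)
        coords = pos[list(state.species.atoms)]
        cec += w * (q[:, None] * coords).sum(axis=0) / q.sum()
        for a, qa in zip(state.species.atoms, q):
            per_atom[a] = per_atom.get(a, 0.0) + w * qa
    dipole = np.zeros(3)
    for a, qa in per_atom.items():
        dipole += qa * pos[a]
    return CECResult(
        cec=cec,
        weights=weights,
        per_atom_excess=per_atom,
        dipole=dipole,
        n_states=len(stateset),
    )


def excess_charge_dipole(frame: Frame, stateset: StateSet, weights, charges):
    """Per-atom excess charges and their dipole moment (e * Angstrom)."""
    res = compute_cec(frame, stateset, weights, charges)
    return res.per_atom_excess, res.dipole


# --------------------------------------------------------------------------
# analytic gradient


def cec_gradient(
    frame: Frame,
    stateset: StateSet,
    params_by_kind: ParamSet,
    charges,
) -> dict[int, np.ndarray]:
    """Per-atom 3x3 Jacobian blocks d(CEC)/d(r_I).

    Combines the COC term (q_I^i times identity for atoms of each species)
    with the weight term, obtained by the chain rule through every hop's
    proton-transfer coordinate. Atoms in no species and no hop have no block
    (exactly zero); the blocks of all listed atoms sum to the identity
    (translational covariance).
    """
    n_states = len(stateset)
    pos = _network_unwrapped(frame, stateset)

    # unique hops, their parameters and which states' paths contain them
    hop_info: dict[tuple[int, int, int], dict] = {}
    raw = np.empty(n_states)
    for i, state in enumerate(stateset):
        prod = 1.0
        for hop in state.path:
            key = hop.key()
            if key not in hop_info:
                f, p = _hop_factor(frame, hop, params_by_kind)
                d = hop_delta(frame, hop)
                d0 = -p.delta0 if hop.reverse else p.delta0
                clipped = abs(p.k * (d - d0)) >= EXPONENT_CLIP
                hop_info[key] = {"hop": hop, "f": f, "k": (0.0 if clipped else p.k), "states": []}
            hop_info[key]["states"].append(i)
            prod *= hop_info[key]["f"]
        raw[i] = prod
    w = raw / raw.sum()

    cocs = np.empty((n_states, 3))
    qs = []
    for i, state in enumerate(stateset):
        q = _species_charges(state.species, charges)
        qs.append(q)
        coords = pos[list(state.species.atoms)]
        cocs[i] = (q[:, None] * coords).sum(axis=0) / q.sum()
    cec = (w[:, None] * cocs).sum(axis=0)

    grads: dict[int, np.ndarray] = {}

    def block(atom: int) -> np.ndarray:
        if atom not in grads:
            grads[atom] = np.zeros((3, 3))
        return grads[atom]

    eye = np.eye(3)
    for i, state in enumerate(stateset):
        for a, qa in zip(state.species.atoms, qs[i]):
            block(a)
            grads[a] += w[i] * qa * eye

    for info in hop_info.values():
        hop: Hop = info["hop"]
        k_eff = info["k"]
        if k_eff == 0.0:
            continue
        members = info["states"]
        W_h = w[members].sum()
        C_h = (w[members, None] * cocs[members]).sum(axis=0)
        A_h = k_eff * (C_h - W_h * cec)  # dCEC/d(delta_h)
        rH, rD, rA = pos[hop.shared_h], pos[hop.donor_o], pos[hop.acceptor_o]
        vD = minimum_image(rH - rD, frame.box)
        vA = minimum_image(rH - rA, frame.box)
        eD = vD / np.linalg.norm(vD)
        eA = vA / np.linalg.norm(vA)
        for atom, dd in ((hop.shared_h, eD - eA), (hop.donor_o, -eD), (hop.acceptor_o, eA)):
            block(atom)
            grads[atom] += np.outer(A_h, dd)
    return grads


# --------------------------------------------------------------------------
# one-call convenience


def cec_for_frame(
    frame: Frame,
    params_by_kind: ParamSet | None = None,
    charges=None,
    acid: AcidSpec | None = None,
    max_shell: int = 3,
    cutoff: float = 2.5,
) -> tuple[CECResult, StateSet]:
    """Topology -> state enumeration -> weights -> CEC for a single frame."""
    params_by_kind = params_by_kind if params_by_kind is not None else DEFAULT_CT_PARAMS
    charges = charges if charges is not None else DEFAULT_CHARGES
    topo = assign_topology(frame, acid=acid)
    states = enumerate_states(frame, topo, max_shell=max_shell, cutoff=cutoff, acid=acid)
    w = state_weights(states, frame, params_by_kind)
    return compute_cec(frame, states, w, charges), states
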