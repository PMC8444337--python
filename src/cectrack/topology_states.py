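"""Bonding topology assignment and diabatic-state enumeration.

A diabatic state is a bonding topology: it names the one species (hydronium
or neutral acid) that carries the excess protonic charge. Starting from the
topology actually realized in a frame (state |1>), further states are
generated breadth-first by Grotthuss hops: a hydrogen of the protonated
species is transferred to a hydrogen-bonded acceptor oxygen, producing a new
protonated species one solvation shell further out. The search covers up to
three shells using a 2.5 Angstrom criterion on the shared-H-to-acceptor-O
distance; a fourth shell contributes negligible weight and is omitted by
default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import TopologyError
from .trajectory_io import Frame

__all__ = [
    "AcidSpec",
    "Species",
    "Topology",
    "Hop",
    "DiabaticState",
    "StateSet",
    "assign_topology",
    "find_acceptor_hops",
    "enumerate_states",
]

DEFAULT_CUTOFF = 2.5  # Angstrom, H...O hydrogen-bond acceptor criterion
DEFAULT_MAX_SHELL = 3


@dataclass(frozen=True)
class AcidSpec:
    """Declaration of a weak-acid group whose oxygens can carry the proton.

    ``oxygens`` are the (two, for a carboxylate) O atom indices; ``carbon``
    the carboxyl carbon if it should be part of the charged species.
    ``label`` selects the charge-table entry and the CT-parameter pair kind
    ``f"{label}-water"``.
    """

    oxygens: tuple[int, ...]
    carbon: int | None = None
    label: str = "glu"

    def __post_init__(self):
        object.__setattr__(self, "oxygens", tuple(int(i) for i in self.oxygens))
        if len(self.oxygens) == 0:
            raise ValueError("acid group needs at least one oxygen")


@dataclass(frozen=True)
class Species:
    """A molecule (plus any transferred H) that may carry the excess charge."""

    label: str  # "water" | "hydronium" | acid label | f"{acid}-ionized"
    atoms: tuple[int, ...]
    o_atoms: tuple[int, ...]
    h_atoms: tuple[int, ...]
    roles: tuple[str, ...]  # charge-table role per entry of ``atoms``

    @property
    def protonated(self) -> bool:
        return self.label not in ("water",) and not self.label.endswith("-ionized")


@dataclass
class Topology:
    """Covalent H-to-oxygen assignment and the molecular partition of a frame."""

    h_to_heavy: dict[int, int]
    species: list[Species]
    root_index: int
    molecule_of_o: dict[int, int] = field(default_factory=dict)

    @property
    def root_species(self) -> Species:
        return self.species[self.root_index]


@dataclass(frozen=True)
class Hop:
    """One proton transfer: ``shared_h`` leaves ``donor_o`` for ``acceptor_o``."""

    donor_o: int
    shared_h: int
    acceptor_o: int
    pair_kind: str
    reverse: bool = False  # True when donor/acceptor roles are mirrored w.r.t. the fit

    def key(self) -> tuple[int, int, int]:
        return (self.donor_o, self.shared_h, self.acceptor_o)


@dataclass(frozen=True)
class DiabaticState:
    id: int
    species: Species
    path: tuple[Hop, ...]

    @property
    def shell(self) -> int:
        return len(self.path)

    @property
    def protonated_atoms(self) -> tuple[int, ...]:
        return self.species.atoms


@dataclass
class StateSet:
    states: list[DiabaticState]
    root_id: int = 0

    def __len__(self) -> int:
        return len(self.states)

    def __iter__(self):
        return iter(self.states)

    @property
    def root(self) -> DiabaticState:
        return self.states[self.root_id]


def _nearest_o(frame: Frame, h: int, o_indices: np.ndarray) -> int:
    d = np.array([frame.distance(h, o) for o in o_indices])
    best = np.min(d)
    # deterministic tie-break: lowest atom index among equidistant oxygens
    cands = o_indices[d <= best + 1e-9]
    return int(np.min(cands))


def assign_topology(frame: Frame, acid: AcidSpec | None = None) -> Topology:
    """Assign each H to its nearest O and partition the frame into species.

    Waters carry 2 H, a hydronium 3; an acid group declared via ``acid`` is
    neutral (protonated) when one of its oxygens holds an H within covalent
    range. Exactly one protonated species must exist.
    """
    o_indices = frame.atoms_of("O")
    h_indices = frame.atoms_of("H")
    if len(o_indices) == 0 or len(h_indices) == 0:
        raise TopologyError("frame must contain O and H atoms")

    h_to_heavy = {int(h): _nearest_o(frame, int(h), o_indices) for h in h_indices}
    h_of_o: dict[int, list[int]] = {int(o): [] for o in o_indices}
    for h, o in h_to_heavy.items():
        h_of_o[o].append(h)

    acid_oxygens = set(acid.oxygens) if acid is not None else set()
    species: list[Species] = []
    molecule_of_o: dict[int, int] = {}
    protonated_indices: list[int] = []

    if acid is not None:
        sp = _acid_species(acid, h_of_o)
        for o in acid.oxygens:
            molecule_of_o[o] = len(species)
        if sp.protonated:
            protonated_indices.append(len(species))
        species.append(sp)

    for o in o_indices:
        o = int(o)
        if o in acid_oxygens:
            continue
        hs = sorted(h_of_o[o])
        n_h = len(hs)
        if n_h == 2:
            label = "water"
        elif n_h == 3:
            label = "hydronium"
            protonated_indices.append(len(species))
        else:
            raise TopologyError(
                f"oxygen {o} has {n_h} bonded hydrogens; only water (2) and "
                "hydronium (3) are supported"
            )
        molecule_of_o[o] = len(species)
        species.append(
            Species(
                label=label,
                atoms=(o, *hs),
                o_atoms=(o,),
                h_atoms=tuple(hs),
                roles=("O",) + ("H",) * n_h,
            )
        )

    if len(protonated_indices) == 0:
        raise TopologyError("no excess proton: no hydronium and no protonated acid")
    if len(protonated_indices) > 1:
        raise TopologyError(
            f"{len(protonated_indices)} protonated species found; only a single "
            "excess proton is supported"
        )
    return Topology(
        h_to_heavy=h_to_heavy,
        species=species,
        root_index=protonated_indices[0],
        molecule_of_o=molecule_of_o,
    )


def _acid_species(acid: AcidSpec, h_of_o: dict[int, list[int]]) -> Species:
    """Build the acid species from the declared group plus any bonded H."""
    hs = sorted(h for o in acid.oxygens for h in h_of_o.get(o, []))
    if len(hs) > 1:
        raise TopologyError(
            f"acid group {acid.label} carries {len(hs)} hydrogens; at most one "
            "is supported"
        )
    atoms: list[int] = []
    roles: list[str] = []
    if acid.carbon is not None:
        atoms.append(acid.carbon)
        roles.append("C")
    if hs:
        h = hs[0]
        # the oxygen actually bearing the H gets the hydroxyl role
        oh = h_of_o  # mapping o -> hydrogens
        for o in acid.oxygens:
            atoms.append(o)
            roles.append("OH" if h in oh.get(o, []) else "O")
        atoms.append(h)
        roles.append("H")
        label = acid.label
    else:
        for o in acid.oxygens:
            atoms.append(o)
            roles.append("O")
        label = f"{acid.label}-ionized"
    return Species(
        label=label,
        atoms=tuple(atoms),
        o_atoms=tuple(acid.oxygens),
        h_atoms=tuple(hs),
        roles=tuple(roles),
    )


def _protonate(species: Species, acceptor_o: int, shared_h: int, acid: AcidSpec | None) -> Species:
    """Species obtained when ``acceptor_o``'s molecule receives ``shared_h``."""
    if species.label == "water":
        hs = tuple(sorted((*species.h_atoms, shared_h)))
        return Species(
            label="hydronium",
            atoms=(species.o_atoms[0], *hs),
            o_atoms=species.o_atoms,
            h_atoms=hs,
            roles=("O",) + ("H",) * 3,
        )
    if species.label.endswith("-ionized"):
        assert acid is not None
        atoms: list[int] = []
        roles: list[str] = []
        if acid.carbon is not None:
            atoms.append(acid.carbon)
            roles.append("C")
        for o in acid.oxygens:
            atoms.append(o)
            roles.append("OH" if o == acceptor_o else "O")
        atoms.append(shared_h)
        roles.append("H")
        return Species(
            label=acid.label,
            atoms=tuple(atoms),
            o_atoms=tuple(acid.oxygens),
            h_atoms=(shared_h,),
            roles=tuple(roles),
        )
    raise TopologyError(f"cannot protonate species with label {species.label!r}")


def _pair_kind(donor: Species, acceptor: Species, acid: AcidSpec | None) -> tuple[str, bool]:
    if donor.label == "hydronium" and acceptor.label == "water":
        return "h3o-water", False
    if acid is not None:
        if donor.label == acid.label and acceptor.label == "water":
            return f"{acid.label}-water", False
        if donor.label == "hydronium" and acceptor.label.endswith("-ionized"):
            # proton moving back onto the acid: mirrored roles of the fitted pair
            return f"{acid.label}-water", True
    raise TopologyError(
        f"no charge-transfer pair kind for {donor.label} -> {acceptor.label}"
    )


def find_acceptor_hops(
    frame: Frame,
    topology: Topology,
    donor: Species,
    cutoff: float = DEFAULT_CUTOFF,
    forbidden: tuple[int, int] | None = None,
    excluded_molecules: frozenset[int] = frozenset(),
    acid: AcidSpec | None = None,
) -> list[Hop]:
    """All hydrogen-bond donor hops from ``donor`` with H...O <= ``cutoff``.

    ``forbidden`` is a (shared_h, acceptor_o) pair that must not be generated
    (the immediately reversing hop); ``excluded_molecules`` are molecule ids
    already protonated along the current path (simple-path rule).
    """
    hops: list[Hop] = []
    donor_atoms = set(donor.atoms)
    o_list = donor.o_atoms
    for h in donor.h_atoms:
        donor_o = (
            o_list[0]
            if len(o_list) == 1
            else _nearest_o(frame, h, np.asarray(o_list, dtype=int))
        )
        for o, mol in topology.molecule_of_o.items():
            if o in donor_atoms or mol in excluded_molecules:
                continue
            if forbidden is not None and (h, o) == forbidden:
                continue
            if frame.distance(h, o) <= cutoff:
                acceptor = topology.species[mol]
                kind, rev = _pair_kind(donor, acceptor, acid)
                hops.append(
                    Hop(donor_o=donor_o, shared_h=h, acceptor_o=o, pair_kind=kind, reverse=rev)
                )
    hops.sort(key=lambda hp: (hp.shared_h, hp.acceptor_o))
    return hops


def enumerate_states(
    frame: Frame,
    topology: Topology,
    max_shell: int = DEFAULT_MAX_SHELL,
    cutoff: float = DEFAULT_CUTOFF,
    acid: AcidSpec | None = None,
) -> StateSet:
    """Breadth-first enumeration of diabatic states up to ``max_shell`` hops.

    The realized topology is the root state |1>. Each hop transfers the
    shared H to the acceptor molecule, which becomes the protonated species
    of the child state. A transferred H may not immediately hop back to its
    donor, and a path never revisits a molecule it already protonated
    (simple paths). Distinct simple paths reaching the same molecule (ring
    closures) are kept as distinct states; since such states share a center
    of charge and the normalization sums their weights, collapsing them
    would leave every downstream quantity unchanged.
    """
    root_state = DiabaticState(id=0, species=topology.root_species, path=())
    states = [root_state]
    root_mol = _molecule_id_of_species(topology, topology.root_species)
    # queue entries: (state, visited molecule ids, forbidden reverse hop)
    queue: list[tuple[DiabaticState, frozenset[int], tuple[int, int] | None]] = [
        (root_state, frozenset({root_mol}), None)
    ]
    while queue:
        state, visited, forbidden = queue.pop(0)
        if state.shell >= max_shell:
            continue
        hops = find_acceptor_hops(
            frame,
            topology,
            state.species,
            cutoff=cutoff,
            forbidden=forbidden,
            excluded_molecules=visited,
            acid=acid,
        )
        for hop in hops:
            mol = topology.molecule_of_o[hop.acceptor_o]
            child_species = _protonate(topology.species[mol], hop.acceptor_o, hop.shared_h, acid)
            child = DiabaticState(
                id=len(states), species=child_species, path=(*state.path, hop)
            )
            states.append(child)
            queue.append((child, visited | {mol}, (hop.shared_h, hop.donor_o)))
    return StateSet(states=states, root_id=0)


def _molecule_id_of_species(topology: Topology, species: Species) -> int:
    return topology.molecule_of_o[species.o_atoms[0]]
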