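"""Interface contact classification, direct/indirect calls, and interface area.

Atomic interactions across the two chains of a dimer are classified with
purely geometric rules on inter-atomic distances:

* disulfide bridge — two cysteine sulfur atoms at ≤ 2.56 Å,
* hydrogen bond — N–O or O–N at ≤ 3.5 Å,
* salt bridge — N–O or O–N at ≤ 5.5 Å,
* van der Waals — two carbon atoms at ≤ 5.0 Å.

The hydrogen-bond and salt-bridge rules deliberately overlap (nested
distance thresholds on the same atom types); a qualifying atom pair carries
every class it satisfies. A residue pair counts as one residue-residue
contact regardless of how many of its atom pairs qualify. A protein pair
with five or more residue contacts in a complex is called a *direct*
contact; fewer, *indirect*.

Interface area is half the difference between the solvent-accessible
surface area of the isolated chains and that of the complex, computed with
Shrake–Rupley sphere sampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .io_formats import DimerStructure, PPIDataset

__all__ = [
    "AtomicInteraction",
    "ResidueContact",
    "InterfaceSummary",
    "DISTANCE_CUTOFFS",
    "atomic_interactions",
    "residue_contacts",
    "classify_direct",
    "direct_fraction",
    "interface_area",
    "summarize_interface",
]

DISTANCE_CUTOFFS = {
    "disulfide": 2.56,
    "hydrogen_bond": 3.5,
    "salt_bridge": 5.5,
    "van_der_waals": 5.0,
}

#: Shrake–Rupley van der Waals radii (Å) by element
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}

DIRECT_CONTACT_MIN = 5  # residue contacts needed to call a pair direct


@dataclass(frozen=True)
class AtomicInteraction:
    atom_a: tuple[str, int, str]  # (chain_id, residue_index, atom_name)
    atom_b: tuple[str, int, str]
    distance: float
    classes: frozenset[str]


@dataclass(frozen=True)
class ResidueContact:
    residue_a: tuple[str, int]  # (chain_id, residue_index)
    residue_b: tuple[str, int]
    interaction_classes: frozenset[str]


@dataclass
class InterfaceSummary:
    contact_count: int
    contact_list: list[ResidueContact]
    interface_area: float
    direct: bool


def _chain_arrays(chain, chain_id):
    """Flatten a chain into parallel numpy arrays for vectorized rules."""
    pos, elem, resname, residx, aname = [], [], [], [], []
    for res in chain:
        for atom in res.atoms:
            pos.append(atom.position)
            elem.append(atom.element)
            resname.append(res.name)
            residx.append(res.index)
            aname.append(atom.atom_name)
    return {
        "pos": np.array(pos, dtype=float).reshape(-1, 3),
        "elem": np.array(elem),
        "resname": np.array(resname),
        "residx": np.array(residx, dtype=int),
        "aname": np.array(aname),
        "chain_id": chain_id,
    }


def atomic_interactions(struct: DimerStructure) -> list[AtomicInteraction]:
    """All inter-chain atom pairs satisfying any interaction rule.

    Each qualifying pair appears once, tagged with every rule it satisfies;
    intra-chain pairs are ignored. Distance comparisons are inclusive (≤)
    at the exact threshold values, with no tolerance epsilon.
    """
    a = _chain_arrays(struct.chain_a, struct.chain_ids[0])
    b = _chain_arrays(struct.chain_b, struct.chain_ids[1])
    if len(a["pos"]) == 0 or len(b["pos"]) == 0:
        return []

    max_cut = max(DISTANCE_CUTOFFS.values())
    pairs = cKDTree(a["pos"]).query_ball_tree(cKDTree(b["pos"]), r=max_cut)

    out = []
    for i, js in enumerate(pairs):
        if not js:
            continue
        js = np.array(sorted(js), dtype=int)
        d = np.linalg.norm(b["pos"][js] - a["pos"][i], axis=1)
        e_i = a["elem"][i]
        for j, dist in zip(js, d):
            e_j = b["elem"][j]
            classes = set()
            if (
                e_i == "S"
                and e_j == "S"
                and a["resname"][i] == "CYS"
                and b["resname"][j] == "CYS"
                and dist <= DISTANCE_CUTOFFS["disulfide"]
            ):
                classes.add("disulfide")
            if {e_i, e_j} == {"N", "O"}:
                if dist <= DISTANCE_CUTOFFS["hydrogen_bond"]:
                    classes.add("hydrogen_bond")
                if dist <= DISTANCE_CUTOFFS["salt_bridge"]:
                    classes.add("salt_bridge")
            if e_i == "C" and e_j == "C" and dist <= DISTANCE_CUTOFFS["van_der_waals"]:
                classes.add("van_der_waals")
            if classes:
                out.append(
                    AtomicInteraction(
                        atom_a=(a["chain_id"], int(a["residx"][i]), str(a["aname"][i])),
                        atom_b=(b["chain_id"], int(b["residx"][j]), str(b["aname"][j])),
                        distance=float(dist),
                        classes=frozenset(classes),
                    )
                )
    return out


def residue_contacts(struct: DimerStructure) -> list[ResidueContact]:
    """Residue-residue contacts: one per residue pair with ≥1 qualifying
    atomic interaction; classes are the union over its atom pairs."""
    grouped: dict[tuple, set[str]] = {}
    for ia in atomic_interactions(struct):
        key = ((ia.atom_a[0], ia.atom_a[1]), (ia.atom_b[0], ia.atom_b[1]))
        grouped.setdefault(key, set()).update(ia.classes)
    return [
        ResidueContact(residue_a=ra, residue_b=rb, interaction_classes=frozenset(classes))
        for (ra, rb), classes in sorted(grouped.items())
    ]


def classify_direct(contact_count: int) -> bool:
    """Direct contact iff the pair has five or more residue-residue contacts."""
    if contact_count < 0:
        raise ValueError("contact_count must be non-negative")
    return contact_count >= DIRECT_CONTACT_MIN


def direct_fraction(
    dataset: PPIDataset | set, direct_set: set, indirect_set: set
) -> float:
    """Fraction of a dataset's structurally annotated pairs that are direct.

    Defined as |dataset ∩ direct| / |dataset ∩ (direct ∪ indirect)|.
    """
    if direct_set & indirect_set:
        raise ValueError("direct and indirect sets must be disjoint")
    pairs = dataset.pairs if isinstance(dataset, PPIDataset) else set(dataset)
    annotated = pairs & (direct_set | indirect_set)
    if not annotated:
        raise ValueError("no structurally annotated pairs in dataset")
    return len(pairs & direct_set) / len(annotated)


# ---------------------------------------------------------------------------
# Solvent-accessible surface area (Shrake–Rupley)

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden-spiral)."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def _sasa(positions: np.ndarray, radii: np.ndarray, n_points: int, probe: float) -> float:
    """Total SASA (Å²) of one atom set by Shrake–Rupley sphere sampling."""
    sphere = _sphere_points(n_points)
    expanded = radii + probe
    tree = cKDTree(positions)
    total = 0.0
    r_max = expanded.max()
    for i in range(len(positions)):
        pts = positions[i] + expanded[i] * sphere
        neighbors = [j for j in tree.query_ball_point(positions[i], expanded[i] + r_max) if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d = np.linalg.norm(pts - positions[j], axis=1)
            accessible &= d >= expanded[j]
        total += accessible.mean() * 4.0 * np.pi * expanded[i] ** 2
    return total


def _atom_geometry(struct: DimerStructure, chain: str):
    pos, rad = [], []
    for atom in struct.atoms(chain):
        if atom.element not in VDW_RADII:
            raise ValueError(
                f"unknown element radius for atom {atom.atom_name} "
                f"({atom.element}) in residue {atom.residue_index} chain {atom.chain_id}"
            )
        pos.append(atom.position)
        rad.append(VDW_RADII[atom.element])
    return np.array(pos).reshape(-1, 3), np.array(rad)


def interface_area(struct: DimerStructure, n_points: int = 960, probe: float = 1.4) -> float:
    """Interface area: (SASA(A) + SASA(B) − SASA(AB)) / 2, clipped at 0.

    SASA uses Shrake–Rupley sampling with ``n_points`` sphere points per
    atom, probe radius 1.4 Å, and standard element radii
    (C 1.70, N 1.55, O 1.52, S 1.80 Å).
    """
    pos_a, rad_a = _atom_geometry(struct, "a")
    pos_b, rad_b = _atom_geometry(struct, "b")
    sasa_a = _sasa(pos_a, rad_a, n_points, probe)
    sasa_b = _sasa(pos_b, rad_b, n_points, probe)
    sasa_ab = _sasa(
        np.vstack([pos_a, pos_b]), np.concatenate([rad_a, rad_b]), n_points, probe
    )
    return max(0.0, (sasa_a + sasa_b - sasa_ab) / 2.0)


def summarize_interface(struct: DimerStructure, n_points: int = 960) -> InterfaceSummary:
    contacts = residue_contacts(struct)
    return InterfaceSummary(
        contact_count=len(contacts),
        contact_list=contacts,
        interface_area=interface_area(struct, n_points=n_points),
        direct=classify_direct(len(contacts)),
    )
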