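"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from contactome.io_formats import AtomRecord, DimerStructure, Residue

# ---------------------------------------------------------------------------
# Hand-built micro-dimers


def build_dimer(atoms_a, atoms_b, chain_ids=("A", "B")) -> DimerStructure:
    """Build a dimer from tuples (residue_index, residue_name, atom_name,
    element, (x, y, z)) per chain."""

    def chain(atom_tuples, chain_id):
        residues: dict[int, Residue] = {}
        for residx, resname, atomname, element, pos in atom_tuples:
            res = residues.setdefault(residx, Residue(index=residx, name=resname))
            res.atoms.append(
                AtomRecord(
                    chain_id=chain_id,
                    residue_index=residx,
                    residue_name=resname,
                    atom_name=atomname,
                    element=element,
                    position=np.array(pos, dtype=float),
                )
            )
        return [residues[i] for i in sorted(residues)]

    return DimerStructure(
        chain_a=chain(atoms_a, chain_ids[0]),
        chain_b=chain(atoms_b, chain_ids[1]),
        pair_label="test",
        chain_ids=chain_ids,
    )


def random_micro_dimer(rng: np.random.Generator, max_atoms_per_chain: int = 250) -> DimerStructure:
    """A random blob of C/N/O/S atoms per chain, close enough that many
    inter-chain pairs fall inside the interaction cutoffs."""
    elements = np.array(["C", "N", "O", "S"])
    atom_names = {"C": "CA", "N": "N", "O": "O", "S": "SG"}

    def chain(n_atoms, offset):
        atoms = []
        n_res = max(1, n_atoms // 3)
        for i in range(n_atoms):
            residx = i % n_res + 1
            elem = str(elements[rng.integers(0, 4)])
            resname = "CYS" if elem == "S" and rng.random() < 0.7 else "ALA"
            pos = rng.uniform(0, 15, size=3) + offset
            atoms.append((residx, resname, atom_names[elem], elem, tuple(pos)))
        # sort so residue indices appear grouped (builder handles any order)
        return atoms

    n_a = int(rng.integers(10, max_atoms_per_chain + 1))
    n_b = int(rng.integers(10, max_atoms_per_chain + 1))
    return build_dimer(chain(n_a, 0.0), chain(n_b, np.array([3.0, 0.0, 0.0])))


# ---------------------------------------------------------------------------
# Independent oracles


def brute_force_residue_contacts(struct: DimerStructure):
    """Literal double loop over all inter-chain atom pairs applying the four
    distance rules; returns {frozenset-free residue pair: set of classes}."""
    contacts: dict[tuple, set] = {}
    for res_a in struct.chain_a:
        for atom_a in res_a.atoms:
            for res_b in struct.chain_b:
                for atom_b in res_b.atoms:
                    d = float(np.linalg.norm(atom_a.position - atom_b.position))
                    classes = set()
                    if (
                        atom_a.element == "S"
                        and atom_b.element == "S"
                        and res_a.name == "CYS"
                        and res_b.name == "CYS"
                        and d <= 2.56
                    ):
                        classes.add("disulfide")
                    if {atom_a.element, atom_b.element} == {"N", "O"}:
                        if d <= 3.5:
                            classes.add("hydrogen_bond")
                        if d <= 5.5:
                            classes.add("salt_bridge")
                    if atom_a.element == "C" and atom_b.element == "C" and d <= 5.0:
                        classes.add("van_der_waals")
                    if classes:
                        key = (
                            (struct.chain_ids[0], res_a.index),
                            (struct.chain_ids[1], res_b.index),
                        )
                        contacts.setdefault(key, set()).update(classes)
    return contacts


def fisher_enumeration_oracle(table, alternative: str = "two-sided") -> float:
    """Exact-integer Fisher p by enumerating the conditional distribution.

    pmf(k) ∝ C(row1, k)·C(row2, col1−k); comparisons between pmf values are
    done on the exact integer numerators, so two-sided tie handling is exact.
    """
    from math import comb

    (a, b), (c, d) = table
    n = a + b + c + d
    if n == 0:
        return 1.0
    row1, row2, col1 = a + b, c + d, a + c
    ks = range(max(0, col1 - row2), min(row1, col1) + 1)
    nums = {k: comb(row1, k) * comb(row2, col1 - k) for k in ks}
    denom = comb(n, col1)
    if alternative == "two-sided":
        total = sum(v for v in nums.values() if v <= nums[a])
    elif alternative == "less":
        total = sum(v for k, v in nums.items() if k <= a)
    elif alternative == "greater":
        total = sum(v for k, v in nums.items() if k >= a)
    else:
        raise ValueError(alternative)
    return total / denom


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
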