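"""Domain containers and file-format I/O.

This module owns the in-memory representations used across the toolkit
(dimer structures, AlphaFold-style confidence bundles, PPI pair sets,
literature evidence records) and the parsing/serialization for the external
formats they live in: PDB/mmCIF (via gemmi), AlphaFold PAE JSON, and TSV
tables for edge lists, evidence, profiles, and the reduced MI ontology.

No science happens here — only faithful reading and writing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from ._util import normalize_pair

__all__ = [
    "AtomRecord",
    "Residue",
    "DimerStructure",
    "ConfidenceBundle",
    "EvidenceRecord",
    "PPIDataset",
    "read_structure",
    "write_structure",
    "read_pae_bundle",
    "write_pae_bundle",
    "read_pairs_table",
    "write_pairs_table",
    "read_evidence_table",
    "read_ontology_table",
]


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a residue: label, element and Cartesian position in Å."""

    chain_id: str
    residue_index: int
    residue_name: str
    atom_name: str
    element: str
    position: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.atom_name}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)


@dataclass
class Residue:
    """A residue: 1-based internal index, 3-letter name, and its atoms.

    ``author_index`` retains the numbering found in the source file; the
    internal ``index`` is contiguous 1..n per chain so that it can line up
    with PAE matrix rows directly.
    """

    index: int
    name: str
    atoms: list[AtomRecord] = field(default_factory=list)
    author_index: int | None = None

    def atom(self, atom_name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.atom_name == atom_name:
                return a
        return None


@dataclass
class DimerStructure:
    """Two labeled chains of residues forming one complex.

    The two chains must carry distinct chain identifiers; residue indices are
    strictly increasing within each chain and every residue holds at least
    one atom.
    """

    chain_a: list[Residue]
    chain_b: list[Residue]
    pair_label: str = ""
    chain_ids: tuple[str, str] = ("A", "B")

    def __post_init__(self):
        if self.chain_ids[0] == self.chain_ids[1]:
            raise ValueError("dimer chains must have two distinct chain_ids")
        for chain in (self.chain_a, self.chain_b):
            idx = [r.index for r in chain]
            if idx != sorted(set(idx)):
                raise ValueError("residue_index must be strictly increasing within a chain")
            if any(len(r.atoms) == 0 for r in chain):
                raise ValueError("every residue must hold at least one atom")

    @property
    def n_residues(self) -> int:
        return len(self.chain_a) + len(self.chain_b)

    def atoms(self, chain: str = "both"):
        chains = {"a": [self.chain_a], "b": [self.chain_b], "both": [self.chain_a, self.chain_b]}[chain]
        for ch in chains:
            for res in ch:
                yield from res.atoms

    def swapped(self) -> "DimerStructure":
        """The same complex with the chain roles exchanged."""
        return DimerStructure(
            chain_a=self.chain_b,
            chain_b=self.chain_a,
            pair_label=self.pair_label,
            chain_ids=(self.chain_ids[1], self.chain_ids[0]),
        )


@dataclass
class ConfidenceBundle:
    """Predicted-structure confidence outputs for one dimer.

    pae is the full (chain_a + chain_b)-residue square matrix in Å with the
    AlphaFold JSON convention: row i = aligned ("anchor") residue, column j =
    scored residue; the matrix may be asymmetric. plddt is per-residue on
    [0, 100]; iptm/ptm are scalars on [0, 1]. ``chain_a_len`` splits the
    matrix index space between the two chains.
    """

    pae: np.ndarray
    plddt: np.ndarray
    iptm: float
    ptm: float
    chain_a_len: int

    def __post_init__(self):
        self.pae = np.asarray(self.pae, dtype=float)
        self.plddt = np.asarray(self.plddt, dtype=float)
        n, m = self.pae.shape if self.pae.ndim == 2 else (-1, -2)
        if n != m:
            raise ValueError("PAE matrix must be square")
        if not (0 < self.chain_a_len < n):
            raise ValueError("chain_a_len must split the PAE index space")
        if not np.all(np.isfinite(self.pae)) or np.any(self.pae < 0):
            raise ValueError("PAE values must be finite and non-negative")
        if len(self.plddt) != n:
            raise ValueError("plddt length must match PAE dimension")

    @property
    def n_residues(self) -> int:
        return self.pae.shape[0]

    @property
    def chain_b_len(self) -> int:
        return self.n_residues - self.chain_a_len


@dataclass(frozen=True)
class EvidenceRecord:
    """One piece of literature evidence: pair + PubMed ID + PSI-MI method term."""

    pair: tuple[str, str]
    pubmed_id: str
    mi_term: str

    def __post_init__(self):
        object.__setattr__(self, "pair", normalize_pair(*self.pair))


@dataclass
class PPIDataset:
    """A named set of unordered protein pairs.

    Pairs are stored sorted-tuple normalized with duplicates collapsed;
    self-pairs (x, x) are kept separately as flagged homodimers since most
    downstream analyses exclude them.
    """

    name: str
    pairs: set[tuple[str, str]] = field(default_factory=set)
    homodimers: set[str] = field(default_factory=set)
    release_date: pd.Timestamp | None = None

    def add(self, a: str, b: str) -> None:
        a, b = normalize_pair(a, b)
        if a == b:
            self.homodimers.add(a)
        else:
            self.pairs.add((a, b))

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair) -> bool:
        return normalize_pair(*pair) in self.pairs


# ---------------------------------------------------------------------------
# Structures (PDB / mmCIF)

def _best_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties broken by altloc label order
    return sorted(atoms, key=lambda a: (-a.occ, a.altloc))[0]


def read_structure(path, chain_select: tuple[str, str] | None = None) -> DimerStructure:
    """Read a dimer from a PDB or mmCIF file.

    Heteroatoms and waters are excluded; alternate locations are resolved to
    the highest-occupancy conformer. Residues are re-indexed 1..n per chain
    (author numbering kept as metadata). ``chain_select`` picks two chains by
    label from a larger assembly; by default the file must contain exactly
    two chains.
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    model = st[0]
    chains = {ch.name: ch for ch in model}
    if chain_select is not None:
        missing = [c for c in chain_select if c not in chains]
        if missing:
            raise KeyError(f"chain not found: {', '.join(missing)}")
        selected = [chains[c] for c in chain_select]
    else:
        selected = list(model)
        if len(selected) < 2:
            raise ValueError(f"not a dimer: file has {len(selected)} chain(s)")
        if len(selected) > 2:
            raise ValueError(
                f"not a dimer: file has {len(selected)} chains; use chain_select"
            )

    parsed: list[list[Residue]] = []
    for ch in selected:
        residues: list[Residue] = []
        idx = 0
        for res in ch:
            if res.is_water() or res.het_flag == "H":
                continue
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in res:
                by_name.setdefault(atom.name, []).append(atom)
            atoms = []
            idx += 1
            for name, copies in by_name.items():
                atom = _best_altloc(copies)
                pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                atoms.append(
                    AtomRecord(
                        chain_id=ch.name,
                        residue_index=idx,
                        residue_name=res.name,
                        atom_name=name,
                        element=atom.element.name.upper(),
                        position=pos,
                    )
                )
            if not atoms:
                idx -= 1
                continue
            residues.append(
                Residue(index=idx, name=res.name, atoms=atoms, author_index=res.seqid.num)
            )
        if not residues:
            raise ValueError(f"chain {ch.name} has no polymer residues")
        parsed.append(residues)

    return DimerStructure(
        chain_a=parsed[0],
        chain_b=parsed[1],
        pair_label=Path(str(path)).stem,
        chain_ids=(selected[0].name, selected[1].name),
    )


def write_structure(struct: DimerStructure, path) -> None:
    """Serialize a dimer as minimal PDB text (ATOM records only)."""
    lines = []
    serial = 0
    for chain_id, chain in ((struct.chain_ids[0], struct.chain_a), (struct.chain_ids[1], struct.chain_b)):
        for res in chain:
            num = res.author_index if res.author_index is not None else res.index
            for atom in res.atoms:
                serial += 1
                name = atom.atom_name
                # PDB columns: 4-char atom name field, element-justified
                name_field = f" {name:<3s}" if len(name) < 4 else name
                x, y, z = atom.position
                lines.append(
                    f"ATOM  {serial:5d} {name_field}{'':1s}{res.name:<3s} {chain_id:1s}"
                    f"{num:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}"
                )
        lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# AlphaFold-style PAE bundles (JSON)

def read_pae_bundle(path, chain_a_len: int) -> ConfidenceBundle:
    """Read a confidence bundle from AlphaFold-dialect JSON.

    The file must carry a top-level square ``predicted_aligned_error`` 2D
    list; ``plddt``, ``iptm`` and ``ptm`` are read if present (defaulting to
    zeros). Values are preserved bit-exact.
    """
    data = json.loads(Path(path).read_text())
    if isinstance(data, list):  # AlphaFold DB wraps the object in a list
        data = data[0]
    pae_list = data["predicted_aligned_error"]
    lengths = {len(row) for row in pae_list}
    if len(lengths) != 1 or lengths.pop() != len(pae_list):
        raise ValueError("predicted_aligned_error is not a square matrix")
    pae = np.array(pae_list, dtype=float)
    n = pae.shape[0]
    plddt = np.asarray(data.get("plddt", np.zeros(n)), dtype=float)
    return ConfidenceBundle(
        pae=pae,
        plddt=plddt,
        iptm=float(data.get("iptm", 0.0)),
        ptm=float(data.get("ptm", 0.0)),
        chain_a_len=chain_a_len,
    )


def write_pae_bundle(bundle: ConfidenceBundle, path) -> None:
    payload = {
        "predicted_aligned_error": bundle.pae.tolist(),
        "plddt": bundle.plddt.tolist(),
        "iptm": bundle.iptm,
        "ptm": bundle.ptm,
    }
    Path(path).write_text(json.dumps(payload))


# ---------------------------------------------------------------------------
# Tabular formats (TSV)

def read_pairs_table(path, name: str | None = None) -> PPIDataset:
    """Read a two-column TSV edge list into an unordered, deduplicated dataset."""
    dataset = PPIDataset(name=name or Path(str(path)).stem)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise ValueError(f"{path}:{lineno}: malformed row: {line!r}")
            dataset.add(fields[0], fields[1])
    return dataset


def write_pairs_table(dataset: PPIDataset, path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(dataset.pairs):
            fh.write(f"{a}\t{b}\n")
        for h in sorted(dataset.homodimers):
            fh.write(f"{h}\t{h}\n")


def read_evidence_table(path) -> list[EvidenceRecord]:
    """Read an evidence TSV with columns id_a, id_b, pubmed_id, mi_term."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"id_a", "id_b", "pubmed_id", "mi_term"}
    if not required.issubset(df.columns):
        raise ValueError(f"evidence table must have columns {sorted(required)}")
    return [
        EvidenceRecord(pair=(row.id_a, row.id_b), pubmed_id=row.pubmed_id, mi_term=row.mi_term)
        for row in df.itertuples()
    ]


def read_ontology_table(path):
    """Read a reduced MI-ontology TSV (term_id, parent_id, category).

    Returns (parent_map, category_map); parent_id may be empty for roots.
    Categories are the interaction-detection classes: invalid, binary,
    co_complex.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    parent_map: dict[str, set[str]] = {}
    category_map: dict[str, str] = {}
    for row in df.itertuples():
        parent_map.setdefault(row.term_id, set())
        if row.parent_id:
            parent_map[row.term_id].add(row.parent_id)
        if getattr(row, "category", ""):
            category_map[row.term_id] = row.category
    return parent_map, category_map
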