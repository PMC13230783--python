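"""Synthetic fixtures with planted ground truth for every pipeline stage.

Each generator is deterministic under a fixed integer seed (NumPy integer
RNG streams only — no hash-order dependence) and plants a known truth that
the consuming stage must recover exactly under noise-free settings: dimer
structures with a chosen number of interface contacts, PAE bundles with a
chosen confident-contact count, assay outcome tables with a chosen
reference-set sensitivity, scale-free or modular networks with planted
module annotations, and literature evidence tables with known Lit-BM/BS/CC
labels.

The geometry is deliberately minimal (two-carbon residues on a straight
backbone): contacts are planted through the van der Waals C–C ≤ 5 Å rule
alone, with every non-planted residue pair kept at least 8 Å away.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .assay_stats import AssayOutcome
from .dataset_assembly import MiOntology
from .io_formats import AtomRecord, ConfidenceBundle, DimerStructure, EvidenceRecord, Residue
from .structural_contacts import residue_contacts

__all__ = [
    "make_dimer",
    "make_bundle",
    "make_assay_outcomes",
    "SyntheticNetwork",
    "make_network",
    "toy_mi_ontology",
    "make_evidence_table",
]

_CONTACT_Y = 4.0  # Å between planted partner residues (< 5.0 C–C cutoff)
_APART_Y = 20.0  # Å for unplanted partners (> any cutoff + jitter)
_SPACING = 10.0  # Å along the backbone (adjacent cross-pairs stay > 8 Å)


def _residue(chain_id: str, index: int, ca: np.ndarray) -> Residue:
    atoms = [
        AtomRecord(chain_id, index, "ALA", "CA", "C", ca),
        AtomRecord(chain_id, index, "ALA", "CB", "C", ca + np.array([0.0, 0.0, 1.5])),
    ]
    return Residue(index=index, name="ALA", atoms=atoms)


def make_dimer(
    n_residues: int,
    n_planted_contacts: int,
    geometry: str = "docked",
    seed: int = 0,
) -> DimerStructure:
    """A toy dimer with exactly ``n_planted_contacts`` residue contacts.

    Two poly-alanine-like chains (CA + CB carbons per residue) run parallel
    along x at 10 Å spacing; the first ``n_planted_contacts`` residue pairs
    of chain B sit 4 Å from their chain A partners (within the C–C ≤ 5 Å
    rule), all other inter-chain residue pairs ≥ 8 Å apart.
    ``geometry="separated"`` places the chains 200 Å apart (no contacts, no
    interface). Coordinates carry a small seeded jitter; the same seed gives
    identical coordinates.
    """
    if geometry not in ("docked", "separated"):
        raise ValueError(f"unknown geometry {geometry!r}")
    if not (0 <= n_planted_contacts <= n_residues):
        raise ValueError(
            f"infeasible geometry: cannot plant {n_planted_contacts} contacts "
            f"on {n_residues}-residue chains"
        )
    rng = np.random.default_rng(seed)
    jitter = lambda: rng.uniform(-0.2, 0.2, size=3)  # noqa: E731

    chain_a = [
        _residue("A", i + 1, np.array([_SPACING * i, 0.0, 0.0]) + jitter())
        for i in range(n_residues)
    ]
    chain_b = []
    for i in range(n_residues):
        if geometry == "separated":
            y = 200.0
        else:
            y = _CONTACT_Y if i < n_planted_contacts else _APART_Y
        ca = np.array([_SPACING * i, y, 0.0]) + jitter()
        chain_b.append(_residue("B", i + 1, ca))
    return DimerStructure(
        chain_a=chain_a,
        chain_b=chain_b,
        pair_label=f"synthetic_{n_residues}_{n_planted_contacts}_{geometry}",
        chain_ids=("A", "B"),
    )


def make_bundle(
    struct: DimerStructure,
    n_confident: int,
    confident_pae: float = 2.0,
    background_pae: float = 20.0,
    seed: int = 0,
) -> ConfidenceBundle:
    """A confidence bundle planting ``n_confident`` confident contacts.

    Exactly ``n_confident`` of the structure's residue contacts receive PAE
    = ``confident_pae`` in both orientations; everything else gets
    ``background_pae`` with ±2 Å seeded noise (still far above the 4 Å
    confidence cutoff). pLDDT is drawn on [70, 95], ipTM/pTM on [0.5, 0.9].
    """
    contacts = residue_contacts(struct)
    if n_confident > len(contacts):
        raise ValueError(
            f"cannot plant {n_confident} confident contacts: structure has "
            f"only {len(contacts)} residue contacts"
        )
    rng = np.random.default_rng(seed)
    n_a = len(struct.chain_a)
    n = struct.n_residues
    pae = background_pae + rng.uniform(-2.0, 2.0, size=(n, n))
    offset = {struct.chain_ids[0]: 0, struct.chain_ids[1]: n_a}
    for contact in contacts[:n_confident]:
        (ch_a, ra), (ch_b, rb) = contact.residue_a, contact.residue_b
        i, j = offset[ch_a] + ra - 1, offset[ch_b] + rb - 1
        pae[i, j] = confident_pae
        pae[j, i] = confident_pae
    return ConfidenceBundle(
        pae=pae,
        plddt=rng.uniform(70.0, 95.0, size=n),
        iptm=float(rng.uniform(0.5, 0.9)),
        ptm=float(rng.uniform(0.5, 0.9)),
        chain_a_len=n_a,
    )


def make_assay_outcomes(
    n_prs: int,
    n_rrs: int,
    n_test: int = 0,
    sensitivity: float = 0.22,
    test_positive_rate: float = 0.1,
    seed: int = 0,
) -> dict[str, list[AssayOutcome]]:
    """Synthetic quantitative assay outcomes for PRS/RRS/test pair sets.

    Random-reference (RRS) pairs all score below the planted positives, so
    thresholding at the top RRS score reproduces the planted calls: each
    positive-reference (PRS) pair is positive with probability
    ``sensitivity`` (the assay's sensitivity), test pairs with
    ``test_positive_rate``.
    """
    if not (0 <= sensitivity <= 1):
        raise ValueError("sensitivity must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    rrs_scores = rng.uniform(0.5, 1.5, size=n_rrs)
    threshold = rrs_scores.max() if n_rrs else 1.5

    def draw(dataset: str, count: int, rate: float):
        outcomes = []
        for i in range(count):
            positive = rng.random() < rate
            score = (
                threshold + rng.uniform(0.5, 5.0)
                if positive
                else rng.uniform(0.05, threshold)
            )
            outcomes.append(
                AssayOutcome(pair=(f"{dataset}a{i:04d}", f"{dataset}b{i:04d}"),
                             dataset=dataset, score=float(score))
            )
        return outcomes

    return {
        "rrs": [
            AssayOutcome(pair=(f"rrsa{i:04d}", f"rrsb{i:04d}"), dataset="rrs", score=float(s))
            for i, s in enumerate(rrs_scores)
        ],
        "prs": draw("prs", n_prs, sensitivity),
        "test": draw("test", n_test, test_positive_rate),
    }


@dataclass
class SyntheticNetwork:
    """A generated network plus its planted ground truth (when modular)."""

    graph: nx.Graph
    modules: dict | None = None
    annotations: dict = field(default_factory=dict)


def make_network(
    n_nodes: int,
    model: str = "scale_free",
    params: dict | None = None,
    seed: int = 0,
) -> SyntheticNetwork:
    """A synthetic simple graph: preferential-attachment ("scale_free") or
    planted-partition ("modular").

    The modular model plants dense within-module edges (``p_in``) against a
    sparse background (``p_out``) and annotates ``annotation_rate`` of each
    module's nodes with that module's term.
    """
    params = dict(params or {})
    names = [f"g{i:04d}" for i in range(n_nodes)]
    if model == "scale_free":
        m = params.get("m", 2)
        if n_nodes <= m:
            g = nx.empty_graph(n_nodes)
        else:
            g = nx.barabasi_albert_graph(n_nodes, m, seed=int(seed))
        g = nx.relabel_nodes(g, dict(enumerate(names)))
        return SyntheticNetwork(graph=g)
    if model == "modular":
        n_modules = params.get("n_modules", 4)
        p_in = params.get("p_in", 0.4)
        p_out = params.get("p_out", 0.02)
        annotation_rate = params.get("annotation_rate", 0.5)
        rng = np.random.default_rng(seed)
        modules = {name: i % n_modules for i, name in enumerate(names)}
        g = nx.Graph()
        g.add_nodes_from(names)
        for i in range(n_nodes):
            for j in range(i + 1, n_nodes):
                p = p_in if modules[names[i]] == modules[names[j]] else p_out
                if rng.random() < p:
                    g.add_edge(names[i], names[j])
        annotations = {
            name: {f"term_m{modules[name]}"}
            for name in names
            if rng.random() < annotation_rate
        }
        return SyntheticNetwork(graph=g, modules=modules, annotations=annotations)
    raise ValueError(f"unknown network model {model!r}")


# ---------------------------------------------------------------------------
# Literature evidence

def toy_mi_ontology() -> MiOntology:
    """A five-term MI-like ontology: binary and co-complex branches (parent
    and specific child each) plus one invalid term."""
    parent_map = {
        "MI:0B00": set(),
        "MI:0B01": {"MI:0B00"},
        "MI:0C00": set(),
        "MI:0C01": {"MI:0C00"},
        "MI:0X00": set(),
    }
    category_map = {
        "MI:0B00": "binary",
        "MI:0B01": "binary",
        "MI:0C00": "co_complex",
        "MI:0C01": "co_complex",
        "MI:0X00": "invalid",
    }
    return MiOntology(parent_map=parent_map, category_map=category_map)


def make_evidence_table(
    n_pairs: int,
    label_mix: dict[str, float] | None = None,
    duplication_rate: float = 0.2,
    seed: int = 0,
):
    """Evidence records with planted Lit-BM/BS/CC/excluded labels.

    Each pair draws a target label from ``label_mix`` and gets evidence
    constructed to guarantee it; with probability ``duplication_rate`` one
    record is additionally duplicated under the same PubMed ID using its
    parent/child term variant (which merging must collapse without changing
    the label). Returns (records, truth_labels, ontology).
    """
    label_mix = label_mix or {"Lit-BM": 0.3, "Lit-BS": 0.3, "Lit-CC": 0.3, "excluded": 0.1}
    if abs(sum(label_mix.values()) - 1.0) > 1e-9:
        raise ValueError("label_mix probabilities must sum to 1")
    rng = np.random.default_rng(seed)
    labels = list(label_mix)
    probs = np.array([label_mix[label] for label in labels])
    ontology = toy_mi_ontology()
    records: list[EvidenceRecord] = []
    truth: dict[tuple, str] = {}
    pub_counter = 0

    def pub():
        nonlocal pub_counter
        pub_counter += 1
        return f"PM{pub_counter:06d}"

    for i in range(n_pairs):
        pair = (f"ya{i:04d}", f"yb{i:04d}")
        label = labels[rng.choice(len(labels), p=probs)]
        truth[pair] = label
        if label == "Lit-BM":
            second = "MI:0C01" if rng.random() < 0.5 else "MI:0B00"
            new = [
                EvidenceRecord(pair, pub(), "MI:0B01"),
                EvidenceRecord(pair, pub(), second),
            ]
        elif label == "Lit-BS":
            term = "MI:0B01" if rng.random() < 0.5 else "MI:0B00"
            new = [EvidenceRecord(pair, pub(), term)]
        elif label == "Lit-CC":
            new = [EvidenceRecord(pair, pub(), "MI:0C01")]
            if rng.random() < 0.5:
                # extra invalid evidence must not change the Lit-CC label:
                # only co-complex evidence remains after filtering
                new.append(EvidenceRecord(pair, pub(), "MI:0X00"))
        else:  # excluded: invalid-only
            new = [EvidenceRecord(pair, pub(), "MI:0X00")]
        if rng.random() < duplication_rate:
            first = new[0]
            parents = ontology.parent_map.get(first.mi_term, set())
            variant = next(iter(parents)) if parents else first.mi_term
            new.append(EvidenceRecord(pair, first.pubmed_id, variant))
        records.extend(new)
    return records, truth, ontology
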