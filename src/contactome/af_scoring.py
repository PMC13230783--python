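"""Predicted-structure confidence metrics and interaction-calling cutoffs.

Five metrics summarize how much to trust a predicted dimer structure:

1. model confidence = 0.8·ipTM + 0.2·pTM,
2. contact probability = max inter-chain residue-pair probability of being
   closer than 12 Å (consumed as a supplied matrix, not recomputed),
3. pDockQ — logistic function of mean interface pLDDT × log(interface
   CB–CB ≤ 8 Å contact count),
4. iPAE — median predicted aligned error over the interface residue pairs,
5. CCC (confident contacts count) — the number of residue-residue contacts
   whose associated PAE is ≤ 4 Å. The associated PAE of an asymmetric pair
   (i, j) is min(PAE[i,j], PAE[j,i]) by default: confidence in at least one
   alignment direction. A dimer is called interacting when CCC ≥ 5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io_formats import ConfidenceBundle, DimerStructure
from .structural_contacts import residue_contacts

__all__ = [
    "MetricSet",
    "CCC_PAE_CUTOFF",
    "CCC_CALL_MIN",
    "model_confidence",
    "contact_probability",
    "ccc",
    "ipae",
    "pdockq",
    "is_interacting",
    "compute_metrics",
    "precision_matched_cutoff",
]

CCC_PAE_CUTOFF = 4.0  # Å, inclusive
CCC_CALL_MIN = 5  # confident contacts needed to call an interaction

# pDockQ logistic constants from its original publication
_PDOCKQ_L = 0.724
_PDOCKQ_K = 0.052
_PDOCKQ_X0 = 152.611
_PDOCKQ_B = 0.018


@dataclass
class MetricSet:
    model_confidence: float
    contact_probability: float | None
    pdockq: float
    ipae: float | None
    ccc: int


def model_confidence(iptm: float, ptm: float) -> float:
    """0.8·ipTM + 0.2·pTM."""
    if not (0 <= iptm <= 1 and 0 <= ptm <= 1):
        raise ValueError("iptm and ptm must lie in [0, 1]")
    return 0.8 * iptm + 0.2 * ptm


def contact_probability(prob_matrix: np.ndarray) -> float:
    """Maximum inter-chain residue-pair contact (<12 Å) probability.

    The matrix is supplied externally (chain A residues × chain B residues).
    """
    prob = np.asarray(prob_matrix, dtype=float)
    if prob.size == 0:
        raise ValueError("empty contact-probability matrix")
    if prob.min() < 0 or prob.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    return float(prob.max())


def _contact_pae_indices(struct: DimerStructure, bundle: ConfidenceBundle):
    """Global PAE indices (i, j) for each inter-chain residue contact."""
    if bundle.n_residues != struct.n_residues:
        raise ValueError(
            f"PAE dimension {bundle.n_residues} does not match structure "
            f"residue count {struct.n_residues}"
        )
    offset = {struct.chain_ids[0]: 0, struct.chain_ids[1]: bundle.chain_a_len}
    idx = []
    for contact in residue_contacts(struct):
        (ch_a, res_a), (ch_b, res_b) = contact.residue_a, contact.residue_b
        idx.append((offset[ch_a] + res_a - 1, offset[ch_b] + res_b - 1))
    return idx


def ccc(
    struct: DimerStructure,
    bundle: ConfidenceBundle,
    pae_cutoff: float = CCC_PAE_CUTOFF,
    pae_reduce: str = "min",
) -> int:
    """Confident contacts count: residue contacts with associated PAE ≤ cutoff.

    ``pae_reduce`` chooses how the two asymmetric PAE orientations combine
    into one associated value per contact: "min" (default) or "mean".
    """
    reduce = {"min": min, "mean": lambda x, y: (x + y) / 2.0}[pae_reduce]
    count = 0
    for i, j in _contact_pae_indices(struct, bundle):
        if reduce(bundle.pae[i, j], bundle.pae[j, i]) <= pae_cutoff:
            count += 1
    return count


def ipae(struct: DimerStructure, bundle: ConfidenceBundle) -> float:
    """Median interface PAE over both orientations of all contact pairs."""
    idx = _contact_pae_indices(struct, bundle)
    if not idx:
        raise ValueError("no interface: structure has no residue contacts")
    values = [bundle.pae[i, j] for i, j in idx] + [bundle.pae[j, i] for i, j in idx]
    return float(np.median(values))


def _beta_carbon_positions(chain, which: str):
    """CB position per residue (CA for glycine); None when absent."""
    out = []
    for res in chain:
        atom = res.atom("CA") if res.name == "GLY" else res.atom("CB")
        out.append(None if atom is None else atom.position)
    return out


def pdockq(struct: DimerStructure, bundle: ConfidenceBundle, contact_cutoff: float = 8.0) -> float:
    """pDockQ: L / (1 + exp(−k·(x − x0))) + b with x = mean interface
    pLDDT × ln(number of inter-chain CB–CB ≤ 8 Å contacts).

    Returns the baseline b (0.018) when there is no CB-contact interface.
    """
    if bundle.n_residues != struct.n_residues:
        raise ValueError("PAE/pLDDT dimension does not match structure residue count")
    cb_a = _beta_carbon_positions(struct.chain_a, "a")
    cb_b = _beta_carbon_positions(struct.chain_b, "b")
    contacts = []
    for i, pa in enumerate(cb_a):
        if pa is None:
            continue
        for j, pb in enumerate(cb_b):
            if pb is None:
                continue
            if np.linalg.norm(pa - pb) <= contact_cutoff:
                contacts.append((i, j))
    if not contacts:
        return _PDOCKQ_B
    iface_a = sorted({i for i, _ in contacts})
    iface_b = sorted({j for _, j in contacts})
    plddt_iface = np.concatenate(
        [bundle.plddt[iface_a], bundle.plddt[[bundle.chain_a_len + j for j in iface_b]]]
    )
    x = plddt_iface.mean() * math.log(len(contacts))
    return _PDOCKQ_L / (1.0 + math.exp(-_PDOCKQ_K * (x - _PDOCKQ_X0))) + _PDOCKQ_B


def is_interacting(ccc_value: int, min_contacts: int = CCC_CALL_MIN) -> bool:
    """Default binary interaction call: at least 5 confident contacts."""
    return ccc_value >= min_contacts


def compute_metrics(
    struct: DimerStructure,
    bundle: ConfidenceBundle,
    prob_matrix: np.ndarray | None = None,
) -> MetricSet:
    """All five confidence metrics for one predicted dimer."""
    try:
        ipae_value = ipae(struct, bundle)
    except ValueError:
        ipae_value = None
    return MetricSet(
        model_confidence=model_confidence(bundle.iptm, bundle.ptm),
        contact_probability=None if prob_matrix is None else contact_probability(prob_matrix),
        pdockq=pdockq(struct, bundle),
        ipae=ipae_value,
        ccc=ccc(struct, bundle),
    )


def precision_matched_cutoff(
    metric_values_positive,
    metric_values_random,
    higher_is_better: bool = True,
) -> tuple[float, float]:
    """Cutoff matching the precision of experimental assays: no random pair
    may score positive.

    Returns (cutoff, recall): the cutoff is the extreme random score, calls
    are strict (score beyond the cutoff), and recall is the fraction of
    positives called at that cutoff.
    """
    pos = np.asarray(list(metric_values_positive), dtype=float)
    rnd = np.asarray(list(metric_values_random), dtype=float)
    if pos.size == 0 or rnd.size == 0:
        raise ValueError("both positive and random score lists must be non-empty")
    if higher_is_better:
        cutoff = float(rnd.max())
        recall = float((pos > cutoff).mean())
    else:
        cutoff = float(rnd.min())
        recall = float((pos < cutoff).mean())
    return cutoff, recall
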