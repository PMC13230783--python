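"""Interaction-dataset assembly: literature classification, novelty
accounting, and interactome-size meta-estimation.

Literature evidence (pair + PubMed ID + PSI-MI interaction-detection term)
is merged over the MI ontology — duplicate curation of the same publication
with identical or ancestor/descendant terms collapses to the more specific
term — then pairs are partitioned by the character of their remaining
evidence: Lit-BM (≥2 pieces including binary), Lit-BS (a single binary
piece), Lit-CC (co-complex only); pairs whose evidence is all from invalid
detection methods are excluded.

Novelty of a new map is accounted against an ordered hierarchy of prior
knowledge: experimental structures > interolog structures > high-quality
binary datasets > co-complex associations > strictly novel, each pair taking
the first category that contains it.

Interactome-size estimates from independent studies are combined with a
DerSimonian–Laird random-effects model under the Hartung–Knapp–Sidik–
Jonkman (HKSJ) variance correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._util import percent
from .io_formats import EvidenceRecord, PPIDataset

__all__ = [
    "MiOntology",
    "NOVELTY_CATEGORIES",
    "SizeEstimate",
    "merge_evidence",
    "classify_literature",
    "assign_interologs",
    "categorize_novelty",
    "delta_over_baseline",
    "growth_timeline",
    "hksj_meta",
    "coverage",
]

#: precedence order of prior-knowledge categories; a pair takes the first hit
NOVELTY_CATEGORIES = ("exp_structure", "interolog_structure", "hq_binary", "co_complex")

VALID_EVIDENCE_CATEGORIES = {"invalid", "binary", "co_complex"}


@dataclass
class MiOntology:
    """A reduced PSI-MI interaction-detection ontology.

    ``parent_map`` gives each term's direct parents (acyclic);
    ``category_map`` assigns each usable term one of invalid / binary /
    co_complex.
    """

    parent_map: dict[str, set[str]]
    category_map: dict[str, str]

    def __post_init__(self):
        for term, cat in self.category_map.items():
            if cat not in VALID_EVIDENCE_CATEGORIES:
                raise ValueError(f"term {term}: unknown evidence category {cat!r}")
        # cycle check via iterative DFS
        state: dict[str, int] = {}
        for start in self.parent_map:
            if state.get(start):
                continue
            stack = [(start, iter(self.parent_map.get(start, ())))]
            state[start] = 1
            while stack:
                node, it = stack[-1]
                advanced = False
                for parent in it:
                    if state.get(parent) == 1:
                        raise ValueError(f"MI ontology parent graph has a cycle at {parent}")
                    if state.get(parent) != 2:
                        state[parent] = 1
                        stack.append((parent, iter(self.parent_map.get(parent, ()))))
                        advanced = True
                        break
                if not advanced:
                    state[node] = 2
                    stack.pop()

    def ancestors(self, term: str) -> set[str]:
        seen: set[str] = set()
        frontier = set(self.parent_map.get(term, ()))
        while frontier:
            nxt = frontier.pop()
            if nxt not in seen:
                seen.add(nxt)
                frontier |= set(self.parent_map.get(nxt, ()))
        return seen

    def is_ancestor(self, candidate: str, of: str) -> bool:
        return candidate in self.ancestors(of)

    def category(self, term: str) -> str:
        if term not in self.category_map:
            raise KeyError(f"MI term not categorized in ontology: {term}")
        return self.category_map[term]


def merge_evidence(records: list[EvidenceRecord], ontology: MiOntology) -> list[EvidenceRecord]:
    """Collapse duplicated curation of the same publication.

    Within one (pair, PubMed ID) group, records whose terms are identical or
    ancestor/descendant merge into a single record carrying the more
    specific (descendant) term; unrelated terms within the group survive
    separately.
    """
    for rec in records:
        if rec.mi_term not in ontology.category_map and rec.mi_term not in ontology.parent_map:
            raise KeyError(f"MI term not in ontology: {rec.mi_term}")
    groups: dict[tuple, list[str]] = {}
    order: list[tuple] = []
    for rec in records:
        key = (rec.pair, rec.pubmed_id)
        if key not in groups:
            order.append(key)
        groups.setdefault(key, []).append(rec.mi_term)
    merged: list[EvidenceRecord] = []
    for key in order:
        pair, pubmed = key
        kept: list[str] = []
        for term in groups[key]:
            dominated = False
            for i, other in enumerate(kept):
                if term == other or ontology.is_ancestor(term, other):
                    dominated = True  # other is equal or more specific
                    break
                if ontology.is_ancestor(other, term):
                    kept[i] = term  # term is more specific; replace
                    dominated = True
                    break
            if not dominated:
                kept.append(term)
        merged.extend(EvidenceRecord(pair=pair, pubmed_id=pubmed, mi_term=t) for t in kept)
    return merged


def classify_literature(
    records: list[EvidenceRecord], ontology: MiOntology, merged: bool = False
) -> dict[tuple[str, str], str]:
    """Partition pairs into Lit-BM / Lit-BS / Lit-CC / excluded.

    Evidence from invalid detection methods is dropped before counting.
    Pairs with ≥2 remaining pieces including at least one binary are Lit-BM;
    a single binary piece and nothing else is Lit-BS; no binary evidence at
    all (but some co-complex) is Lit-CC; nothing left is excluded.
    """
    if not merged:
        records = merge_evidence(records, ontology)
    by_pair: dict[tuple, list[str]] = {}
    for rec in records:
        by_pair.setdefault(rec.pair, []).append(ontology.category(rec.mi_term))
    labels: dict[tuple, str] = {}
    for pair, cats in by_pair.items():
        cats = [c for c in cats if c != "invalid"]
        n_binary = sum(c == "binary" for c in cats)
        if not cats:
            labels[pair] = "excluded"
        elif n_binary == 0:
            labels[pair] = "Lit-CC"
        elif len(cats) == 1:
            labels[pair] = "Lit-BS"
        else:
            labels[pair] = "Lit-BM"
    return labels


def assign_interologs(pair_hits, pairs) -> dict[tuple[str, str], set[str]]:
    """Map pairs to structures supporting them as interologs.

    ``pair_hits`` is an iterable of (protein, structure_id, chain_id)
    alignment hits (pre-filtered by the supplier, e.g. E ≤ 1e−5). A pair is
    an interolog of structure S iff two *different* chains of S are hit by
    the two proteins (for a homodimer: by the one protein twice).
    """
    hits: dict[str, dict[str, set[str]]] = {}
    for protein, structure, chain in pair_hits:
        hits.setdefault(protein, {}).setdefault(structure, set()).add(chain)
    out: dict[tuple, set[str]] = {}
    for pair in pairs:
        p, q = pair
        supported: set[str] = set()
        if p == q:
            for structure, chains in hits.get(p, {}).items():
                if len(chains) >= 2:
                    supported.add(structure)
        else:
            shared = set(hits.get(p, {})) & set(hits.get(q, {}))
            for structure in shared:
                chains_p, chains_q = hits[p][structure], hits[q][structure]
                if len(chains_p | chains_q) >= 2:
                    supported.add(structure)
        if supported:
            out[pair] = supported
    return out


def categorize_novelty(dataset: PPIDataset, reference_sets: dict[str, set]):
    """Assign each pair its novelty category and count the partition.

    ``reference_sets`` maps category name → pair set, in precedence order
    (insertion order respected; defaults to NOVELTY_CATEGORIES order when
    those names are used). A pair takes the first category whose set
    contains it, else "strictly_novel". Counts always partition the dataset.
    """
    per_pair: dict[tuple, str] = {}
    counts = {name: 0 for name in reference_sets}
    counts["strictly_novel"] = 0
    for pair in dataset.pairs:
        for name, ref in reference_sets.items():
            if pair in ref:
                per_pair[pair] = name
                break
        else:
            per_pair[pair] = "strictly_novel"
        counts[per_pair[pair]] += 1
    return per_pair, counts


def delta_over_baseline(novel_count: int, known_count: int) -> int:
    """A dataset's delta beyond prior knowledge, as an integer percentage."""
    if known_count <= 0:
        raise ValueError("baseline of known pairs must be positive")
    return percent(novel_count, known_count)


def growth_timeline(datasets: list[PPIDataset]) -> pd.DataFrame:
    """Cumulative growth of unique pairs over release dates.

    Returns one row per dataset (sorted by release date) with its novel
    contribution (pairs absent from all earlier releases), the cumulative
    unique-pair count, and the delta percentage over the prior cumulative
    total (NA for the first release).
    """
    dated = [d for d in datasets]
    if any(d.release_date is None for d in dated):
        raise ValueError("all datasets need a release_date for the timeline")
    dated.sort(key=lambda d: (pd.Timestamp(d.release_date), d.name))
    seen: set = set()
    rows = []
    for d in dated:
        novel = d.pairs - seen
        known_before = len(seen)
        delta = percent(len(novel), known_before) if known_before else np.nan
        seen |= d.pairs
        rows.append(
            {
                "name": d.name,
                "date": pd.Timestamp(d.release_date),
                "size": len(d.pairs),
                "novel": len(novel),
                "cumulative": len(seen),
                "delta_pct": delta,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Interactome-size meta-estimation

@dataclass
class SizeEstimate:
    """An interactome-size estimate with its 95% confidence interval."""

    central: float
    ci_low: float
    ci_high: float
    includes_homodimers: bool = True
    label: str = ""

    def __post_init__(self):
        if not (self.ci_low <= self.central <= self.ci_high):
            raise ValueError("need ci_low <= central <= ci_high")

    @property
    def se(self) -> float:
        """Standard error recovered from the symmetric-normal 95% CI."""
        return (self.ci_high - self.ci_low) / (2.0 * 1.96)


def hksj_meta(estimates: list[SizeEstimate], alpha: float = 0.05) -> SizeEstimate:
    """Random-effects meta-estimate with the HKSJ variance correction.

    Between-study variance τ² by DerSimonian–Laird; inverse-variance weights
    1/(v_i + τ²); the combined variance uses the Hartung–Knapp–Sidik–
    Jonkman correction q/Σw* with a t(k−1) interval.
    """
    if len(estimates) < 2:
        warnings.warn("hksj_meta: single estimate returned unchanged")
        return estimates[0]
    y = np.array([e.central for e in estimates], dtype=float)
    v = np.array([e.se**2 for e in estimates], dtype=float)
    k = len(y)
    w = 1.0 / v
    mu_fixed = (w * y).sum() / w.sum()
    q_stat = (w * (y - mu_fixed) ** 2).sum()
    tau2 = max(0.0, (q_stat - (k - 1)) / (w.sum() - (w**2).sum() / w.sum()))
    w_star = 1.0 / (v + tau2)
    mu = (w_star * y).sum() / w_star.sum()
    q_hksj = (w_star * (y - mu) ** 2).sum() / (k - 1)
    se = np.sqrt(q_hksj / w_star.sum())
    t_crit = stats.t(df=k - 1).ppf(1.0 - alpha / 2.0)
    return SizeEstimate(
        central=float(mu),
        ci_low=float(mu - t_crit * se),
        ci_high=float(mu + t_crit * se),
        includes_homodimers=all(e.includes_homodimers for e in estimates),
        label="HKSJ combined",
    )


def coverage(dataset_size: int, estimate: SizeEstimate) -> tuple[float, float, float]:
    """Fraction of the estimated complete interactome covered by a dataset.

    Returns (fraction, low, high) with the interval taken from the
    estimate's CI: size/ci_high .. size/ci_low.
    """
    if estimate.central <= 0:
        raise ValueError("size estimate must be positive")
    return (
        dataset_size / estimate.central,
        dataset_size / estimate.ci_high,
        dataset_size / estimate.ci_low if estimate.ci_low > 0 else np.inf,
    )
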