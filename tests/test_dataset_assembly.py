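import numpy as np
import pandas as pd
import pytest
from scipy.stats import t as t_dist

from contactome import dataset_assembly as da
from contactome.io_formats import EvidenceRecord, PPIDataset
from contactome.synthetic_data import toy_mi_ontology


@pytest.fixture
def ontology():
    return toy_mi_ontology()


class TestMiOntology:
    def test_ancestors_walk_transitively(self):
        ont = da.MiOntology(
            parent_map={"c": {"b"}, "b": {"a"}, "a": set()},
            category_map={"a": "binary", "b": "binary", "c": "binary"},
        )
        assert ont.ancestors("c") == {"a", "b"}
        assert ont.is_ancestor("a", "c") and not ont.is_ancestor("c", "a")

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            da.MiOntology(parent_map={"a": {"b"}, "b": {"a"}},
                          category_map={"a": "binary", "b": "binary"})

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError, match="category"):
            da.MiOntology(parent_map={"a": set()}, category_map={"a": "bogus"})


class TestMergeEvidence:
    def test_same_pub_parent_child_collapse_to_child(self, ontology):
        records = [
            EvidenceRecord(("x", "y"), "PM1", "MI:0B00"),
            EvidenceRecord(("x", "y"), "PM1", "MI:0B01"),
        ]
        merged = da.merge_evidence(records, ontology)
        assert len(merged) == 1 and merged[0].mi_term == "MI:0B01"
        # order-insensitive: child first collapses the same way
        merged_rev = da.merge_evidence(records[::-1], ontology)
        assert len(merged_rev) == 1 and merged_rev[0].mi_term == "MI:0B01"

    def test_same_pub_unrelated_terms_both_kept(self, ontology):
        records = [
            EvidenceRecord(("x", "y"), "PM1", "MI:0B01"),
            EvidenceRecord(("x", "y"), "PM1", "MI:0C01"),
        ]
        assert len(da.merge_evidence(records, ontology)) == 2

    def test_different_pubs_same_term_both_kept(self, ontology):
        records = [
            EvidenceRecord(("x", "y"), "PM1", "MI:0B01"),
            EvidenceRecord(("x", "y"), "PM2", "MI:0B01"),
        ]
        assert len(da.merge_evidence(records, ontology)) == 2

    def test_unknown_term_named_in_error(self, ontology):
        with pytest.raises(KeyError, match="MI:9999"):
            da.merge_evidence([EvidenceRecord(("x", "y"), "PM1", "MI:9999")], ontology)


class TestClassifyLiterature:
    def test_partition_rules(self, ontology):
        records = [
            # bm: binary + co-complex, two publications
            EvidenceRecord(("bm", "z"), "PM1", "MI:0B01"),
            EvidenceRecord(("bm", "z"), "PM2", "MI:0C01"),
            # bs: a single binary piece
            EvidenceRecord(("bs", "z"), "PM3", "MI:0B00"),
            # cc: co-complex only, two publications
            EvidenceRecord(("cc", "z"), "PM4", "MI:0C00"),
            EvidenceRecord(("cc", "z"), "PM5", "MI:0C01"),
            # ex: invalid-only
            EvidenceRecord(("ex", "z"), "PM6", "MI:0X00"),
        ]
        labels = da.classify_literature(records, ontology)
        assert labels[("bm", "z")] == "Lit-BM"
        assert labels[("bs", "z")] == "Lit-BS"
        assert labels[("cc", "z")] == "Lit-CC"
        assert labels[("ex", "z")] == "excluded"

    def test_invalid_evidence_dropped_before_counting(self, ontology):
        records = [
            EvidenceRecord(("p", "q"), "PM1", "MI:0B01"),
            EvidenceRecord(("p", "q"), "PM2", "MI:0X00"),
        ]
        # the invalid piece does not promote the single binary piece to Lit-BM
        assert da.classify_literature(records, ontology)[("p", "q")] == "Lit-BS"

    def test_invariant_to_order_and_duplication(self, ontology, rng):
        records = [
            EvidenceRecord(("p", "q"), "PM1", "MI:0B01"),
            EvidenceRecord(("p", "q"), "PM1", "MI:0B00"),  # duplicate curation
            EvidenceRecord(("p", "q"), "PM2", "MI:0C01"),
        ]
        base = da.classify_literature(records, ontology)
        for _ in range(5):
            shuffled = [records[i] for i in rng.permutation(len(records))]
            assert da.classify_literature(shuffled + [records[0]], ontology) == base
        assert base[("p", "q")] == "Lit-BM"


class TestAssignInterologs:
    def test_distinct_chains_of_one_structure(self):
        hits = [("p1", "S1", "A"), ("p2", "S1", "B"), ("p3", "S2", "A")]
        out = da.assign_interologs(hits, [("p1", "p2"), ("p1", "p3")])
        assert out == {("p1", "p2"): {"S1"}}

    def test_same_chain_hits_do_not_qualify(self):
        hits = [("p1", "S1", "A"), ("p2", "S1", "A")]
        assert da.assign_interologs(hits, [("p1", "p2")]) == {}

    def test_homodimer_needs_two_chains_hit_by_one_protein(self):
        hits = [("p", "S1", "A"), ("p", "S1", "B"), ("q", "S2", "A")]
        out = da.assign_interologs(hits, [("p", "p"), ("q", "q")])
        assert out == {("p", "p"): {"S1"}}


def _planted_dataset(total, memberships):
    """Dataset of ``total`` pairs with the first blocks planted into the
    given reference categories (counts in precedence order)."""
    pairs = [(f"n{i:04d}", f"m{i:04d}") for i in range(total)]
    ds = PPIDataset(name="planted", pairs=set(pairs))
    refs, start = {}, 0
    for category, count in memberships.items():
        refs[category] = set(pairs[start:start + count])
        start += count
    return ds, refs


class TestNoveltyAccounting:
    def test_partition_property(self):
        ds, refs = _planted_dataset(100, {"exp_structure": 10, "hq_binary": 20})
        _, counts = da.categorize_novelty(ds, refs)
        assert sum(counts.values()) == len(ds)
        assert counts["strictly_novel"] == 70

    def test_precedence_order(self):
        pairs = {("a", "b")}
        ds = PPIDataset(name="t", pairs=pairs)
        refs = {"exp_structure": set(pairs), "hq_binary": set(pairs)}
        per_pair, counts = da.categorize_novelty(ds, refs)
        assert per_pair[("a", "b")] == "exp_structure"
        assert counts == {"exp_structure": 1, "hq_binary": 0, "strictly_novel": 0}

    @pytest.mark.parametrize("novel, known, expected", [
        (577, 494, 117), (0, 10, 0), (7, 7, 100),
    ])
    def test_delta_over_baseline(self, novel, known, expected):
        assert da.delta_over_baseline(novel, known) == expected

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            da.delta_over_baseline(5, 0)


class TestGrowthTimeline:
    def _ds(self, name, pairs, date):
        return PPIDataset(name=name, pairs=set(pairs), release_date=pd.Timestamp(date))

    def test_disjoint_datasets_sum(self):
        d1 = self._ds("d1", [("a", "b"), ("c", "d")], "2000-01-01")
        d2 = self._ds("d2", [("e", "f")], "2005-01-01")
        tl = da.growth_timeline([d1, d2])
        assert tl["cumulative"].tolist() == [2, 3]
        assert tl["novel"].tolist() == [2, 1]

    def test_identical_dataset_contributes_nothing(self):
        pairs = [("a", "b"), ("c", "d")]
        tl = da.growth_timeline([
            self._ds("first", pairs, "2000-01-01"), self._ds("again", pairs, "2010-01-01")
        ])
        assert tl["novel"].tolist() == [2, 0]

    def test_three_dataset_overlap_hand_enumeration(self):
        d1 = self._ds("d1", [("a", "b"), ("c", "d")], "1999-06-01")
        d2 = self._ds("d2", [("c", "d"), ("e", "f"), ("g", "h")], "2003-06-01")
        d3 = self._ds("d3", [("a", "b"), ("g", "h"), ("i", "j")], "2008-06-01")
        tl = da.growth_timeline([d3, d1, d2])  # order given must not matter
        assert tl["name"].tolist() == ["d1", "d2", "d3"]
        assert tl["novel"].tolist() == [2, 2, 1]
        assert tl["cumulative"].tolist() == [2, 4, 5]
        assert tl["cumulative"].iloc[-1] == len(d1.pairs | d2.pairs | d3.pairs)
        assert tl["delta_pct"].tolist()[1:] == [100, 25]


def _hksj_oracle(estimates):
    """Independent formula-level evaluation with plain loops."""
    y = [e.central for e in estimates]
    v = [((e.ci_high - e.ci_low) / (2 * 1.96)) ** 2 for e in estimates]
    k = len(y)
    w = [1 / vi for vi in v]
    mu_f = sum(wi * yi for wi, yi in zip(w, y)) / sum(w)
    q = sum(wi * (yi - mu_f) ** 2 for wi, yi in zip(w, y))
    tau2 = max(0.0, (q - (k - 1)) / (sum(w) - sum(wi**2 for wi in w) / sum(w)))
    ws = [1 / (vi + tau2) for vi in v]
    mu = sum(wi * yi for wi, yi in zip(ws, y)) / sum(ws)
    q_hk = sum(wi * (yi - mu) ** 2 for wi, yi in zip(ws, y)) / (k - 1)
    se = (q_hk / sum(ws)) ** 0.5
    half = t_dist(df=k - 1).ppf(0.975) * se
    return mu, mu - half, mu + half


PRINTED_ESTIMATES = [
    da.SizeEstimate(19500, 15000, 24000, label="range-midpoint study"),
    da.SizeEstimate(18000, 13500, 22500, label="retest-based study"),
    da.SizeEstimate(28472, 26650, 30460, includes_homodimers=False, label="capture-recapture study"),
    da.SizeEstimate(37600, 32252, 43472, label="overlap-based study"),
]


class TestHksjMeta:
    def test_identical_estimates_combine_to_themselves(self):
        ests = [da.SizeEstimate(100, 90, 110), da.SizeEstimate(100, 90, 110)]
        assert da.hksj_meta(ests).central == pytest.approx(100.0)

    def test_matches_independent_oracle_to_6_digits(self):
        combined = da.hksj_meta(PRINTED_ESTIMATES)
        mu, lo, hi = _hksj_oracle(PRINTED_ESTIMATES)
        assert combined.central == pytest.approx(mu, rel=1e-7)
        assert combined.ci_low == pytest.approx(lo, rel=1e-7)
        assert combined.ci_high == pytest.approx(hi, rel=1e-7)
        assert min(e.central for e in PRINTED_ESTIMATES) <= combined.central <= max(
            e.central for e in PRINTED_ESTIMATES
        )

    def test_random_effects_se_wider_than_fixed_when_heterogeneous(self):
        ests = PRINTED_ESTIMATES
        v = np.array([e.se**2 for e in ests])
        fixed_se = (1 / (1 / v).sum()) ** 0.5
        combined = da.hksj_meta(ests)
        hksj_se = (combined.ci_high - combined.central) / t_dist(df=len(ests) - 1).ppf(0.975)
        assert hksj_se >= fixed_se

    def test_single_estimate_returned_with_warning(self):
        est = da.SizeEstimate(100, 90, 110)
        with pytest.warns(UserWarning):
            assert da.hksj_meta([est]) is est


class TestCoverage:
    def test_fraction_and_interval(self):
        est = da.SizeEstimate(20000, 16000, 25000)
        frac, lo, hi = da.coverage(10000, est)
        assert frac == pytest.approx(0.5)
        assert lo == pytest.approx(10000 / 25000)
        assert hi == pytest.approx(10000 / 16000)

    def test_size_equal_to_central_is_full_coverage(self):
        assert da.coverage(100, da.SizeEstimate(100, 80, 120))[0] == 1.0

    def test_monotone_decreasing_in_estimate(self):
        fracs = [da.coverage(9817, e)[0] for e in PRINTED_ESTIMATES]
        order = np.argsort([e.central for e in PRINTED_ESTIMATES])
        assert all(np.diff(np.array(fracs)[order]) <= 0)
        # the printed dataset size spans roughly a quarter to a half of the
        # smaller and larger size estimates
        assert min(fracs) == pytest.approx(0.261, abs=0.01)
        assert max(fracs) == pytest.approx(0.545, abs=0.01)

    def test_zero_estimate_rejected(self):
        with pytest.raises(ValueError):
            da.coverage(10, da.SizeEstimate(0, 0, 0))
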