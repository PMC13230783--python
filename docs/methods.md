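# Methods

This note documents the models, rules, numerical choices and limitations
behind each module, in the order data flows through the toolkit.

## Structures and formats

Dimer structures are read from PDB/mmCIF via gemmi; waters and heteroatoms
are excluded and alternate locations resolved to the highest-occupancy
conformer (ties broken by altloc label order). Residues are re-indexed
contiguously 1..n per chain so that residue i of chain A maps to PAE row
i−1 and residue j of chain B to row len(A)+j−1; the author numbering is
kept as metadata. PAE matrices follow the AlphaFold JSON convention (row =
aligned/anchor residue, column = scored residue) and may be asymmetric.
Protein pairs are stored unordered (sorted-tuple normalization,
whitespace-stripped, case-preserved, no alias resolution); self-pairs are
flagged as homodimers and excluded from network analyses, where a
self-comparison is not meaningful.

## Interface contacts and area

The four atomic interaction classes are purely geometric, with inclusive
(≤) comparisons at the exact thresholds and no tolerance epsilon:
disulfide 2.56 Å (S–S on cysteines), hydrogen bond 3.5 Å and salt bridge
5.5 Å (both on N–O/O–N pairs — the rules nest, so an atom pair at ≤ 3.5 Å
carries both tags), van der Waals 5.0 Å (C–C). No residue-identity
restriction is applied to salt bridges: the rule as stated names only
atoms, and we follow it literally. A residue pair counts once as a contact
no matter how many of its atom pairs qualify; only the count feeds the
direct/indirect call (direct ⇔ ≥ 5 contacts).

Interface area is half of (SASA of the isolated chains minus SASA of the
complex), clipped at zero. SASA uses Shrake–Rupley sampling with 960
deterministic golden-spiral points per atom, probe radius 1.4 Å, and radii
C 1.70, N 1.55, O 1.52, S 1.80 Å; an atom with any other element raises an
error naming it. Against the exact two-sphere spherical-cap formula the
implementation agrees to ~0.5%; the contact and area computations are
invariant under rigid motions to the sampling resolution.

## Confidence metrics

The associated PAE of a contact (i, j) is min(PAE[i,j], PAE[j,i]) — the
permissive reading, confident in at least one alignment direction; a mean
variant is available (`pae_reduce="mean"`). The CCC boundary is inclusive
(≤ 4 Å) and the default interaction call is CCC ≥ 5. pDockQ uses the
logistic constants of its original description (L = 0.724, k = 0.052,
x₀ = 152.611, b = 0.018) with x = mean interface pLDDT × ln(number of
CB–CB ≤ 8 Å inter-chain contacts), CA standing in for glycine CB; with no
CB interface the baseline b is returned. Contact probability is consumed
as an externally supplied matrix — recomputing it requires model
internals (distograms) out of scope here. `precision_matched_cutoff`
chooses the strictest cutoff at which zero random-reference pairs score
positive (calls are strict inequalities beyond the extreme random score)
and reports recall among positives at that cutoff.

## Assay statistics

Recovery is p/(p+n) over successfully tested pairs with the central
68.27% interval of Beta(p+1, n+1) (binomial likelihood, uniform prior).
Note a property of such intervals: at fixed n their *frequentist* coverage
oscillates around the nominal mass because the binomial is discrete. At
n = 108 the exact coverage is 73.8% at a true rate of 0.05, 64.8% at 0.22
and 71.0% at 0.5 — so simulation-based calibration checks should expect
deviations of ±6 points from 68.3% at this sample size; this is a property
of the interval, not an implementation artifact (the quantiles themselves
are verified against direct CDF integration).

Quantitative assays are called positive iff the score strictly exceeds the
highest valid random-reference score in the same experiment, which makes
the top random pair itself negative and guarantees zero random positives.
MAPPIT scores are pair fold-induction over the maximum of the two negative
controls. Fisher's exact test sums the conditional hypergeometric pmf
directly (two-sided: all tables at most as probable as the observed one,
with a 1e−7 relative guard for floating-point ties, matching scipy); the
one-sided variant tests the first row's rate lower, the convention for
comparing a dataset against the positive control.

Threshold derivation: the binned rule returns the start of the first bin
not significantly below the control (one-sided Fisher, p ≥ 0.05); because
"first non-significant bin" is ambiguous when bins are non-monotone, the
default additionally requires all higher bins to be non-significant, with
the literal first-bin rule behind a flag. The sliding-window rule sorts
pairs by score descending (ties in stable input order), slides a 250-pair
window one rank at a time, and returns the minimum score inside the
lowest-scoring window whose unweighted positive rate is not below the
control bound. Balanced precision is TPR/(TPR+FPR) — precision corrected
to a balanced class mix — monotonized by a running maximum from the
low-recall end.

## Dataset assembly

Evidence merging collapses records sharing pair and PubMed ID whose MI
terms are identical or ancestor/descendant (keeping the descendant);
evidence from invalid detection methods is then dropped, and pairs
classify as Lit-BM (≥ 2 remaining pieces including binary), Lit-BS (a
single binary piece), Lit-CC (no binary evidence), or excluded (nothing
left). Evidence pieces are counted after merging. The novelty hierarchy is
applied in the fixed precedence order experimental structure > interolog
structure > high-quality binary > co-complex, each pair taking the first
category containing it; the counts therefore always partition the dataset.
Printed percentages round half away from zero (1382/1880 → 74%,
577/494 → 117%).

Interactome-size meta-estimation recovers standard errors from the
symmetric-normal 95% CIs as (hi − lo)/(2·1.96), estimates between-study
variance τ² by DerSimonian–Laird, and applies the Hartung–Knapp–Sidik–
Jonkman variance correction q/Σw\* with a t(k−1) interval. The
implementation reproduces R metafor (`method="DL", test="knha"`) exactly
on the four published size estimates. Coverage of a map is size/central
with the interval size/ci_high .. size/ci_low; per-study homodimer
adjustments are not reproduced (the flag is carried, the arithmetic is
each study's own), so coverage against the raw central values can exceed
the published 25–50% range at the high end.

## Network analyses

The degree-preserved null randomizes a graph by double-edge switches
(10·|E| successful switches, proposals creating self-loops or multi-edges
rejected), which preserves every node's degree exactly, needs no
connectivity assumption, and is driven by a seeded NumPy generator. This
replaces connected-graph generators of the Viger–Latapy type, which cannot
handle the disconnected graphs that fragmented contact maps produce.

Fragmentation curves subsample ⌊f·|E|⌋ edges at f = 5..95% (step 5), 1000
replicates per point, and report the largest-connected-component node
fraction relative to the full node set with the innermost 90% band. Degree
distributions are log-binned (powers of 2), densities normalized by bin
width and the number of degree ≥ 1 nodes (degree-0 nodes cannot appear on
a log axis; their count is reported separately). Enrichment divides the
observed count of property-sharing edges by its mean over 1000 randomized
networks, CI from the innermost 68.27% of the null counts. Profile
similarity networks average duplicate profiles, skip zero-variance ones
with a warning, and link pairs with Pearson correlation at or above the
(1 − top_fraction) quantile of all pairwise values, ties included.
Density heatmaps bin ranked nodes into equal-size bins (remainder to the
last), with diagonal cells multiplied by N²/(N²/2 − N/2) = 2N/(N−1) to
correct for the smaller number of unordered within-bin pairs; ranking ties
are shuffled under a seed.

Guilt-by-association compares each (node, term) annotated-neighbor count n
to its mean n̄ and *population* SD σ over 2000 degree-preserved
randomizations. The effect size is n − (n̄ + ασ): the typeset form of this
expression in the source literature is corrupted, and this reading both
matches its prose description and preserves the stated property that α = 5
selects exactly the z ≥ 5 candidates while ranking them by absolute signal
rather than favoring low-degree nodes with tiny σ. When σ = 0 the z-score
is undefined; such rows are flagged and carry effect size n − n̄.

## Synthetic data

Generators emulate the *shape* of real inputs, not their physics. Dimers
are parallel two-carbon-per-residue chains at 10 Å backbone spacing;
planted partner residues sit 4 Å apart (inside the C–C ≤ 5 Å rule only —
one rule suffices for planting; the other rules are covered by hand-built
micro-fixtures in the tests) and all other inter-chain pairs ≥ 8 Å apart,
with ±0.2 Å seeded jitter. Bundles plant confident contacts at PAE 2 Å in
both orientations against a ~20 Å background. Assay outcomes draw PRS
positives at the assay's published 22% sensitivity by default, with all
random-reference scores below every planted positive score. Networks are
Barabási–Albert (scale-free) or planted-partition (modular, defaults
p_in = 0.4, p_out = 0.02, 4 modules, half the nodes annotated with their
module's term); property tests that need a z ≥ 5 regime use a strongly
modular fixture (p_in = 0.9, full annotation). Evidence tables plant the
target Lit label first and construct evidence guaranteeing it, optionally
duplicating a record under a parent/child term variant that merging must
collapse. Everything is bit-deterministic under a fixed integer seed.

What passing on synthetic data does *not* show: real interfaces have
chemistry (the planted dimers exercise geometry only), real PAE matrices
have correlated structure, real assay scores are not cleanly separable,
and real networks mix scale-free and modular character with annotation
noise. The toolkit's rules are validated; their biological adequacy rests
on the studies that defined them.

## Problem sizes in tests and the acceptance script

Tests and `scripts/acceptance.py` use desk-scale instances: micro-dimers up
to ~500 atoms with a brute-force contact oracle, exhaustive Fisher
comparisons over all 2×2 tables with row margins ≤ 30 (≤ 20 in the
script), 10,000-replicate interval-calibration simulations at n = 108,
100–400 network randomizations on 48–200-node graphs, and 1000-replicate
fragmentation on toy graphs. Dataset-scale published quantities tied to
database snapshots (e.g., literature-map sizes) are not recomputed; the
accounting operations are instead exercised on the published per-study
summary counts, which are their natural inputs.
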