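# contactome

Assessment toolkit for protein–protein *contactome* maps — interactome maps
resolved to direct physical contacts. It implements the computational
machinery needed to benchmark experimental and AI-predicted interaction
datasets against each other: structural interface analysis, confidence
scoring of predicted dimer structures, reference-set assay statistics,
dataset assembly with novelty accounting, and network-topology/function
analyses. Every stage can be exercised end-to-end on synthetic data with
planted ground truth, so no downloads or deposited accessions are needed.

It is intended for interactome researchers who need to answer questions
like: *is this reported pair a direct contact or a co-complex association?
Should I trust this AlphaFold-multimer model of a dimer? What fraction of a
new map is strictly novel? How much of the complete interactome do we have?*

## What it computes

**Structural contacts** (`structural_contacts`). Atomic interactions across
a dimer interface are classified geometrically: disulfide bridges (two
cysteine sulfurs ≤ 2.56 Å), hydrogen bonds (N–O/O–N ≤ 3.5 Å), salt bridges
(N–O/O–N ≤ 5.5 Å), and van der Waals contacts (C–C ≤ 5.0 Å). A residue pair
with at least one qualifying atom pair is one residue–residue contact; a
protein pair with **≥ 5 contacts is a direct contact**, fewer is indirect.
Interface area is (SASA(A) + SASA(B) − SASA(AB)) / 2 by Shrake–Rupley
sampling.

**Predicted-structure confidence** (`af_scoring`). Five metrics for an
AlphaFold-multimer style prediction: model confidence (0.8·ipTM + 0.2·pTM),
contact probability (max inter-chain residue-pair P(<12 Å)), pDockQ, iPAE
(median interface PAE), and the **confident contacts count**

> CCC = #{residue–residue contacts (i, j) with min(PAE\[i,j\], PAE\[j,i\]) ≤ 4 Å},

with the default binary call *interacting ⇔ CCC ≥ 5*. CCC is robust to
disordered regions outside the true interface, which defeat averaging-based
metrics.

**Assay benchmarking** (`assay_stats`). Recovery rates p/(p+n) with
Bayesian credible intervals (central 68.27% of Beta(p+1, n+1)), positive
calling of quantitative assays against the top random-reference score,
Fisher exact comparisons, binned and sliding-window threshold derivation,
balanced precision–recall curves, and the SWIM pooled-screen score
S = 2/((a+M)/x + (d+N)/y).

**Dataset assembly** (`dataset_assembly`). PSI-MI evidence merging over the
ontology, Lit-BM / Lit-BS / Lit-CC literature classification, interolog
assignment, the novelty hierarchy (experimental structure > interolog >
high-quality binary > co-complex > strictly novel) with delta-over-time
accounting, and interactome-size meta-estimation with the
Hartung–Knapp–Sidik–Jonkman random-effects model.

**Network analysis** (`network_analysis`). Edge-sampling fragmentation
curves (largest-connected-component fraction), log-binned degree
distributions, enrichment against degree-preserved randomized networks,
profile-similarity networks (top-percentile Pearson correlation),
diagonal-corrected interaction density heatmaps, and guilt-by-association
function prediction ranked by the effect size n − (n̄ + ασ) with α = 5.

**Synthetic data** (`synthetic_data`). Deterministic generators for toy
dimers with planted interface contacts, PAE bundles with planted confident
contacts, assay outcomes at a chosen sensitivity, scale-free/modular
networks with planted annotations, and evidence tables with known Lit
labels.

## Worked example

Generate a toy dimer with 7 planted interface contacts and a PAE bundle
planting 5 confident contacts, then score it:

```
$ assess --seed 3 --config n_residues=20 --config n_planted_contacts=7 \
    --config n_confident=5 simulate --what bundle --out demo/
$ assess contacts --pdb demo/dimer.pdb
{
  "pair": "dimer",
  "contacts": 7,
  "classes": ["van_der_waals"],
  "direct": true,
  "interface_area": 194.98
}
$ assess score-af --pdb demo/dimer.pdb --pae demo/bundle.json --iptm 0.8 --ptm 0.7
{
  "model_confidence": 0.7800000000000001,
  "pdockq": 0.4646432931207117,
  "ipae": 2.0,
  "ccc": 5,
  "interacting": true
}
```

The dimer has 7 residue–residue contacts (all van der Waals by
construction), so it is a *direct* contact pair burying ~195 Å² of surface.
Exactly 5 of those contacts were planted with PAE 2 Å, so CCC recovers 5,
the median interface PAE is 2.0 Å, and the pair is called interacting —
right at the CCC ≥ 5 boundary. Model confidence is 0.8·0.8 + 0.2·0.7 = 0.78.

Other entry points: `assess benchmark` (recovery tables and PR curves),
`assess assemble` (literature classification / novelty counts),
`assess network` (fragmentation, degree, enrichment, guilt-by-association).

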