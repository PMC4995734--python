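# Methods

This note records the models the package implements, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices a maintainer would need to know.

## Pan-genome clustering

Protein pairs are aligned globally with affine gaps (BLOSUM62, gap open
−11, extend −1 — the classic protein-search scoring). *Identity* is
identical residue pairs over alignment columns; *coverage* is the aligned
(residue-paired) fraction of the shorter of the two coverages, so a short
fragment cannot claim full coverage of a long protein. Both must reach the
70% default for an edge. Proteins must be strictly longer than 50 residues
to enter the graph.

Aligning every pair exactly is quadratic, so a prescreen skips pairs that
cannot pass: coverage is bounded by the length ratio, and identity by
1 − d/(L_a + L_b) where d is the edit distance (computed with edlib's C
implementation). Both bounds are exact, so the thresholded graph is
identical to the brute-force one; only guaranteed-rejected alignments are
skipped.

MCL runs per connected component (exact — expansion cannot cross
components) on the column-normalised weighted adjacency with self-loops at
each node's maximum incident weight; inflation 2.0, convergence tolerance
1e-6, at most 200 iterations; clusters are connected components of the
converged matrix's support. Non-convergence yields best-effort clusters
flagged `converged=False` plus a warning.

Presence of a genome in a family is binary: paralogs do not count twice in
the presence/absence matrix or the pan-genome classes.

## Gene-content tree

Jaccard distance on family sets; UPGMA with size-weighted average linkage.
Tie-breaking merges the pair whose (smallest label, other smallest label)
is lexicographically least, making output deterministic; two genomes with
identical content get distance exactly 0 and merge first. Heights are half
the merge distance, so the tree is ultrametric by construction.

## Core-genome phylogeny

Single-copy core families are aligned as proteins by a progressive
aligner (3-mer Jaccard guide distances, UPGMA guide tree, profile–profile
Needleman–Wunsch with linear gaps: match +2 / mismatch −1 / gap −2). This
is a deterministic stand-in adequate for closely related orthologs, not a
general-purpose aligner. Back-translation replaces each residue by its
codon and each gap by `---`, after verifying the CDS translates exactly to
the aligned protein (terminal stop stripped).

Concatenated alignments are filtered column-wise: any column with a gap is
dropped, and a column is "too divergent" when fewer than half the rows
(configurable `divergence_rule`, default 0.5) share the majority residue.
Filtering is idempotent.

The topology comes from neighbor joining on Jukes–Cantor-corrected
distances (p-distances ≥ 0.75 are capped at distance 5); negative NJ
branch lengths are clamped to zero with a warning. Branch lengths, the
five free GTR exchangeabilities (r_GT ≡ 1) and the gamma shape α are then
optimised by L-BFGS-B on log scale; base frequencies default to empirical
counts. The discrete gamma uses four equal-probability categories
represented by their conditional means. Likelihoods are computed by
Felsenstein pruning over unique site patterns, with per-pattern rescaling
against underflow; gaps and ambiguous bases are missing data (partial
likelihood 1 for every state).

Bootstrap replicates resample columns with replacement (seeded) and
rebuild each replicate tree by NJ on Jukes–Cantor distances; support is
the percentage of replicates containing each bipartition of the ML tree.
The pipeline default is 100 replicates (the CLI `core-tree` command
defaults to the conventional 1000); at desk scale the supermatrix signal
is strong and supports saturate at 100%.

## Codon models and the selection scan

Goldman–Yang rate matrices: single-nucleotide codon changes at rate
π_target × κ^[transition] × ω^[nonsynonymous]; multi-nucleotide changes
forbidden. `codon_rate_matrix` returns the generator scaled to one
expected substitution per codon at equilibrium.

**Mixture time scale.** In site-class mixtures the classes share one time
scale per branch type: branch lengths count expected substitutions per
codon under the whole mixture (scale s = Σ_k p_k μ_k, with μ_k the class's
equilibrium rate), so a class with ω = 10 genuinely evolves faster than a
purifying class rather than being silently renormalised. This matches how
the standard codon-model software treats mixtures; normalising each class
separately erases the rate component of positive selection and costs most
of the branch-site test's power at shallow divergence. Foreground and
background branch types get their own s in the branch-site models.

Codon frequencies default to F3x4 (position-specific nucleotide
frequencies with one pseudo-count); uniform frequencies are available and
used in simulations.

**Fitting.** All fits run L-BFGS-B on transformed parameters (proportions
via stick-breaking logits, ω₀ through a sigmoid into (0,1), ω₂ as
1 + exp(·), κ on log scale). M2a is warm-started from the fitted M1a and
the branch-site alternative from its null; because each alternative
contains its null as a boundary point, the warm start guarantees
ll_alt ≥ ll_null up to optimiser tolerance, and LRT statistics in
[−1e−6, 0] are clamped to 0. `fit_site_models`/`fit_branch_site` default
to 3 starts (one heuristic, the warm embed, plus random); the genome-scale
scan uses 1 start per model and additionally fixes κ at the per-gene M0
estimate — at a few hundred genes this halves runtime and, in pilot
simulations, left every LRT statistic essentially unchanged.

**Branch lengths** are estimated once per gene: an M0 (single-ω) fit of a
global scale applied to the input (core-genome) tree, then held fixed
across the four model fits. Foreground marking accepts a leaf set; when
the set is a split of an unrooted tree rather than a clade of the current
rooting, the tree is rerooted on that split (the shared edge is divided
50/50 — the true division is unidentifiable without a clock or outgroup,
and this choice dilutes the foreground stem signal accordingly).

LRTs: M2a vs M1a at 2 df, branch-site alternative vs null at 1 df,
p-values from the chi-square upper tail. Both nulls lie on the boundary of
the alternative's parameter space, so the tests are conservative; the
acceptance suite verifies empirical size ≤ nominal. P-values are reported
raw (Benjamini–Hochberg is available as an option) and the scan flags
genes at a configurable α, reporting the species-wide/branch-specific
overlap split.

## Enrichment

Exact binomial upper tail P(X ≥ k) with the background proportion of each
category as p₀; one-sided in the enrichment direction only. Multi-letter
COG assignments count once per category; unknown letters are bucketed as
"uncategorized" with a warning. In simulated pipeline runs the COG map is
a seeded random assignment over 14 common categories — it exercises the
machinery but plants no enrichment signal.

## Fitness

w = ln(x_F/x_0) / ln(y_F/y_0). This ratio-of-realized-Malthusian-growth
form is adopted as the definition of serial-transfer relative fitness
(w = 1 ⇔ equal growth; w_xy · w_yx = 1); it is stated here explicitly as
an assumption of the package. Start abundances default to the inoculum
fraction (default 0.05, i.e. 1 part ripe culture into 20 parts fresh
substrate; 0.1 also supported) times the previous cycle's end abundance
when not measured directly. The qPCR detection limit (default 10²
copies/g) censors inclusively-below values; censored cycles are excluded
from the mean and standard deviation, never imputed or zeroed. Pooling is
over all finite per-cycle w values across cycles and replicate series.

## Synthetic data

All generators are pure functions of (config, seed) with per-component
substreams, so outputs are reproducible and regimes independent.

* **Gene content**: two-state (present/absent) continuous-time process
  along the genome tree, gain and loss rates per unit branch length
  (default 0.7 each), root state stationary, jump times simulated
  explicitly so realised event counts are exact. Families observed nowhere
  are dropped (and listed in the truth record).
* **Codon alignments**: per site a class is drawn by its proportion, the
  root codon from the equilibrium distribution, and substitutions follow
  the class's (foreground-aware) transition matrices under the shared
  mixture time scale. No indels are simulated within codon alignments.
* **Proteomes**: core families are simulated codon alignments split into
  per-genome CDS with translated proteins; accessory families follow the
  simulated presence pattern. Gene identifiers carry no family
  information.
* **Competition**: within each cycle the strains grow to a carrying
  capacity (total returns to start/inoculum_fraction); strain y grows by a
  factor g solved from the capacity constraint and strain x by g^w*, so
  noise-free measurements invert to w* exactly while the losing strain
  declines cycle over cycle and eventually crosses the detection limit.
  Measurement noise is multiplicative lognormal (default σ = 0.05).

**The paper-mini fixture** (`SimConfig` defaults): 6 genomes on a fixed
tree with a 3-leaf foreground clade (G4, G5, G6), 200 core plus 300
accessory families, 100 codons per gene, background ω₀ = 0.2, κ = 2, and
3 core genes planted under branch-site selection (ω₂ = 10 on 30% of
sites, foreground only). These conditions were set by a design-time power
analysis: most of the planted foreground signal sits on the within-clade
branches (G4/G5 at 0.12 substitutions/codon) because stem signal is
halved by the unrooted-split rerooting, and longer stems push cross-clade
protein identity toward the 70% clustering threshold below which a family
would fragment. Under these conditions planted branch-site LRT statistics
fall around 7–40 while unselected genes sit near 0, and cross-clade
identities stay ≥ 75%.

What the generator does **not** emulate: genome architecture (operons,
synteny, mobile elements), indels inside codon alignments, sequencing or
annotation error, horizontal transfer of core genes, and COG-category
signal. Passing tests therefore demonstrate that the inference chain
recovers truth under its own model assumptions at desk scale — they do not
certify behaviour on real genomes with assembly artefacts or model
violations.

## Pipeline

Stages write plain-text TSV/Newick artifacts plus a `.stage.done` marker
holding the config echo; rerunning with an unchanged config and intact
outputs skips completed stages, and a fresh run with the same seed is
byte-identical. Input validation happens before anything is written. A
single gene's failed fit flags its row and never aborts the scan.

## Problem sizes

The test suite and `scripts/acceptance.py` use: 100 null replicates per
LRT calibration (5 taxa, 100 codons) in the tests and 60 in the script;
20 (tests) / 12 (script) replicates for ω₂ recovery at 8 taxa × 300
codons; 50 gain/loss replicates at 300 accessory families for
gene-content recovery; 100 random 6×6 matrices for the UPGMA oracle
comparison; and one (script) or two (tests, for the determinism check)
full paper-mini pipeline runs. These sizes are the package's choice of
desk-scale study conditions; the underlying code handles larger inputs
unchanged.

## Known limitations

* The progressive aligner is a minimal stand-in; for divergent or
  indel-rich families use an external aligner and feed alignments in.
* NJ topology + ML branch lengths is not a full ML topology search; on
  well-separated desk-scale data the topology is recovered exactly, but
  hard topologies deserve a dedicated tree searcher.
* Branch-site power at shallow divergence is intrinsically low; single
  genes with few foreground substitutions can carry no recoverable
  signal regardless of implementation.
* Bayes-Empirical-Bayes identification of individual selected sites is
  not implemented (the scan reports gene-level tests only).
* The 50/50 division of the unrooted central edge when rerooting for
  foreground marking is a convention; with an outgroup or clock the stem
  could be placed more accurately.
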