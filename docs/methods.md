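# Methods

## Model and pipeline

The package ranks drugs for a disease by how well their *pathway-level*
transcriptomic signatures oppose the disease's. Three ideas are combined:

1. **Genetic contextualization.** A transcriptomic signature is more
   trustworthy for a disease when its genes are also genetically associated
   with that disease. This is operationalized as one-sided Fisher's exact
   tests of gene-set overlap (hypergeometric upper tail), BH-corrected
   jointly over all pairs tested in a stage. Three optional cascaded stages:
   disease-DEG vs disease-GWAS (q ≤ 0.05), drug-DEG vs disease-GWAS
   (q ≤ 1e-10; candidate pairs default to the indications table, with an
   all-pairs option), and the intersection of the two survivors (q ≤ 0.05).
   Each stage can be skipped; the cascade removes candidates, it never adds
   any.
2. **Signed pathway enrichment.** Per pathway the gene effects ΔE are
   propagated through the signed regulatory topology: each gene's
   perturbation factor is its own ΔE plus the out-degree-normalized, signed
   perturbations of its direct upstream regulators, i.e. the linear system
   (I − B)·PF = ΔE with B[i, j] = β_ij / outdeg(j). The net accumulation
   tA = Σ(PF − ΔE) carries the direction of dysregulation. Evidence is
   two-fold: the hypergeometric over-representation tail pNDE of the
   pathway's DE-member count, and a bootstrap tail pPERT for |tA| (observed
   nonzero effects reassigned, in shuffled order, to uniformly random member
   subsets of the same size; two-sided distance from the null median with
   the (1+k)/(n+1) estimator so p is never 0). They are combined as
   pG = c − c·ln c with c = pNDE·pPERT and BH-adjusted within each entity's
   run — each entity's enrichment is its own multiple-testing family.
3. **Anti-correlation scoring.** Significant directional pathways
   (q < 0.05, tA ≠ 0) become sparse ±1 vectors. Drug and disease vectors
   are materialized over the union of their supports (zero-filled; a
   disease-only index is available) and compared by Pearson correlation.
   Coverage is the percentage of the disease's significant pathways also
   significant for the drug, counted regardless of sign — "affected", with
   a reverted-only variant a caller can compute from the signs. A
   Levenshtein distance over the lexicographically ordered {−1, 0, +1}
   strings is reported as an alternative dissimilarity but never drives the
   default ranking. Two-drug combinations use elementwise sign-of-sum with
   conflicts cancelling to 0. Shortlists keep correlation ≤ −0.4 (the sign
   test is inclusive) and coverage strictly > 50% (pairs: ≤ −0.5 / ≥ 80%),
   ranked by correlation, then coverage, then drug key — total and
   deterministic. Zero-variance vectors have undefined correlation; such
   pairs are reported but never ranked.

## Tunable parameters

| parameter | default | meaning |
| --- | --- | --- |
| `q_disease_gwas` | 0.05 | BH cutoff, disease-DEG vs GWAS overlap |
| `q_drug_gwas` | 1e-10 | BH cutoff, drug-DEG vs GWAS overlap (drug data has no intrinsic disease context, so the false-positive control is much stricter) |
| `q_triple` | 0.05 | BH cutoff, stage-3 intersection |
| `q_pathway` | 0.05 | pG FDR cutoff for a pathway to enter a signature vector |
| `corr_max` / `affected_min_pct` | −0.4 / 50 | single-drug shortlist thresholds |
| `pair_corr_max` / `pair_affected_min_pct` | −0.50 / 80 | two-drug shortlist thresholds |
| `n_boot` | 200 | pPERT bootstrap replicates per pathway (raise for production runs; 200 keeps the standard benchmark fast while the smallest attainable p, 1/201, is well below the 0.05 significance cutoff in combination with pNDE) |
| `universe_policy` | observed_union | Fisher background: union of genes observed in the two tables compared; callers with a declared assay universe should pass it explicitly — a hit-only union understates the background and weakens every overlap test |
| `index_policy` | union | vector index for correlation; `union` penalizes drugs with large off-disease footprints |

## Numerical choices

* The perturbation system is solved by LU factorization, computed once per
  pathway and reused across bootstrap replicates as one multi-RHS solve.
  A system whose smallest singular value is below 1e-10 is declared
  singular and the pathway is skipped (recorded by a warning), e.g. a pure
  two-gene activation cycle.
* Bootstrap substreams are keyed by (run seed, pathway id) — common random
  numbers. Two entities evaluated on the same pathway see identical
  reassignments, so paired comparisons (a disease against its candidate
  drugs) are not blurred by independent bootstrap noise; by linearity an
  exactly negated signature receives exactly the same pPERT. Passing an
  explicit generator decouples runs instead.
* BH is statsmodels' step-up implementation; p-value inputs are validated
  into (0, 1]. Hypergeometric tails come from scipy; tails are clipped to
  (tiny, 1]. Edit distance is computed by edlib on a 3-letter alphabet.
* For pathway collections without topology, `run_ora` is a fallback:
  over-representation only (pPERT = 1) with direction from the dominant
  summed effect sign. An extension, not the demonstrated enrichment path.
* Ties in shortlists break by coverage then lexicographic drug key.
  Duplicate (entity, gene) measurements collapse to the largest |effect|
  (the strongest perturbation survives); identifier harmonization drops
  unmappable rows with a logged count and re-collapses.

## The synthetic benchmark

`SynthConfig` defaults define the standard benchmark: 2,000 genes; 50
pathways of 10–30 genes drawn as disjoint slices of the gene universe
(overlapping draws only once the universe is exhausted); per pathway a
random spanning tree plus extra edges, each inhibitory with probability
0.3; 5 diseases with 4 driver pathways each; per disease one inverter
(gene effects exactly negated) and one mimicker (copied), plus 20 random
decoy drugs sized like a disease signature; indications label each inverter
for its disease.

Rates: GWAS hits at 0.5 in driver members vs 0.01 background; DE at 0.7 in
drivers vs 0.005 background; 5% sign noise; effect magnitudes uniform on
[0.5, 3] (continuous so the perturbation system is nondegenerate). The
driver rates are set high enough that a driver pathway is decisively
significant, and the DE background low enough that disease signatures stay
driver-dominated — with a dense background of single-gene pathway hits, the
true-vs-simulated comparison at this scale drowns in bulk noise long before
the planted biology does.

Two generator details matter and are deliberate:

* **The planted quantity is the pathway-level direction.** Gene signs are
  drawn from the planted direction (with noise), then the pathway system is
  solved and the pathway's gene effects are negated if the *propagated*
  direction disagrees — exact by linearity. A signed topology can invert
  the net accumulation relative to raw gene signs; planting directions in
  propagated currency keeps the ground truth in the same units the pipeline
  estimates. Driver directions alternate +1/−1 (shuffled), so every disease
  vector is mixed and scoreable; singular pathways are not driver-eligible.
* **The signal-free control decouples, it does not flatten.** With
  `decouple_drugs=True` planted drugs are built from a cyclically shifted
  disease assignment while their labels stay put: scores remain defined,
  labels are independent of them, and the ROC of negated correlation
  against indication labels sits at chance. (Setting driver rates equal to
  background instead removes the disease signatures themselves — then no
  correlation is defined and a ROC cannot be computed; that rates-equal
  regime is exercised where it is well-posed, as the no-signal invariant of
  the overlap filter.)

What the benchmark does *not* emulate: linkage disequilibrium, eQTL
structure, tissue specificity, dose/cell-line covariates, correlated drug
mechanisms, or realistic pathway cross-talk (default memberships are
disjoint). Passing tests therefore demonstrate that the machinery recovers
a known signal of the stated shape — not performance on real LINCS- or
Open-Targets-scale data.

## Validation design

* Planted-signal recovery: every inverter should rank first for its disease
  with correlation −1 and coverage 100%; every mimicker should have the most
  positive correlation.
* ROC: negated correlation as predictor, planted inverters as positives,
  percentile-bootstrap CI (resamples with one class redrawn up to 10×).
  The control benchmark uses 40 diseases so chance-level AUC is estimated
  with 40 positives rather than 5.
* True vs simulated pathways: one-sided Mann–Whitney on pooled pG from
  diseases and planted drugs (random decoys carry no pathway dysregulation,
  so the claim under test does not apply to them), against label-randomized
  pathways of identical size and topology. Exact enumeration for small
  tie-free samples, tie-corrected normal approximation otherwise.
* Bootstrap calibration: under random reassignment of effects, pPERT is
  approximately U(0, 1) (KS distance < 0.1 at 500 replicates, 200 boots).
* Score-distribution diagnostics are descriptive (moments and normal Q-Q
  points), not a formal normality test.

## Problem sizes

The standard benchmark (2,000 genes, 50 pathways, 5 diseases, 30 drugs,
200 bootstrap replicates per pathway) runs end to end in a couple of
seconds on one CPU; the 40-disease control takes a few seconds more. These
sizes were chosen so the full validation suite iterates quickly while every
statistical check retains comfortable power; all of them scale up by
configuration only.

## Known limitations

* The Fisher-overlap background defaults to the observed union of the two
  tables compared; without a declared assay universe this understates the
  true background and makes all three filters conservative in a
  data-dependent way.
* pPERT's smallest attainable value is 1/(n_boot+1); with the default 200
  replicates, pathway significance is driven primarily by pNDE.
* The indication table doubles as ROC labels; on real data label noise
  (trials that failed, indications missing) would bias AUC downward.
* Combinations beyond two drugs are out of scope (combinatorial cost), as
  are side-effect and tissue-expression modeling.
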