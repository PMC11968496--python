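# Methods

## Problem and model

The package analyzes two-condition (disease vs. healthy) gene-expression
cohorts for *differential co-expression*: gene pairs whose correlation differs
between conditions, as opposed to genes whose mean level differs.  The
motivating use case is neurodegenerative-disease transcriptomics (muscle and
motor-neuron cohorts), but every stage is generic over tissues and diseases.

The pipeline is a chain of standard building blocks around two data-driven
thresholds and a module score:

1. **DEG substrate.**  Per-dataset differential-expression tables (linear fold
   change, BH-adjusted p) are filtered with adj p < 0.05 and FC > 1.5 (up) or
   FC < 0.67 (down), strictly; genes with FC in the dead zone are excluded no
   matter how significant.  DEG sets from several datasets of one tissue are
   intersected by identifier only — direction may disagree across datasets.
   The pipeline does not re-derive DE statistics (no limma/DESeq2 step);
   pre-computed tables are the input contract.  Multi-probe genes are
   collapsed to the minimum-adj-p row, a reader default that callers can
   bypass by collapsing upstream.

2. **Condition-specific correlation.**  Per gene pair and condition the
   correlation method is chosen by normality: Pearson if Shapiro–Wilk
   (α = 0.05, per gene, on raw values) fails to reject for both genes,
   Spearman otherwise.  Spearman coefficients are computed for every pair
   regardless, because the differential statistic is defined on rank
   correlations.  P-values use the t approximation on n − 2 df; ties get
   average ranks.  Z-score normalization (per gene, sample sd) is applied for
   output matrices and drops zero-variance genes explicitly; both Pearson and
   Spearman are invariant under that per-gene affine map, so coefficients are
   computed on the raw rows of the retained genes.

3. **Differential edges.**  Per condition, the magnitude threshold
   `p_critic = mean|r| + 1.96·sd|r|` is computed over all pairs (absolute
   coefficients; sample sd with ddof 1 — the convention is ours, the
   definition leaves both open).  A pair becomes a differential edge iff

   * it is significantly co-expressed in at least one condition: correlation
     p < 0.05 **and** |r| > that condition's p_critic (`pcritic_gate: any`,
     configurable to `both` or `none`), and
   * |SCC_d − SCC_h| > ε with ε = 0.5.

   When the chosen method differs between conditions for a pair, both sides
   fall back to Spearman for comparability.  The `any` gate is deliberate:
   requiring significance in *both* conditions would reject exactly the
   edges of interest (a disease-gained module is near-zero-correlated, hence
   never significant, in the healthy condition).  The cost is a higher null
   pass rate at small n — see "statistical behavior" below.

4. **Module detection.**  On the differential-edge graph, a seed-and-grow
   detector in the MCODE family: vertices are weighted by (highest-k-core
   number × that core's density) over the closed neighborhood; complexes grow
   from the highest-weighted unused seed over vertices with weight
   ≥ seed weight × (1 − node_score_cutoff), default cutoff 0.2, degree cutoff
   2; complexes are reduced to their 2-core (haircut).  One refinement is
   ours: reported modules must be 2-edge-connected, so complexes are split at
   cut edges before reporting.  A single bridge between two dense modules
   carries no module membership evidence, and without the split the grow step
   fuses two equal-weight cliques connected by one edge into a single
   complex.  The split is label-free, so clustering is invariant under node
   relabeling; clusters are vertex-disjoint, connected, and sorted by score.
   Density is the simple-graph density D = 2E/(V(V−1)); the module score is
   D·V (for the two reference cluster graphs, 28 nodes/174 edges and 20
   nodes/130 edges, this gives 46%/12.89 and 68%/13.68).  Cluster selection
   keeps scores ≥ 10 (a knob, chosen so that only modules of roughly a dozen
   tightly co-expressed genes or more qualify), top 1 by default, with a
   deterministic tie-break (score, then size, then lexicographic members).

5. **Enrichment.**  Over-representation per GMT gene set: upper-tail
   hypergeometric P(X ≥ overlap) with the universe defaulting to the union of
   the collection (logged, since p depends on it); BH correction across the
   collection; rich factor = overlap / set size.  No pathway content is
   bundled; tests and drivers use synthetic collections.

6. **Classifier validation.**  Stratified 80/20 split; standardization fitted
   on the training partition only; accuracy/F1/recall on the held-out set
   with disease positive, per model and optionally per single gene.  The
   registry holds nine models (k-NN, SVM, decision tree, random forest, MLP,
   classic and histogram gradient boosting, XGBoost, LightGBM) with library
   defaults; a single split mirrors the validation design rather than k-fold.

7. **Drug repurposing.**  A drug signature row (drug, gene, FC, p, q,
   specificity) counts iff p < 0.05, q < 0.05 and FC outside (0.67, 1.5); a
   drug is a candidate with ≥ 1 counting row against the cluster genes
   (`min_genes` knob for stricter policies; the gate is direction-agnostic by
   default, matching the stated thresholds).  Candidate sets are intersected
   across tissues.  The regression panel predicts drug FC from the gene's
   disease FC (standardized) plus one-hot gene identity, with linear, SVR,
   random-forest, gradient-boosting and MLP regressors; `cv_error` is defined
   as out-of-fold mean absolute error under 5-fold CV (the metric name is
   reported, since "error rate" alone is ambiguous), with small fixed grids
   searched inside training folds only.

8. **Literature novelty.**  With per-drug counts (articles mentioning the
   drug; articles co-mentioning drug and disease):
   TF = co-mentions / Σ co-mentions over the candidate set,
   IDF = log10(Σ articles / articles), TF-IDF = TF·IDF.  These formulas are
   reconstructed from the packaged 20-drug reference table and reproduce its
   printed TF column (total 335) to ±0.001 and its IDF column to ±0.01
   (article total 661,680).  TF-IDF = 0 ⇔ zero co-mentions ⇔ novel.
   Counting against a local corpus uses case-insensitive whole-phrase
   matching; no live literature service is on any test path.

## Synthetic data: what it emulates and what it does not

`dcx.synthdata` plants exactly the structures the stages detect:

* **Expression**: an equicorrelated multivariate-Gaussian module (pairwise ρ
  per condition) inside an i.i.d. Gaussian background, on a log-like scale
  with unit noise sd.  Defaults mirror a small two-cohort design (13 disease
  vs 8 healthy samples, 100 genes, 15-gene module, ρ 0.85 vs 0.05, 2-fold DE
  shift); recovery-grade analyses use ≥ 40 samples per condition.  Because
  the analysis is rank-based, only the correlation structure matters, so the
  Gaussian choice is innocuous.  The DE set is the module plus twice as many
  independent background genes — in real cohorts the common DEGs far
  outnumber any one module, and a DEG substrate equal to the module would
  make p_critic self-defeating by construction.
* **DE tables**: planted DE genes significant in every dataset, plus
  disjoint per-dataset pseudo-DEGs so intersection does real work.
* **Drug signatures**: planted reversing drugs push every DE gene's FC below
  0.67 with p, q < 0.05; all other drugs stay in the FC dead zone.
* **Literature counts**: log-normal article totals; exactly `n_novel` drugs
  with zero co-mentions.

Not emulated: count noise (negative binomial), batch effects, probe-level
artifacts, heavy-tailed marginals, correlated background blocks, and
dataset-specific normalization differences.  Passing tests therefore show
that the machinery recovers the structures it defines, under clean sampling
noise — not that those structures are recoverable from any particular real
cohort.

## Statistical behavior and numerical choices

* Null behavior of the ε filter: under no planted structure, a pair passes
  only if one |r| clears p_critic (~0.32 under the null) and the Spearman
  difference exceeds 0.5.  The null Spearman sd is ≈ 1/√(n−1), so the pass
  rate falls steeply with cohort size: ≈ 2% at 40 samples per condition and
  < 0.1% at 100, which is the regime the false-positive test uses.  With a
  planted module, p_critic rises with the signal (self-calibration), and at
  40 samples per condition ≥ 95% of module pairs pass while background pairs
  stay ~1%.
* Determinism: every generator owns a single `numpy.random.Generator` seeded
  from its config; sklearn models receive explicit `random_state`; pipeline
  reruns with identical (config, seed) produce identical file digests.
* Degenerate inputs: zero-variance genes are excluded (never silently
  zeroed); empty graphs yield empty cluster lists; an all-zero co-mention
  table gives TF ≡ 0; a single correlation gives sd 0 with a warning.
* Tie-breaks: cluster ordering and selection break ties by (score desc,
  size desc, lexicographic members); the novelty report orders novel first,
  then ascending TF-IDF, then drug label.
* Rounding happens only at output formatting (reported percentages, 2-d.p.
  scores, 4-d.p. novelty columns), never inside computations.

## Problem sizes

Tests and the analysis drivers run at desk scale, chosen to keep every Monte
Carlo estimate's sampling error well inside its acceptance band: 60–100-gene
substrates (≈ 2,000–5,000 pairs per condition), 40–100 samples per condition,
1,000-replicate oracles for BH and the normality-gate rate, 200-replicate
oracles for Spearman expectations, and 100 random graphs for isomorphism
invariance.

## Known limitations

* The MCODE variant implements the canonical weighting and growth rules plus
  the bridge-split refinement; "fluff" expansion and the max-depth bound are
  not implemented (growth is component-bounded instead).
* The per-pair method choice tests marginal normality only; joint
  non-Gaussianity with Gaussian marginals will be treated as Pearson-safe.
* `p_critic` uses a fixed 1.96 multiplier (a normal-tail convention); it is
  not re-derived from the empirical |r| distribution.
* The regression panel's grids are intentionally tiny; it benchmarks model
  families, it does not tune them.
* Enrichment results depend on the universe; the collection-union default is
  a convention and should be overridden when a measured background exists.
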