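# dcx — differential co-expression analysis for two-condition transcriptomics

`dcx` finds gene modules whose *co-expression* — not just expression level —
changes between a disease and a healthy condition, and carries those modules
through enrichment, classifier validation, drug-signature repurposing and
literature-novelty scoring.  It is aimed at systems-biology analyses of
paired case/control cohorts (the bundled drivers emulate a muscle and a
motor-neuron cohort for a neurodegenerative disease), and at anyone who wants
the full chain runnable and testable at desk scale with no downloads.

## The statistics at the core

For each condition, pairwise gene correlations are computed (Pearson when
both genes pass Shapiro–Wilk normality at α = 0.05, Spearman otherwise), and
a per-condition magnitude threshold is derived from the data:

    p_critic = mean|r| + 1.96 · sd|r|

A gene pair (with Spearman coefficients SCC_d, SCC_h in the disease and
healthy states) is a **differential edge** iff it is significantly
co-expressed in at least one condition (p < 0.05 and |r| > p_critic) and

    |SCC_d − SCC_h| > ε,     ε = 0.5 by default.

On the resulting graph, an MCODE-style seed-and-grow detector extracts dense,
vertex-disjoint modules, scored by

    D = 2E / (V(V−1)),     score = D · V.

Downstream: hypergeometric over-representation with BH correction and rich
factor (overlap / set size); a nine-classifier panel on a stratified 80/20
split; drug-candidate filtering at p, q < 0.05 and FC > 1.5 or < 0.67;
and TF-IDF literature novelty, where TF = per-drug disease co-mentions over
the candidate set total, IDF = log10(total articles / per-drug articles),
and TF-IDF = 0 flags a drug never co-mentioned with the disease — a novel
repurposing candidate.

## Worked example

The numbered drivers under `analysis/` run the whole chain on synthetic
cohorts with a planted 15-gene module (pairwise ρ = 0.85 in disease, 0.05 in
healthy, 40 samples per condition, 100 genes):

```sh
cd analysis
python 01_simulate.py && python 02_filter_degs.py && python 03_coexpress.py
python 04_cluster.py
```

```
muscle/disease: 990 pairs, mean|SCC|=0.211, p_critic=0.686
muscle/healthy: 990 pairs, mean|SCC|=0.127, p_critic=0.307
muscle: 108 differential edges at epsilon=0.5
muscle: graph V=20 E=108, 1 clusters, 1 significant
  cluster: V=15 E=104 density=99.05% score=14.86 | Jaccard vs planted module = 1.00
```

Read: of the 45 common DEGs, 990 pairs were correlated per condition; the
disease-state p_critic (0.686) is inflated by the planted module, exactly as
intended; 108 pairs survive the ε filter, and the detector recovers the
planted module perfectly (Jaccard 1.00) as a 15-node cluster of density 99%
and module score 14.86.  Continuing with `05_enrich.py` … `08_novelty.py`
ranks the planted gene set first (q ≈ 3·10⁻¹⁷, rich factor 1.0), classifies
disease vs healthy samples from the cluster genes (best model accuracy ≈
0.81–0.88), recovers the three planted expression-reversing drugs exactly,
and flags the zero-co-mention ones as novel.

The same chain is available as a library (`import dcx`), as one call
(`dcx.pipeline.run_pipeline`), or as a CLI:

```sh
dcx simulate --outdir out --seed 1
dcx novelty --out novelty.tsv        # scores the packaged 20-drug reference table
dcx run --config config.yaml
```

`dcx novelty` on the packaged reference count table (20 candidate drugs for a
motor-neuron disease; 335 disease co-mentions in total) reports exactly five
zero-score, novel candidates: Nilotinib, Trovafloxacin, Apratoxin A,
Carboplatin, Clinafloxacin.

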