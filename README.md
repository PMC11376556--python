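# tcdiv — cross-group time-course divergence scoring

`tcdiv` identifies features (genes, proteins) whose *temporal response*
to a stimulus differs between two groups measured over a shared time
grid — the setting of comparative stress experiments such as two
species' fibroblasts sampled in triplicate at 0, 1, 2, 3 and 4 h of
anoxia, with RNA-seq counts and label-free MS protein intensities for
orthologous feature pairs.

## The statistic

Each feature's curve is first anchored to its own baseline:

```
r_g(t) = log2( mean abundance at t / mean abundance at t0 )
```

so every curve starts at 0 and static abundance offsets between the
groups cancel. For an ortholog pair with curves `r_A(t)`, `r_B(t)`:

```
score = (1 − |A|) × B
```

where **A** is the Pearson correlation between the two curves (shape
agreement, scale invariant) and **B** is the absolute geometric area
between their piecewise-linear interpolants (log2-ratio × hours;
segments where the difference changes sign are split at the crossing).
The score is zero for identical, positively scaled, or sign-flipped
curve pairs, and large only when the shapes disagree *and* the curves
are far apart. Pairs with scores strictly above the 75th percentile are
flagged as divergent responders.

Around this core the package provides per-timepoint differential calls
(Welch t vs baseline on the log2 scale, Benjamini–Hochberg FDR < 0.05),
Ward hierarchical clustering of paired temporal profiles into k = 4
abundance-profile groups, RNA–protein call overlap through a one-to-one
ortholog map, one-sided Fisher gene-set over-representation, replicate
and cross-layer correlation QC, and a seeded synthetic-data generator
that plants shared / scaled / anticorrelated / divergent temporal
archetypes with truth labels for recovery benchmarking.

## Worked example

The numbered scripts under `analysis/` run the full study on the
default synthetic design (2,000 ortholog pairs, seed 42) and write
their tables under `results/`:

```sh
python analysis/01_simulate.py
python analysis/02_normalize_qc.py
python analysis/03_score_divergence.py
python analysis/04_de_cluster_overlap.py
python analysis/05_enrichment.py
```

`03_score_divergence.py` prints:

```
scored 2000 ortholog pairs
75th-percentile cutoff = 0.0291; 500 pairs flagged (25.0%)
divergent-archetype recovery AUROC = 0.9994
median score by planted archetype:
  divergent       3.4728
  anticorrelated  0.0455
  scaled          0.0173
  shared          0.0036
```

Exactly a quarter of the pairs clear the percentile cutoff, the planted
divergent archetype is ranked essentially perfectly (AUROC 0.999), and
the scale-invariance of A plus the sign-flip geometry of the score push
the scaled and anticorrelated archetypes down with the shared features.
`05_enrichment.py` then shows the flagged set contains all 200
divergent pairs (fold enrichment 4.0, q ≈ 3e-136).

The same pipeline is available as a CLI (`tcdiv run-all --outdir out
--seed 42`, plus per-stage subcommands `simulate`, `normalize`, `qc`,
`score`, `de`, `cluster`, `overlap`, `enrich`) and works identically on
user-supplied TSV matrices, a sample sheet, an ortholog map and GMT
gene sets — see `docs/methods.md` for formats and conventions.

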