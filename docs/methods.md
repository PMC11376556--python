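# Methods

## Setting and model

The pipeline compares how two groups (A and B — e.g. naked-mole-rat vs
mouse embryonic fibroblasts) respond over time to a shared stimulus
(0–4 h of anoxia in the motivating design), using one abundance matrix
per group and layer (RNA counts, protein intensities), a sample sheet
(group, time in hours, replicate), and a one-to-one ortholog map
joining the two groups' feature namespaces.

Per feature and group, replicates are aggregated (arithmetic mean on
the raw scale by default; median available via `aggregate`) and the
curve is expressed as a baseline-anchored log2 ratio
`r_g(t) = log2(mean_t / mean_t0)`, which is exactly 0 at the first time
point. Anchoring removes static abundance offsets between the groups —
important when absolute levels are not comparable across species or
platforms — at the cost of amplifying noise for features with weak
baseline signal.

For each mapped pair the divergence score is `(1 − |A|) × B`:

- **A** — Pearson correlation of the two curves over the shared grid
  (≥ 3 points). The baseline point is included by default
  (`include_baseline_in_shape=False` exposes the alternative): both
  curves are 0 there by construction, which mildly biases A upward but
  is the literal reading of scoring the anchored response curves. If
  either curve has zero variance A := 0, so a flat curve against a
  responsive one scores the full area; the alternative (undefined
  score) would silently drop exactly the flat-vs-responsive genes the
  method should surface.
- **B** — the absolute area between the piecewise-linear interpolants,
  in log2-ratio × hours. The default `crossing` convention splits any
  segment where the difference changes sign at the zero crossing, so B
  is the exact geometry of the curves and B = 0 iff they agree at every
  grid point. The `trapezoid_abs` alternative (trapezoid rule on the
  absolute endpoint differences) over-counts sign-crossing segments —
  e.g. curves (−1, 1) vs (0, 0) on times (0, 1) give B = 0.5 under
  `crossing` but 1.0 under `trapezoid_abs`; both are implemented
  because published descriptions of "absolute area between curves" do
  not always pin the convention down.

Pairs are ranked by descending score (dense ranks, ties ordered by the
group-A id for determinism) and flagged when strictly above the q-th
percentile of all finite scores (q = 75 by default, linear-interpolation
percentile). The percentile cutoff is an empirical quantile of each
dataset, not a portable constant. One boundary effect is worth noting:
with the interpolated percentile and strict inequality, the flagged
fraction sits in [25% − 1/n, 25%] for most n but can exceed 25% by less
than 1/(4n) when n ≡ 3 (mod 4).

## Supporting analyses

**Differential calls.** Each non-baseline time is tested against the
within-group baseline by a Welch two-sample t-test on
log2(value + pseudocount), with a variance floor of 1e-8 (log2² scale)
so exactly-replicated shifts still yield finite, extreme statistics;
degenerate features with equal means get statistic 0 and p = 1.
P-values are BH-adjusted across features separately per (group, time)
stratum, calls are q < 0.05. This is a deliberately simple, transparent
test: it feeds the same downstream set algebra (per-timepoint call
sets, cross-layer overlap) that moderated count/intensity models would,
and its monotonicity properties (calls anti-monotone in alpha) are
tested. `bh_adjust` computes the step-up values literally as
`min_{j≥i} p_(j)·m/j`, which matches the textbook definition bit for
bit; it is cross-checked against statsmodels in the tests.

**Clustering.** Ortholog pairs are clustered on the concatenated vector
[curve_A ‖ curve_B], z-scored per feature across its 2T entries
(constant vectors map to zeros), with Euclidean distance and Ward
linkage, cut into k = 4 groups by default. Labels I..k are assigned by
decreasing cluster size with lexicographic tie-breaking, so repeated
runs on identical input give identical labels. Distance, linkage and
the z-score choice are conventions, not identifiable from first
principles; they are config-exposed.

**Overlap.** RNA and protein call sets are intersected within a group
at matched times (the two layers of one group share a namespace);
overlapping features are reported as ortholog pairs where the map
covers them.

**Enrichment.** One-sided Fisher's exact test (hypergeometric upper
tail, `scipy.stats.hypergeom`), BH across the sets tested. The universe
defaults to the features scored in the run rather than the GMT union —
an inflated universe is a classic source of spurious enrichment. Gene
sets intersect the universe before testing; sets with no members in the
universe are dropped.

**QC.** Replicate reproducibility is the pairwise Pearson r between
replicates of one (group, time), computed across features on
log2(value + pseudocount) (raw scale behind a flag); RNA–protein
coupling is the per-timepoint Pearson r between the two layers' log2
ratios over jointly complete features (≥ 3 required, else NA with a
warning).

## Synthetic data

The generator emulates the motivating design: 2 groups × 5 time points
(0–4 h) × 3 replicates, RNA and protein layers, identity ortholog map
with group-prefixed ids. Latent log2 curves are piecewise linear over
the design grid with random knots (the sampling grid is the only scale
at which smoothness is observable), baseline knot forced to 0 so the
anchoring is exact on noiseless data. Archetypes relate the two groups'
curves: `shared` (identical), `scaled` (B = c·A, c ∈ [1.5, 3]),
`anticorrelated` (B = −A), `divergent` (independent), `flat` (zero).
Protein replicates are `base · 2^(curve + N(0, noise_sd))` with base
intensities log-uniform over 1e5–1e8; RNA counts are negative binomial
with mean `base · 2^(curve + noise)`, dispersion 0.1 (variance
μ + 0.1 μ²), base means log-uniform over 10–1000.

Defaults: 2,000 features — 70% shared, 10% each divergent / scaled /
anticorrelated — amplitude 2.0 log2 units (knot sd; ~4-fold typical
swings, a realistic magnitude for acute stress responses), noise_sd
0.25. These are the benchmark conditions used by the acceptance script
and the recovery tests.

What the generator does *not* model — and what passing tests therefore
do not demonstrate about real data: intensity-dependent MS missingness,
batch and library-size effects, mean–variance trends beyond the fixed
NB dispersion, and any coupling noise between RNA and protein beyond
the shared latent curve. That last simplification makes the synthetic
RNA–protein correlation high (~0.95); in real cross-species data the
coupling is far weaker, which is precisely why both layers are measured.
Recovery results (AUROC, ARI) quantify the method's behavior under the
planted-archetype model, not its power on any particular real dataset.

## Numerical choices and conventions

- TSV (tab, header, UTF-8, decimal point) is the only matrix dialect;
  `NA` is the only missing-value token; floats are written at shortest
  round-trip precision so write-then-read is exact.
- Feature ids are case-sensitive opaque strings; cross-group
  reconciliation goes only through the ortholog map. Rows of the map
  participating in many-to-many relations are dropped (and counted) to
  enforce a strict one-to-one pairing — a documented choice; validation
  is idempotent.
- Missing values propagate as per-feature "incomplete" flags, never
  imputed: a protein with zero or missing baseline, or any non-finite
  ratio, is excluded from scoring and reported.
- RNA pseudocount 1 count (added to the aggregated mean before the
  ratio); protein has none — a zero intensity means "not quantified".
- Whether replicates should be averaged before or after the log is not
  determined by the anchoring definition; aggregation happens on the
  raw scale before the ratio, and the median alternative is exposed for
  sensitivity checks.
- All stages are pure functions of their inputs; `run_all` with a fixed
  config and seed produces byte-identical tables, and writes a YAML
  manifest (config echo, seed, per-stage paths and row counts, version).

## Problem sizes

The default benchmark (2,000 pairs, 30 samples per layer-group) runs
end to end in a few seconds; the oracle suites use 1,000 random curve
pairs against a 10⁴-step Riemann sum for the area, 500 random p-vectors
against a literal step-up implementation for BH, and 200 random
configurations (N ≤ 50) against exhaustive hypergeometric summation for
Fisher p-values.

## Known limitations

- The Welch stand-in has lower power than moderated models at n = 3
  replicates; its calls are conservative inputs to the overlap step.
- The score has no attached significance measure (none is defined for
  it); the percentile flag is a ranking device, not a test.
- Two-group designs only; the score is undefined for more than two
  response curves per feature.
- Time grids must match across groups for scoring; no interpolation
  across mismatched designs is attempted.
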