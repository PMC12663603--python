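# Methods

This note describes what `musicnet` computes and how, in the package's own
terms. Mathematical conventions are stated exactly as implemented so every
number in a run report can be re-derived.

## 1. Synthetic cohort with planted structure

Because no fMRI recordings or audio ship with the package, analyses run on a
synthetic cohort whose generative structure is exported as ground truth
(`synthgen`).

**Latent regimes.** Two correlation matrices over `P` parcels define the
regimes. The *modular* regime is block-structured: `n_blocks` near-equal
contiguous blocks with within-block correlation `r_within = 0.7` and
between-block correlation `r_between = 0.1`. The *integrated* regime has
uniform off-diagonal correlation `0.4`. Both are projected to the nearest
positive-semidefinite matrix (eigenvalue clipping, diagonal rescaled to 1).
At construction the planted contrast is asserted: Louvain modularity of the
modular matrix exceeds the integrated one by at least 0.1, and global
efficiency of the integrated matrix exceeds the modular one by at least 0.05.

**Regime schedules.** Each subject x condition run follows a first-order
Markov chain over the two regimes. Transition probabilities are scaled so the
stationary modular probability is `p` and the switching timescale is
`mean_dwell_s = 30 s`. The dwell bias is condition-dependent: `p = 0.62` in
condition 1 (tonal piece) and `p = 0.38` in condition 2 (complex piece).
Per-time-point samples are zero-mean multivariate normal draws with the
scheduled regime's covariance; the standard-normal innovations are drawn once
per run so output is bit-identical given the seed.

**Group effect.** Group A ("aspiring professionals", n = 24 at study scale)
has `delta = 0.075` added to all between-block correlations of both regimes
in condition 2 only, raising its planted static global efficiency (calibrated
to a group difference of Cohen's d near 1.2 at study sample sizes). Group B
("amateurs", n = 17) uses the baseline matrices.

**Audio and coupling.** Each condition's audio is
`s(t) = (1 - alpha) * harmonic + alpha * noise`, where the harmonic part is a
unit-RMS C-major chord and the noise is iid standard normal; `alpha` is
constant per 60-s segment (condition 1: 0.0-0.4; condition 2: 0.5-1.0).
With entropy coupling enabled, each segment's modular-regime probability is
`p = clip(0.9 - 0.7 * alpha, 0, 1)`, so segment-wise audio complexity and
modular occupancy are anticorrelated by construction.

## 2. Audio descriptors (`audiofeat`)

- **Chromagram**: FFT magnitudes of 200-ms frames (5% hop) are mapped to the
  12 pitch classes by nearest semitone relative to A4 = 440 Hz, restricted to
  55-2000 Hz.
- **Key clarity**: maximum Pearson correlation between the chroma vector
  (averaged over 5-s windows, 33% hop) and the 24 Krumhansl-Kessler
  major/minor key profiles; zero-variance windows score 0.
- **Pulse clarity**: onset envelope = half-wave-rectified first difference of
  20-ms frame energies; clarity = maximum of the normalized autocorrelation
  over beat lags 0.25-2 s.
- **Permutation entropy** (Bandt-Pompe): ordinal patterns of embedding
  dimension `m = 7`, delay 1, via stable argsort (ties resolved by temporal
  order); Shannon entropy of the pattern distribution in nats, computed per
  60-s segment. The iid upper bound is `log(7!) = 8.525` nats.

## 3. Connectivity (`connectivity`)

Static FC is the Pearson correlation matrix over the full run (T = 140,
TR = 2 s), diagonal zeroed. Edges are screened by the exact t-transform
`t = r * sqrt((T-2)/(1-r^2))` with Benjamini-Hochberg FDR at q = 0.05 across
all unique edges; surviving negative edges are then zeroed before graph
analysis (and binarized for degree). Dynamic FC uses 60-s sliding windows
(30 samples) advanced 1 TR at a time — 111 windows per run — vectorized as
the row-major upper triangle.

## 4. Graph metrics (`graphmetrics`)

- **Modularity** `Q = (1/2m) * sum_ij [W_ij - s_i s_j / 2m] * delta(c_i, c_j)`
  (Newman, weighted).
- **Louvain**: igraph's multilevel algorithm, best of `n_runs` seeded
  restarts (the trivial one-community partition is always a candidate);
  negative weights are rejected.
- **Global efficiency**: mean of `1/d_ij` over pairs, with shortest paths on
  edge lengths `1/w` (Dijkstra); disconnected pairs contribute 0.
- **Degree**: binary edge count. **Participation coefficient**:
  `P_i = 1 - sum_s (k_is / k_i)^2` over communities `s`.

## 5. Brain states (`states`)

Window vectors pooled over all subjects and conditions are clustered with
k-means (best of `n_replicates` initializations). The number of states is
selected by majority vote of four validity indices — elbow (maximum second
difference of inertia, anchored at k = 1), silhouette, Calinski-Harabasz,
Davies-Bouldin — with ties to the smallest k; a maximum silhouette below 0.1
flags "no state structure". States are canonically ordered by decreasing
centroid modularity, so state 0 is always the segregated state. Downstream:
per subject x condition state frequencies, per-state window-averaged Q and
efficiency, 60-s segment occupancy, and the Pearson correlation between
segment audio entropy and modular-state occupancy pooled across conditions
(n = 10 segments).

## 6. Statistics (`groupstats`)

All formulas are written out; scipy supplies only tail probabilities. They
are cross-checked against scipy/statsmodels to 1e-10 in the test suite.

- t-tests (one-sample, Student two-sample, paired) with Cohen's d.
- Unbalanced two-way ANOVA with Type-II sums of squares via nested OLS
  residual comparisons; partial eta squared as effect size.
- Tukey-Kramer post hoc with the studentized-range distribution and the
  Kramer standard error for unequal n.
- Mann-Whitney U: exact two-sided p by the count-distribution recursion for
  untied samples with combined n <= 20, otherwise a tie-corrected normal
  approximation with continuity correction; rank-biserial effect size.
- Benjamini-Hochberg step-up FDR.
- Nodal hub workflow: per-node one-sample screen (FDR across nodes), then
  group comparison restricted to screen survivors (FDR across tested nodes),
  run per condition and metric family; edge density as a control comparison.

## 7. Pipeline (`pipeline`)

A run is a validated `RunConfig` (unknown keys rejected). `run_full` executes
synthesis -> audio features -> windows -> states -> state-wise metrics and
ANOVA -> entropy coupling -> static networks and group statistics, persisting
every intermediate under `audio/`, `fc/`, `windows/`, `states/`, `graph/`,
`stats/` and writing `report.json` with the config hash. Identical configs
give bit-identical reports; when no audio is configured the coupling stage is
skipped with an explicit flag.
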