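# musicnet

Expertise-dependent brain network organization during naturalistic music
listening, as a reproducible analysis pipeline on synthetic data.

## The scientific problem

When people listen to music, whole-brain functional connectivity is not
static: sliding-window analyses reveal recurring *brain states*, typically a
**segregated** state (high modularity, strong within-module coupling) and an
**integrated** state (high global efficiency, diffuse coupling). Three
questions drive this package:

1. **Dynamics**: do listeners alternate between segregated and integrated
   connectivity states, and does the balance depend on the piece being
   played?
2. **Audio coupling**: does the moment-to-moment complexity of the audio
   (measured by permutation entropy) track the brain's state occupancy —
   more complex sound, less time in the segregated state?
3. **Expertise**: do musicians with more training show higher static global
   efficiency of their listening networks, and in which condition?

The original study data (fMRI during music listening, copyrighted audio) is
not distributable, so `musicnet` ships a **synthetic cohort generator** that
plants exactly these three effects — two latent covariance regimes with
condition-dependent dwell, a per-segment audio-complexity/regime coupling,
and a group-wise efficiency boost — and the analysis pipeline that recovers
them. Every planted parameter is exported as ground truth, so recovery is
testable end to end.

## The model in brief

- **Cohort**: two groups (24 + 17 subjects at study scale; 7 + 5 in the fast
  small profile), two 5-minute listening conditions, 112 (or 20) parcels at
  TR = 2 s.
- **Regimes**: a modular block-structured correlation matrix vs. a uniform
  integrated one; a first-order Markov chain switches between them
  (mean dwell 30 s), biased toward the modular regime under the tonal piece
  (p = 0.62) and away from it under the complex piece (p = 0.38).
- **Audio**: per 60-s segment, `s(t) = (1-alpha) * C-major chord +
  alpha * noise`; with coupling enabled the modular-regime probability is
  `0.9 - 0.7 * alpha`.
- **Group effect**: between-block correlations boosted by 0.075 for group A
  in condition 2, a static global-efficiency difference of d ≈ 1.2 at study
  sample sizes.
- **Analysis**: 60-s sliding-window Pearson FC → pooled k-means brain states
  (k by four validity indices) → per-state Louvain modularity and global
  efficiency → two-way ANOVA + Tukey–Kramer, paired frequency t-test,
  entropy–occupancy correlation → static FC with FDR edge screening → group
  t / Mann–Whitney tests and a nodal hub workflow.

See `docs/methods.md` for exact conventions.

## Worked example

The full demo pipeline (small synthetic profile, entropy-coupled audio) runs
in under half a minute:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

which prints (real output):

```
modular_state_frequency_pct: 56.9820
integrated_state_frequency_pct: 43.0180
modular_state_modularity_q: 0.2773
integrated_state_modularity_q: 0.0589
modular_state_global_efficiency: 0.3240
integrated_state_global_efficiency: 0.4089
state_frequency_paired_t: 8.1200
state_frequency_paired_p: 0.0000
anova_state_f_modularity: 391.2071
anova_state_f_efficiency: 119.6707
entropy_state_pearson_r: -0.7741
entropy_state_pearson_p: 0.0086
group_efficiency_t_cond2: 1.0244
group_efficiency_p_cond2: 0.3298
group_efficiency_cohens_d_cond2: 0.5999
group_efficiency_mannwhitney_u_cond2: 12.0000
edge_density_group_p_cond2: 0.6875
audio_entropy_mean_cond1: 6.1452
audio_entropy_mean_cond2: 8.4115
```

All three planted effects appear: the modular state is more frequent overall
and far more modular (Q 0.277 vs 0.059) while the integrated state is more
efficient (E 0.409 vs 0.324); segment audio entropy anticorrelates with
modular-state occupancy (r = −0.77, p = 0.009); and the group-A efficiency
advantage in condition 2 points the right way (d = 0.60) but is underpowered
at the 12-subject demo size — the acceptance suite verifies ≈95% power at the
study size of 24 + 17.

The same run is available through the CLI:

```bash
musicnet demo --out scratch/demo --seed 1   # full run directory + report.json
musicnet run --config run.yaml              # any schema-validated config
```

## Repository layout

```
src/musicnet/     synthgen, audiofeat, connectivity, graphmetrics,
                  states, groupstats, pipeline, cli
analysis/         numbered analysis drivers writing results/
tests/            unit suite + oracle-based end-to-end recovery tests
scripts/          acceptance.py (seeded headline-number run)
docs/methods.md   methods note
```
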