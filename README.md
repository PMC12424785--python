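# fishsleep

Poisson hidden-Markov-model analysis of larval-zebrafish sleep/wake
architecture from 1-minute-binned locomotor activity.

The package implements the full behavioral sleep-analysis pipeline:

- **`fishsleep.hmm`** — count-emission (Poisson) HMM: scaled
  forward–backward likelihood and posteriors, exact Viterbi decoding,
  Baum–Welch EM over one or more animals, seeded sampling, BIC scoring
  (`p = K² + K − 1`), per-observation emission posteriors, and stationary
  occupancy via the dominant left eigenvector of the transition matrix.
- **`fishsleep.selection`** — multi-restart maximum-likelihood fitting, BIC
  selection of the number of states (default range 2–6), surrogate-data
  model-order recovery, and data-length sufficiency experiments.
- **`fishsleep.semantics`** — canonical state naming by ascending activity
  rate (4 states: S2, S1, W1, W2; 3 states: S2, S1, W), 60-min smoothed
  state-probability time courses, day/night state proportions, bout
  statistics (bouts split at light transitions), and activity-conditioned
  state-assignment fractions.
- **`fishsleep.metrics`** — conventional sleep (zero-activity bins) and its
  comparison with decoded S2 occupancy against the identity line.
- **`fishsleep.stats`** — seeded label-permutation tests on per-animal HMM
  parameters (Bonferroni families: ×4 occupancies/rates, ×16 transitions),
  Welch/paired t-tests with Benjamini–Hochberg correction on state amounts,
  and the sleep-deprivation rebound contrast (night-2 rebound window vs the
  clock-matched night-1 window).
- **`fishsleep.arousal`** — stimulus-response analysis: shared-model cohort
  fitting, complete-state-usage filtering, baseline-corrected 2-s response
  proportions per state, and matched-activity arousability.
- **`fishsleep.synth`** — seeded generators for diel regime-switching
  cohorts, effect cohorts (phenomenological rate/transition edits),
  sleep-deprivation schedules with a rebound regime, and per-second arousal
  assays. Ground truth (hidden paths, per-animal parameters) is kept in the
  manifest for recovery testing.
- **`fishsleep.io` / `fishsleep.pipeline` / `fishsleep.cli`** — wide-CSV
  trace I/O with strict validation, YAML experiment config, and an
  end-to-end orchestrator.

## CLI

```sh
fishsleep simulate --scenario baseline --n 24 --seed 3 --out sim/
fishsleep select-k --input sim/traces.csv --k-min 2 --k-max 6 --restarts 20 --seed 7 --out selection.json
fishsleep fit --input sim/traces.csv --k 4 --restarts 20 --seed 1 --out fit.json
fishsleep recover --params fit.json --replicates 100 --length 2880 --out recovery.json
fishsleep label --input sim/traces.csv --params fit.json --out states.csv
fishsleep metrics --input sim/traces.csv --out metrics/
fishsleep compare --group-a a/traces.csv --group-b b/traces.csv --perms 10000 --seed 11 --out compare.tsv
fishsleep simulate --scenario arousal --n 24 --seed 5 --out assay/
fishsleep arousal --seconds assay/seconds.csv --out arousal/
fishsleep simulate --scenario deprivation --n 12 --seed 9 --out dep/
fishsleep deprivation --input dep/traces.csv --out rebound.tsv
```

Production-scale runs use 1000 EM restarts per fit; the CLI defaults are
smaller so desk-scale runs finish quickly — pass `--restarts 1000` to match
the full protocol.

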