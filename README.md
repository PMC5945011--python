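# racestop

Tools for picture-word-interference **stop-signal** experiments: build the
counterbalanced 320-trial schedule, simulate trial outcomes under the
independent horse-race model, apply the standard exclusion/trimming rules,
estimate stop-signal RTs (SSRT) with the integration method, and run
within-subject permutation inference.

## What it does

- **`racestop.stimuli`** — 40-item picture/distractor set (TSV fixture plus
  loader): each picture is paired with a semantically related distractor from
  its own category and an unrelated distractor borrowed from another item.
- **`racestop.design`** — builds 4 blocks x 80 trials (60 go + 20 stop per
  block; stop trials split 10 related / 10 unrelated and 10 per SSD at 250 or
  325 ms), counterbalances which pictures get which SSD across participants,
  and pseudorandomizes block order by rejection sampling (no run of more than
  4 same-condition trials, no consecutive same-category or same-onset
  pictures). `validate_design` audits any schedule against the full contract.
- **`racestop.racemodel`** — independent race between an ex-Gaussian go
  process and a stop process launched at SSD; supports fixed-SSD experiments
  and the one-up/one-down tracking staircase; responses beyond the 1250 ms
  window are unobservable.
- **`racestop.preprocess`** — trial classification (go correct / error /
  miss, stop success / fail), single-pass mean +/- 2.5 SD trimming per
  participant x condition, and tidy per-condition summary tables.
- **`racestop.ssrt`** — integration-method SSRT per participant x SSD x
  condition (`nth go RT - SSD`, with `n = round(N x p(respond|signal))`),
  plus the mean method for tracking data.
- **`racestop.stats`** — paired sign-flip permutation tests (exact
  enumeration for small n) and the 2x2 within-subject factorial version.
- **`racestop.synthetic_data`** — calibrated cohort generator with a
  ground-truth sidecar for parameter-recovery testing.

## CLI

```sh
# one pseudorandomized schedule CSV per participant
racestop design --participants 4 --seed 1 --out designs/

# synthetic cohort of trial logs + ground_truth.json
racestop simulate --participants 36 --seed 42 --out data/

# classify, summarize, estimate SSRT, permutation inference
racestop analyze --in data/ --out results/
```

`racestop simulate --config params.yaml` accepts a YAML race-parameter file
mirroring `RaceParameters` (see `racestop.synthetic_data.params_to_yaml`).

## Python example

```python
import racestop as rs

stimuli = rs.bundled_stimuli()
assignment = rs.default_assignments(stimuli, seed=1)[0]
schedule = rs.build_design(stimuli, assignment, seed=1)

params, shifts = rs.default_parameters()
records = rs.simulate_experiment(schedule, params, seed=1)

from racestop.preprocess import classify_trials
from racestop.racemodel import records_to_frame

classified = classify_trials(records_to_frame(records))
estimates = rs.estimate_table(classified)   # SSRT per SSD x condition
```

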