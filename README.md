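# sleeplife

Estimation of cardiovascular-disease-free life expectancy and years of
life lost across sleep profiles, as a tested, reusable pipeline:

1. **Sleep phenotyping** (`sleeplife.phenotyping`) — a composite sleep
   score from five questionnaire responses (morning chronotype, 7 to <9
   h/day duration, no usual insomnia complaints, no snoring, no frequent
   daytime sleepiness; poor ≤1 / intermediate 2–3 / healthy ≥4), and
   clinical sleep-disorder flags (insomnia, sleep-related breathing
   disorders, other) from coded clinical events and prescriptions via
   vocabulary-aware code lists (ICD-9/10, Read v2, CTV3, BNF) with a
   2-year pre-enrollment lookback. Includes a confusion-matrix operation
   for self-report vs diagnosis agreement.
2. **Cohort building** (`sleeplife.cohort`) — a fixed four-stage
   exclusion cascade (missing sleep responses → prevalent CVD → missing
   covariates → events within a 2-year landmark), follow-up truncation at
   the τ = 81 restriction, and expansion into counting-process rows for
   the three-state illness-death structure (CVD-free → CVD → death) on
   the age timescale with left truncation at enrollment.
3. **Survival engine** (`sleeplife.survival`) — transition-specific Cox
   proportional-hazards fits (Newton–Raphson with step-halving, Efron
   ties, delayed entry), Breslow baseline cumulative hazards, profile
   prediction, and Fine–Gray subdistribution-hazard models with IPCW
   weighting for competing risks.
4. **Lifetime estimation** (`sleeplife.lifetime`) — Aalen–Johansen
   product-integral occupation curves from age 40 to 81, exact
   integration into restricted CVD-free / with-CVD / total life
   expectancies, years-of-life-lost contrasts, and person-level
   nonparametric bootstrap percentile confidence intervals.
5. **Synthetic cohorts** (`sleeplife.synthetic`) — a generator with known
   Gompertz proportional-hazards transition intensities, correlated sleep
   responses, covariates, coded events, missingness, plus a quadrature
   oracle for the true restricted life expectancies, so every stage is
   testable offline against ground truth.

## Command line

```sh
sleeplife simulate --n 20000 --seed 1 --out results/sim
sleeplife phenotype --participants results/sim/participants.csv \
    --events results/sim/events.csv --out results/phenotyped.csv
sleeplife build --phenotyped results/phenotyped.csv --out results
sleeplife estimate --followup results/followup.csv --bootstrap 200 --seed 1
sleeplife finegray --followup results/followup.csv
sleeplife run-all --n 20000 --seed 1 --bootstrap 200 --out results/run
```

`run-all` chains every stage and writes the exclusion report, the
multistate dataset, the Table-2-shaped estimates (per-sex expectancy and
years-of-life-lost with 95% CIs), the Fine–Gray hazard-ratio table, and a
run manifest (`manifest.json`) recording config, seed, versions and stage
counts. Reruns with the same config and seed are byte-identical. A YAML
config can replace the flags: `sleeplife run-all --config run.yaml`.

User data can be supplied in `files` mode as delimited text in the same
schema the simulator writes (`participants.csv`, `events.csv`; `NA` as
the missing token, ISO-8601 dates). Code lists are editable YAML
(disorder → vocabulary/code entries with exact or prefix matching); the
shipped defaults are illustrative one-code-per-disorder lists.

## Library use

```python
import sleeplife as sl
from sleeplife import cohort, phenotyping, pipeline

truth = sl.SimulationTruth(seed=1)
participants, events = sl.generate_cohort(truth, 20_000)
scored = phenotyping.score_frame(participants)
kept, report = cohort.apply_exclusions(scored, sl.DEFAULT_COVARIATES)
followup = cohort.build_followup(kept)
summaries, fits = pipeline.estimate_expectancies(
    followup, covariates=sl.DEFAULT_COVARIATES
)
pipeline.bootstrap_expectancies(followup, summaries,
                                covariates=sl.DEFAULT_COVARIATES,
                                B=1000, seed=1)
```

Life expectancies are profile-conditional: covariates are fixed at the
stratum mean (continuous), median category (ordered) or mode (nominal),
and when contrasting one sleep characteristic the remaining sleep
variables are held at their healthy level. All randomness flows from a
single seed; fits serialize to JSON for reuse and resumption.
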