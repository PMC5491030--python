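# milieu

Health behaviors — exercising, smoking, drinking, eating fruit or fast food —
are performed inside a crowded two-week routine of *other* lifestyle
activities (studying, socializing, clubbing, sleeping in).  `milieu`
implements an analysis strategy for two-wave lifestyle questionnaires that
asks whether cognitions about, and performance of, those other activities
improve the prediction of health behavior beyond behavior-specific
cognitions and past behavior, and *for whom* they matter most.  It is aimed
at health-psychology and behavioral-epidemiology researchers working with
theory-of-planned-behavior style questionnaires.

## The analysis

Per participant the data are: baseline two-week frequency counts for 5
health behaviors and 23 lifestyle activities, four cognition scores
(intention, attitude, subjective norm, perceived behavioral control) on 1–7
scales for each behavior, five personality scales (locus of control,
ACS-preoccupation, ACS-hesitation, self-esteem, generalized self-efficacy),
and follow-up counts for all 28 behaviors two weeks later.

1. **Target.** Every variable is z-scored; counts of the three health-*risk*
   behaviors (smoking, getting drunk, fast food) are multiplied by −1.  The
   *health behavior index* is the mean of the five reversed follow-up health
   z-scores.
2. **Prediction waves.** A small early-stopped perceptron (one hidden tanh
   layer, linear output) estimates the index from each of five predictor
   blocks separately — health cognitions (20 columns), personality (5),
   lifestyle cognitions (92), lifestyle activities (23), baseline health
   behaviors (5) — plus a sixth *saturated* wave on all blocks together.
3. **Incremental validity.** The actual index is regressed on the wave
   estimates hierarchically: step 1 health cognitions, step 2 + personality,
   step 3 + both lifestyle estimates, step 4 + baseline behavior, with
   adjusted R², ΔR², standardized β and F-change per step,

   `F_change = ((R²_full − R²_reduced)/q) / ((1 − R²_full)/(n − p − 1))`.
4. **Subgroups.** Participants are clustered on their standardized
   predictors plus the saturated estimate (Ward tree for choosing k, k-means
   refinement), ordered by mean index into high → very-low engagement
   groups, and every variable is profiled per group with Cohen's d against
   the remaining participants pooled,

   `d = (x̄_g − x̄_rest) / s_pooled`,

   flagged *salient* when `|d| ≥ 0.50`.

Because raw data of this design are not publicly deposited, the package
ships a synthetic generator (`milieu.simulate`) that emulates the schema and
plants known structure — a four-group mixture with unequal sizes (92/50/64/5
at n = 211), block-specific incremental variance, a lifestyle–health
conflict mechanism, and an activity–activity interaction — so every stage of
the pipeline can be validated by recovery.

## Worked example

```bash
milieu analyze --out run/ --seed 1        # simulates the default design
milieu report --run run/
```

or in Python:

```python
import milieu
raw, truth = milieu.generate_dataset(milieu.default_study_config(), seed=42)
std    = milieu.standardize(raw)
blocks = milieu.assemble_blocks(std)
y      = std.health_index.to_numpy()
waves  = milieu.run_prediction_waves(blocks, y, random_state=1)
result = milieu.hierarchical_regression(waves, y)
```

On the default synthetic design with master seed 1 the pipeline prints:

```
step 1: adjR2=0.58  dadj=0.58  F(1,209)=286.94
step 2: adjR2=0.58  dadj=0.01  F(1,208)=4.88
step 3: adjR2=0.61  dadj=0.03  F(2,206)=8.59
step 4: adjR2=0.66  dadj=0.05  F(1,205)=32.32
final : adjR2=0.66  F(5,205)=83.89
k=4  sizes=(91, 65, 50, 5)  engagement d = 1.29 / 0.13 / -1.28 / -2.52
```

Reading: health cognitions alone already predict the index well here (the
generator routes much of the planted signal through motivation); the two
lifestyle estimates still add significant incremental variance at step 3
(F-change p < .001), which is the planted lifestyle-conflict mechanism being
detected.  The cluster stage recovers the four planted groups (adjusted Rand
index 0.98 against ground truth), including the five committed smokers, and
the salience profile flags the planted signature of the low-engagement
group — e.g. "go clubbing" counts at d = 1.40, well past the 0.50 salience
rule.

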