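# sealteb

Time–energy budgets for fur seals from low-resolution tri-axial
accelerometry.

Juvenile otariids (fur seals and sea lions) make multi-day foraging
trips during which direct metabolic measurement is impossible.
`sealteb` implements a captive-to-wild pipeline for reconstructing
their daily energy expenditure (DEE) from 1 Hz accelerometer, wet/dry,
depth and temperature channels:

1. **Classify behaviour.** Acceleration is windowed into epochs (7, 15
   or 21 samples at 1 Hz; 13, 25 or 75 at 20 Hz) and summarised by a
   fixed registry of 52 statistics — per-axis moments, the magnitude
   statistic *q*, axis correlations, posture angles, and the dynamic
   body acceleration family (static = 3-s running mean; PDBA = raw −
   static; ODBA = Σ|PDBA|; VeDBA = ‖PDBA‖₂). A gradient-boosted tree
   ensemble trained on labelled captive sessions assigns each epoch a
   probability of *foraging*, *travelling*, *grooming* or *resting*.
2. **Segment.** Location per second comes from the wet/dry switch and
   depth (dry → land; wet ≤ 1 m → surface; > 1 m → underwater).
   Classified epochs are merged into behaviour events with a 15-s
   persistence rule; dives (≥ 5 m) and trips (wet intervals with a
   dive ≥ 10 m) are summarised from the zero-offset-corrected depth
   channel.
3. **Cost.** Each event is costed in l O₂ kg⁻¹ min⁻¹ by behaviour
   group, location and austral season — e.g. resting in water follows
   the temperature-dependent postprandial rule
   1.6 × (0.00195 + 0.00029 · T), resting on land is 0.0049 (winter) /
   0.0063 (summer), activity costs 0.0303 in water and twice that on
   land — then summed midnight-to-midnight and converted to MJ
   (5 kcal per l O₂, 4.186 kJ per kcal):

   DEE (l O₂) = Σₑ R_{s,l} + Σₑ A_{s,l} + Σₑ G_{s,l}

4. **Probe.** A sensitivity analysis simulates daily time-budget
   proportions over (active, grooming, resting), costs each simulated
   day, and relates DEE to the fraction of time per behaviour and
   location.

A synthetic-data module generates labelled captive-style sessions
(semi-Markov behaviour runs with behaviour-specific acceleration
signatures) and wild-style deployments (haul-outs, trips, dive cycles,
optional depth-sensor drift and 20 Hz dive-triggered bursts), so the
whole pipeline is testable end-to-end without field data.

## Worked example

```python
import numpy as np
from sealteb import (
    generate_captive_session, epoch_features, EpochConfig,
    TrainConfig, train_gbm, BehaviourEvent, daily_budgets,
)
from sealteb.classifier import SMALL_GRID

# train on a synthetic captive session (2 h per behaviour, 1 Hz)
trace, labels = generate_captive_session(seed=11, duration_s=8 * 3600)
feats = epoch_features(trace, labels, EpochConfig(rate_hz=1, epoch_samples=21))
model, report = train_gbm(feats, TrainConfig(parameter_grid=SMALL_GRID,
                                             cv_folds=3, seed=11))
print(f"out-of-sample accuracy {report.out_of_sample_accuracy:.3f}, "
      f"kappa {report.kappa:.3f}")

# cost a known day: 12 h resting ashore + 12 h active at sea, 50 kg, winter
events = [
    BehaviourEvent("resting", "land", 0, 720 * 60, season="winter"),
    BehaviourEvent("travelling", "surface", 720 * 60, 1440 * 60,
                   season="winter", water_temp_c=14.0),
]
(day,) = daily_budgets(events, mass_kg=50.0)
print(f"DEE = {day.dee_l_o2:.1f} l O2 = {day.dee_mj:.2f} MJ")
```

prints

```
out-of-sample accuracy 0.953, kappa 0.938
DEE = 1267.2 l O2 = 26.52 MJ
```

i.e. the model recovers the four behaviours from the synthetic session
well above chance, and the example day costs (0.0049 × 720 + 0.0303 ×
720) × 50 = 1267.2 l O₂ ≈ 26.5 MJ.

The same stages are available from a shell:

```sh
sealteb run-all --seed 1 --out runs/demo
sealteb sensitivity --seed 1 --out sens.csv --plot sens.png
```

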