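# molli-ptnn

Personalized, simulation-trained neural-network T1 mapping for cardiac MOLLI
acquisitions — with a full Bloch-equation MOLLI simulator, the conventional
3-parameter Look-Locker fit as baseline, and ground-truthed digital phantoms.

## The problem

MOLLI (Modified Look-Locker Inversion recovery) is the clinical workhorse for
myocardial T1 mapping: after an adiabatic inversion, single-shot bSSFP images
are acquired at several heartbeats, e.g. 5(3)3 (5 images, 3 recovery beats, 3
images) or the faster 5(0)3. The standard pixelwise estimator fits

    S(TI) = A − B·exp(−TI/T1*),   T1 = T1*·(B/A − 1)

to the 8 magnitude samples (Levenberg–Marquardt, with magnitude-polarity
restoration). This model ignores the bSSFP readout physics, so the fitted T1
reads systematically low — worst for short-T2 tissue like myocardium.

The alternative implemented here trains a small regression network **per
acquisition**: the subject's actual ECG R-wave times fix the exact inversion
times of that scan, a Bloch simulator generates the 8-sample MOLLI signal for
every (T1, T2) combination on a physiological grid under precisely that
timing, Gaussian noise augmentation (SNR 40, ×10) and unit-norm scaling
produce a training set, and a dense network (8 → 40 → 20 → 8 → 1, ReLU, Adam
with lr 0.001, β₁ 0.6, β₂ 0.95, batch 20, 100 epochs, 70/28/2 split) learns
the mapping from a normalized signal to T1 in ms. Because the network is
trained on the true acquisition physics, it does not inherit the fit model's
T2-dependent bias.

The simulator propagates 21 isochromats across the slice profile through the
scheduled sequence — 4.74 ms hyperbolic-secant adiabatic inversion, 490 µs
TBW-4 sinc excitations at 35°, 10 ramped preparation pulses and 62
phase-encode lines per single-shot image — integrating shaped RF at the 5 µs
raster with relaxation inside the pulses.

## Worked example

```python
import numpy as np
from molli_ptnn import *

# 1. a 60 bpm simulated ECG and the clinical 5(3)3 scheme
triggers = synthesize_triggers(mean_rr=1000, sd_rr=0, n_beats=12, seed=1)
schedule = build_schedule("5(3)3", triggers)
print("effective TIs (ms):", schedule.effective_tis)

# 2. personalized signal database on the reduced (T1, T2) grid
params = SequenceParams()
db = build_database(schedule, params, GridSpec(t1_step=100, t2_step=5))
db = augment_with_noise(db, NoiseConfig(snr=40, n_instances=10, seed=1))
db = normalize_database(db)
print("database entries:", len(db))

# 3. train the per-acquisition network (70/28/2 split, 100 epochs)
train, val, test = split_dataset(db, SplitSpec(seed=1))
net = train_network(train, val, seed=1)
print(f"validation MSE: {net.validation_loss_curve[0]:.0f} -> "
      f"{net.validation_loss_curve[-1]:.0f} ms^2")

# 4. estimate T1 for a myocardium-like tissue (T1 1000 ms, T2 45 ms)
signal = simulate_molli_signal(schedule, params, 1000.0, 45.0)
t1_nn = net.predict(normalize_signal(signal).magnitudes[None, :])[0]
t1_fit = fit_three_parameter(signal.effective_tis, signal.magnitudes).t1
print(f"true T1 1000 ms -> network {t1_nn:.0f} ms, conventional fit {t1_fit:.0f} ms")
```

Output (about one minute on one CPU):

```
effective TIs (ms): [ 100. 1100. 2100. 3100. 4100.  180. 1180. 2180.]
database entries: 10780
validation MSE: 3098 -> 1806 ms^2
true T1 1000 ms -> network 970 ms, conventional fit 872 ms
```

The effective TIs show the two inversion groups accumulating the actual RR
intervals; the 1,078-entry grid becomes 10,780 training rows after tenfold
noise augmentation. For this short-T2 tissue the conventional fit
underestimates T1 by ~13 % while the simulation-trained network lands within
3 % — the central accuracy claim, reproduced end to end.

Pixelwise maps work the same way through `compute_t1_map`, digital phantoms
through `default_phantom_set` / `generate_phantom_stack`, and agreement
statistics (modified Bland–Altman bias and limits, slope/intercept/R²,
percent error) through `agreement`. A thin CLI (`molli-ptnn triggers /
simulate-db / train / map / phantom / evaluate`) wraps the same functions for
shell use.

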