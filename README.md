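# repcount

Training-free counting of exercise repetitions from 3-axis accelerometer
recordings.

In home physical therapy, the movements worth tracking are often unique to
the patient, so classifiers pretrained on a fixed exercise vocabulary do not
apply. `repcount` implements three simple counting methods that need no
training data and no knowledge of the exercise being performed, together
with the preprocessing that makes them work, a synthetic benchmark
generator with known ground-truth counts, and an RMSE evaluation harness.

## Method

A recording (time, x, y, z; m/s² or g) is resampled onto a uniform grid
(default 50 Hz) and collapsed to one scalar signal per sample. Taking the
plain vector norm would half-wave-rectify the motion, so the norm is signed
relative to a gravity baseline ĝ estimated by a long-window (2 s) centered
moving average of each axis: with dynamic component d = a − g,

    X_i = sgn(d_i · ĝ_i) · ‖d_i‖ .

Three counters consume X:

- **threshold** — place a threshold at τ = min X + ⅔·(max X − min X); count
  upward crossings (X_{i−1} < τ ≤ X_i), suppressing crossings within a
  0.1 s refractory period after each counted one.
- **threshold_lowpass** — identical, after the first-order recursive
  low-pass A_{i+1} = 0.9·A_i + 0.1·X_i (τ recomputed on the filtered
  signal).
- **fourier** — remove the mean, find the dominant frequency f* of the
  magnitude spectrum within 0.2–5 Hz, and report count = round(f*·T) for a
  session of duration T.

Accuracy is scored as the root-mean-square error between estimated and true
counts over sessions, tabulated per exercise and per method.

Because raw recordings of this kind are generally not shareable, the
package ships a simulator of 30-second exercise bouts (gravity + periodic
motion with harmonics, tempo and amplitude jitter, end-of-rep holds, white
noise) with ten archetypes spanning large periodic motions (arm circles,
squats) to small irregular ones (bridges, upper trunk rotations). See
`docs/methods.md` for the model and its limits.

## Worked example

Simulate a benchmark (18 simulated subjects × 10 archetypes), count one
session, and score all methods:

```sh
$ repcount simulate --out demo_bench --subjects 18 --seed 20201010
wrote 180 sessions, manifest: demo_bench/manifest.csv

$ repcount count --input demo_bench/s00_arm_circle.csv --method all
threshold: count=21  duration=30.00 s  threshold=2.2261 m/s2
threshold_lowpass: count=21  duration=30.00 s  threshold=1.4716 m/s2
fourier: count=21  duration=30.00 s  dominant_freq=0.6995 Hz

$ repcount evaluate --manifest demo_bench/manifest.csv
                      threshold  threshold_lowpass  fourier
exercise
arm_circle                 0.24               0.00     0.58
bicep_curl                27.36               1.11     0.91
bridge                    60.76               4.67    10.90
...
Avg RMSE                  41.20               2.20     3.84
```

This arm-circle session truly contains 21 repetitions; all three methods
recover it exactly (the spectral peak at 0.70 Hz × 30 s = 21). In the full
table, rows are exercises and cells are RMSE in counts — lower is better.
The noisy, irregular archetypes (bridge, upper trunk rotation) are hardest
for every method; the unfiltered threshold counter over-counts badly on
them because noise re-crosses the threshold, while low-pass filtering
suppresses most of that. The final row is the pooled RMSE over all 180
sessions: threshold crossing with low-pass filtering is the most effective
method, the Fourier approach is close behind, and raw threshold crossing
trails far behind.

The same pipeline runs on real recordings: any delimited text file with
columns `t,x,y,z` works with `repcount count`, and `repcount evaluate`
scores a manifest of labeled sessions (sessions whose participant and
observer counts disagree are excluded from scoring).

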