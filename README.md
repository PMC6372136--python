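# pulseattractor

Attractor-reconstruction analysis of arterial pulse waveforms (and any
other approximately periodic physiological signal: PPG, respiratory
impedance, central venous pressure).

## The problem

Continuous waveforms from bedside monitors and telemetry implants are
routinely collapsed into a handful of averaged numbers — heart rate,
systolic/diastolic pressure — discarding the morphology of every pulse
wave. Beat-by-beat feature detection (peak finding) recovers some of
that information but is fragile under baseline wander and requires
editing or filtering that can bias the signal.

`pulseattractor` takes the opposite approach: it uses **every raw
sample, with no preprocessing** beyond optional exclusion of
non-physiological artifact intervals, and re-plots the signal in a
coordinate system where baseline wander is invisible by construction
and waveform shape and its beat-to-beat variability become directly
measurable quantities.

## The method

For a signal x(t) with average cycle length T (estimated from a
Hann-tapered normalized autocorrelation of the whole window — no beat
detection), the signal is embedded in three dimensions with delay
coordinates at τ = T/3:

    (x(t), x(t−τ), x(t−2τ))

The trajectory is then rotated so one axis lies along the main
diagonal (1,1,1):

    u = (x + y + z)/√3          — carries the mean level and all
                                  baseline wander
    v = (x + y − 2z)/√6         — the "morphology plane", invariant
    w = (x − y)/√2                to any additive baseline shift

Viewed in the (v, w) plane, an approximately periodic pulse traces a
triangular attractor with three-fold symmetry (advancing time by T/3
rotates the plane by 120°). Per sliding window the package quantifies:

| feature          | physiological correlate                              |
|------------------|------------------------------------------------------|
| `HR_bpm` = 60/T  | heart rate, robust to baseline wander                |
| `size`           | pulse pressure (amplitude of the waveform)           |
| `rotation_deg`   | downstroke concavity; clockwise = more concave       |
| `arm*_width`     | beat-to-beat variability of specific waveform parts  |
| `edge_cv*`       | non-uniform density along a side (upstroke convexity)|
| `periodicity`    | mean arm width / size; 0 = perfectly repeating pulse |
| `u_mean, u_trend`| absolute level and drift (what (v,w) factors out)    |

A parametric pulse-train generator (`pulse_synth`-style in-silico
waveforms with controllable period, amplitude, upstroke fraction,
downstroke concavity, per-beat jitter, baseline wander and noise)
provides ground-truthed inputs for calibration and testing.

## Worked example

```python
from pulseattractor import AttractorModel, PulseModelParams, generate_pulse_train

sig = generate_pulse_train(
    PulseModelParams(T=0.5, A=40.0, noise_sd=0.8, seed=1), 60.0, 1000.0
)
res = AttractorModel(sig).fit()
print(res.summary())
```

```
Attractor reconstruction results
==========================================================
record duration            60.0 s   fs 1000 Hz
windows                      11   (0 flagged)
window / step              10.0 / 5 s
----------------------------------------------------------
feature                 mean          sd           units
----------------------------------------------------------
HR_bpm                   120     0.00625             bpm
size                   39.85      0.0132            a.u.
rotation_deg       -0.008188      0.0621             deg
arm1_width            0.6467     0.00764            a.u.
arm2_width            0.5598      0.0047            a.u.
arm3_width            0.6506     0.00497            a.u.
periodicity          0.01553    0.000123               -
u_mean                 19.99     0.00427            a.u.
u_trend             0.003661     0.00215          a.u./s
==========================================================
```

The 60 s record at 120 bpm yields 11 overlapping 10 s windows. The
estimated rate is exact (60/0.5 s = 120 bpm); the attractor size 39.85
recovers the generated pulse amplitude of 40 signal units within 0.4%;
rotation sits at the zero reference because the generated downstroke
is straight; and the small periodicity score (≈0.016) reflects a
nearly periodic train whose arm widths come only from the 2% additive
measurement noise. `res.plot_attractor(0)` renders the first window's
triangular density; `res.features` is the full per-window DataFrame.

The same pipeline is available from the shell:

```bash
pulseattractor synth --T 0.5 --A 40 --noise-sd 0.8 --duration 60 \
    --fs 1000 --seed 1 --out wave.csv
pulseattractor track --input wave.csv --window 10 --step 5 \
    --species human --out features.csv
pulseattractor features   # column documentation
```

`track` writes one CSV row per window plus a JSON sidecar echoing the
resolved configuration; `--mask intervals.csv` excludes artifact
intervals, and `--fixed-extent B` pins the density grid extent when
densities from different windows must be compared.

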