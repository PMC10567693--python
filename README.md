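# pitchload

Per-pitch elbow-load analysis for repetitive baseball pitching: marker-based
inverse dynamics of the throwing arm yielding the peak external elbow valgus
torque, EMG-derived flexor-pronator activity and biceps-triceps
co-contraction, 10-pitch moving-window magnitude/variability series, and
nested random-intercept/random-slope linear mixed-model comparison. A
synthetic session generator with full ground truth stands in for
motion-capture recordings, so every stage is testable end to end.

## Modules

| module | role |
| --- | --- |
| `pitchload.synthetic` | multi-pitcher session generator: smooth parameterized throwing-arm motion with a numerically calibrated mapping from true peak valgus torque to motion amplitude; EMG bursts on the 150 ms pre-MER window; accelerometer traces with device clock offsets; lossless ground truth |
| `pitchload.kinematics` | anatomical frames from six arm landmarks + trunk markers, elbow floating-axis (flexion - ab/adduction - pronation) and shoulder y-x-y angle decompositions, MER detection, differentiation, gap handling, mirroring of left-handed throwers |
| `pitchload.dynamics` | segment inertial scaling (embedded adjusted male fraction table), top-down Newton-Euler propagation from the hand to the elbow, torque expressed in the elbow anatomical frame, quadratic-refined peak valgus torque near MER |
| `pitchload.emg` | rectify + zero-phase low-pass linear envelope (2nd-order design run forward/backward), MVC normalization, per-sample co-contraction index `(low/high)*(low+high)`, trapezoid AUC over the EMD-compensated 150 ms window |
| `pitchload.session` | device synchronization on peak trunk forward acceleration, per-participant 10-pitch moving-window means and SDs (sample SD, windows over consecutive valid pitches; strict mode available) |
| `pitchload.stats` | nested ML mixed models M1 (random intercept) ⊂ M2 (+ fixed window-number slope) ⊂ M3 (+ random slope, unstructured covariance); chi-square LRT ladder with AIC tie-break; Wald-t CIs for the slope, Wald-log CIs for random-effect SDs; 50:50 chi-square mixture p reported as a boundary diagnostic |

## CLI

```bash
pitchload simulate --config session.yaml --out data/
pitchload torque   --markers data/markers --anthro data/anthro.csv --out pitches.csv
pitchload emg      --signals data/signals --mvc data/mvc --markers data/markers \
                   --events pitches.csv --out pitches_emg.csv
pitchload windows  --pitches pitches_emg.csv --out windows.csv
pitchload lmm      --windows windows.csv --out results/
```

`session.yaml` holds `pitchload.synthetic.SessionSpec` fields, e.g.

```yaml
n_participants: 4
pitches_per_participant: 60
torque_slope_mean: 0.05
torque_slope_sd: 0.04
rng_seed: 1
```

All angles are stored in radians; marker and signal files are plain CSV with
`#`-prefixed metadata lines; ground truth is JSON.

## Conventions and documented free parameters

- Global frame: z up, gravity (0, 0, -9.81) m/s²; left-handed throwers are
  mirrored about the sagittal plane before processing.
- External valgus torque is positive when loading the medial elbow of a
  (mirrored-to-)right-handed thrower; it is the floating-axis component of
  the elbow torque.
- Marker smoothing: zero-phase 4th-order Butterworth, 12 Hz (configurable).
- MER = minimum of the unwrapped shoulder axial-rotation series; ties break
  to the earliest sample.
- Peak search window around MER: ±50 ms (configurable).
- Moving windows use the sample (n−1) SD and, by default, run over
  consecutive valid pitches.
- Mixed models are fitted by maximum likelihood; AIC = 2k − 2·logLik with k
  counting fixed effects + variance/covariance parameters + residual.
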