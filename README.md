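# fogkit

Detection of freezing of gait (FOG) and festination in Parkinson's disease
from a **single shank-mounted inertial sensor** (3-axis accelerometer +
gyroscope, 100 Hz).

Freezing episodes — the feet suddenly "glued to the ground" for one to ten
seconds — are a major fall risk in advanced Parkinsonism. Spectral freeze
detectors catch the trembling form of FOG but are blind to **festination**,
the run of increasingly rapid, ever-smaller steps that often precedes a
freeze. fogkit implements both detector families side by side:

* **Freeze Index (FI)** — for each instant *t*, the squared ratio of the
  area under the power spectrum of a leg acceleration channel in the
  *freeze band* (3–8 Hz) to the area in the *locomotor band* (0.5–3 Hz),
  over a sliding window (6 s by default) centred at *t*. Its threshold can
  be calibrated from quiet-standing epochs as mean + 1 SD of the per-epoch
  peak FI.
* **FOG criterion (FOGC)** — a per-stride index built from cadence *Cₙ*
  (strides/s) and stride length *Lₙ* (m):

  ```
  FOGCₙ = Cₙ · L_min / (C_max · (Lₙ + L_min))
  ```

  with C_max = 5 strides/s and L_min = 5 cm. It rises with cadence and
  falls with stride length, reaching 1 as Lₙ → 0 at Cₙ = C_max, so a rising
  FOGC announces an imminent freeze while the patient is still stepping.

Around the two indices the package provides gyro-based stride segmentation
(mid-swing angular-velocity peaks), stride-length estimation by
drift-corrected integration of the forward acceleration, sagittal-plane
projection from a standing calibration window, threshold-event extraction,
severity-stratified scoring against clinician annotations, and a seeded
synthetic parkinsonian-gait generator with exact ground truth, so the whole
chain is testable without patient recordings.

## Worked example

Simulate the festination-into-freeze scenario (8 s of walking, 8 s of
festination with cadence ramping 1 → 3 strides/s while the stride shrinks
1 → 0.1 m, then 8 s of trembling freeze), and run both detectors:

```sh
fogkit simulate --preset festination_freeze --seed 1 --out demo
fogkit detect --input demo/festination_freeze.csv \
              --annotations demo/festination_freeze_annotations.csv \
              --out demo/det
```

which prints

```
wrote demo/festination_freeze.csv (2700 samples, 22 strides, 2 episodes)
                 Video  FI  FOGC
FOG Intensity
Green                0   0     0
Orange               1   1     1
Red                  1   1     1
False positives      0   0     0
FI events: 1, FOGC events: 1
```

The orange row is the festination episode, the red row the trembling
freeze. The FOGC event (`demo/det/events_fogc.csv`) starts at 10.2 s —
while the patient is still stepping, before the 19 s freeze onset — and
rides through the stride-free freeze to the end of the recording, peak
value 0.149 ≫ the 0.008 threshold. The FI event only brackets the
trembling: the FI series itself stays below threshold throughout
festination (its credit in the orange row comes from event overlap with
the adjacent freeze at the 1 s matching tolerance, not from any response
to festination). This is the complementary behaviour the two detectors
are designed around; `fogkit detect` also writes the two series, the event
lists and a two-panel plot with thresholds and annotation bands.

Library use mirrors the CLI:

```python
from fogkit import load_recording, run_detection
rec = load_recording("demo/festination_freeze.csv")
result = run_detection(rec)
print(len(result.strides), result.fogc_events)
```

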