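# pulsevit

Remote heart-rate estimation from facial video (remote photoplethysmography,
rPPG). The cardiac cycle modulates the blood volume in skin capillaries and
thereby the light the skin reflects — most strongly in the green channel.
`pulsevit` turns a facial video plus per-frame landmark tracks into a
heart-rate estimate in beats per minute (BPM), for researchers who want a
fully testable, CPU-runnable rPPG pipeline with known-ground-truth synthetic
data.

## Method

Frames are masked to the convex hull of 68 facial landmarks plus 2
constructed forehead points, cropped, resized and standardized, then cut
into non-overlapping 15-frame windows. A frame-wise vision transformer
extracts per-frame class-token embeddings; class tokens tapped at five
transformer depths (blocks 0, 3, 6, 9, 11 of a 12-block ViT-small geometry)
feed five decoder heads (BiLSTM → batch norm → 1D conv → linear), each
predicting the window's minimum, maximum, and average heart rate. The five
interval triples are averaged and fused into one estimate:

    HR = 0.25 * (MinHR + MaxHR) / 2 + 0.75 * AvgHR

Training minimizes the MAE of the averaged triple against the window label;
evaluation reports MAE and RMSE of the fused BPM. A single-output variant
(backbone → BiLSTM → three linear layers → 1 BPM) and a classical
green-channel spectral baseline are included. A synthetic-scene generator
produces facial videos with exact landmark tracks and an exact BPM trace, so
every stage is testable without downloading any corpus. See
`docs/methods.md` for assumptions and design choices.

## Worked example

Generate two 10 s synthetic videos and read their heart rate back with the
learning-free green-channel oracle:

```sh
pulsevit synth --n 2 --seed 7 --duration 10 --hr-low 70 --hr-high 90 \
    --out demo
pulsevit oracle --video-dir demo/video_000 \
    --landmarks demo/video_000/landmarks.csv --fps 25
```

which prints

```
{"video": "demo/video_000", "hr_bpm": 87.890625, "peak_power_ratio": 0.0196...}
```

`hr_bpm` is the spectral-peak estimate (this scene was programmed at
87.94 BPM, so the error is under 0.06 BPM); `peak_power_ratio` is the
peak's share of the in-band power, a crude reliability score. The Python API mirrors
the CLI:

```python
import pulsevit as pv

ppg = pv.gen_ppg_trace(lambda t: 72.0, duration=30.0, fs=60.0, seed=1)
scene = pv.SyntheticScene(ppg=ppg, frame_rate=25.0)
frames, landmarks, hr_rows = pv.render_scene(scene)
masked = [pv.mask_face(f, pv.add_forehead_points(lm))
          for f, lm in zip(frames, landmarks)]
est = pv.green_hr(masked, fps=25.0)
print(round(est.hr_bpm, 2))   # 71.96
```

Training the interval model on a synthetic fixture:

```sh
pulsevit synth --n 8 --seed 7 --duration 30 --out fixture
pulsevit train --manifest fixture/manifest.json --preset tiny --variant B \
    --seed 7 --out run
pulsevit predict --checkpoint run/checkpoint.npz --video-dir fixture/video_000 \
    --landmarks fixture/video_000/landmarks.csv --fps 25 --out pred.csv
pulsevit evaluate --pred pred.csv --truth fixture/video_000/hr.csv
```

`train` fits the five decoder heads on cached backbone features, then
fine-tunes end to end (see `docs/methods.md`), logging train loss and
validation MAE/RMSE to `run/metrics.csv` and keeping the best-validation
checkpoint; `predict` writes
one row per 15-frame window (`window_start_s,bpm,min_bpm,max_bpm,avg_bpm`);
`evaluate` prints MAE and RMSE against the ground-truth trace.

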