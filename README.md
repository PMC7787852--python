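# snorescreen

Acoustic screening for obstructive sleep apnea-hypopnea syndrome (OSAHS)
from whole-night snore recordings.

Polysomnography — the clinical gold standard for diagnosing sleep apnea —
requires an instrumented night in a sleep lab. A cheap alternative is to
record the sleeper with a single microphone and exploit the fact that
apnea events leave an acoustic signature: the airway obstruction produces
a faint snore *during* the event, and the resumption of breathing produces
a loud gasp *just after* it. `snorescreen` implements this idea as a
complete pipeline, for researchers in biomedical acoustics and for anyone
who wants a transparent, dependency-light reference implementation:

1. **Segmentation** — snore episodes are located in the recording by
   dual-threshold endpoint detection on short-time energy and
   zero-crossing rate, and cut into 3 s clips (48 000 samples at 16 kHz).
2. **Features** — each clip becomes a 298 × 40 matrix of cepstral
   coefficients: MFCC (mel filterbank log energies + DCT), LPCC
   (Levinson–Durbin all-pole fit + cepstral recursion), or LPMFCC
   (mel cepstrum of the LPC coefficient spectrum).
3. **Classification** — a 3-layer CNN, a 5-layer CNN, or a 298-step LSTM
   (one step per frame, final hidden state to a 2-way softmax) labels
   each clip *normal* or *abnormal* (apnea-related). The networks are
   implemented directly in numpy, including training.
4. **Screening** — with AB abnormal snores counted over SH hours of
   sleep, the apnea-hypopnea index is

   ```
   AHI = (AB / 2) / SH
   ```

   (each apnea event contributes one faint snore and one gasp), graded as
   normal (AHI ≤ 5), slight (5 < AHI ≤ 15), moderate (15 < AHI ≤ 30) or
   serious (AHI > 30).

Because no public snore corpus with apnea annotations exists, the package
ships a synthetic-data module (`snorescreen.synthetic_data`) that
generates labelled clips and whole overnight sessions with planted apnea
events at a controllable rate, so every stage is trainable and testable
end to end.

## Worked example

```python
import numpy as np
import snorescreen as ss

# a labelled synthetic benchmark: 2000 clips, two classes
clips = ss.gen_clip_dataset(1000, seed=12345)
X = np.stack([ss.mfcc(c.audio).values for c in clips]).astype(np.float32)
y = np.array([0 if c.label == "normal" else 1 for c in clips])

# 80/20 split, train the LSTM
order = np.random.default_rng(54321).permutation(len(X))
test, train = order[:400], order[400:]
model = ss.train(ss.build_model(ss.ModelConfig("lstm")),
                 X[train], y[train], ss.TrainConfig(seed=54321),
                 feature_kind="mfcc")
probs = ss.predict_proba(model, X[test])
print("test accuracy:", np.mean(np.argmax(probs, 1) == y[test]))

# screen a synthetic 1 h session with 20 apnea events/hour
audio, annotations, true_ahi = ss.gen_session(
    ss.SessionSpec(hours=1.0, events_per_hour=20, seed=12345))
report = ss.screen_recording(audio, model, feature_kind="mfcc",
                             sleep_hours=1.0)
print(report.to_text())
print("true AHI:", true_ahi)
```

Output from this exact script:

```
test accuracy: 0.9975
snorescreen report
  clips classified : 199
  abnormal snores  : 38
  sleep hours      : 1.00
  AHI              : 19.00 events/hour
  severity         : 2 (moderate)
true AHI: 19.0
```

The model separates normal from apnea-related snores at 99.75% held-out
accuracy on the synthetic benchmark. Screening then finds 199 snore
episodes in the hour-long session, labels 38 of them abnormal, and the
resulting AHI of 19.0 events/hour matches the planted ground truth
exactly (19 apnea events were placed in this realisation, each
contributing one faint snore and one gasp).

The same flow is available from the shell:

```sh
snorescreen simulate --mode clips --n-per-class 100 --seed 1 --out-dir data/
snorescreen extract --manifest data/manifest.csv --feature mfcc --out feats.npz
snorescreen train --features feats.npz --arch lstm --out model.npz
snorescreen evaluate --model model.npz --features feats.npz
snorescreen screen night.wav --model model.npz --sleep-hours 7.5
```

## Documentation

`docs/methods.md` describes the model and its assumptions, the synthetic
data generator, the numerical choices, and known limitations.
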