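# sketchvep

Constrained-maximum-entropy selection of "optimal" visual features and a
visual-evoked-potential (VEP) pipeline that tests, on synthetic EEG,
whether the earliest cortical response (the C1 component) is faster for
stimuli made of those features.

## The science

Efficient-coding accounts of early vision hold that the visual system,
facing a severe information bottleneck, transmits only a small set of
image features chosen to maximize information per unit computational
cost. In the reference pattern-filtering model, images are digitized to
1 bit at their median luminance and split into 3×3 pixel patches (512
possible patterns). Each pattern with occurrence probability *p*
contributes entropy *H(p) = −p log₂ p*; transmitting it costs
*C(p) = max(p/W, 1/N)*, where *N* is the number of patterns the system
can represent (50) and *W* the output bandwidth it can occupy (total
transmitted probability mass, 0.025). The **optimal set** maximizes
total entropy subject to ≤ *N* members and bandwidth ≤ *W* — which
rejects both uniform patches (too expensive in bandwidth) and very rare
patterns (inefficient per slot), and lands on intermediate-probability
patterns that look like edges, bars and corners. **Non-optimal**
features are the 50 patterns with the lowest positive probability.

The electrophysiological prediction: compound stimuli containing a
larger fraction of optimal features (the stimulus "SNR": 0, 30, 60 or
100% of ten glyphs) should evoke an earlier C1 — the first cortical
deflection, which reverses polarity between upper- and lower-visual-
field stimulation. The package's forward model plants exactly this
structure (group-mean C1 peak latencies 74/71/70/69 ms for SNR
0/30/60/100%, polarity-reversed, plus an SNR-*independent* C2 as
negative control) into 30-channel, 500 Hz synthetic recordings, and the
analysis pipeline (sinc FIR high-pass and notch, common-average
reference, epoching with 150 ms baseline, lower-minus-upper difference
waves over POz/PO3/PO4/Pz, peak measurement with 0.2 µV prominence and
height criteria) must recover it.

## Worked example

```python
import numpy as np
import sketchvep as sv

rng = np.random.default_rng(42)
corpus = [sv.binarize_image(im) for im in sv.make_image_corpus(20, 128, rng)]
dist = sv.extract_pattern_distribution(corpus, mode="tile")
opt = sv.select_optimal(dist)              # N=50, W=0.025 defaults
non = sv.select_nonoptimal(dist, 50)
print(f"optimal set: {len(opt)} patterns, bandwidth {opt.bandwidth:.4f}")

schedule = sv.build_schedule(sv.scaled_schedule_config(4), rng)
session = sv.simulate_session(schedule, participant="demo", rng=rng)
measures, waves = sv.analyze_session(session)
c1 = measures[measures.component == "C1"]
for _, row in c1.iterrows():
    print(f"SNR {row.snr:>3}%: C1 latency {row.latency_s*1000:5.1f} ms, "
          f"amplitude {row.amplitude_uv:.2f} uV")
```

prints

```
optimal set: 50 patterns, bandwidth 0.0250
SNR   0%: C1 latency  75.0 ms, amplitude 3.50 uV
SNR  30%: C1 latency  70.0 ms, amplitude 3.30 uV
SNR  60%: C1 latency  68.8 ms, amplitude 3.21 uV
SNR 100%: C1 latency  68.2 ms, amplitude 2.35 uV
```

The selection uses the full constraints on a surrogate corpus (50
patterns filling the 0.025 bandwidth exactly, uniform patches excluded),
and a single quarter-length synthetic session already shows the planted
latency ordering: C1 peaks later for all-non-optimal stimuli (SNR 0%)
than for all-optimal ones (SNR 100%), with single-participant jitter of
a millisecond or two around the planted 74 → 69 ms group means.

A command-line interface mirrors the library:
`sketchvep select-features`, `make-schedule`, `make-stimuli`,
`simulate`, `analyze-vep`, `stats` (see `sketchvep --help`).

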