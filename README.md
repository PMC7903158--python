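# alpharhythm

Sensor-level analysis of **rhythmically modulated hemispheric alpha-power
lateralization** during spatio-temporal auditory attention, with a
synthetic-data generator that makes every stage verifiable without any data
download.

## The problem

In dichotic listening, attending to one ear lateralizes 8–12 Hz alpha power:
it rises in the hemisphere ipsilateral to the attended side and falls
contralaterally. When the competing speech streams have a regular rhythm
(spoken numbers every 1.25 s, i.e. 0.8 Hz) and a visual cue provides
*temporal* foreknowledge about which item will be probed, the question is
whether the spatial filter is also deployed in time — i.e. whether the
lateralization index

```
topographic:    AL = (Pow_attend-left − Pow_attend-right) / (Pow_attend-left + Pow_attend-right)
time-resolved:  AL(t) = (Pow_ipsi(t) − Pow_contra(t)) / (Pow_ipsi(t) + Pow_contra(t))
```

is modulated at the 0.8-Hz stimulus rate more strongly after instructive
than after neutral temporal cues, and specifically around the cued item's
onset. The package implements the full analysis chain for this question:

- **simulate** — trial schedules with the exact design marginals (160
  trials; 80/80 cue types; cued-position counts 8/18/28/18/8; 70%-valid
  probes), validity-dependent behavior, and MEG-like epochs with planted
  alpha lateralization, 0.8-Hz modulation, onset-locked evoked transients,
  and 1/f noise;
- **preprocess** — zero-phase FIR band-pass, polyphase resampling,
  amplitude-threshold epoch rejection (3 pT/cm-equivalent);
- **timefreq** — Hann-tapered moving-window Fourier coefficients (0.5-s
  windows, 0.05-s steps, 1–20 Hz), oscillatory power, inter-trial phase
  coherence (ITPC), gradiometer-pair combination;
- **lateralization** — the two indices above;
- **rhythm** — zero-padded FFT of index time courses over the 1.5–7.5 s
  number window at 0.02-Hz resolution, 0.76–0.84 Hz band amplitude/phase,
  phase↔lag conversion;
- **subepoch** — cued / uncued / neutral sub-epochs around number positions
  2–4, count-matched sub-sampling (without replacement, per side × position
  cell), z-standardization of the cued time course, group sign-flip
  permutation tests with bootstrap confidence intervals;
- **stats** — adjusted logit, 1/RT response speed, sign-flip permutation
  t-tests, permutation Spearman correlation, Rayleigh and paired Hotelling
  circular tests, linear-trend test.

See `docs/methods.md` for the signal model, estimator conventions, and
numerical choices.

## Worked example

`examples/` holds one short script per capability. Running
`python examples/03_rhythm_spectrum.py` simulates one participant and
prints:

```
instructive  0.8-Hz amplitude = 0.201, phase =  -132.3 deg
neutral      0.8-Hz amplitude = 0.073, phase =  -130.8 deg
133 deg at 0.8 Hz corresponds to a lag of 0.46 s
```

The instructive-cue 0.8-Hz amplitude of the lateralization index is about
twice the neutral one — recovering the planted modulation depths (0.2 vs
0.1) — and the phase corresponds to the planted 0.46-s lag of the
lateralization rhythm behind the number onsets. The full pipeline
(`examples/06_full_pipeline.py`) assembles the group report:

```
accuracy: {'valid': 0.952, 'invalid': 0.806, 'neutral': 0.802}
0.8-Hz lateralization amplitude: instructive 0.201 | neutral 0.078 | p = 0.0312
lateralization lags ITPC by 0.265 s (76 deg)
min cued-vs-uncued p near cued onsets: 0.03125
```

i.e. valid temporal foreknowledge improves accuracy, instructive cues
amplify the 0.8-Hz modulation of alpha lateralization, and the effect is
temporally specific to the cued onsets.

There is also a thin CLI:

```bash
alpharhythm simulate --n-participants 5 --seed 1 --out data/
alpharhythm analyze --dataset data/ --seed 1 --out report.json
alpharhythm report report.json
```

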