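# icspread

Neurometric analysis of the **spread of excitation** in the auditory
midbrain, for experiments that compare how focally different cochlear
stimulation modalities — acoustic tones, electric current from
intracochlear microelectrodes, and magnetic fields from implantable
micro-coils — recruit the auditory pathway.

The intended user records multi-unit activity on a multichannel probe
placed along the tonotopic axis of the inferior colliculus (IC) while
stepping stimulus intensity, and wants quantitative, comparable answers
to: *how sharp is the activation along the tonotopic axis, where is it
centred, and how much intensity resolution does the modality offer?*

## What it computes

1. **aMUA** — analog multi-unit activity. Raw voltage is band-pass
   filtered to the spike band (325–6000 Hz Butterworth), the
   artifact-contaminated first 2 ms after stimulus onset is excised,
   the signal is rectified, low-pass filtered at 475 Hz, downsampled
   25 → 12 kHz, and integrated over the 2–15 ms post-onset window,
   giving one scalar response per (level, channel, trial).

2. **Cumulative d′** — for each channel, discriminability between
   successive stimulus levels,

   d′ = |μ_a − μ_b| / σ_rms,   σ_rms = √((σ_a² + σ_b²)/2),

   accumulated up the level grid. Cumulative d′ is the
   response-strength axis of all downstream measures.

3. **Spatial tuning curves (STC)** — the cumulative-d′ surface over
   (level, channel), with marching-squares iso-contours at d′ ∈
   {1, 2, 4}. Threshold is the first d′ = 1 crossing; the **best site
   (BS)** is the channel with the lowest threshold.

4. **Spread of excitation** — at the stimulus level where the BS
   reaches cumulative d′ of 2 (and 4), the span between the ventral-
   and dorsal-most channels with d′ > 1, in channels, micrometres, and
   — via the tonotopic map fitted from acoustic best sites — octaves.
   Isolated suprathreshold channel groups are counted as **tips**
   (multi-site recruitment indicator).

5. **Dynamic range (DR)** — a logistic fit to the rate-level function
   at the BS; DR = the level range spanning 10–90 % of the fitted
   maximum = 2·s·ln 9 for logistic slope s, in the modality's dB
   convention (dB SPL, dB re 1 mA, dB re 1 V).

6. **Group statistics** — two-way ANOVA (Type II) with Tukey HSD on
   least-squares means for modality × d′-level tables, Student t-tests
   for single-factor contrasts, mean ± SD summaries.

A **synthetic-recording generator** produces 16-channel, 25 kHz
recordings with known ground truth (tonotopy, recruitment center,
spread, threshold, slope, peak rate, noise, artifact) so the entire
chain is testable without animal data.

## Worked example

```python
import icspread as ic

truth = ic.default_truth("magnetic", site="base", seed=42)
proto = ic.default_protocol("magnetic")          # 8 levels, 39 repeats
rec   = ic.generate_recording(truth, proto)      # (312, 16, 750) @ 25 kHz

amua  = ic.compute_amua(rec)
stc   = ic.build_stc(ic.cumulative_dprime(amua))
tmap  = ic.tonotopic_ground_truth(truth)
sp    = ic.measure_spread(stc, rec.channel_pitch_um, tmap)
rlf   = ic.fit_sigmoid(ic.rate_level_at_bs(amua, stc.best_site))
```

prints (via the obvious formatting):

```
best site      : channel 5 (CF 26.4 kHz)
threshold      : 3.08 dB V
spread @ d'=2  : 1 ch / 50 um / 0.17 oct
spread @ d'=4  : 4 ch / 200 um / 0.69 oct
tips           : 1
dynamic range  : 10.18 dB V (slope 2.32 dB, saturated=True)
```

i.e. this simulated basal micro-coil insertion activates a single
focal region of the IC centred on the ~26 kHz channel, one contiguous
tip, and offers ~10 dB of usable intensity range.

## Command line

```bash
icspread simulate --config cfg.json --seed 3 --out sim/   # write HDF5 containers
icspread analyze  --input sim/m0.h5 --out results/        # full chain on one recording
icspread stats    --input results/summary.csv --out st/   # ANOVA + Tukey
```

Recordings are HDF5 (`data` tensor + `fs`, `channel_pitch_um` attrs)
with a JSON protocol sidecar; all derived tables are CSV, run manifests
JSON. Every numeric default is overridable through the JSON config.

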