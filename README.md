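# efmon

Insect counts, wing-beat frequencies (WBF), and biomass estimates from
1-minute, 16-bit, 4 kHz electric-field sensor recordings — plus a synthetic
signal simulator so every stage is testable without field data.

## Pipeline

For each recording (WAV, PCM-16 mono, `<sensor_id>_<ISO8601>.wav`):

1. **powerline** — 50/60 Hz mains interference is detected by comparing
   Welch-PSD band energy against adjacent bands in four signal chunks
   (confirmed only when all four agree) and cancelled by a comb of IIR
   notches at the mains frequency and its harmonics.
2. **signals** — the recording is cut into 1-s segments (trailing partial
   second dropped); each 4000-sample segment becomes a 129x32 magnitude
   spectrogram (FFT 256, hop 128, Hann, centred).
3. **detector** — a small CNN (conv 16 + conv 32 + dense 256, batch-norm,
   dropout, sigmoid head) classifies each spectrogram as insect /
   non-insect. Training uses class-weighted BCE and stochastic waveform
   augmentation (pitch shift, time shift/stretch, Gaussian and real-noise
   mixing). The network runs on a numpy engine — no deep-learning framework
   required.
4. **wbf** — probabilistic YIN (threshold-prior YIN candidates + Viterbi
   over a pitch grid with voicing states) yields a frame-level F0 track per
   insect-positive segment; per-segment mu/sigma are filtered by
   plausibility rules (mu >= 20 Hz, sigma >= 1 Hz, bounded sigma/mu).
5. **events** — adjacent surviving segments merge into single insect events
   when their frequency intervals overlap (IoU >= 0.1) and their Gaussians
   are similar (Bhattacharyya coefficient >= 0.7); merged statistics are
   inverse-variance weighted.
6. **biomass** — each event's WBF is mapped to body mass through a
   region-structured reference table (dense <= 240 Hz, less dense
   240-340 Hz, sparse > 340 Hz) with expanding-window candidate search,
   Europe filtering, observation-probability weighting, and per-region
   fallbacks.
7. **fieldstats** — Spearman correlations, Fisher r-to-z comparison of two
   correlations, and OLS slopes for paired-method validation series.

## CLI

```bash
efmon simulate scene.yaml -o sim/        # render scenes + ground truth
efmon train manifest.csv -o detector     # train from a dataset manifest
efmon detect rec.wav --model detector.npz
efmon run *.wav --model detector.npz --table table.csv -o out/
efmon biomass events.csv --table table.csv
efmon validate pairs.csv                 # rho / beta / z / p report
```

`efmon run` accepts `--config config.yaml` (see `PipelineConfig`), a
`--periods periods.csv` schedule for per-trapping-period aggregation, and
flags exposing documented alternative readings of the aggregation rules
(`--bc-as-printed`, `--sigma-as-printed`, `--ratio-as-printed`).

A scene YAML looks like:

```yaml
duration_s: 12.0
seed: 7
noise_level: 0.001
mains_hz: 50
mains_amplitude: 0.02
events:
  - {true_wbf: 210.0, onset_s: 2.0, duration_s: 2.0, target_snr_db: 20}
```

## Reference table

CSV with columns `taxon,wbf_hz,mass_mg,in_europe,obs_prob`. A 50-row
synthetic demo ships in `efmon/data/reference_table_demo.csv`;
`efmon.simulate.synth_reference_table` generates tables of any shape, and
`efmon.biomass.load_reference_table` accepts user-supplied transcriptions
of literature tables.

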