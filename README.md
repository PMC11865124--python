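# tempobias

An end-to-end, tested pipeline for analyzing how pitch biases perceived
tempo in relative tempo-judgment experiments: stimulus/trial design,
participant screening, per-subject response-scale calibration, a
log2-percent tempo-shift statistic, orthogonal-polynomial curve
characterization, and multivariate group-level inference — plus a synthetic
rater simulator with a known truth ledger for validation without any real
data.

## What it does

Participants hear a metronome (550-ms interonset interval) followed by a
repeating tone whose pitch (six levels, A2–A7), tempo (15 log-spaced
interonset intervals from 1000 down to 302 ms), and loudness (−3/0/+3 dB)
vary across trials, and rate the tone's speed relative to the metronome on a
0–100 slider. The pipeline:

1. **design** — builds the tempo grid and 12-TET pitch ladder, bins tempos
   into quintile "tempo ranges", generates constrained random trial orders
   (every pitch × range once per block, consecutive trials differ in both
   pitch and range, loudness balanced across blocks), and can synthesize the
   complex-tone stimuli (4 harmonics, −6 dB/octave, 5/170/25-ms envelope) to
   mono 16-bit WAV.
2. **screening** — excludes discrete responders (≥75/90 trials rated
   exactly 0/50/100, scaled pro rata) and participants whose ratings
   correlate r < .5 with true log2 relative tempo.
3. **scoring** — regresses each subject's ratings on log2 relative tempo,
   flags trials with Cook's distance > 4/n, refits once, and converts
   residual ratings to tempo shifts `tau = 100 * rho / beta1` (log2-percent:
   +100 means "rated as if the tempo doubled").
4. **curves** — fits orthonormal polynomial contrasts of tau over pitch
   codes per subject (degree 5 omnibus, degree 2 within condition slices)
   and computes Cousineau–Morey within-subject CIs.
5. **inference** — one-sample / independent / paired Hotelling's T²,
   repeated-measures MANOVA (Wilks' Λ on contrast scores), repeated-measures
   ANOVA with Mauchly's test and Greenhouse–Geisser / Huynh–Feldt epsilons,
   Holm–Bonferroni post hocs, Cohen's d, partial η², Box's M.
6. **simulate** — generates whole synthetic studies
   (`rating = beta0 + beta1*(log2(t/t_ref) + curve(pitch)/100) + noise`,
   clipped to the slider) with configurable responder types and tap-failure
   rates, keeping the generative truth in a separate ledger.

## CLI

```sh
tempobias simulate --subjects 50 --seed 1 --out trials.csv --truth truth.json
tempobias screen   --trials trials.csv --out screening.csv
tempobias score    --trials trials.csv --screening screening.csv --out shifts.csv
tempobias curves   --shifts shifts.csv --degree 5 --out curves.csv
tempobias curves   --shifts shifts.csv --degree 2 --by tempo_range --out curves_by_range.csv
tempobias infer    --curves curves.csv --out results.json --posthoc posthoc.csv
tempobias report   --shifts shifts.csv --curves curves.csv --out-dir report/
tempobias render-audio --pitch A5 --ioi 550 --out trial.wav
```

All artifacts are plain text (CSV/JSON) except WAV audio; every results file
embeds the configuration hash and seed on a `# meta:` line (CSV) or under a
`meta` key (JSON).

## Input CSV schema

`participant_id, experiment, tap_instruction, timbre, register, block,
trial, pitch_label, pitch_code, f0_hz, ioi_ms, loudness_db, rating, tapped,
practice` — ratings in [0, 100], loudness in {−3, 0, 3}, `tap_instruction`
in {tap, no_tap, n/a}. Malformed rows are reported with row numbers.

## Notes

- BPM values are computed from the rounded integer-millisecond intervals
  (60000/550 = 109.1 BPM); the fastest interval (302 ms) computes to
  198.7 BPM.
- The discrete-responder threshold generalizes as ceil(75/90 · n_trials)
  and can be disabled (`--no-discrete-rule`) for 180-trial designs.
- Participants with constant ratings (undefined r) are excluded under the
  low-correlation rule.
- The paired Hotelling test uses the standard one-sample reduction df
  (p, n − p).
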