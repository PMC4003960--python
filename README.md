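# pdgait

Accelerometry gait-analysis pipeline for wearable body-area-network
recordings, built around five tri-axial sensors (belt, both wrists, both
legs) sampled at 62.5 Hz.  The package covers the full chain:

1. **Packet I/O** (`pdgait.ban_io`) — CSV packet streams
   (`sensor_id,timestamp_ms,ax_g,ay_g,az_g`) with strict validation of the
   16 ms timestamp grid and the ±6 g full scale; gzip transparent.
2. **Transmission QC** (`pdgait.qc`) — gap detection from timestamp holes,
   per-window data-loss percentages (mean ± sd), burst-length statistics
   (mean ± sd, mode), and startup trimming: everything before the first
   sustained gap-free window is discarded, removing the long
   connection-phase bursts and leaving sporadic 64 ms reconnect gaps.
3. **Preprocessing** (`pdgait.preprocess`) — `[0,1]` normalization
   (`(a+6)/12`), the 3-axis module, linear interpolation of gaps up to one
   64 ms burst, splitting at longer gaps, multi-sensor grid alignment.
4. **Walking-bout segmentation** (`pdgait.segmentation`) — overlapping
   2.56 s windows of the two leg sensors summarized by variance, dominant
   gait-band frequency, band power ratio and inter-leg correlation, scored
   by a frozen logistic model, then merged into walking segments.
5. **Gait features** (`pdgait.features`) — sample entropy (m=2, r=0.2·sd,
   Chebyshev distance, self-matches excluded), step detection on the
   band-passed cranio-caudal belt channel, step frequency, stride-time
   coefficient of variation, inverted-pendulum stride length
   (`s = 2·sqrt(2·l·h − h²)` from the double-integrated vertical
   excursion `h`), and walking velocity.
6. **Synthetic data** (`pdgait.synthetic`) — sessions with known ground
   truth: raised-cosine vertical-displacement gait with controllable step
   frequency, stride-time CV, excursion amplitude and left/right
   asymmetry; resting and arm-task activities; and a wireless loss
   process (Poisson disconnections with a 4-sample/64 ms reconnect
   minimum plus geometric extension, and a long startup burst).

`pdgait.pipeline` ties everything into reproducible runs driven by a
serializable `RunConfig`; `pdgait.benchmarks` recomputes the headline
reference numbers end to end.

## CLI

```sh
# simulate a session (packets.csv + ground_truth.json + QC + features)
pdgait simulate --seed 42 --duration 600 --out run/

# quality report for a packet CSV (Data loss % / avg burst / modal burst)
pdgait qc --in run/packets.csv

# full analysis of a recorded packet CSV
pdgait analyze --in run/packets.csv --leg-length 0.95 --out analysis/

# render a saved QC report; compare two cohorts' feature tables
pdgait report --in analysis/loss_report.json
pdgait compare --a healthy/features.csv --b patient/features.csv --names healthy,pd
```

All subcommands also accept `--config cfg.yaml` (a serialized
`RunConfig`); the config file wins over flags with a logged notice.

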