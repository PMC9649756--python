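# granuletrace

Quantitative analysis of fluorescence time traces from RNA–protein
granules.

Synthetic long non-coding RNAs (slncRNAs) carrying tandem phage coat-protein
hairpins (PP7/MS2/Qβ) condense with fluorescent coat-protein fusions into
phase-separated granules that appear as bright puncta. The granule's
fluorescence changes in discrete steps as individual slncRNA–protein
complexes enter or are shed. `granuletrace` turns time-lapse movies or
pre-extracted intensity traces of such puncta into quantified dynamics:

* **image extraction** — bright-spot detection, greedy track linking, and
  per-frame 14×14-pixel sub-frame classification by three-class Otsu into
  spot / cell-background / dark-background, yielding paired
  spot-and-background traces;
* **signal normalization** — with spot signal y(t) = (S(t)+c₀)·f(t) and
  background c(t) = c₀·f(t), photobleaching f(t) cancels in the ratio, and
  S(t) = c₀·(y/c − 1) recovers the granule signal (y smoothed by a
  13-point moving average, c replaced by a cubic trend fit);
* **burst detection** — per-trace step probabilities p_inc, p_dec feed the
  run-length threshold m = −10/log₂(p) (null probability 2⁻¹⁰ per run,
  minimum threshold = the smoothing span); significant runs become entry
  (positive) or shedding (negative) events with amplitude ΔI and duration
  Δt, with one isolated reversal tolerated per run;
* **amplitude fitting** — the quantized-Poisson model
  p(I) = λ^(I/K₀)e^(−λ)/(I/K₀)! fitted by MSE over a λ grid, giving the
  per-complex intensity K₀ and typical occupancy λ;
* **summary statistics** — inter-event intervals, net loss rates, content
  ratios (molecules per granule), dye-quenching factors, two-channel
  Pearson correlation, rank-sum/t group tests;
* **synthetic data** — a seeded generator of ground-truth schedules,
  rendered trace pairs and toy Gaussian-spot TIFF stacks, so the whole
  pipeline is testable without microscopy data.

## Worked example

Simulate fifty in-vitro-like granules (shedding roughly every 10 minutes,
rarer entries, occupancy λ = 2.5, K₀ = 100 A.U., mild bleaching, σ = 20),
run the full analysis and fit the amplitude distribution:

```python
import numpy as np
from granuletrace import (TraceRenderConfig, generate_burst_schedule,
                          render_trace, normalize_trace, detect_bursts,
                          inter_event_intervals, fit_modified_poisson,
                          net_loss_rate)

cfg = TraceRenderConfig(c0=400.0, bleach_timescale_s=7200.0, noise_sd=20.0)
all_events, neg_iv = [], []
for i in range(50):
    sched = generate_burst_schedule(
        entry_rate_per_min=1/30, shedding_rate_per_min=0.1,
        amplitude_unit=100.0, occupancy=2.5, duration_s=3600.0,
        seed=i, initial_content=2000.0)
    trace = render_trace(sched, cfg, seed=1000 + i)
    events, thresholds = detect_bursts(
        normalize_trace(trace, c0=cfg.c0).S, cfg.frame_interval_s)
    all_events += events
    neg_iv += inter_event_intervals(events, "negative", cfg.frame_interval_s)

sig = [e for e in all_events if e.direction != "unclassified"]
fit = fit_modified_poisson(np.array([abs(e.amplitude) for e in sig]))
```

Output (printed by the snippet's reporting lines):

```
traces analysed        : 50
significant events     : 271 (191 shedding, 80 entry)
net loss rate          : +2.22 events/granule/hour
median inter-shedding  : 490 s
amplitude fit          : lambda = 2.25, K0 = 118.5 A.U. (MSE 1.24e-04)
```

The shedding bias (positive net loss rate) reflects the degrading
in-vitro-like conditions; the median time between shedding events sits
near the generator's 10-minute scale (detection merges closely spaced
events, so the detected median is not exactly the latent one); and the
fitted λ ≈ 2.25, K₀ ≈ 119 recover the generator's occupancy 2.5 and
per-complex unit 100 from the detected amplitudes alone.

The same pipeline is available from the shell:

```sh
granuletrace simulate --preset invitro-PCP14x --n-traces 50 --seed 1 --out sim/
granuletrace analyze bursts --traces sim/ --out events.csv
granuletrace analyze summary --events events.csv
granuletrace fit poisson --events events.csv --direction negative
granuletrace extract --stack movie.tif --out traces/   # from a TIFF stack
```

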