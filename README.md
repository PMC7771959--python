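# dendroscan

Analysis of simultaneous dendritic **voltage and calcium linescan
recordings** from cerebellar Purkinje neuron spiny dendrites, built for
studying dendritic coincidence detection during sensory stimulation in awake
mice — together with a fully parameterized synthetic linescan generator with
ground truth, so that every stage of the pipeline is testable without any
raw data.

## Who this is for

Experimenters and analysts working with high-speed (2 kHz) two-photon
linescans in which a voltage-sensitive dye (red channel) and a calcium
indicator (green channel) are imaged simultaneously, and who need to:

* convert raw two-channel linescans into motion-corrected, crosstalk-free,
  spatially averaged ΔF/F traces (10 kHz timebase, 2.1 mV per % ΔF/F);
* detect dendritic spikelets and classify them into **dendritic complex
  spikes (DCS)** — climbing-fiber-evoked bursts of 2–5 spikelets — and
  single **dendritic spikes (DS)** attributed to strong parallel-fiber
  input;
* classify sub-threshold evoked voltage responses (depolarizing /
  hyperpolarizing / both / none, thresholds at ±2 SD of a 500 ms baseline);
* quantify peri-stimulus statistics (10 ms-bin PSTHs, rate fold-changes,
  trial-outcome probabilities with bootstrapped SDs, evoked vs non-evoked
  calcium comparisons);
* quantify coincidence-detection effects: the sub-threshold voltage–calcium
  relation on spike-free trials, the timing dependence of DCS+DS pair
  supralinearity (boxcar-of-10 smoothing and a two-term Gaussian fit), and
  the pre-DCS depolarization with its linear-sum calcium prediction.

## Core quantities

For spikelet detection, local maxima of the 1 ms boxcar-filtered voltage
trace with amplitude ≥ 3σ and prominence ≥ 1σ (σ = SD of the full trace),
minimum separation 2.5 ms. A burst chained by ≤ 10 ms gaps is a DCS if the
calcium gate holds (mean ΔF/F over the 20 ms after the first spikelet
exceeds the 20 ms before it by > 1 %); a singleton is a DS if the calcium
gate holds **and** the voltage returns to baseline (10 ms mean < 1σ).

For a DCS+DS pair at lag Δt (DS onset − DCS onset), the **relative calcium
peak** is the pair's calcium peak divided by the mean peak of unpaired
single DCS with the same spikelet count. Its timing dependence is fitted
with

    f(Δt) = a₁·exp(−((Δt−b₁)/c₁)²) + a₂·exp(−((Δt−b₂)/c₂)²)

and summarized by the fitted-curve maximum (location, value) and adjusted R².

## Worked example

```python
import numpy as np
import dendroscan as d

cfg = d.SimConfig()                       # 10.5 s, 2 kHz, stimulus at 5 s
rec, truth = d.simulate_trial(cfg, np.random.default_rng(0))
traces, report = d.preprocess_recording(rec)
print(f"crosstalk scale {report['crosstalk_scale']:.3f}, "
      f"mask {report['mask_size_px']} px")
res = d.detect_events(traces)
for e in res.events[:4]:
    print(f"{e.kind}: onset {e.onset_ms:.1f} ms, {e.spikelet_count} "
          f"spikelet(s), calcium peak {e.calcium_peak_dff:.1f} %dF/F")
```

prints (seed 0):

```
crosstalk scale 0.150, mask 277 px
DCS: onset 377.6 ms, 5 spikelet(s), calcium peak 19.3 %dF/F
DS: onset 934.9 ms, 1 spikelet(s), calcium peak 1.8 %dF/F
DS: onset 2127.9 ms, 1 spikelet(s), calcium peak 2.1 %dF/F
DS: onset 3535.7 ms, 1 spikelet(s), calcium peak 2.1 %dF/F
```

The crosstalk regression recovers the configured green→red leak (0.15), and
detected events match the injected schedule to sub-millisecond precision:
the 5-spikelet DCS carries a large calcium transient, the DS small ones.

The full pipeline (simulate → preprocess → detect → classify-response →
stats → coincidence) runs from the shell:

```bash
dendroscan run-all --seed 1 --n-trials 20 --out runs/demo
cat runs/demo/summary.txt
```

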