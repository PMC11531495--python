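# condensig

Quantitative analysis of oncogenic fusion-protein condensates and their
signaling consequences in live-cell fluorescence microscopy.

Oncogenic fusion kinases such as EML4-ALK form micron-scale cytoplasmic
condensates (puncta) that sequester the shared RTK adapters GRB2 and SOS1,
blunting the cell's response to receptor stimulation; inhibiting the fusion
kinase releases the adapters and resensitizes receptors like EGFR, visible as
restored membrane translocation, adapter dissociation kinetics, and sporadic
single-cell ERK activity pulses near dying neighbors. `condensig` packages
the bespoke quantitative analyses this biology requires into a tested,
reusable pipeline:

- **`condensig.puncta`** — per-cell condensate detection. Each cell's
  intensities are normalized to their internal median, enhanced with
  sequential Gaussian, white top-hat, and (negated) Laplacian-of-Gaussian
  filters, seeded at local maxima above a user cutoff, and grown iteratively:
  a pixel joins a cluster when its normalized intensity exceeds
  `growth_scale × median(unassigned cell pixels)`, repeated until no neighbor
  qualifies. Two-channel colocalization is the per-cell fraction of
  channel-A puncta whose pixel sets overlap any channel-B punctum.
- **`condensig.translocation`** — membrane localization
  `ML = mean(edge) / mean(core)`, where the edge is a fixed-width ring
  (default 10 px) inside the cell boundary; translocation is
  `ML(post) − ML(pre)` across a stimulation (default scored 1.5 min
  post-EGF), and suppression summaries compare oncogene-expressing vs
  untransfected cells from the same field of view.
- **`condensig.ktr_pulses`** — ERK pulse calling from cytoplasmic/nuclear
  kinase-translocation-reporter ratios: expression QC, prominence-based peak
  detection, exclusion of pulses within 10 frames (50 min) before cell
  division, truncation at cell death, and lineage deduplication so pulses in
  a duplicated parental history are counted once.
- **`condensig.neighbor_analysis`** — for every death event, the neighbors
  (cells within 100 px of the dying cell during the 10 frames preceding
  death) are compared against count-matched random non-neighbor controls;
  pulse enrichment is tested with a paired one-sided bootstrap.
- **`condensig.stats_kinetics`** — bootstrap comparison of medians
  (`median(a*) − median(b*)` over 1000 resamples with a one-sided empirical
  p-value), exponential dissociation fitting
  `I(t) = offset + amplitude · 2^(−t/t½)`, and Wilson score intervals.
- **`condensig.synthetic_data`** — generators for every input above with
  known ground truth (condensate scenes, translocation pairs, 22-h KTR
  trace sets at 5-min frames, decay ensembles), so each stage is benchmarked
  without external data.

## Worked example

```python
import numpy as np
from condensig import (
    PunctaSceneConfig, simulate_puncta_scene, detect_puncta, coloc_fraction,
    DecaySimConfig, simulate_decay_traces, decay_matrix, fit_dissociation,
)

# condensates and adapter colocalization
cfg = PunctaSceneConfig(n_cells=9, puncta_per_cell=5, coloc_fraction=0.8, seed=3)
chan_a, chan_b, truth = simulate_puncta_scene(cfg)
puncta_a = detect_puncta(chan_a)
table = coloc_fraction(puncta_a, detect_puncta(chan_b))
print(f"detected {len(puncta_a)} EML4-ALK puncta in {cfg.n_cells} cells "
      f"({len(puncta_a) / cfg.n_cells:.1f} per cell)")
print(f"mean per-cell colocalization with the adapter channel: "
      f"{table.coloc_fraction.mean():.2f}")

# adapter dissociation kinetics after kinase inhibition
decay = simulate_decay_traces(DecaySimConfig(t_half_min=17.0, seed=1))
t, traces = decay_matrix(decay)
fit = fit_dissociation(t, traces, seed=1)
print(f"dissociation half-life: {fit.t_half_min:.1f} +/- {fit.t_half_se_min:.1f} min")
```

This prints:

```
detected 45 EML4-ALK puncta in 9 cells (5.0 per cell)
mean per-cell colocalization with the adapter channel: 0.80
dissociation half-life: 17.0 +/- 0.2 min
```

The detector recovers all 45 simulated condensates, the per-cell overlap
fraction reproduces the generator's 0.8 co-placement rate, and the
exponential fit recovers the 17-min half-life with its bootstrap standard
error over traces.

A command-line interface mirrors the library (`condensig simulate
puncta|transloc|ktr|decay`, `condensig puncta detect|coloc`, `condensig
transloc`, `condensig pulses`, `condensig neighbors`, `condensig bootstrap`,
`condensig fit-dissociation`); see `condensig --help`.

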