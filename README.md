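# spectint — two-tone spectrotemporal interaction analysis

`spectint` is an analysis pipeline for two-photon calcium imaging
experiments that probe how auditory cortical neurons integrate pairs of
tones across frequency and time.  Neurons in primary auditory cortex (A1)
and the secondary field (A2) respond nonlinearly to two-tone stimuli: a
pair can evoke more (supralinear) or less (sublinear) than the sum of the
single-tone responses, depending on the frequency offset dF (octaves) and
onset interval dT (ms) between the tones.  The pipeline turns trial-aligned
dF/F traces and a stimulus schedule into:

- per-neuron **spectrotemporal interaction maps** — the linearity index
  `LI = (T − L)/(T + L)` over a 9 × 9 dF–dT grid, where `T` is the
  two-tone response amplitude and `L` the linear sum of the component-tone
  amplitudes (amplitudes clamped at zero, so LI ∈ [−1, 1]);
- per-cell significance of facilitation/suppression by a trial-resampling
  rank-sum test (5 two-tone trials against the 25 pairwise sums of
  component-tone trials, α = 0.1);
- **timing-preference classification** (coincidence- vs. shift-preferring,
  1.5× ratio rule) and the temporal asymmetry index `|(P − N)/(P + N)|`;
- **FM-sweep direction selectivity** `DSI = (U − D)/(U + D)` and its
  correlation with the Upward-minus-Downward linearity-index biases
  (`Bias_fac`, `Bias_supp`), the map signature of asymmetric lateral
  inhibition;
- **ensemble population-vector analysis** — Pearson correlations between
  significance-gated two-tone population vectors and the linear sum /
  single-tone vectors, with a two-way (area × timing) ANOVA + Tukey HSD.

Because raw recordings of this kind are rarely public, the package ships a
first-class synthetic-data generator (`spectint.synth`): ground-truth cells
with known LI kernels, GCaMP6s-like transients, lognormal trial noise, and
a pixel-level neuropil-contamination model.  The generator inverts the LI
definition (`T = L (1 + LI)/(1 − LI)`), so every downstream stage is
testable by parameter recovery.

## Worked example

```python
import numpy as np
from spectint import PipelineConfig, run_pipeline

cfg = PipelineConfig(seed=1, template="a2_coincident", n_cells=100,
                     include_fm=False)
res = run_pipeline(cfg)
s = res["summary"]
print(f"responsive ROIs:        {s['n_responsive']}/{cfg.n_cells}")
print(f"two-tone responsive:    {s['n_twotone_responsive']}")
fr = s["timing_fractions"].get("coincident_preferring", 0.0)
print(f"coincidence-preferring: {100*fr:.1f}%")
by_dt = res["ensemble_by_dt"].set_index("dT")["r_linear_sum"]
print(f"r(two-tone, linear sum) at dT=0:       {by_dt[0.0]:.2f}")
print(f"r(two-tone, linear sum), shifted mean: {by_dt.drop(0.0).mean():.2f}")
pm = np.array(s["population_map"])
print(f"population-map LI, dT=0 column:   {np.nanmean(pm[:, 4]):+.2f}")
print(f"population-map LI, shifted cells: {np.nanmean(np.delete(pm, 4, axis=1)):+.2f}")
```

prints

```
responsive ROIs:        98/100
two-tone responsive:    98
coincidence-preferring: 100.0%
r(two-tone, linear sum) at dT=0:       0.86
r(two-tone, linear sum), shifted mean: 0.89
population-map LI, dT=0 column:   +0.39
population-map LI, shifted cells: -0.22
```

A population drawn from the coincidence-tuned kernel template behaves the
way such neurons do in vivo: the averaged interaction map is supralinear
along the dT = 0 column (+0.39) and sublinear at shifted timings (−0.22),
essentially every responsive neuron prefers coincident over shifted pairs,
and the ensemble pattern for coincident two tones resembles the linear sum
of the component-tone ensembles less (0.86) than shifted pairs do (0.89) —
coincident sounds recruit a partly distinct ensemble.

## Analysis sequence

The `analysis/` scripts run the same stages as a narrative sequence on two
simulated populations (an asymmetric, direction-selective one and a
coincidence-tuned one), writing tables under `results/`:

```bash
python analysis/01_simulate.py        # HDF5 datasets + schedules
python analysis/02_process_traces.py  # amplitudes, AUC, significance
python analysis/03_interaction_maps.py
python analysis/04_fm_direction.py
python analysis/05_ensemble.py
```

The same stages are exposed as a CLI (`spectint simulate|process|twotone|
fmsweep|ensemble|run-all`).

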