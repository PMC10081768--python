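# myoslip

Semi-automated quantification of **slippage** — the degree to which cortical
actomyosin flow is (un)coupled from the adjacent cell membrane — in
apically constricting cells, from two-channel fluorescence time-lapses.

During apical constriction (e.g. internalization of the *C. elegans*
endodermal precursor cells Ea/Ep), the apical actomyosin cortex contracts
centripetally in a conveyor-belt fashion, initially without pulling
cell–cell junctions inward. The quantity of interest along each
**centripetal vector** (a "Spyderleg": a ray from a boundary anchor toward
the cell center) is the slippage rate

```
slippage = v_myo − v_mem        [µm/min]
```

where `v_myo` is the mean centripetal component of the dense myosin optical
flow inside a 2 µm window at the outer end of the vector (flow vectors
slower than 1.5 µm/min or moving away from the center are discarded), and
`v_mem` is the signed inward speed of the sub-pixel boundary crossing along
the same ray between consecutive membrane frames. Slippage of 0 means
membrane and myosin move in concert; positive slippage means the myosin
outruns the membrane. Measurements are binned on the developmental clock
(minutes post MSxx birth): **early** = [3, 7] min, **late** = ≥ 13 min.

## Pipeline

1. **Segmentation** (`myoslip.segmentation`) — a trainable three-class
   random-forest pixel classifier (interior / border / background, Labkit
   style) over a small feature bank segments the membrane channel; script-
   driven curation (merge/split/relabel/paint/erase) and centroid tracking
   with per-frame manual overrides keep the workflow replayable.
2. **Flow** (`myoslip.flow`) — optional denoising (pluggable; passthrough
   by default), maximum-intensity Z-projection, and dense Farnebäck
   (polynomial-expansion) optical flow between consecutive myosin frames.
3. **Coupling** (`myoslip.coupling`) — Spyderleg construction, the 2 µm
   window, the 1.5 µm/min filter, centripetal projection, and per-leg
   `SlippageRecord`s.
4. **Statistics** (`myoslip.stats`) — replicate-aware (superplot)
   aggregation leg → cell → embryo → condition, 95% CIs on replicate means,
   Welch and paired t-tests, and chi-square arithmetic for gastrulation-
   defective (Gad) proportions.
5. **Synthetic ground truth** (`myoslip.synthetic`) — a two-channel movie
   generator with known myosin-flow and membrane-contraction speeds, so
   every stage of the pipeline is testable against an exact oracle.

`myoslip.intensity` additionally implements junction line-scan
quantification (50 × 5 px line means, background correction, per-group
normalization, paired embryo ratios, apical:basal enrichment).

## Worked example

Simulate one embryo spanning both stages (myosin flow 1.8 µm/min
throughout; membrane contraction 0.3 µm/min early, 1.0 µm/min from 13 min),
run the full pipeline, and summarize:

```python
import numpy as np
from myoslip import SyntheticMovieSpec, generate_movie
from myoslip.segmentation import annotations_from_mask
from myoslip.pipeline import run_slippage
from myoslip.coupling import records_to_frame
from myoslip.stats import stage_report

spec = SyntheticMovieSpec(n_myosin_frames=144, seed=4)
movie, truth = generate_movie(spec)

rng = np.random.default_rng(4)
annotations = []
n_mem = len(movie.membrane_frames)
for frame in (0, n_mem // 2, n_mem - 1):
    annotations += annotations_from_mask(truth.mask(frame), frame, rng)

result = run_slippage(movie, annotations=annotations, seed=4)
records = records_to_frame(result.records)
print(stage_report(records).round(3).to_string(index=False))
```

prints

```
condition       measurement  mean_early  ci95_early  n_early  mean_late  ci95_late  n_late  mean_difference  p_early_vs_late
      all   Myosin velocity       1.887         NaN        1      1.825        NaN       1            0.062              NaN
      all Membrane movement       0.298         NaN        1      1.005        NaN       1           -0.707              NaN
      all          Slippage       1.589         NaN        1      0.820        NaN       1            0.769              NaN
```

The recovered myosin velocity (≈1.89/1.83 µm/min vs true 1.8), membrane
speed (0.30/1.01 vs true 0.3/1.0) and slippage (1.59/0.82 vs true 1.5/0.8)
show the end-to-end bias of the method under the generator's conditions;
confidence intervals and the paired early-vs-late p-value appear once
several replicate embryos are pooled (see `myoslip.validation`).

The same workflow is available from the shell:

```
myoslip simulate --out movie/ --seed 4
myoslip slippage --input movie/ --annotations ann.csv --out records.csv
myoslip report --records records.csv --out report/
```

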