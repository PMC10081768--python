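"""Synthetic end-to-end benchmark: known-truth replicates through the full
pipeline.

Simulates replicate movies spanning the early and late stages with known
myosin-flow and membrane-contraction speeds, runs segmentation -> flow ->
coupling on each, and summarizes recovery at the condition level.  This is
the package's self-validation: it bounds the method's bias under the
generator's idealizations (see the methods note), not under real imaging.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .coupling import records_to_frame
from .pipeline import run_slippage
from .segmentation import annotations_from_mask
from .stats import aggregate, paired_t
from .synthetic import SyntheticMovieSpec, generate_movie


@dataclass
class BenchmarkResult:
    records: pd.DataFrame  # leg-level records pooled over replicates
    condition: pd.DataFrame  # condition-level means per stage
    expected: dict  # stage -> {v_myo, v_mem, slippage} from the generator
    paired_p: float  # early vs late slippage, paired across replicates


def run_synthetic_benchmark(n_replicates: int = 6, seed: int = 1,
                            spec: SyntheticMovieSpec | None = None,
                            annotate_per_class: int = 300) -> BenchmarkResult:
    """Simulate ``n_replicates`` movies and run the full pipeline on each.

    The default movie spec spans 3 to ~16.6 min post MSxx birth (144 myosin
    frames) so both stage windows are sampled.  Annotations for the pixel
    classifier are sampled from the ground-truth masks on three frames
    (beginning, middle, end), mimicking the sparse manual scribbles of the
    interactive workflow.  All randomness derives from ``seed``.
    """
    if spec is None:
        spec = SyntheticMovieSpec(n_myosin_frames=144)
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=n_replicates)

    frames = []
    for rseed in rep_seeds:
        rspec = replace(spec, seed=int(rseed))
        movie, truth = generate_movie(rspec)
        ann_rng = np.random.default_rng(int(rseed) + 1)
        ann = []
        n_mem = len(movie.membrane_frames)
        for fi in (0, n_mem // 2, n_mem - 1):
            ann.extend(annotations_from_mask(truth.mask(fi), fi, ann_rng,
                                             n_per_class=annotate_per_class))
        result = run_slippage(movie, annotations=ann, seed=int(rseed) % 10000)
        frames.append(records_to_frame(result.records))
    records = pd.concat(frames, ignore_index=True)

    agg = aggregate(records)
    emb = agg["embryo"].pivot(index="embryo", columns="stage", values="slippage")
    p = float("nan")
    if {"early", "late"} <= set(emb.columns):
        both = emb.dropna(subset=["early", "late"])
        if len(both) >= 2:
            _, p = paired_t(both[["early", "late"]].to_numpy())

    expected = {}
    for stage, t_probe in (("early", 0.5 * (3 + 7)), ("late", 14.0)):
        expected[stage] = {
            "v_myo": spec.v_myo_at(t_probe),
            "v_mem": spec.v_mem_at(t_probe),
            "slippage": spec.v_myo_at(t_probe) - spec.v_mem_at(t_probe),
        }
    return BenchmarkResult(records=records, condition=agg["condition"],
                           expected=expected, paired_p=p)
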