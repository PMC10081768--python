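"""End-to-end driver: membrane segmentation -> myosin flow -> coupling.

Chains the stages on an in-memory :class:`~myoslip.model.TimeLapse` with
the manual steps of the workflow (annotations, curation script, centroid
seeds and overrides) supplied as replayable inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coupling import CouplingConfig, SlippageRecord, slippage_records
from .flow import FlowParams, denoise, max_project, movie_flows
from .model import TimeLapse
from .segmentation import (
    CentroidTrack,
    LabelMaskSeries,
    PixelAnnotation,
    PixelClassifier,
    apply_curation,
    predict_masks,
    track_centroid,
    train_pixel_classifier,
)
from .stats import StageBinning


@dataclass
class PipelineResult:
    records: list[SlippageRecord]
    masks: LabelMaskSeries
    track: CentroidTrack


def coupling_config_for(movie: TimeLapse, **overrides) -> CouplingConfig:
    """CouplingConfig with units taken from the movie's metadata."""
    kwargs = dict(pixel_size=movie.pixel_size, myosin_interval=movie.myosin_interval,
                  membrane_stride=movie.membrane_stride)
    kwargs.update(overrides)
    return CouplingConfig(**kwargs)


def segment_movie(movie: TimeLapse, annotations: list[PixelAnnotation] | None = None,
                  classifier: PixelClassifier | None = None, *,
                  curation: list[dict] | None = None, n_trees: int = 100,
                  seed: int = 0, min_area: int = 200
                  ) -> tuple[LabelMaskSeries, PixelClassifier]:
    """Segment the projected membrane channel; train the classifier first if
    one is not supplied."""
    mem = max_project(movie.membrane)
    if classifier is None:
        if annotations is None:
            raise ValueError("segment_movie needs annotations or a trained classifier")
        classifier = train_pixel_classifier(mem, annotations, n_trees=n_trees, seed=seed)
    masks = predict_masks(classifier, mem, min_area=min_area)
    masks.frame_indices = np.asarray(movie.membrane_frames)
    if curation:
        masks = apply_curation(masks, curation)
    return masks, classifier


def run_slippage(movie: TimeLapse, *,
                 annotations: list[PixelAnnotation] | None = None,
                 classifier: PixelClassifier | None = None,
                 masks: LabelMaskSeries | None = None,
                 seeds: dict[int, tuple[float, float]] | None = None,
                 overrides: dict[tuple[int, int], tuple[float, float]] | None = None,
                 curation: list[dict] | None = None,
                 config: CouplingConfig | None = None,
                 flow_params: FlowParams | None = None,
                 binning: StageBinning | None = None,
                 denoise_method: str = "passthrough",
                 n_trees: int = 100, seed: int = 0) -> PipelineResult:
    """Full coupling analysis of one movie.

    Stages: (1) segment the membrane channel (or use supplied masks), with
    optional curation; (2) track cell centers from seeds with optional
    overrides; (3) denoise (default passthrough), maximum-project and
    Farnebäck-flow the myosin channel for every consecutive frame pair the
    membrane intervals span; (4) build Spyderlegs per membrane frame pair
    and emit slippage records.
    """
    if masks is None:
        masks, classifier = segment_movie(movie, annotations, classifier,
                                          curation=curation, n_trees=n_trees, seed=seed)
    if seeds is None:
        # default: seed every labeled cell in the first un-flagged frame
        first = next((i for i in range(len(masks)) if i not in masks.flagged), None)
        if first is None:
            raise ValueError("all mask frames are flagged; cannot seed centroids")
        from scipy import ndimage as ndi
        seeds = {}
        for lid in np.unique(masks.masks[first])[1:]:
            cy, cx = ndi.center_of_mass(masks.masks[first] == lid)
            seeds[int(lid)] = (float(cx), float(cy))
    track = track_centroid(masks, seeds, overrides)

    myo = max_project(denoise(movie.myosin, denoise_method))
    mem_frames = np.asarray(movie.membrane_frames)
    pairs = [j for j in range(int(mem_frames[0]), int(mem_frames[-1]))]
    flows = movie_flows(myo, flow_params, pixel_size=movie.pixel_size,
                        myosin_interval=movie.myosin_interval, pairs=pairs)

    if config is None:
        config = coupling_config_for(movie)
    records = slippage_records(masks, track, flows, config,
                               msxx_birth_offset=movie.msxx_birth_offset,
                               embryo_id=movie.embryo_id, binning=binning)
    return PipelineResult(records=records, masks=masks, track=track)
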