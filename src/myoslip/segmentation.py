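"""Coarse cell segmentation from the membrane channel.

A trainable three-class pixel classifier (random forest over a small bank
of local image features, in the style of Labkit/ilastik) produces class
maps that are post-processed into per-cell integer labels.  Manual steps of
the original workflow — curation of the automatic segmentation and centroid
overrides — are represented as replayable scripts so analyses stay
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
from scipy import ndimage
from skimage import draw, measure, morphology, segmentation as skseg
from sklearn.ensemble import RandomForestClassifier

CLASSES = ("background", "interior", "border")
_CLASS_TO_INT = {c: i for i, c in enumerate(CLASSES)}

# Fixed default feature bank: raw intensity, Gaussian blurs at 3 scales,
# gradient magnitude at 2 scales, Laplacian at 1 scale.
DEFAULT_FEATURES = (
    ("raw", None),
    ("gaussian", 1.0),
    ("gaussian", 2.0),
    ("gaussian", 4.0),
    ("gradient", 1.0),
    ("gradient", 2.0),
    ("laplacian", 2.0),
)


@dataclass
class PixelAnnotation:
    """A user-annotated pixel: frame index, (x, y) position, class name."""

    frame: int
    x: int
    y: int
    label: str

    def __post_init__(self) -> None:
        if self.label not in CLASSES:
            raise ValueError(f"annotation class must be one of {CLASSES}, got {self.label!r}")


@dataclass
class LabelMaskSeries:
    """Per-membrane-frame integer label rasters; 0 is background.

    ``flagged`` lists frames where automatic segmentation found no cell and
    curation is needed.
    """

    masks: np.ndarray  # (Tm, H, W) integer labels
    frame_indices: np.ndarray  # myosin-frame index of each mask
    flagged: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks)
        self.frame_indices = np.asarray(self.frame_indices, dtype=int)
        if self.masks.ndim != 3:
            raise ValueError("masks must be (Tm, H, W)")
        if len(self.frame_indices) != self.masks.shape[0]:
            raise ValueError("frame_indices length must match number of mask frames")

    def __len__(self) -> int:
        return self.masks.shape[0]

    def labels_at(self, i: int) -> np.ndarray:
        return np.unique(self.masks[i][self.masks[i] > 0])


@dataclass
class CentroidTrack:
    """Per-membrane-frame center point per cell, with provenance flags.

    ``centers[cell]`` is (Tm, 2) in (x, y) px; ``flags[cell][i]`` is one of
    ``seeded`` (manual seed frame), ``automatic`` (area centroid of the
    tracked label), ``overridden`` (user-supplied point used verbatim).
    ``labels[cell][i]`` is the mask label id tracked for that cell.
    """

    centers: dict[int, np.ndarray]
    flags: dict[int, list[str]]
    labels: dict[int, np.ndarray]


def compute_features(frame: np.ndarray, features=DEFAULT_FEATURES) -> np.ndarray:
    """Per-pixel feature bank, shape (H, W, n_features)."""
    f = np.asarray(frame, dtype=np.float64)
    out = []
    for kind, sigma in features:
        if kind == "raw":
            out.append(f)
        elif kind == "gaussian":
            out.append(ndimage.gaussian_filter(f, sigma))
        elif kind == "gradient":
            out.append(ndimage.gaussian_gradient_magnitude(f, sigma))
        elif kind == "laplacian":
            out.append(ndimage.gaussian_laplace(f, sigma))
        else:
            raise ValueError(f"unknown feature kind {kind!r}")
    return np.stack(out, axis=-1)


@dataclass
class PixelClassifier:
    """Trained three-class pixel classifier plus its feature-bank descriptor."""

    model: RandomForestClassifier
    features: tuple = DEFAULT_FEATURES

    def predict_frame(self, frame: np.ndarray) -> np.ndarray:
        """Class map (H, W) of ints indexing ``CLASSES``."""
        feats = compute_features(frame, self.features)
        h, w, nf = feats.shape
        return self.model.predict(feats.reshape(-1, nf)).reshape(h, w)

    def save(self, path) -> None:
        joblib.dump({"model": self.model, "features": self.features,
                     "classes": CLASSES, "format_version": 1}, path)

    @classmethod
    def load(cls, path) -> "PixelClassifier":
        blob = joblib.load(path)
        if tuple(blob.get("classes", ())) != CLASSES:
            raise ValueError("classifier file has an incompatible class set")
        return cls(model=blob["model"], features=tuple(map(tuple, blob["features"])))


def train_pixel_classifier(frames: np.ndarray, annotations: list[PixelAnnotation],
                           n_trees: int = 100, seed: int = 0,
                           features=DEFAULT_FEATURES) -> PixelClassifier:
    """Train the random-forest pixel classifier from sparse annotations.

    ``frames`` is the (Tm, H, W) membrane series (projected); annotations
    typically cover a few pixels of each class on ~3 time points.
    """
    present = {a.label for a in annotations}
    missing = [c for c in CLASSES if c not in present]
    if missing:
        raise ValueError(f"annotations missing class(es): {missing}")
    n_frames = frames.shape[0]
    bad = [a.frame for a in annotations if not (0 <= a.frame < n_frames)]
    if bad:
        raise ValueError(f"annotations reference frames not in input: {sorted(set(bad))}")

    feats_cache: dict[int, np.ndarray] = {}
    X, y = [], []
    for a in annotations:
        if a.frame not in feats_cache:
            feats_cache[a.frame] = compute_features(frames[a.frame], features)
        X.append(feats_cache[a.frame][a.y, a.x])
        y.append(_CLASS_TO_INT[a.label])
    model = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    model.fit(np.asarray(X), np.asarray(y))
    return PixelClassifier(model=model, features=tuple(features))


def annotations_from_mask(mask: np.ndarray, frame: int, rng: np.random.Generator,
                          n_per_class: int = 400, border_width: int = 3
                          ) -> list[PixelAnnotation]:
    """Sample sparse annotations from a reference binary cell mask.

    Stands in for the manual scribbles of the interactive workflow when a
    reference segmentation (e.g. synthetic ground truth) is available:
    interior pixels from the eroded mask, border pixels from a band around
    the outline, background pixels away from the cell.
    """
    selem = morphology.disk(border_width)
    interior = morphology.erosion(mask, selem)
    border = morphology.dilation(mask, selem) & ~interior
    # background starts right beyond the border band so the classifier sees
    # no unannotated no-man's-land around the cell outline
    background = ~morphology.dilation(mask, morphology.disk(border_width + 1))
    out = []
    for name, region in (("interior", interior), ("border", border), ("background", background)):
        ys, xs = np.nonzero(region)
        if len(ys) == 0:
            raise ValueError(f"reference mask yields no {name} pixels")
        idx = rng.choice(len(ys), size=min(n_per_class, len(ys)), replace=False)
        out.extend(PixelAnnotation(frame, int(xs[i]), int(ys[i]), name) for i in idx)
    return out


def predict_masks(classifier: PixelClassifier, frames: np.ndarray,
                  min_area: int = 200, border_grow: float = 2.0) -> LabelMaskSeries:
    """Predict class maps and post-process into per-cell labels.

    Interior components above ``min_area`` px² become cell labels (largest
    first); holes inside a cell are filled.  Labels are then grown up to
    ``border_grow`` px into the border class so the cell edge sits near the
    middle of the membrane signal rather than its inner rim; growth is by
    nearest label, so the shared border between adjacent cells is split
    equidistantly and cells never merge.  Frames without any interior
    component are flagged for curation rather than silently empty.
    """
    frames = np.asarray(frames)
    tm = frames.shape[0]
    masks = np.zeros(frames.shape, dtype=np.uint16)
    flagged: set[int] = set()
    for i in range(tm):
        cmap = classifier.predict_frame(frames[i])
        interior = cmap == _CLASS_TO_INT["interior"]
        border = cmap == _CLASS_TO_INT["border"]
        comp = measure.label(interior, connectivity=1)
        regions = [r for r in measure.regionprops(comp) if r.area >= min_area]
        if not regions:
            flagged.add(i)
            continue
        regions.sort(key=lambda r: r.area, reverse=True)
        lab = np.zeros(frames.shape[1:], dtype=np.uint16)
        new_id = 0
        for r in regions:
            cell = comp == r.label
            # hollow shells (misclassified halos around a cell) are not cells
            if ndimage.binary_fill_holes(cell).sum() > 1.5 * cell.sum():
                continue
            cell = ndimage.binary_fill_holes(cell & ~border)
            new_id += 1
            lab[cell & (lab == 0)] = new_id
        if new_id == 0:
            flagged.add(i)
            continue
        if border_grow > 0:
            grown = skseg.expand_labels(lab, distance=border_grow)
            lab = np.where(border & (lab == 0), grown, lab).astype(np.uint16)
            for lid in np.unique(lab[lab > 0]):
                lab[ndimage.binary_fill_holes(lab == lid) & (lab == 0)] = lid
        masks[i] = lab
    return LabelMaskSeries(masks=masks, frame_indices=np.arange(tm), flagged=flagged)


# -- curation ---------------------------------------------------------------

def _polygon_mask(shape, polygon) -> np.ndarray:
    poly = np.asarray(polygon, dtype=float)
    rr, cc = draw.polygon(poly[:, 1], poly[:, 0], shape)
    m = np.zeros(shape, dtype=bool)
    m[rr, cc] = True
    return m


def apply_curation(series: LabelMaskSeries, edits: list[dict]) -> LabelMaskSeries:
    """Apply a replayable curation script to a label series.

    Each edit is a mapping with a ``frame`` and a ``verb``:

    - ``merge``: ``labels`` merged into their smallest id
    - ``relabel``: ``from`` renamed ``to``
    - ``split``: ``label`` partitioned among ``seeds`` (list of (x, y)) by
      seeded watershed on the distance transform; the first seed keeps the
      original id
    - ``paint``: ``polygon`` (list of (x, y)) set to ``label``
    - ``erase``: ``polygon`` set to background

    Edits are idempotent (re-applying a script is a no-op), so scripts can
    be replayed safely; an edit whose labels never existed raises.
    """
    masks = series.masks.copy()
    tm = len(series)
    for edit in edits:
        frame = int(edit["frame"])
        if not (0 <= frame < tm):
            raise ValueError(f"curation edit references missing frame {frame}")
        verb = edit["verb"]
        lab = masks[frame]
        if verb == "merge":
            ids = [int(v) for v in edit["labels"]]
            present = [v for v in ids if (lab == v).any()]
            if not present:
                raise ValueError(f"merge at frame {frame}: none of labels {ids} exist")
            target = min(present)
            for v in present:
                lab[lab == v] = target
        elif verb == "relabel":
            src, dst = int(edit["from"]), int(edit["to"])
            if (lab == src).any():
                lab[lab == src] = dst
            elif not (lab == dst).any():
                raise ValueError(f"relabel at frame {frame}: label {src} does not exist")
        elif verb == "split":
            target = int(edit["label"])
            region = lab == target
            if not region.any():
                raise ValueError(f"split at frame {frame}: label {target} does not exist")
            seeds = [(float(x), float(y)) for x, y in edit["seeds"]]
            inside = [(x, y) for x, y in seeds if region[int(round(y)), int(round(x))]]
            if len(inside) >= 2:
                markers = np.zeros(lab.shape, dtype=np.int32)
                for i, (x, y) in enumerate(inside, start=1):
                    markers[int(round(y)), int(round(x))] = i
                dist = ndimage.distance_transform_edt(region)
                ws = skseg.watershed(-dist, markers=markers, mask=region)
                new_ids = [target] + [int(masks[frame].max()) + i for i in range(1, len(inside))]
                for i, nid in enumerate(new_ids, start=1):
                    lab[ws == i] = nid
        elif verb == "paint":
            lab[_polygon_mask(lab.shape, edit["polygon"])] = int(edit["label"])
        elif verb == "erase":
            lab[_polygon_mask(lab.shape, edit["polygon"])] = 0
        else:
            raise ValueError(f"unknown curation verb {verb!r}")
        masks[frame] = lab
    return LabelMaskSeries(masks=masks, frame_indices=series.frame_indices.copy(),
                           flagged=set(series.flagged))


# -- centroid tracking ------------------------------------------------------

def track_centroid(series: LabelMaskSeries, seeds: dict[int, tuple[float, float]],
                   overrides: dict[tuple[int, int], tuple[float, float]] | None = None
                   ) -> CentroidTrack:
    """Track each cell's center across membrane frames.

    ``seeds`` maps a cell id to an (x, y) point inside that cell's label at
    the first frame; subsequent frames use the area centroid of the label
    containing the previous center (nearest label if the point falls on
    background).  ``overrides`` maps (cell, frame) to a point used verbatim
    and flagged ``overridden``.
    """
    overrides = overrides or {}
    tm = len(series)
    centers: dict[int, np.ndarray] = {}
    flags: dict[int, list[str]] = {}
    labels: dict[int, np.ndarray] = {}
    for cell, (sx, sy) in seeds.items():
        c = np.empty((tm, 2))
        fl = []
        ids = np.zeros(tm, dtype=int)
        point = (float(sx), float(sy))
        for i in range(tm):
            lab = series.masks[i]
            lid = _label_at(lab, point)
            if i == 0 and lid == 0:
                raise ValueError(f"seed {point} for cell {cell} falls outside all labels")
            if lid == 0:
                lid = _nearest_label(lab, point)
            ids[i] = lid
            if (cell, i) in overrides:
                point = tuple(map(float, overrides[(cell, i)]))
                c[i] = point
                fl.append("overridden")
            else:
                cy, cx = ndimage.center_of_mass(lab == lid)
                point = (float(cx), float(cy))
                c[i] = point
                fl.append("seeded" if i == 0 else "automatic")
        centers[cell] = c
        flags[cell] = fl
        labels[cell] = ids
    return CentroidTrack(centers=centers, flags=flags, labels=labels)


def _label_at(lab: np.ndarray, point: tuple[float, float]) -> int:
    x, y = int(round(point[0])), int(round(point[1]))
    if not (0 <= y < lab.shape[0] and 0 <= x < lab.shape[1]):
        return 0
    return int(lab[y, x])


def _nearest_label(lab: np.ndarray, point: tuple[float, float]) -> int:
    ids = np.unique(lab[lab > 0])
    if len(ids) == 0:
        raise ValueError("no labels present in frame while tracking centroid")
    best, best_d = 0, np.inf
    for lid in ids:
        cy, cx = ndimage.center_of_mass(lab == lid)
        d = (cx - point[0]) ** 2 + (cy - point[1]) ** 2
        if d < best_d:
            best, best_d = int(lid), d
    return best
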