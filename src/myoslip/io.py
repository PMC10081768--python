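"""Readers/writers and run configuration.

File contracts: OME-TIFF (TZYX) per channel plus a YAML sidecar with the
acquisition metadata (the sidecar, being explicit, overrides embedded TIFF
metadata when both exist); 16-bit label TIFF for masks; (T, 2, H, W)
float32 TIFF for flow fields (bands dx, dy); tidy CSV for records and
summaries; YAML for configs, annotations, curation scripts and ROIs; a
plain-text YAML run log capturing config, versions and seeds.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .coupling import CouplingConfig, SlippageRecord, records_to_frame
from .flow import FlowField
from .model import TimeLapse
from .segmentation import LabelMaskSeries, PixelAnnotation

SIDECAR_NAME = "metadata.yaml"


def write_timelapse(movie: TimeLapse, outdir) -> Path:
    """Write a movie as myosin.ome.tif + membrane.ome.tif + metadata.yaml."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    res = (1.0 / movie.pixel_size, 1.0 / movie.pixel_size)
    tifffile.imwrite(outdir / "myosin.ome.tif", movie.myosin,
                     metadata={"axes": "TZYX"}, resolution=res)
    tifffile.imwrite(outdir / "membrane.ome.tif", movie.membrane,
                     metadata={"axes": "TZYX"}, resolution=res)
    sidecar = {
        "pixel_size_um": float(movie.pixel_size),
        "myosin_interval_s": float(movie.myosin_interval),
        "membrane_stride": int(movie.membrane_stride),
        "z_step_um": float(movie.z_step),
        "msxx_birth_offset_min": float(movie.msxx_birth_offset),
        "membrane_frames": [int(i) for i in movie.membrane_frames],
        "embryo_id": movie.embryo_id,
    }
    (outdir / SIDECAR_NAME).write_text(yaml.safe_dump(sidecar, sort_keys=True))
    return outdir


REQUIRED_METADATA = ("pixel_size_um", "myosin_interval_s", "membrane_stride")


def read_timelapse(path) -> TimeLapse:
    """Read a movie directory written by :func:`write_timelapse`.

    Metadata comes from the YAML sidecar; units cannot default silently, so
    a missing sidecar or missing mandatory keys is a hard error naming what
    is absent.
    """
    path = Path(path)
    sidecar_path = path / SIDECAR_NAME
    if not sidecar_path.exists():
        raise FileNotFoundError(
            f"no {SIDECAR_NAME} sidecar in {path}; pixel size and frame timing "
            "cannot default silently — provide the sidecar")
    meta = yaml.safe_load(sidecar_path.read_text())
    missing = [k for k in REQUIRED_METADATA if k not in meta]
    if missing:
        raise ValueError(f"sidecar {sidecar_path} missing mandatory metadata: {missing}")
    myosin = _read_tzyx(path / "myosin.ome.tif")
    membrane = _read_tzyx(path / "membrane.ome.tif")
    stride = int(meta["membrane_stride"])
    mem_frames = meta.get("membrane_frames")
    if mem_frames is None:
        mem_frames = list(range(0, myosin.shape[0], stride))
    return TimeLapse(
        myosin=myosin, membrane=membrane, membrane_frames=np.asarray(mem_frames),
        pixel_size=float(meta["pixel_size_um"]),
        myosin_interval=float(meta["myosin_interval_s"]),
        membrane_stride=stride,
        z_step=float(meta.get("z_step_um", 0.5)),
        msxx_birth_offset=float(meta.get("msxx_birth_offset_min", 0.0)),
        embryo_id=str(meta.get("embryo_id", path.name)),
    )


def _read_tzyx(path) -> np.ndarray:
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None, None]
    elif arr.ndim == 3:
        arr = arr[:, None]
    elif arr.ndim != 4:
        raise ValueError(f"{path}: cannot resolve axes of a {arr.ndim}-D stack to TZYX; "
                         "expected 2-4 dimensions")
    return arr


# -- masks ------------------------------------------------------------------

def write_masks(series: LabelMaskSeries, path) -> None:
    path = Path(path)
    tifffile.imwrite(path, series.masks.astype(np.uint16), metadata={"axes": "TYX"},
                     photometric="minisblack")
    side = {"frame_indices": [int(i) for i in series.frame_indices],
            "flagged": sorted(int(i) for i in series.flagged)}
    path.with_suffix(".yaml").write_text(yaml.safe_dump(side, sort_keys=True))


def read_masks(path) -> LabelMaskSeries:
    path = Path(path)
    masks = tifffile.imread(path)
    if masks.ndim == 2:
        masks = masks[None]
    side_path = path.with_suffix(".yaml")
    if side_path.exists():
        side = yaml.safe_load(side_path.read_text())
        idx = np.asarray(side["frame_indices"])
        flagged = set(side.get("flagged", []))
    else:
        idx = np.arange(masks.shape[0])
        flagged = set()
    return LabelMaskSeries(masks=masks, frame_indices=idx, flagged=flagged)


# -- flow -------------------------------------------------------------------

def write_flows(flows: dict[int, FlowField], path) -> None:
    """(T, 2, H, W) float32 TIFF, bands (dx, dy), plus a pair-index sidecar."""
    path = Path(path)
    keys = sorted(flows)
    stack = np.stack([flows[k].flow.transpose(2, 0, 1) for k in keys]).astype(np.float32)
    tifffile.imwrite(path, stack, metadata={"axes": "TCYX"})
    f0 = flows[keys[0]]
    side = {"pair_indices": keys, "pixel_size_um": float(f0.pixel_size),
            "myosin_interval_s": float(f0.myosin_interval)}
    path.with_suffix(".yaml").write_text(yaml.safe_dump(side, sort_keys=True))


def read_flows(path) -> dict[int, FlowField]:
    path = Path(path)
    stack = tifffile.imread(path)
    side = yaml.safe_load(path.with_suffix(".yaml").read_text())
    keys = side["pair_indices"]
    return {k: FlowField(flow=stack[i].transpose(1, 2, 0).astype(np.float64),
                         pair_index=k, pixel_size=side["pixel_size_um"],
                         myosin_interval=side["myosin_interval_s"])
            for i, k in enumerate(keys)}


# -- records / annotations / scripts ---------------------------------------

def write_records(records: list[SlippageRecord] | pd.DataFrame, path) -> None:
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    df.to_csv(path, index=False)


def read_records(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "flag" in df.columns:
        df["flag"] = df["flag"].fillna("")
    return df


def read_annotations(path) -> list[PixelAnnotation]:
    """Annotations CSV with columns frame,x,y,class."""
    df = pd.read_csv(path)
    return [PixelAnnotation(int(row["frame"]), int(row["x"]), int(row["y"]),
                            str(row["class"]))
            for _, row in df.iterrows()]


def write_annotations(annotations: list[PixelAnnotation], path) -> None:
    pd.DataFrame([{"frame": a.frame, "x": a.x, "y": a.y, "class": a.label}
                  for a in annotations]).to_csv(path, index=False)


def read_curation(path) -> list[dict]:
    edits = yaml.safe_load(Path(path).read_text()) or []
    if not isinstance(edits, list):
        raise ValueError(f"curation script {path} must be a YAML list of edits")
    return edits


def write_run_log(outdir, entries: dict) -> Path:
    """Append-style run log: config, package/library versions, seeds."""
    import myoslip

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = {
        "myoslip_version": myoslip.__version__,
        "numpy_version": np.__version__,
        **{k: (asdict(v) if hasattr(v, "__dataclass_fields__") else v)
           for k, v in entries.items()},
    }
    path = outdir / "run_log.yaml"
    path.write_text(yaml.safe_dump(log, sort_keys=True, default_flow_style=False))
    return path
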