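"""Readers and writers for the pipeline's on-disk artifacts.

Frames travel as zero-padded numbered PNG files in a directory with a
JSON sidecar; detections, tracks, ground truth and embryo records as
CSV; heatmaps as a CSV grid plus an optional rendered PNG. Every writer
can attach a provenance sidecar (config, seed, package version, input
hashes) so runs are reproducible from their outputs alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .detect import Detection, FrameStack
from .embryo import EmbryoRecord
from .simulate import GroundTruth
from .spatial import Heatmap
from .track import Track

logger = logging.getLogger(__name__)

SIDECAR_NAME = "provenance.json"
FRAME_PATTERN = "frame_{:06d}.png"


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    return obj


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_sidecar(
    directory: str | Path,
    config: Any = None,
    seed: int | None = None,
    inputs: Sequence[str | Path] = (),
) -> Path:
    """Write a provenance sidecar JSON into ``directory``."""
    from . import __version__

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    payload = {
        "package": "fintrack",
        "version": __version__,
        "seed": seed,
        "config": _jsonable(config),
        "inputs": {str(p): sha256_of(p) for p in inputs},
    }
    path = directory / SIDECAR_NAME
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path


# ---------------------------------------------------------------------------
# frames


def write_frames(stack: FrameStack, directory: str | Path, config: Any = None,
                 seed: int | None = None) -> Path:
    """Write frames as zero-padded PNGs plus a provenance sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i in range(stack.n_frames):
        iio.imwrite(directory / FRAME_PATTERN.format(i),
                    stack.frames[i].astype(np.uint8))
    sidecar = config if config is not None else {}
    write_sidecar(
        directory,
        config={"frame_period_s": stack.frame_period_s, "source": _jsonable(sidecar)},
        seed=seed,
    )
    logger.info("wrote %d frames to %s", stack.n_frames, directory)
    return directory


def read_frames(directory: str | Path, frame_period_s: float | None = None) -> FrameStack:
    """Read a PNG/TIFF image-sequence directory back into a FrameStack.

    The frame period is taken from the sidecar when present unless
    overridden.
    """
    directory = Path(directory)
    paths = sorted(
        p for p in directory.iterdir()
        if p.suffix.lower() in {".png", ".tif", ".tiff"}
    )
    if not paths:
        raise FileNotFoundError(f"no image frames in {directory}")
    frames = np.stack([np.asarray(iio.imread(p)) for p in paths])
    if frames.ndim == 4:  # collapse accidental RGB to grayscale
        frames = frames.mean(axis=-1)
    if frame_period_s is None:
        frame_period_s = 1.0
        sidecar = directory / SIDECAR_NAME
        if sidecar.exists():
            cfg = json.loads(sidecar.read_text()).get("config") or {}
            frame_period_s = float(cfg.get("frame_period_s", 1.0))
    return FrameStack(frames=frames.astype(np.uint8), frame_period_s=frame_period_s)


# ---------------------------------------------------------------------------
# tabular artifacts


def ground_truth_to_csv(truth: GroundTruth, path: str | Path) -> None:
    truth.as_dataframe().to_csv(path, index=False)


def ground_truth_from_csv(path: str | Path) -> GroundTruth:
    df = pd.read_csv(path)
    fish_ids = sorted(df["fish_id"].unique())
    frames = sorted(df["frame"].unique())
    pos = np.zeros((len(fish_ids), len(frames), 2))
    for k, fid in enumerate(fish_ids):
        sub = df[df["fish_id"] == fid].sort_values("frame")
        pos[k, :, 0] = sub["x"].to_numpy()
        pos[k, :, 1] = sub["y"].to_numpy()
    return GroundTruth(pos)


def detections_to_csv(detections_by_frame: Sequence[Sequence[Detection]],
                      path: str | Path) -> None:
    rows = [
        {"frame": d.frame_index, "x": d.centroid_x, "y": d.centroid_y,
         "area": d.area_px}
        for dets in detections_by_frame for d in dets
    ]
    pd.DataFrame(rows, columns=["frame", "x", "y", "area"]).to_csv(path, index=False)


def detections_from_csv(path: str | Path, n_frames: int | None = None
                        ) -> list[list[Detection]]:
    df = pd.read_csv(path)
    last = int(df["frame"].max()) if len(df) else -1
    n = n_frames if n_frames is not None else last + 1
    out: list[list[Detection]] = [[] for _ in range(n)]
    for row in df.itertuples(index=False):
        out[int(row.frame)].append(
            Detection(frame_index=int(row.frame), centroid_x=float(row.x),
                      centroid_y=float(row.y), area_px=int(row.area))
        )
    return out


def tracks_to_csv(tracks: Sequence[Track], path: str | Path) -> None:
    rows = [
        {"frame": t, "fish_id": tr.fish_id, "x": tr.positions[t, 0],
         "y": tr.positions[t, 1], "observed": bool(tr.observed[t])}
        for tr in tracks for t in range(tr.n_frames)
    ]
    pd.DataFrame(rows, columns=["frame", "fish_id", "x", "y", "observed"]).to_csv(
        path, index=False)


def tracks_from_csv(path: str | Path) -> list[Track]:
    df = pd.read_csv(path)
    tracks = []
    for fid in sorted(df["fish_id"].unique()):
        sub = df[df["fish_id"] == fid].sort_values("frame")
        tracks.append(
            Track(fish_id=int(fid),
                  positions=sub[["x", "y"]].to_numpy(float),
                  observed=sub["observed"].to_numpy(bool))
        )
    return tracks


def embryo_records_to_csv(records: Sequence[EmbryoRecord], path: str | Path) -> None:
    """Long-format CSV: one row per embryo-day (dish,embryo,day,stage,
    abnormal,abnormal_feature,hatch_day)."""
    rows = []
    for r in records:
        for day in sorted(r.daily_stages):
            rows.append({
                "dish": r.dish_id, "embryo": r.embryo_id, "day": day,
                "stage": r.daily_stages[day], "abnormal": r.abnormal,
                "abnormal_feature": r.abnormal_feature or "",
                "hatch_day": "" if r.hatch_day is None else r.hatch_day,
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def embryo_records_from_csv(path: str | Path) -> list[EmbryoRecord]:
    df = pd.read_csv(path, keep_default_na=False)
    records = []
    for (dish, embryo), sub in df.groupby(["dish", "embryo"], sort=True):
        first = sub.iloc[0]
        hatch = first["hatch_day"]
        feature = str(first["abnormal_feature"]) or None
        records.append(
            EmbryoRecord(
                dish_id=int(dish), embryo_id=int(embryo),
                daily_stages={int(r.day): int(r.stage)
                              for r in sub.itertuples(index=False)},
                abnormal=str(first["abnormal"]).lower() in {"true", "1"},
                abnormal_feature=feature,
                hatch_day=None if hatch in ("", None) else float(hatch),
            )
        )
    return records


def heatmap_to_csv(heatmap: Heatmap, path: str | Path) -> None:
    np.savetxt(path, heatmap.counts, fmt="%d", delimiter=",")


def heatmap_from_csv(path: str | Path, bin_size_px: int = 1) -> Heatmap:
    return Heatmap(counts=np.loadtxt(path, delimiter=",", dtype=np.int64, ndmin=2),
                   bin_size_px=bin_size_px)


def render_heatmap_png(heatmap: Heatmap, path: str | Path,
                       title: str = "occupancy") -> None:
    """Render the dwell-count grid to PNG (matplotlib, headless)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    im = ax.imshow(heatmap.counts, cmap="hot", origin="upper")
    ax.set_title(title)
    ax.set_xlabel("x bin")
    ax.set_ylabel("y bin")
    fig.colorbar(im, ax=ax, label="dwell count")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
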