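"""Readers/writers and dataset tiling.

Formats:

* COCO-style JSON for boxes — ``images`` / ``annotations`` / ``categories``
  with a single category and ``bbox = [x, y, w, h]``;
* clicks CSV with columns ``image_id, x, y``;
* an optional difficulty sidecar JSON (synthetic datasets only);
* per-episode log CSV.

Tiling slices each image into a non-overlapping grid and applies one of two
partial-object rules: ``drop-image`` discards any tile containing a partial
object (or no object at all), while ``drop-annotation`` discards only the
partial annotations and keeps the tile if at least one whole object remains.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd

from .data import Dataset, ImageRecord, ObjectAttributes
from .geometry import Box, Click
from .loop import EpisodeLog

__all__ = [
    "read_annotations",
    "write_annotations",
    "read_clicks",
    "write_clicks",
    "write_difficulties",
    "read_difficulties",
    "tile_dataset",
    "write_episode_logs",
    "read_episode_logs",
]

CATEGORY = {"id": 1, "name": "panicle"}


def write_annotations(dataset: Dataset, path: str | Path) -> None:
    """COCO-style JSON with deterministic ordering (byte-stable re-writes)."""
    images = []
    annotations = []
    ann_id = 1
    for iid in sorted(dataset):
        rec = dataset[iid]
        images.append(
            {"id": iid, "width": rec.width, "height": rec.height, "file_name": f"{iid}.png"}
        )
        for b in rec.gt_boxes:
            annotations.append(
                {
                    "id": ann_id,
                    "image_id": iid,
                    "category_id": CATEGORY["id"],
                    "bbox": [b.xmin, b.ymin, b.width, b.height],
                    "area": b.width * b.height,
                    "iscrowd": 0,
                }
            )
            ann_id += 1
    payload = {"images": images, "annotations": annotations, "categories": [CATEGORY]}
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_annotations(path: str | Path) -> dict[str, ImageRecord]:
    """Read a COCO-style JSON file into ImageRecords (boxes only)."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"{path}: not valid JSON ({e})") from e
    records: dict[str, ImageRecord] = {}
    for entry in payload.get("images", []):
        iid = str(entry["id"])
        if iid in records:
            raise ValueError(f"{path}: duplicate image id {iid!r}")
        records[iid] = ImageRecord(
            id=iid, width=float(entry["width"]), height=float(entry["height"])
        )
    for k, ann in enumerate(payload.get("annotations", [])):
        iid = str(ann["image_id"])
        if iid not in records:
            raise ValueError(
                f"{path}: annotation #{k} references missing image {iid!r}"
            )
        try:
            x, y, w, h = ann["bbox"]
        except (KeyError, ValueError) as e:
            raise ValueError(f"{path}: annotation #{k}: bad bbox field ({e})") from e
        records[iid].gt_boxes.append(Box(x, y, x + w, y + h))
    return records


def write_clicks(dataset: Dataset, path: str | Path) -> None:
    rows = [
        {"image_id": iid, "x": c.x, "y": c.y}
        for iid in sorted(dataset)
        for c in dataset[iid].clicks
    ]
    pd.DataFrame(rows, columns=["image_id", "x", "y"]).to_csv(path, index=False)


def read_clicks(path: str | Path, dataset: dict[str, ImageRecord]) -> None:
    """Attach clicks from CSV to an existing dataset, in place."""
    df = pd.read_csv(path)
    for row in df.itertuples(index=False):
        iid = str(row.image_id)
        if iid not in dataset:
            raise ValueError(f"{path}: click references missing image {iid!r}")
        dataset[iid].clicks.append(Click(float(row.x), float(row.y)))


def write_difficulties(dataset: Dataset, path: str | Path) -> None:
    payload = {
        iid: [[a.blur, a.occlusion, a.lighting] for a in dataset[iid].difficulties]
        for iid in sorted(dataset)
        if dataset[iid].difficulties
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_difficulties(path: str | Path, dataset: dict[str, ImageRecord]) -> None:
    payload = json.loads(Path(path).read_text())
    for iid, rows in payload.items():
        if iid not in dataset:
            raise ValueError(f"{path}: difficulties for missing image {iid!r}")
        dataset[iid].difficulties = [ObjectAttributes(*r) for r in rows]


TileMode = Literal["drop-image", "drop-annotation"]


def _tile_origin_grid(extent: float, tile: float) -> list[float]:
    n = int(extent // tile)
    return [i * tile for i in range(n)]


def tile_dataset(
    dataset: Dataset, tile_size: float, mode: TileMode = "drop-image"
) -> dict[str, ImageRecord]:
    """Slice every image into a non-overlapping ``tile_size`` grid.

    A "partial object" is any box not fully contained in its tile.  Tiles
    with zero whole objects are always removed.  Box coordinates are
    re-expressed in the tile frame; per-object difficulty follows its box.
    """
    if tile_size <= 0:
        raise ValueError("tile_size must be > 0")
    out: dict[str, ImageRecord] = {}
    for iid in sorted(dataset):
        rec = dataset[iid]
        if tile_size > rec.width or tile_size > rec.height:
            raise ValueError(
                f"tile size {tile_size} exceeds image {iid!r} "
                f"({rec.width}x{rec.height})"
            )
        for ox in _tile_origin_grid(rec.width, tile_size):
            for oy in _tile_origin_grid(rec.height, tile_size):
                whole: list[Box] = []
                whole_attrs: list[ObjectAttributes] = []
                partial = False
                for k, b in enumerate(rec.gt_boxes):
                    intersects = (
                        b.xmin < ox + tile_size
                        and b.xmax > ox
                        and b.ymin < oy + tile_size
                        and b.ymax > oy
                    )
                    if not intersects:
                        continue
                    inside = (
                        b.xmin >= ox
                        and b.ymin >= oy
                        and b.xmax <= ox + tile_size
                        and b.ymax <= oy + tile_size
                    )
                    if inside:
                        whole.append(Box(b.xmin - ox, b.ymin - oy, b.xmax - ox, b.ymax - oy))
                        if k < len(rec.difficulties):
                            whole_attrs.append(rec.difficulties[k])
                    else:
                        partial = True
                if mode == "drop-image" and partial:
                    continue
                if not whole:
                    continue
                tid = f"{iid}_x{int(ox)}_y{int(oy)}"
                out[tid] = ImageRecord(
                    id=tid,
                    width=tile_size,
                    height=tile_size,
                    gt_boxes=whole,
                    difficulties=whole_attrs if len(whole_attrs) == len(whole) else [],
                )
    return out


_LOG_COLUMNS = [
    "episode",
    "method",
    "n_labeled",
    "n_weak",
    "n_unlabeled",
    "n_clicks_added",
    "n_boxes_added",
    "episode_seconds",
    "cumulative_seconds",
    "ap",
]


def write_episode_logs(logs: Iterable[EpisodeLog], path: str | Path) -> None:
    rows = [{k: getattr(log, k) for k in _LOG_COLUMNS} for log in logs]
    pd.DataFrame(rows, columns=_LOG_COLUMNS).to_csv(path, index=False)


def read_episode_logs(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
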