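"""State carried between axial slices: per-tooth seeds and per-slice masks."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .region_grow import BoundingBox

__all__ = ["ToothSeedSet", "SliceSegState", "ACTIVE", "TERMINATED"]

ACTIVE = "active"
TERMINATED = "terminated"


@dataclass
class ToothSeedSet:
    """User input: per-tooth seed pixels on one reference slice plus a 3D
    bounding box enclosing the dentition.

    The reference slice should be one where teeth and their sockets are
    clearly distinguishable; the bounding box delimits the region (in-plane
    and in z) the segmentation is allowed to occupy.
    """

    reference_slice: int
    seeds: dict[int, list[tuple[int, int]]]
    bbox: BoundingBox

    def __post_init__(self) -> None:
        if self.bbox.ndim != 3:
            raise ValueError("seed-set bounding box must be 3D")
        z = self.reference_slice
        if not self.bbox.mins[2] <= z < self.bbox.maxs[2]:
            raise ValueError(f"reference slice {z} outside bounding box z-range")
        self.seeds = {int(k): [tuple(int(c) for c in s) for s in v] for k, v in self.seeds.items()}
        for tid, pts in self.seeds.items():
            if not pts:
                raise ValueError(f"tooth {tid} has no seeds")
            for x, y in pts:
                if not self.bbox.contains((x, y, z)):
                    raise ValueError(f"seed {(x, y)} of tooth {tid} outside bounding box")

    @property
    def tooth_ids(self) -> list[int]:
        return sorted(self.seeds)

    # JSON schema: {"<tooth_id>": [[x, y, z], ...], "bbox": [xmin, ymin, zmin,
    # xmax, ymax, zmax], "reference_slice": z}
    def to_json(self, path) -> None:
        obj: dict = {
            str(tid): [[x, y, self.reference_slice] for x, y in pts]
            for tid, pts in self.seeds.items()
        }
        obj["bbox"] = list(self.bbox.mins) + list(self.bbox.maxs)
        obj["reference_slice"] = self.reference_slice
        Path(path).write_text(json.dumps(obj, indent=1))

    @classmethod
    def from_json(cls, path) -> "ToothSeedSet":
        obj = json.loads(Path(path).read_text())
        ref = int(obj.pop("reference_slice"))
        box = obj.pop("bbox")
        bbox = BoundingBox(tuple(int(v) for v in box[:3]), tuple(int(v) for v in box[3:]))
        seeds = {int(tid): [(int(p[0]), int(p[1])) for p in pts] for tid, pts in obj.items()}
        return cls(reference_slice=ref, seeds=seeds, bbox=bbox)


@dataclass
class SliceSegState:
    """Per-slice result: one binary mask and the T-value that produced it for
    every tooth still active, plus a status flag per tooth."""

    z: int
    masks: dict[int, np.ndarray]
    t_values: dict[int, float]
    status: dict[int, str]

    def __post_init__(self) -> None:
        for tid, st in self.status.items():
            if st not in (ACTIVE, TERMINATED):
                raise ValueError(f"tooth {tid}: unknown status {st!r}")
            if st == ACTIVE and not self.masks.get(tid, np.zeros(0, bool)).any():
                raise ValueError(f"tooth {tid} is active but has an empty mask")

    @property
    def active_ids(self) -> list[int]:
        return sorted(t for t, s in self.status.items() if s == ACTIVE)
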