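"""Queue-based seeded region growing (SRG) and inverse-SRG hole filling.

A candidate voxel x joins the region A iff it is connectivity-adjacent to A,
lies inside the bounding box, has intensity >= the working threshold, and
satisfies the homogeneity test |I(x) - mean(A)| < delta.  Expansion is
first-in-first-out from the seed set.

With ``mean_mode="frozen"`` (the default) mean(A) is fixed to the mean of the
seed intensities, which makes the admission predicate static: the result is
exactly the set of voxels reachable from the seeds through admissible voxels
and is therefore independent of seed ordering and of any partitioning of the
seed set — the property that makes scatter-based parallel growing safe.
``mean_mode="running"`` updates mean(A) as voxels join; its FIFO order is
fixed by lexicographic seed sorting so results stay reproducible.

Hole filling is the inverse operation: the *background* is grown from every
bounding-box boundary voxel not in the mask, by pure connectivity with no
intensity test; the complement of that background inside the box is the mask
plus all enclosed cavities (the dark dentin/pulp interiors of teeth).
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["GrowParams", "BoundingBox", "grow", "fill_holes", "scatter_seeds"]

_CONN_2D = {4, 8}
_CONN_3D = {6, 26}


@dataclass
class GrowParams:
    """delta: max HU deviation from the region mean; connectivity 4/8 (2D) or
    6/26 (3D); mean_mode "frozen" (order-independent) or "running"."""

    delta: float = 60.0
    connectivity: int = 4
    mean_mode: str = "frozen"

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be > 0")
        if self.connectivity not in _CONN_2D | _CONN_3D:
            raise ValueError(f"connectivity must be one of {{4, 8, 6, 26}}, got {self.connectivity}")
        if self.mean_mode not in ("frozen", "running"):
            raise ValueError(f"mean_mode must be 'frozen' or 'running', got {self.mean_mode!r}")


@dataclass(frozen=True)
class BoundingBox:
    """Half-open axis-aligned voxel box: ``mins`` inclusive, ``maxs`` exclusive."""

    mins: tuple[int, ...]
    maxs: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.mins) != len(self.maxs):
            raise ValueError("mins and maxs must have the same length")
        if any(lo >= hi for lo, hi in zip(self.mins, self.maxs)):
            raise ValueError(f"need min < max on every axis, got {self.mins} .. {self.maxs}")

    @property
    def ndim(self) -> int:
        return len(self.mins)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(hi - lo for lo, hi in zip(self.mins, self.maxs))

    def slices(self) -> tuple[slice, ...]:
        return tuple(slice(lo, hi) for lo, hi in zip(self.mins, self.maxs))

    def contains(self, idx: Sequence[int]) -> bool:
        return all(lo <= i < hi for i, lo, hi in zip(idx, self.mins, self.maxs))

    @classmethod
    def full(cls, shape: Sequence[int]) -> "BoundingBox":
        return cls(tuple(0 for _ in shape), tuple(int(n) for n in shape))

    @classmethod
    def from_mask(cls, mask: np.ndarray, margin: int = 0) -> "BoundingBox":
        """Tight box around the nonzero voxels, grown by ``margin`` and
        clipped to the array bounds."""
        nz = np.nonzero(mask)
        if nz[0].size == 0:
            raise ValueError("mask is empty")
        mins = tuple(max(0, int(ax.min()) - margin) for ax in nz)
        maxs = tuple(
            min(n, int(ax.max()) + 1 + margin) for ax, n in zip(nz, mask.shape)
        )
        return cls(mins, maxs)

    def intersect(self, other: "BoundingBox") -> "BoundingBox | None":
        """Intersection with ``other``, or None when they are disjoint."""
        mins = tuple(max(a, b) for a, b in zip(self.mins, other.mins))
        maxs = tuple(min(a, b) for a, b in zip(self.maxs, other.maxs))
        if any(lo >= hi for lo, hi in zip(mins, maxs)):
            return None
        return BoundingBox(mins, maxs)

    def project_xy(self) -> "BoundingBox":
        """The in-plane (x, y) box of a 3D box."""
        if self.ndim != 3:
            raise ValueError("project_xy needs a 3D box")
        return BoundingBox(self.mins[:2], self.maxs[:2])


def neighbor_offsets(ndim: int, connectivity: int) -> list[tuple[int, ...]]:
    allowed = _CONN_2D if ndim == 2 else _CONN_3D
    if connectivity not in allowed:
        raise ValueError(f"connectivity {connectivity} invalid for {ndim}D")
    if connectivity in (4, 6):
        offs = []
        for ax in range(ndim):
            for d in (-1, 1):
                o = [0] * ndim
                o[ax] = d
                offs.append(tuple(o))
        return offs
    return [o for o in product((-1, 0, 1), repeat=ndim) if any(o)]


def grow(
    img: np.ndarray,
    seeds: Sequence[tuple[int, ...]],
    threshold: float,
    params: GrowParams,
    bbox: BoundingBox | None = None,
) -> np.ndarray:
    """FIFO seeded region growing; returns a boolean mask over ``img``."""
    if not seeds:
        raise ValueError("seeds must be nonempty")
    if bbox is None:
        bbox = BoundingBox.full(img.shape)
    if bbox.ndim != img.ndim:
        raise ValueError("bounding box dimensionality must match the image")
    seeds = sorted(tuple(int(i) for i in s) for s in seeds)
    for s in seeds:
        if len(s) != img.ndim:
            raise ValueError(f"seed {s} has wrong dimensionality")
        if not bbox.contains(s):
            raise ValueError(f"seed {s} outside bounding box")
        if img[s] < threshold:
            raise ValueError(f"seed {s} has intensity {img[s]} below threshold {threshold}")

    offs = neighbor_offsets(img.ndim, params.connectivity)
    mask = np.zeros(img.shape, dtype=bool)
    imgf = img.astype(np.float64, copy=False)
    running = params.mean_mode == "running"
    total = 0.0
    count = 0
    queue: deque[tuple[int, ...]] = deque()
    for s in seeds:
        if not mask[s]:
            mask[s] = True
            total += imgf[s]
            count += 1
            queue.append(s)
    mean = total / count
    delta = params.delta
    while queue:
        x = queue.popleft()
        for o in offs:
            y = tuple(xi + oi for xi, oi in zip(x, o))
            if not bbox.contains(y) or mask[y]:
                continue
            v = imgf[y]
            if v < threshold or abs(v - mean) >= delta:
                continue
            mask[y] = True
            queue.append(y)
            if running:
                total += v
                count += 1
                mean = total / count
    return mask


def fill_holes(
    mask: np.ndarray, bbox: BoundingBox | None = None, warn_degenerate: bool = True
) -> np.ndarray:
    """Fill cavities enclosed by ``mask`` via inverse region growing.

    The background is flood-grown (pure connectivity, no intensity test) from
    every boundary voxel of ``bbox`` not in the mask; the complement of the
    grown background within the box is returned.  The background flood uses
    the minimal connectivity (4 in 2D, 6 in 3D), the conservative choice that
    cannot leak through diagonal gaps in the mask.  Output is a superset of
    the input and the operation is idempotent.
    """
    mask = np.asarray(mask, dtype=bool)
    if bbox is None:
        bbox = BoundingBox.full(mask.shape)
    out = mask.copy()
    sub = mask[bbox.slices()]
    if sub.sum() != mask.sum():
        raise ValueError("mask has voxels outside the bounding box")
    shape = sub.shape
    bg = np.zeros(shape, dtype=bool)
    queue: deque[tuple[int, ...]] = deque()
    # seed the background flood with every non-mask voxel on the box boundary
    for ax in range(sub.ndim):
        for face in (0, shape[ax] - 1):
            idx: list = [slice(None)] * sub.ndim
            idx[ax] = face
            face_sel = tuple(idx)
            face_bg = ~sub[face_sel] & ~bg[face_sel]
            for coord in zip(*np.nonzero(face_bg)):
                full = list(coord)
                full.insert(ax, face)
                pos = tuple(full)
                if not bg[pos]:
                    bg[pos] = True
                    queue.append(pos)
    if not queue:
        if warn_degenerate:
            logger.warning("mask covers the entire bounding-box boundary; returning the full box")
        out[bbox.slices()] = True
        return out
    offs = neighbor_offsets(sub.ndim, 4 if sub.ndim == 2 else 6)
    inner = BoundingBox.full(shape)
    while queue:
        x = queue.popleft()
        for o in offs:
            y = tuple(xi + oi for xi, oi in zip(x, o))
            if not inner.contains(y) or bg[y] or sub[y]:
                continue
            bg[y] = True
            queue.append(y)
    out[bbox.slices()] = ~bg
    return out


def scatter_seeds(
    seeds: Sequence[tuple[int, ...]], n_parts: int
) -> list[list[tuple[int, ...]]]:
    """Partition seeds into ``n_parts`` spatially interleaved groups.

    Seeds are sorted lexicographically by coordinate and dealt round-robin,
    so each group is spread across the volume — the layout that minimizes
    memory-write collisions when groups are grown concurrently.  The union of
    the groups is the input and groups are pairwise disjoint; with frozen-mean
    growing, growing the union of any such partition equals growing the full
    seed set (the determinism contract).
    """
    if n_parts < 1:
        raise ValueError("n_parts must be >= 1")
    ordered = sorted(tuple(int(i) for i in s) for s in seeds)
    parts: list[list[tuple[int, ...]]] = [[] for _ in range(n_parts)]
    for i, s in enumerate(ordered):
        parts[i % n_parts].append(s)
    return parts
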