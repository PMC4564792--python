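"""The core control loop: propagate per-tooth thresholds and shapes from a
reference axial slice outward in both z directions.

Per slice and per tooth the steps are: median-denoise the slice; derive
seeds from the previous mask (eroded by one pixel, kept where the slice
exceeds the previous T-value); find the working threshold by bisection under
the previous slice's area constraint, warm-started at the previous T; grow by
seeded region growing; fill enclosed pulp cavities; prune any region that
escaped the dilation of the previous mask (branch removal); then compare the
new area to the previous one and retry with an adjusted threshold on over- or
under-segmentation.  A tooth whose mask empties — past the root apex or the
crown tip, or outside the user's bounding box — is marked terminated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import dilation, disk, erosion

from .errors import ReferenceSegmentationError, ThresholdSearchError
from .phantom import histogram
from .region_grow import BoundingBox, GrowParams, fill_holes, grow
from .slice_state import ACTIVE, TERMINATED, SliceSegState, ToothSeedSet
from .threshold_search import ThresholdSearchParams, initial_t_value, optimal_slice_threshold
from .volume_io import LabelVolume, VolumeImage

logger = logging.getLogger(__name__)

__all__ = [
    "PropagationParams",
    "median_denoise",
    "remove_branches",
    "check_segmentation",
    "propagate_slice",
    "segment_teeth",
]

OK, OVER, UNDER = "ok", "over", "under"


@dataclass
class PropagationParams:
    """Knobs of the slice-to-slice loop.

    ``median_kernel``: odd width of the denoising median filter.
    ``dilation_radius``: pixels the previous mask is dilated by before branch
    pruning (2-5 px; 3 is the default middle of that range).
    ``size_change_max``: relative area change versus the previous slice that
    triggers an over-/under-segmentation retry.
    ``retry_t_step``: HU added (over) or subtracted (under) per retry;
    ``max_retries`` bounds the loop, after which the attempt whose area ratio
    was closest to 1 is accepted with a warning.
    """

    median_kernel: int = 3
    dilation_radius: int = 3
    size_change_max: float = 0.3
    max_retries: int = 5
    retry_t_step: float = 20.0

    def __post_init__(self) -> None:
        if self.median_kernel < 1 or self.median_kernel % 2 == 0:
            raise ValueError("median_kernel must be odd and >= 1")
        if not 2 <= self.dilation_radius <= 5:
            raise ValueError("dilation_radius must be within 2..5 pixels")
        if not 0 < self.size_change_max < 1:
            raise ValueError("size_change_max must be in (0, 1)")
        if self.max_retries < 1:
            raise ValueError("max_retries must be >= 1")
        if self.retry_t_step <= 0:
            raise ValueError("retry_t_step must be > 0")


def median_denoise(slice_img: np.ndarray, kernel: int) -> np.ndarray:
    """Median filter with reflecting edges; ``kernel`` must be odd (1 = identity)."""
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError("median kernel must be odd and >= 1")
    if kernel == 1:
        return slice_img.copy()
    return ndimage.median_filter(slice_img, size=kernel, mode="reflect")


def remove_branches(
    cur_mask: np.ndarray,
    prev_mask: np.ndarray,
    radius: int,
    seeds: list[tuple[int, int]],
) -> np.ndarray:
    """Prune regions that escaped the dilated previous-slice mask.

    The current mask is intersected with the previous mask dilated by
    ``radius`` pixels (disk footprint); of the resulting components, only
    those containing a propagated seed survive.  An empty result signals
    termination to the driver.
    """
    if radius < 1:
        raise ValueError("dilation radius must be >= 1 pixel")
    if not prev_mask.any():
        raise ValueError("prev_mask must be nonempty")
    allowed = cur_mask & dilation(prev_mask, disk(radius))
    if not allowed.any():
        return np.zeros_like(cur_mask, dtype=bool)
    labeled, _ = ndimage.label(allowed, structure=ndimage.generate_binary_structure(2, 1))
    keep = {int(labeled[s]) for s in seeds if allowed[s]}
    keep.discard(0)
    if not keep:
        return np.zeros_like(cur_mask, dtype=bool)
    return np.isin(labeled, list(keep))


def check_segmentation(
    cur_mask: np.ndarray, prev_mask: np.ndarray, size_change_max: float
) -> str:
    """Classify the area ratio r = area(cur)/area(prev) as ok/over/under."""
    prev_area = int(np.count_nonzero(prev_mask))
    if prev_area == 0:
        raise ValueError("prev_mask must be nonempty")
    r = np.count_nonzero(cur_mask) / prev_area
    if r > 1.0 + size_change_max:
        return OVER
    if r < 1.0 - size_change_max:
        return UNDER
    return OK


def _derive_seeds(
    pmask: np.ndarray, den: np.ndarray, prev_t: float
) -> list[tuple[int, int]]:
    """Seeds for the next slice: previous mask eroded by 1 px where the
    denoised slice still exceeds the previous T-value; fallback is the
    previous mask's centroid (erosion guards against boundary drift)."""
    eroded = erosion(pmask, disk(1))
    cand = eroded & (den >= prev_t)
    if cand.any():
        return [tuple(p) for p in np.argwhere(cand)]
    # fallback: the brightest previous-mask pixel.  (The mask centroid is a
    # poor fallback for annular cross-sections: it lands in the dark pulp.)
    masked = np.where(pmask, den, den.min() - 1)
    return [tuple(int(i) for i in np.unravel_index(np.argmax(masked), den.shape))]


def _segment_one_tooth(
    den: np.ndarray,
    pmask: np.ndarray,
    prev_t: float,
    params: PropagationParams,
    tparams: ThresholdSearchParams,
    gparams: GrowParams,
) -> tuple[np.ndarray, float, int, str]:
    """Steps (b)-(g) for one tooth on one (already denoised, cropped) slice.

    Returns (mask, t_value, retries, final_verdict); an empty mask means the
    tooth terminates here.
    """
    seeds = _derive_seeds(pmask, den, prev_t)
    try:
        t_cur = optimal_slice_threshold(den, pmask, prev_t, seeds, tparams)
    except ThresholdSearchError:
        return np.zeros_like(pmask, dtype=bool), prev_t, 0, UNDER

    empty = np.zeros_like(pmask, dtype=bool)
    best: tuple[float, np.ndarray, float] | None = None  # (|r-1|, mask, T)
    verdict = UNDER
    retries = 0
    for attempt in range(params.max_retries + 1):
        live = [s for s in seeds if den[s] >= t_cur]
        if live:
            m = grow(den, live, t_cur, gparams)
            m = fill_holes(m)
            m = remove_branches(m, pmask, params.dilation_radius, live)
        else:
            m = empty
        r = np.count_nonzero(m) / np.count_nonzero(pmask)
        verdict = check_segmentation(m, pmask, params.size_change_max) if m.any() else UNDER
        if best is None or abs(r - 1.0) < best[0]:
            best = (abs(r - 1.0), m, t_cur)
        if verdict == OK:
            return m, t_cur, retries, verdict
        step = params.retry_t_step if verdict == OVER else -params.retry_t_step
        t_next = float(np.clip(t_cur + step, tparams.t_min, tparams.t_max))
        if t_next == t_cur:
            break
        t_cur = t_next
        retries = attempt + 1
    assert best is not None
    logger.warning(
        "retry budget exhausted (%d tries); accepting attempt with area ratio "
        "closest to 1 (|r-1| = %.3f)",
        retries,
        best[0],
    )
    return best[1], best[2], retries, verdict


def propagate_slice(
    prev: SliceSegState,
    slice_img: np.ndarray,
    z: int,
    params: PropagationParams,
    tparams: ThresholdSearchParams,
    gparams: GrowParams,
    plane_bbox: BoundingBox | None = None,
    records: list[dict] | None = None,
) -> SliceSegState:
    """Propagate every active tooth from state ``prev`` onto slice ``z``.

    Teeth are processed independently; pixels claimed by more than one tooth
    are assigned to the tooth whose previous-slice mask is nearest (Euclidean
    distance transform, ties to the smaller tooth id).
    """
    if not prev.active_ids:
        raise ValueError("no active teeth to propagate")
    if plane_bbox is None:
        plane_bbox = BoundingBox.full(slice_img.shape)
    den = median_denoise(slice_img, params.median_kernel)

    masks: dict[int, np.ndarray] = {}
    t_values: dict[int, float] = {}
    status: dict[int, str] = {t: TERMINATED for t, s in prev.status.items() if s == TERMINATED}
    retries_by_tooth: dict[int, int] = {}
    verdicts: dict[int, str] = {}

    for tid in prev.active_ids:
        pmask = prev.masks[tid]
        dil = dilation(pmask, disk(params.dilation_radius))
        crop = BoundingBox.from_mask(dil, margin=2).intersect(plane_bbox)
        if crop is None:
            status[tid] = TERMINATED
            continue
        sl = crop.slices()
        pmask_c = pmask[sl]
        if not pmask_c.any():
            status[tid] = TERMINATED
            continue
        mask_c, t_val, retries, verdict = _segment_one_tooth(
            den[sl], pmask_c, prev.t_values[tid], params, tparams, gparams
        )
        if not mask_c.any():
            status[tid] = TERMINATED
            verdicts[tid] = verdict
            continue
        full = np.zeros(slice_img.shape, dtype=bool)
        full[sl] = mask_c
        masks[tid] = full
        t_values[tid] = t_val
        status[tid] = ACTIVE
        retries_by_tooth[tid] = retries
        verdicts[tid] = verdict

    _resolve_contested(masks, {t: prev.masks[t] for t in masks})
    for tid in list(masks):
        if not masks[tid].any():
            del masks[tid]
            del t_values[tid]
            status[tid] = TERMINATED

    if records is not None:
        for tid in sorted(status):
            records.append(
                {
                    "z": z,
                    "tooth": tid,
                    "t_value": t_values.get(tid),
                    "area": int(masks[tid].sum()) if tid in masks else 0,
                    "status": status[tid],
                    "retries": retries_by_tooth.get(tid, 0),
                    "verdict": verdicts.get(tid),
                }
            )
    return SliceSegState(z=z, masks=masks, t_values=t_values, status=status)


def _resolve_contested(
    masks: dict[int, np.ndarray], ref_masks: dict[int, np.ndarray]
) -> None:
    """Assign pixels claimed by several teeth to the nearest reference mask
    (the previous slice's masks, or the seed pixels on the reference slice).
    Ties go to the smaller tooth id.  Mutates ``masks`` in place."""
    if len(masks) < 2:
        return
    ids = sorted(masks)
    claims = np.zeros(next(iter(masks.values())).shape, dtype=np.int16)
    for tid in ids:
        claims += masks[tid]
    contested = claims > 1
    if not contested.any():
        return
    dist = np.stack(
        [ndimage.distance_transform_edt(~ref_masks[tid]) for tid in ids], axis=0
    )
    winner_idx = np.argmin(dist, axis=0)  # argmin takes the first = smallest id on ties
    for pos, tid in enumerate(ids):
        lose = contested & (winner_idx != pos)
        masks[tid] &= ~lose


def _reference_state(
    den: np.ndarray,
    seedset: ToothSeedSet,
    t0: float,
    gparams: GrowParams,
    plane_bbox: BoundingBox,
) -> SliceSegState:
    masks: dict[int, np.ndarray] = {}
    seed_masks: dict[int, np.ndarray] = {}
    for tid in seedset.tooth_ids:
        seeds = seedset.seeds[tid]
        for s in seeds:
            if den[s] < t0:
                raise ReferenceSegmentationError(
                    f"tooth {tid}: seed {s} has intensity {den[s]} below the "
                    f"initial T-value {t0}; re-seed on a clearer slice"
                )
        m = grow(den, seeds, t0, gparams, plane_bbox)
        m = fill_holes(m, BoundingBox.from_mask(m, margin=1))
        if not m.any():
            raise ReferenceSegmentationError(f"tooth {tid}: empty reference mask; re-seed")
        masks[tid] = m
        sm = np.zeros_like(m)
        for s in seeds:
            sm[s] = True
        seed_masks[tid] = sm
    _resolve_contested(masks, seed_masks)
    for tid in seedset.tooth_ids:
        if not masks[tid].any():
            raise ReferenceSegmentationError(
                f"tooth {tid}: reference mask vanished when resolving overlap; re-seed"
            )
    return SliceSegState(
        z=seedset.reference_slice,
        masks=masks,
        t_values={tid: float(t0) for tid in masks},
        status={tid: ACTIVE for tid in masks},
    )


def segment_teeth(
    vol: VolumeImage,
    seedset: ToothSeedSet,
    params: PropagationParams | None = None,
    tparams: ThresholdSearchParams | None = None,
    gparams: GrowParams | None = None,
    use_bone_premask: bool = False,
    records: list[dict] | None = None,
) -> LabelVolume:
    """Segment every seeded tooth by bidirectional slice propagation.

    The reference slice is segmented by growing from the user seeds at the
    histogram-derived initial T-value and filling holes; the resulting state
    then propagates independently toward +z and -z until every tooth
    terminates or the seed set's bounding box ends.  Deterministic for fixed
    inputs and parameters.

    With ``use_bone_premask`` voxels below ``tparams.bone_premask_hu``
    (default 1400 HU, the classical mandible extraction threshold) are
    suppressed before any per-slice work.
    """
    params = params or PropagationParams()
    gparams = gparams or GrowParams()
    nx, ny, nz = vol.shape
    if not 0 <= seedset.reference_slice < nz:
        raise ValueError(f"reference slice {seedset.reference_slice} outside volume")

    data = vol.data
    if tparams is None:
        t0 = initial_t_value(histogram(vol, bin_width=10.0))
        tparams = ThresholdSearchParams(t_min=t0)
    else:
        try:
            t0 = initial_t_value(histogram(vol, bin_width=10.0))
            t0 = float(np.clip(t0, tparams.t_min, tparams.t_max))
        except Exception:
            t0 = tparams.t_min
    if use_bone_premask:
        data = np.where(data >= tparams.bone_premask_hu, data, data.min())

    bbox = seedset.bbox
    plane_bbox = BoundingBox(
        (max(0, bbox.mins[0]), max(0, bbox.mins[1])),
        (min(nx, bbox.maxs[0]), min(ny, bbox.maxs[1])),
    )
    z_lo = max(0, bbox.mins[2])
    z_hi = min(nz, bbox.maxs[2])

    z_ref = seedset.reference_slice
    den_ref = median_denoise(data[:, :, z_ref], params.median_kernel)
    ref = _reference_state(den_ref, seedset, t0, gparams, plane_bbox)

    labels = np.zeros(vol.shape, dtype=np.int16)
    for tid, m in ref.masks.items():
        labels[:, :, z_ref][m] = tid

    for z_range in (range(z_ref + 1, z_hi), range(z_ref - 1, z_lo - 1, -1)):
        state = ref
        for z in z_range:
            if not state.active_ids:
                break
            state = propagate_slice(
                state, data[:, :, z], z, params, tparams, gparams, plane_bbox, records
            )
            for tid, m in state.masks.items():
                labels[:, :, z][m] = tid
    return LabelVolume(labels, vol.spacing, vol.origin)
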