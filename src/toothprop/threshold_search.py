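"""Threshold selection: histogram valley for the initial T-value, and the
per-slice optimal threshold found by bisection under the previous slice's
shape-area constraint.

The initial T-value separates the soft-tissue mode from the bone mode of the
volume histogram (teeth and alveolar bone share the bone mode, which is why a
single global threshold cannot split them).  Per slice, the working threshold
is the *greatest* T whose seed-connected thresholded component keeps at least
a ``(1 - area_tolerance)`` fraction of the previous slice's tooth area: the
greatest such T is the leak-safest choice, since any higher one would shrink
the tooth below tolerance and any lower one only admits more socket bone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage, signal

from .errors import DegenerateHistogramError, ThresholdSearchError

__all__ = [
    "Histogram",
    "ThresholdSearchParams",
    "initial_t_value",
    "seed_component_area",
    "optimal_slice_threshold",
]


@dataclass
class Histogram:
    """Intensity histogram: ``counts[i]`` covers ``[bin_edges[i], bin_edges[i+1])``."""

    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts)
        if len(self.counts) != len(self.bin_edges) - 1:
            raise ValueError("len(counts) must equal len(bin_edges) - 1")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class ThresholdSearchParams:
    """Bracket and tolerances for the per-slice threshold search.

    ``t_min``/``t_max`` bracket the search in HU; ``area_tolerance`` is the
    allowed relative shrinkage versus the previous slice's area;
    ``bisection_tol`` is the bracket width at termination (>= 1 HU on
    integer-valued CT); ``bone_premask_hu`` is the classical mandible
    extraction threshold, used only by the optional bone pre-mask.
    """

    t_min: float
    t_max: float = 3000.0
    area_tolerance: float = 0.10
    bisection_tol: float = 1.0
    bone_premask_hu: float = 1400.0
    overseg_factor: float = 2.0

    def __post_init__(self) -> None:
        if not self.t_min < self.t_max:
            raise ValueError(f"need t_min < t_max, got [{self.t_min}, {self.t_max}]")
        if not 0.0 < self.area_tolerance < 1.0:
            raise ValueError("area_tolerance must be in (0, 1)")
        if self.bisection_tol < 1.0:
            raise ValueError("bisection_tol must be >= 1 HU")
        if self.overseg_factor <= 1.0:
            raise ValueError("overseg_factor must be > 1")


def initial_t_value(h: Histogram, prominence_frac: float = 0.05) -> float:
    """Initial threshold from the deepest valley between tissue and bone modes.

    Peaks are detected with a prominence floor of ``prominence_frac`` times
    the tallest count.  When three or more peaks exist, the lowest-intensity
    one is taken as the dark background (air) and discarded; of the rest, the
    two most populated peaks are the tissue and bone modes.  The returned
    T-value is the center of the minimum-count bin strictly between them;
    ties are broken to the midpoint of the longest tied run of bins (the
    lowest-intensity run on equal length).

    Raises :class:`DegenerateHistogramError` when fewer than two candidate
    modes exist (caller must supply T manually).
    """
    counts = np.asarray(h.counts, dtype=float)
    # pad so peaks at the array ends (e.g. the air spike) are detected
    padded = np.concatenate([[0.0], counts, [0.0]])
    peaks, _ = signal.find_peaks(padded, prominence=prominence_frac * counts.max())
    peaks = np.asarray(peaks) - 1
    if len(peaks) >= 3:
        peaks = peaks[1:]  # drop the background (lowest-intensity) peak
    if len(peaks) < 2:
        raise DegenerateHistogramError(
            "histogram has fewer than two modes above background; supply T manually"
        )
    # the two dominant modes, kept in intensity order
    dominant = peaks[np.argsort(counts[peaks])[-2:]]
    lo, hi = int(dominant.min()), int(dominant.max())
    if hi - lo < 2:
        raise DegenerateHistogramError("dominant modes are adjacent; no valley between them")
    between = counts[lo + 1 : hi]
    cmin = between.min()
    tied = np.flatnonzero(between == cmin)
    # midpoint of the longest contiguous tied run
    runs: list[tuple[int, int]] = []
    start = tied[0]
    prev = tied[0]
    for idx in tied[1:]:
        if idx != prev + 1:
            runs.append((start, prev))
            start = idx
        prev = idx
    runs.append((start, prev))
    best = max(runs, key=lambda r: r[1] - r[0])
    valley = lo + 1 + (best[0] + best[1]) // 2
    return float(h.centers[valley])


def _structure(ndim: int, connectivity: int) -> np.ndarray:
    if ndim == 2:
        order = {4: 1, 8: 2}
    else:
        order = {6: 1, 26: 3}
    if connectivity not in order:
        raise ValueError(f"connectivity {connectivity} invalid for {ndim}D")
    return ndimage.generate_binary_structure(ndim, order[connectivity])


def seed_component_area(
    img: np.ndarray,
    seeds: Sequence[tuple[int, ...]],
    threshold: float,
    connectivity: int = 4,
    fill: bool = False,
) -> int:
    """Area of the thresholded connected component(s) containing the seeds.

    ``img >= threshold`` is labeled; the areas of all components holding at
    least one seed are summed.  With ``fill`` the components' enclosed
    cavities are counted too, so the measure is comparable to a mask whose
    pulp interior has been filled.  Non-increasing in ``threshold`` either
    way (hole filling preserves set inclusion).
    """
    fg = img >= threshold
    labeled, _ = ndimage.label(fg, structure=_structure(img.ndim, connectivity))
    ids = {int(labeled[tuple(s)]) for s in seeds}
    ids.discard(0)
    if not ids:
        return 0
    comp = np.isin(labeled, list(ids))
    if fill:
        from .region_grow import fill_holes

        # a component spanning the whole crop is routine while probing low
        # thresholds, not the degenerate case worth warning about
        comp = fill_holes(comp, warn_degenerate=False)
    return int(comp.sum())


def optimal_slice_threshold(
    slice_img: np.ndarray,
    prev_mask: np.ndarray,
    t_init: float,
    seeds: Sequence[tuple[int, int]],
    params: ThresholdSearchParams,
    connectivity: int = 4,
    fill: bool = True,
    anchor: str = "midband",
) -> float:
    """Per-slice threshold bracketed by the previous slice's tooth area.

    Let ``A(T)`` be the area of the seed-connected component of
    ``slice_img >= T``, with enclosed cavities counted when ``fill`` is set
    (the default: ``prev_mask`` comes out of hole filling, so the measure
    must fill too or teeth with pulp interiors would look too small the
    moment surrounding bone drops away).  ``A`` is non-increasing in ``T``,
    so two bisections over integer thresholds locate

    * ``t_high`` — the greatest ``T`` with ``A(T) >= (1 - tau) * prev``
      (keeping the shape and size of the previous slice), and
    * ``t_low``  — the least ``T`` with
      ``A(T) <= overseg_factor * prev`` (preventing oversegmentation: below
      this edge the component has merged into the surrounding socket bone,
      which multiplies its area, while legitimate slice-to-slice growth of
      the tooth itself stays far under the factor),

    with ``tau = params.area_tolerance``.  ``anchor="midband"`` (default)
    returns the midpoint of ``[t_low, t_high]``: on slices where tooth and
    socket intensities are separable, ``A`` plateaus at the true tooth area
    across that band and the midpoint sits safely inside it, so the tracked
    area follows the tooth rather than the constraint edge.
    ``anchor="greatest"`` returns ``t_high`` itself, the most erosion-prone
    but maximally leak-safe choice.  Both bisections are warm-started at
    ``t_init`` (the value carried over from the neighboring slice), which
    only shrinks the initial bracket — the result is independent of
    ``t_init``.

    Raises :class:`ThresholdSearchError` if no threshold in the bracket
    keeps ``A`` above the lower bound (the propagation driver treats this as
    tooth termination).
    """
    prev_area = int(np.count_nonzero(prev_mask))
    if prev_area == 0:
        raise ValueError("prev_mask must be nonempty")
    if not seeds:
        raise ValueError("seeds must be nonempty")
    if anchor not in ("midband", "greatest"):
        raise ValueError(f"anchor must be 'midband' or 'greatest', got {anchor!r}")
    lower = (1.0 - params.area_tolerance) * prev_area
    upper = params.overseg_factor * prev_area

    cache: dict[int, int] = {}

    def area(t: int) -> int:
        if t not in cache:
            cache[t] = seed_component_area(slice_img, seeds, t, connectivity, fill=fill)
        return cache[t]

    lo = int(np.ceil(params.t_min))
    hi = int(np.floor(params.t_max))
    t0 = int(round(min(max(t_init, lo), hi)))

    if area(lo) < lower:
        raise ThresholdSearchError(
            f"no threshold in [{lo}, {hi}] keeps the seed component above "
            f"{lower:.1f} px (previous area {prev_area})"
        )
    # greatest T with A(T) >= lower
    if area(hi) >= lower:
        t_high = hi
    else:
        a, b = lo, hi  # invariant: A(a) >= lower > A(b)
        if a < t0 < b:
            if area(t0) >= lower:
                a = t0
            else:
                b = t0
        while b - a > 1:
            mid = (a + b) // 2
            if area(mid) >= lower:
                a = mid
            else:
                b = mid
        t_high = a
    if anchor == "greatest":
        return float(t_high)
    # least T with A(T) <= upper
    if area(lo) <= upper:
        t_low = lo
    elif area(t_high) > upper:
        t_low = t_high + 1  # no non-oversegmenting T; keep-size bound wins
    else:
        a, b = lo, t_high  # invariant: A(a) > upper >= A(b)
        if a < t0 < b:
            if area(t0) <= upper:
                b = t0
            else:
                a = t0
        while b - a > 1:
            mid = (a + b) // 2
            if area(mid) <= upper:
                b = mid
            else:
                a = mid
        t_low = b
    if t_low > t_high:
        return float(t_high)
    return float((t_low + t_high) // 2)
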