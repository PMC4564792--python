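"""Segmentation error metrics and dataset-level reporting.

For an automatic mask A and a manual (reference) mask M, all in voxel
counts:

* false positive error   E_fp  = (|A| - |A∩M|) / |M| x 100
* false negative error   E_fn  = (|M| - |A∩M|) / |M| x 100
* volume error           E_vol = (|A| / |M| - 1) x 100
* similarity error       E_sim = (1 - 2|A∩M| / (|A| + |M|)) x 100

E_vol is signed (E_vol = E_fp - E_fn identically); tables report its
absolute value, the convention used when quoting a single accuracy number.
E_sim is the complement of the Dice index as a percentage, so it always lies
in [0, 100].  Metrics are computed per tooth, then aggregated as
mean ± sample standard deviation across teeth.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volume_io import LabelVolume

__all__ = [
    "ToothMetrics",
    "MetricsReport",
    "tooth_metrics",
    "compute_metrics",
    "evaluate_labels",
    "report_table",
]

_METRIC_COLS = ["e_fp", "e_fn", "e_vol_abs", "e_sim"]


@dataclass(frozen=True)
class ToothMetrics:
    """The four errors for a single tooth, in percent; ``e_vol`` is signed."""

    e_fp: float
    e_fn: float
    e_vol: float
    e_sim: float

    @property
    def e_vol_abs(self) -> float:
        return abs(self.e_vol)


def tooth_metrics(auto: np.ndarray, manual: np.ndarray) -> ToothMetrics:
    """Errors for one automatic/manual mask pair on the same grid."""
    if auto.shape != manual.shape:
        raise ValueError(f"mask shapes differ: {auto.shape} vs {manual.shape}")
    a = int(np.count_nonzero(auto))
    m = int(np.count_nonzero(manual))
    if m == 0:
        raise ValueError("manual mask is empty: metric denominators undefined")
    inter = int(np.count_nonzero(np.asarray(auto, bool) & np.asarray(manual, bool)))
    return ToothMetrics(
        e_fp=(a - inter) / m * 100.0,
        e_fn=(m - inter) / m * 100.0,
        e_vol=(a / m - 1.0) * 100.0,
        e_sim=(1.0 - 2.0 * inter / (a + m)) * 100.0,
    )


@dataclass
class MetricsReport:
    """Per-tooth errors plus mean ± sd aggregates across teeth."""

    per_tooth: dict[int, ToothMetrics]

    def __post_init__(self) -> None:
        if not self.per_tooth:
            raise ValueError("report needs at least one tooth")

    def _values(self, name: str) -> np.ndarray:
        return np.array([getattr(t, name) for t in self.per_tooth.values()], dtype=float)

    def mean(self, name: str) -> float:
        return float(self._values(name).mean())

    def sd(self, name: str) -> float:
        vals = self._values(name)
        return float(vals.std(ddof=1)) if len(vals) > 1 else 0.0

    def summary(self) -> dict[str, tuple[float, float]]:
        """``{metric: (mean, sd)}`` over teeth; e_vol is reported absolute,
        the signed mean is available as ``e_vol_signed``."""
        out = {name: (self.mean(name), self.sd(name)) for name in _METRIC_COLS}
        out["e_vol_signed"] = (self.mean("e_vol"), self.sd("e_vol"))
        return out


def compute_metrics(
    auto: dict[int, np.ndarray], manual: dict[int, np.ndarray]
) -> MetricsReport:
    """Per-tooth metrics for matching tooth ids.

    Every id present in ``manual`` is scored; an id missing from ``auto``
    counts as an empty automatic mask (100% false negative).
    """
    if not manual:
        raise ValueError("manual mask set is empty")
    per: dict[int, ToothMetrics] = {}
    for tid in sorted(manual):
        m = manual[tid]
        a = auto.get(tid, np.zeros_like(m, dtype=bool))
        per[tid] = tooth_metrics(a, m)
    return MetricsReport(per)


def evaluate_labels(pred: LabelVolume, truth: LabelVolume) -> MetricsReport:
    """Score a predicted label volume against ground truth, label by label."""
    if pred.shape != truth.shape:
        raise ValueError("label volumes must share a grid")
    return compute_metrics(
        {tid: pred.mask(tid) for tid in pred.labels()},
        {tid: truth.mask(tid) for tid in truth.labels()},
    )


def report_table(
    reports: list[MetricsReport], names: list[str] | None = None
) -> tuple[pd.DataFrame, str]:
    """Dataset-level table: one row of mean/sd per report plus a grand mean.

    Returns the numeric DataFrame (write with ``df.to_csv(...)``) and a
    human-readable text rendering with ``mean ± sd`` cells.
    """
    if not reports:
        raise ValueError("need at least one report")
    if names is None:
        names = [str(i + 1) for i in range(len(reports))]
    rows = []
    for name, rep in zip(names, reports):
        row: dict = {"dataset": name}
        for col in _METRIC_COLS:
            row[f"{col}_mean"] = rep.mean(col)
            row[f"{col}_sd"] = rep.sd(col)
        rows.append(row)
    grand: dict = {"dataset": "all"}
    for col in _METRIC_COLS:
        means = np.array([r[f"{col}_mean"] for r in rows], dtype=float)
        grand[f"{col}_mean"] = float(means.mean())
        grand[f"{col}_sd"] = float(means.std(ddof=1)) if len(means) > 1 else 0.0
    df = pd.DataFrame(rows + [grand])

    buf = io.StringIO()
    headers = ["dataset"] + [c.replace("_abs", "") + " (%)" for c in _METRIC_COLS]
    buf.write("  ".join(f"{h:>16s}" for h in headers) + "\n")
    for _, row in df.iterrows():
        cells = [f"{row['dataset']:>16s}"]
        for col in _METRIC_COLS:
            cells.append(f"{row[f'{col}_mean']:8.2f} ± {row[f'{col}_sd']:<5.2f}")
        buf.write("  ".join(cells) + "\n")
    return df, buf.getvalue()
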