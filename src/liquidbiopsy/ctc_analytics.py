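"""Cellular-fraction analytics: CTC enumeration and kinetics, SDOM
morphometry, and longitudinal variant (VAF) trajectories.

Enumeration converts raw cell detections into CTCs/ml using the analyzed
blood volume back-calculated from the slide's nucleated-cell count and the
patient's WBC concentration.  Every CTC-class cell counts individually —
members of a cluster are counted as cells, never as a single entity.
Positivity is >= 1 CTC/ml (inclusive); between-draw kinetics are stable
when the change is < 5 CTCs/ml in magnitude, otherwise increasing or
decreasing.

SDOM (standard deviation over the mean) expresses a cell's channel
intensity as a signed z-score against the nearest 50 background WBCs in the
frame.  Variant trajectories classify each hotspot mutation across draws as
persistent, acquired, lost, or transient from its presence pattern.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .synthetic_data import SlideTable

__all__ = [
    "CTCTimepoint",
    "KineticsLabel",
    "SdomResult",
    "VariantTrajectory",
    "DegenerateBackgroundError",
    "volume_analyzed",
    "enumerate_ctcs",
    "classify_kinetics",
    "sdom",
    "track_variants",
    "POSITIVITY_THRESHOLD",
    "STABILITY_THRESHOLD",
]

POSITIVITY_THRESHOLD = 1.0  # CTCs/ml; >= 1 is a positive sample
STABILITY_THRESHOLD = 5.0   # CTCs/ml; |change| < 5 is stable
SDOM_BACKGROUND_K = 50


class DegenerateBackgroundError(ValueError):
    """Raised when the background WBC intensities have zero spread."""


@dataclass(frozen=True)
class CTCTimepoint:
    draw_index: int
    day: float
    n_ctc: int
    volume_ml: float
    ctc_per_ml: float
    positive: bool


@dataclass(frozen=True)
class KineticsLabel:
    interval: tuple[int, int]
    delta: float
    label: str  # {"increasing", "decreasing", "stable"}


@dataclass(frozen=True)
class SdomResult:
    value: float
    n_background: int
    used_all_wbcs: bool  # True when fewer than k WBCs were available


@dataclass(frozen=True)
class VariantTrajectory:
    gene: str
    protein_change: str
    vaf_by_draw: Mapping[int, float]  # draw position -> VAF (%); absent draws omitted
    status: str  # {"persistent", "acquired", "lost", "transient"}
    monotone_increasing: bool

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene, self.protein_change)


def volume_analyzed(slide_nucleated_count: float, wbc_per_ml: float) -> float:
    """Blood volume (ml) actually analyzed on a slide:
    nucleated cells deposited / WBC concentration of the blood."""
    if slide_nucleated_count <= 0 or wbc_per_ml <= 0:
        raise ValueError("cell count and WBC concentration must be positive")
    return slide_nucleated_count / wbc_per_ml


def enumerate_ctcs(
    slide: SlideTable,
    wbc_per_ml: float,
    draw_index: int = 0,
    day: float = 0.0,
) -> CTCTimepoint:
    """Enumerate CTCs on a slide as a fractional CTCs/ml rate.

    Each CTC-class row is one cell; cluster members appear as individual
    rows and therefore each contribute 1 to the count.
    """
    volume = volume_analyzed(slide.slide_nucleated_count, wbc_per_ml)
    n_ctc = int((slide.cells["cell_class"] == "CTC").sum())
    rate = n_ctc / volume
    return CTCTimepoint(
        draw_index=draw_index,
        day=day,
        n_ctc=n_ctc,
        volume_ml=volume,
        ctc_per_ml=rate,
        positive=rate >= POSITIVITY_THRESHOLD,
    )


def classify_kinetics(
    series: Sequence[float],
    stability_threshold: float = STABILITY_THRESHOLD,
) -> list[KineticsLabel]:
    """Label each consecutive pair of CTCs/ml values.

    Stable when |change| < threshold (strict), increasing when change >=
    threshold, decreasing when change <= -threshold.
    """
    if len(series) < 2:
        raise ValueError("need at least two draws to classify kinetics")
    labels = []
    for i in range(len(series) - 1):
        delta = float(series[i + 1] - series[i])
        if abs(delta) < stability_threshold:
            label = "stable"
        elif delta > 0:
            label = "increasing"
        else:
            label = "decreasing"
        labels.append(KineticsLabel(interval=(i, i + 1), delta=delta, label=label))
    return labels


def sdom(
    cell_id: str,
    slide: SlideTable,
    channel: str,
    k: int = SDOM_BACKGROUND_K,
) -> SdomResult:
    """Signed background z-score of one cell's channel intensity.

    The background is the ``k`` WBCs nearest to the cell in frame
    coordinates (Euclidean distance, ties broken by cell_id); when fewer
    than ``k`` WBCs exist, all of them are used and the result is flagged.
    SDOM = (I_cell - mean(I_bg)) / sd(I_bg).
    """
    cells = slide.cells
    row = cells[cells["cell_id"] == cell_id]
    if len(row) != 1:
        raise KeyError(f"cell {cell_id!r} not found exactly once on slide")
    row = row.iloc[0]
    wbcs = cells[(cells["cell_class"] == "WBC") & (cells["cell_id"] != cell_id)]
    if len(wbcs) < 2:
        raise ValueError("need at least two background WBCs")
    dist = np.hypot(
        wbcs["frame_x"].to_numpy() - float(row["frame_x"]),
        wbcs["frame_y"].to_numpy() - float(row["frame_y"]),
    )
    order = np.lexsort((wbcs["cell_id"].to_numpy(), dist))
    used_all = len(wbcs) < k
    background = wbcs.iloc[order[: min(k, len(wbcs))]]
    bg = background[channel].to_numpy(dtype=float)
    sd = bg.std(ddof=1)
    if sd == 0:
        raise DegenerateBackgroundError("background intensities have zero SD")
    value = (float(row[channel]) - bg.mean()) / sd
    return SdomResult(value=value, n_background=len(bg), used_all_wbcs=used_all)


def track_variants(tables: Sequence[pd.DataFrame]) -> list[VariantTrajectory]:
    """Classify each variant's trajectory across an ordered sequence of
    per-draw VAF tables (columns: gene, protein_change, vaf_percent).

    Status from the presence pattern over the analyzed draws:
    present at both first and last draw -> persistent; absent first but
    present at the last -> acquired; present first but absent at the last
    -> lost; present only at interior draws -> transient.  "Absent" means
    not reported by the assay, never VAF 0.  A single draw makes every
    variant persistent by convention.  Output order and content are
    independent of row order within each table.
    """
    n_draws = len(tables)
    per_variant: dict[tuple[str, str], dict[int, float]] = {}
    for d, tab in enumerate(tables):
        if tab is None or len(tab) == 0:
            continue
        for _, r in tab.iterrows():
            key = (str(r["gene"]), str(r["protein_change"]))
            per_variant.setdefault(key, {})[d] = float(r["vaf_percent"])
    trajectories = []
    for key in sorted(per_variant):
        vafs = per_variant[key]
        present_first = 0 in vafs
        present_last = (n_draws - 1) in vafs
        if n_draws == 1:
            status = "persistent"
        elif present_first and present_last:
            status = "persistent"
        elif present_first:
            status = "lost"
        elif present_last:
            status = "acquired"
        else:
            status = "transient"
        ordered = [vafs[d] for d in sorted(vafs)]
        monotone = len(ordered) >= 2 and all(
            b > a for a, b in zip(ordered[:-1], ordered[1:])
        )
        trajectories.append(
            VariantTrajectory(
                gene=key[0],
                protein_change=key[1],
                vaf_by_draw=dict(sorted(vafs.items())),
                status=status,
                monotone_increasing=monotone,
            )
        )
    return trajectories
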