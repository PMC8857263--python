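"""Genomic-instability scoring and gain/loss alteration calls.

The genomic instability (GI) score summarises how far a copy-number profile
departs from flat diploid.  Working on the segmented per-bin values v, each
bin contributes

    tanh(3 * |ln RM_i| - 2) + tanh(2),        RM_i = v_i / median(v)

so a bin exactly at the median contributes 0, a complete one-copy loss
(RM = 1/2) contributes the same as a one-copy gain (RM = 2) because the log
is symmetric in RM and 1/RM, and the contribution saturates at 1 + tanh(2)
for extreme ratios.  Summed over the genome, a copy-neutral profile scores
near 0 (<= 30 in the neutral band), while a profile with a few chromosomal
breaks scores > 100 (aberrant band).

The natural log is used; the symmetry property holds in any base, a base
change only rescales what the constants 3 and 2 mean in ratio units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cna_pipeline import RATIO_FLOOR, SegmentedProfile

__all__ = [
    "GIScore",
    "AlterationCalls",
    "ratio_to_median",
    "gi_from_values",
    "gi_score",
    "classify_gi",
    "call_alterations",
]

NEUTRAL_MAX = 30.0    # GI <= 30: copy-neutral band
ABERRANT_MIN = 100.0  # GI > 100: aberrant band
GAIN_LIMIT = 1.25
LOSS_LIMIT = 0.75

_TANH2 = float(np.tanh(2.0))


@dataclass(frozen=True)
class GIScore:
    value: float
    n_bins: int
    band: str  # {"neutral", "intermediate", "aberrant"}


@dataclass(frozen=True)
class AlterationCalls:
    """Non-neutral segments of one sample: gains (mean >= upper limit) and
    losses (mean <= lower limit).  Neutral segments are not listed."""

    sample_id: str
    calls: pd.DataFrame  # chrom, start_bin, end_bin, direction, mean_ratio
    grid: object
    upper_limit: float = GAIN_LIMIT
    lower_limit: float = LOSS_LIMIT


def ratio_to_median(values: np.ndarray) -> np.ndarray:
    """RM_i = v_i / median(v); scale-invariant, median(RM) = 1."""
    v = np.asarray(values, dtype=float)
    if v.size == 0 or not np.any(v > 0):
        raise ValueError("need at least one positive value")
    med = float(np.median(v))
    if med <= 0:
        raise ValueError("median of values must be positive")
    return v / med


def gi_from_values(values: np.ndarray) -> float:
    """GI score of a per-bin value vector (RM recomputed internally, so the
    analyzed vector's median is exactly 1)."""
    rm = ratio_to_median(np.maximum(np.asarray(values, dtype=float), RATIO_FLOOR))
    contrib = np.tanh(3.0 * np.abs(np.log(rm)) - 2.0) + _TANH2
    return float(contrib.sum())


def gi_score(profile: SegmentedProfile) -> GIScore:
    """GI score of a segmented profile, computed on the segmented per-bin
    values (segmentation suppresses bin-level noise, which is what makes the
    neutral band <= 30 attainable on real-depth data)."""
    if profile.grid.n_bins == 0:
        raise ValueError("empty profile")
    value = gi_from_values(profile.per_bin_value)
    return GIScore(value=value, n_bins=profile.grid.n_bins, band=classify_gi(value))


def classify_gi(value: float) -> str:
    """Band of a GI score: neutral (<= 30, inclusive), aberrant (> 100,
    exclusive boundary at 100), intermediate otherwise."""
    if value < 0:
        raise ValueError("GI score cannot be negative")
    if value <= NEUTRAL_MAX:
        return "neutral"
    if value > ABERRANT_MIN:
        return "aberrant"
    return "intermediate"


def call_alterations(
    profile: SegmentedProfile,
    upper: float = GAIN_LIMIT,
    lower: float = LOSS_LIMIT,
) -> AlterationCalls:
    """Call one gain/loss per non-neutral segment.

    Boundaries are inclusive: a segment mean of exactly ``upper`` is a gain
    and exactly ``lower`` a loss.
    """
    if not lower < 1.0 < upper:
        raise ValueError("limits must satisfy lower < 1 < upper")
    rows = []
    for _, seg in profile.segments.iterrows():
        mean = float(seg["mean_ratio"])
        if mean >= upper:
            direction = "gain"
        elif mean <= lower:
            direction = "loss"
        else:
            continue
        rows.append(
            {"chrom": seg["chrom"], "start_bin": int(seg["start_bin"]),
             "end_bin": int(seg["end_bin"]), "direction": direction,
             "mean_ratio": mean}
        )
    calls = pd.DataFrame(
        rows, columns=["chrom", "start_bin", "end_bin", "direction", "mean_ratio"]
    )
    return AlterationCalls(
        sample_id=profile.sample_id, calls=calls, grid=profile.grid,
        upper_limit=upper, lower_limit=lower,
    )
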