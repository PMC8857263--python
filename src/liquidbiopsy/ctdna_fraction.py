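"""Tumor fraction of cfDNA estimated against a clonal CTC reference.

The read depth behind a copy-number alteration in cfDNA is proportional to
the tumor fraction f: over a reference segment with true ratio r_ref, the
cfDNA mixture sits at (1 - f) + f * r_ref, so

    f_s = (r_cf(s) - 1) / (r_ref(s) - 1)

recovers f from each informative segment s (one where the reference
deviates from diploid by at least the call limits).  The point estimate is
the median of the per-segment values clamped to [0, 1] — the median
tolerates a minority of outlier segments — with a bootstrap-over-segments
confidence interval.  Estimates below 5% are flagged as under the method's
confidence floor rather than suppressed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cna_pipeline import NormalizedProfile, SegmentedProfile
from .synthetic_data import CloneProfile

__all__ = [
    "TumorFractionEstimate",
    "NotEstimableError",
    "informative_segments",
    "estimate_tumor_fraction",
    "fraction_report",
    "CONFIDENCE_FLOOR",
]

CONFIDENCE_FLOOR = 0.05
MIN_DEVIATION = 0.25  # reference informativeness, aligned with 1.25/0.75 limits


class NotEstimableError(ValueError):
    """Raised when the reference carries no informative segment."""


@dataclass(frozen=True)
class TumorFractionEstimate:
    f_hat: float
    per_segment_f: pd.DataFrame  # chrom, start_bin, end_bin, ref_ratio, cf_ratio, f_s
    n_informative: int
    ci_low: float
    ci_high: float
    below_floor: bool
    sample_id: str = ""


def _reference_segments(reference) -> pd.DataFrame:
    """Segment table (chrom, start_bin, end_bin, mean_ratio) of a reference,
    whether it is a SegmentedProfile or a ground-truth CloneProfile."""
    if isinstance(reference, SegmentedProfile):
        return reference.segments[["chrom", "start_bin", "end_bin", "mean_ratio"]].copy()
    if isinstance(reference, CloneProfile):
        rows = []
        grid = reference.grid
        for c, chrom in enumerate(grid.chrom_names):
            sl = grid.chrom_slice(c)
            r = reference.true_ratio[sl]
            change = np.flatnonzero(np.diff(r) != 0) + 1
            edges = [0, *change.tolist(), len(r)]
            for a, b in zip(edges[:-1], edges[1:]):
                rows.append({"chrom": chrom, "start_bin": a, "end_bin": b,
                             "mean_ratio": float(r[a])})
        return pd.DataFrame(rows)
    raise TypeError("reference must be a SegmentedProfile or CloneProfile")


def informative_segments(reference, min_deviation: float = MIN_DEVIATION) -> pd.DataFrame:
    """Reference segments whose mean ratio deviates from 1 by at least
    ``min_deviation`` (default 0.25 — the gain/loss call limits)."""
    segs = _reference_segments(reference)
    keep = (segs["mean_ratio"] - 1.0).abs() >= min_deviation
    return segs[keep].reset_index(drop=True)


def _bin_values(profile) -> np.ndarray:
    if isinstance(profile, NormalizedProfile):
        return profile.ratio
    if isinstance(profile, SegmentedProfile):
        return profile.per_bin_value
    raise TypeError("cfDNA profile must be a NormalizedProfile or SegmentedProfile")


def estimate_tumor_fraction(
    cfdna,
    reference,
    n_boot: int = 200,
    seed: int = 0,
    min_deviation: float = MIN_DEVIATION,
) -> TumorFractionEstimate:
    """Estimate the cfDNA tumor fraction from a CTC-derived reference.

    ``cfdna`` may be a NormalizedProfile or SegmentedProfile; in both cases
    the cfDNA signal over each informative reference segment is the mean of
    the profile's bin-level values across that segment's bins, so the
    estimate does not depend on how (or whether) the cfDNA itself was
    segmented.  Neutral reference segments are non-informative by
    construction and never contribute.
    """
    grid = cfdna.grid
    ref_grid = reference.grid
    if grid != ref_grid:
        raise ValueError("cfDNA and reference must share one grid")
    segs = informative_segments(reference, min_deviation)
    if len(segs) == 0:
        raise NotEstimableError(
            "reference has no informative segments (all within "
            f"{min_deviation} of diploid)"
        )
    values = _bin_values(cfdna)
    rows = []
    for _, seg in segs.iterrows():
        sl = grid.chrom_slice(str(seg["chrom"]))
        a, b = int(seg["start_bin"]), int(seg["end_bin"])
        cf = float(values[sl.start + a: sl.start + b].mean())
        r_ref = float(seg["mean_ratio"])
        f_s = (cf - 1.0) / (r_ref - 1.0)
        rows.append({"chrom": seg["chrom"], "start_bin": a, "end_bin": b,
                     "ref_ratio": r_ref, "cf_ratio": cf, "f_s": f_s})
    per_segment = pd.DataFrame(rows)
    f_vals = per_segment["f_s"].to_numpy()
    f_hat = float(np.clip(np.median(f_vals), 0.0, 1.0))

    rng = np.random.default_rng(seed)
    boots = np.median(
        f_vals[rng.integers(0, len(f_vals), size=(n_boot, len(f_vals)))], axis=1
    )
    boots = np.clip(boots, 0.0, 1.0)
    ci_low, ci_high = (float(q) for q in np.percentile(boots, [2.5, 97.5]))
    return TumorFractionEstimate(
        f_hat=f_hat,
        per_segment_f=per_segment,
        n_informative=len(per_segment),
        ci_low=ci_low,
        ci_high=ci_high,
        below_floor=f_hat < CONFIDENCE_FLOOR,
        sample_id=getattr(cfdna, "sample_id", ""),
    )


def fraction_report(
    estimates: list[TumorFractionEstimate],
    draw_labels: list | None = None,
) -> pd.DataFrame:
    """Longitudinal tumor-fraction table: per-draw estimate, CI, confidence
    floor flag, and draw-over-draw change (blank for the first draw)."""
    if len(estimates) == 0:
        raise ValueError("need at least one estimate")
    labels = draw_labels if draw_labels is not None else list(range(1, len(estimates) + 1))
    rows = []
    prev = None
    for label, est in zip(labels, estimates):
        if isinstance(est, (int, float)):  # bare fractions are accepted too
            f_hat, ci_low, ci_high, n_inf = float(est), np.nan, np.nan, 0
            below = f_hat < CONFIDENCE_FLOOR
        else:
            f_hat, ci_low, ci_high = est.f_hat, est.ci_low, est.ci_high
            n_inf, below = est.n_informative, est.below_floor
        change = np.nan if prev is None else f_hat - prev
        rows.append(
            {"draw": label, "f_hat": f_hat, "ci_low": ci_low,
             "ci_high": ci_high, "n_informative": n_inf,
             "below_floor": below, "change": change}
        )
        prev = f_hat
    return pd.DataFrame(rows)
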