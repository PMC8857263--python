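"""From raw bin counts to a segmented genome-wide copy-ratio profile.

Normalization divides each bin count by the sample median, so a diploid
genome sits at ratio 1.0 regardless of sequencing depth.  Segmentation is a
circular-binary-segmentation (CBS) scheme: within each chromosome the
splitting statistic is the two-sample t on log2 ratios between every
candidate arc and its complement; the best split is kept when a permutation
test rejects homogeneity, and the procedure recurses into the pieces.  An
undo pass re-merges adjacent segments whose means differ by less than a
configurable multiple of the estimated per-bin noise SD, which suppresses
borderline false splits on flat chromosomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping

import numpy as np
import pandas as pd

from .grid import BinGrid
from .synthetic_data import RawBinCounts

__all__ = [
    "NormalizedProfile",
    "SegmentedProfile",
    "normalize_counts",
    "segment_profile",
    "write_seg",
    "read_seg",
]

RATIO_FLOOR = 1e-6  # zero-count bins are floored here before taking logs


@dataclass(frozen=True)
class NormalizedProfile:
    """Per-bin copy ratios normalized to the sample median."""

    grid: BinGrid
    ratio: np.ndarray
    sample_id: str
    analyte: str

    def __post_init__(self) -> None:
        ratio = np.asarray(self.ratio, dtype=float)
        if ratio.shape != (self.grid.n_bins,):
            raise ValueError("ratio length must equal grid.n_bins")
        if np.any(ratio < 0):
            raise ValueError("normalized ratios must be non-negative")
        object.__setattr__(self, "ratio", ratio)


@dataclass(frozen=True)
class SegmentedProfile:
    """Piecewise-constant copy-ratio profile.

    ``segments`` holds one row per segment (chrom, start_bin, end_bin,
    n_bins, mean_ratio) in chromosome-local half-open bin coordinates;
    ``per_bin_value`` assigns every bin its segment mean on the ratio scale.
    """

    grid: BinGrid
    segments: pd.DataFrame
    per_bin_value: np.ndarray
    sample_id: str
    analyte: str
    params: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        value = np.asarray(self.per_bin_value, dtype=float)
        if value.shape != (self.grid.n_bins,):
            raise ValueError("per_bin_value length must equal grid.n_bins")
        object.__setattr__(self, "per_bin_value", value)
        # segments must exactly partition each chromosome
        for c, chrom in enumerate(self.grid.chrom_names):
            sub = self.segments[self.segments["chrom"] == chrom]
            if len(sub) == 0:
                raise ValueError(f"no segments on {chrom}")
            starts = sub["start_bin"].to_numpy()
            ends = sub["end_bin"].to_numpy()
            if starts[0] != 0 or ends[-1] != self.grid.chrom_sizes[c]:
                raise ValueError(f"segments do not cover {chrom}")
            if np.any(starts[1:] != ends[:-1]):
                raise ValueError(f"segments not contiguous on {chrom}")
        if (self.segments["mean_ratio"] <= 0).any():
            raise ValueError("segment means must be positive")


# ----------------------------------------------------------------------
# normalization
# ----------------------------------------------------------------------
def normalize_counts(raw: RawBinCounts) -> NormalizedProfile:
    """Divide each bin count by the median over bins with nonzero counts.

    Scale-invariant: multiplying all counts by a constant leaves the output
    unchanged.  Raises on an all-zero input.
    """
    x = raw.counts.astype(float)
    positive = x[x > 0]
    if positive.size == 0:
        raise ValueError("cannot normalize an all-zero count vector")
    med = float(np.median(positive))
    return NormalizedProfile(
        grid=raw.grid, ratio=x / med, sample_id=raw.sample_id, analyte=raw.analyte
    )


# ----------------------------------------------------------------------
# CBS-style segmentation
# ----------------------------------------------------------------------
@lru_cache(maxsize=128)
def _arc_weights(n: int, min_width: int) -> np.ndarray:
    """Weight matrix w[i, j] = sqrt(n / (k (n - k))) for arc [i, j) of width
    k = j - i, with -inf where the width constraint fails.  Cached because a
    permutation test reuses it for every shuffle of the same segment."""
    idx = np.arange(n + 1)
    k = (idx[None, :] - idx[:, None]).astype(float)  # arc width
    valid = (k >= min_width) & ((n - k) >= min_width)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.sqrt(n / (k * (n - k)))
    w[~valid] = -np.inf
    return w


def _max_u(y: np.ndarray, min_width: int) -> tuple[int, int, float] | None:
    """Exhaustive arc search maximizing the between/within split statistic.

    For arc [i, j) versus its complement, the pooled-variance two-sample
    |t| on a fixed value multiset is a monotone function of

        u = |z_j - z_i| * sqrt(n / (k (n - k))),   z_m = S_m - m * mean(y)

    (z are centered partial sums; u^2 is the between-group sum of squares).
    Returns ``(i, j, u)`` or None when no arc satisfies the width
    constraints.  Ties resolve to the leftmost (smallest i, then smallest
    j) candidate via row-major argmax.
    """
    n = len(y)
    if n < 2 * min_width:
        return None
    w = _arc_weights(n, min_width)
    if not np.any(np.isfinite(w)):
        return None
    z = np.concatenate([[0.0], np.cumsum(y)])
    z -= np.arange(n + 1) * (z[-1] / n)
    with np.errstate(invalid="ignore"):
        u = np.abs(z[None, :] - z[:, None]) * w
    u[~np.isfinite(u)] = -np.inf  # invalid arcs (0 * -inf included)
    flat = int(np.argmax(u))  # row-major => smallest i, then smallest j
    i, j = divmod(flat, n + 1)
    if not np.isfinite(u[i, j]):
        return None
    return i, j, float(u[i, j])


def _u_to_t(u: float, sstot: float, n: int) -> float:
    """Convert the split statistic u to the pooled two-sample |t|:
    t^2 = u^2 (n - 2) / (sstot - u^2), sstot the total centered sum of
    squares of the segment."""
    u2 = min(u * u, sstot * (1.0 - 1e-12))
    denom = max(sstot - u2, 1e-24)
    return math.sqrt(u2 * max(n - 2, 1) / denom)


def _max_t_split(y: np.ndarray, min_width: int) -> tuple[int, int, float] | None:
    """Exhaustive max-|t| arc search (two-sample pooled t of arc versus
    complement); the test-facing wrapper around :func:`_max_u`."""
    res = _max_u(y, min_width)
    if res is None:
        return None
    i, j, u = res
    sstot = float(np.sum((y - y.mean()) ** 2))
    if sstot <= 0:
        return i, j, 0.0
    return i, j, _u_to_t(u, sstot, len(y))


def _perm_test(
    y: np.ndarray,
    u_obs: float,
    min_width: int,
    alpha: float,
    n_perm: int,
    rng: np.random.Generator,
) -> float:
    """Permutation p-value (+1 corrected) of the observed max split
    statistic, with sequential early stopping.

    Permuting a segment keeps its value multiset, hence its total sum of
    squares, so comparing the u statistics is equivalent to comparing the
    two-sample |t| values.  Stops early (a) rejecting the split once the
    exceedance count already forces the final p above alpha, or (b)
    accepting it once zero exceedances make the corrected p-estimate fall
    below alpha.  Both rules reproduce the full-``n_perm`` decision except
    for splits whose p sits exactly at the threshold.
    """
    count = 0
    done = 0
    block = 64
    y = y.copy()
    while done < n_perm:
        b = min(block, n_perm - done)
        for _ in range(b):
            rng.shuffle(y)
            res = _max_u(y, min_width)
            if res is not None and res[2] >= u_obs:
                count += 1
        done += b
        if count > alpha * n_perm:
            return (count + 1) / (done + 1)
        # accept early only once enough shuffles make a borderline p unlikely
        if count == 0 and done >= min(n_perm, 300) and (1.0 / (done + 1)) < alpha:
            return 1.0 / (done + 1)
    return (count + 1) / (n_perm + 1)


def _cbs_boundaries(
    y: np.ndarray,
    alpha: float,
    min_width: int,
    n_perm: int,
    rng: np.random.Generator,
) -> list[int]:
    """Recursive CBS on one chromosome's log2 ratios; returns interior
    boundary positions (sorted, exclusive of 0 and n)."""
    boundaries: set[int] = set()

    def recurse(lo: int, hi: int) -> None:
        seg = y[lo:hi]
        res = _max_u(seg, min_width)
        if res is None:
            return
        i, j, u_obs = res
        p = _perm_test(seg, u_obs, min_width, alpha, n_perm, rng)
        if p >= alpha:
            return
        cuts = [lo + i, lo + j]
        for c in cuts:
            if lo < c < hi:
                boundaries.add(c)
        pieces = sorted({lo, *[c for c in cuts if lo < c < hi], hi})
        for a, b in zip(pieces[:-1], pieces[1:]):
            recurse(a, b)

    recurse(0, len(y))
    return sorted(boundaries)


def _smooth_outliers(
    y: np.ndarray, sigma: float, region: int = 5,
    outlier_scale: float = 4.0, trim_scale: float = 2.0,
) -> np.ndarray:
    """Cap single-bin outliers toward their local median.

    Bins further than ``outlier_scale * sigma`` from the median of their
    ±``region`` neighborhood are pulled in to ``trim_scale * sigma`` from
    it.  This mirrors the outlier-smoothing step conventionally run before
    circular binary segmentation so that isolated extreme bins neither
    trigger spurious splits nor inflate segment variance.
    """
    if sigma <= 0 or len(y) < 2:
        return y
    padded = np.pad(y, region, mode="edge")
    windows = np.lib.stride_tricks.sliding_window_view(padded, 2 * region + 1)
    med = np.median(windows, axis=1)
    dev = y - med
    outliers = np.abs(dev) > outlier_scale * sigma
    out = y.copy()
    out[outliers] = med[outliers] + np.sign(dev[outliers]) * trim_scale * sigma
    return out


def _noise_sd(y: np.ndarray) -> float:
    """Robust per-bin noise SD from successive differences of log2 ratios."""
    d = np.diff(y)
    if d.size == 0:
        return 0.0
    return float(np.median(np.abs(d)) / (0.6744897501960817 * math.sqrt(2.0)))


def _undo_merge(y: np.ndarray, boundaries: list[int], threshold: float) -> list[int]:
    """Drop boundaries whose adjacent segment means differ by < threshold,
    smallest difference first, re-evaluating after each merge."""
    bounds = list(boundaries)
    while bounds:
        edges = [0, *bounds, len(y)]
        means = [y[a:b].mean() for a, b in zip(edges[:-1], edges[1:])]
        diffs = [abs(means[i + 1] - means[i]) for i in range(len(bounds))]
        worst = int(np.argmin(diffs))
        if diffs[worst] >= threshold:
            break
        bounds.pop(worst)
    return bounds


def segment_profile(
    norm: NormalizedProfile,
    alpha: float = 0.01,
    min_width: int = 20,
    n_perm: int = 1000,
    seed: int = 0,
    undo_sd: float = 1.0,
    smooth: bool = True,
) -> SegmentedProfile:
    """Segment a normalized profile chromosome by chromosome.

    Parameters
    ----------
    alpha
        Permutation significance level for accepting a split.
    min_width
        Minimum bins on each side of a candidate split; chromosomes shorter
        than ``2 * min_width`` become a single segment.
    n_perm
        Permutations per split test.
    undo_sd
        Re-merge adjacent segments whose log2 means differ by less than this
        multiple of the estimated per-bin noise SD; 0 disables the pass.
    smooth
        Cap single-bin outliers toward the local median before boundary
        detection.  Segment means are always computed from the unsmoothed
        ratios, so smoothing affects where boundaries fall, never the
        reported levels.
    """
    if min_width < 2:
        raise ValueError("min_width must be >= 2")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    ratio = np.maximum(norm.ratio, RATIO_FLOOR)
    log2r = np.log2(ratio)
    sd = _noise_sd(log2r)

    seg_rows: list[dict] = []
    per_bin = np.empty(norm.grid.n_bins)
    for c, chrom in enumerate(norm.grid.chrom_names):
        sl = norm.grid.chrom_slice(c)
        y = log2r[sl]
        if smooth:
            y = _smooth_outliers(y, sd)
        bounds = _cbs_boundaries(y, alpha, min_width, n_perm, rng)
        if undo_sd > 0 and sd > 0:
            bounds = _undo_merge(y, bounds, undo_sd * sd)
        edges = [0, *bounds, len(y)]
        for a, b in zip(edges[:-1], edges[1:]):
            mean_ratio = float(norm.ratio[sl.start + a: sl.start + b].mean())
            mean_ratio = max(mean_ratio, RATIO_FLOOR)
            seg_rows.append(
                {"chrom": chrom, "start_bin": a, "end_bin": b,
                 "n_bins": b - a, "mean_ratio": mean_ratio}
            )
            per_bin[sl.start + a: sl.start + b] = mean_ratio
    return SegmentedProfile(
        grid=norm.grid,
        segments=pd.DataFrame(seg_rows),
        per_bin_value=per_bin,
        sample_id=norm.sample_id,
        analyte=norm.analyte,
        params={"alpha": alpha, "min_width": min_width, "n_perm": n_perm,
                "seed": seed, "undo_sd": undo_sd, "smooth": smooth},
    )


# ----------------------------------------------------------------------
# SEG i/o
# ----------------------------------------------------------------------
def write_seg(profile: SegmentedProfile, path) -> None:
    """Write IGV SEG rows: sample, chrom, start, end, num_mark,
    seg_mean (log2 of the segment mean ratio, 6 decimals)."""
    rows = profile.segments.copy()
    rows.insert(0, "sample", profile.sample_id)
    rows["seg_mean"] = np.round(np.log2(rows.pop("mean_ratio")), 6)
    rows = rows.rename(
        columns={"start_bin": "loc.start", "end_bin": "loc.end", "n_bins": "num.mark"}
    )
    rows.to_csv(path, sep="\t", index=False)


def read_seg(path, grid: BinGrid, analyte: str = "single_cell") -> SegmentedProfile:
    """Read a SEG file written by :func:`write_seg` back onto ``grid``."""
    table = pd.read_csv(path, sep="\t")
    per_bin = np.empty(grid.n_bins)
    seg_rows = []
    for _, row in table.iterrows():
        chrom = str(row["chrom"])
        a, b = int(row["loc.start"]), int(row["loc.end"])
        mean_ratio = float(2.0 ** row["seg_mean"])
        sl = grid.chrom_slice(chrom)
        per_bin[sl.start + a: sl.start + b] = mean_ratio
        seg_rows.append(
            {"chrom": chrom, "start_bin": a, "end_bin": b,
             "n_bins": b - a, "mean_ratio": mean_ratio}
        )
    sample = str(table["sample"].iloc[0]) if len(table) else "sample"
    return SegmentedProfile(
        grid=grid,
        segments=pd.DataFrame(seg_rows),
        per_bin_value=per_bin,
        sample_id=sample,
        analyte=analyte,
    )
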