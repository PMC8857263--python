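"""Shared fixtures: small deterministic genomes and profile builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from liquidbiopsy import BinGrid, SegmentedProfile


@pytest.fixture
def small_grid() -> BinGrid:
    """Two chromosomes, 60 + 40 bins."""
    return BinGrid(chrom_names=("chr1", "chr2"), chrom_sizes=(60, 40))


def profile_from_segments(grid, segs, sample_id="s", analyte="single_cell"):
    """Build a SegmentedProfile from explicit (chrom, start, end, mean) rows."""
    per_bin = np.empty(grid.n_bins)
    rows = []
    for chrom, start, end, mean in segs:
        sl = grid.chrom_slice(chrom)
        per_bin[sl.start + start: sl.start + end] = mean
        rows.append({"chrom": chrom, "start_bin": start, "end_bin": end,
                     "n_bins": end - start, "mean_ratio": mean})
    return SegmentedProfile(
        grid=grid,
        segments=pd.DataFrame(rows),
        per_bin_value=per_bin,
        sample_id=sample_id,
        analyte=analyte,
    )


@pytest.fixture
def flat_profile(small_grid) -> SegmentedProfile:
    return profile_from_segments(
        small_grid, [("chr1", 0, 60, 1.0), ("chr2", 0, 40, 1.0)], sample_id="flat"
    )
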