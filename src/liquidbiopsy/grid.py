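"""Abstract genome partition used throughout the package.

The genome is modelled as an ordered set of chromosomes, each tiled by
contiguous unit-width bins in 0-based half-open coordinates.  All copy-number
work in this package happens on bins, not base pairs: per-bin read counts are
the primary observable and bin indices are the coordinate system for events,
segments and alteration calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["BinGrid"]


@dataclass(frozen=True)
class BinGrid:
    """An ordered partition of an abstract genome into per-chromosome bins.

    Parameters
    ----------
    chrom_names
        Chromosome labels, in genome order.
    chrom_sizes
        Number of bins in each chromosome; must be >= 1 each and the total
        must be >= 2.

    Bins are unit-width and restart at coordinate 0 within each chromosome,
    so bin ``k`` of a chromosome spans ``[k, k+1)``.
    """

    chrom_names: tuple[str, ...]
    chrom_sizes: tuple[int, ...]
    _offsets: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_sizes):
            raise ValueError("chrom_names and chrom_sizes length mismatch")
        if len(self.chrom_names) == 0:
            raise ValueError("grid needs at least one chromosome")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("duplicate chromosome names")
        if any(int(s) < 1 for s in self.chrom_sizes):
            raise ValueError("every chromosome needs at least one bin")
        if sum(self.chrom_sizes) < 2:
            raise ValueError("grid needs at least two bins in total")
        offsets = np.concatenate([[0], np.cumsum(self.chrom_sizes)])
        object.__setattr__(self, "_offsets", offsets)

    # ------------------------------------------------------------------
    @property
    def n_bins(self) -> int:
        return int(self._offsets[-1])

    @property
    def n_chromosomes(self) -> int:
        return len(self.chrom_names)

    def chrom_index(self, chrom: str) -> int:
        try:
            return self.chrom_names.index(chrom)
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def chrom_slice(self, chrom: str | int) -> slice:
        """Global-bin slice covering one chromosome."""
        c = chrom if isinstance(chrom, int) else self.chrom_index(chrom)
        return slice(int(self._offsets[c]), int(self._offsets[c + 1]))

    def global_bin(self, chrom: str | int, local_bin: int) -> int:
        c = chrom if isinstance(chrom, int) else self.chrom_index(chrom)
        size = self.chrom_sizes[c]
        if not 0 <= local_bin < size:
            raise IndexError(f"bin {local_bin} outside chromosome of {size} bins")
        return int(self._offsets[c]) + local_bin

    @property
    def bin_chrom_index(self) -> np.ndarray:
        """Per-bin chromosome index (length n_bins)."""
        return np.repeat(np.arange(self.n_chromosomes), self.chrom_sizes)

    @property
    def bin_start(self) -> np.ndarray:
        """Per-bin chromosome-local start coordinate (unit-width bins)."""
        return np.concatenate([np.arange(s) for s in self.chrom_sizes])

    def to_frame(self) -> pd.DataFrame:
        """Per-bin (chrom, start, end) table in 0-based half-open convention."""
        starts = self.bin_start
        return pd.DataFrame(
            {
                "chrom": np.array(self.chrom_names)[self.bin_chrom_index],
                "start": starts,
                "end": starts + 1,
            }
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinGrid):
            return NotImplemented
        return (
            self.chrom_names == other.chrom_names
            and self.chrom_sizes == other.chrom_sizes
        )

    def __hash__(self) -> int:
        return hash((self.chrom_names, self.chrom_sizes))
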