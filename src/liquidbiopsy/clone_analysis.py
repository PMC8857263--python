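"""Clonal CTC populations from per-cell alteration calls, and the
heatmap/dendrogram representation of multi-cell copy-number data.

Clonality follows the two-by-two rule: a clone is two or more cells that
share two or more genomic alterations.  "Sharing" an alteration is
operationalized as two same-direction calls with reciprocal bin overlap of
at least 50% (configurable); the clone relation is closed transitively, so
clones are connected components of the sharing graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .cna_pipeline import RATIO_FLOOR, SegmentedProfile
from .genomic_metrics import GAIN_LIMIT, LOSS_LIMIT, AlterationCalls

__all__ = [
    "CloneAssignment",
    "HeatmapMatrix",
    "shared_alterations",
    "assign_clones",
    "cluster_profiles",
    "heatmap_export",
    "read_heatmap_tsv",
]


@dataclass(frozen=True)
class CloneAssignment:
    cells: tuple[str, ...]
    clone_labels: tuple[str, ...]  # clone id or "unclonal", parallel to cells
    shared_counts: np.ndarray      # pairwise shared-alteration counts
    min_cells: int = 2
    min_shared: int = 2

    def members(self, clone: str) -> list[str]:
        return [c for c, l in zip(self.cells, self.clone_labels) if l == clone]

    @property
    def clones(self) -> list[str]:
        seen: list[str] = []
        for label in self.clone_labels:
            if label != "unclonal" and label not in seen:
                seen.append(label)
        return seen


@dataclass(frozen=True)
class HeatmapMatrix:
    """Tri-level (loss/neutral/gain) bin-by-cell matrix plus the Ward
    linkage tree that orders the columns."""

    codes: pd.DataFrame          # rows: bins in genome order; cols: cells in leaf order
    bin_table: pd.DataFrame      # chrom/start/end per row
    linkage: np.ndarray | None   # scipy linkage matrix (None for one column)
    column_meta: Mapping[str, Mapping[str, object]] = field(default_factory=dict)


def _call_spans(calls: AlterationCalls) -> pd.DataFrame:
    """Calls with global-bin start/end added, in genome order."""
    grid = calls.grid
    rows = calls.calls.copy()
    if len(rows) == 0:
        rows["gstart"] = pd.Series(dtype=int)
        rows["gend"] = pd.Series(dtype=int)
        return rows
    offsets = [grid.chrom_slice(c).start for c in rows["chrom"]]
    rows["gstart"] = np.asarray(offsets) + rows["start_bin"].to_numpy()
    rows["gend"] = np.asarray(offsets) + rows["end_bin"].to_numpy()
    return rows.sort_values(["gstart", "gend"], kind="stable").reset_index(drop=True)


def shared_alterations(
    a: AlterationCalls,
    b: AlterationCalls,
    min_reciprocal_overlap: float = 0.5,
) -> int:
    """Count alteration calls shared by two cells.

    A pair of calls matches when directions agree and the bin overlap is at
    least ``min_reciprocal_overlap`` of *both* call lengths.  Each call is
    matched at most once; candidate pairs are taken greedily by overlap
    size, ties resolved toward the leftmost pair.  Symmetric in (a, b).
    """
    if a.grid != b.grid:
        raise ValueError("calls must share one grid")
    ra, rb = _call_spans(a), _call_spans(b)
    candidates = []
    for i, ca in ra.iterrows():
        for j, cb in rb.iterrows():
            if ca["direction"] != cb["direction"]:
                continue
            ov = min(ca["gend"], cb["gend"]) - max(ca["gstart"], cb["gstart"])
            if ov <= 0:
                continue
            len_a = ca["gend"] - ca["gstart"]
            len_b = cb["gend"] - cb["gstart"]
            if ov / len_a >= min_reciprocal_overlap and ov / len_b >= min_reciprocal_overlap:
                candidates.append((-ov, min(ca["gstart"], cb["gstart"]), i, j))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    count = 0
    for _, _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        count += 1
    return count


def assign_clones(
    cells: Sequence[AlterationCalls],
    min_shared: int = 2,
    min_cells: int = 2,
    min_reciprocal_overlap: float = 0.5,
) -> CloneAssignment:
    """Partition cells into clones.

    Cells are joined by an edge when they share at least ``min_shared``
    alterations; clones are connected components with at least ``min_cells``
    members, every other cell is labeled "unclonal".  Clone ids are numbered
    by the input position of each component's first member, so the partition
    is deterministic given input order and reordering inputs permutes labels
    consistently.
    """
    n = len(cells)
    shared = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            s = shared_alterations(cells[i], cells[j], min_reciprocal_overlap)
            shared[i, j] = shared[j, i] = s
    adjacency = csr_matrix(shared >= min_shared) if n else csr_matrix((0, 0))
    if n:
        _, comp = connected_components(adjacency, directed=False)
    else:
        comp = np.zeros(0, dtype=int)
    labels = ["unclonal"] * n
    next_clone = 1
    for c in range(comp.max() + 1 if n else 0):
        members = np.flatnonzero(comp == c)
        if len(members) >= min_cells:
            label = f"clone_{next_clone}"
            next_clone += 1
            for m in members:
                labels[m] = label
    return CloneAssignment(
        cells=tuple(c.sample_id for c in cells),
        clone_labels=tuple(labels),
        shared_counts=shared,
        min_cells=min_cells,
        min_shared=min_shared,
    )


def cluster_profiles(
    profiles: Sequence[SegmentedProfile],
    upper: float = GAIN_LIMIT,
    lower: float = LOSS_LIMIT,
    column_meta: Mapping[str, Mapping[str, object]] | None = None,
) -> HeatmapMatrix:
    """Ward-linkage clustering of segmented profiles into a tri-level
    heatmap matrix.

    Distances are Euclidean between per-bin log2 segmented values; columns
    appear in dendrogram leaf order.  Inputs are sorted by sample_id first,
    so equal profiles order lexicographically and the result is independent
    of input order.
    """
    if len(profiles) == 0:
        raise ValueError("need at least one profile")
    grid = profiles[0].grid
    if any(p.grid != grid for p in profiles):
        raise ValueError("profiles must share one grid")
    profiles = sorted(profiles, key=lambda p: p.sample_id)
    values = np.vstack([
        np.log2(np.maximum(p.per_bin_value, RATIO_FLOOR)) for p in profiles
    ])
    if len(profiles) == 1:
        linkage = None
        order = [0]
    else:
        linkage = hierarchy.linkage(values, method="ward")
        order = hierarchy.leaves_list(linkage).tolist()
    codes = {}
    for idx in order:
        p = profiles[idx]
        v = p.per_bin_value
        code = np.where(v >= upper, "gain", np.where(v <= lower, "loss", "neutral"))
        codes[p.sample_id] = code
    return HeatmapMatrix(
        codes=pd.DataFrame(codes),
        bin_table=grid.to_frame(),
        linkage=linkage,
        column_meta=column_meta or {},
    )


def heatmap_export(
    matrix: HeatmapMatrix,
    tsv_path,
    png_path=None,
) -> None:
    """Write the tri-level matrix as TSV (bins as rows, cells as columns)
    and optionally render the white/red/blue raster with per-column draw or
    clone color keys."""
    out = pd.concat([matrix.bin_table.reset_index(drop=True), matrix.codes], axis=1)
    out.to_csv(tsv_path, sep="\t", index=False)
    if png_path is None:
        return

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    level = matrix.codes.apply(
        lambda col: col.map({"loss": -1, "neutral": 0, "gain": 1})
    ).to_numpy(dtype=float)
    fig, ax = plt.subplots(figsize=(max(4, 0.3 * level.shape[1] + 2), 8))
    ax.imshow(
        level,
        aspect="auto",
        interpolation="nearest",
        cmap=ListedColormap(["#2166ac", "#ffffff", "#b2182b"]),
        vmin=-1,
        vmax=1,
    )
    ax.set_xticks(range(level.shape[1]))
    labels = []
    for col in matrix.codes.columns:
        meta = matrix.column_meta.get(col, {})
        extra = "/".join(str(meta[k]) for k in ("draw", "clone") if k in meta)
        labels.append(f"{col}\n{extra}" if extra else col)
    ax.set_xticklabels(labels, rotation=90, fontsize=6)
    ax.set_ylabel("genome bins")
    fig.tight_layout()
    fig.savefig(png_path, dpi=120)
    plt.close(fig)


def read_heatmap_tsv(path) -> pd.DataFrame:
    """Read back the code columns of a heatmap TSV (drops bin coordinates)."""
    table = pd.read_csv(path, sep="\t")
    return table.drop(columns=["chrom", "start", "end"])
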