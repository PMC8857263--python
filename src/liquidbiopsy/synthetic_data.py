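"""Synthetic liquid-biopsy inputs: clone-structured genomes, noisy bin
counts, slide cell tables and longitudinal draw series.

Every generator is a pure function of its arguments and a seed, so any
downstream result is reproducible from the call that produced its inputs.
The simulated study mirrors a single-cell / cfDNA copy-number workflow:

* a genome partitioned into bins (default 5000 across 22 chromosomes);
* tumor clones defined by explicit copy-ratio event lists (1.0 = diploid,
  0.5 = one-copy loss, 1.5 = one-copy gain);
* single-cell read counts drawn per bin from a negative binomial whose mean
  is depth x true ratio — the heavy dispersion stands in for whole-genome
  amplification noise;
* cfDNA counts drawn from a (1-f)/f mixture of neutral background and clone
  profiles, f being the tumor fraction of the cell-free DNA;
* slide tables with per-cell fluorescence channel intensities against a
  white-blood-cell background;
* longitudinal draw series (CTC counts, WBC concentrations, variant tables)
  following bundled responder scenarios.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .grid import BinGrid

__all__ = [
    "BinGrid",
    "CloneProfile",
    "RawBinCounts",
    "SlideTable",
    "DrawSeries",
    "CHANNELS",
    "DRAW_TEMPLATES",
    "make_genome",
    "simulate_clone",
    "simulate_cell_counts",
    "simulate_cfdna_counts",
    "cfdna_expected_ratio",
    "simulate_slide",
    "simulate_draw_series",
    "write_bin_counts",
    "read_bin_counts",
    "write_slide_table",
    "read_slide_table",
    "write_draw_series",
    "read_draw_series",
]

CHANNELS = ("CK", "ER", "CD45", "DAPI")


# ----------------------------------------------------------------------
# domain types
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class CloneProfile:
    """Ground-truth per-bin copy ratio for one tumor clone.

    ``true_ratio`` is relative to diploid: 1.0 neutral, 0.5 one-copy loss,
    1.5 one-copy gain.  Bins outside the declared events are exactly 1.0.
    """

    grid: BinGrid
    true_ratio: np.ndarray
    clone_id: str
    events: tuple[tuple[str, int, int, float], ...] = ()

    def __post_init__(self) -> None:
        ratio = np.asarray(self.true_ratio, dtype=float)
        if ratio.shape != (self.grid.n_bins,):
            raise ValueError("true_ratio length must equal grid.n_bins")
        if not np.all(ratio > 0):
            raise ValueError("copy ratios must be positive")
        object.__setattr__(self, "true_ratio", ratio)


@dataclass(frozen=True)
class RawBinCounts:
    """Per-bin integer read counts for one sample (single cell or cfDNA)."""

    grid: BinGrid
    counts: np.ndarray
    sample_id: str
    analyte: str  # {"single_cell", "cfdna"}
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (self.grid.n_bins,):
            raise ValueError("counts length must equal grid.n_bins")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if counts.sum() <= 0:
            raise ValueError("total read count must be positive")
        if self.analyte not in ("single_cell", "cfdna"):
            raise ValueError("analyte must be 'single_cell' or 'cfdna'")
        object.__setattr__(self, "counts", counts.astype(np.int64))


@dataclass(frozen=True)
class SlideTable:
    """Feature table of all detected cells on one stained slide.

    ``cells`` has one row per detected cell: cell_id, cell_class (CTC/WBC),
    frame_x/frame_y coordinates, one intensity column per fluorescence
    channel, nuclear_area and nuclear_eccentricity.
    ``slide_nucleated_count`` is the total number of nucleated cells the
    assay deposited on the slide (used to back-calculate analyzed blood
    volume from the WBC concentration).
    """

    cells: pd.DataFrame
    slide_nucleated_count: int
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"cell_id", "cell_class", "frame_x", "frame_y",
                    "nuclear_area", "nuclear_eccentricity"}
        required |= set(CHANNELS)
        missing = required - set(self.cells.columns)
        if missing:
            raise ValueError(f"slide table missing columns: {sorted(missing)}")
        if not np.all(np.isfinite(self.cells[["frame_x", "frame_y"]].to_numpy())):
            raise ValueError("cell coordinates must be finite")
        if (self.cells[list(CHANNELS)].to_numpy() < 0).any():
            raise ValueError("channel intensities must be >= 0")
        ecc = self.cells["nuclear_eccentricity"].to_numpy()
        if np.any((ecc < 0) | (ecc >= 1)):
            raise ValueError("nuclear eccentricity must lie in [0, 1)")
        if self.slide_nucleated_count < len(self.cells):
            raise ValueError("slide_nucleated_count below number of detected cells")


@dataclass(frozen=True)
class DrawSeries:
    """Ordered longitudinal record of blood draws for one patient.

    ``draws`` has one row per draw: draw_index, day, n_ctc_detected,
    slide_nucleated_count, wbc_per_ml.  ``vaf_tables`` maps draw_index to a
    variant table (gene, protein_change, vaf_percent) for draws where
    mutational analysis was run.
    """

    patient_id: str
    draws: pd.DataFrame
    vaf_tables: Mapping[int, pd.DataFrame] = field(default_factory=dict)
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"draw_index", "day", "n_ctc_detected",
                    "slide_nucleated_count", "wbc_per_ml"}
        missing = required - set(self.draws.columns)
        if missing:
            raise ValueError(f"draw table missing columns: {sorted(missing)}")
        days = self.draws["day"].to_numpy()
        if len(days) and np.any(np.diff(days) <= 0):
            raise ValueError("draw days must be strictly increasing")
        if (self.draws["n_ctc_detected"] < 0).any():
            raise ValueError("CTC counts must be non-negative")

    @property
    def ctc_per_ml(self) -> np.ndarray:
        vol = self.draws["slide_nucleated_count"] / self.draws["wbc_per_ml"]
        return (self.draws["n_ctc_detected"] / vol).to_numpy(dtype=float)


# ----------------------------------------------------------------------
# generators
# ----------------------------------------------------------------------
def make_genome(n_bins: int, n_chromosomes: int, seed: int) -> BinGrid:
    """Draw a random genome partition with ``n_bins`` bins over
    ``n_chromosomes`` chromosomes.

    Chromosome sizes come from a Dirichlet-multinomial (concentration 5) so
    that, like a real karyotype, sizes vary around the mean and the largest
    chromosomes can hold arm-scale (hundreds of bins) events.  Sizes sum to
    exactly ``n_bins`` and every chromosome has at least one bin.
    """
    if n_chromosomes < 1:
        raise ValueError("need at least one chromosome")
    if n_bins < n_chromosomes:
        raise ValueError("n_bins must be >= n_chromosomes")
    if n_bins < 2:
        raise ValueError("need at least two bins")
    rng = np.random.default_rng(seed)
    probs = rng.dirichlet(np.full(n_chromosomes, 5.0))
    sizes = rng.multinomial(n_bins - n_chromosomes, probs) + 1
    names = tuple(f"chr{i + 1}" for i in range(n_chromosomes))
    return BinGrid(chrom_names=names, chrom_sizes=tuple(int(s) for s in sizes))


def simulate_clone(
    grid: BinGrid,
    events: Sequence[tuple[str, int, int, float]],
    clone_id: str = "clone",
) -> CloneProfile:
    """Build a clone's per-bin copy-ratio vector from an explicit event list.

    Each event is ``(chrom, start_bin, end_bin, ratio)`` with chromosome-local
    0-based half-open bin coordinates.  Later events overwrite earlier ones
    where they overlap; bins not covered by any event stay at 1.0.
    """
    ratio = np.ones(grid.n_bins, dtype=float)
    for chrom, start, end, r in events:
        c = grid.chrom_index(chrom)
        size = grid.chrom_sizes[c]
        if not (0 <= start < end <= size):
            raise ValueError(
                f"event [{start}, {end}) outside {chrom} ({size} bins)"
            )
        if r <= 0:
            raise ValueError("event ratio must be positive")
        sl = grid.chrom_slice(c)
        ratio[sl.start + start: sl.start + end] = r
    return CloneProfile(
        grid=grid,
        true_ratio=ratio,
        clone_id=clone_id,
        events=tuple((c, int(s), int(e), float(r)) for c, s, e, r in events),
    )


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draw with mean ``mean`` and size ``dispersion``
    (variance mean + mean^2/dispersion)."""
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def simulate_cell_counts(
    clone: CloneProfile,
    mean_depth: float,
    dispersion: float = 10.0,
    seed: int = 0,
    sample_id: str | None = None,
) -> RawBinCounts:
    """Sample single-cell bin counts: independent negative binomials with
    per-bin mean ``mean_depth * true_ratio``.

    The default dispersion of 10 is deliberately heavy-tailed to emulate
    whole-genome-amplification noise on single-cell libraries.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    rng = np.random.default_rng(seed)
    counts = _nb_counts(rng, mean_depth * clone.true_ratio, dispersion)
    return RawBinCounts(
        grid=clone.grid,
        counts=counts,
        sample_id=sample_id or f"{clone.clone_id}_cell_s{seed}",
        analyte="single_cell",
        meta={"seed": seed, "mean_depth": mean_depth, "dispersion": dispersion,
              "clone_id": clone.clone_id},
    )


def cfdna_expected_ratio(
    clones: Sequence[CloneProfile],
    weights: Sequence[float],
    tumor_fraction: float,
) -> np.ndarray:
    """Analytic per-bin expected copy ratio of a cfDNA mixture:
    ``(1 - f) * 1 + f * sum_c w_c * ratio_c``."""
    if not clones:
        raise ValueError("need at least one clone")
    grid = clones[0].grid
    if any(c.grid != grid for c in clones):
        raise ValueError("all clones must share one grid")
    w = np.asarray(weights, dtype=float)
    if w.shape != (len(clones),) or np.any(w < 0) or not math.isclose(w.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("weights must be a simplex over the clones")
    f = float(tumor_fraction)
    if not 0.0 <= f <= 1.0:
        raise ValueError("tumor_fraction must lie in [0, 1]")
    tumor = np.zeros(grid.n_bins)
    for wc, clone in zip(w, clones):
        tumor += wc * clone.true_ratio
    return (1.0 - f) + f * tumor


def simulate_cfdna_counts(
    clones: Sequence[CloneProfile],
    weights: Sequence[float],
    tumor_fraction: float,
    mean_depth: float = 100.0,
    dispersion: float = 50.0,
    seed: int = 0,
    sample_id: str | None = None,
) -> RawBinCounts:
    """Sample cfDNA bin counts from a neutral-background / tumor-clone
    mixture at tumor fraction ``tumor_fraction``.

    cfDNA libraries are less noisy than amplified single cells, hence the
    milder default dispersion of 50.
    """
    if mean_depth <= 0 or dispersion <= 0:
        raise ValueError("mean_depth and dispersion must be positive")
    expected = cfdna_expected_ratio(clones, weights, tumor_fraction)
    rng = np.random.default_rng(seed)
    counts = _nb_counts(rng, mean_depth * expected, dispersion)
    return RawBinCounts(
        grid=clones[0].grid,
        counts=counts,
        sample_id=sample_id or f"cfdna_f{tumor_fraction:g}_s{seed}",
        analyte="cfdna",
        meta={"seed": seed, "mean_depth": mean_depth, "dispersion": dispersion,
              "tumor_fraction": tumor_fraction},
    )


def simulate_slide(
    n_ctc: int,
    n_wbc: int,
    ctc_intensity_shift: float,
    bg_mean: float = 20.0,
    bg_sd: float = 4.0,
    seed: int = 0,
    frame_size: float = 2000.0,
    slide_nucleated_count: int | None = None,
) -> SlideTable:
    """Simulate a stained-slide feature table (no images).

    WBC channel intensities are Normal(bg_mean, bg_sd) truncated at zero.
    CTCs get ``ctc_intensity_shift`` added to their epithelial channels (CK
    and ER), so a shift of k*bg_sd puts their expected background z-score
    (SDOM) near k.  Coordinates are uniform on the square frame.
    """
    if n_wbc < 1:
        raise ValueError("need at least one WBC on the slide")
    if n_ctc < 0:
        raise ValueError("n_ctc must be non-negative")
    if bg_sd <= 0:
        raise ValueError("bg_sd must be positive")
    rng = np.random.default_rng(seed)
    n = n_ctc + n_wbc
    classes = np.array(["CTC"] * n_ctc + ["WBC"] * n_wbc)
    intensities = {
        ch: np.clip(rng.normal(bg_mean, bg_sd, size=n), 0.0, None)
        for ch in CHANNELS
    }
    for ch in ("CK", "ER"):
        intensities[ch][:n_ctc] += ctc_intensity_shift
        intensities[ch] = np.clip(intensities[ch], 0.0, None)
    area = np.where(
        classes == "CTC",
        rng.lognormal(mean=np.log(150.0), sigma=0.3, size=n),
        rng.lognormal(mean=np.log(50.0), sigma=0.2, size=n),
    )
    ecc = np.clip(rng.beta(2.0, 5.0, size=n), 0.0, 1.0 - 1e-9)
    cells = pd.DataFrame(
        {
            "cell_id": [f"cell_{i:05d}" for i in range(n)],
            "cell_class": classes,
            "frame_x": rng.uniform(0.0, frame_size, size=n),
            "frame_y": rng.uniform(0.0, frame_size, size=n),
            **{ch: intensities[ch] for ch in CHANNELS},
            "nuclear_area": area,
            "nuclear_eccentricity": ecc,
        }
    )
    return SlideTable(
        cells=cells,
        slide_nucleated_count=slide_nucleated_count or n,
        meta={"seed": seed, "ctc_intensity_shift": ctc_intensity_shift,
              "bg_mean": bg_mean, "bg_sd": bg_sd},
    )


# ----------------------------------------------------------------------
# longitudinal draw-series scenarios
# ----------------------------------------------------------------------
def _vaf(gene: str, change: str, vaf: float) -> dict[str, object]:
    return {"gene": gene, "protein_change": change, "vaf_percent": vaf}


#: Bundled responder scenarios.  Target CTCs/ml trajectories and variant
#: schedules are modelled on the study arcs this package emulates: a best
#: responder whose transient CTC spike clears to below 1.5 CTCs/ml, an
#: average responder fluctuating at low counts, and a poor responder with
#: monotonically rising counts who acquires new kinase-domain and TP53
#: variants at follow-up while losing one baseline ESR1 variant.
DRAW_TEMPLATES: dict[str, dict] = {
    "flat": {
        "days": [0, 60, 120],
        "ctc_per_ml": [0.0, 0.0, 0.0],
        "vafs": {},
    },
    "best_responder": {
        "days": [0, 28, 56, 84, 112, 150, 180, 210, 240, 270],
        "ctc_per_ml": [0.5, 1.0, 0.9, 80.0, 222.0, 0.0, 0.4, 1.0, 0.3, 1.2],
        "vafs": {
            0: [_vaf("TP53", "R213*", 0.08)],
            4: [_vaf("TP53", "R213*", 0.47)],
            8: [_vaf("TP53", "R213*", 2.91), _vaf("ERBB2", "S310F", 0.18)],
            9: [_vaf("TP53", "R213*", 4.5), _vaf("ERBB2", "S310F", 0.29)],
        },
    },
    "average_responder": {
        "days": [0, 60, 120, 180],
        "ctc_per_ml": [1.9, 2.5, 10.9, 1.0],
        "vafs": {
            1: [_vaf("ERBB2", "G776V", 1.94)],
            3: [_vaf("ERBB2", "G776V", 2.1)],
        },
    },
    "poor_responder": {
        "days": [15, 51, 100],
        "ctc_per_ml": [37.0, 52.0, 70.0],
        "vafs": {
            0: [
                _vaf("ESR1", "E380Q", 0.50),
                _vaf("ESR1", "Y537N", 0.33),
                _vaf("PIK3CA", "E545K", 2.7),
                _vaf("TP53", "R248Q", 0.31),
            ],
            1: [
                _vaf("ESR1", "E380Q", 0.07),
                _vaf("PIK3CA", "E545K", 30.0),
                _vaf("PIK3CA", "E726K", 0.09),
                _vaf("TP53", "R248Q", 0.19),
                _vaf("TP53", "G245D", 0.11),
                _vaf("ERBB2", "L755S", 0.13),
            ],
            2: [
                _vaf("ESR1", "E380Q", 0.05),
                _vaf("PIK3CA", "E545K", 42.0),
                _vaf("PIK3CA", "E726K", 0.30),
                _vaf("TP53", "R248Q", 0.25),
                _vaf("TP53", "G245D", 0.40),
                _vaf("ERBB2", "L755S", 1.2),
            ],
        },
    },
}


def simulate_draw_series(
    template: str,
    seed: int = 0,
    patient_id: str | None = None,
) -> DrawSeries:
    """Generate a longitudinal draw series from a bundled responder scenario.

    Draw-level nuisance quantities (WBC concentration, nucleated cells
    deposited per slide) are sampled around typical clinical values, CTC
    counts are chosen so the realized CTCs/ml track the template trajectory,
    and VAF tables follow the template's acquired/lost schedule with mild
    multiplicative noise.
    """
    if template not in DRAW_TEMPLATES:
        raise ValueError(
            f"unknown template {template!r}; available: {sorted(DRAW_TEMPLATES)}"
        )
    spec = DRAW_TEMPLATES[template]
    rng = np.random.default_rng(seed)
    days = list(spec["days"])
    targets = np.asarray(spec["ctc_per_ml"], dtype=float)
    n_draws = len(days)

    wbc_per_ml = np.clip(rng.normal(6e6, 5e5, size=n_draws), 3e6, None)
    nucleated = np.clip(rng.normal(3e6, 3e5, size=n_draws), 1e6, None).astype(np.int64)
    volume = nucleated / wbc_per_ml
    n_ctc = np.rint(targets * volume).astype(np.int64)

    if template == "poor_responder":
        # realized rate must stay monotone increasing despite count rounding
        for i in range(1, n_draws):
            while n_ctc[i] / volume[i] <= n_ctc[i - 1] / volume[i - 1]:
                n_ctc[i] += 1
    elif template == "best_responder":
        # cleared draws must realize below 1.5 CTCs/ml despite rounding
        for i in range(n_draws):
            if targets[i] < 1.5:
                cap = int(np.ceil(1.5 * volume[i])) - 1
                n_ctc[i] = min(n_ctc[i], max(cap, 0))

    draws = pd.DataFrame(
        {
            "draw_index": np.arange(n_draws),
            "day": days,
            "n_ctc_detected": n_ctc,
            "slide_nucleated_count": nucleated,
            "wbc_per_ml": wbc_per_ml,
        }
    )
    vaf_tables: dict[int, pd.DataFrame] = {}
    for draw_idx, rows in spec["vafs"].items():
        tab = pd.DataFrame(rows)
        noise = rng.lognormal(mean=0.0, sigma=0.05, size=len(tab))
        tab["vaf_percent"] = tab["vaf_percent"] * noise
        vaf_tables[draw_idx] = tab
    return DrawSeries(
        patient_id=patient_id or f"{template}_s{seed}",
        draws=draws,
        vaf_tables=vaf_tables,
        meta={"seed": seed, "template": template},
    )


# ----------------------------------------------------------------------
# plain-text writers / readers
# ----------------------------------------------------------------------
def _meta_header(meta: Mapping[str, object]) -> str:
    parts = " ".join(f"{k}={v}" for k, v in meta.items())
    return f"# liquidbiopsy {parts}".rstrip()


def _parse_meta(line: str) -> dict[str, str]:
    meta: dict[str, str] = {}
    if line.startswith("#"):
        for token in line.lstrip("#").split():
            if "=" in token:
                k, _, v = token.partition("=")
                meta[k] = v
    return meta


def write_bin_counts(raw: RawBinCounts, path) -> None:
    """Write per-bin counts as TSV (chrom, start, end, count) with a one-line
    '#' header carrying sample id, analyte and generator parameters."""
    table = raw.grid.to_frame()
    table["count"] = raw.counts
    meta = {"sample_id": raw.sample_id, "analyte": raw.analyte, **raw.meta}
    with open(path, "w") as fh:
        fh.write(_meta_header(meta) + "\n")
        table.to_csv(fh, sep="\t", index=False)


def read_bin_counts(path, grid: BinGrid | None = None) -> RawBinCounts:
    """Read a bin-count TSV written by :func:`write_bin_counts`.

    If ``grid`` is omitted it is reconstructed from the chrom/start/end
    columns (contiguous unit-width bins per chromosome).
    """
    with open(path) as fh:
        first = fh.readline()
        meta = _parse_meta(first)
        body = first if not first.startswith("#") else ""
        table = pd.read_csv(io.StringIO(body + fh.read()), sep="\t")
    if grid is None:
        names: list[str] = []
        sizes: list[int] = []
        for chrom, sub in table.groupby("chrom", sort=False):
            names.append(str(chrom))
            sizes.append(len(sub))
        grid = BinGrid(chrom_names=tuple(names), chrom_sizes=tuple(sizes))
    return RawBinCounts(
        grid=grid,
        counts=table["count"].to_numpy(),
        sample_id=meta.get("sample_id", "sample"),
        analyte=meta.get("analyte", "single_cell"),
        meta=meta,
    )


def write_slide_table(slide: SlideTable, path) -> None:
    meta = {"slide_nucleated_count": slide.slide_nucleated_count, **slide.meta}
    with open(path, "w") as fh:
        fh.write(_meta_header(meta) + "\n")
        slide.cells.to_csv(fh, sep="\t", index=False)


def read_slide_table(path) -> SlideTable:
    with open(path) as fh:
        meta = _parse_meta(fh.readline())
        cells = pd.read_csv(fh, sep="\t")
    return SlideTable(
        cells=cells,
        slide_nucleated_count=int(meta.get("slide_nucleated_count", len(cells))),
        meta=meta,
    )


def write_draw_series(series: DrawSeries, path, vaf_path=None) -> None:
    """Write the draw table as TSV; if ``vaf_path`` is given, write all VAF
    tables to it in long form (draw_index, gene, protein_change, vaf_percent)."""
    meta = {"patient_id": series.patient_id, **series.meta}
    with open(path, "w") as fh:
        fh.write(_meta_header(meta) + "\n")
        series.draws.to_csv(fh, sep="\t", index=False)
    if vaf_path is not None:
        rows = []
        for draw_idx in sorted(series.vaf_tables):
            tab = series.vaf_tables[draw_idx].copy()
            tab.insert(0, "draw_index", draw_idx)
            rows.append(tab)
        long = (
            pd.concat(rows, ignore_index=True)
            if rows
            else pd.DataFrame(columns=["draw_index", "gene", "protein_change", "vaf_percent"])
        )
        with open(vaf_path, "w") as fh:
            fh.write(_meta_header(meta) + "\n")
            long.to_csv(fh, sep="\t", index=False)


def read_draw_series(path, vaf_path=None) -> DrawSeries:
    with open(path) as fh:
        meta = _parse_meta(fh.readline())
        draws = pd.read_csv(fh, sep="\t")
    vaf_tables: dict[int, pd.DataFrame] = {}
    if vaf_path is not None:
        with open(vaf_path) as fh:
            fh.readline()
            long = pd.read_csv(fh, sep="\t")
        for draw_idx, sub in long.groupby("draw_index"):
            vaf_tables[int(draw_idx)] = sub.drop(columns="draw_index").reset_index(drop=True)
    return DrawSeries(
        patient_id=meta.get("patient_id", "patient"),
        draws=draws,
        vaf_tables=vaf_tables,
        meta=meta,
    )
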