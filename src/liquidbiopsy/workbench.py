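"""End-to-end reproducible runs: configuration, the simulation studies that
exercise the whole pipeline, and per-patient report bundles.

A run is fully determined by its :class:`RunConfig` (serializable to YAML),
whose seed drives every stochastic step.  The simulation study covers the
three method-level experiments the pipeline is designed around:

* copy-neutral profiles must score in the neutral GI band (<= 30);
* profiles with a few arm-scale single-copy events must score aberrant
  (> 100);
* the CTC-referenced tumor-fraction estimator must recover mixtures down to
  the method's 5% confidence floor.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .clone_analysis import cluster_profiles, heatmap_export
from .cna_pipeline import normalize_counts, segment_profile
from .ctc_analytics import classify_kinetics, track_variants, POSITIVITY_THRESHOLD
from .ctdna_fraction import estimate_tumor_fraction, fraction_report
from .genomic_metrics import ABERRANT_MIN, NEUTRAL_MAX, gi_score
from .synthetic_data import (
    CloneProfile,
    DrawSeries,
    make_genome,
    simulate_cell_counts,
    simulate_cfdna_counts,
    simulate_clone,
)

__all__ = [
    "RunConfig",
    "arm_scale_events",
    "neutral_gi_study",
    "aberrant_gi_study",
    "fraction_recovery_study",
    "detection_floor",
    "run_simulation_study",
    "generate_patient_report",
]


# ----------------------------------------------------------------------
# configuration
# ----------------------------------------------------------------------
@dataclass
class RunConfig:
    """Serializable configuration of a full simulation run.

    All clinically printed thresholds (1.25/0.75 call limits, 30/100 GI
    bands, 1 CTC/ml positivity, 5 CTCs/ml stability, 5% fraction floor,
    2-cells/2-alterations clonality) live here rather than in code.
    """

    seed: int = 0
    n_bins: int = 5000
    n_chromosomes: int = 22
    cell_depth: float = 50.0
    cell_dispersion: float = 10.0
    cfdna_depth: float = 100.0
    cfdna_dispersion: float = 50.0
    alpha: float = 0.01
    min_width: int = 20
    n_perm: int = 1000
    undo_sd: float = 1.0
    upper_limit: float = 1.25
    lower_limit: float = 0.75
    gi_neutral_max: float = NEUTRAL_MAX
    gi_aberrant_min: float = ABERRANT_MIN
    min_shared: int = 2
    min_cells: int = 2
    overlap: float = 0.5
    fraction_floor: float = 0.05
    n_boot: int = 200
    n_seeds: int = 20
    fraction_grid: tuple[float, ...] = (0.1, 0.3, 0.63)
    fraction_reps: int = 20
    outdir: str = "results"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fraction_grid"] = list(d["fraction_grid"])
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        if "fraction_grid" in data:
            data["fraction_grid"] = tuple(data["fraction_grid"])
        return cls(**data)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def segmentation_kwargs(self) -> dict:
        return {"alpha": self.alpha, "min_width": self.min_width,
                "n_perm": self.n_perm, "undo_sd": self.undo_sd}


def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    """n reproducible child seeds, each below 2**31."""
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


# ----------------------------------------------------------------------
# scenario builders
# ----------------------------------------------------------------------
def arm_scale_events(
    grid,
    ratios: tuple[float, ...],
    min_bins: int = 200,
) -> list[tuple[str, int, int, float]]:
    """One arm-scale event per ratio, placed on the largest chromosomes.

    Each event spans ``min_bins`` bins (or the whole chromosome when it is
    shorter) from the start of its chromosome, emulating whole-arm gains
    and losses.
    """
    order = np.argsort(grid.chrom_sizes)[::-1]
    if len(ratios) > grid.n_chromosomes:
        raise ValueError("more events than chromosomes")
    events = []
    for ratio, c in zip(ratios, order):
        size = grid.chrom_sizes[c]
        span = min(size, max(min_bins, size // 2))
        events.append((grid.chrom_names[c], 0, span, ratio))
    return events


def _gi_for_clone(clone: CloneProfile, depth, dispersion, seed, seg_kwargs) -> float:
    counts = simulate_cell_counts(clone, mean_depth=depth, dispersion=dispersion, seed=seed)
    seg = segment_profile(normalize_counts(counts), seed=seed, **seg_kwargs)
    return gi_score(seg).value


def neutral_gi_study(
    n_seeds: int = 20,
    seed: int = 0,
    n_bins: int = 5000,
    n_chromosomes: int = 22,
    depth: float = 50.0,
    dispersion: float = 10.0,
    **seg_kwargs,
) -> list[float]:
    """GI scores of ``n_seeds`` simulated copy-neutral single-cell profiles
    (normalized and segmented before scoring)."""
    values = []
    for s in _spawn_seeds(seed, n_seeds):
        s = int(s)
        grid = make_genome(n_bins, n_chromosomes, seed=s)
        clone = simulate_clone(grid, [], clone_id="neutral")
        values.append(_gi_for_clone(clone, depth, dispersion, s, seg_kwargs))
    return values


def aberrant_gi_study(
    n_seeds: int = 20,
    seed: int = 0,
    n_bins: int = 5000,
    n_chromosomes: int = 22,
    depth: float = 50.0,
    dispersion: float = 10.0,
    event_ratios: tuple[float, ...] = (0.5, 1.5),
    min_event_bins: int = 200,
    **seg_kwargs,
) -> list[float]:
    """GI scores of simulated single cells carrying arm-scale single-copy
    events (default: one >= 200-bin loss at ratio 0.5 and one gain at 1.5)."""
    values = []
    for s in _spawn_seeds(seed, n_seeds):
        s = int(s)
        grid = make_genome(n_bins, n_chromosomes, seed=s)
        events = arm_scale_events(grid, event_ratios, min_bins=min_event_bins)
        clone = simulate_clone(grid, events, clone_id="aberrant")
        values.append(_gi_for_clone(clone, depth, dispersion, s, seg_kwargs))
    return values


def fraction_recovery_study(
    f_values,
    n_reps: int = 20,
    seed: int = 0,
    n_bins: int = 5000,
    n_chromosomes: int = 22,
    depth: float = 100.0,
    dispersion: float = 50.0,
    n_events: int = 4,
    min_event_bins: int = 200,
) -> pd.DataFrame:
    """Recover known cfDNA tumor fractions against a fixed clonal reference.

    The reference clone carries ``n_events`` alternating arm-scale
    single-copy losses/gains; each replicate simulates a cfDNA mixture at
    tumor fraction f with negative-binomial counts, normalizes it, and runs
    the per-segment ratio / median-combiner estimator.  Returns a tidy
    table (f_true, rep, f_hat).
    """
    rng = np.random.default_rng(seed)
    grid = make_genome(n_bins, n_chromosomes, seed=int(rng.integers(0, 2**31 - 1)))
    ratios = tuple(0.5 if i % 2 == 0 else 1.5 for i in range(n_events))
    reference = simulate_clone(
        grid, arm_scale_events(grid, ratios, min_bins=min_event_bins), clone_id="reference"
    )
    rows = []
    for f in f_values:
        for rep in range(n_reps):
            s = int(rng.integers(0, 2**31 - 1))
            cfdna = simulate_cfdna_counts(
                [reference], [1.0], tumor_fraction=f,
                mean_depth=depth, dispersion=dispersion, seed=s,
            )
            est = estimate_tumor_fraction(normalize_counts(cfdna), reference, seed=s)
            rows.append({"f_true": f, "rep": rep, "f_hat": est.f_hat})
    return pd.DataFrame(rows)


def detection_floor(
    recovery: pd.DataFrame,
    truth_tol: float = 0.02,
    null_quantile: float = 0.95,
) -> float:
    """Smallest simulated tumor fraction reliably recovered.

    A fraction f counts as recovered when the median estimate across
    replicates lies within ``truth_tol`` of f *and* exceeds the
    ``null_quantile`` of the zero-fraction estimates.  Returns NaN when no
    tested fraction qualifies.  The table must include f_true == 0 rows.
    """
    null = recovery.loc[recovery["f_true"] == 0, "f_hat"]
    if len(null) == 0:
        raise ValueError("recovery table needs f_true == 0 replicates")
    threshold = float(null.quantile(null_quantile))
    for f in sorted(set(recovery["f_true"]) - {0}):
        med = float(recovery.loc[recovery["f_true"] == f, "f_hat"].median())
        if abs(med - f) <= truth_tol and med > threshold:
            return float(f)
    return float("nan")


# ----------------------------------------------------------------------
# full study + reports
# ----------------------------------------------------------------------
def run_simulation_study(config: RunConfig) -> tuple[pd.DataFrame, dict]:
    """Run the scenario grid defined by ``config`` and write a tidy results
    TSV plus a pass/fail summary against the configured GI bands and
    fraction floor.  Identical configs produce byte-identical outputs."""
    seg = config.segmentation_kwargs()
    common = dict(
        n_seeds=config.n_seeds, n_bins=config.n_bins,
        n_chromosomes=config.n_chromosomes,
        depth=config.cell_depth, dispersion=config.cell_dispersion,
    )
    neutral = neutral_gi_study(seed=config.seed, **common, **seg)
    aberrant = aberrant_gi_study(seed=config.seed + 1, **common, **seg)
    recovery = fraction_recovery_study(
        config.fraction_grid, n_reps=config.fraction_reps, seed=config.seed + 2,
        n_bins=config.n_bins, n_chromosomes=config.n_chromosomes,
        depth=config.cfdna_depth, dispersion=config.cfdna_dispersion,
    )

    rows = []
    for i, v in enumerate(neutral):
        rows.append({"scenario": "gi_neutral", "index": i, "truth": 0.0, "value": v})
    for i, v in enumerate(aberrant):
        rows.append({"scenario": "gi_aberrant", "index": i, "truth": np.nan, "value": v})
    for _, r in recovery.iterrows():
        rows.append({"scenario": "fraction_recovery", "index": int(r["rep"]),
                     "truth": r["f_true"], "value": r["f_hat"]})
    results = pd.DataFrame(rows)

    by_f = recovery.groupby("f_true")["f_hat"]
    recovery_summary = {
        float(f): {
            "median_f_hat": float(vals.median()),
            "bias": float(vals.mean() - f),
            "rmse": float(np.sqrt(((vals - f) ** 2).mean())),
        }
        for f, vals in by_f
    }
    summary = {
        "config_hash": config.hash(),
        "gi_neutral_max": float(np.max(neutral)),
        "gi_neutral_pass": bool(np.max(neutral) <= config.gi_neutral_max),
        "gi_aberrant_min": float(np.min(aberrant)),
        "gi_aberrant_pass": bool(np.min(aberrant) > config.gi_aberrant_min),
        "fraction_recovery": recovery_summary,
        "fraction_recovery_pass": bool(
            all(abs(v["median_f_hat"] - f) <= 0.05 for f, v in recovery_summary.items())
        ),
    }

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results.to_csv(outdir / "simulation_results.tsv", sep="\t", index=False,
                   float_format="%.6g")
    with open(outdir / "simulation_summary.yaml", "w") as fh:
        yaml.safe_dump(summary, fh, sort_keys=True)
    config.to_yaml(outdir / "config.yaml")
    return results, summary


def generate_patient_report(
    series: DrawSeries,
    outdir,
    profiles=None,
    fraction_estimates=None,
) -> dict:
    """Write a per-patient report bundle: CTCs/ml timeline with kinetics
    labels, variant trajectory table, and (when profiles / estimates are
    supplied) GI trajectory, heatmap matrix and fraction trajectory.

    Missing inputs are listed in the returned manifest; a partial report is
    still produced.  Regeneration is idempotent for all TSV outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    missing: list[str] = []

    rates = series.ctc_per_ml
    timeline = series.draws.copy()
    timeline["ctc_per_ml"] = rates
    timeline["positive"] = rates >= POSITIVITY_THRESHOLD
    kin = [""] + [k.label for k in classify_kinetics(rates)] if len(rates) >= 2 else [""] * len(rates)
    timeline["kinetics_vs_previous"] = kin
    timeline.to_csv(outdir / "timeline.tsv", sep="\t", index=False, float_format="%.6g")
    written.append("timeline.tsv")

    analyzed = sorted(series.vaf_tables)
    trajectories = track_variants([series.vaf_tables[d] for d in analyzed])
    var_rows = [
        {"gene": t.gene, "protein_change": t.protein_change, "status": t.status,
         "monotone_increasing": t.monotone_increasing,
         **{f"draw_{analyzed[i]}_vaf": t.vaf_by_draw.get(i, np.nan)
            for i in range(len(analyzed))}}
        for t in trajectories
    ]
    pd.DataFrame(var_rows).to_csv(outdir / "variants.tsv", sep="\t", index=False)
    written.append("variants.tsv")
    if not analyzed:
        missing.append("vaf_tables")

    if profiles:
        gi_rows = [
            {"sample_id": p.sample_id, "gi": gi_score(p).value, "band": gi_score(p).band}
            for p in profiles
        ]
        pd.DataFrame(gi_rows).to_csv(outdir / "gi_trajectory.tsv", sep="\t",
                                     index=False, float_format="%.6g")
        written.append("gi_trajectory.tsv")
        if len(profiles) >= 2:
            matrix = cluster_profiles(profiles)
            heatmap_export(matrix, outdir / "heatmap_matrix.tsv", outdir / "heatmap.png")
            written += ["heatmap_matrix.tsv", "heatmap.png"]
    else:
        missing.append("profiles")

    if fraction_estimates:
        fraction_report(fraction_estimates).to_csv(
            outdir / "fraction_trajectory.tsv", sep="\t", index=False,
            float_format="%.6g")
        written.append("fraction_trajectory.tsv")
    else:
        missing.append("fraction_estimates")

    manifest = {"patient_id": series.patient_id, "written": written, "missing": missing}
    with open(outdir / "report.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
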