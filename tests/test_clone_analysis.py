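"""Shared-alteration counting, clone assignment (vs a brute-force
component oracle), and heatmap clustering/export."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from liquidbiopsy import (
    BinGrid,
    assign_clones,
    cluster_profiles,
    heatmap_export,
    shared_alterations,
)
from liquidbiopsy.clone_analysis import read_heatmap_tsv
from liquidbiopsy.genomic_metrics import AlterationCalls
from conftest import profile_from_segments


GRID = BinGrid(("chr1", "chr2", "chr3"), (100, 80, 60))


def calls_from(sample_id, rows):
    """rows: (chrom, start, end, direction) with mean implied by direction."""
    table = pd.DataFrame(
        [{"chrom": c, "start_bin": s, "end_bin": e, "direction": d,
          "mean_ratio": 1.5 if d == "gain" else 0.5} for c, s, e, d in rows],
        columns=["chrom", "start_bin", "end_bin", "direction", "mean_ratio"],
    )
    return AlterationCalls(sample_id=sample_id, calls=table, grid=GRID)


# ----------------------------------------------------------------------
# brute-force oracles
# ----------------------------------------------------------------------
def oracle_max_matching(a_rows, b_rows, min_overlap=0.5):
    """Exhaustive maximum one-to-one matching of qualifying call pairs."""
    pairs = []
    for i, (ca, sa, ea, da) in enumerate(a_rows):
        for j, (cb, sb, eb, db) in enumerate(b_rows):
            if da != db or ca != cb:
                continue
            ov = min(ea, eb) - max(sa, sb)
            if ov > 0 and ov / (ea - sa) >= min_overlap and ov / (eb - sb) >= min_overlap:
                pairs.append((i, j))
    best = 0
    for r in range(len(pairs), 0, -1):
        for combo in itertools.combinations(pairs, r):
            if len({i for i, _ in combo}) == r and len({j for _, j in combo}) == r:
                return r
    return best


def oracle_components(n, edges):
    """Brute-force connected components via label propagation."""
    labels = list(range(n))
    changed = True
    while changed:
        changed = False
        for i, j in edges:
            lo = min(labels[i], labels[j])
            if labels[i] != lo or labels[j] != lo:
                labels[i] = labels[j] = lo
                changed = True
    return labels


class TestSharedAlterations:
    def test_identical_call_sets(self):
        rows = [("chr1", 0, 30, "gain"), ("chr2", 0, 40, "loss"), ("chr3", 10, 50, "gain")]
        a, b = calls_from("a", rows), calls_from("b", rows)
        assert shared_alterations(a, b) == 3

    def test_disjoint_regions_share_nothing(self):
        a = calls_from("a", [("chr1", 0, 30, "gain")])
        b = calls_from("b", [("chr1", 50, 80, "gain")])
        assert shared_alterations(a, b) == 0

    def test_direction_must_match(self):
        a = calls_from("a", [("chr1", 0, 30, "gain")])
        b = calls_from("b", [("chr1", 0, 30, "loss")])
        assert shared_alterations(a, b) == 0
        assert oracle_max_matching(
            [("chr1", 0, 30, "gain")], [("chr1", 0, 30, "loss")]
        ) == 0

    def test_reciprocal_overlap_threshold(self):
        # 30/60 = 50% of the longer call: inclusive boundary passes
        a = calls_from("a", [("chr1", 0, 60, "gain")])
        b = calls_from("b", [("chr1", 0, 30, "gain")])
        assert shared_alterations(a, b, min_reciprocal_overlap=0.5) == 1
        assert shared_alterations(a, b, min_reciprocal_overlap=0.6) == 0

    def test_symmetry_and_oracle_agreement_random_sets(self):
        rng = np.random.default_rng(13)
        for _ in range(25):
            def random_rows():
                rows = []
                for _ in range(rng.integers(0, 4)):
                    chrom = GRID.chrom_names[rng.integers(0, 3)]
                    size = GRID.chrom_sizes[GRID.chrom_index(chrom)]
                    s = int(rng.integers(0, size - 5))
                    e = int(rng.integers(s + 5, size + 1))
                    rows.append((chrom, s, e, "gain" if rng.random() < 0.5 else "loss"))
                return rows
            ra, rb = random_rows(), random_rows()
            a, b = calls_from("a", ra), calls_from("b", rb)
            assert shared_alterations(a, b) == shared_alterations(b, a)
            # greedy-by-overlap equals the exhaustive maximum matching on
            # these small instances
            assert shared_alterations(a, b) == oracle_max_matching(ra, rb)

    def test_mismatched_grids_rejected(self):
        other = AlterationCalls(
            sample_id="x",
            calls=calls_from("x", []).calls,
            grid=BinGrid(("chr1",), (50,)),
        )
        with pytest.raises(ValueError):
            shared_alterations(calls_from("a", []), other)


class TestAssignClones:
    def test_two_cells_sharing_two_alterations_form_clone(self):
        rows = [("chr1", 0, 40, "gain"), ("chr2", 0, 40, "loss")]
        result = assign_clones([calls_from("a", rows), calls_from("b", rows)])
        assert result.clone_labels == ("clone_1", "clone_1")

    def test_single_shared_alteration_insufficient(self):
        a = calls_from("a", [("chr1", 0, 40, "gain"), ("chr2", 0, 40, "loss")])
        b = calls_from("b", [("chr1", 0, 40, "gain"), ("chr3", 0, 40, "loss")])
        result = assign_clones([a, b])
        assert result.clone_labels == ("unclonal", "unclonal")

    def test_transitive_closure_chains_cells(self):
        # A-B share 2, B-C share 2, A-C share 0 -> one clone {A, B, C}
        a = calls_from("a", [("chr1", 0, 40, "gain"), ("chr1", 60, 100, "loss")])
        b = calls_from("b", [("chr1", 0, 40, "gain"), ("chr1", 60, 100, "loss"),
                             ("chr2", 0, 40, "gain"), ("chr2", 40, 80, "loss")])
        c = calls_from("c", [("chr2", 0, 40, "gain"), ("chr2", 40, 80, "loss")])
        result = assign_clones([a, b, c])
        assert shared_alterations(a, c) == 0
        assert set(result.clone_labels) == {"clone_1"}

    def test_matches_bruteforce_components_on_random_instances(self):
        rng = np.random.default_rng(99)
        for _ in range(10):
            n = int(rng.integers(2, 9))
            cells = []
            for i in range(n):
                rows = []
                for _ in range(rng.integers(0, 4)):
                    chrom = GRID.chrom_names[rng.integers(0, 3)]
                    size = GRID.chrom_sizes[GRID.chrom_index(chrom)]
                    s = int(rng.integers(0, size - 20))
                    rows.append((chrom, s, s + 20, "gain" if rng.random() < 0.5 else "loss"))
                cells.append(calls_from(f"c{i}", rows))
            result = assign_clones(cells)
            edges = [
                (i, j)
                for i in range(n) for j in range(i + 1, n)
                if shared_alterations(cells[i], cells[j]) >= 2
            ]
            labels = oracle_components(n, edges)
            # same partition restricted to clones of size >= 2
            for i in range(n):
                for j in range(i + 1, n):
                    together = (
                        result.clone_labels[i] == result.clone_labels[j]
                        and result.clone_labels[i] != "unclonal"
                    )
                    oracle_together = labels[i] == labels[j] and sum(
                        1 for l in labels if l == labels[i]
                    ) >= 2
                    assert together == oracle_together

    def test_permutation_invariance_of_partition(self):
        rows1 = [("chr1", 0, 40, "gain"), ("chr2", 0, 40, "loss")]
        rows2 = [("chr3", 0, 40, "gain"), ("chr1", 60, 100, "loss")]
        cells = [calls_from("a", rows1), calls_from("b", rows1),
                 calls_from("c", rows2), calls_from("d", rows2)]
        forward = assign_clones(cells)
        backward = assign_clones(cells[::-1])
        def partition(assignment):
            groups = {}
            for cell, label in zip(assignment.cells, assignment.clone_labels):
                groups.setdefault(label, set()).add(cell)
            return {frozenset(v) for k, v in groups.items() if k != "unclonal"}
        assert partition(forward) == partition(backward)

    def test_empty_and_single_inputs(self):
        empty = assign_clones([])
        assert empty.cells == ()
        single = assign_clones([calls_from("a", [("chr1", 0, 40, "gain")])])
        assert single.clone_labels == ("unclonal",)


class TestClusterProfiles:
    def _profile(self, sample_id, gain_span=None):
        segs = []
        for chrom, size in zip(GRID.chrom_names, GRID.chrom_sizes):
            segs.append((chrom, 0, size, 1.0))
        profile = profile_from_segments(GRID, segs, sample_id=sample_id)
        if gain_span:
            chrom, s, e = gain_span
            segs = [(chrom, 0, s, 1.0), (chrom, s, e, 1.6)]
            size = GRID.chrom_sizes[GRID.chrom_index(chrom)]
            if e < size:
                segs.append((chrom, e, size, 1.0))
            segs += [(c, 0, sz, 1.0) for c, sz in zip(GRID.chrom_names, GRID.chrom_sizes)
                     if c != chrom]
            profile = profile_from_segments(GRID, segs, sample_id=sample_id)
        return profile

    def test_duplicate_profiles_merge_at_distance_zero(self):
        profiles = [self._profile("a"), self._profile("b")]
        matrix = cluster_profiles(profiles)
        assert matrix.linkage[0, 2] == pytest.approx(0.0)

    def test_planted_groups_separate_at_first_split(self):
        group1 = [self._profile(f"g1_{i}", ("chr1", 0, 60)) for i in range(5)]
        group2 = [self._profile(f"g2_{i}", ("chr2", 0, 60)) for i in range(5)]
        matrix = cluster_profiles(group1 + group2)
        from scipy.cluster.hierarchy import fcluster
        top = fcluster(matrix.linkage, t=2, criterion="maxclust")
        # columns are in leaf order; map back to sample ids
        cols = list(matrix.codes.columns)
        split = {c: t for c, t in zip(sorted(cols), top)}
        g1_labels = {split[c] for c in cols if c.startswith("g1")}
        g2_labels = {split[c] for c in cols if c.startswith("g2")}
        assert len(g1_labels) == 1 and len(g2_labels) == 1 and g1_labels != g2_labels

    def test_column_count_matches_inputs(self):
        profiles = [self._profile(f"p{i}") for i in range(4)]
        assert cluster_profiles(profiles).codes.shape[1] == 4

    def test_single_profile_has_no_tree(self):
        matrix = cluster_profiles([self._profile("only")])
        assert matrix.linkage is None
        assert matrix.codes.shape[1] == 1


class TestHeatmapExport:
    def test_all_neutral_export(self, tmp_path):
        profiles = [
            profile_from_segments(GRID, [(c, 0, s, 1.0) for c, s in
                                         zip(GRID.chrom_names, GRID.chrom_sizes)],
                                  sample_id=f"p{i}")
            for i in range(2)
        ]
        matrix = cluster_profiles(profiles)
        tsv, png = tmp_path / "m.tsv", tmp_path / "m.png"
        heatmap_export(matrix, tsv, png)
        codes = read_heatmap_tsv(tsv)
        assert (codes.to_numpy() == "neutral").all()
        assert png.exists() and png.stat().st_size > 0

    def test_tsv_round_trip_and_gain_rows(self, tmp_path):
        segs = [("chr1", 0, 30, 1.5), ("chr1", 30, 100, 1.0),
                ("chr2", 0, 80, 1.0), ("chr3", 0, 60, 1.0)]
        p1 = profile_from_segments(GRID, segs, sample_id="a")
        p2 = profile_from_segments(GRID, segs, sample_id="b")
        matrix = cluster_profiles([p1, p2])
        tsv = tmp_path / "m.tsv"
        heatmap_export(matrix, tsv)
        codes = read_heatmap_tsv(tsv)
        pd.testing.assert_frame_equal(codes, matrix.codes)
        # the gain occupies exactly its 30 bin rows in column a
        assert (codes["a"][:30] == "gain").all()
        assert (codes["a"][30:] == "neutral").all()
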