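import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from conftest import make_norm
from hepazone.geometry import build_geometry, hex_full_lattice, ring_neighbors
from hepazone.zonation import (
    RING_CLASSES,
    Tertile,
    ZoneConfig,
    assign_tertiles,
    normalize_profile_rows,
    ring_membership,
    select_top_range,
    wilcoxon_rank_sum,
    zonation_profile,
    zone_volcano,
)


def marker_norm(alb, cyp, extra_genes=0):
    alb = np.asarray(alb, dtype=float)
    values = np.column_stack([alb, np.asarray(cyp, dtype=float)])
    if extra_genes:
        values = np.column_stack([values, np.zeros((len(alb), extra_genes))])
    gene_ids = ["Alb", "Cyp2e1"] + [f"g{i}" for i in range(extra_genes)]
    return make_norm(values, gene_ids=gene_ids)


class TestAssignTertiles:
    def test_anticorrelated_markers(self):
        norm = marker_norm(np.arange(9, 0, -1), np.arange(1, 10))
        labels = assign_tertiles(norm, ZoneConfig())
        assert list(labels[:3]) == [Tertile.ALB_HIGH.value] * 3
        assert list(labels[-3:]) == [Tertile.CYP_HIGH.value] * 3
        assert list(labels[3:6]) == [Tertile.INTERMEDIATE.value] * 3

    def test_full_ties_deterministic_split(self):
        # all spots conflict; greedy hands s1..s3 to the portal class,
        # the central class backfills with s4..s6
        norm = marker_norm(np.ones(9), np.ones(9))
        labels = assign_tertiles(norm, ZoneConfig())
        assert list(labels[["s1", "s2", "s3"]]) == [Tertile.ALB_HIGH.value] * 3
        assert list(labels[["s4", "s5", "s6"]]) == [Tertile.CYP_HIGH.value] * 3
        again = assign_tertiles(norm, ZoneConfig())
        assert labels.equals(again)

    def test_remainder_goes_to_intermediate(self):
        norm = marker_norm(np.arange(10, 0, -1), np.arange(1, 11))
        labels = assign_tertiles(norm, ZoneConfig())
        counts = labels.value_counts()
        assert counts[Tertile.ALB_HIGH.value] == 3
        assert counts[Tertile.CYP_HIGH.value] == 3
        assert counts[Tertile.INTERMEDIATE.value] == 4

    def test_marker_absent(self):
        norm = make_norm(np.ones((5, 2)), gene_ids=["Alb", "other"])
        with pytest.raises(KeyError):
            assign_tertiles(norm, ZoneConfig())

    def test_too_few_spots(self):
        norm = marker_norm([1, 2], [2, 1])
        with pytest.raises(ValueError):
            assign_tertiles(norm, ZoneConfig())

    @pytest.mark.parametrize("n", range(3, 51))
    def test_partition_sizes_all_n(self, n):
        rng = np.random.default_rng(n)
        norm = marker_norm(rng.normal(size=n), rng.normal(size=n))
        labels = assign_tertiles(norm, ZoneConfig())
        counts = labels.value_counts()
        t = n // 3
        assert counts.get(Tertile.ALB_HIGH.value, 0) == t
        assert counts.get(Tertile.CYP_HIGH.value, 0) == t
        assert counts.get(Tertile.INTERMEDIATE.value, 0) == n - 2 * t
        assert counts.sum() == n


class TestRingMembership:
    @staticmethod
    def geometry_and_norm(top_value_spots, n_rows=7, n_cols=14):
        geom = build_geometry(hex_full_lattice(n_rows, n_cols), 100.0)
        n = len(geom)
        alb = np.zeros(n)
        for s in top_value_spots:
            alb[geom.index_of(s)] = 10.0
        cyp = np.zeros(n)
        cyp[-1] = 5.0  # arbitrary, keeps the CYP family non-degenerate
        values = np.column_stack([alb, cyp])
        norm = make_norm(values, gene_ids=["Alb", "Cyp2e1"])
        # align spot ids with the geometry barcodes
        return geom, type(norm)(tuple(geom.spot_ids), norm.gene_ids, values)

    def test_single_interior_top_spot(self):
        geom, norm = self.geometry_and_norm(["S003x015"])
        cfg = ZoneConfig(top_fraction=0.5 / len(geom))
        mem = ring_membership(norm, geom, cfg)
        assert mem["ALB_TOP"] == frozenset({"S003x015"})
        assert len(mem["ALB_R1"]) == 6
        assert len(mem["ALB_R2"]) == 6

    def test_adjacent_top_spots_share_neighbors_once(self):
        geom, norm = self.geometry_and_norm(["S003x015", "S003x017"])
        cfg = ZoneConfig(top_fraction=1.5 / len(geom))
        mem = ring_membership(norm, geom, cfg)
        tops = {"S003x015", "S003x017"}
        assert mem["ALB_TOP"] == frozenset(tops)
        expected_r1 = (
            ring_neighbors(geom, "S003x015").ring1
            | ring_neighbors(geom, "S003x017").ring1
        ) - tops
        assert mem["ALB_R1"] == expected_r1
        expected_r2 = (
            ring_neighbors(geom, "S003x015").ring2
            | ring_neighbors(geom, "S003x017").ring2
        ) - tops - expected_r1
        assert mem["ALB_R2"] == expected_r2

    def test_corner_top_spot_partial_rings(self):
        geom, norm = self.geometry_and_norm(["S000x000"])
        cfg = ZoneConfig(top_fraction=0.5 / len(geom))
        mem = ring_membership(norm, geom, cfg)
        assert len(mem["ALB_R1"]) == 2
        assert len(mem["ALB_R2"]) == 2

    def test_top_size_is_ceil(self):
        geom, norm = self.geometry_and_norm(["S003x015"])
        mem = ring_membership(norm, geom, ZoneConfig(top_fraction=0.10))
        assert len(mem["ALB_TOP"]) == math.ceil(0.10 * len(geom))

    def test_family_classes_disjoint(self):
        rng = np.random.default_rng(2)
        geom = build_geometry(hex_full_lattice(8, 10), 100.0)
        values = rng.normal(size=(len(geom), 2))
        norm = make_norm(values, gene_ids=["Alb", "Cyp2e1"])
        norm = type(norm)(tuple(geom.spot_ids), norm.gene_ids, values)
        mem = ring_membership(norm, geom, ZoneConfig())
        for fam in ("ALB", "CYP"):
            classes = [mem[f"{fam}_TOP"], mem[f"{fam}_R1"], mem[f"{fam}_R2"]]
            for a, b in itertools.combinations(classes, 2):
                assert not a & b


def enumeration_pvalue(x, y):
    """Independent oracle: exhaustive two-sided rank-sum p for no-tie data."""
    pooled = sorted(list(x) + list(y))
    n, n1 = len(pooled), len(x)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    w = sum(ranks[v] for v in x)
    sums = [sum(c) for c in itertools.combinations(range(1, n + 1), n1)]
    n_le = sum(1 for s in sums if s <= w)
    n_ge = sum(1 for s in sums if s >= w)
    return min(1.0, 2.0 * min(n_le, n_ge) / len(sums))


class TestWilcoxonRankSum:
    def test_exact_3v3(self):
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_groups_p1(self):
        assert wilcoxon_rank_sum([1.0, 2.0], [1.0, 2.0]) == 1.0

    def test_all_identical_p1(self):
        assert wilcoxon_rank_sum([3.0] * 5, [3.0] * 4) == 1.0

    def test_empty_group(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n1 = int(rng.integers(1, 9))
            n2 = int(rng.integers(1, 10 - n1 + 1)) if n1 < 9 else 1
            vals = rng.permutation(rng.normal(size=n1 + n2) * 10)
            x, y = vals[:n1], vals[n1:]
            assert wilcoxon_rank_sum(x, y) == pytest.approx(enumeration_pvalue(x, y))

    def test_normal_approx_close_to_exact(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            x = rng.normal(size=6)
            y = rng.normal(size=6)
            exact = enumeration_pvalue(x, y)
            assert abs(wilcoxon_rank_sum_approx(x, y) - exact) < 0.02

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=8), rng.normal(size=13)
        assert wilcoxon_rank_sum(x, y) == pytest.approx(wilcoxon_rank_sum(y, x))

    def test_large_sample_matches_scipy(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=40)
        y = rng.normal(size=35) + 0.4
        ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        assert wilcoxon_rank_sum(x, y) == pytest.approx(ref, rel=1e-9)

    def test_tied_large_sample_matches_scipy(self):
        rng = np.random.default_rng(4)
        x = rng.integers(0, 5, size=30).astype(float)
        y = rng.integers(0, 5, size=25).astype(float)
        ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        assert wilcoxon_rank_sum(x, y) == pytest.approx(ref, rel=1e-9)


def wilcoxon_rank_sum_approx(x, y):
    """Call the implementation's approximation branch on small no-tie data."""
    from hepazone import zonation

    old = zonation._EXACT_LIMIT
    zonation._EXACT_LIMIT = 0
    try:
        return wilcoxon_rank_sum(x, y)
    finally:
        zonation._EXACT_LIMIT = old


def scores_and_labels(alb_scores, cyp_scores, inter_scores=()):
    scores = list(alb_scores) + list(cyp_scores) + list(inter_scores)
    labels = (
        [Tertile.ALB_HIGH.value] * len(alb_scores)
        + [Tertile.CYP_HIGH.value] * len(cyp_scores)
        + [Tertile.INTERMEDIATE.value] * len(inter_scores)
    )
    index = [f"s{i}" for i in range(len(scores))]
    return (
        pd.DataFrame({"SET": scores}, index=index),
        pd.Series(labels, index=index),
    )


class TestZoneVolcano:
    def test_identical_zones(self):
        scores, labels = scores_and_labels([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        row = zone_volcano(scores, labels).iloc[0]
        assert row["delta"] == 0.0
        assert row["p"] == 1.0
        assert row["minus_log10_p"] == 0.0

    def test_hand_fixture(self):
        scores, labels = scores_and_labels([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        row = zone_volcano(scores, labels).iloc[0]
        assert row["delta"] == pytest.approx(-3.0)
        assert row["p"] == pytest.approx(0.1)
        assert row["minus_log10_p"] == pytest.approx(1.0)

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        scores, labels = scores_and_labels(rng.normal(size=5), rng.normal(size=5))
        base = zone_volcano(scores, labels)
        perm = rng.permutation(len(scores))
        shuffled = zone_volcano(scores.iloc[perm], labels)
        pd.testing.assert_frame_equal(base, shuffled)

    def test_marker_swap_flips_delta_keeps_p(self):
        rng = np.random.default_rng(1)
        scores, labels = scores_and_labels(rng.normal(size=6), rng.normal(size=7))
        swapped = labels.map(
            {
                Tertile.ALB_HIGH.value: Tertile.CYP_HIGH.value,
                Tertile.CYP_HIGH.value: Tertile.ALB_HIGH.value,
            }
        )
        a = zone_volcano(scores, labels).iloc[0]
        b = zone_volcano(scores, swapped).iloc[0]
        assert a["delta"] == pytest.approx(-b["delta"])
        assert a["p"] == pytest.approx(b["p"])

    def test_empty_zone_errors(self):
        scores, labels = scores_and_labels([1.0, 2.0], [])
        with pytest.raises(ValueError):
            zone_volcano(scores, labels)

    def test_bh_column_present(self):
        rng = np.random.default_rng(2)
        scores, labels = scores_and_labels(rng.normal(size=5), rng.normal(size=5))
        scores["SET2"] = rng.normal(size=len(scores))
        out = zone_volcano(scores, labels)
        assert "bh_fdr" in out.columns
        assert (out["bh_fdr"] >= out["p"] - 1e-12).all()


def profile_fixture():
    membership = {
        "ALB_TOP": frozenset({"a1", "a2"}),
        "ALB_R1": frozenset({"b1", "b2"}),
        "ALB_R2": frozenset({"c1", "c2"}),
        "CYP_TOP": frozenset({"d1", "d2"}),
        "CYP_R1": frozenset({"e1", "e2"}),
        "CYP_R2": frozenset({"f1", "f2"}),
    }
    spots = sorted({s for v in membership.values() for s in v})
    return membership, spots


class TestZonationProfile:
    def test_constant_scores(self):
        membership, spots = profile_fixture()
        scores = pd.DataFrame({"SET": [0.5] * len(spots)}, index=spots)
        prof = zonation_profile(scores, membership, "sample1")
        assert len(prof) == len(RING_CLASSES)
        assert (prof["mean"] == 0.5).all()

    def test_hand_means(self):
        membership, spots = profile_fixture()
        values = {s: i * 1.0 for i, s in enumerate(spots)}
        scores = pd.DataFrame({"SET": [values[s] for s in spots]}, index=spots)
        prof = zonation_profile(scores, membership, "x").set_index("class")
        for cls in RING_CLASSES:
            expected = np.mean([values[s] for s in membership[cls]])
            assert prof.loc[cls, "mean"] == pytest.approx(expected)

    def test_empty_class_flagged_missing(self):
        membership, spots = profile_fixture()
        membership = dict(membership)
        membership["CYP_R2"] = frozenset()
        scores = pd.DataFrame({"SET": np.ones(len(spots))}, index=spots)
        prof = zonation_profile(scores, membership, "x").set_index("class")
        assert math.isnan(prof.loc["CYP_R2", "mean"])
        assert prof.drop("CYP_R2")["mean"].notna().all()


class TestSelectTopRange:
    @staticmethod
    def profiles_from_ranges(ranges):
        rows = []
        for name, rng_ in ranges.items():
            rows.append({"set": name, "sample": "s", "class": "ALB_TOP", "mean": 0.0})
            rows.append({"set": name, "sample": "s", "class": "CYP_TOP", "mean": rng_})
        return pd.DataFrame(rows)

    def test_top_k(self):
        profiles = self.profiles_from_ranges({"A": 0.5, "B": 0.2, "C": 0.9})
        assert select_top_range(profiles, k=2) == ["C", "A"]

    def test_k_exceeding_count(self):
        profiles = self.profiles_from_ranges({"A": 0.5, "B": 0.2})
        assert select_top_range(profiles, k=10) == ["A", "B"]

    def test_range_tie_lexicographic(self):
        profiles = self.profiles_from_ranges({"B": 0.5, "A": 0.5, "C": 0.1})
        assert select_top_range(profiles, k=2) == ["A", "B"]

    def test_missing_excluded(self):
        profiles = self.profiles_from_ranges({"A": 0.5})
        profiles.loc[len(profiles)] = {
            "set": "A", "sample": "s", "class": "ALB_R1", "mean": float("nan"),
        }
        assert select_top_range(profiles, k=1) == ["A"]


class TestNormalizeProfileRows:
    @staticmethod
    def one_row_profile(values, name="A"):
        return pd.DataFrame(
            {
                "set": [name] * len(values),
                "sample": ["s"] * len(values),
                "class": RING_CLASSES[: len(values)],
                "mean": values,
            }
        )

    def test_symmetric_row(self):
        out = normalize_profile_rows(self.one_row_profile([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(out["normalized"], [-1.0, 0.0, 1.0])

    def test_constant_row_zeros(self):
        out = normalize_profile_rows(self.one_row_profile([2.0, 2.0, 2.0]))
        np.testing.assert_allclose(out["normalized"], 0.0)

    def test_hand_zscore_six_values(self):
        vals = [0.1, 0.4, -0.3, 0.8, 0.0, -0.5]
        out = normalize_profile_rows(self.one_row_profile(vals))
        expected = (np.array(vals) - np.mean(vals)) / np.std(vals, ddof=1)
        np.testing.assert_allclose(out["normalized"], expected, atol=1e-12)

    def test_minmax_mode(self):
        out = normalize_profile_rows(self.one_row_profile([1.0, 3.0, 2.0]), mode="minmax")
        np.testing.assert_allclose(out["normalized"], [0.0, 1.0, 0.5])

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            normalize_profile_rows(self.one_row_profile([1.0, 2.0]), mode="nope")
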