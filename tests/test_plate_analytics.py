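import numpy as np
import pytest

from conftest import enumerate_mann_whitney
from organoscore.plate_analytics import (
    GroupComparison,
    build_plate_result,
    compare_groups,
    half_plate_counts,
    layout_text,
    mann_whitney,
    plot_plate,
    welch_t,
)
from organoscore.plate_io import ALL_WELLS, ValidationError


def make_plate(positive_wells, scored_wells=ALL_WELLS, plate_id="P1", scores=None):
    labels = {
        w: ("positive" if w in positive_wells else "negative") for w in scored_wells
    }
    return build_plate_result(labels, scores=scores, plate_id=plate_id)


class TestBuildPlateResult:
    def test_all_negative(self):
        p = make_plate([])
        assert (p.n_positive, p.n_scored) == (0, 96)
        assert p.positive_fraction == 0.0

    def test_all_positive(self):
        p = make_plate(set(ALL_WELLS))
        assert p.positive_fraction == 1.0

    def test_half_positive_by_columns(self):
        pos = {w for w in ALL_WELLS if int(w[1:]) <= 6}
        p = make_plate(pos)
        assert p.n_positive == 48
        assert p.positive_fraction == 0.5

    def test_missing_wells_excluded_from_n_scored(self):
        scored = [w for w in ALL_WELLS if w not in ("A1", "H12")]
        p = make_plate(["B2"], scored_wells=scored)
        assert p.n_scored == 94
        assert p.grid[0, 0] == "missing"
        assert p.positive_fraction == pytest.approx(1 / 94)


class TestHalfPlateCounts:
    def test_positives_on_left_half_only(self):
        pos = {"A1", "B3", "C6", "H2"}
        assert half_plate_counts(make_plate(pos)) == (4, 0)

    def test_checkerboard_splits_evenly(self):
        pos = {
            f"{r}{c}"
            for r in "ABCDEFGH"
            for c in range(1, 13)
            if ("ABCDEFGH".index(r) + c) % 2 == 0
        }
        assert len(pos) == 48
        assert half_plate_counts(make_plate(pos)) == (24, 24)
        assert half_plate_counts(make_plate(pos), axis="row") == (24, 24)

    def test_row_split(self):
        pos = {"A1", "B12", "E5", "H9"}
        assert half_plate_counts(make_plate(pos), axis="row") == (2, 2)
        assert half_plate_counts(make_plate(pos), axis="row", boundary=2) == (2, 2)

    def test_halves_sum_to_total(self, rng):
        """For any random plate and any split, the halves partition the
        positives."""
        for _ in range(20):
            pos = set(rng.choice(ALL_WELLS, size=rng.integers(0, 97), replace=False))
            plate = make_plate(pos)
            for axis, bmax in (("column", 11), ("row", 7)):
                b = int(rng.integers(1, bmax + 1))
                a, c = half_plate_counts(plate, axis=axis, boundary=b)
                assert a + c == plate.n_positive

    def test_invalid_split_rejected(self):
        with pytest.raises(ValidationError):
            half_plate_counts(make_plate([]), axis="diagonal")
        with pytest.raises(ValidationError):
            half_plate_counts(make_plate([]), boundary=12)


class TestMannWhitney:
    def test_fully_separated_groups(self):
        """a below b entirely: U = 0 and exact two-sided p = 2/C(6,3) = 0.1."""
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)

    def test_single_tied_pair_uninformative(self):
        u, p = mann_whitney([5], [5])
        assert p == 1.0

    def test_group_swap_symmetry(self, rng):
        a = list(rng.uniform(0, 1, 5))
        b = list(rng.uniform(0, 1, 7))
        u_ab, p_ab = mann_whitney(a, b)
        u_ba, p_ba = mann_whitney(b, a)
        assert u_ba == pytest.approx(len(a) * len(b) - u_ab)
        assert p_ba == pytest.approx(p_ab)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney([], [1.0])

    def test_exact_p_matches_full_enumeration(self, rng):
        """For every group-size pair up to 6 (tie-free draws), the p-value
        equals full enumeration over all label arrangements."""
        for na in range(1, 7):
            for nb in range(1, 7):
                vals = rng.permutation(np.arange(1.0, na + nb + 1))
                a, b = list(vals[:na]), list(vals[na:])
                u, p = mann_whitney(a, b)
                u_ref, p_ref = enumerate_mann_whitney(a, b)
                assert u == u_ref
                assert p == pytest.approx(p_ref, abs=1e-12)

    def test_large_or_tied_samples_use_normal_approximation(self, rng):
        a = list(rng.integers(0, 5, size=30).astype(float))
        b = list(rng.integers(2, 7, size=25).astype(float))
        u, p = mann_whitney(a, b)
        assert 0 <= u <= 30 * 25
        assert 0 <= p <= 1


class TestCompareGroups:
    def test_identical_groups(self):
        plates = [make_plate({"A1", "A2"}, plate_id=f"P{i}") for i in range(3)]
        cmp = compare_groups(plates, plates)
        assert cmp.p_value == 1.0
        assert cmp.mean_a == cmp.mean_b
        assert cmp.sd_a == 0.0

    def test_disjoint_fraction_ranges(self):
        """Three plates per group with disjoint fractions: U = 9, p = 0.1."""
        def plate_with_fraction(k, pid):
            return make_plate(set(ALL_WELLS[:k]), plate_id=pid)

        a = [plate_with_fraction(k, f"A{k}") for k in (32, 34, 30)]  # ~0.33,0.35,0.31
        b = [plate_with_fraction(k, f"B{k}") for k in (19, 21, 20)]  # ~0.20,0.22,0.21
        cmp = compare_groups(a, b, group_names=("treated", "control"))
        assert cmp.u_statistic == 9
        assert cmp.p_value == pytest.approx(0.1)
        assert "treated" in cmp.summary()

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            compare_groups([], [make_plate([])])

    def test_per_organoid_units(self):
        scores_a = {w: 100.0 + i for i, w in enumerate(ALL_WELLS[:5])}
        scores_b = {w: 10.0 + i for i, w in enumerate(ALL_WELLS[:5])}
        a = make_plate([], scored_wells=ALL_WELLS[:5], scores=scores_a)
        b = make_plate([], scored_wells=ALL_WELLS[:5], scores=scores_b)
        cmp = compare_groups([a], [b], per_organoid=True)
        assert cmp.values_a == sorted(scores_a.values())
        assert cmp.u_statistic == 25  # all a above all b

    def test_welch_t_secondary(self, rng):
        a = [make_plate(set(ALL_WELLS[: 20 + i]), plate_id=f"A{i}") for i in range(4)]
        b = [make_plate(set(ALL_WELLS[: 40 + i]), plate_id=f"B{i}") for i in range(4)]
        cmp = compare_groups(a, b, with_t_test=True)
        assert cmp.t_p_value is not None
        t, p = welch_t(cmp.values_a, cmp.values_b)
        assert cmp.t_p_value == pytest.approx(p)

    def test_null_type_i_error_controlled(self, rng):
        """Under a shared continuous null the exact test rejects at 5% no
        more than 5% of the time (up to Monte-Carlo error)."""
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            x = rng.normal(size=5)
            y = rng.normal(size=5)
            _, p = mann_whitney(list(x), list(y))
            rejections += p <= 0.05
        assert rejections / n_rep <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_rep)


class TestReports:
    def test_layout_text_markers(self):
        scored = [w for w in ALL_WELLS if w != "A3"]
        plate = make_plate({"A1"}, scored_wells=scored)
        text = layout_text(plate)
        lines = text.splitlines()
        assert len(lines) == 9  # header + 8 rows
        row_a = lines[1]
        assert row_a.startswith("A")
        cells = row_a.split()[1:]
        assert cells[0] == "+" and cells[1] == "-" and cells[2] == "."

    def test_plot_plate_writes_png(self, tmp_path):
        scores = {w: float(i) for i, w in enumerate(ALL_WELLS)}
        plate = make_plate({"B2", "C9"}, scores=scores)
        out = tmp_path / "plate.png"
        plot_plate(plate, str(out))
        assert out.stat().st_size > 1000
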