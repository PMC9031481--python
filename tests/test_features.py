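import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from palsygest.features import (
    FEATURE_NAMES,
    MEASURE_NAMES,
    SLOPE_SENTINEL,
    angle_between,
    closed_perimeter,
    compute_features,
    compute_measures,
    euclidean,
    slope_between,
)
from palsygest.landmarks import (
    DegenerateGeometryError,
    InvalidLandmarksError,
    SimilarityTransform,
    apply_transform,
    tilt_correct,
)
from palsygest.synthetic import GestureParams, default_template, generate_face

finite = st.floats(-1e6, 1e6, allow_nan=False)


# ---------------------------------------------------------------------------
# independent naive oracle: a direct, scalar-math transcription of each
# feature's definition, sharing no code with the implementation


def naive_measures(lm):
    p = [tuple(q) for q in lm.points]
    aux = {k: tuple(v) for k, v in lm.aux.items()}

    def dd(a, b):
        return math.sqrt((a[0] - b[0]) ** 2 + (a[1] - b[1]) ** 2)

    eye_y = (p[10][1] + p[19][1]) / 2
    pm = ((p[31][0] + p[37][0]) / 2, (p[31][1] + p[37][1]) / 2)
    m = {
        "A": dd(aux["left_face_side"], aux["right_face_side"]),
        "Bl": dd(p[10], p[13]), "Br": dd(p[16], p[19]),
        "C": dd(p[37], aux["chin"]),
        "D": dd(p[10], aux["left_face_side"]), "E": dd(p[19], aux["right_face_side"]),
        "F": dd(p[10], p[28]), "G": dd(p[19], p[34]),
        "H": dd(p[13], p[22]), "I": dd(p[16], p[22]),
        "J": dd(p[23], p[28]), "K": dd(p[27], p[34]),
        "L": sum(eye_y - p[i][1] for i in range(0, 5)) / 5,
        "M": sum(eye_y - p[i][1] for i in range(5, 10)) / 5,
        "Nl": dd(p[11], p[15]), "Nr": dd(p[12], p[14]),
        "Ol": dd(p[17], p[21]), "Or": dd(p[18], p[20]),
        "Pl": dd(p[29], p[39]), "Pu": dd(p[41], p[47]),
        "Ql": dd(p[33], p[35]), "Qu": dd(p[43], p[45]),
        "R": dd(p[0], p[28]), "S": dd(p[9], p[34]),
        "T": dd(p[4], p[28]), "U": dd(p[5], p[34]),
        "Vl": dd(p[28], pm), "Vr": dd(p[34], pm),
        "W": dd(p[28], p[34]), "X": dd(p[22], p[31]),
    }
    m["N"] = (m["Nl"] + m["Nr"]) / 2
    m["O"] = (m["Ol"] + m["Or"]) / 2

    def perim(idxs):
        total = 0.0
        for a, b in zip(idxs, idxs[1:]):
            total += dd(p[a], p[b])
        return total + dd(p[idxs[0]], p[idxs[-1]])

    m["Wl"] = perim([28, 29, 30, 31, 37, 38, 39])
    m["Wr"] = perim([31, 32, 33, 34, 35, 36, 37])
    return m


def naive_features(lm):
    p = [tuple(q) for q in lm.points]
    m = naive_measures(lm)

    def ang(a, b):
        return abs(math.degrees(math.atan2(a[0] - b[0], a[1] - b[1])))

    def slope(a, b):
        if a[0] == b[0]:
            return math.copysign(SLOPE_SENTINEL, a[1] - b[1]) if a[1] != b[1] else 0.0
        return (a[1] - b[1]) / (a[0] - b[0])

    def mx(a, b):
        return max(m[a] / m[b], m[b] / m[a])

    return [
        ang(p[0], p[9]), ang(p[2], p[7]), ang(p[4], p[5]), mx("L", "M"),
        slope(p[0], p[9]), slope(p[2], p[7]), slope(p[4], p[5]),
        ang(p[10], p[19]), mx("Bl", "Br"), mx("D", "E"), mx("H", "I"),
        mx("N", "O"), mx("Nl", "Or"), mx("Nr", "Ol"),
        ang(p[28], p[34]), mx("F", "G"), mx("Pl", "Ql"), mx("Pu", "Qu"),
        max(m["Vl"] / m["A"], m["Vr"] / m["A"]),
        max(m["Pl"] / m["W"], m["Ql"] / m["W"]),
        max(m["Pu"] / m["W"], m["Qu"] / m["W"]),
        max(m["Wl"] / m["W"], m["Wr"] / m["W"]),
        ang(p[23], p[27]), ang(p[22], p[37]), mx("J", "K"),
        max(m["T"] / m["A"], m["U"] / m["A"]),
        max(m["R"] / m["A"], m["S"] / m["A"]),
        m["C"] / m["A"], m["X"] / m["A"],
    ]


# ---------------------------------------------------------------------------
# primitives


class TestAngleBetween:
    def test_horizontal_pair(self):
        # dx = -1, dy = 0 -> arctan2(-1, 0) = -pi/2
        assert angle_between((0, 0), (1, 0)) == pytest.approx(-90.0)

    def test_vertical_pair(self):
        # dx = 0, dy = -1 -> arctan2(0, -1) = pi
        assert angle_between((0, 0), (0, 1)) == pytest.approx(180.0)

    def test_coincident_points_zero_by_convention(self):
        assert angle_between((3, 4), (3, 4)) == 0.0

    @given(ax=finite, ay=finite, bx=finite, by=finite)
    @settings(max_examples=50, deadline=None)
    def test_range(self, ax, ay, bx, by):
        a = angle_between((ax, ay), (bx, by))
        assert -180.0 < a <= 180.0


class TestSlopeBetween:
    def test_worked_example(self):
        # (0-1)/(0-2) = 0.5 by direct substitution
        assert slope_between((0, 0), (2, 1)) == pytest.approx(0.5)

    def test_equal_y_zero(self):
        assert slope_between((1, 5), (9, 5)) == 0.0

    def test_vertical_sentinel_sign(self):
        assert slope_between((2, 7), (2, 3)) == SLOPE_SENTINEL
        assert slope_between((2, 3), (2, 7)) == -SLOPE_SENTINEL


class TestEuclidean:
    def test_345(self):
        assert euclidean((0, 0), (3, 4)) == pytest.approx(5.0)

    def test_zero(self):
        assert euclidean((2, 2), (2, 2)) == 0.0

    def test_other(self):
        assert euclidean((1, 1), (4, 5)) == pytest.approx(5.0)

    @given(ax=finite, ay=finite, bx=finite, by=finite)
    @settings(max_examples=50, deadline=None)
    def test_symmetric_nonnegative(self, ax, ay, bx, by):
        d = euclidean((ax, ay), (bx, by))
        assert d >= 0.0
        assert d == pytest.approx(euclidean((bx, by), (ax, ay)))


class TestClosedPerimeter:
    def test_triangle(self):
        assert closed_perimeter([(0, 0), (3, 0), (0, 4)]) == pytest.approx(12.0)

    def test_unit_square(self):
        assert closed_perimeter([(0, 0), (1, 0), (1, 1), (0, 1)]) == pytest.approx(4.0)

    def test_collinear_triple(self):
        # 1 + 1 consecutive plus closing 2
        assert closed_perimeter([(0, 0), (1, 0), (2, 0)]) == pytest.approx(4.0)

    def test_too_few_points(self):
        with pytest.raises(InvalidLandmarksError):
            closed_perimeter([(0, 0), (1, 1)])


# ---------------------------------------------------------------------------
# measures


class TestComputeMeasures:
    def test_exactly_30_named_measures(self, rest_face_corrected):
        m = compute_measures(rest_face_corrected)
        assert len(m.as_dict()) == 30
        assert tuple(m.as_dict()) == MEASURE_NAMES

    def test_symmetric_template_mirror_equalities(self, rest_face_corrected):
        m = compute_measures(rest_face_corrected)
        for a, b in [("Bl", "Br"), ("D", "E"), ("H", "I"), ("Nl", "Or"),
                     ("Nr", "Ol"), ("Pl", "Ql"), ("Pu", "Qu"), ("F", "G"),
                     ("J", "K"), ("R", "S"), ("T", "U"), ("Vl", "Vr"),
                     ("L", "M")]:
            assert m[a] == pytest.approx(m[b], abs=1e-9), (a, b)

    def test_all_nonnegative_finite(self, random_landmark_sets):
        for lm in random_landmark_sets[:20]:
            m = compute_measures(lm)
            vals = np.array(list(m.as_dict().values()))
            assert np.all(np.isfinite(vals)) and np.all(vals >= 0)
            assert m["W"] > 0 and m["A"] > 0

    def test_scaling_homogeneity(self, rest_face_corrected):
        tf = SimilarityTransform(np.array([[2.0, 0.0, 0.0], [0.0, 2.0, 0.0]]))
        scaled = apply_transform(rest_face_corrected, tf)
        m1 = compute_measures(rest_face_corrected).as_dict()
        m2 = compute_measures(scaled).as_dict()
        for name in MEASURE_NAMES:
            assert m2[name] == pytest.approx(2.0 * m1[name], rel=1e-12), name

    def test_half_mouth_perimeter_matches_bruteforce(self, random_landmark_sets):
        for lm in random_landmark_sets[:20]:
            m = compute_measures(lm)
            oracle = naive_measures(lm)
            assert m["Wl"] == pytest.approx(oracle["Wl"], rel=1e-12)
            assert m["Wr"] == pytest.approx(oracle["Wr"], rel=1e-12)

    def test_half_perimeters_exceed_half_width(self, random_landmark_sets):
        for lm in random_landmark_sets[:20]:
            m = compute_measures(lm)
            assert m["Wl"] >= m["W"] / 2
            assert m["Wr"] >= m["W"] / 2

    def test_degenerate_mouth_rejected(self, rest_face_corrected):
        pts = rest_face_corrected.points.copy()
        pts[34] = pts[28]
        lm = rest_face_corrected.replace(points=pts)
        with pytest.raises(DegenerateGeometryError):
            compute_measures(lm)

    def test_missing_aux_rejected(self, rest_face_corrected):
        lm = rest_face_corrected.replace(aux={})
        with pytest.raises(InvalidLandmarksError):
            compute_measures(lm)


# ---------------------------------------------------------------------------
# features


class TestComputeFeatures:
    def test_length_29(self, rest_face_corrected):
        f = compute_features(rest_face_corrected)
        assert f.shape == (29,)
        assert len(FEATURE_NAMES) == 29

    def test_requires_tilt_correction(self, rest_face):
        with pytest.raises(InvalidLandmarksError):
            compute_features(rest_face)

    def test_symmetric_template_feature_values(self, rest_face_corrected):
        f = compute_features(rest_face_corrected)
        # all reciprocal max-ratio features are exactly 1 on a symmetric face
        for i in (3, 8, 9, 10, 11, 12, 13, 15, 16, 17, 24):
            assert f[i] == pytest.approx(1.0, abs=1e-9), f"f{i}"
        # horizontal pairs give |angle| = 90 under the dx-first convention
        for i in (0, 1, 2, 7, 14, 22):
            assert f[i] == pytest.approx(90.0, abs=1e-9), f"f{i}"
        # vertical nose-to-mouth line gives 180
        assert f[23] == pytest.approx(180.0, abs=1e-9)
        for i in (4, 5, 6):
            assert f[i] == pytest.approx(0.0, abs=1e-12)

    def test_eye_closure_raises_opening_ratios(self, template):
        open_f = compute_features(tilt_correct(generate_face(template, GestureParams(gesture=0))))
        closed = generate_face(template, GestureParams(gesture=2, severity=1.0))
        closed_f = compute_features(tilt_correct(closed))
        for i in (11, 12, 13):
            assert closed_f[i] > open_f[i], f"f{i}"

    def test_similarity_invariance(self, random_landmark_sets):
        rng = np.random.RandomState(0)
        for lm in random_landmark_sets[:10]:
            base = compute_features(lm)
            s = float(rng.uniform(0.5, 3.0))
            tx, ty = rng.uniform(-100, 100, 2)
            tf = SimilarityTransform(np.array([[s, 0.0, tx], [0.0, s, ty]]))
            moved = apply_transform(lm, tf)
            assert np.allclose(compute_features(moved), base, rtol=1e-9, atol=1e-9)

    def test_max_ratio_floor(self, random_landmark_sets):
        for lm in random_landmark_sets:
            f = compute_features(lm)
            for i in (3, 8, 9, 10, 11, 12, 13, 15, 16, 17, 24):
                assert f[i] >= 1.0

    def test_mirror_symmetry(self, random_landmark_sets):
        # reflect about the vertical midline and relabel left<->right;
        # reciprocal ratios are unchanged, |angle| maps to 180-|angle|
        # (equal deviation from horizontal), slopes are negated
        mirror_map = _mirror_index_map()
        for lm in random_landmark_sets[:10]:
            pts = lm.points.copy()
            cx = pts[:, 0].mean()
            ref = pts.copy()
            ref[:, 0] = 2 * cx - ref[:, 0]
            ref = ref[mirror_map]
            aux = {
                "chin": np.array([2 * cx - lm.aux["chin"][0], lm.aux["chin"][1]]),
                "left_face_side": np.array(
                    [2 * cx - lm.aux["right_face_side"][0], lm.aux["right_face_side"][1]]),
                "right_face_side": np.array(
                    [2 * cx - lm.aux["left_face_side"][0], lm.aux["left_face_side"][1]]),
            }
            mirrored = lm.replace(points=ref, aux=aux, tilt_corrected=False)
            fm = compute_features(tilt_correct(mirrored))
            f = compute_features(lm)
            ratio_idx = (3, 8, 9, 10, 11, 12, 13, 15, 16, 17, 18, 19, 20, 21, 24, 25, 26)
            assert np.allclose(fm[list(ratio_idx)], f[list(ratio_idx)], rtol=1e-6)
            for i in (0, 1, 2, 7, 14, 22, 23):
                assert abs(90.0 - fm[i]) == pytest.approx(abs(90.0 - f[i]), abs=1e-6)
            for i in (4, 5, 6):
                assert fm[i] == pytest.approx(-f[i], abs=1e-6)
            assert fm[27] == pytest.approx(f[27], rel=1e-6)
            assert fm[28] == pytest.approx(f[28], rel=1e-6)

    def test_oracle_equivalence_100_random_sets(self, random_landmark_sets):
        for lm in random_landmark_sets:
            f = compute_features(lm)
            oracle = naive_features(lm)
            assert np.allclose(f, oracle, rtol=1e-9, atol=1e-9)


def _mirror_index_map():
    """Primary-index permutation realizing the left/right relabeling."""
    m = list(range(51))
    # brows: P0..P4 <-> P9..P5
    for i in range(5):
        m[i], m[9 - i] = 9 - i, i
    # eyes: left (10..15) <-> right read mirror-wise
    eye_pairs = [(10, 19), (11, 18), (12, 17), (13, 16), (14, 21), (15, 20)]
    for a, b in eye_pairs:
        m[a], m[b] = b, a
    # nose base
    for a, b in [(23, 27), (24, 26)]:
        m[a], m[b] = b, a
    # outer lip
    for a, b in [(28, 34), (29, 33), (30, 32), (35, 39), (36, 38)]:
        m[a], m[b] = b, a
    # inner lip
    for a, b in [(40, 44), (41, 43), (45, 47)]:
        m[a], m[b] = b, a
    return m
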