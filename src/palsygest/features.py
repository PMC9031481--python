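"""Geometric primitives, the 30 face measures, and the 29 asymmetry features.

All quantities are computed on a tilt-corrected :class:`~palsygest.landmarks.LandmarkSet`
in the package's y-down image convention.  The feature vector contains only
angles, slopes, and ratios of distances, so it is invariant to translation
and uniform scaling of the input, and (after tilt correction) to in-plane
rotation.

Measure endpoint ledger
-----------------------
28 distances + 2 averages = 30 measures.  ``d`` is the Euclidean distance,
``Pm`` is the mouth-centre midpoint of P31 and P37, and the *eye line* is
the horizontal through the mean y of the outer eye corners (well defined
after tilt correction).

====  ===================================  =================================
name  definition                           meaning
====  ===================================  =================================
A     d(left_face_side, right_face_side)   head width
Bl    d(P10, P13)                          left eye width
Br    d(P16, P19)                          right eye width
C     d(P37, chin)                         bottom-mid outer lip to chin
D     d(P10, left_face_side)               left eye to head side
E     d(P19, right_face_side)              right eye to head side
F     d(P10, P28)                          left eye to left mouth corner
G     d(P19, P34)                          right eye to right mouth corner
H     d(P13, P22)                          left inner eye corner to nose tip
I     d(P16, P22)                          right inner eye corner to nose tip
J     d(P23, P28)                          left nostril to left mouth corner
K     d(P27, P34)                          right nostril to right mouth corner
L     mean(eye-line y - y(P0..P4))         mean left eyebrow height
M     mean(eye-line y - y(P5..P9))         mean right eyebrow height
Nl    d(P11, P15)                          left eye opening, outer pair
Nr    d(P12, P14)                          left eye opening, inner pair
Ol    d(P17, P21)                          right eye opening, inner pair
Or    d(P18, P20)                          right eye opening, outer pair
Pl    d(P29, P39)                          mouth outer opening, left
Pu    d(P41, P47)                          mouth inner opening, left
Ql    d(P33, P35)                          mouth outer opening, right
Qu    d(P43, P45)                          mouth inner opening, right
R     d(P0, P28)                           left outer brow to mouth corner
S     d(P9, P34)                           right outer brow to mouth corner
T     d(P4, P28)                           left inner brow to mouth corner
U     d(P5, P34)                           right inner brow to mouth corner
Vl    d(P28, Pm)                           mouth half width, left
Vr    d(P34, Pm)                           mouth half width, right
W     d(P28, P34)                          mouth width
X     d(P22, P31)                          nose tip to top-mid outer lip
====  ===================================  =================================

The eye-opening letters group by eye: N* is the left eye, O* the right,
and the second letter follows the left-to-right reading within each eye
(left eye: outer pair Nl then inner Nr; right eye: inner pair Ol then
outer Or).  Mirroring the face swaps Nl with Or and Nr with Ol, which is
exactly what the outer/inner opening-ratio features compare.

Derived auxiliaries (not counted among the 30): N = (Nl+Nr)/2 and
O = (Ol+Or)/2 (mean left/right eye openings), plus the half-mouth perimeters
Wl = perimeter(P28,P29,P30,P31,P37,P38,P39) and
Wr = perimeter(P31,P32,P33,P34,P35,P36,P37).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np

from .landmarks import DegenerateGeometryError, InvalidLandmarksError, LandmarkSet

__all__ = [
    "MEASURE_NAMES",
    "FEATURE_NAMES",
    "N_FEATURES",
    "MeasureSet",
    "angle_between",
    "slope_between",
    "euclidean",
    "closed_perimeter",
    "compute_measures",
    "compute_features",
]

#: Magnitude cap standing in for an infinite slope (vertical segment) or an
#: unbounded ratio (zero denominator); keeps batch feature extraction
#: exception-free on pathological inputs.
SLOPE_SENTINEL = 1e6

MEASURE_NAMES: tuple[str, ...] = (
    "A", "Bl", "Br", "C", "D", "E", "F", "G", "H", "I", "J", "K",
    "L", "M", "Nl", "Nr", "Ol", "Or", "Pl", "Pu", "Ql", "Qu",
    "R", "S", "T", "U", "Vl", "Vr", "W", "X",
)

N_FEATURES = 29
FEATURE_NAMES: tuple[str, ...] = tuple(f"f{i}" for i in range(N_FEATURES))


def angle_between(pa, pb) -> float:
    """Angle of the segment pa-pb in degrees, in (-180, 180].

    Computed as ``arctan2(dx, dy) * 180 / pi`` with ``dx = pa.x - pb.x`` and
    ``dy = pa.y - pb.y`` — note the x-difference is the *first* arctan2
    argument, so a horizontal left-to-right pair yields -90 (|angle| = 90).
    Coincident points return 0 by convention.
    """
    pa = np.asarray(pa, dtype=float)
    pb = np.asarray(pb, dtype=float)
    dx, dy = pa[0] - pb[0], pa[1] - pb[1]
    if dx == 0.0 and dy == 0.0:
        return 0.0
    ang = float(np.degrees(np.arctan2(dx, dy)))
    if ang <= -180.0:  # arctan2(-0.0, negative) -> -pi; fold onto +180
        ang = 180.0
    return ang


def slope_between(pa, pb) -> float:
    """Slope (pa.y - pb.y) / (pa.x - pb.x); vertical segments return the
    signed sentinel ``+-SLOPE_SENTINEL`` (sign of dy, 0 for a point)."""
    pa = np.asarray(pa, dtype=float)
    pb = np.asarray(pb, dtype=float)
    dx, dy = pa[0] - pb[0], pa[1] - pb[1]
    if dx == 0.0:
        return float(np.sign(dy) * SLOPE_SENTINEL)
    return float(dy / dx)


def euclidean(pa, pb) -> float:
    pa = np.asarray(pa, dtype=float)
    pb = np.asarray(pb, dtype=float)
    return float(np.hypot(pa[0] - pb[0], pa[1] - pb[1]))


def closed_perimeter(points: Iterable) -> float:
    """Perimeter of the closed shape through ``points`` in order: the sum of
    consecutive segment lengths plus the closing first-to-last segment."""
    pts = np.atleast_2d(np.asarray(list(points), dtype=float))
    if pts.shape[0] < 3 or pts.shape[1] != 2:
        raise InvalidLandmarksError("closed_perimeter needs at least 3 (x, y) points")
    diffs = np.diff(pts, axis=0)
    closing = pts[0] - pts[-1]
    return float(np.sum(np.hypot(diffs[:, 0], diffs[:, 1])) + np.hypot(*closing))


@dataclasses.dataclass(frozen=True)
class MeasureSet:
    """The 30 named scalar measures of one face (28 distances, 2 averages)
    plus the derived auxiliaries N, O, Wl, Wr used by the features."""

    values: dict[str, float]
    derived: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(MEASURE_NAMES) - set(self.values)
        if missing:
            raise InvalidLandmarksError(f"measure set missing {sorted(missing)}")

    def __getitem__(self, name: str) -> float:
        if name in self.values:
            return self.values[name]
        return self.derived[name]

    def as_dict(self) -> dict[str, float]:
        """The 30 canonical measures, in ledger order."""
        return {name: self.values[name] for name in MEASURE_NAMES}

    def __len__(self) -> int:
        return len(MEASURE_NAMES)


def compute_measures(lm: LandmarkSet) -> MeasureSet:
    """Evaluate the measure ledger on a tilt-corrected landmark set."""
    p = lm.points
    try:
        chin = lm.aux["chin"]
        lface = lm.aux["left_face_side"]
        rface = lm.aux["right_face_side"]
    except KeyError as exc:
        raise InvalidLandmarksError(
            "auxiliary points chin/left_face_side/right_face_side are required"
        ) from exc

    d = euclidean
    eye_line_y = (p[10][1] + p[19][1]) / 2.0
    mouth_mid = (p[31] + p[37]) / 2.0

    v: dict[str, float] = {
        "A": d(lface, rface),
        "Bl": d(p[10], p[13]),
        "Br": d(p[16], p[19]),
        "C": d(p[37], chin),
        "D": d(p[10], lface),
        "E": d(p[19], rface),
        "F": d(p[10], p[28]),
        "G": d(p[19], p[34]),
        "H": d(p[13], p[22]),
        "I": d(p[16], p[22]),
        "J": d(p[23], p[28]),
        "K": d(p[27], p[34]),
        "L": float(np.mean(eye_line_y - p[0:5, 1])),
        "M": float(np.mean(eye_line_y - p[5:10, 1])),
        "Nl": d(p[11], p[15]),
        "Nr": d(p[12], p[14]),
        "Ol": d(p[17], p[21]),
        "Or": d(p[18], p[20]),
        "Pl": d(p[29], p[39]),
        "Pu": d(p[41], p[47]),
        "Ql": d(p[33], p[35]),
        "Qu": d(p[43], p[45]),
        "R": d(p[0], p[28]),
        "S": d(p[9], p[34]),
        "T": d(p[4], p[28]),
        "U": d(p[5], p[34]),
        "Vl": d(p[28], mouth_mid),
        "Vr": d(p[34], mouth_mid),
        "W": d(p[28], p[34]),
        "X": d(p[22], p[31]),
    }
    if v["W"] <= 0.0 or v["A"] <= 0.0:
        raise DegenerateGeometryError("zero mouth or head width; not a valid face")

    derived = {
        "N": (v["Nl"] + v["Nr"]) / 2.0,
        "O": (v["Ol"] + v["Or"]) / 2.0,
        "Wl": closed_perimeter(p[[28, 29, 30, 31, 37, 38, 39]]),
        "Wr": closed_perimeter(p[[31, 32, 33, 34, 35, 36, 37]]),
    }
    return MeasureSet(values=v, derived=derived)


def _sym_ratio(a: float, b: float) -> float:
    """max(a/b, b/a), capped at the sentinel; 1.0 for the 0/0 case."""
    a, b = abs(a), abs(b)
    hi, lo = max(a, b), min(a, b)
    if lo == 0.0:
        return 1.0 if hi == 0.0 else SLOPE_SENTINEL
    return hi / lo


def _ratio(a: float, b: float) -> float:
    if b == 0.0:
        return SLOPE_SENTINEL if a != 0.0 else 0.0
    return a / b


def compute_features(lm: LandmarkSet) -> np.ndarray:
    """The 29-element asymmetry feature vector f0..f28.

    Angle features are in degrees and taken as absolute values; paired
    left/right measures enter as ``max(a/b, b/a)`` so perfect balance gives
    exactly 1; slope features carry sign.
    """
    if not lm.tilt_corrected:
        raise InvalidLandmarksError("features require a tilt-corrected landmark set")
    m = compute_measures(lm)
    p = lm.points

    f = np.empty(N_FEATURES, dtype=float)
    # eyebrows
    f[0] = abs(angle_between(p[0], p[9]))
    f[1] = abs(angle_between(p[2], p[7]))
    f[2] = abs(angle_between(p[4], p[5]))
    f[3] = _sym_ratio(m["L"], m["M"])
    f[4] = slope_between(p[0], p[9])
    f[5] = slope_between(p[2], p[7])
    f[6] = slope_between(p[4], p[5])
    # eyes
    f[7] = abs(angle_between(p[10], p[19]))
    f[8] = _sym_ratio(m["Bl"], m["Br"])
    f[9] = _sym_ratio(m["D"], m["E"])
    f[10] = _sym_ratio(m["H"], m["I"])
    f[11] = _sym_ratio(m["N"], m["O"])
    f[12] = _sym_ratio(m["Nl"], m["Or"])
    f[13] = _sym_ratio(m["Nr"], m["Ol"])
    # mouth
    f[14] = abs(angle_between(p[28], p[34]))
    f[15] = _sym_ratio(m["F"], m["G"])
    f[16] = _sym_ratio(m["Pl"], m["Ql"])
    f[17] = _sym_ratio(m["Pu"], m["Qu"])
    f[18] = max(_ratio(m["Vl"], m["A"]), _ratio(m["Vr"], m["A"]))
    f[19] = max(_ratio(m["Pl"], m["W"]), _ratio(m["Ql"], m["W"]))
    f[20] = max(_ratio(m["Pu"], m["W"]), _ratio(m["Qu"], m["W"]))
    f[21] = max(_ratio(m["Wl"], m["W"]), _ratio(m["Wr"], m["W"]))
    # nose / combined
    f[22] = abs(angle_between(p[23], p[27]))
    f[23] = abs(angle_between(p[22], p[37]))
    f[24] = _sym_ratio(m["J"], m["K"])
    f[25] = max(_ratio(m["T"], m["A"]), _ratio(m["U"], m["A"]))
    f[26] = max(_ratio(m["R"], m["A"]), _ratio(m["S"], m["A"]))
    f[27] = _ratio(m["C"], m["A"])
    f[28] = _ratio(m["X"], m["A"])
    return f
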