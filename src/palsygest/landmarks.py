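"""Facial landmark sets: 68-to-51 selection, tilt correction, rotation.

Coordinate convention (used everywhere in this package): origin at the
image top-left, x increasing rightward, y increasing *downward*.  A facial
element that rises therefore has a *decreasing* y coordinate.  "Left"
always means image-left (the subject's right side).

The 51 primary points are reindexed from the standard 68-point layout
(jaw 0-16, brows 17-26, nose 27-35, eyes 36-47, mouth 48-67) by dropping
the 17 jaw-contour points.  Three jaw points are retained as named
auxiliary references (chin and the two face-side extremes) so that the
head-width and mouth-to-chin measures stay computable.

Reindex map (51-index <- 68-index):

==========  ==================  =========================================
51 range    68 range            semantics
==========  ==================  =========================================
P0-P4       17-21               left eyebrow, outer (P0) to inner (P4)
P5-P9       22-26               right eyebrow, inner (P5) to outer (P9)
P10-P15     36-41               left eye; P10 outer corner, P13 inner
P16-P21     42-47               right eye; P16 inner corner, P19 outer
P22         30                  nose tip
P23-P27     31-35               nose base, left nostril (P23) to right
                                nostril (P27); P25 subnasale
P28-P39     48-59               outer lip; P28 left corner, P31 top mid,
                                P34 right corner, P37 bottom mid
P40-P47     60-67               inner lip; P40 left corner, P44 right
P48-P50     27-29               nose bridge, top to bottom
==========  ==================  =========================================

aux: chin <- 68:8, left_face_side <- 68:0, right_face_side <- 68:16.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

import numpy as np

__all__ = [
    "RawLandmarks68",
    "LandmarkSet",
    "SimilarityTransform",
    "SELECT_51_MAP",
    "AUX_MAP",
    "select_51",
    "compute_tilt_transform",
    "apply_transform",
    "rotate_landmarks",
    "load_landmarks_json",
    "dump_landmarks_json",
    "InvalidLandmarksError",
    "DegenerateGeometryError",
]

N_RAW = 68
N_PRIMARY = 51

#: 51-point reindexing of the 68-point layout (position i holds the 68-index
#: of primary point Pi).  See the module docstring for the rationale.
SELECT_51_MAP: tuple[int, ...] = tuple(
    list(range(17, 27))        # P0-P9   eyebrows
    + list(range(36, 48))      # P10-P21 eyes
    + [30]                     # P22     nose tip
    + list(range(31, 36))      # P23-P27 nose base
    + list(range(48, 68))      # P28-P47 outer + inner lip
    + list(range(27, 30))      # P48-P50 nose bridge
)

#: Auxiliary reference points retained from the dropped jaw contour.
AUX_MAP: Mapping[str, int] = {"chin": 8, "left_face_side": 0, "right_face_side": 16}

#: Named primary indices used throughout the geometry code.
LEFT_EYE_OUTER = 10
RIGHT_EYE_OUTER = 19

# relative tolerance (w.r.t. inter-corner distance) for "horizontally aligned"
TILT_TOLERANCE = 1e-6


class InvalidLandmarksError(ValueError):
    """Raised when a landmark container violates its structural contract."""


class DegenerateGeometryError(ValueError):
    """Raised when a geometric construction has no valid solution."""


def _as_points(points, n: int, what: str) -> np.ndarray:
    arr = np.asarray(points, dtype=float)
    if arr.shape != (n, 2):
        raise InvalidLandmarksError(
            f"{what} requires exactly {n} (x, y) points, got shape {arr.shape}"
        )
    if not np.all(np.isfinite(arr)):
        raise InvalidLandmarksError(f"{what} contains non-finite coordinates")
    return arr


@dataclasses.dataclass(frozen=True)
class RawLandmarks68:
    """An ordered 68-point landmark prediction in image pixels."""

    points: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", _as_points(self.points, N_RAW, "RawLandmarks68"))


@dataclasses.dataclass(frozen=True)
class LandmarkSet:
    """51 ordered primary points P0..P50 plus named auxiliary references.

    ``aux`` maps ``chin`` / ``left_face_side`` / ``right_face_side`` to (x, y)
    pairs in the same frame as ``points``.  ``tilt_corrected`` is set only by
    :func:`apply_transform` when the transform came from
    :func:`compute_tilt_transform`.
    """

    points: np.ndarray
    aux: dict[str, np.ndarray] = dataclasses.field(default_factory=dict)
    source_id: str = ""
    tilt_corrected: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", _as_points(self.points, N_PRIMARY, "LandmarkSet"))
        clean_aux = {}
        for name, p in self.aux.items():
            p = np.asarray(p, dtype=float)
            if p.shape != (2,) or not np.all(np.isfinite(p)):
                raise InvalidLandmarksError(f"auxiliary point {name!r} must be a finite (x, y)")
            clean_aux[name] = p
        object.__setattr__(self, "aux", clean_aux)
        if self.tilt_corrected:
            p10, p19 = self.points[LEFT_EYE_OUTER], self.points[RIGHT_EYE_OUTER]
            dist = float(np.hypot(*(p19 - p10)))
            if dist > 0 and abs(p10[1] - p19[1]) > 1e-5 * dist:
                raise InvalidLandmarksError(
                    "tilt_corrected set but outer eye corners are not horizontally aligned"
                )

    def replace(self, **kw) -> "LandmarkSet":
        return dataclasses.replace(self, **kw)

    @property
    def eye_corners(self) -> tuple[np.ndarray, np.ndarray]:
        return self.points[LEFT_EYE_OUTER], self.points[RIGHT_EYE_OUTER]

    @property
    def interocular(self) -> float:
        p10, p19 = self.eye_corners
        return float(np.hypot(*(p19 - p10)))


@dataclasses.dataclass(frozen=True)
class SimilarityTransform:
    """A 2x3 matrix whose linear block is a positively scaled rotation."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (2, 3) or not np.all(np.isfinite(m)):
            raise InvalidLandmarksError("transform matrix must be a finite 2x3 array")
        lin = m[:, :2]
        scale2 = float(np.linalg.det(lin))
        col_norms = np.linalg.norm(lin, axis=0)
        if scale2 <= 0:
            raise InvalidLandmarksError("linear block must have positive determinant")
        if abs(col_norms[0] - col_norms[1]) > 1e-9 * max(col_norms) or (
            abs(float(lin[:, 0] @ lin[:, 1])) > 1e-9 * col_norms[0] * col_norms[1]
        ):
            raise InvalidLandmarksError("linear block is not a uniform-scale rotation")
        object.__setattr__(self, "matrix", m)

    @property
    def scale(self) -> float:
        return float(np.sqrt(np.linalg.det(self.matrix[:, :2])))

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return pts @ self.matrix[:, :2].T + self.matrix[:, 2]

    @classmethod
    def rotation(cls, angle_rad: float, center=(0.0, 0.0)) -> "SimilarityTransform":
        """Rigid rotation by ``angle_rad`` (counter-clockwise in the y-down
        frame this package uses) about ``center``."""
        c, s = np.cos(angle_rad), np.sin(angle_rad)
        cx, cy = float(center[0]), float(center[1])
        rot = np.array([[c, -s], [s, c]])
        t = np.array([cx, cy]) - rot @ np.array([cx, cy])
        return cls(np.column_stack([rot, t]))

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))


def select_51(raw: RawLandmarks68) -> LandmarkSet:
    """Reindex a 68-point prediction into the 51 primary points.

    The 17 jaw-contour points are dropped; the chin and the two outermost
    jaw points survive as named auxiliaries so every face measure remains
    computable without the image.
    """
    if not isinstance(raw, RawLandmarks68):
        raw = RawLandmarks68(np.asarray(raw, dtype=float))
    pts = raw.points[list(SELECT_51_MAP)]
    aux = {name: raw.points[i].copy() for name, i in AUX_MAP.items()}
    return LandmarkSet(points=pts, aux=aux)


def compute_tilt_transform(lm: LandmarkSet) -> SimilarityTransform:
    """Pure rotation aligning the outer eye corners horizontally.

    The target corner positions keep the input midpoint and inter-corner
    distance, so the transform is rotation-only (unit scale).  Features are
    ratio based, which makes any scaling choice irrelevant; rotation is the
    minimal conformant transform.
    """
    p10, p19 = lm.eye_corners
    delta = p19 - p10
    if np.hypot(*delta) == 0.0:
        raise DegenerateGeometryError("outer eye corners coincide; tilt is undefined")
    angle = float(np.arctan2(delta[1], delta[0]))
    center = (p10 + p19) / 2.0
    return SimilarityTransform.rotation(-angle, center=center)


def apply_transform(lm: LandmarkSet, tf: SimilarityTransform) -> LandmarkSet:
    """Map every primary and auxiliary point by ``[x'; y'] = Tf @ [x; y; 1]``."""
    pts = tf(lm.points)
    aux = {name: tf(p)[0] for name, p in lm.aux.items()}
    y10, y19 = pts[LEFT_EYE_OUTER, 1], pts[RIGHT_EYE_OUTER, 1]
    dist = float(np.hypot(*(pts[RIGHT_EYE_OUTER] - pts[LEFT_EYE_OUTER])))
    corrected = dist > 0 and abs(y10 - y19) <= TILT_TOLERANCE * dist
    return lm.replace(points=pts, aux=aux, tilt_corrected=bool(corrected))


def tilt_correct(lm: LandmarkSet) -> LandmarkSet:
    """Convenience: compute and apply the tilt transform."""
    return apply_transform(lm, compute_tilt_transform(lm))


def rotate_landmarks(lm: LandmarkSet, angle_deg: float, center=None) -> LandmarkSet:
    """Rigid in-plane rotation used to create augmented copies.

    The result is never flagged ``tilt_corrected`` even for angle 0: the
    augmentation pipeline re-runs tilt correction on every copy.
    """
    if center is None:
        p10, p19 = lm.eye_corners
        center = (p10 + p19) / 2.0
    tf = SimilarityTransform.rotation(np.deg2rad(angle_deg), center=center)
    pts = tf(lm.points)
    aux = {name: tf(p)[0] for name, p in lm.aux.items()}
    return lm.replace(points=pts, aux=aux, tilt_corrected=False)


# --------------------------------------------------------------------------
# JSON interchange


def landmarks_to_dict(lm: LandmarkSet, label: int | None = None, grade: str | None = None,
                      subject: str | None = None) -> dict:
    d: dict = {
        "points": lm.points.tolist(),
        "aux": {k: v.tolist() for k, v in lm.aux.items()},
        "tilt_corrected": lm.tilt_corrected,
        "source_id": lm.source_id,
    }
    if label is not None:
        d["label"] = int(label)
    if grade is not None:
        d["grade"] = grade
    if subject is not None:
        d["subject"] = subject
    return d


def landmarks_from_dict(d: Mapping) -> LandmarkSet:
    try:
        points = d["points"]
    except KeyError as exc:
        raise InvalidLandmarksError("landmark record is missing 'points'") from exc
    return LandmarkSet(
        points=np.asarray(points, dtype=float),
        aux={k: np.asarray(v, dtype=float) for k, v in d.get("aux", {}).items()},
        source_id=str(d.get("source_id", "")),
        tilt_corrected=bool(d.get("tilt_corrected", False)),
    )


def dump_landmarks_json(records: list[dict], path: str | Path) -> None:
    Path(path).write_text(json.dumps(records, indent=1))


def load_landmarks_json(path: str | Path) -> list[dict]:
    raw = json.loads(Path(path).read_text())
    if not isinstance(raw, list):
        raise InvalidLandmarksError("landmark JSON must contain a list of records")
    for rec in raw:
        landmarks_from_dict(rec)  # validates counts/finiteness
    return raw
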