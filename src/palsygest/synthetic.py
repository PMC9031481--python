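"""Parametric synthetic faces: six posed gestures with a one-sided palsy model.

The generator exists so the whole pipeline is testable without restricted
clinical imagery.  A canonical, perfectly symmetric 51-point rest face (the
template) is deformed by per-gesture displacement fields; palsy is modeled
by (a) attenuating the displacement on the affected side by ``1 - severity``
and (b) a resting droop of the affected brow, lid, and mouth corner that
grows with severity.  Gaussian coordinate noise and a global head tilt are
applied last.  Everything is deterministic given the seed.

Displacement magnitudes are expressed in units of the template's
inter-ocular distance (outer eye corners 100 units apart), so generated
faces are scale-free.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .data import GestureDataset, GestureSample, PALSY_GRADES, Provenance
from .landmarks import LandmarkSet, rotate_landmarks

__all__ = [
    "FaceTemplate",
    "GestureParams",
    "MOVEMENT_NAMES",
    "GRADE_SEVERITY_BANDS",
    "default_template",
    "generate_face",
    "generate_movement",
    "generate_dataset",
]

#: The eight posed movements a subject performs, and how they group into the
#: six gesture classes: rest->0, eyebrow elevation->1, both eye-closure
#: efforts->2, full smile and lip depression->3, light smile->4 (or 3 when
#: it parts the lips beyond the threshold), pucker->5.
MOVEMENT_NAMES: tuple[str, ...] = (
    "rest",
    "eyebrow_elevation",
    "light_eye_closure",
    "full_eye_closure",
    "light_smile",
    "full_smile",
    "pucker",
    "lip_depression",
)

#: Severity interval sampled per palsy-grade annotation.
GRADE_SEVERITY_BANDS: dict[str, tuple[float, float]] = {
    "normal": (0.0, 0.05),
    "near-normal": (0.10, 0.25),
    "mild": (0.25, 0.45),
    "moderate": (0.45, 0.65),
    "severe": (0.65, 0.85),
    "complete": (0.85, 1.0),
}

_IDX = {
    "brows_left": list(range(0, 5)),
    "brows_right": list(range(5, 10)),
    "top_lids": [11, 12, 17, 18],
    "bottom_lids": [14, 15, 20, 21],
    "mouth": list(range(28, 48)),
    "outer_top": [29, 30, 31, 32, 33],
    "outer_bottom": [35, 36, 37, 38, 39],
    "inner_top": [41, 42, 43],
    "inner_bottom": [45, 46, 47],
    "corners": [28, 34, 40, 44],
    "left_corners": [28, 40],
    "right_corners": [34, 44],
}


def _template_points() -> tuple[np.ndarray, dict[str, np.ndarray]]:
    # Left half is authored; the right half is an exact mirror, so the
    # template is bilaterally symmetric by construction.
    left_brow = [(-55, -25), (-45, -30), (-35, -32), (-25, -30), (-15, -27)]
    left_eye = [(-50, 0), (-42, -5), (-28, -5), (-20, 0), (-28, 5), (-42, 5)]

    def mirror(pts):
        return [(-x, y) for x, y in pts]

    pts = np.zeros((51, 2))
    pts[0:5] = left_brow
    pts[5:10] = mirror(left_brow)[::-1]
    pts[10:16] = left_eye
    # right eye runs inner-corner -> top -> outer-corner -> bottom
    le = left_eye
    pts[16:22] = [(-le[3][0], le[3][1]), (-le[2][0], le[2][1]), (-le[1][0], le[1][1]),
                  (-le[0][0], le[0][1]), (-le[5][0], le[5][1]), (-le[4][0], le[4][1])]
    pts[22] = (0, 28)                                   # nose tip
    pts[23:28] = [(-12, 32), (-6, 34), (0, 35), (6, 34), (12, 32)]
    outer_left_top = [(-25, 60), (-13, 55), (-6, 53)]
    pts[28:31] = outer_left_top
    pts[31] = (0, 52)
    pts[32:35] = [(6, 53), (13, 55), (25, 60)]
    pts[35:38] = [(13, 66), (6, 68), (0, 69)]
    pts[38:40] = [(-6, 68), (-13, 66)]
    pts[40:44] = [(-19, 60), (-8, 58), (0, 57.5), (8, 58)]
    pts[44:48] = [(19, 60), (8, 62), (0, 62.5), (-8, 62)]
    pts[48:51] = [(0, -5), (0, 6), (0, 17)]             # nose bridge
    aux = {
        "chin": np.array([0.0, 95.0]),
        "left_face_side": np.array([-70.0, 10.0]),
        "right_face_side": np.array([70.0, 10.0]),
    }
    return pts, aux


@dataclasses.dataclass(frozen=True)
class FaceTemplate:
    """Canonical symmetric rest pose; inter-ocular distance is the unit."""

    points: np.ndarray
    aux: dict[str, np.ndarray]

    @property
    def interocular(self) -> float:
        return float(np.hypot(*(self.points[19] - self.points[10])))


def default_template() -> FaceTemplate:
    pts, aux = _template_points()
    return FaceTemplate(points=pts, aux=aux)


@dataclasses.dataclass(frozen=True)
class GestureParams:
    """Parameters of one generated frame.

    ``severity`` in [0, 1] attenuates gesture displacement on
    ``affected_side`` by ``1 - severity`` and drives the resting droop;
    0 means healthy.  ``intensity`` scales the gesture displacement field
    (light-effort variants use < 1).
    """

    gesture: int
    severity: float = 0.0
    affected_side: str = "left"
    noise_sd: float = 0.0
    seed: int = 0
    global_tilt_deg: float = 0.0
    intensity: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= int(self.gesture) <= 5):
            raise ValueError(f"gesture id must be 0..5, got {self.gesture}")
        if not (0.0 <= self.severity <= 1.0):
            raise ValueError("severity must be in [0, 1]")
        if self.affected_side not in ("left", "right"):
            raise ValueError("affected_side must be 'left' or 'right'")


# --------------------------------------------------------------------------
# displacement fields (y grows downward: negative dy moves a point up)


def _disp_rest(_: np.ndarray) -> np.ndarray:
    return np.zeros((51, 2))


def _disp_brow_elevation(_: np.ndarray) -> np.ndarray:
    d = np.zeros((51, 2))
    d[_IDX["brows_left"] + _IDX["brows_right"], 1] = -12.0
    # brow raise comes with a whole opening of the eyes
    d[_IDX["top_lids"], 1] = -2.0
    d[_IDX["bottom_lids"], 1] = 1.0
    return d


def _disp_eye_closure(_: np.ndarray) -> np.ndarray:
    d = np.zeros((51, 2))
    d[_IDX["top_lids"], 1] = 4.0     # lids converge; full effort leaves ~2 units
    d[_IDX["bottom_lids"], 1] = -4.0
    return d


def _disp_open_smile(_: np.ndarray) -> np.ndarray:
    d = np.zeros((51, 2))
    d[_IDX["left_corners"], 0] = -8.0
    d[_IDX["right_corners"], 0] = 8.0
    d[_IDX["corners"], 1] = -6.0
    d[_IDX["outer_top"], 1] = -2.0
    d[_IDX["outer_bottom"], 1] = 8.0
    d[_IDX["inner_top"], 1] = -2.0
    d[_IDX["inner_bottom"], 1] = 10.0   # lips part, teeth show
    return d


def _disp_lip_depression(_: np.ndarray) -> np.ndarray:
    d = np.zeros((51, 2))
    d[_IDX["left_corners"], 0] = -6.0
    d[_IDX["right_corners"], 0] = 6.0
    d[_IDX["corners"], 1] = -2.0
    d[_IDX["outer_bottom"], 1] = 11.0   # lower teeth shown
    d[_IDX["inner_bottom"], 1] = 12.0
    d[_IDX["inner_top"], 1] = -1.0
    return d


def _disp_closed_smile(_: np.ndarray) -> np.ndarray:
    d = np.zeros((51, 2))
    d[_IDX["left_corners"], 0] = -10.0
    d[_IDX["right_corners"], 0] = 10.0
    d[_IDX["corners"], 1] = -6.0
    d[_IDX["outer_top"], 1] = -1.0
    d[_IDX["outer_bottom"], 1] = -1.0   # lips stay together, stretch up a bit
    return d


def _disp_pucker(pts: np.ndarray) -> np.ndarray:
    d = np.zeros((51, 2))
    mouth = _IDX["mouth"]
    mouth_cx = 0.0
    d[mouth, 0] = -0.45 * (pts[mouth, 0] - mouth_cx)  # mouth narrows
    d[_IDX["outer_top"], 1] = -2.0                    # lips push out vertically
    d[_IDX["outer_bottom"], 1] = 2.0
    return d


#: gesture-class id -> canonical displacement field
_GESTURE_FIELDS = {
    0: _disp_rest,
    1: _disp_brow_elevation,
    2: _disp_eye_closure,
    3: _disp_open_smile,
    4: _disp_closed_smile,
    5: _disp_pucker,
}

#: movement name -> (field, gesture intensity)
_MOVEMENT_FIELDS = {
    "rest": (_disp_rest, 1.0),
    "eyebrow_elevation": (_disp_brow_elevation, 1.0),
    "light_eye_closure": (_disp_eye_closure, 0.9),  # lids meet gently, no squeeze
    "full_eye_closure": (_disp_eye_closure, 1.0),
    "light_smile": (_disp_closed_smile, 0.6),
    "full_smile": (_disp_open_smile, 1.0),
    "pucker": (_disp_pucker, 1.0),
    "lip_depression": (_disp_lip_depression, 1.0),
}


def _droop_field(severity: float) -> np.ndarray:
    """Resting asymmetry of a palsied hemiface, before side masking."""
    d = np.zeros((51, 2))
    d[_IDX["brows_left"] + _IDX["brows_right"], 1] = 6.0 * severity
    d[_IDX["top_lids"], 1] = 1.5 * severity
    d[_IDX["corners"], 1] = 5.0 * severity
    d[[28, 40], 0] = 3.0 * severity    # corners sag toward the midline
    d[[34, 44], 0] = -3.0 * severity
    return d


def _side_factors(template_pts: np.ndarray, affected_side: str,
                  factor: float) -> np.ndarray:
    """Per-point multiplier: ``factor`` on the affected side, 1 on the
    healthy side, their mean on midline points."""
    x = template_pts[:, 0]
    eps = 1e-9
    on_left = x < -eps
    on_right = x > eps
    affected = on_left if affected_side == "left" else on_right
    healthy = on_right if affected_side == "left" else on_left
    w = np.full(len(x), (1.0 + factor) / 2.0)
    w[affected] = factor
    w[healthy] = 1.0
    return w


def _realize(tpl: FaceTemplate, field, intensity: float, severity: float,
             affected_side: str, noise_sd: float, seed: int,
             tilt_deg: float, source_id: str,
             extra_displacement: np.ndarray | None = None) -> LandmarkSet:
    pts = tpl.points.copy()
    if extra_displacement is not None:
        pts += extra_displacement
    disp = field(tpl.points) * intensity
    w = _side_factors(tpl.points, affected_side, 1.0 - severity)
    pts += disp * w[:, None]
    droop = _droop_field(severity)
    x = tpl.points[:, 0]
    affected = x < 0 if affected_side == "left" else x > 0
    pts[affected] += droop[affected]
    aux = {k: v.copy() for k, v in tpl.aux.items()}

    rng = np.random.RandomState(seed)
    pts += rng.normal(0.0, noise_sd, size=pts.shape)
    for k in aux:
        aux[k] = aux[k] + rng.normal(0.0, noise_sd, size=2)

    lm = LandmarkSet(points=pts, aux=aux, source_id=source_id)
    if tilt_deg != 0.0:
        lm = rotate_landmarks(lm, tilt_deg)
    return lm


def generate_face(tpl: FaceTemplate, gp: GestureParams,
                  source_id: str = "") -> LandmarkSet:
    """Realize one gesture frame from the template under the palsy model."""
    field = _GESTURE_FIELDS[int(gp.gesture)]
    return _realize(tpl, field, gp.intensity, gp.severity, gp.affected_side,
                    gp.noise_sd, gp.seed, gp.global_tilt_deg, source_id)


def generate_movement(tpl: FaceTemplate, movement: str, *, severity: float = 0.0,
                      affected_side: str = "left", noise_sd: float = 0.0,
                      seed: int = 0, global_tilt_deg: float = 0.0,
                      amplitude: float = 1.0, source_id: str = "",
                      extra_displacement: np.ndarray | None = None) -> LandmarkSet:
    """Realize one of the eight posed movements (light/full effort variants)."""
    try:
        field, intensity = _MOVEMENT_FIELDS[movement]
    except KeyError as exc:
        raise ValueError(f"unknown movement {movement!r}") from exc
    return _realize(tpl, field, intensity * amplitude, severity, affected_side,
                    noise_sd, seed, global_tilt_deg, source_id,
                    extra_displacement=extra_displacement)


def movement_class(movement: str, lm: LandmarkSet,
                   open_threshold: float = 0.15) -> int:
    """Map a posed movement to its gesture class.

    The light smile is assigned by appearance: class 3 when the inner-lip
    opening exceeds ``open_threshold`` of the mouth width, else class 4.
    """
    fixed = {
        "rest": 0,
        "eyebrow_elevation": 1,
        "light_eye_closure": 2,
        "full_eye_closure": 2,
        "full_smile": 3,
        "lip_depression": 3,
        "pucker": 5,
    }
    if movement in fixed:
        return fixed[movement]
    if movement != "light_smile":
        raise ValueError(f"unknown movement {movement!r}")
    p = lm.points
    width = float(np.hypot(*(p[34] - p[28])))
    inner = max(float(np.hypot(*(p[41] - p[47]))), float(np.hypot(*(p[43] - p[45]))))
    return 3 if width > 0 and inner / width > open_threshold else 4


def generate_dataset(n_subjects: int, grades=None, movements: int = 8,
                     seed: int = 0, noise_sd: float = 0.3,
                     global_tilt_sd: float = 3.0, natural_asym_sd: float = 0.3,
                     open_threshold: float = 0.15) -> GestureDataset:
    """Generate ``n_subjects`` subjects, each performing the posed movements.

    Subjects cycle over ``grades`` (default: all six palsy-grade bands);
    severity is drawn uniformly from each subject's grade band and the
    affected side alternates.  Each subject also gets a fixed random
    *natural* facial asymmetry (sd ``natural_asym_sd`` units, shared by all
    of their frames) plus amplitude jitter, so subjects are mutually
    distinguishable and near-closed features behave like real faces.
    Deterministic given ``seed``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if grades is None:
        grades = list(PALSY_GRADES)
    rng = np.random.RandomState(seed)
    tpl = default_template()
    samples = []
    for i in range(n_subjects):
        subject = f"s{i:03d}"
        grade = grades[i % len(grades)]
        lo, hi = GRADE_SEVERITY_BANDS[grade]
        severity = float(rng.uniform(lo, hi))
        side = "left" if i % 2 == 0 else "right"
        amplitude = float(rng.uniform(0.85, 1.15))
        tilt = float(rng.normal(0.0, global_tilt_sd))
        natural = rng.normal(0.0, natural_asym_sd, size=(51, 2))
        for movement in MOVEMENT_NAMES[:movements]:
            frame_seed = int(rng.randint(0, 2**31 - 1))
            source_id = f"{subject}:{movement}"
            lm = generate_movement(
                tpl, movement, severity=severity, affected_side=side,
                noise_sd=noise_sd, seed=frame_seed, global_tilt_deg=tilt,
                amplitude=amplitude, source_id=source_id,
                extra_displacement=natural,
            )
            samples.append(
                GestureSample(
                    label=movement_class(movement, lm, open_threshold),
                    grade=grade,
                    subject=subject,
                    provenance=Provenance(source_id),
                    landmarks=lm,
                )
            )
    return GestureDataset(samples)
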