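import numpy as np
import pytest

from palsygest.landmarks import AUX_MAP, SELECT_51_MAP, RawLandmarks68, select_51, tilt_correct
from palsygest.synthetic import GestureParams, default_template, generate_face


@pytest.fixture(scope="session")
def template():
    return default_template()


@pytest.fixture()
def rest_face(template):
    """Perfectly symmetric rest-pose landmark set (no noise, no tilt)."""
    return generate_face(template, GestureParams(gesture=0))


@pytest.fixture()
def rest_face_corrected(rest_face):
    return tilt_correct(rest_face)


@pytest.fixture()
def raw68(template):
    """A synthetic 68-point prediction whose 51-selection reproduces the
    template: primary points scattered back to their 68 slots, jaw points
    filled in along a plausible contour."""
    pts68 = np.zeros((68, 2))
    pts68[list(SELECT_51_MAP)] = template.points
    # jaw contour: interpolate an arc through the three auxiliaries
    t = np.linspace(0.0, np.pi, 17)
    pts68[0:17, 0] = -70.0 * np.cos(t)
    pts68[0:17, 1] = 10.0 + 85.0 * np.sin(t)
    for name, idx in AUX_MAP.items():
        pts68[idx] = template.aux[name]
    return RawLandmarks68(pts68)


@pytest.fixture()
def random_landmark_sets(template):
    """100 noisy valid landmark sets for oracle-equivalence sweeps."""
    rng = np.random.RandomState(7)
    sets = []
    for i in range(100):
        gp = GestureParams(
            gesture=int(rng.randint(0, 6)),
            severity=float(rng.uniform(0, 1)),
            affected_side="left" if rng.rand() < 0.5 else "right",
            noise_sd=0.5,
            seed=int(rng.randint(0, 10_000)),
            global_tilt_deg=float(rng.uniform(-10, 10)),
        )
        sets.append(tilt_correct(generate_face(template, gp)))
    return sets
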