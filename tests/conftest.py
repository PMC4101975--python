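import numpy as np
import pytest

from cochleoplan import (
    LandmarkSet,
    PhantomSpec,
    build_cochlear_frame,
    end_to_end_recovery,
    generate_phantom,
)


@pytest.fixture(scope="session")
def default_phantom():
    """Noiseless default phantom (basal half-turn tube, no distractors)."""
    return generate_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def default_recovery(default_phantom):
    """Full pipeline run on the noiseless default phantom."""
    return end_to_end_recovery(default_phantom.spec, phantom=default_phantom)


@pytest.fixture(scope="session")
def distractor_recovery():
    """Full pipeline run with vestibule / coplanar / second-turn distractors."""
    return end_to_end_recovery(PhantomSpec(include_distractors=True))


@pytest.fixture
def axis_aligned_frame():
    """Identity-like frame: local axes coincide with the world axes."""
    lm = LandmarkSet(R=[5, 0, 0], C=[0, 0, 0], A=[0, 0, 4], I=[4, 0, 0], side="right")
    return build_cochlear_frame(lm)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (QR-based, seeded)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def random_landmarks(rng: np.random.Generator) -> LandmarkSet:
    """Random well-posed landmark set (right ear)."""
    c = rng.uniform(-10, 10, 3)
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    r = c + rng.uniform(2.0, 8.0) * u
    while True:
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        ang = np.degrees(np.arccos(np.clip(np.dot(u, v), -1, 1)))
        if 20.0 <= ang <= 160.0:
            break
    a = c + rng.uniform(2.0, 6.0) * v
    i = c + rng.uniform(0.5, 0.9) * (r - c)
    return LandmarkSet(R=r, C=c, A=a, I=i, side="right")
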