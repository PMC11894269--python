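import numpy as np
import pytest

from monsonsphere import (
    OcclusalFrame,
    SyntheticTruth,
    generate_dentition_mesh,
    generate_landmarks,
    read_repeated_radii,
    table1_fixture_path,
)

# Printed Table 2 summary rows: (mean, sd, n, median, ci_low, ci_high)
TABLE2 = {
    "males": (83.57, 13.12, 32, 80.35, 78.84, 88.29),
    "females": (71.13, 10.59, 32, 71.87, 67.31, 74.95),
    "total": (77.35, 13.38, 64, 75.36, 74.00, 80.69),
}


@pytest.fixture(scope="session")
def table1():
    return read_repeated_radii(table1_fixture_path())


@pytest.fixture(scope="session")
def noiseless_dentition():
    truth = SyntheticTruth(noise_sd=0.0, seed=0)
    lms, truth = generate_landmarks(truth)
    return lms, truth


@pytest.fixture(scope="session")
def noisy_dentition():
    truth = SyntheticTruth(noise_sd=0.1, seed=42)
    lms, truth = generate_landmarks(truth)
    return lms, truth


@pytest.fixture(scope="session")
def dentition_mesh():
    truth = SyntheticTruth(noise_sd=0.0, seed=0)
    mesh, apices = generate_dentition_mesh(truth)
    return mesh, apices, truth


@pytest.fixture(scope="session")
def occlusal_frame():
    return OcclusalFrame(axis=(0.0, 0.0, 1.0), origin=(0.0, 0.0, 0.0))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix via QR of a Gaussian matrix."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
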