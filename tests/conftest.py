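"""Shared fixtures: parameter table, synthetic complexes, cached FMO runs."""

import warnings

import numpy as np
import pytest

from qmregion import default_params, fmo1, fmo2, min_distance_profile, strip_guest
from qmregion.synth import gen_host_guest


@pytest.fixture(autouse=True)
def _quiet_scc_warnings():
    # Individual tests assert on convergence flags; the warnings themselves
    # would otherwise drown the report.
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def complex_fixture():
    """Default synthetic host-guest complex (seed 7)."""
    host, cplx, fmap, truth = gen_host_guest(seed=7)
    return host, cplx, fmap, truth


@pytest.fixture(scope="session")
def complex_runs(complex_fixture, params):
    """Converged apo/holo FMO1 runs + FMO2 pairs for the session complex."""
    _, cplx, fmap, _ = complex_fixture
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        host_s, host_m, kept = strip_guest(cplx, fmap)
        apo = fmo1(host_s, host_m, params)
        holo = fmo1(cplx, fmap, params)
        pairs = fmo2(holo)
    rmin = min_distance_profile(cplx, fmap)
    return {
        "apo": apo,
        "holo": holo,
        "pairs": pairs,
        "rmin": rmin,
        "kept": kept,
        "cplx": cplx,
        "fmap": fmap,
    }


def rigid_motion(coords: np.ndarray, seed: int = 0) -> np.ndarray:
    """Random proper rotation + translation (test helper)."""
    rng = np.random.default_rng(seed)
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    t = rng.uniform(-20, 20, 3)
    return coords @ q.T + t
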