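import numpy as np
import pytest

from dkireg.simulation import (NoiseModel, sample_plausible_substrates,
                               simulate_signals, study_scheme)
from dkireg.tensor_model import DKIParams, GradientScheme


@pytest.fixture(scope="session")
def scheme():
    """Study acquisition: b = 0 (x5), 0.5, 1, 2.5 ms/um^2, 30 dirs/shell."""
    return study_scheme()


@pytest.fixture(scope="session")
def substrates():
    """Small pool of plausible ground-truth substrates (deterministic)."""
    return sample_plausible_substrates(40, seed=101)


@pytest.fixture(scope="session")
def noisy_table(scheme, substrates):
    """(signals, ground-truth params) at SNR 30, one rep per substrate."""
    rng = np.random.default_rng(202)
    sigs = np.vstack([
        simulate_signals(s, scheme, NoiseModel(snr=30), rng=rng)
        for s in substrates])
    return sigs, [s.params() for s in substrates]


def random_valid_params(rng, log_s0=0.0):
    """One random well-conditioned DKIParams (positive-definite D, bounded
    W) for round-trip and invariance checks."""
    from dkireg.simulation import mixture_cumulants
    # an exact two-tensor Gaussian mixture always yields admissible (D, W)
    def rand_pd():
        a = rng.standard_normal((3, 3)) * 0.4
        return a @ a.T + np.eye(3) * rng.uniform(0.3, 1.2)
    f = rng.uniform(0.3, 0.7)
    dt, kt = mixture_cumulants([f, 1 - f], [rand_pd(), rand_pd()])
    return DKIParams(log_s0=log_s0, dt=dt, kt=kt)


def rotate_params(params: DKIParams, rot: np.ndarray) -> DKIParams:
    """Jointly rotate the diffusion and kurtosis tensors."""
    from dkireg.tensor_model import DT_INDICES, KT_INDICES
    d = rot @ params.d_matrix() @ rot.T
    w4 = kt_full_tensor(params.kt)
    w4r = np.einsum("ai,bj,ck,dl,ijkl->abcd", rot, rot, rot, rot, w4)
    dt = np.array([d[i, j] for i, j in DT_INDICES])
    kt = np.array([w4r[i, j, k, l] for i, j, k, l in KT_INDICES])
    return DKIParams(log_s0=params.log_s0, dt=dt, kt=kt)


def kt_full_tensor(kt: np.ndarray) -> np.ndarray:
    """Expand 15 unique kurtosis elements to the full (3,3,3,3) tensor."""
    from itertools import permutations
    from dkireg.tensor_model import KT_INDICES
    w = np.zeros((3, 3, 3, 3))
    for val, idx in zip(kt, KT_INDICES):
        for perm in set(permutations(idx)):
            w[perm] = val
    return w


def random_rotation(rng) -> np.ndarray:
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
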