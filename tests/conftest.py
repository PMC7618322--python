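import numpy as np
import pytest

from seqmotion import (FixtureSpec, extract_principal_components,
                       make_synthetic_collection, normalize_component,
                       superpose)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_collection():
    """Fully resolved synthetic collection with two planted motions."""
    spec = FixtureSpec(L=40, M=8, amplitudes=(2.0, 1.0), noise_sd=0.05,
                       seed=11)
    collection, planted = make_synthetic_collection(spec)
    return collection, planted


@pytest.fixture
def superposed_with_motions(small_collection):
    collection, planted = small_collection
    sup = superpose(collection)
    motions = extract_principal_components(sup, K=2)
    return sup, motions, planted


def random_motion_set(rng, L, K, normalised=True):
    comps = []
    for _ in range(K):
        v = rng.standard_normal((L, 3))
        comps.append(normalize_component(v) if normalised else v)
    return np.stack(comps, axis=1)


def random_orthogonal(rng, n=3, reflections=True):
    q, r = np.linalg.qr(rng.standard_normal((n, n)))
    q *= np.sign(np.diag(r))
    if reflections and rng.random() < 0.5:
        q[:, 0] *= -1
    elif not reflections and np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
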