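import numpy as np
import pytest

from hiergrad.io import ParcelAtlas
from hiergrad.synthetic import synth_atlas


@pytest.fixture
def toy_atlas() -> ParcelAtlas:
    """Six parcels: two per cortical hemisphere plus two subcortical."""
    c = 1 / np.sqrt(2)
    centroids = np.array([
        [-c, c, 0.0],
        [-c, 0.0, c],
        [c, c, 0.0],
        [c, 0.0, c],
        [np.nan] * 3,
        [np.nan] * 3,
    ])
    return ParcelAtlas(
        labels=np.array(["L1", "L2", "R1", "R2", "S1", "S2"], object),
        hemisphere=np.array(["L", "L", "R", "R", "SUBCORTICAL", "SUBCORTICAL"],
                            object),
        network=np.array(["VIS1", "DMN", "VIS1", "DMN", "SMM", "FPN"], object),
        centroids=centroids,
    )


@pytest.fixture(scope="session")
def atlas100() -> ParcelAtlas:
    return synth_atlas(100, seed=7)


def oracle_diffusion_embed(W: np.ndarray, alpha: float, k: int):
    """Independent dense reference: generalized eigenproblem
    W' v = lam D1 v solved directly (scipy.linalg.eigh with the D1 mass
    matrix), components returned unit-norm.  Kept free of any code from
    hiergrad.gradients."""
    import scipy.linalg

    d = W.sum(axis=1)
    Wp = W / np.outer(d**alpha, d**alpha)
    d1 = Wp.sum(axis=1)
    evals, evecs = scipy.linalg.eigh(Wp, np.diag(d1))
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    comps = evecs[:, 1 : k + 1]
    comps = comps / np.linalg.norm(comps, axis=0)
    return evals[1 : k + 1], comps


def brute_force_bh(p: np.ndarray, q: float):
    """Textbook step-up rule, written independently of the package:
    reject H_(1..i*) where i* = max{i : p_(i) <= q i/m}; adjusted value
    q_i = min_{j >= i} m p_(j) / j (capped at 1)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ps = p[order]
    thresh = q * np.arange(1, m + 1) / m
    below = np.flatnonzero(ps <= thresh)
    reject_sorted = np.zeros(m, bool)
    if below.size:
        reject_sorted[: below[-1] + 1] = True
    adj_sorted = np.minimum.accumulate((m * ps / np.arange(1, m + 1))[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    reject = np.zeros(m, bool)
    adjusted = np.zeros(m)
    reject[order] = reject_sorted
    adjusted[order] = adj_sorted
    return adjusted, reject
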