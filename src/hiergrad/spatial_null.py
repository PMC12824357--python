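"""Spin-test spatial permutation for parcel maps on the sphere.

A random rotation is applied to the left-hemisphere parcel centroids and
its x-mirrored image to the right hemisphere; each cortical parcel then
takes the value of the parcel whose original centroid is nearest (great
circle) to its rotated position, within hemisphere.  This permutes map
values with replacement while preserving spatial autocorrelation.
Subcortical parcels have no spherical coordinates and are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation
from scipy import stats

from .errors import ConfigError, DegenerateDataError, GeometryError
from .io import ParcelAtlas

_MIRROR = np.diag([-1.0, 1.0, 1.0])


@dataclass(frozen=True)
class RotationSet:
    """Proper rotations (n_perm, 3, 3) for the left hemisphere; the right
    hemisphere uses the mirrored rotation M R M, M = diag(-1, 1, 1)."""

    matrices: np.ndarray
    seed: int

    def __post_init__(self):
        R = np.asarray(self.matrices, float)
        eye = np.einsum("nij,nkj->nik", R, R)
        if not np.allclose(eye, np.eye(3), atol=1e-10):
            raise ConfigError("rotation matrices are not orthogonal")
        if not np.allclose(np.linalg.det(R), 1.0, atol=1e-10):
            raise ConfigError("rotation determinant != +1")
        object.__setattr__(self, "matrices", R)

    def __len__(self) -> int:
        return self.matrices.shape[0]

    @property
    def mirrored(self) -> np.ndarray:
        return _MIRROR @ self.matrices @ _MIRROR


@dataclass(frozen=True)
class SpinResult:
    """Observed correlation against its rotation null."""

    r_obs: float
    null_r: np.ndarray
    p: float
    n_perm: int
    criterion: str  # 'percentile_95' (one-sided on r) or 'two_sided'


def random_rotations(n_perm: int, seed: int) -> RotationSet:
    """Uniform (Haar) random proper rotations, reproducible from seed."""
    rng = np.random.default_rng(seed)
    R = Rotation.random(n_perm, rng=rng).as_matrix()
    return RotationSet(matrices=R, seed=seed)


def _hemisphere_indices(atlas: ParcelAtlas) -> dict[str, np.ndarray]:
    out = {}
    for hemi in ("L", "R"):
        idx = np.flatnonzero(atlas.hemisphere == hemi)
        if idx.size:
            out[hemi] = idx
    if not out:
        raise GeometryError("atlas has no cortical parcels")
    return out


def spin_permutations(atlas: ParcelAtlas, rotations: RotationSet) -> np.ndarray:
    """Source-parcel index per permutation, shape (n_perm, N).

    Entry (k, i) is the parcel whose value parcel i receives under
    rotation k; subcortical entries are -1.
    """
    n_perm = len(rotations)
    n = atlas.n_parcels
    perm = np.full((n_perm, n), -1, dtype=np.int64)
    for hemi, idx in _hemisphere_indices(atlas).items():
        C = atlas.centroids[idx]                       # (m, 3) unit vectors
        R = rotations.matrices if hemi == "L" else rotations.mirrored
        rotated = np.einsum("nij,mj->nmi", R, C)       # (n_perm, m, 3)
        # nearest original centroid by max cosine == min great-circle dist
        cos = np.einsum("nmi,ki->nmk", rotated, C)     # (n_perm, m, m)
        nearest = np.argmax(cos, axis=2)               # (n_perm, m)
        perm[:, idx] = idx[nearest]
    return perm


def spin_map(x: np.ndarray, atlas: ParcelAtlas, rotation: np.ndarray) -> np.ndarray:
    """Apply one rotation to a parcel map.  Cortical parcels take the value
    of the nearest original centroid after rotation; subcortical entries
    are set to NaN (dropped from any correlation)."""
    rset = RotationSet(matrices=np.asarray(rotation, float)[None], seed=-1)
    perm = spin_permutations(atlas, rset)[0]
    x = np.asarray(x, float)
    out = np.full(atlas.n_parcels, np.nan)
    cort = perm >= 0
    out[cort] = x[perm[cort]]
    return out


def spin_test(
    x: np.ndarray,
    y: np.ndarray,
    atlas: ParcelAtlas,
    n_perm: int = 10000,
    seed: int = 0,
    criterion: str = "percentile_95",
) -> SpinResult:
    """Spatial correlation of two parcel maps against a rotation null.

    ``x`` is spun against the fixed ``y`` (the asymmetry is intentional
    and documented).  The observed statistic is the Pearson r over
    cortical parcels.  The default criterion is one-sided on r
    (significant when r exceeds the 95th percentile of the null), with
    p = (1 + #{null >= r_obs}) / (1 + n_perm); ``two_sided`` uses |r|.
    """
    if criterion not in ("percentile_95", "two_sided"):
        raise ConfigError(f"unknown criterion '{criterion}'")
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1")
    if n_perm < 100:
        import warnings

        warnings.warn(f"n_perm={n_perm} gives a coarse null; use >= 100")
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    cort = atlas.is_cortical
    xc, yc = x[cort], y[cort]
    if xc.std() == 0 or yc.std() == 0:
        raise DegenerateDataError("constant map on cortical parcels")
    r_obs = float(np.corrcoef(xc, yc)[0, 1])

    rotations = random_rotations(n_perm, seed)
    perm = spin_permutations(atlas, rotations)[:, cort]   # (n_perm, m)
    spun = x[perm]                                        # values with replacement
    sx = (spun - spun.mean(axis=1, keepdims=True))
    sx_sd = sx.std(axis=1)
    yz = (yc - yc.mean()) / yc.std()
    with np.errstate(divide="ignore", invalid="ignore"):
        null_r = (sx @ yz) / (len(yc) * sx_sd)
    null_r = np.where(sx_sd > 0, null_r, 0.0)

    if criterion == "percentile_95":
        p = (1 + int(np.sum(null_r >= r_obs))) / (1 + n_perm)
    else:
        p = (1 + int(np.sum(np.abs(null_r) >= abs(r_obs)))) / (1 + n_perm)
    return SpinResult(r_obs=r_obs, null_r=null_r, p=float(p),
                      n_perm=n_perm, criterion=criterion)


def pearson_map_correlation(x, y, atlas) -> tuple[float, float]:
    """Naive (non-spatial) Pearson correlation over cortical parcels, for
    comparison with the spin test."""
    cort = atlas.is_cortical
    r, p = stats.pearsonr(np.asarray(x, float)[cort], np.asarray(y, float)[cort])
    return float(r), float(p)
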