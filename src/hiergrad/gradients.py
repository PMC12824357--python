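"""Connectivity gradients: connectome -> sparsified cosine affinity ->
diffusion-map embedding -> template construction and alignment.

The embedding follows the diffusion-map construction: the affinity W is
density-normalized as ``W' = D^-alpha W D^-alpha`` (D the row-sum diagonal
of W, anisotropy exponent alpha), row-normalized to a Markov transition
matrix P, and eigendecomposed.  The trivial constant eigenvector
(eigenvalue 1) is discarded; the next ``n_components`` eigenvectors,
each scaled by its eigenvalue (diffusion time t = 1 convention), are the
connectivity gradients.  Everything downstream is invariant to any
positive per-component rescaling; the scaling convention is recorded in
the result's provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg
from scipy.sparse.csgraph import connected_components
from scipy.sparse import csr_matrix

from .errors import (
    ConfigError,
    ConnectivityError,
    DegenerateDataError,
    ShapeError,
)
from .io import ParcelTimeSeries, SessionMeta

#: eigenvalue-degeneracy flagging tolerance
_DEGEN_TOL = 1e-10


@dataclass(frozen=True)
class Connectome:
    """N x N Pearson correlation matrix for one scan."""

    matrix: np.ndarray
    meta: SessionMeta | None = None

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ShapeError(f"connectome must be square, got {m.shape}")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ShapeError("connectome is not symmetric")
        if np.abs(m).max() > 1 + 1e-9:
            raise ShapeError("correlation entries outside [-1, 1]")
        if not np.allclose(np.diag(m), 1.0, atol=1e-9):
            raise ShapeError("connectome diagonal is not 1")
        object.__setattr__(self, "matrix", (m + m.T) / 2.0)

    @property
    def n_parcels(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class AffinityMatrix:
    """Cosine similarities of row-sparsified connectivity profiles."""

    matrix: np.ndarray
    density: float

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ShapeError(f"affinity must be square, got {m.shape}")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ShapeError("affinity is not symmetric")
        if m.min() < -1e-12 or m.max() > 1 + 1e-9:
            raise ShapeError("affinity entries outside [0, 1]")
        object.__setattr__(self, "matrix", np.clip((m + m.T) / 2.0, 0.0, 1.0))

    @property
    def n_parcels(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class GradientSet:
    """Embedding components (columns, descending eigenvalue) for one scan.

    ``components[:, i]`` is the i-th non-trivial diffusion coordinate,
    unit-norm then scaled by its eigenvalue.  ``degenerate`` flags
    component indices involved in near-equal eigenvalue pairs.
    """

    components: np.ndarray
    eigenvalues: np.ndarray
    alpha: float
    density: float
    scaling: str = "eigenvalue"
    degenerate: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))

    @property
    def n_components(self) -> int:
        return self.components.shape[1]


@dataclass(frozen=True)
class GradientTemplate:
    """Group-level principal and secondary gradient templates."""

    principal: np.ndarray
    secondary: np.ndarray
    source: str = "group-average connectome"

    def __post_init__(self):
        p = np.asarray(self.principal, float)
        s = np.asarray(self.secondary, float)
        if p.std() == 0 or s.std() == 0:
            raise DegenerateDataError("template gradient is constant")
        r = np.corrcoef(p, s)[0, 1]
        if abs(r) >= 1 - 1e-12:
            raise DegenerateDataError("principal and secondary templates collinear")
        object.__setattr__(self, "principal", p)
        object.__setattr__(self, "secondary", s)


@dataclass(frozen=True)
class AlignedGradients:
    """Template-matched principal and secondary gradients for one scan."""

    principal: np.ndarray
    secondary: np.ndarray
    match_r: tuple[float, float]
    sign_flipped: tuple[bool, bool]
    source_component_index: tuple[int, int]
    low_match_warning: bool = False
    meta: SessionMeta | None = None


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def build_connectome(ts: ParcelTimeSeries | np.ndarray,
                     meta: SessionMeta | None = None) -> Connectome:
    """Pearson correlation matrix across parcels for one scan."""
    if isinstance(ts, ParcelTimeSeries):
        data, meta = ts.data, ts.meta
    else:
        data = np.asarray(ts, float)
        if data.var(axis=1).min() == 0:
            raise DegenerateDataError("constant timeseries row")
    c = np.corrcoef(data)
    np.fill_diagonal(c, 1.0)
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    return Connectome(matrix=c, meta=meta)


def sparsify_rows(matrix: np.ndarray, density: float) -> np.ndarray:
    """Per row, keep the k = round(density*(N-1)) largest strictly positive
    off-diagonal entries and zero everything else (fewer if fewer positives
    exist).  Ties at the retention boundary are broken by dropping the
    larger column index first.  The result is generally asymmetric; the
    diagonal is zeroed (it is never counted against the retention budget).
    """
    if not (0 < density <= 1):
        raise ConfigError(f"density must be in (0, 1], got {density}")
    m = np.asarray(matrix, float).copy()
    n = m.shape[0]
    np.fill_diagonal(m, 0.0)
    k = int(round(density * (n - 1)))
    k = max(k, 1)
    out = np.zeros_like(m)
    for i in range(n):
        row = m[i]
        pos = np.flatnonzero(row > 0)
        if pos.size == 0:
            raise DegenerateDataError(
                f"row {i} has no positive off-diagonal entries"
            )
        # descending value, ascending column index on ties
        order = pos[np.lexsort((pos, -row[pos]))]
        keep = order[:k]
        out[i, keep] = row[keep]
    return out


def affinity_from_connectome(conn: Connectome | np.ndarray,
                             density: float = 0.10) -> AffinityMatrix:
    """Sparsify each connectivity profile, then take pairwise cosine
    similarity of the sparsified rows.  Cosine of row profiles restores
    symmetry; entries land in [0, 1] because retained entries are
    positive."""
    matrix = conn.matrix if isinstance(conn, Connectome) else np.asarray(conn, float)
    sparse = sparsify_rows(matrix, density)
    norms = np.linalg.norm(sparse, axis=1)
    if np.any(norms == 0):
        raise DegenerateDataError("sparsified row with zero norm")
    unit = sparse / norms[:, None]
    aff = unit @ unit.T
    np.fill_diagonal(aff, 1.0)
    return AffinityMatrix(matrix=np.clip((aff + aff.T) / 2, 0.0, 1.0),
                          density=density)


def diffusion_embed(aff: AffinityMatrix | np.ndarray,
                    alpha: float = 0.5,
                    n_components: int = 10,
                    scaling: str = "dt0") -> GradientSet:
    """Diffusion-map embedding of an affinity matrix.

    Uses the symmetric reformulation: with ``W' = D^-a W D^-a`` and
    ``D1 = rowsum(W')``, the Markov matrix ``P = D1^-1 W'`` is similar to
    the symmetric ``S = D1^-1/2 W' D1^-1/2``, so eigenvalues are real by
    construction.  Components are the non-trivial right eigenvectors of P
    normalized against the stationary eigenvector (``v_k / v_0``
    elementwise, i.e. unit norm under the stationary distribution),
    scaled per the ``scaling`` convention:

    * ``"dt0"`` (default) — ``lambda / (1 - lambda)``, the diffusion-time-0
      convention of the reference embedding implementation.  This keeps
      the component amplitude sensitive to the spectral gap, which is what
      carries gradient-range compression.
    * ``"eigenvalue"`` — ``lambda`` (diffusion time t = 1).

    The convention used is recorded in the result's provenance.
    """
    if scaling not in ("dt0", "eigenvalue"):
        raise ConfigError(f"unknown scaling convention '{scaling}'")
    if isinstance(aff, AffinityMatrix):
        W, density = aff.matrix, aff.density
    else:
        W, density = np.asarray(aff, float), float("nan")
    n = W.shape[0]
    if n_components > n - 1:
        raise ConfigError(
            f"n_components={n_components} exceeds N-1={n - 1}"
        )
    ncomp_graph, labels = connected_components(csr_matrix(W != 0), directed=False)
    if ncomp_graph > 1:
        sizes = np.bincount(labels)
        raise ConnectivityError(
            f"affinity graph has {ncomp_graph} components (sizes {sizes.tolist()})"
        )
    d = W.sum(axis=1)
    if np.any(d <= 0):
        raise DegenerateDataError("all-zero affinity row; embedding refused")
    Wp = W / np.outer(d**alpha, d**alpha)
    d1 = Wp.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d1)
    S = Wp * np.outer(inv_sqrt, inv_sqrt)
    S = (S + S.T) / 2.0
    evals, evecs = scipy.linalg.eigh(S)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # drop the trivial stationary eigenvector (eigenvalue 1)
    lam = evals[1 : n_components + 1]
    if np.any(lam <= 0) or np.any(lam >= 1):
        raise DegenerateDataError(
            f"requested eigenvalues outside (0, 1): {lam.min():.3g}..{lam.max():.3g}"
        )
    # right eigenvectors of P via v / v0 elementwise (stationary-weighted
    # unit norm) — the reference implementation's normalization
    v0 = evecs[:, 0]
    if np.any(v0 == 0):
        raise DegenerateDataError("zero entry in the stationary eigenvector")
    v0 = v0 * np.sign(v0[np.argmax(np.abs(v0))])
    psi = evecs[:, 1 : n_components + 1] / v0[:, None]
    weight = lam / (1.0 - lam) if scaling == "dt0" else lam
    components = psi * weight[None, :]
    gaps = np.abs(np.diff(evals[: n_components + 2]))
    degen = np.zeros(n_components, bool)
    for i in range(n_components):
        # component i corresponds to evals[i+1]; flag near-equal neighbors
        if gaps[i] < _DEGEN_TOL or (i + 1 < len(gaps) and gaps[i + 1] < _DEGEN_TOL):
            degen[i] = True
    return GradientSet(
        components=components,
        eigenvalues=lam,
        alpha=alpha,
        density=density,
        scaling=scaling,
        degenerate=degen,
    )


def markov_matrix(aff: AffinityMatrix | np.ndarray, alpha: float = 0.5) -> np.ndarray:
    """The row-stochastic transition matrix the embedding diagonalizes
    (exposed for verification)."""
    W = aff.matrix if isinstance(aff, AffinityMatrix) else np.asarray(aff, float)
    d = W.sum(axis=1)
    Wp = W / np.outer(d**alpha, d**alpha)
    return Wp / Wp.sum(axis=1)[:, None]


def _orient(vec: np.ndarray) -> tuple[np.ndarray, bool]:
    """Deterministic sign: the largest-magnitude entry is made positive."""
    i = int(np.argmax(np.abs(vec)))
    if vec[i] < 0:
        return -vec, True
    return vec, False


def build_templates(connectomes: Sequence[Connectome],
                    density: float = 0.10,
                    alpha: float = 0.5,
                    n_components: int = 10) -> GradientTemplate:
    """Group templates: element-wise mean connectome, then the same
    affinity + embedding procedure; components 1 and 2 become the
    principal and secondary templates, deterministically oriented."""
    if len(connectomes) < 2:
        raise ConfigError("need at least 2 connectomes for a template")
    n = connectomes[0].n_parcels
    for c in connectomes:
        if c.n_parcels != n:
            raise ShapeError("mixed parcel counts across connectomes")
    mean = np.mean([c.matrix for c in connectomes], axis=0)
    np.fill_diagonal(mean, 1.0)
    gset = diffusion_embed(
        affinity_from_connectome(mean, density),
        alpha=alpha,
        n_components=min(n_components, n - 1),
    )
    principal, _ = _orient(gset.components[:, 0])
    secondary, _ = _orient(gset.components[:, 1])
    return GradientTemplate(principal=principal, secondary=secondary)


def align_gradients(gset: GradientSet,
                    templates: GradientTemplate,
                    floor: float = 0.1,
                    meta: SessionMeta | None = None) -> AlignedGradients:
    """Greedy template matching without replacement.

    The principal template first claims the component with the largest
    |Pearson r|; the secondary template claims the best remaining one.
    A claimed component is sign-flipped when its correlation with its
    template is negative.  A |r| below ``floor`` sets a warning flag
    (never an error).
    """
    if gset.n_components < 2:
        raise ConfigError("need at least 2 components to align")
    comps = gset.components
    k = comps.shape[1]
    r_p = np.array([np.corrcoef(templates.principal, comps[:, j])[0, 1]
                    for j in range(k)])
    j_p = int(np.argmax(np.abs(r_p)))
    remaining = [j for j in range(k) if j != j_p]
    r_s = np.array([np.corrcoef(templates.secondary, comps[:, j])[0, 1]
                    for j in remaining])
    j_s = remaining[int(np.argmax(np.abs(r_s)))]
    rp = r_p[j_p]
    rs = np.corrcoef(templates.secondary, comps[:, j_s])[0, 1]
    principal = comps[:, j_p] * (np.sign(rp) or 1.0)
    secondary = comps[:, j_s] * (np.sign(rs) or 1.0)
    return AlignedGradients(
        principal=principal,
        secondary=secondary,
        match_r=(abs(float(rp)), abs(float(rs))),
        sign_flipped=(rp < 0, rs < 0),
        source_component_index=(j_p, j_s),
        low_match_warning=bool(min(abs(rp), abs(rs)) < floor),
        meta=meta,
    )


def embed_scan(ts: ParcelTimeSeries | np.ndarray,
               density: float = 0.10,
               alpha: float = 0.5,
               n_components: int = 10,
               meta: SessionMeta | None = None) -> GradientSet:
    """Convenience: timeseries -> connectome -> affinity -> gradients."""
    conn = build_connectome(ts, meta=meta)
    return diffusion_embed(
        affinity_from_connectome(conn, density),
        alpha=alpha,
        n_components=n_components,
    )
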