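"""Synthetic cohorts with known ground truth.

Every generator is a pure function of (config, seed) and stores enough
ground truth to score downstream recovery:

* ``synth_atlas`` — quasi-uniform spherical parcellation (Fibonacci
  lattice), ~10% subcortical parcels without centroids, 12 network
  labels assigned by latent-position bands.
* ``synth_cohort`` — paired-condition connectome cohorts with a planted
  one-dimensional hierarchy: parcel latent positions h, population
  connectome C_ij = exp(-|h_i - h_j| / l), condition-specific latent
  spread (compression = spread ratio), subject-level affine jitter,
  independent noise per scan.
* ``synth_targets`` — scalar targets linearly coupled to gradient maps
  with a chosen signal fraction (for PLS recovery).
* ``synth_smooth_map`` — Gaussian random fields on the sphere with a
  great-circle covariance kernel (for spin-test calibration).
* ``synth_ref_tac`` — gamma-variate reference TAC on the 22-frame /
  60-min schedule (for kinetic-model recovery).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ConfigError, DegenerateDataError
from .io import NETWORKS, ParcelAtlas, ParcelTimeSeries, SessionMeta
from .pet_kinetics import TAC, raclopride_frames


@dataclass(frozen=True)
class SynthConfig:
    """Cohort-generator parameters.

    Defaults mirror the study conditions: 438 parcels, 471 timepoints per
    scan, 3 scans per condition, paired PL/MP design with the MP latent
    spread at 60% of PL (the planted compression), timeseries noise
    sigma = 0.05.
    """

    seed: int
    n_parcels: int = 438
    n_subjects: int = 38
    n_scans_per_condition: int = 3
    n_timepoints: int = 471
    latent_spread_pl: float = 1.0
    latent_spread_mp: float = 0.6
    length_scale: float = 0.5
    transverse_weight: float = 0.4
    noise_sigma: float = 0.05
    subject_scale_sd: float = 0.05
    subject_shift_sd: float = 0.05
    subject_jitter_sd: float = 0.02
    smoothness: float = 0.5

    def validate(self) -> "SynthConfig":
        if self.latent_spread_pl <= 0 or self.latent_spread_mp <= 0:
            raise ConfigError("latent spreads must be > 0")
        if self.length_scale <= 0:
            raise ConfigError("length_scale must be > 0")
        if self.n_parcels < 6:
            raise ConfigError("n_parcels must be >= 6")
        return self


@dataclass(frozen=True)
class GroundTruth:
    """Everything needed to score recovery of the planted structure."""

    latent_base: np.ndarray            # (N,) parcel latent positions u
    latents: dict                      # condition -> (S, N) subject latents h
    transverse: np.ndarray             # (N, 3) fixed weighted local geometry
    subject_scale: np.ndarray
    subject_shift: np.ndarray
    planted_ratio: float               # latent_spread_mp / latent_spread_pl
    config: SynthConfig


@dataclass(frozen=True)
class SynthCohort:
    atlas: ParcelAtlas
    sessions: list[SessionMeta]
    timeseries: list[ParcelTimeSeries]
    ground_truth: GroundTruth


# ---------------------------------------------------------------------------
# atlas
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack([
        np.sin(phi) * np.cos(theta),
        np.sin(phi) * np.sin(theta),
        np.cos(phi),
    ])


def synth_atlas(n_parcels: int = 438, seed: int = 0) -> ParcelAtlas:
    """Quasi-uniform spherical atlas.

    Cortical centroids are a Fibonacci lattice randomly rotated by the
    seed; hemisphere is the sign of x.  About 10% of parcels are flagged
    SUBCORTICAL without centroids.  The 12 network labels are assigned by
    bands of the latent (z) coordinate.
    """
    if n_parcels < 6:
        raise ConfigError(f"n_parcels must be >= 6, got {n_parcels}")
    rng = np.random.default_rng(seed)
    n_sub = int(round(0.1 * n_parcels))
    n_cort = n_parcels - n_sub
    if n_cort < 12:
        raise ConfigError(
            f"{n_cort} cortical parcels cannot cover 12 networks"
        )
    pts = _fibonacci_sphere(n_cort) @ Rotation.random(rng=rng).as_matrix().T
    hemi_c = np.where(pts[:, 0] > 0, "R", "L").astype(object)
    # networks from z-bands (the latent axis used by the cohort generator)
    band = np.minimum((np.argsort(np.argsort(pts[:, 2])) * 12) // n_cort, 11)
    net_c = np.array([NETWORKS[b] for b in band], object)

    labels = np.array(
        [f"CTX_{h}_{i:03d}" for i, h in enumerate(hemi_c)]
        + [f"SUB_{i:03d}" for i in range(n_sub)], object
    )
    hemi = np.concatenate([hemi_c, np.full(n_sub, "SUBCORTICAL", object)])
    net = np.concatenate(
        [net_c, np.array([NETWORKS[i % 12] for i in range(n_sub)], object)]
    )
    cen = np.vstack([pts, np.full((n_sub, 3), np.nan)])
    return ParcelAtlas(labels=labels, hemisphere=hemi, network=net, centroids=cen)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

_RACE_LEVELS = ("black", "other", "white")


def _synth_covariates(rng: np.random.Generator) -> dict:
    return {
        "age": float(rng.uniform(22, 64)),
        "sex": str(rng.choice(["F", "M"])),
        "race": str(rng.choice(_RACE_LEVELS)),
        "bmi": float(rng.normal(26, 4)),
        "iq": float(rng.normal(110, 12)),
    }


def latent_kernel(h: np.ndarray, length_scale: float,
                  transverse: np.ndarray | None = None) -> np.ndarray:
    """Population connectome implied by the planted geometry.

    With only the hierarchy axis h: C_ij = exp(-|h_i - h_j| / l).  With
    transverse coordinates (fixed local geometry, already weighted), the
    distance is the Euclidean combination
    sqrt(|h_i - h_j|^2 + |v_i - v_j|^2).  The transverse part is what
    makes a change in hierarchy spread visible to a fixed-density
    sparsification: it reallocates each parcel's strongest edges between
    along-hierarchy and local neighbors.
    """
    dh2 = (h[:, None] - h[None, :]) ** 2
    if transverse is not None:
        dv = transverse[:, None, :] - transverse[None, :, :]
        dh2 = dh2 + np.einsum("ijk,ijk->ij", dv, dv)
    return np.exp(-np.sqrt(dh2) / length_scale)


def _timeseries_from_kernel(K: np.ndarray, n_timepoints: int,
                            noise_sigma: float,
                            rng: np.random.Generator) -> np.ndarray:
    n = K.shape[0]
    L = np.linalg.cholesky(K + 1e-10 * np.eye(n))
    data = L @ rng.standard_normal((n, n_timepoints))
    if noise_sigma > 0:
        data = data + noise_sigma * rng.standard_normal((n, n_timepoints))
    return data


def synth_cohort(config: SynthConfig,
                 atlas: ParcelAtlas | None = None) -> SynthCohort:
    """Paired-condition cohort with a planted 1-D hierarchy.

    Parcel latents: cortical parcels use their centroid z coordinate,
    subcortical parcels draw uniform latents; subjects apply a small
    affine perturbation (scale, shift) plus parcel-level jitter; each
    condition rescales the latents by its spread.  Each scan is an
    independent realization of a Gaussian process with the implied
    exponential-kernel covariance plus white noise.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    if atlas is None:
        atlas = synth_atlas(config.n_parcels, seed=rng.integers(2**31))
    n = atlas.n_parcels
    # raw axis: centroid z for cortical parcels, uniform draws subcortical;
    # then rank-uniform onto an even grid in [-1, 1] so the planted
    # hierarchy is gap-free (a density gap wider than the sparsification
    # neighborhood would disconnect the affinity graph)
    raw = np.where(
        atlas.is_cortical,
        np.nan_to_num(atlas.centroids[:, 2]),
        0.0,
    )
    n_sub_parcels = int((~atlas.is_cortical).sum())
    raw[~atlas.is_cortical] = rng.uniform(-1, 1, n_sub_parcels)
    u = np.empty(n)
    u[np.argsort(raw)] = np.linspace(-1.0, 1.0, n)
    # fixed transverse (local) geometry: the sphere centroid, weighted;
    # subcortical parcels get seeded pseudo-coordinates on the same sphere
    V = atlas.centroids.copy()
    if n_sub_parcels:
        P = rng.standard_normal((n_sub_parcels, 3))
        V[~atlas.is_cortical] = P / np.linalg.norm(P, axis=1, keepdims=True)
    V = V * config.transverse_weight

    S = config.n_subjects
    scale = 1.0 + config.subject_scale_sd * rng.standard_normal(S)
    shift = config.subject_shift_sd * rng.standard_normal(S)
    jitter = config.subject_jitter_sd * rng.standard_normal((S, n))

    spreads = {"PL": config.latent_spread_pl, "MP": config.latent_spread_mp}
    latents = {c: np.empty((S, n)) for c in spreads}
    sessions: list[SessionMeta] = []
    timeseries: list[ParcelTimeSeries] = []
    for s in range(S):
        cov = _synth_covariates(rng)
        for cond, spread in spreads.items():
            h = spread * (scale[s] * (u + jitter[s]) + shift[s])
            latents[cond][s] = h
            K = latent_kernel(h, config.length_scale, transverse=V)
            for scan in range(1, config.n_scans_per_condition + 1):
                meta = SessionMeta(
                    subject_id=f"sub{s:03d}", condition=cond, scan_index=scan,
                    covariates=cov, fd=float(abs(rng.normal(0.118, 0.04))),
                )
                data = _timeseries_from_kernel(
                    K, config.n_timepoints, config.noise_sigma, rng
                )
                timeseries.append(ParcelTimeSeries(data=data, meta=meta))
                sessions.append(meta)
    gt = GroundTruth(
        latent_base=u, latents=latents, transverse=V, subject_scale=scale,
        subject_shift=shift,
        planted_ratio=config.latent_spread_mp / config.latent_spread_pl,
        config=config,
    )
    return SynthCohort(atlas=atlas, sessions=sessions,
                       timeseries=timeseries, ground_truth=gt)


# ---------------------------------------------------------------------------
# scalar targets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TargetTruth:
    weights: np.ndarray
    signal_r2: float
    noise_sd: float


def synth_targets(X: np.ndarray,
                  weights: np.ndarray | None = None,
                  signal_r2: float = 0.5,
                  seed: int = 0,
                  n_support: int | None = None) -> tuple[np.ndarray, TargetTruth]:
    """Scalar targets linearly coupled to subject gradient maps.

    y = X w + eps, with eps scaled so the planted population R^2 equals
    ``signal_r2`` (noise-free when signal_r2 == 1).  Weights default to
    standard normal, optionally supported on ``n_support`` parcels.
    """
    X = np.asarray(X, float)
    rng = np.random.default_rng(seed)
    n, p = X.shape
    if weights is None:
        weights = rng.standard_normal(p)
        if n_support is not None:
            mask = np.zeros(p, bool)
            mask[rng.choice(p, size=n_support, replace=False)] = True
            weights = np.where(mask, weights, 0.0)
    weights = np.asarray(weights, float)
    if len(weights) != p:
        raise ConfigError("weights length must match parcel count")
    signal = X @ weights
    sig_var = signal.var(ddof=0)
    if sig_var == 0 and signal_r2 == 1:
        raise DegenerateDataError("all-zero signal with zero noise")
    if not (0 < signal_r2 <= 1):
        raise ConfigError("signal_r2 must be in (0, 1]")
    noise_sd = float(np.sqrt(sig_var * (1 - signal_r2) / signal_r2))
    y = signal + noise_sd * rng.standard_normal(n)
    return y, TargetTruth(weights=weights, signal_r2=signal_r2,
                          noise_sd=noise_sd)


def synth_scalar_targets(cohort: SynthCohort, signal_r2: float = 0.7,
                         seed: int = 0):
    """Striatal receptor-availability tables coupled to the planted
    hierarchy (putamen rows; D2R(MP) plants a 10-20% reduction).

    D1R couples to the hierarchy axis itself (a smooth structured
    weighting, the regime PLS can recover from gradient maps); D2R(PL)
    uses unstructured weights (a mostly idiosyncratic target).
    """
    from .io import ScalarTargets
    import pandas as pd

    rng = np.random.default_rng(seed)
    X = cohort.ground_truth.latents["PL"]       # (S, N) subject latent maps
    subjects = sorted({s.subject_id for s in cohort.sessions})
    y1, _ = synth_targets(X, weights=cohort.ground_truth.latent_base,
                          signal_r2=signal_r2, seed=int(rng.integers(2**31)))
    y2, _ = synth_targets(X, signal_r2=signal_r2, seed=int(rng.integers(2**31)))
    z1 = (y1 - y1.mean()) / y1.std()
    z2 = (y2 - y2.mean()) / y2.std()
    d1r = np.maximum(2.0 + 0.5 * z1, 0.1)
    d2r_pl = np.maximum(2.5 + 0.4 * z2, 0.1)
    d2r_mp = d2r_pl * (1 - rng.uniform(0.10, 0.20, len(subjects)))
    return ScalarTargets(pd.DataFrame({
        "subject_id": subjects, "roi": "putamen",
        "d1r_bpnd": d1r, "d2r_bpnd_pl": d2r_pl, "d2r_bpnd_mp": d2r_mp,
    }))


def write_cohort(cohort: SynthCohort, out_dir, timeseries_format: str = "npy",
                 targets: "object | None" = None) -> None:
    """Write a generated cohort to disk in the study's input layout:
    atlas.tsv, sessions.tsv, timeseries/<subject>_<cond>_<scan>.<ext>,
    ground_truth.tsv (latent base per parcel), optionally targets.tsv."""
    from pathlib import Path

    import pandas as pd

    from .io import save_atlas, save_sessions, save_targets, write_matrix

    out = Path(out_dir)
    (out / "timeseries").mkdir(parents=True, exist_ok=True)
    save_atlas(cohort.atlas, out / "atlas.tsv")
    save_sessions(cohort.sessions, out / "sessions.tsv")
    for ts in cohort.timeseries:
        m = ts.meta
        name = f"{m.subject_id}_{m.condition}_{m.scan_index}.{timeseries_format}"
        write_matrix(ts.data, out / "timeseries" / name)
    pd.DataFrame({
        "label": cohort.atlas.labels,
        "latent": cohort.ground_truth.latent_base,
    }).to_csv(out / "ground_truth.tsv", sep="\t", index=False)
    if targets is not None:
        save_targets(targets, out / "targets.tsv")


# ---------------------------------------------------------------------------
# smooth spherical maps
# ---------------------------------------------------------------------------

def smooth_map_cholesky(atlas: ParcelAtlas, smoothness: float) -> np.ndarray:
    """Cholesky factor of the great-circle exponential kernel over cortical
    centroids (precompute once when drawing many maps)."""
    if smoothness <= 0:
        raise ConfigError("smoothness must be > 0")
    C = atlas.centroids[atlas.is_cortical]
    if len(C) == 0:
        raise ConfigError("atlas has no cortical centroids")
    cos = np.clip(C @ C.T, -1.0, 1.0)
    theta = np.arccos(cos)
    K = np.exp(-theta / smoothness)
    return np.linalg.cholesky(K + 1e-8 * np.eye(len(C)))


def synth_smooth_map(atlas: ParcelAtlas, smoothness: float = 0.5,
                     seed: int = 0,
                     cholesky: np.ndarray | None = None) -> np.ndarray:
    """Gaussian field on the sphere with covariance exp(-angle/smoothness);
    subcortical entries are NaN."""
    if cholesky is None:
        cholesky = smooth_map_cholesky(atlas, smoothness)
    rng = np.random.default_rng(seed)
    vals = cholesky @ rng.standard_normal(cholesky.shape[0])
    out = np.full(atlas.n_parcels, np.nan)
    out[atlas.is_cortical] = vals
    return out


# ---------------------------------------------------------------------------
# reference TAC
# ---------------------------------------------------------------------------

def synth_ref_tac(seed: int = 0,
                  amplitude: float = 20.0,
                  shape: float = 0.7,
                  t_peak: float = 12.0,
                  jitter: float = 0.0,
                  dt: float = 0.01) -> TAC:
    """Gamma-variate reference TAC, frame-averaged onto the 22-frame /
    60-min raclopride schedule:

        C(t) = A (t/tp)^a exp(a (1 - t/tp))

    The default shape/peak give a cerebellum-like curve that clears to
    ~20% of peak by scan end (a pure gamma with an early sharp peak would
    decay to numerical zero within the window).  ``jitter`` (fractional)
    randomizes amplitude/shape/peak via the seed.
    """
    if amplitude <= 0 or shape <= 0 or t_peak <= 0:
        raise ConfigError("gamma-variate parameters must be > 0")
    if jitter:
        rng = np.random.default_rng(seed)
        amplitude *= 1 + jitter * rng.uniform(-1, 1)
        shape *= 1 + jitter * rng.uniform(-1, 1)
        t_peak *= 1 + jitter * rng.uniform(-1, 1)
    mids, durations = raclopride_frames()
    t_end = float(mids[-1] + durations[-1] / 2)
    tg = np.arange(0.0, t_end + dt, dt)
    cg = amplitude * (tg / t_peak) ** shape * np.exp(shape * (1 - tg / t_peak))
    activity = np.array([
        cg[(tg >= m - d / 2 - 1e-12) & (tg <= m + d / 2 + 1e-12)].mean()
        for m, d in zip(mids, durations)
    ])
    return TAC(mids, durations, activity)


# ---------------------------------------------------------------------------
# gradient-level panel (for the group-statistics tests)
# ---------------------------------------------------------------------------

def synth_gradient_panel(
    n_subjects: int = 38,
    n_parcels: int = 50,
    n_scans_per_condition: int = 3,
    effect: np.ndarray | float = 0.0,
    subject_sd: float = 1.0,
    scan_sd: float = 1.0,
    seed: int = 0,
    covariates: bool = True,
) -> tuple[np.ndarray, list[SessionMeta]]:
    """Scan-level gradient values with a planted MP - PL effect.

    value[scan, parcel] = subject_intercept + effect * 1[MP] + noise,
    subject intercepts N(0, subject_sd^2) per (subject, parcel), noise
    N(0, scan_sd^2) per scan.  ``effect`` may be scalar or length-N.
    """
    rng = np.random.default_rng(seed)
    eff = np.broadcast_to(np.asarray(effect, float), (n_parcels,))
    u = subject_sd * rng.standard_normal((n_subjects, n_parcels))
    rows, sessions = [], []
    for s in range(n_subjects):
        cov = _synth_covariates(rng) if covariates else {}
        for cond in ("PL", "MP"):
            for scan in range(1, n_scans_per_condition + 1):
                val = u[s] + (eff if cond == "MP" else 0.0) \
                    + scan_sd * rng.standard_normal(n_parcels)
                rows.append(val)
                sessions.append(SessionMeta(
                    subject_id=f"sub{s:03d}", condition=cond,
                    scan_index=scan, covariates=cov,
                    fd=float(abs(rng.normal(0.118, 0.04))),
                ))
    return np.vstack(rows), sessions
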