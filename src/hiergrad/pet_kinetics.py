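"""Reference-tissue kinetic modeling of PET time-activity curves.

Implements the simplified reference tissue model (SRTM; parameters R1,
k2, BPnd) with a basis-function fit, Logan graphical analysis with a
reference-region input (slope = DVR), and the dopamine-increase score
delta_DA = BPnd(PL) - BPnd(MP).  Under the reference-tissue assumptions
DVR = BPnd + 1, which the test suite verifies on simulated curves.

Frames are assumed decay-corrected; activities are in arbitrary but
consistent concentration units (e.g. kBq/mL), times in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import minimize_scalar
from scipy.signal import fftconvolve

from .errors import ConfigError, FitError, FormatError, ShapeError

#: fine-grid step (minutes) for convolution of the SRTM forward model
_DT = 0.01


@dataclass(frozen=True)
class TAC:
    """Time-activity curve: frame mid-times and durations (min), activity."""

    frame_mid_times: np.ndarray
    frame_durations: np.ndarray
    activity: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.frame_mid_times, float)
        d = np.asarray(self.frame_durations, float)
        a = np.asarray(self.activity, float)
        if not (len(t) == len(d) == len(a)):
            raise ShapeError("TAC fields must have equal length")
        if np.any(np.diff(t) <= 0):
            raise FormatError("frame mid-times must be strictly increasing")
        if np.any(t < 0) or np.any(d <= 0):
            raise FormatError("times must be >= 0 and durations > 0")
        object.__setattr__(self, "frame_mid_times", t)
        object.__setattr__(self, "frame_durations", d)
        object.__setattr__(self, "activity", a)

    @property
    def n_frames(self) -> int:
        return len(self.frame_mid_times)

    @property
    def end_time(self) -> float:
        return float(self.frame_mid_times[-1] + self.frame_durations[-1] / 2)


def read_tac(path: str | Path) -> TAC:
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    missing = {"time_min", "duration_min", "activity"} - set(df.columns)
    if missing:
        raise FormatError(f"TAC table missing columns: {sorted(missing)}")
    return TAC(df["time_min"].to_numpy(float), df["duration_min"].to_numpy(float),
               df["activity"].to_numpy(float))


def write_tac(tac: TAC, path: str | Path) -> None:
    pd.DataFrame({
        "time_min": tac.frame_mid_times,
        "duration_min": tac.frame_durations,
        "activity": tac.activity,
    }).to_csv(path, sep="\t", index=False, float_format="%.17g")


def raclopride_frames() -> tuple[np.ndarray, np.ndarray]:
    """The 22-frame / 60-min schedule: 6x0.5, 4x1, 4x2, 4x5, 4x6.25 min.
    Returns (mid-times, durations)."""
    durations = np.concatenate([
        np.full(6, 0.5), np.full(4, 1.0), np.full(4, 2.0),
        np.full(4, 5.0), np.full(4, 6.25),
    ])
    ends = np.cumsum(durations)
    mids = ends - durations / 2
    return mids, durations


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def _fine_grid(tac: TAC, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-linear continuous curve through (0, 0) and the frame
    mid-time samples, on a uniform grid covering the scan."""
    t_end = tac.end_time
    tg = np.arange(0.0, t_end + dt, dt)
    cg = np.interp(tg, np.concatenate([[0.0], tac.frame_mid_times]),
                   np.concatenate([[0.0], tac.activity]))
    return tg, cg


def _frame_masks(tg: np.ndarray, mids: np.ndarray,
                 durations: np.ndarray) -> list[np.ndarray]:
    return [np.flatnonzero((tg >= m - d / 2 - 1e-12) & (tg <= m + d / 2 + 1e-12))
            for m, d in zip(mids, durations)]


def _frame_average(values: np.ndarray, masks: list[np.ndarray]) -> np.ndarray:
    return np.array([values[m].mean() for m in masks])


def _convolve_exp(cg: np.ndarray, theta: float, dt: float) -> np.ndarray:
    """(cg * exp(-theta t))(t) on the uniform grid, trapezoid weights."""
    kernel = np.exp(-theta * np.arange(len(cg)) * dt)
    out = fftconvolve(cg, kernel)[: len(cg)] * dt
    # trapezoid end-correction for the two rectangle ends
    out -= 0.5 * dt * (cg * kernel[0] + cg[0] * kernel)
    return out


def simulate_srtm_tac(ref: TAC, r1: float, k2: float, bpnd: float,
                      dt: float = _DT) -> TAC:
    """SRTM forward model.

    target(t) = R1 * ref(t) + (k2 - R1 * k2a) * (ref conv exp(-k2a t)),
    k2a = k2 / (1 + BPnd); computed on a fine grid then frame-averaged to
    the reference frame schedule.
    """
    if k2 <= 0:
        raise ConfigError(f"k2 must be > 0, got {k2}")
    if 1 + bpnd <= 0:
        raise ConfigError(f"1 + BPnd must be > 0, got BPnd={bpnd}")
    if r1 <= 0:
        raise ConfigError(f"R1 must be > 0, got {r1}")
    k2a = k2 / (1.0 + bpnd)
    tg, cg = _fine_grid(ref, dt)
    conv = _convolve_exp(cg, k2a, dt)
    target_fine = r1 * cg + (k2 - r1 * k2a) * conv
    masks = _frame_masks(tg, ref.frame_mid_times, ref.frame_durations)
    return TAC(ref.frame_mid_times.copy(), ref.frame_durations.copy(),
               _frame_average(target_fine, masks))


# ---------------------------------------------------------------------------
# SRTM basis-function fit
# ---------------------------------------------------------------------------

class SRTMBasis:
    """Precomputed convolution bases for one reference curve and k2a grid.

    Reusable across many target fits against the same reference — the
    expensive convolutions depend only on the reference."""

    def __init__(self, ref: TAC, k2a_grid: np.ndarray | None = None,
                 dt: float = _DT):
        if k2a_grid is None:
            k2a_grid = np.logspace(np.log10(0.01), np.log10(1.0), 100)
        self.ref = ref
        self.dt = dt
        self.k2a_grid = np.asarray(k2a_grid, float)
        self._tg, self._cg = _fine_grid(ref, dt)
        self._masks = _frame_masks(self._tg, ref.frame_mid_times,
                                   ref.frame_durations)
        self.bases = np.column_stack(
            [self.basis_at(th) for th in self.k2a_grid]
        )  # (n_frames, n_basis)

    def basis_at(self, k2a: float) -> np.ndarray:
        return _frame_average(_convolve_exp(self._cg, k2a, self.dt), self._masks)


@dataclass(frozen=True)
class SRTMFit:
    bpnd: float
    r1: float
    k2: float
    residual_rms: float
    k2a: float
    boundary_warning: bool


def _srtm_linear(ref_act: np.ndarray, basis: np.ndarray, y: np.ndarray):
    A = np.column_stack([ref_act, basis])
    coef, rss_arr, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < 2:
        return None
    rss = float(rss_arr[0]) if rss_arr.size else float(((A @ coef - y) ** 2).sum())
    return rss, coef


def fit_srtm(target: TAC, ref: TAC | None = None,
             basis: SRTMBasis | None = None,
             dt: float = _DT) -> SRTMFit:
    """Basis-function SRTM fit.

    For each k2a on a grid (default 100 log-spaced in [0.01, 1] /min) the
    model is linear in (R1, phi = k2 - R1*k2a); the best gridpoint is
    then refined by a bounded 1-D search between its neighbors.
    BPnd = k2/k2a - 1.
    """
    if basis is None:
        if ref is None:
            raise ConfigError("provide either ref or a precomputed basis")
        basis = SRTMBasis(ref, dt=dt)
    ref = basis.ref
    if target.n_frames < 10:
        raise FitError(f"need >= 10 frames, got {target.n_frames}")
    if not np.allclose(target.frame_mid_times, ref.frame_mid_times):
        raise FitError("target and reference frame times do not overlap")
    y = target.activity
    grid = basis.k2a_grid
    results = [(_srtm_linear(ref.activity, basis.bases[:, j], y), grid[j])
               for j in range(len(grid))]
    valid = [(res[0], k2a, res[1]) for res, k2a in results if res is not None]
    if not valid:
        raise FitError("all basis functions produced singular designs")
    rss_best, k2a_best, coef_best = min(valid, key=lambda v: v[0])
    j = int(np.argmin(np.abs(grid - k2a_best)))
    lo = grid[max(j - 1, 0)]
    hi = grid[min(j + 1, len(grid) - 1)]

    def objective(log_k2a):
        res = _srtm_linear(ref.activity, basis.basis_at(np.exp(log_k2a)), y)
        return res[0] if res is not None else np.inf

    if hi > lo:
        opt = minimize_scalar(objective, bounds=(np.log(lo), np.log(hi)),
                              method="bounded", options={"xatol": 1e-10})
        k2a_ref = float(np.exp(opt.x))
        res = _srtm_linear(ref.activity, basis.basis_at(k2a_ref), y)
        if res is not None and res[0] <= rss_best:
            rss_best, k2a_best, coef_best = res[0], k2a_ref, res[1]
    r1, phi = coef_best
    k2 = phi + r1 * k2a_best
    bpnd = k2 / k2a_best - 1.0
    if bpnd < -0.5 or not np.isfinite(bpnd):
        raise FitError(f"BPnd={bpnd:.3g} outside sanity bound (>= -0.5)")
    boundary = bool(k2a_best <= grid[0] * 1.0001 or k2a_best >= grid[-1] * 0.9999)
    return SRTMFit(bpnd=float(bpnd), r1=float(r1), k2=float(k2),
                   residual_rms=float(np.sqrt(rss_best / target.n_frames)),
                   k2a=float(k2a_best), boundary_warning=boundary)


# ---------------------------------------------------------------------------
# Logan reference-region graphical analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LoganFit:
    dvr: float
    t_star: float
    r_squared: float
    n_frames_used: int
    k2_ref_used: bool


def logan_dvr(target: TAC, ref: TAC, t_star: float = 20.0,
              k2_ref: float | None = None) -> LoganFit:
    """Logan reference-tissue analysis: OLS slope of

        int_0^t C_t / C_t(t)  on  [int_0^t C_r + C_r(t)/k2_ref] / C_t(t)

    over frames with mid-time >= t_star.  With the correct reference
    clearance k2_ref the relation is exactly linear for one-tissue
    kinetics and the slope is the DVR (= BPnd + 1).  Without k2_ref the
    clearance term is omitted (logged caveat: slope is then biased for
    fast-clearing references).
    """
    if not (0 <= t_star <= target.end_time):
        raise ConfigError(f"t_star={t_star} outside the scan window")
    t = target.frame_mid_times
    # running integrals: linear rise from (0, 0) to the first mid-time,
    # then trapezoid across mid-times
    int_t = cumulative_trapezoid(target.activity, t, initial=0.0) \
        + 0.5 * t[0] * target.activity[0]
    int_r = cumulative_trapezoid(ref.activity, t, initial=0.0) \
        + 0.5 * t[0] * ref.activity[0]
    if np.any(np.diff(int_r) < 0) or np.any(np.diff(int_t) < 0):
        raise FormatError("nonmonotone running integrals (negative activity?)")
    sel = t >= t_star
    if sel.sum() < 4:
        raise ConfigError(
            f"only {int(sel.sum())} frames after t_star={t_star}; need >= 4"
        )
    ct = target.activity[sel]
    if np.any(ct == 0):
        raise FormatError("zero target activity in the Logan window")
    yv = int_t[sel] / ct
    xr = int_r[sel]
    if k2_ref is not None:
        if k2_ref <= 0:
            raise ConfigError("k2_ref must be > 0")
        xr = xr + ref.activity[sel] / k2_ref
    else:
        import warnings

        warnings.warn("Logan fit without k2_ref: reference-clearance term "
                      "omitted; slope may be biased")
    xv = xr / ct
    A = np.column_stack([xv, np.ones_like(xv)])
    coef, _, _, _ = np.linalg.lstsq(A, yv, rcond=None)
    fitted = A @ coef
    ss_res = float(((yv - fitted) ** 2).sum())
    ss_tot = float(((yv - yv.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    dvr = float(coef[0])
    if dvr <= 0:
        raise FitError(f"nonpositive DVR {dvr:.3g}")
    return LoganFit(dvr=dvr, t_star=float(t_star), r_squared=float(r2),
                    n_frames_used=int(sel.sum()), k2_ref_used=k2_ref is not None)


def dopamine_increase(bp_pl: float, bp_mp: float, percent: bool = False) -> float:
    """delta_DA = BPnd(PL) - BPnd(MP); percent mode reports
    100 * (PL - MP) / PL."""
    if not (np.isfinite(bp_pl) and np.isfinite(bp_mp)):
        raise FormatError("BPnd values must be finite")
    if bp_pl < 0 or bp_mp < 0:
        raise FormatError("BPnd values must be >= 0")
    if percent:
        if bp_pl == 0:
            raise ZeroDivisionError("percent mode undefined for BPnd(PL) = 0")
        return 100.0 * (bp_pl - bp_mp) / bp_pl
    return bp_pl - bp_mp
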