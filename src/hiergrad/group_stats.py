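"""Group-level statistics on aligned gradients.

Covers the paired drug contrast (random-intercept LME per parcel), the
covariate-adjusted two-group contrast, Benjamini-Hochberg FDR, and the
gradient-compression summary (range narrowing, cross-condition
correlation, per-network shifts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateDataError, FormatError, ModelError
from .io import NETWORKS, ParcelAtlas, SessionMeta
from .lmm import fit_random_intercept


@dataclass(frozen=True)
class ContrastResult:
    """Per-parcel condition/group contrast with FDR control.

    ``table`` columns: estimate (MP - PL in gradient units), t, df,
    cohens_d, p, q, significant (and label/network when an atlas was
    supplied).
    """

    table: pd.DataFrame
    model: str
    covariates: tuple[str, ...]
    q_level: float

    @property
    def t(self) -> np.ndarray:
        return self.table["t"].to_numpy()

    @property
    def p(self) -> np.ndarray:
        return self.table["p"].to_numpy()

    @property
    def q(self) -> np.ndarray:
        return self.table["q"].to_numpy()

    @property
    def significant(self) -> np.ndarray:
        return self.table["significant"].to_numpy()


@dataclass(frozen=True)
class CompressionSummary:
    """Range narrowing of the cohort-mean principal gradient."""

    range_pl: tuple[float, float]
    range_mp: tuple[float, float]
    range_ratio: float
    cross_condition_r: float
    network_shift: pd.DataFrame  # columns: network, mean_shift


def normalize_gradient(vec: np.ndarray) -> np.ndarray:
    """Z-score a gradient across parcels within one scan."""
    vec = np.asarray(vec, float)
    sd = vec.std(ddof=0)
    if sd == 0:
        raise DegenerateDataError("cannot normalize a constant gradient")
    return (vec - vec.mean()) / sd


def bh_fdr(p: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns (adjusted values, rejection mask at level ``q``).  Adjusted
    values are monotone nondecreasing in p and bounded by 1.
    """
    p = np.asarray(p, float)
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise FormatError("p-values must lie in [0, 1]")
    reject, qvals, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return qvals, reject


# ---------------------------------------------------------------------------
# design-matrix construction
# ---------------------------------------------------------------------------

def _is_numeric(values: list) -> bool:
    try:
        np.asarray(values, dtype=float)
        return True
    except (TypeError, ValueError):
        return False


def build_covariate_columns(
    rows: pd.DataFrame, covariates: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    """Continuous covariates centered; categorical covariates one-hot with
    the first (sorted) level dropped as reference."""
    cols, names = [], []
    for cov in covariates:
        if cov not in rows.columns:
            raise FormatError(f"covariate '{cov}' missing from metadata")
        vals = rows[cov].tolist()
        if _is_numeric(vals):
            x = np.asarray(vals, float)
            if np.isnan(x).any():
                raise FormatError(f"covariate '{cov}' has missing values")
            cols.append(x - x.mean())
            names.append(cov)
        else:
            levels = sorted(set(map(str, vals)))
            for lev in levels[1:]:
                cols.append(np.asarray([1.0 if str(v) == lev else 0.0 for v in vals]))
                names.append(f"{cov}[{lev}]")
    if not cols:
        return np.empty((len(rows), 0)), []
    return np.column_stack(cols), names


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        _, R = np.linalg.qr(X)
        bad = [names[i] for i in range(X.shape[1])
               if abs(R[i, i]) < 1e-10 * max(1.0, abs(R[0, 0]))]
        raise ModelError(f"singular design; collinear columns: {bad or names}")


# ---------------------------------------------------------------------------
# paired (drug) contrast
# ---------------------------------------------------------------------------

def parcelwise_drug_contrast(
    values: np.ndarray,
    sessions: Sequence[SessionMeta],
    covariates: Sequence[str] = (),
    q: float = 0.05,
    atlas: ParcelAtlas | None = None,
) -> ContrastResult:
    """Per-parcel MP-vs-PL contrast with a subject random intercept.

    ``values`` is scans x parcels (one row per session, aligned gradient
    values).  For each parcel the model
    ``gradient ~ condition + covariates + (1 | subject)`` is fit by
    REML; the Wald t for the condition term (MP coded 1) is reported with
    residual-method degrees of freedom, and Cohen's d is the paired d of
    per-subject condition means.  Subjects missing a condition are
    excluded with a warning.
    """
    values = np.asarray(values, float)
    if values.shape[0] != len(sessions):
        raise FormatError("one row of values per session is required")
    meta = pd.DataFrame(
        [{"subject_id": s.subject_id, "condition": s.condition,
          **{k: s.covariates.get(k) for k in covariates}} for s in sessions]
    )
    if not set(meta["condition"]) <= {"PL", "MP"}:
        raise FormatError("conditions must be PL or MP")
    conds = meta.groupby("subject_id")["condition"].agg(lambda c: set(c))
    complete = conds[conds == {"PL", "MP"}].index
    dropped = sorted(set(meta["subject_id"]) - set(complete))
    if dropped:
        warnings.warn(f"excluding subjects missing a condition: {dropped}")
    keep = meta["subject_id"].isin(complete).to_numpy()
    meta, values = meta[keep].reset_index(drop=True), values[keep]
    if meta["subject_id"].nunique() < 2:
        raise ModelError("need at least 2 complete subjects")

    cond = (meta["condition"] == "MP").to_numpy(float)
    covX, covnames = build_covariate_columns(meta, covariates)
    X = np.column_stack([np.ones(len(meta)), cond, covX])
    names = ["intercept", "condition[MP]"] + covnames
    _check_rank(X, names)
    groups = meta["subject_id"].to_numpy()

    n_parcels = values.shape[1]
    est = np.empty(n_parcels)
    tval = np.empty(n_parcels)
    dfv = np.empty(n_parcels)
    for j in range(n_parcels):
        fit = fit_random_intercept(values[:, j], X, groups, tuple(names))
        est[j], tval[j], dfv[j] = fit.params[1], fit.tvalues[1], fit.df_resid
    pvals = 2 * stats.t.sf(np.abs(tval), dfv)

    # paired Cohen's d from per-subject condition means
    dfw = pd.DataFrame(values)
    dfw["subject_id"], dfw["condition"] = meta["subject_id"], meta["condition"]
    means = dfw.groupby(["subject_id", "condition"]).mean()
    diffs = (means.xs("MP", level="condition") -
             means.xs("PL", level="condition")).to_numpy()
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cohens_d = np.where(sd > 0, diffs.mean(axis=0) / sd, 0.0)

    qvals, reject = bh_fdr(pvals, q)
    table = pd.DataFrame(
        {"estimate": est, "t": tval, "df": dfv, "cohens_d": cohens_d,
         "p": pvals, "q": qvals, "significant": qvals < q}
    )
    if atlas is not None:
        table.insert(0, "label", atlas.labels)
        table.insert(1, "network", atlas.network)
    return ContrastResult(table=table, model="lme_random_intercept",
                          covariates=tuple(covariates), q_level=q)


# ---------------------------------------------------------------------------
# two-group (covariate-adjusted) contrast
# ---------------------------------------------------------------------------

def two_group_contrast(
    values: np.ndarray,
    groups: Sequence[str],
    covariates_table: pd.DataFrame | None = None,
    covariates: Sequence[str] = (),
    q: float = 0.05,
    p_uncorrected: float | None = None,
    atlas: ParcelAtlas | None = None,
) -> ContrastResult:
    """Per-parcel ANCOVA-style group contrast (OLS, vectorized).

    ``values`` is subjects x parcels; ``groups`` has exactly two levels,
    the lexicographically later one coded 1.  With ``p_uncorrected`` set
    (e.g. 0.001), significance uses the uncorrected threshold instead of
    FDR, mirroring large-cohort validation analyses.
    """
    values = np.asarray(values, float)
    groups = np.asarray([str(g) for g in groups], object)
    levels = sorted(set(groups.tolist()))
    if len(levels) != 2:
        raise FormatError(f"exactly 2 group levels required, got {levels}")
    if np.sum(groups == levels[0]) == 0 or np.sum(groups == levels[1]) == 0:
        raise FormatError("both groups must be non-empty")
    g = (groups == levels[1]).astype(float)

    covX = np.empty((len(groups), 0))
    covnames: list[str] = []
    if covariates:
        if covariates_table is None:
            raise FormatError("covariates named but no covariates table given")
        covX, covnames = build_covariate_columns(
            covariates_table.reset_index(drop=True), covariates)
        # warn when a categorical level occurs in only one group
        for name, col in zip(covnames, covX.T):
            if "[" in name and len(set(g[col == 1.0])) == 1:
                warnings.warn(
                    f"covariate level {name} present in one group only "
                    "(confounded with group)"
                )
    X = np.column_stack([np.ones(len(g)), g, covX])
    names = ["intercept", f"group[{levels[1]}]"] + covnames
    _check_rank(X, names)

    n, p = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ values                     # p x parcels
    resid = values - X @ beta
    df = n - p
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(sigma2 * XtX_inv[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, beta[1] / se, 0.0)
    pvals = 2 * stats.t.sf(np.abs(tval), df)

    # pooled-SD Cohen's d for the adjusted group difference
    n0, n1 = float(np.sum(g == 0)), float(np.sum(g == 1))
    cohens_d = tval * np.sqrt(1 / n0 + 1 / n1)

    qvals, _ = bh_fdr(pvals, q)
    if p_uncorrected is not None:
        significant = pvals < p_uncorrected
        mode = f"ols_ancova(p<{p_uncorrected:g} uncorrected)"
    else:
        significant = qvals < q
        mode = "ols_ancova(fdr)"
    table = pd.DataFrame(
        {"estimate": beta[1], "t": tval, "df": float(df), "cohens_d": cohens_d,
         "p": pvals, "q": qvals, "significant": significant}
    )
    if atlas is not None:
        table.insert(0, "label", atlas.labels)
        table.insert(1, "network", atlas.network)
    return ContrastResult(table=table, model=mode,
                          covariates=tuple(covariates), q_level=q)


# ---------------------------------------------------------------------------
# compression summary
# ---------------------------------------------------------------------------

def compression_summary(
    values: np.ndarray,
    sessions: Sequence[SessionMeta],
    atlas: ParcelAtlas | None = None,
) -> CompressionSummary:
    """Range narrowing of the cohort-mean principal gradient.

    ``values`` is scans x parcels of aligned principal gradients.  The
    cohort mean per condition gives the (min, max) ranges, the MP/PL
    range ratio, the cross-condition Pearson r, and (with an atlas) the
    per-network mean shift MP - PL.
    """
    values = np.asarray(values, float)
    cond = np.asarray([s.condition for s in sessions], object)
    if values.shape[0] != len(cond):
        raise FormatError("one row of values per session is required")
    mean_pl = values[cond == "PL"].mean(axis=0)
    mean_mp = values[cond == "MP"].mean(axis=0)
    range_pl = (float(mean_pl.min()), float(mean_pl.max()))
    range_mp = (float(mean_mp.min()), float(mean_mp.max()))
    span_pl = range_pl[1] - range_pl[0]
    if span_pl <= 0:
        raise DegenerateDataError("PL cohort-mean gradient has zero range")
    ratio = (range_mp[1] - range_mp[0]) / span_pl
    r = float(np.corrcoef(mean_pl, mean_mp)[0, 1])
    shift = mean_mp - mean_pl
    if atlas is not None:
        net = pd.DataFrame({"network": atlas.network, "shift": shift})
        network_shift = (
            net.groupby("network")["shift"].mean()
            .reindex([n for n in NETWORKS if n in set(atlas.network)])
            .rename("mean_shift").reset_index()
        )
    else:
        network_shift = pd.DataFrame(columns=["network", "mean_shift"])
    return CompressionSummary(
        range_pl=range_pl,
        range_mp=range_mp,
        range_ratio=float(ratio),
        cross_condition_r=r,
        network_shift=network_shift,
    )


def significance_gradient_coupling(t: np.ndarray, pl_mean: np.ndarray) -> float:
    """Pearson correlation between |t| of the drug contrast and the PL
    cohort-mean gradient — the labeled convention for relating effect
    topography to baseline gradient strength."""
    return float(np.corrcoef(np.abs(np.asarray(t, float)),
                             np.asarray(pl_mean, float))[0, 1])
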