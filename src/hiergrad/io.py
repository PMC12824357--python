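"""Domain types and delimited-text readers/writers.

All tables are tab-separated with a header row; matrices are TSV
(parcels in rows) or ``.npy`` for large arrays.  Lines starting with
``#`` are provenance comments (e.g. the study-config hash) and are
ignored on read.  Parcels are indexed 0-based internally; user-facing
tables always carry the parcel label.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DegenerateDataError, FormatError, ShapeError

#: The 12 canonical network partitions of the 438-parcel atlas.
NETWORKS: tuple[str, ...] = (
    "VIS1", "VIS2", "SMM", "CON", "DAN", "LAN",
    "FPN", "AUD", "DMN", "PMM", "VMM", "ORA",
)

HEMISPHERES: tuple[str, ...] = ("L", "R", "SUBCORTICAL")

CONDITIONS: tuple[str, ...] = ("PL", "MP")

#: Unit-norm tolerance accepted (and silently renormalized) for centroids.
_CENTROID_TOL = 1e-6


# ---------------------------------------------------------------------------
# ParcelAtlas
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParcelAtlas:
    """Parcel identity, hemisphere, network membership and spherical geometry.

    Parameters
    ----------
    labels
        Unique parcel labels, index-aligned with every length-N map.
    hemisphere
        One of ``L``, ``R``, ``SUBCORTICAL`` per parcel.
    network
        One of the 12 canonical network names per parcel.
    centroids
        ``(N, 3)`` array of unit vectors on the sphere for cortical
        parcels; rows for subcortical parcels are NaN.
    """

    labels: np.ndarray
    hemisphere: np.ndarray
    network: np.ndarray
    centroids: np.ndarray

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=object)
        hemi = np.asarray(self.hemisphere, dtype=object)
        net = np.asarray(self.network, dtype=object)
        cen = np.asarray(self.centroids, dtype=float)
        n = len(labels)
        if n < 3:
            raise FormatError(f"atlas needs at least 3 parcels, got {n}")
        if len(set(labels.tolist())) != n:
            raise FormatError("duplicate parcel labels in atlas")
        bad = set(hemi.tolist()) - set(HEMISPHERES)
        if bad:
            raise FormatError(f"unknown hemisphere codes: {sorted(bad)}")
        badnet = set(net.tolist()) - set(NETWORKS)
        if badnet:
            raise FormatError(f"unknown network names: {sorted(badnet)}")
        if cen.shape != (n, 3):
            raise ShapeError(f"centroids must be ({n}, 3), got {cen.shape}")
        cortical = hemi != "SUBCORTICAL"
        if np.isnan(cen[cortical]).any():
            raise FormatError("cortical parcel lacking centroid coordinates")
        norms = np.linalg.norm(cen[cortical], axis=1)
        if np.any(np.abs(norms - 1.0) > _CENTROID_TOL):
            worst = float(np.max(np.abs(norms - 1.0)))
            raise FormatError(
                f"cortical centroid norm deviates from 1 by {worst:.2e} "
                f"(tolerance {_CENTROID_TOL:g})"
            )
        cen = cen.copy()
        off = np.abs(norms - 1.0) > 1e-12   # renormalize only when needed,
        if off.any():                        # keeping exact values byte-stable
            rows = np.flatnonzero(cortical)[off]
            cen[rows] /= norms[off][:, None]
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "hemisphere", hemi)
        object.__setattr__(self, "network", net)
        object.__setattr__(self, "centroids", cen)

    @property
    def n_parcels(self) -> int:
        return len(self.labels)

    @property
    def is_cortical(self) -> np.ndarray:
        return self.hemisphere != "SUBCORTICAL"

    def __eq__(self, other) -> bool:
        if not isinstance(other, ParcelAtlas):
            return NotImplemented
        return (
            np.array_equal(self.labels, other.labels)
            and np.array_equal(self.hemisphere, other.hemisphere)
            and np.array_equal(self.network, other.network)
            and np.allclose(self.centroids, other.centroids, equal_nan=True)
        )


def load_atlas(path: str | Path) -> ParcelAtlas:
    """Read a ParcelAtlas from a TSV with columns
    ``parcel_id label hemisphere network cx cy cz``."""
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    required = {"parcel_id", "label", "hemisphere", "network"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"atlas table missing columns: {sorted(missing)}")
    df = df.sort_values("parcel_id").reset_index(drop=True)
    if not np.array_equal(df["parcel_id"].to_numpy(), np.arange(len(df))):
        raise FormatError("parcel_id must be 0..N-1 without gaps")
    if {"cx", "cy", "cz"} <= set(df.columns):
        cen = df[["cx", "cy", "cz"]].to_numpy(float)
    else:
        if (df["hemisphere"] != "SUBCORTICAL").any():
            raise FormatError("cortical rows present but centroid columns absent")
        cen = np.full((len(df), 3), np.nan)
    return ParcelAtlas(
        labels=df["label"].to_numpy(object),
        hemisphere=df["hemisphere"].to_numpy(object),
        network=df["network"].to_numpy(object),
        centroids=cen,
    )


def save_atlas(atlas: ParcelAtlas, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "parcel_id": np.arange(atlas.n_parcels),
            "label": atlas.labels,
            "hemisphere": atlas.hemisphere,
            "network": atlas.network,
            "cx": atlas.centroids[:, 0],
            "cy": atlas.centroids[:, 1],
            "cz": atlas.centroids[:, 2],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# SessionMeta / ParcelTimeSeries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SessionMeta:
    """One scan's identity: subject, drug condition (or group), scan index,
    covariates and mean framewise displacement (mm)."""

    subject_id: str
    condition: str
    scan_index: int
    covariates: Mapping[str, float | str] = field(default_factory=dict)
    fd: float = 0.0

    def __post_init__(self):
        if self.fd < 0:
            raise FormatError(f"fd must be >= 0, got {self.fd}")
        object.__setattr__(self, "covariates", dict(self.covariates))


def sessions_to_frame(sessions: Sequence[SessionMeta]) -> pd.DataFrame:
    """Long-format session table; covariates become columns."""
    keys = sorted({k for s in sessions for k in s.covariates})
    rows = []
    for s in sessions:
        row = {
            "subject_id": s.subject_id,
            "condition": s.condition,
            "scan_index": s.scan_index,
            "fd": s.fd,
        }
        row.update({k: s.covariates.get(k) for k in keys})
        rows.append(row)
    df = pd.DataFrame(rows)
    dup = df.duplicated(subset=["subject_id", "condition", "scan_index"])
    if dup.any():
        raise FormatError("duplicate (subject_id, condition, scan_index) rows")
    return df


def frame_to_sessions(df: pd.DataFrame) -> list[SessionMeta]:
    base = {"subject_id", "condition", "scan_index", "fd"}
    covkeys = [c for c in df.columns if c not in base]
    out = []
    for _, row in df.iterrows():
        out.append(
            SessionMeta(
                subject_id=str(row["subject_id"]),
                condition=str(row["condition"]),
                scan_index=int(row["scan_index"]),
                covariates={k: row[k] for k in covkeys},
                fd=float(row["fd"]),
            )
        )
    return out


def load_sessions(path: str | Path) -> list[SessionMeta]:
    return frame_to_sessions(pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip"))


def save_sessions(sessions: Sequence[SessionMeta], path: str | Path) -> None:
    sessions_to_frame(sessions).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class ParcelTimeSeries:
    """N parcels x T timepoints of BOLD signal for one scan."""

    data: np.ndarray
    meta: SessionMeta

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ShapeError(f"timeseries must be 2-D, got {data.ndim}-D")
        if data.shape[1] < 2:
            raise ShapeError("timeseries needs at least 2 timepoints")
        if not np.isfinite(data).all():
            raise FormatError("timeseries contains missing or non-finite values")
        var = data.var(axis=1)
        flat = np.flatnonzero(var == 0.0)
        if flat.size:
            raise DegenerateDataError(
                f"constant timeseries in parcel rows {flat[:5].tolist()}"
            )
        object.__setattr__(self, "data", data)

    @property
    def n_parcels(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


def read_matrix(path: str | Path) -> np.ndarray:
    """Read a numeric matrix from TSV (rows = parcels) or ``.npy``."""
    path = Path(path)
    if path.suffix == ".npy":
        return np.load(path)
    return np.loadtxt(path, delimiter="\t", comments="#", ndmin=2)


def write_matrix(mat: np.ndarray, path: str | Path, header: str | None = None) -> None:
    path = Path(path)
    if path.suffix == ".npy":
        np.save(path, np.asarray(mat))
        return
    np.savetxt(
        path,
        np.asarray(mat),
        delimiter="\t",
        fmt="%.17g",
        header=header or "",
        comments="# " if header else "# ",
    )


def load_timeseries(
    path: str | Path, meta: SessionMeta, atlas: ParcelAtlas
) -> ParcelTimeSeries:
    """Load one scan's parcel x time matrix, validated against the atlas.

    Orientation is explicit: rows are parcels.  A row count that differs
    from the atlas raises :class:`ShapeError`; a constant row raises
    :class:`DegenerateDataError` naming the offending parcel label.
    """
    data = read_matrix(path)
    if data.shape[0] != atlas.n_parcels:
        raise ShapeError(
            f"timeseries has {data.shape[0]} rows, atlas has "
            f"{atlas.n_parcels} parcels"
        )
    var = data.var(axis=1)
    flat = np.flatnonzero(var == 0.0)
    if flat.size:
        names = [str(atlas.labels[i]) for i in flat[:5]]
        raise DegenerateDataError(f"constant timeseries in parcels {names}")
    return ParcelTimeSeries(data=data, meta=meta)


# ---------------------------------------------------------------------------
# ScalarTargets
# ---------------------------------------------------------------------------

STRIATAL_ROIS: tuple[str, ...] = ("caudate", "putamen", "nucleus_accumbens", "striatum")


@dataclass(frozen=True)
class ScalarTargets:
    """Per-subject striatal receptor availability (BPnd) and the derived
    dopamine-increase score delta_da = D2R BPnd(PL) - D2R BPnd(MP)."""

    table: pd.DataFrame  # columns: subject_id roi d1r_bpnd d2r_bpnd_pl d2r_bpnd_mp delta_da

    def __post_init__(self):
        df = self.table.copy()
        required = {"subject_id", "roi", "d1r_bpnd", "d2r_bpnd_pl", "d2r_bpnd_mp"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"targets table missing columns: {sorted(missing)}")
        badroi = set(df["roi"]) - set(STRIATAL_ROIS)
        if badroi:
            raise FormatError(f"unknown ROI names: {sorted(badroi)}")
        for col in ("d1r_bpnd", "d2r_bpnd_pl", "d2r_bpnd_mp"):
            if (df[col].dropna() < 0).any():
                raise FormatError(f"negative BPnd in column {col}")
        df["delta_da"] = df["d2r_bpnd_pl"] - df["d2r_bpnd_mp"]
        object.__setattr__(self, "table", df.reset_index(drop=True))

    def for_roi(self, roi: str) -> pd.DataFrame:
        return self.table[self.table["roi"] == roi].set_index("subject_id")


def load_targets(path: str | Path) -> ScalarTargets:
    return ScalarTargets(pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip"))


def save_targets(targets: ScalarTargets, path: str | Path) -> None:
    targets.table.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# StudyConfig
# ---------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """End-to-end study parameters.

    Defaults follow the reference analysis: retain the top 10% of positive
    edges per row, diffusion normalization alpha = 0.5, 10 embedding
    components per scan, 10,000 spin permutations, FDR at q = 0.05.
    """

    density: float = 0.10
    alpha: float = 0.5
    n_components: int = 10
    n_perm: int = 10000
    fdr_q: float = 0.05
    rng_seed: int = 0
    atlas_path: str = ""
    sessions_path: str = ""
    timeseries_dir: str = ""
    targets_path: str = ""
    reference_map_path: str = ""
    out_dir: str = ""
    covariates: tuple[str, ...] = ("age", "sex", "race", "bmi", "iq")
    pls_components: int = 2
    pls_target: str = "d1r_bpnd"
    pls_roi: str = "putamen"
    pls_gradient: str = "secondary"  # which aligned gradient predicts

    def validate(self) -> "StudyConfig":
        if not (0 < self.density <= 1):
            raise ConfigError(f"density must be in (0, 1], got {self.density}")
        if self.n_components < 1:
            raise ConfigError("n_components must be >= 1")
        if self.n_perm < 1:
            raise ConfigError(f"n_perm must be >= 1, got {self.n_perm}")
        if not (0 < self.fdr_q < 1):
            raise ConfigError(f"fdr_q must be in (0, 1), got {self.fdr_q}")
        return self

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["covariates"] = list(d["covariates"])
        return json.dumps(d, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "StudyConfig":
        d = json.loads(text)
        d["covariates"] = tuple(d["covariates"])
        return cls(**d)

    @property
    def config_hash(self) -> str:
        """First 12 hex digits of the SHA-256 of the canonical JSON form,
        excluding the output directory (where results land does not change
        what was computed)."""
        d = json.loads(self.to_json())
        d.pop("out_dir")
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()
        ).hexdigest()[:12]


def load_config(path: str | Path) -> StudyConfig:
    return StudyConfig.from_json(Path(path).read_text())


def save_config(config: StudyConfig, path: str | Path) -> None:
    Path(path).write_text(config.to_json())
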