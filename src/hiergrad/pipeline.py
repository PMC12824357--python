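"""End-to-end study orchestrator.

``run_study`` drives the full chain on files laid out as written by
:func:`hiergrad.synthetic.write_cohort` (or equivalently prepared real
data): atlas + session table + per-scan timeseries matrices, optional
scalar-target and reference-map tables.  Stages:

1. load and validate inputs
2. per-scan connectomes
3. group templates from the mean connectome
4. per-scan embedding + template alignment
5. paired drug contrast (random-intercept LME per parcel, FDR)
6. compression summary
7. spin test of the contrast t-map against a reference map (if given)
8. PLS prediction of scalar targets from subject-mean gradient maps,
   within-condition LOO plus both cross-condition transfers (if targets
   given)

Every output table carries the config hash in a ``#`` comment line;
outputs are deterministic given the input files and ``rng_seed``.  A
failing stage raises :class:`~hiergrad.errors.StageError` naming the
stage, and the manifest marks the run incomplete.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import gradients as gr
from . import group_stats as gs
from . import pls_predict as pls
from . import spatial_null as sn
from .errors import ConfigError, HiergradError, StageError
from .io import (
    ParcelAtlas,
    SessionMeta,
    StudyConfig,
    load_atlas,
    load_sessions,
    load_targets,
    load_timeseries,
    read_matrix,
)

logger = logging.getLogger("hiergrad")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    logger.addHandler(_h)
logger.setLevel(logging.INFO)


@dataclass
class StudyResults:
    config: StudyConfig
    atlas: ParcelAtlas
    sessions: list[SessionMeta]
    templates: gr.GradientTemplate
    aligned: list[gr.AlignedGradients]
    contrast: gs.ContrastResult
    compression: gs.CompressionSummary
    spin: sn.SpinResult | None = None
    pls_within: dict = field(default_factory=dict)
    pls_transfer: dict = field(default_factory=dict)


def _write_table(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def run_study(config: StudyConfig) -> StudyResults:
    config.validate()
    out = Path(config.out_dir) if config.out_dir else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash
    manifest = {"config_hash": chash, "status": "incomplete", "stages": []}

    def _manifest():
        if out is not None:
            (out / "manifest.json").write_text(json.dumps(manifest, indent=1))

    def stage(name):
        logger.info("stage %s", name)
        manifest["stages"].append({"stage": name, "time": time.time()})
        _manifest()

    try:
        stage("load")
        atlas = load_atlas(config.atlas_path)
        sessions = load_sessions(config.sessions_path)
        ts_dir = Path(config.timeseries_dir)
        scans = []
        for meta in sessions:
            matches = sorted(ts_dir.glob(
                f"{meta.subject_id}_{meta.condition}_{meta.scan_index}.*"
            ))
            if not matches:
                raise ConfigError(
                    f"no timeseries file for {meta.subject_id} "
                    f"{meta.condition} scan {meta.scan_index}"
                )
            scans.append(load_timeseries(matches[0], meta, atlas))
        subjects = {}
        for meta in sessions:
            subjects.setdefault(meta.subject_id, set()).add(meta.condition)
        paired = [s for s, c in subjects.items() if c == {"PL", "MP"}]
        if len(paired) < 2:
            raise ConfigError("need at least 2 subjects with both conditions")
    except HiergradError as e:
        _manifest()
        raise StageError("load", str(e)) from e

    try:
        stage("connectomes")
        conns = [gr.build_connectome(ts) for ts in scans]
    except HiergradError as e:
        raise StageError("connectomes", str(e)) from e

    try:
        stage("templates")
        templates = gr.build_templates(
            conns, density=config.density, alpha=config.alpha,
            n_components=config.n_components,
        )
    except HiergradError as e:
        raise StageError("templates", str(e)) from e

    try:
        stage("gradients")
        aligned = []
        for conn in conns:
            gset = gr.diffusion_embed(
                gr.affinity_from_connectome(conn, config.density),
                alpha=config.alpha, n_components=config.n_components,
            )
            aligned.append(gr.align_gradients(gset, templates, meta=conn.meta))
        if out is not None:
            rows = []
            for al in aligned:
                for i, label in enumerate(atlas.labels):
                    rows.append({
                        "subject_id": al.meta.subject_id,
                        "condition": al.meta.condition,
                        "scan_index": al.meta.scan_index,
                        "label": label,
                        "principal": al.principal[i],
                        "secondary": al.secondary[i],
                        "match_r_principal": al.match_r[0],
                        "match_r_secondary": al.match_r[1],
                        "source_principal": al.source_component_index[0],
                        "source_secondary": al.source_component_index[1],
                    })
            _write_table(pd.DataFrame(rows), out / "gradients.tsv", chash)
            _write_table(
                pd.DataFrame({
                    "label": atlas.labels,
                    "principal": templates.principal,
                    "secondary": templates.secondary,
                }),
                out / "templates.tsv", chash,
            )
    except HiergradError as e:
        raise StageError("gradients", str(e)) from e

    principal = np.vstack([al.principal for al in aligned])

    try:
        stage("contrast")
        contrast = gs.parcelwise_drug_contrast(
            principal, sessions, covariates=config.covariates,
            q=config.fdr_q, atlas=atlas,
        )
        if out is not None:
            _write_table(contrast.table, out / "contrast.tsv", chash)
    except HiergradError as e:
        raise StageError("contrast", str(e)) from e

    try:
        stage("compression")
        compression = gs.compression_summary(principal, sessions, atlas)
        if out is not None:
            payload = {
                "config_hash": chash,
                "range_pl": compression.range_pl,
                "range_mp": compression.range_mp,
                "range_ratio": compression.range_ratio,
                "cross_condition_r": compression.cross_condition_r,
                "network_shift": compression.network_shift.to_dict("records"),
            }
            (out / "compression.json").write_text(json.dumps(payload, indent=1))
    except HiergradError as e:
        raise StageError("compression", str(e)) from e

    spin_res = None
    if config.reference_map_path:
        try:
            stage("spin")
            ref_map = read_matrix(config.reference_map_path).ravel()
            spin_res = sn.spin_test(
                contrast.t, ref_map, atlas, n_perm=config.n_perm,
                seed=config.rng_seed,
            )
            if out is not None:
                (out / "spin.json").write_text(json.dumps({
                    "config_hash": chash, "r_obs": spin_res.r_obs,
                    "p": spin_res.p, "n_perm": spin_res.n_perm,
                    "criterion": spin_res.criterion,
                }, indent=1))
        except HiergradError as e:
            raise StageError("spin", str(e)) from e

    pls_within: dict = {}
    pls_transfer: dict = {}
    if config.targets_path:
        try:
            stage("pls")
            targets = load_targets(config.targets_path)
            roi = targets.for_roi(config.pls_roi)
            cond_of = {"PL": [], "MP": []}
            for al in aligned:
                cond_of[al.meta.condition].append(al)
            if config.pls_gradient not in ("principal", "secondary"):
                raise ConfigError(
                    f"pls_gradient must be principal|secondary, got "
                    f"'{config.pls_gradient}'"
                )
            X, y = {}, None
            for cond, als in cond_of.items():
                vals = np.vstack([getattr(al, config.pls_gradient)
                                  for al in als])
                subj = [al.meta.subject_id for al in als]
                Xc, subjects_sorted = pls.subject_mean_gradients(vals, subj)
                X[cond] = Xc
            y = roi.loc[subjects_sorted, config.pls_target].to_numpy(float)
            for cond in ("PL", "MP"):
                cv = pls.loo_cv(X[cond], y, k_max=config.pls_components)
                pls_within[cond] = {
                    "rmse": cv.rmse.tolist(), "r": cv.r.tolist(),
                    "k_opt": cv.k_opt, "training_r2": cv.training_r2,
                }
            for train, test in (("PL", "MP"), ("MP", "PL")):
                model = pls.fit_pls(X[train], y, k=config.pls_components)
                rep = pls.transfer_predict(model, X[test], y)
                pls_transfer[f"{train}->{test}"] = {"r": rep.r, "p": rep.p}
            if out is not None:
                (out / "pls.json").write_text(json.dumps({
                    "config_hash": chash, "target": config.pls_target,
                    "roi": config.pls_roi, "within": pls_within,
                    "transfer": pls_transfer,
                }, indent=1))
        except HiergradError as e:
            raise StageError("pls", str(e)) from e

    manifest["status"] = "complete"
    _manifest()
    return StudyResults(
        config=config, atlas=atlas, sessions=sessions, templates=templates,
        aligned=aligned, contrast=contrast, compression=compression,
        spin=spin_res, pls_within=pls_within, pls_transfer=pls_transfer,
    )
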