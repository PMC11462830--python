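"""End-to-end orchestration: phantom cohort -> model fitting -> ROI feature
extraction -> group statistics -> OPLS-DA, with deterministic seeding and
a JSON/CSV report bundle.

Every stochastic stage derives its seed from the global seed through a
named ``numpy.random.SeedSequence`` spawn key, so partial reruns of a
stage reproduce the full-run results.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort_stats, oplsda
from .fodf_afd import CSDEstimator
from .noddi_models import BinghamNODDIEstimator, WatsonNODDIEstimator
from .phantom import METRICS, Cohort, CohortConfig, make_cohort
from .protocol_io import paper_scheme
from .smi_model import SMIEstimator
from .tensor_models import DKIEstimator, DTIEstimator

logger = logging.getLogger("gliomicro")

__all__ = ["RunConfig", "run_pipeline", "extract_features"]

_STAGE_KEYS = {"phantom": 1, "fit": 2, "features": 3, "stats": 4, "oplsda": 5}


def stage_seed(global_seed: int, stage: str) -> int:
    """Named, documented per-stage seed derivation (SeedSequence spawn)."""
    ss = np.random.SeedSequence([int(global_seed), _STAGE_KEYS[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "gliomicro_run"
    preset: str = "paper-like"
    level: str = "features"       # features | signals
    n_nonrec: int = 25
    n_rec: int = 23
    snr: float = 30.0
    normalize: bool = False
    n_ortho: int | str = 1
    cv_folds: int = 7
    n_perm: int = 200
    volume_shape: tuple = (16, 16, 3)
    n_rois: int = 5

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if isinstance(cfg.volume_shape, list):
            cfg.volume_shape = tuple(cfg.volume_shape)
        return cfg

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("outdir")  # output location does not affect results
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str)
                              .encode()).hexdigest()[:12]


def extract_features(cohort: Cohort, normalize: bool = False) -> pd.DataFrame:
    """Fit all seven reconstruction models on each patient's ROI voxels and
    aggregate to the per-patient feature table."""
    scheme = next(iter(cohort.datasets.values()))[0].scheme
    estimators = {
        "DTI": DTIEstimator(scheme),
        "DKI": DKIEstimator(scheme),
        "NODDI": WatsonNODDIEstimator(scheme),
        "BinNODDI": BinghamNODDIEstimator(scheme),
        "SMI": SMIEstimator(scheme),
        "AFD": CSDEstimator(scheme),
    }
    rows = []
    for pid, (dataset, rois) in cohort.datasets.items():
        t0 = time.time()
        union_idx = [tuple(ix) for roi in rois.tumor_rois for ix in zip(*np.nonzero(roi))]
        # voxel-batch fits over the tumor ROI voxels; maps stay on the grid
        maps = {}
        vox = np.array([dataset.signal[ix] for ix in union_idx])
        ref_idx = [tuple(ix) for ix in zip(*np.nonzero(rois.reference_roi))]
        ref_vox = np.array([dataset.signal[ix] for ix in ref_idx])
        allvox = np.vstack([vox, ref_vox])
        for name, est in estimators.items():
            est.fit(allvox)
            for mname, values in est.maps_.items():
                vol = np.zeros(dataset.signal.shape[:3])
                for ix, v in zip(union_idx + ref_idx, values):
                    vol[ix] = v
                maps[mname] = vol
        row = {"patient_id": pid,
               "group": cohort.clinical.df.set_index("patient_id").loc[pid, "group"]}
        row.update(cohort_stats.aggregate_roi(maps, rois, normalize=normalize))
        rows.append(row)
        logger.info("patient %s: %d tumor voxels fitted in %.1fs",
                    pid, len(vox), time.time() - t0)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Run phantom -> (fit) -> features -> stats -> OPLS-DA; returns the
    report dict and writes the bundle under ``config.outdir``."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()

    cc = CohortConfig(n_nonrec=config.n_nonrec, n_rec=config.n_rec,
                      preset=config.preset, level=config.level, snr=config.snr,
                      seed=stage_seed(config.seed, "phantom"),
                      volume_shape=config.volume_shape, n_rois=config.n_rois)
    scheme = paper_scheme()
    cohort = make_cohort(cc, scheme=scheme)
    cohort.clinical.to_csv(out / "clinical.csv")

    if config.level == "signals":
        features = extract_features(cohort, normalize=config.normalize)
    else:
        features = cohort.features
    features.to_csv(out / "features.csv", index=False)

    labels = (features["group"] == "recurrence").to_numpy(dtype=int)
    present = [m for m in METRICS if m in features.columns]
    stats_tab = cohort_stats.metric_table(features, labels, metrics=present)
    stats_tab.to_csv(out / "metric_stats.csv")
    t1 = cohort_stats.table1(cohort.clinical)
    t1.to_csv(out / "table1.csv")
    t2 = cohort_stats.table2(features, labels, metrics=present)
    t2.to_csv(out / "table2.csv")

    X = features[present].to_numpy()
    report = oplsda.permutation_test(
        X, labels, n_perm=config.n_perm, seed=stage_seed(config.seed, "oplsda"),
        n_ortho=config.n_ortho, folds=config.cv_folds)
    vip_rank = sorted(zip(present, report.vip), key=lambda t: -t[1])

    bundle = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_patients": int(len(labels)),
        "metrics": present,
        "oplsda": {
            "r2y": report.r2y, "q2y": report.q2y,
            "r2y_intercept": report.r2y_intercept,
            "q2y_intercept": report.q2y_intercept,
            "auc_train": report.roc_train.auc,
            "auc_cv": report.roc_cv.auc,
            "n_perm": int(len(report.q2y_perm)),
            "perm_q2_below_original": float(np.mean(report.q2y_perm < report.q2y))
            if len(report.q2y_perm) else None,
            "vip_ranking": [[m, float(v)] for m, v in vip_rank],
        },
        "significant_metrics": stats_tab.index[stats_tab["pvalue"] < 0.05].tolist(),
    }
    logger.info("pipeline finished in %.1fs", time.time() - t_start)
    with open(out / "report.json", "w") as fh:
        json.dump(bundle, fh, indent=2, sort_keys=True)
    manifest = {"config": asdict(config), "hash": config.config_hash()}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return bundle
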