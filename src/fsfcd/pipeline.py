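"""End-to-end orchestration: simulate -> prep -> decompose -> foi -> fcd ->
stats -> classify, with per-stage artifacts and a run manifest.

Each stage writes its outputs under the run directory; a stage requested
without its upstream artifacts raises an error naming the stage to run
first.  Reruns with an identical config and seed reproduce identical
TSV/JSON artifacts because every random draw is derived from the master
seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .cohort import CohortSpec, generate_cohort, mask_array, save_spec, spec_to_dict
from .core import MaskedBoldSeries, mask_coordinates
from .classify import SvmConfig, loocv_classify, roc_points
from .emd import CeemdanConfig, decompose_cohort
from .fcd import FcdConfig, compute_fcd, smooth_map, zscore_map
from .foi import bands_from_json, bands_to_json, cohort_band_series, conventional_band, derive_bands
from .prep import prepare
from .stats import (
    CorrectionConfig,
    demographics_table,
    estimate_smoothness,
    extract_clusters,
    monte_carlo_cluster_threshold,
    voxelwise_ttest,
)

log = logging.getLogger("fsfcd")

STAGE_ORDER = ("simulate", "prep", "decompose", "foi", "fcd", "stats", "classify")


@dataclass
class RunConfig:
    out_dir: str = "fsfcd_run"
    stages: tuple = STAGE_ORDER
    spec: CohortSpec = field(default_factory=CohortSpec)
    ceemdan: CeemdanConfig = field(default_factory=CeemdanConfig)
    fcd: FcdConfig = field(default_factory=FcdConfig)
    correction: CorrectionConfig = field(default_factory=CorrectionConfig)
    svm: SvmConfig = field(default_factory=SvmConfig)
    seed: int = 0
    f_low: float = 0.0
    f_high: float = 0.08
    discard_volumes: int = 0  # synthetic cohorts are already "retained" volumes
    classify_kinds: tuple = ("short", "long")
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["spec"] = spec_to_dict(self.spec)
        return d


def _series_to_npz_dict(subjects: list) -> dict:
    arrays = {}
    for s in subjects:
        arrays[f"data::{s.subject_id}"] = s.data
        arrays[f"coords::{s.subject_id}"] = s.voxel_index
    return arrays


class PipelineRun:
    """Stateful runner holding in-memory artifacts between stages."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.subjects = None
        self.table = None
        self.prepared = None
        self.decomps = None
        self.hwf_table = None
        self.bands = None
        self.maps = None  # dict (band, kind, stage) -> {sid: FcdMap}
        self.min_extent = None
        self.fwhm_mm = None
        self.manifest_entries = {}
        logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))

    # -- helpers -----------------------------------------------------------

    def _require(self, attr, stage_needed):
        if getattr(self, attr) is None:
            raise RuntimeError(
                f"missing upstream artifact '{attr}': run stage '{stage_needed}' first"
            )

    def _record(self, stage, t0, **extra):
        self.manifest_entries[stage] = {
            "wall_s": round(time.time() - t0, 3),
            **extra,
        }

    def _geometry(self):
        s = self.prepared[0]
        return (s.voxel_index, s.grid_shape, s.voxel_size_mm)

    # -- stages ------------------------------------------------------------

    def simulate(self):
        t0 = time.time()
        cfg = self.config
        spec = dataclasses.replace(cfg.spec, seed=cfg.seed)
        self.subjects, self.table = generate_cohort(spec)
        save_spec(spec, self.out / "spec.yaml")
        self.table.to_csv(self.out / "subjects.tsv", sep="\t", index=False)
        fio.save_mask_nifti(
            mask_array(spec), spec.voxel_size_mm, self.out / "mask.nii"
        )
        nifti_dir = self.out / "bold"
        nifti_dir.mkdir(exist_ok=True)
        for s in self.subjects:
            fio.save_series_nifti(s, nifti_dir / f"{s.subject_id}_bold.nii")
        demo = demographics_table(self.table)
        with open(self.out / "demographics.json", "w") as fh:
            json.dump(demo, fh, indent=2, sort_keys=True)
        self._record("simulate", t0, n_subjects=len(self.subjects))

    def prep(self):
        t0 = time.time()
        self._require("subjects", "simulate")
        cfg = self.config
        self.prepared = []
        for s in self.subjects:
            if cfg.discard_volumes:
                s = s.with_data(
                    s.data[:, cfg.discard_volumes:], f"discard({cfg.discard_volumes})"
                )
            self.prepared.append(
                prepare(s, f_low=cfg.f_low, f_high=cfg.f_high, steps=("detrend", "filter"))
            )
        np.savez(self.out / "prepared.npz", **_series_to_npz_dict(self.prepared))
        self._record("prep", t0, steps=["detrend", f"filter({cfg.f_low},{cfg.f_high})"])

    def decompose(self):
        t0 = time.time()
        self._require("prepared", "prep")
        self.decomps, self.hwf_table, qc = decompose_cohort(
            self.prepared, self.config.ceemdan
        )
        groups = dict(zip(self.table["subject_id"], self.table["group"]))
        self.hwf_table["group"] = self.hwf_table["subject_id"].map(groups)
        self.hwf_table.to_csv(self.out / "hwf.tsv", sep="\t", index=False)
        self._record("decompose", t0, **qc)

    def foi(self):
        t0 = time.time()
        self._require("hwf_table", "decompose")
        orders = tuple(range(1, self.config.ceemdan.max_imfs + 1))
        self.bands = derive_bands(self.hwf_table, orders=orders)
        self.bands.append(conventional_band())
        bands_to_json(self.bands, self.out / "bands.json")
        self._record("foi", t0, bands=[b.label for b in self.bands])

    def fcd(self):
        t0 = time.time()
        self._require("prepared", "prep")
        if self.bands is None:
            path = self.out / "bands.json"
            if path.exists():
                self.bands = bands_from_json(path)
            else:
                raise RuntimeError("missing upstream artifact 'bands': run stage 'foi' first")
        cfg = self.config.fcd
        self.maps = {}
        dropped = 0
        for si, series in enumerate(self.prepared):
            dec = None if self.decomps is None else self.decomps[series.subject_id]
            for band in self.bands:
                if band.source == "derived" and dec is None:
                    raise RuntimeError(
                        "derived bands need decompositions: run stage 'decompose' first"
                    )
                bser, keep = cohort_band_series(series, dec, band)
                dropped += int((~keep).sum())
                raw = compute_fcd(bser, cfg, band=band.label)
                for kind, m in raw.items():
                    z = zscore_map(m, ddof=cfg.zscore_ddof)
                    sm = smooth_map(z, cfg)
                    for stage_map in (m, z, sm):
                        self.maps.setdefault(
                            (band.label, kind, stage_map.stage), {}
                        )[series.subject_id] = stage_map
        smoothed = [
            m
            for (b, k, st), d in self.maps.items()
            if st == "smoothed"
            for m in d.values()
        ]
        fio.fcd_long_table(smoothed).to_csv(self.out / "fcd.tsv", sep="\t", index=False)
        self._record("fcd", t0, dropped_voxels=dropped, n_maps=len(smoothed))

    def _stacked(self, band_label, kind):
        """(subjects-in-table-order stacked smoothed maps, ids)."""
        d = self.maps[(band_label, kind, "smoothed")]
        ids = list(self.table["subject_id"])
        # intersect voxels across subjects (derived bands may drop voxels)
        common = None
        for sid in ids:
            key = set(map(tuple, d[sid].voxel_index))
            common = key if common is None else common & key
        ref = sorted(common)
        stacked = []
        for sid in ids:
            m = d[sid]
            lut = {tuple(c): i for i, c in enumerate(m.voxel_index)}
            rows = [lut[c] for c in ref]
            stacked.append(m.values[rows])
        vi = np.asarray(ref, dtype=np.intp)
        geom = (vi, d[ids[0]].grid_shape, d[ids[0]].voxel_size_mm)
        return np.vstack(stacked), ids, geom

    def stats(self):
        t0 = time.time()
        self._require("maps", "fcd")
        cfg = self.config.correction
        spec = self.config.spec
        mask = mask_array(spec)
        results = {}
        labels = np.asarray(self.table["group"])
        for band in self.bands:
            for kind in self.config.classify_kinds:
                stacked, ids, geom = self._stacked(band.label, kind)
                A, B = stacked[labels == "patient"], stacked[labels == "control"]
                stat = voxelwise_ttest(A, B, geometry=geom)
                resid = np.vstack([A - A.mean(0), B - B.mean(0)])
                res_maps = [
                    _as_map(r, geom) for r in resid
                ]
                fwhm = cfg.fwhm_mm or estimate_smoothness(res_maps)
                self.fwhm_mm = fwhm
                mc_cfg = dataclasses.replace(
                    cfg, fwhm_mm=tuple(fwhm), seed=self.config.seed + 2
                )
                min_extent = monte_carlo_cluster_threshold(
                    mask, mc_cfg, spec.voxel_size_mm
                )
                self.min_extent = min_extent
                clusters = extract_clusters(stat, cfg, min_extent)
                rows = [
                    {
                        "cluster_id": c.cluster_id,
                        "size": c.size,
                        "peak_x": c.peak_voxel[0],
                        "peak_y": c.peak_voxel[1],
                        "peak_z": c.peak_voxel[2],
                        "peak_mm_x": c.peak_mm[0],
                        "peak_mm_y": c.peak_mm[1],
                        "peak_mm_z": c.peak_mm[2],
                        "peak_t": c.peak_t,
                        "sign": c.sign,
                    }
                    for c in clusters
                ]
                pd.DataFrame(
                    rows,
                    columns=[
                        "cluster_id", "size", "peak_x", "peak_y", "peak_z",
                        "peak_mm_x", "peak_mm_y", "peak_mm_z", "peak_t", "sign",
                    ],
                ).to_csv(
                    self.out / f"clusters_{band.label}_{kind}.tsv",
                    sep="\t",
                    index=False,
                )
                results[f"{band.label}/{kind}"] = {
                    "min_extent": min_extent,
                    "fwhm_mm": [round(f, 3) for f in fwhm],
                    "n_clusters": len(clusters),
                }
        with open(self.out / "stats.json", "w") as fh:
            json.dump(results, fh, indent=2, sort_keys=True)
        self._record("stats", t0, **{"n_contrasts": len(results)})

    def classify(self):
        t0 = time.time()
        self._require("maps", "fcd")
        if self.min_extent is None:
            raise RuntimeError("missing upstream artifact 'min_extent': run stage 'stats' first")
        cohort_maps = {}
        geom = None
        for band in self.bands:
            for kind in self.config.classify_kinds:
                stacked, ids, geom = self._stacked(band.label, kind)
                cohort_maps[(band.label, kind)] = stacked
        cohort_maps["geometry"] = geom
        labels = np.asarray(self.table["group"])
        report = loocv_classify(
            cohort_maps,
            labels,
            subject_ids=list(self.table["subject_id"]),
            svm_config=self.config.svm,
            cfg=self.config.correction,
            min_extent=self.min_extent,
        )
        report.to_json(self.out / "classification.json")
        scores = [f.decision_score for f in report.folds]
        truth = [f.true_label for f in report.folds]
        roc_points(scores, truth).to_csv(self.out / "roc.tsv", sep="\t", index=False)
        self._record(
            "classify",
            t0,
            accuracy_pct=report.accuracy_pct,
            auc=report.auc,
            featureless_folds=sum(1 for f in report.folds if f.n_features == 0),
        )

    def run(self):
        for stage in STAGE_ORDER:
            if stage in self.config.stages:
                log.info("stage %s", stage)
                getattr(self, stage)()
        fio.write_manifest(
            self.out, self.config.to_dict(), self.config.seed, self.manifest_entries
        )
        return self


def _as_map(values, geom):
    from .fcd import FcdMap

    vi, gs, vs = geom
    return FcdMap(
        values=values, voxel_index=vi, grid_shape=gs, voxel_size_mm=vs,
        kind="global", stage="zscored",
    )


def run_pipeline(config: RunConfig) -> PipelineRun:
    """Execute the configured stages in canonical order; returns the run."""
    return PipelineRun(config).run()
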