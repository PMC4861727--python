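"""End-to-end orchestration: simulate -> preprocess -> DC -> group stats.

A run is fully described by a :class:`RunConfig` (YAML-serializable); the
single seed is expanded deterministically into per-stage substreams, so
re-running an identical config reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import centrality, groupstats, preprocess, synthio

log = logging.getLogger("voxdc")


@dataclass
class RunConfig:
    """Parameters of a full pipeline run (defaults follow the study protocol)."""

    cohort: synthio.CohortConfig = field(default_factory=synthio.CohortConfig)
    n_discard: int = 10
    trans_max_mm: float = 1.5
    rot_max_deg: float = 1.5
    low_hz: float = 0.01
    high_hz: float = 0.08
    r_threshold: float = 0.25
    mode: str = "weighted"
    fwhm_mm: float = 4.0
    gm_threshold: float = 0.20
    voxel_p: float = 0.01
    alpha: float = 0.01
    rmm_mm: float = 5.0
    n_iterations: int = 1000
    seed: int = 0
    outdir: str = "voxdc_run"

    def __post_init__(self) -> None:
        if self.mode not in ("weighted", "binarized"):
            raise ValueError("mode must be 'weighted' or 'binarized'")
        if not (0 < self.voxel_p < 1 and 0 < self.alpha <= 1):
            raise ValueError("voxel_p and alpha must be valid probabilities")

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort_raw = raw.pop("cohort", {})
        acq_raw = cohort_raw.pop("acquisition", {}) if cohort_raw else {}
        for key in ("grid_shape", "voxel_size_mm"):
            if key in acq_raw:
                acq_raw[key] = tuple(acq_raw[key])
        acq = synthio.AcquisitionConfig(**acq_raw)
        if "n_per_group" in cohort_raw:
            cohort_raw["n_per_group"] = tuple(cohort_raw["n_per_group"])
        cohort = synthio.CohortConfig(acquisition=acq, **cohort_raw)
        return cls(cohort=cohort, **raw)

    def to_yaml(self, path: Path | str) -> None:
        d = dataclasses.asdict(self)
        d["cohort"]["acquisition"].pop("affine", None)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, default_flow_style=None)


def _stage_seeds(seed: int) -> dict[str, int]:
    names = ["cohort", "alphasim"]
    states = np.random.SeedSequence([seed, 99]).generate_state(len(names)) % (2**31)
    return {name: int(s) for name, s in zip(names, states)}


def subject_zmaps(
    config: RunConfig,
) -> tuple[dict[str, list[np.ndarray]], np.ndarray, synthio.CohortTruth, list, list]:
    """In-memory cohort analysis up to per-subject smoothed z-maps.

    Returns (zmaps per group, analysis mask, truth, records, QC rows).
    Subjects failing motion QC are excluded (and logged), mirroring a
    clinical exclusion report.
    """
    seeds = _stage_seeds(config.seed)
    cohort = dataclasses.replace(config.cohort, seed=seeds["cohort"])
    acq = cohort.acquisition
    truth = synthio.build_truth(cohort)
    n_total = sum(cohort.n_per_group)
    subj_seeds = np.random.SeedSequence([cohort.seed, 2]).generate_state(n_total) % (2**31)

    zmaps: dict[str, list[np.ndarray]] = {"A": [], "B": []}
    records, qc_rows = [], []
    mask = None
    i = 0
    for group, n in zip(("A", "B"), cohort.n_per_group):
        for j in range(n):
            data, motion, rec = synthio.simulate_subject(
                cohort, truth, group, int(subj_seeds[i])
            )
            rec.subject_id = f"sub-{group}{j:03d}"
            i += 1
            res = preprocess.preprocess_subject(
                data,
                motion,
                truth.gm_probability,
                acq.tr_seconds,
                n_discard=config.n_discard,
                trans_max_mm=config.trans_max_mm,
                rot_max_deg=config.rot_max_deg,
                low_hz=config.low_hz,
                high_hz=config.high_hz,
            )
            qc_rows.append(
                {
                    "subject_id": rec.subject_id,
                    "mean_fd": res.fd.mean_fd,
                    "max_trans_mm": res.qc.max_trans_mm,
                    "max_rot_deg": res.qc.max_rot_deg,
                    "excluded_flag": int(res.qc.excluded),
                }
            )
            if res.qc.excluded:
                log.warning(
                    "excluding %s: motion offenders %s",
                    rec.subject_id,
                    res.qc.offenders[:5],
                )
                continue
            z, mask = centrality.dc_zmap(
                res.data,
                truth.gm_probability,
                r_threshold=config.r_threshold,
                mode=config.mode,
                fwhm_mm=config.fwhm_mm,
                voxel_size_mm=acq.voxel_size_mm,
                gm_threshold=config.gm_threshold,
            )
            zmaps[group].append(z)
            records.append(rec)
    if mask is None:
        raise RuntimeError("all subjects were excluded by motion QC")
    return zmaps, mask, truth, records, qc_rows


def analyze_cohort(
    zmaps: dict[str, list[np.ndarray]],
    mask: np.ndarray,
    config: RunConfig,
    null: groupstats.NullClusterDistribution | None = None,
) -> tuple[groupstats.TMap, pd.DataFrame, groupstats.NullClusterDistribution]:
    """Group t-map + Monte Carlo extent threshold + cluster table."""
    acq = config.cohort.acquisition
    if null is None:
        null = groupstats.alphasim_threshold(
            acq.grid_shape,
            acq.voxel_size_mm,
            config.fwhm_mm,
            config.voxel_p,
            config.rmm_mm,
            config.alpha,
            config.n_iterations,
            seed=_stage_seeds(config.seed)["alphasim"],
        )
    tmap = groupstats.two_sample_t(zmaps["A"], zmaps["B"], mask)
    table = groupstats.cluster_report(
        tmap,
        config.voxel_p,
        null.extent_threshold_voxels,
        config.rmm_mm,
        acq.voxel_size_mm,
        acq.affine,
    )
    return tmap, table, null


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write outputs + a provenance manifest.

    Outputs under ``config.outdir``: the simulated cohort, a QC TSV, the
    group t-map (NIfTI), the null distribution (JSON), the cluster table
    (TSV) and a score-correlation report (TSV). Returns the manifest dict.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    acq = config.cohort.acquisition
    timings: dict[str, float] = {}
    manifest: dict = {
        "parameters": {
            k: v
            for k, v in dataclasses.asdict(config).items()
            if k not in ("cohort", "outdir")
        },
        "seed": config.seed,
    }

    stage = "simulate+preprocess+centrality"
    t0 = time.time()
    try:
        zmaps, mask, truth, records, qc_rows = subject_zmaps(config)
    except Exception as exc:  # noqa: BLE001 - annotate stage and re-raise
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    timings[stage] = time.time() - t0
    pd.DataFrame(qc_rows).to_csv(outdir / "qc.tsv", sep="\t", index=False)

    stage = "groupstats"
    t0 = time.time()
    try:
        tmap, table, null = analyze_cohort(zmaps, mask, config)
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    timings[stage] = time.time() - t0

    nib.save(
        nib.Nifti1Image(tmap.data.astype(np.float32), acq.affine),
        outdir / "group_tmap.nii.gz",
    )
    table.to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    with open(outdir / "null_distribution.json", "w") as fh:
        json.dump(null.to_dict(), fh)

    # covariate-adjusted correlation of regional DC with the clinical score
    # in the patient-like group
    b_records = [r for r in records if r.group == "B"]
    corr_row = {}
    if len(b_records) > 5:
        region_z = groupstats.extract_region_z(zmaps["B"], truth.score_region_mask)
        scores = np.array([r.clinical_score for r in b_records])
        ages = np.array([r.age for r in b_records])
        sexes = np.array([1.0 if r.sex == "M" else 0.0 for r in b_records])
        r, p, n = groupstats.partial_correlation(
            region_z, scores, np.column_stack([ages, sexes])
        )
        corr_row = {"region": "score_region", "r": r, "p": p, "n": n}
        pd.DataFrame([corr_row]).to_csv(
            outdir / "score_correlation.tsv", sep="\t", index=False
        )

    manifest.update(
        {
            "n_subjects_analyzed": {g: len(v) for g, v in zmaps.items()},
            "extent_threshold_voxels": null.extent_threshold_voxels,
            "n_clusters": int(len(table)),
            "score_correlation": corr_row,
            "timings_seconds": {k: round(v, 3) for k, v in timings.items()},
            "outputs": {},
        }
    )
    for p_ in sorted(outdir.glob("*")):
        if p_.is_file() and p_.name != "manifest.json":
            manifest["outputs"][p_.name] = _sha256(p_)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
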