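"""End-to-end driver: phantom -> cohort -> parcellation -> MPM -> metrics -> stats.

Stages write their products under the configured output directory and later
stages read them back from disk, so a run can be resumed or partially
re-executed, and a missing per-subject file fails loudly with the stage and
subject named.  Every JSON sidecar carries the configuration hash; stages
refuse to consume outputs stamped with a different hash.  The whole run is
deterministic given the master seed.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .config import RunConfig, check_config_hash
from .metrics import compute_sdi, records_to_table, sample_parcel_fa
from .parcellation import (
    Parcellation, build_mpm, two_step_parcellate, TERRITORY_LABELS,
)
from .phantom import SIDES, build_cohort, build_phantom, default_phantom_spec
from .tracking import TrackingParams

log = logging.getLogger(__name__)

MEASURES = ("sdi_striatum", "sdi_midbrain", "fa")


def _subject_dirs(out):
    return Path(out) / "phantom", Path(out) / "cohort", \
        Path(out) / "parcellations", Path(out) / "mpm"


def _load_meta(path, cfg_hash, source):
    meta = json.loads(Path(path).read_text())
    check_config_hash(meta, cfg_hash, source=str(path))
    return meta


def stage_phantom(config: RunConfig, out_dir=None):
    """Build the phantom and write its volumes and orientation field."""
    out = Path(out_dir or config.out_dir)
    ph_dir = out / "phantom"
    ph_dir.mkdir(parents=True, exist_ok=True)
    ph = config.phantom
    spec = default_phantom_spec(
        grid_shape=ph.grid_shape, voxel_size=ph.voxel_size,
        crossing_fraction=ph.crossing_fraction,
        angular_noise_deg=ph.angular_noise_deg,
        rng_seed=config.master_seed)
    phantom = build_phantom(spec)
    A = phantom.affine
    for name, mask in phantom.seed_masks.items():
        mio.write_volume(ph_dir / f"{name}.nii.gz", mask, A, config.hash)
        mio.write_volume(ph_dir / f"{name}_truth.nii.gz",
                         phantom.ground_truth.territories[name], A,
                         config.hash)
    for side in SIDES:
        mio.write_volume(ph_dir / f"cortical_targets_{side}.nii.gz",
                         phantom.cortical_targets[side], A, config.hash)
    phantom.field.to_nifti().to_filename(str(ph_dir / "orientation_field.nii.gz"))
    (ph_dir / "phantom.json").write_text(json.dumps({
        "config_hash": config.hash,
        "labels": list(TERRITORY_LABELS),
        "grid_shape": list(spec.grid_shape),
        "voxel_size": spec.voxel_size,
    }, indent=2))
    return phantom


def stage_cohort(config: RunConfig, phantom=None, out_dir=None):
    """Generate per-subject FA volumes and the cohort manifest."""
    out = Path(out_dir or config.out_dir)
    co_dir = out / "cohort"
    co_dir.mkdir(parents=True, exist_ok=True)
    if phantom is None:
        phantom = stage_phantom(config, out)
    cohort = build_cohort(phantom, _cohort_spec(config))
    A = phantom.affine
    for i, row in cohort.manifest.iterrows():
        mio.write_volume(co_dir / f"{row.subject}_fa.nii.gz",
                         cohort.fa_volumes[i], A, config.hash)
    manifest = cohort.manifest.to_dict(orient="records")
    (co_dir / "manifest.json").write_text(json.dumps({
        "config_hash": config.hash, "subjects": manifest}, indent=2))
    return cohort


def _cohort_spec(config):
    spec = config.cohort
    # cohort seeds derive from the master seed unless explicitly pinned
    if spec.master_seed == 0 and config.master_seed != 0:
        spec = type(spec)(**{**spec.__dict__,
                             "master_seed": config.master_seed})
    return spec


def _subject_tracking_seed(subject_seed, salt):
    ss = np.random.SeedSequence([int(subject_seed), int(salt)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def stage_parcellate(config: RunConfig, phantom=None, out_dir=None,
                     save_tractograms=None):
    """Two-step parcellation per subject and side, written as label volumes.

    With ``save_tractograms`` (or the config flag) the step-1 and step-2
    tractograms are also serialized as TCK + JSON sidecars.
    """
    out = Path(out_dir or config.out_dir)
    pc_dir = out / "parcellations"
    pc_dir.mkdir(parents=True, exist_ok=True)
    if phantom is None:
        phantom = stage_phantom(config, out)
    manifest = _read_manifest(out, config)
    A = phantom.affine
    if save_tractograms is None:
        save_tractograms = config.parcellation.save_tractograms
    if save_tractograms:
        (out / "tractograms").mkdir(parents=True, exist_ok=True)
    results = {}
    for row in manifest:
        subject = row["subject"]
        t0 = time.perf_counter()
        try:
            for side in SIDES:
                params = TrackingParams(**{
                    **config.tracking.__dict__,
                    "rng_seed": _subject_tracking_seed(
                        row["rng_seed"], 1000 + (side == "R"))})
                striatal, midbrain, tg1, tg2 = two_step_parcellate(
                    phantom.seed_masks[f"striatum_{side}"],
                    phantom.cortical_targets[side],
                    phantom.seed_masks[f"midbrain_{side}"],
                    phantom.field, params,
                    endpoints_only=config.parcellation.endpoints_only,
                    provenance=dict(subject=subject, side=side,
                                    config_hash=config.hash),
                    return_tractograms=True)
                for seed, parc in (("striatum", striatal),
                                   ("midbrain", midbrain)):
                    mio.write_volume(
                        pc_dir / f"{subject}_{seed}_{side}.nii.gz",
                        parc.labels, A, config.hash)
                if save_tractograms:
                    for seed, tg in (("striatum", tg1), ("midbrain", tg2)):
                        mio.write_tck(
                            tg, out / "tractograms"
                            / f"{subject}_{seed}_{side}.tck",
                            config_hash=config.hash)
                results[(subject, side)] = (striatal, midbrain)
        except Exception as e:
            raise RuntimeError(
                f"stage parcellate failed for subject {subject}: {e}") from e
        log.info("parcellated %s in %.2fs", subject,
                 time.perf_counter() - t0)
    (pc_dir / "parcellations.json").write_text(json.dumps({
        "config_hash": config.hash,
        "labels": list(TERRITORY_LABELS)}, indent=2))
    return results


def _read_manifest(out, config):
    mpath = Path(out) / "cohort" / "manifest.json"
    if not mpath.exists():
        raise FileNotFoundError(
            f"stage requires cohort manifest {mpath}; run stage_cohort first")
    return _load_meta(mpath, config.hash, "manifest")["subjects"]


def _load_parcellation(out, config, subject, seed, side, seed_mask):
    p = Path(out) / "parcellations" / f"{subject}_{seed}_{side}.nii.gz"
    if not p.exists():
        raise FileNotFoundError(
            f"parcellation missing for subject {subject}: {p}")
    labels, _ = mio.read_volume(p)
    return Parcellation(labels=np.asarray(labels, np.int16),
                        seed_mask=seed_mask,
                        provenance=dict(subject=subject, side=side))


def stage_mpm(config: RunConfig, phantom=None, out_dir=None):
    """Group maximum probability maps, HC and SZ separately, per seed ROI."""
    out = Path(out_dir or config.out_dir)
    mpm_dir = out / "mpm"
    mpm_dir.mkdir(parents=True, exist_ok=True)
    if phantom is None:
        phantom = stage_phantom(config, out)
    manifest = _read_manifest(out, config)
    A = phantom.affine
    thr = config.parcellation.mpm_threshold
    mpms = {}
    for group in ("HC", "SZ"):
        rows = [r for r in manifest if r["diagnosis"] == group]
        for seed in ("striatum", "midbrain"):
            for side in SIDES:
                parcs = [
                    _load_parcellation(out, config, r["subject"], seed, side,
                                       phantom.seed_masks[f"{seed}_{side}"])
                    for r in rows]
                mpm = build_mpm(parcs, threshold=thr)
                mpms[(group, seed, side)] = mpm
                binmaps = mpm.thresholded()
                vol = np.zeros(mpm.counts.shape[1:], dtype=np.int16)
                for k, lab in enumerate(mpm.label_names, start=1):
                    vol[binmaps[lab]] = k
                mio.write_volume(
                    mpm_dir / f"mpm_{group}_{seed}_{side}.nii.gz",
                    vol, A, config.hash)
    (mpm_dir / "mpm.json").write_text(json.dumps({
        "config_hash": config.hash, "threshold": thr,
        "min_subjects": {g: mpms[(g, "striatum", "L")].min_subjects()
                         for g in ("HC", "SZ")}}, indent=2))
    return mpms


def stage_metrics(config: RunConfig, phantom=None, out_dir=None):
    """Per-subject SDI and FA records pooled into one long-format TSV."""
    out = Path(out_dir or config.out_dir)
    if phantom is None:
        phantom = stage_phantom(config, out)
    manifest = _read_manifest(out, config)
    popt = config.parcellation
    sdi_records, fa_records = [], []

    shared_points = {}
    if popt.shared_fa_tracks:
        # shared FA streamline geometry: tracked once per side and territory
        # from the phantom's ground-truth parcels (identical for all
        # subjects of one phantom); FA volumes still differ per subject
        from .metrics import sample_fa_tracks, streamline_points
        for side in SIDES:
            truth = phantom.ground_truth.territories[f"midbrain_{side}"]
            for k, lab in enumerate(TERRITORY_LABELS, start=1):
                params = TrackingParams(**{
                    **config.tracking.__dict__,
                    "n_streamlines": popt.fa_n_streamlines,
                    "rng_seed": _subject_tracking_seed(
                        config.master_seed, 7000 + 10 * k + (side == "R"))})
                tg = sample_fa_tracks(truth == k, phantom.field, params)
                shared_points[(side, lab)] = streamline_points(tg)

    for row in manifest:
        subject = row["subject"]
        fa_path = Path(out) / "cohort" / f"{subject}_fa.nii.gz"
        if not fa_path.exists():
            raise FileNotFoundError(
                f"stage metrics: FA volume missing for subject {subject}: "
                f"{fa_path}")
        fa_vol, fa_aff = mio.read_volume(fa_path)
        mio.check_same_affine([phantom.affine, fa_aff],
                              names=["phantom", f"{subject}_fa"])
        try:
            for side in SIDES:
                for seed, measure in (("striatum", "sdi_striatum"),
                                      ("midbrain", "sdi_midbrain")):
                    parc = _load_parcellation(
                        out, config, subject, seed, side,
                        phantom.seed_masks[f"{seed}_{side}"])
                    recs = compute_sdi(parc, subject=subject,
                                       diagnosis=row["diagnosis"], side=side)
                    sdi_records.append((measure, recs, parc))
                # FA along streamlines seeded from each midbrain parcel
                parc = _load_parcellation(
                    out, config, subject, "midbrain", side,
                    phantom.seed_masks[f"midbrain_{side}"])
                for k, lab in enumerate(TERRITORY_LABELS, start=1):
                    params = TrackingParams(**{
                        **config.tracking.__dict__,
                        "n_streamlines": popt.fa_n_streamlines,
                        "rng_seed": _subject_tracking_seed(
                            row["rng_seed"], 5000 + 10 * k + (side == "R"))})
                    pts = shared_points.get((side, lab))
                    mask = parc.labels == k
                    if pts is None and not mask.any():
                        log.warning("subject %s: midbrain parcel %r empty; "
                                    "FA record skipped", subject, lab)
                        continue
                    fa_records.append(sample_parcel_fa(
                        mask, phantom.field, fa_vol, params,
                        subject=subject, diagnosis=row["diagnosis"],
                        side=side, parcel=lab, interp=popt.fa_interp,
                        points_mm=pts))
        except FileNotFoundError:
            raise
        except Exception as e:
            raise RuntimeError(
                f"stage metrics failed for subject {subject}: {e}") from e

    tables = []
    for measure in ("sdi_striatum", "sdi_midbrain"):
        recs = [r for m, rs, _ in sdi_records if m == measure for r in rs]
        tables.append(records_to_table(recs, measure))
    tables.append(records_to_table([r for r in fa_records if r], "fa"))
    table = pd.concat(tables, ignore_index=True)
    table.to_csv(Path(out) / "metrics.tsv", sep="\t", index=False,
                 float_format="%.10g")
    (Path(out) / "metrics.json").write_text(json.dumps({
        "config_hash": config.hash, "n_rows": len(table)}, indent=2))
    return table


def stage_stats(config: RunConfig, out_dir=None):
    """Group analysis of the metrics table; JSON report + summary TSV."""
    from .stats import run_group_analysis

    out = Path(out_dir or config.out_dir)
    mpath = out / "metrics.tsv"
    if not mpath.exists():
        raise FileNotFoundError(f"stage stats requires {mpath}")
    check_config_hash(json.loads((out / "metrics.json").read_text()),
                      config.hash, source="metrics.json")
    table = pd.read_csv(mpath, sep="\t")
    manifest = _read_manifest(out, config)
    report = run_group_analysis(
        table, measures=[m for m in MEASURES
                         if m in set(table["measure"])],
        alpha=config.stats.alpha, ss_type=config.stats.ss_type,
        expected_subjects=[r["subject"] for r in manifest])
    payload = report.to_dict()
    payload["config_hash"] = config.hash
    (out / "stats.json").write_text(json.dumps(payload, indent=2))
    pd.concat(
        [s.assign(measure=m) for m, s in report.summaries.items()],
        ignore_index=True,
    ).to_csv(out / "summary.tsv", sep="\t", index=False, float_format="%.10g")
    return report


def run_all(config: RunConfig, out_dir=None):
    """Run every stage in order; returns the final group report."""
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_config.yaml").write_text(config.to_yaml())
    stages = []
    t0 = time.perf_counter()
    phantom = stage_phantom(config, out)
    stages.append(("phantom", time.perf_counter() - t0))
    for name, fn in (("cohort", stage_cohort),
                     ("parcellate", stage_parcellate),
                     ("mpm", stage_mpm),
                     ("metrics", stage_metrics)):
        t = time.perf_counter()
        fn(config, phantom=phantom, out_dir=out)
        stages.append((name, time.perf_counter() - t))
    t = time.perf_counter()
    report = stage_stats(config, out_dir=out)
    stages.append(("stats", time.perf_counter() - t))
    for name, dt in stages:
        log.info("stage %-10s %.2fs", name, dt)
    return report
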