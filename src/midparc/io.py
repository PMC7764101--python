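"""Volume and streamline I/O.

NIfTI-1 for all volumes (RAS affines preserved; integer label volumes
round-trip exactly), TCK for streamlines (mm coordinates, readable by
standard tractography viewers), JSON sidecars for tractogram metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .tracking import Status, Tractogram, TrackingParams


def write_volume(path, data, affine=None, descrip=""):
    """Write a 3-D volume as NIfTI-1 (int volumes stay int)."""
    data = np.asarray(data)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    if data.dtype in (np.int64,):
        data = data.astype(np.int32)
    img = nib.Nifti1Image(data, np.eye(4) if affine is None else affine)
    if descrip:
        img.header["descrip"] = descrip.encode()[:79]
    nib.save(img, str(path))
    return Path(path)


def read_volume(path):
    """Read a NIfTI volume; returns (data, affine). 3-D input only."""
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise ValueError(
            f"{path}: expected a 3-D volume, got shape {tuple(img.shape)}")
    return np.asarray(img.dataobj), img.affine


def check_same_affine(affines, names=None, atol=1e-6):
    """Raise when volumes of one subject disagree on their affine."""
    affines = [np.asarray(a, float) for a in affines]
    names = names or [f"volume{i}" for i in range(len(affines))]
    ref = affines[0]
    for a, n in zip(affines[1:], names[1:]):
        if not np.allclose(a, ref, atol=atol):
            raise ValueError(
                f"affine mismatch between {names[0]!r} and {n!r}")


def write_tck(tractogram: Tractogram, path, sidecar=True, config_hash=""):
    """Serialize streamlines to TCK plus a JSON metadata sidecar."""
    path = Path(path)
    streams = [np.asarray(tractogram.points[i, : tractogram.lengths[i]],
                          dtype=np.float32)
               for i in range(len(tractogram))]
    nt = nib.streamlines.Tractogram(streams, affine_to_rasmm=np.eye(4))
    nib.streamlines.save(nt, str(path))
    if sidecar:
        meta = {
            "seed_roi": tractogram.seed_roi,
            "n_streamlines": len(tractogram),
            "target_names": list(tractogram.target_names),
            "target_counts": tractogram.target_counts,
            "statuses": {s.name.lower(): int(np.sum(tractogram.statuses == s))
                         for s in Status},
            "params": dict(tractogram.params.__dict__),
            "config_hash": config_hash,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return path


def read_tck(path):
    """Read a TCK file back into a list of (L, 3) float32 point arrays."""
    tf = nib.streamlines.load(str(path))
    return [np.asarray(s, dtype=np.float32) for s in tf.streamlines]


def tractogram_from_tck(path, params=None):
    """Rebuild a bare Tractogram (points only) from TCK + sidecar if present."""
    streams = read_tck(path)
    maxlen = max((len(s) for s in streams), default=1)
    P = np.full((len(streams), maxlen, 3), np.nan)
    lengths = np.zeros(len(streams), dtype=np.int64)
    for i, s in enumerate(streams):
        P[i, : len(s)] = s
        lengths[i] = len(s)
    side = Path(path).with_suffix(".json")
    meta = json.loads(side.read_text()) if side.exists() else {}
    return Tractogram(
        points=P, lengths=lengths,
        statuses=np.zeros(len(streams), dtype=np.int8),
        target_idx=np.zeros(len(streams), dtype=np.int32),
        seed_points=P[:, 0].copy() if len(streams) else np.zeros((0, 3)),
        target_names=tuple(meta.get("target_names", ())),
        seed_roi=meta.get("seed_roi", ""),
        params=TrackingParams(**meta["params"]) if "params" in meta
        else TrackingParams(),
    )
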