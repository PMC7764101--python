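"""Quantitative per-parcel read-outs: streamline density index and mean FA.

The streamline density index of a parcel is its volume as a percentage of
the seed-ROI volume,

    SDI = v_parcel / V_seed * 100,

so per parcellation the SDIs plus 100 times the unclassified fraction sum
to exactly 100.  Mean FA is sampled along freely propagated streamlines
(no target masks) seeded from each parcel, by trilinear interpolation of
the FA volume at every streamline point, pooled across streamlines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .parcellation import Parcellation
from .tracking import TrackingParams, draw_seed_points, track_batch

log = logging.getLogger(__name__)


@dataclass
class SDIRecord:
    subject: str
    diagnosis: str
    side: str
    parcel: str
    v_parcel: int
    v_seed: int

    @property
    def sdi(self):
        return 100.0 * self.v_parcel / self.v_seed


@dataclass
class FARecord:
    subject: str
    diagnosis: str
    side: str
    parcel: str
    mean_fa: float
    n_streamlines: int
    n_points: int


def compute_sdi(parcellation: Parcellation, subject="", diagnosis="",
                side="") -> list[SDIRecord]:
    """One SDI record per non-unclassified label of a parcellation."""
    V = parcellation.seed_volume
    return [
        SDIRecord(subject=subject, diagnosis=diagnosis, side=side,
                  parcel=name, v_parcel=parcellation.volume(name), v_seed=V)
        for name in parcellation.label_names
    ]


def interpolate_fa(fa_volume, points_mm, affine=None, interp="trilinear"):
    """FA values at mm points (trilinear by default, nearest as a switch)."""
    A = np.eye(4) if affine is None else np.asarray(affine, float)
    inv = np.linalg.inv(A)
    vox = points_mm @ inv[:3, :3].T + inv[:3, 3]
    order = 1 if interp == "trilinear" else 0
    return map_coordinates(np.asarray(fa_volume, float), vox.T, order=order,
                           mode="nearest")


def streamline_points(tractogram):
    """All points of all streamlines pooled into one (P, 3) array."""
    chunks = [tractogram.points[i, : tractogram.lengths[i]]
              for i in range(len(tractogram))]
    return np.concatenate(chunks, axis=0)


def sample_parcel_fa(parcel_mask, field, fa_volume, params: TrackingParams,
                     subject="", diagnosis="", side="", parcel="",
                     interp="trilinear", pooled=True,
                     points_mm=None) -> FARecord | None:
    """Mean FA along streamlines randomly seeded from one parcel.

    Streamlines propagate freely (no target masks) until field or angle
    termination; FA is interpolated at every point.  ``pooled`` averages
    over all points of all streamlines (default); otherwise per-streamline
    means are averaged.  An empty parcel is skipped with a warning.
    ``points_mm`` bypasses tracking and samples precomputed points (used
    when streamline geometry is shared across subjects of one phantom).
    """
    if points_mm is None:
        if not parcel_mask.any():
            log.warning("parcel %r of %s is empty; FA record skipped",
                        parcel, subject)
            return None
        tg = sample_fa_tracks(parcel_mask, field, params)
        n_stream = len(tg)
        if pooled:
            points_mm = streamline_points(tg)
        else:
            vals = [
                interpolate_fa(fa_volume, tg.points[i, : tg.lengths[i]],
                               field.affine, interp).mean()
                for i in range(len(tg))
            ]
            return FARecord(subject, diagnosis, side, parcel,
                            float(np.mean(vals)), n_stream,
                            int(tg.lengths.sum()))
    else:
        n_stream = params.n_streamlines
    fa = interpolate_fa(fa_volume, points_mm, field.affine, interp)
    return FARecord(subject, diagnosis, side, parcel, float(fa.mean()),
                    n_stream, len(fa))


def sample_fa_tracks(parcel_mask, field, params: TrackingParams):
    """Freely propagated streamlines seeded from a parcel (no targets)."""
    rng = np.random.default_rng(params.rng_seed)
    seeds = draw_seed_points(parcel_mask, params.n_streamlines, rng,
                             affine=field.affine, mode=params.seeding)
    return track_batch(field, seeds, None, params, rng)


def records_to_table(records, measure) -> pd.DataFrame:
    """Long-format table (subject, diagnosis, side, parcel, measure, value)."""
    rows = []
    for r in records:
        if r is None:
            continue
        value = r.sdi if isinstance(r, SDIRecord) else r.mean_fa
        rows.append(dict(subject=r.subject, diagnosis=r.diagnosis,
                         side=r.side, parcel=r.parcel, measure=measure,
                         value=value))
    return pd.DataFrame(rows)
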