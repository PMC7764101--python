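"""Probabilistic streamline tractography on discrete orientation fields.

Streamlines are propagated with a fixed step (default 1.25 mm) by drawing,
at every step, a direction from the current voxel's direction-weight
mixture restricted to a cone (default 30 degrees) around the incoming
direction, with candidate directions sign-flipped into the hemisphere of
the incoming direction.  A streamline terminates the first time a point
lands inside a target mask (target-inclusion semantics: the target point is
the last point and the streamline is counted for that target), or when the
local mixture is empty (``terminated_field``), when no candidate survives
the cone (``terminated_angle``), or at the safety step bound.

This is a first-order sampler over a discrete mixture — a deliberate
simplification of second-order FOD-amplitude integrators (iFOD2): the
downstream quantities of interest (topography of seed-to-target streamline
counts) depend on which bundle a streamline follows, not on the order of
the integrator.

All propagation is batched across streamlines with NumPy, which makes
5000-streamline tractograms on a 64^3 grid a sub-second operation.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from enum import IntEnum

import numpy as np

from .orientation import canonical_sign


class Status(IntEnum):
    """Why a streamline stopped."""

    REACHED_TARGET = 1
    TERMINATED_FIELD = 2
    TERMINATED_ANGLE = 3
    TERMINATED_MAXSTEPS = 4


@dataclass
class TrackingParams:
    n_streamlines: int = 5000
    step_size: float = 1.25          # mm
    max_angle_deg: float = 30.0      # per-step turning limit
    max_steps: int = 2000            # safety bound
    rng_seed: int = 0
    seeding: str = "volume"          # "volume" | "voxel"

    def validate(self):
        if self.step_size <= 0:
            raise ValueError("step_size must be positive")
        if not 0 < self.max_angle_deg < 90:
            raise ValueError("max_angle_deg must lie in (0, 90)")
        if self.n_streamlines < 1:
            raise ValueError("n_streamlines must be >= 1")
        if self.seeding not in ("volume", "voxel"):
            raise ValueError("seeding must be 'volume' or 'voxel'")


@dataclass
class Streamline:
    points: np.ndarray           # (L, 3) mm
    status: Status
    target: str | None           # target name when status == REACHED_TARGET
    seed_point: np.ndarray


@dataclass
class Tractogram:
    """All streamlines launched from one seed ROI."""

    points: np.ndarray           # (M, Lmax, 3), NaN padded
    lengths: np.ndarray          # (M,) point counts
    statuses: np.ndarray         # (M,) Status codes
    target_idx: np.ndarray       # (M,) 0 = none, 1..K target labels
    seed_points: np.ndarray      # (M, 3)
    target_names: tuple = ()
    seed_roi: str = ""
    params: TrackingParams = dc_field(default_factory=TrackingParams)
    affine: np.ndarray | None = None    # voxel-to-mm of the tracked space

    def __len__(self):
        return len(self.lengths)

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]

    def __getitem__(self, i):
        t = self.target_idx[i]
        return Streamline(
            points=self.points[i, : self.lengths[i]],
            status=Status(self.statuses[i]),
            target=self.target_names[t - 1] if t > 0 else None,
            seed_point=self.seed_points[i],
        )

    @property
    def target_counts(self):
        """Streamlines per target name; sums to the number reaching any."""
        c = np.bincount(self.target_idx, minlength=len(self.target_names) + 1)
        return {name: int(c[k + 1]) for k, name in enumerate(self.target_names)}


def _categorical(weights, rng):
    """Vectorized categorical draw per row; rows must have positive totals."""
    c = np.cumsum(weights, axis=1)
    r = rng.random(len(weights)) * c[:, -1]
    return np.minimum((r[:, None] >= c).sum(axis=1), weights.shape[1] - 1)


def sample_direction(field, pos, prev_dir, max_angle_deg, rng):
    """Draw one direction from the voxel mixture at ``pos`` (mm).

    Candidates are sign-flipped into the hemisphere of ``prev_dir`` and
    restricted to the ``max_angle_deg`` cone; returns ``None`` when the
    restricted mixture carries no weight (or ``pos`` is outside the grid).
    With ``prev_dir=None`` no cone applies and the polarity is random.
    """
    idx, inb = field.voxel_of(pos)
    d, w = field.mixture_at(idx, inb)
    d, w = canonical_sign(d[0]), w[0]
    if w.sum() <= 0:
        return None
    if prev_dir is None:
        k = _categorical(w[None], rng)[0]
        sign = 1.0 if rng.random() < 0.5 else -1.0
        return sign * d[k]
    prev = np.asarray(prev_dir, float)
    dots = d @ prev
    flip = np.where(dots < 0, -1.0, 1.0)
    d = d * flip[:, None]
    cosang = d @ prev
    ok = (w > 0) & (cosang >= np.cos(np.radians(max_angle_deg)) - 1e-12)
    if not ok.any():
        return None
    wr = np.where(ok, w, 0.0)
    k = _categorical(wr[None], rng)[0]
    return d[k]


def _probe(field, targets_vol, pos):
    """(target label, field nonzero) at mm positions; label 0 outside targets."""
    idx, inb = field.voxel_of(pos)
    safe = np.clip(idx, 0, np.array(field.grid_shape) - 1)
    lab = np.zeros(len(pos), dtype=np.int32)
    if targets_vol is not None:
        lab = np.where(inb, targets_vol[safe[:, 0], safe[:, 1], safe[:, 2]], 0)
    _, w = field.mixture_at(idx, inb)
    return lab, w.sum(axis=1) > 0


def track_batch(field, seeds, targets_vol, params, rng,
                target_names=(), seed_roi=""):
    """Propagate a batch of streamlines from given seed points (mm).

    The initial direction is drawn from the seed voxel's mixture with no
    cone constraint and a random polarity; if the very first step would
    terminate (leaves the field without hitting a target), the opposite
    polarity is attempted instead.
    """
    params.validate()
    h = params.step_size
    cosmax = np.cos(np.radians(params.max_angle_deg)) - 1e-12
    seeds = np.atleast_2d(np.asarray(seeds, float))
    M = len(seeds)
    gs = np.array(field.grid_shape)

    status = np.zeros(M, dtype=np.int8)
    tgt = np.zeros(M, dtype=np.int32)
    nsteps = np.zeros(M, dtype=np.int64)
    active = np.ones(M, dtype=bool)

    # initial directions
    idx, inb = field.voxel_of(seeds)
    d_all, w_all = field.mixture_at(idx, inb)
    d_all = canonical_sign(d_all)
    tot = w_all.sum(axis=1)
    dead = tot <= 0
    status[dead] = Status.TERMINATED_FIELD
    active[dead] = False

    prev = np.zeros((M, 3))
    signs = np.where(rng.random(M) < 0.5, 1.0, -1.0)
    ai = np.flatnonzero(active)
    if len(ai):
        k = _categorical(w_all[ai], rng)
        prev[ai] = d_all[ai, k] * signs[ai, None]
        # polarity retry on immediate failure
        p1 = seeds[ai] + h * prev[ai]
        lab1, ok1 = _probe(field, targets_vol, p1)
        fail = (lab1 == 0) & ~ok1
        prev[ai[fail]] *= -1.0

    cur = seeds.copy()
    snapshots = []
    for _ in range(params.max_steps):
        ai = np.flatnonzero(active)
        if len(ai) == 0:
            break
        newpos = cur[ai] + h * prev[ai]
        cur[ai] = newpos
        nsteps[ai] += 1
        snapshots.append((ai, newpos.copy()))

        idx = np.rint(newpos @ field._inv[:3, :3].T + field._inv[:3, 3]).astype(np.int64)
        inb = np.all((idx >= 0) & (idx < gs), axis=1)
        safe = np.clip(idx, 0, gs - 1)

        rem = np.ones(len(ai), dtype=bool)
        if targets_vol is not None:
            lab = np.where(inb, targets_vol[safe[:, 0], safe[:, 1], safe[:, 2]], 0)
            hit = lab > 0
            if hit.any():
                status[ai[hit]] = Status.REACHED_TARGET
                tgt[ai[hit]] = lab[hit]
                active[ai[hit]] = False
                rem &= ~hit

        ri = ai[rem]
        if len(ri) == 0:
            continue
        d = canonical_sign(field.directions[safe[rem, 0], safe[rem, 1], safe[rem, 2]])
        w = field.weights[safe[rem, 0], safe[rem, 1], safe[rem, 2]].copy()
        w[~inb[rem]] = 0.0
        p = prev[ri]
        dots = np.einsum("mnk,mk->mn", d, p)
        d = d * np.where(dots < 0, -1.0, 1.0)[:, :, None]
        cosang = np.einsum("mnk,mk->mn", d, p)
        ok = (w > 0) & (cosang >= cosmax)
        wtot = w.sum(axis=1)
        wok = np.where(ok, w, 0.0)
        wok_tot = wok.sum(axis=1)

        f_field = wtot <= 0
        f_angle = ~f_field & (wok_tot <= 0)
        status[ri[f_field]] = Status.TERMINATED_FIELD
        status[ri[f_angle]] = Status.TERMINATED_ANGLE
        active[ri[f_field | f_angle]] = False

        alive = ~(f_field | f_angle)
        if alive.any():
            k = _categorical(wok[alive], rng)
            prev[ri[alive]] = d[alive][np.arange(alive.sum()), k]

    status[active] = Status.TERMINATED_MAXSTEPS

    lengths = nsteps + 1
    P = np.full((M, int(lengths.max()), 3), np.nan)
    P[:, 0] = seeds
    for s, (ai, xp) in enumerate(snapshots):
        P[ai, s + 1] = xp

    return Tractogram(
        points=P, lengths=lengths, statuses=status.astype(np.int8),
        target_idx=tgt, seed_points=seeds, target_names=tuple(target_names),
        seed_roi=seed_roi, params=params, affine=field.affine.copy(),
    )


def track_streamline(field, start, targets_vol, params, rng,
                     target_names=()) -> Streamline:
    """Track a single streamline from ``start`` (mm)."""
    tg = track_batch(field, np.asarray(start, float)[None], targets_vol,
                     params, rng, target_names=target_names)
    return tg[0]


def draw_seed_points(seed_mask, n, rng, affine=None, mode="volume"):
    """Seed points over the continuous volume of seed-ROI voxels (mm).

    ``volume`` draws voxels uniformly at random; ``voxel`` cycles through
    seed voxels round-robin.  Either way the point is uniform within the
    chosen voxel's cube.
    """
    vox = np.argwhere(seed_mask)
    if len(vox) == 0:
        raise ValueError("seed ROI is empty")
    if mode == "volume":
        pick = rng.integers(0, len(vox), size=n)
    else:
        order = rng.permutation(len(vox))
        pick = order[np.arange(n) % len(vox)]
    jitter = rng.random((n, 3)) - 0.5
    ijk = vox[pick] + jitter
    A = np.eye(4) if affine is None else affine
    return ijk @ A[:3, :3].T + A[:3, 3]


def seed_tractography(seed_mask, targets_vol, field, params,
                      target_names=(), seed_roi="") -> Tractogram:
    """The seeding front-end: ``n_streamlines`` attempts from the seed ROI.

    Seed points are uniform over the seed volume (attempts are not re-drawn
    until a quota of successes; every attempt is kept in the tractogram).
    """
    params.validate()
    rng = np.random.default_rng(params.rng_seed)
    seeds = draw_seed_points(seed_mask, params.n_streamlines, rng,
                             affine=field.affine, mode=params.seeding)
    return track_batch(field, seeds, targets_vol, params, rng,
                       target_names=target_names, seed_roi=seed_roi)
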