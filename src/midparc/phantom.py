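"""Digital tractography phantoms with known connectivity ground truth.

A phantom emulates, at desk scale, the anatomy exercised by the two-step
connectivity-based parcellation: a striatum-like seed whose three
territories (limbic, prefrontal, sensorimotor) are connected to three
cortex-like target groups by distinct fiber bundles stacked along a
ventro-dorsal gradient, and a midbrain-like seed (SNc/VTA stand-in) whose
medio-lateral subdivisions connect to the corresponding striatal
territories.  Left and right hemispheres are mirror images by default.

Everything is generated on a regular grid: integer label volumes for ROIs,
a discrete per-voxel orientation mixture (:class:`~midparc.orientation.
OrientationField`) standing in for the fiber orientation distribution, and
per-subject fractional-anisotropy volumes for a two-group (HC/SZ) cohort
with an injectable global FA offset.

The geometry is parametric, not anatomical: bundles are defined by
centerline polylines with rectangular perpendicular cross-sections, which
is sufficient to give every seed voxel a known ground-truth territory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .orientation import (
    MAX_DIRECTIONS,
    OrientationField,
    canonical_sign,
    normalize_weights,
)

#: Fixed territory label order (label codes 1, 2, 3 in every label volume).
TERRITORY_LABELS = ("limbic", "prefrontal", "sensorimotor")
SIDES = ("L", "R")


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class RegionSpec:
    """Axis-aligned box (``low <= index < high``) or ellipsoid region."""

    name: str
    kind: str = "box"  # "box" | "ellipsoid"
    low: tuple = (0, 0, 0)
    high: tuple = (0, 0, 0)
    center: tuple | None = None  # ellipsoid only, index units
    radii: tuple | None = None

    def mask(self, grid_shape):
        m = np.zeros(grid_shape, dtype=bool)
        if self.kind == "box":
            lo = np.maximum(np.asarray(self.low, int), 0)
            hi = np.minimum(np.asarray(self.high, int), grid_shape)
            if np.all(hi > lo):
                m[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
        elif self.kind == "ellipsoid":
            idx = np.indices(grid_shape, dtype=float)
            c = np.asarray(self.center, float).reshape(3, 1, 1, 1)
            r = np.asarray(self.radii, float).reshape(3, 1, 1, 1)
            m = (((idx - c) / r) ** 2).sum(axis=0) <= 1.0
        else:
            raise ValueError(f"unknown region kind {self.kind!r}")
        return m


@dataclass
class BundleSpec:
    """Fiber bundle: centerline polyline + rectangular cross-section.

    ``centerline`` is a sequence of mm points; the bundle occupies every
    voxel whose center lies within ``half_widths`` (per world axis, mm) of
    the centerline perpendicular to the local tangent.  The voxel's fiber
    direction is the local tangent.  ``seed``/``territory``/``target`` name
    the connectivity this bundle realizes.
    """

    name: str
    seed: str
    territory: str
    target: str
    centerline: tuple
    half_widths: tuple = (1.9, 1.9, 1.9)


@dataclass
class PhantomSpec:
    grid_shape: tuple = (64, 64, 64)
    voxel_size: float = 1.0
    seed_roi_defs: dict = dc_field(default_factory=dict)
    target_defs: dict = dc_field(default_factory=dict)
    territory_defs: dict = dc_field(default_factory=dict)  # seed -> {label: RegionSpec}
    bundle_defs: tuple = ()
    topography_axis: dict = dc_field(
        default_factory=lambda: {"striatum": 2, "midbrain": 0}
    )
    crossing_fraction: float = 0.0
    angular_noise_deg: float = 0.0
    rng_seed: int = 0

    @property
    def affine(self):
        a = np.eye(4)
        a[0, 0] = a[1, 1] = a[2, 2] = self.voxel_size
        return a

    def validate(self):
        if len(self.grid_shape) != 3 or any(g < 16 for g in self.grid_shape):
            raise ValueError("grid_shape must be three ints, each >= 16")
        if not 0.0 <= self.crossing_fraction <= 1.0:
            raise ValueError("crossing_fraction must lie in [0, 1]")
        masks = {}
        for name, reg in {**self.seed_roi_defs, **self.target_defs}.items():
            masks[name] = reg.mask(self.grid_shape)
        names = list(masks)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if np.any(masks[a] & masks[b]):
                    raise ValueError(
                        f"regions {a!r} and {b!r} overlap; seed and target "
                        "ROIs must be disjoint"
                    )
        # territories partition each seed
        for seed, terr in self.territory_defs.items():
            smask = masks[seed]
            cover = np.zeros(self.grid_shape, dtype=np.int32)
            for reg in terr.values():
                cover += (reg.mask(self.grid_shape) & smask).astype(np.int32)
            if np.any(cover[smask] != 1):
                raise ValueError(
                    f"territories of seed {seed!r} do not partition it"
                )
        return masks


@dataclass
class CohortSpec:
    """Two-group synthetic cohort of FA volumes.

    Defaults mirror the study conditions: 24 healthy controls (HC) vs 30
    schizophrenia patients (SZ), a baseline FA near 0.47 and a global
    SZ-minus-HC offset of -0.036, with per-voxel Gaussian noise.
    ``fa_subject_sd`` adds an optional between-subject random FA intercept
    (0 by default, where all variability is per-voxel noise).
    """

    n_hc: int = 24
    n_sz: int = 30
    fa_baseline: float = 0.47
    fa_group_offset: float = -0.036
    fa_noise_sd: float = 0.05
    fa_subject_sd: float = 0.0
    master_seed: int = 0

    def validate(self):
        if self.n_hc < 1 or self.n_sz < 1:
            raise ValueError("n_hc and n_sz must both be >= 1")
        if not 0.0 < self.fa_baseline < 1.0:
            raise ValueError("fa_baseline must lie in (0, 1)")
        if not 0.0 < self.fa_baseline + self.fa_group_offset < 1.0:
            raise ValueError("fa_baseline + fa_group_offset must lie in (0, 1)")
        for f in (self.fa_noise_sd, self.fa_subject_sd):
            if f < 0:
                raise ValueError("FA noise SDs must be nonnegative")

    def subject_seeds(self):
        """Deterministic per-subject integer seeds derived from master_seed."""
        ss = np.random.SeedSequence(self.master_seed)
        return [
            int(c.generate_state(1)[0] % (2 ** 31))
            for c in ss.spawn(self.n_hc + self.n_sz)
        ]


@dataclass
class GroundTruth:
    """Known voxel-to-territory maps (one int volume per seed ROI)."""

    territories: dict          # seed name -> int volume, 0 = none
    label_names: tuple = TERRITORY_LABELS


@dataclass
class Phantom:
    spec: PhantomSpec
    seed_masks: dict           # seed name -> bool volume
    cortical_targets: dict     # side -> int volume (labels 1..3)
    field: OrientationField
    ground_truth: GroundTruth

    @property
    def affine(self):
        return self.spec.affine


@dataclass
class Cohort:
    spec: CohortSpec
    manifest: pd.DataFrame     # subject, diagnosis, rng_seed, true_mean_fa
    fa_volumes: list           # float32 volumes, manifest order

    def fa_of(self, subject):
        i = self.manifest.index[self.manifest.subject == subject]
        if len(i) == 0:
            raise KeyError(f"unknown subject {subject!r}")
        return self.fa_volumes[int(i[0])]


# ---------------------------------------------------------------------------
# default geometry
# ---------------------------------------------------------------------------

def _mirror_box(low, high, nx):
    return (nx - high[0], low[1], low[2]), (nx - low[0], high[1], high[2])


def _mirror_pts(pts, nx, vs):
    pts = np.asarray(pts, float)
    out = pts.copy()
    out[:, 0] = (nx - 1) * vs - pts[:, 0]
    return out


def default_phantom_spec(grid_shape=(64, 64, 64), voxel_size=1.0,
                         crossing_fraction=0.0, angular_noise_deg=0.0,
                         rng_seed=0):
    """Canonical two-seed, three-territory, mirror-symmetric phantom.

    Geometry scales linearly with ``grid_shape`` (designed at 64 voxels per
    axis, 1 mm isotropic).  Striatal territories are slabs along the
    ventro-dorsal axis (z); midbrain territories are slabs along the
    medio-lateral axis (x).  Cortical bundles run straight along +y;
    midbrain bundles rise along +z and turn into the striatum through a
    quarter arc wide enough that the 30 degree per-step angular limit is
    never the binding constraint.
    """
    gx, gy, gz = grid_shape
    vs = float(voxel_size)

    def sx(v):  # scale canonical 64-grid coordinates per axis
        return int(round(v * gx / 64))

    def sy(v):
        return int(round(v * gy / 64))

    def sz(v):
        return int(round(v * gz / 64))

    # right-hemisphere canonical boxes (index space)
    str_lo, str_hi = (sx(34), sy(14), sz(22)), (sx(46), sy(22), sz(46))
    mb_lo, mb_hi = (sx(34), sy(5), sz(8)), (sx(46), sy(9), sz(12))
    tgt_ylo, tgt_yhi = sy(46), sy(54)

    n_slab_z = (str_hi[2] - str_lo[2]) // 3          # striatal slab depth
    n_slab_x = (mb_hi[0] - mb_lo[0]) // 3            # midbrain slab width

    seed_roi_defs, target_defs, territory_defs, bundles = {}, {}, {}, []

    def mid(lo, hi):
        # voxel centers of box [lo, hi) span lo .. hi-1
        return 0.5 * (lo + hi - 1)

    def half(lo, hi):
        # covers every voxel center with 0.4 vox margin, excludes neighbors
        return 0.5 * (hi - lo - 1) + 0.4

    for side in SIDES:
        def box(name, lo, hi):
            if side == "L":
                lo, hi = _mirror_box(lo, hi, gx)
            return RegionSpec(name=name, kind="box", low=tuple(lo), high=tuple(hi))

        striatum = f"striatum_{side}"
        midbrain = f"midbrain_{side}"
        seed_roi_defs[striatum] = box(striatum, str_lo, str_hi)
        seed_roi_defs[midbrain] = box(midbrain, mb_lo, mb_hi)

        territory_defs[striatum] = {}
        territory_defs[midbrain] = {}
        str_cx = mid(str_lo[0], str_hi[0])
        half_x = half(str_lo[0], str_hi[0])

        for k, lab in enumerate(TERRITORY_LABELS):
            zlo = str_lo[2] + k * n_slab_z
            zhi = str_lo[2] + (k + 1) * n_slab_z if k < 2 else str_hi[2]
            zc = mid(zlo, zhi)
            # striatal territory: z slab of the striatum
            territory_defs[striatum][lab] = box(
                f"{striatum}_{lab}", (str_lo[0], str_lo[1], zlo),
                (str_hi[0], str_hi[1], zhi))
            # cortical target box at matching z
            tname = f"{lab}_{side}"
            target_defs[tname] = box(
                tname, (str_lo[0], tgt_ylo, zlo), (str_hi[0], tgt_yhi, zhi))
            # straight cortical bundle along +y
            line = np.array([
                [str_cx, str_lo[1] - 2.0, zc],
                [str_cx, tgt_ylo + 2.0, zc],
            ]) * vs
            if side == "L":
                line = _mirror_pts(line, gx, vs)
            bundles.append(BundleSpec(
                name=f"cortical_{lab}_{side}", seed=striatum, territory=lab,
                target=tname, centerline=tuple(map(tuple, line)),
                half_widths=(half_x * vs, 1.0 * vs, half(zlo, zhi) * vs),
            ))

            # midbrain territory: x slab of the midbrain box
            xlo = mb_lo[0] + k * n_slab_x
            xhi = mb_lo[0] + (k + 1) * n_slab_x if k < 2 else mb_hi[0]
            territory_defs[midbrain][lab] = box(
                f"{midbrain}_{lab}", (xlo, mb_lo[1], mb_lo[2]),
                (xhi, mb_hi[1], mb_hi[2]))
            # curved midbrain bundle: vertical leg, quarter arc, horizontal leg
            xc = mid(xlo, xhi)
            yc = mid(mb_lo[1], mb_hi[1])
            arc_r = max(3.0, 6.0 * gz / 64) * vs
            y_turn = yc * vs + arc_r
            pts = [[xc * vs, yc * vs, (mb_lo[2] - 0.5) * vs]]
            z_arc0 = zc * vs - arc_r
            pts.append([xc * vs, yc * vs, z_arc0])
            for t in np.linspace(0.0, np.pi / 2, 13)[1:]:
                pts.append([
                    xc * vs,
                    y_turn - arc_r * np.cos(t),
                    z_arc0 + arc_r * np.sin(t),
                ])
            pts.append([xc * vs, (str_lo[1] + 3.5) * vs, zc * vs])
            pts = np.asarray(pts)
            if side == "L":
                pts = _mirror_pts(pts, gx, vs)
            hw = half(xlo, xhi) * vs
            bundles.append(BundleSpec(
                name=f"nigrostriatal_{lab}_{side}", seed=midbrain,
                territory=lab, target=f"{striatum}:{lab}",
                centerline=tuple(map(tuple, pts)),
                half_widths=(hw, hw, hw),
            ))

    return PhantomSpec(
        grid_shape=tuple(grid_shape), voxel_size=vs,
        seed_roi_defs=seed_roi_defs, target_defs=target_defs,
        territory_defs=territory_defs, bundle_defs=tuple(bundles),
        crossing_fraction=crossing_fraction,
        angular_noise_deg=angular_noise_deg, rng_seed=rng_seed,
    )


# ---------------------------------------------------------------------------
# phantom construction
# ---------------------------------------------------------------------------

def _densify(polyline, spacing):
    """Resample a polyline at ~`spacing` arc-length; returns (points, tangents)."""
    pts = np.asarray(polyline, float)
    out = [pts[0]]
    for a, b in zip(pts[:-1], pts[1:]):
        seg = b - a
        L = np.linalg.norm(seg)
        if L < 1e-12:
            continue
        n = max(1, int(np.ceil(L / spacing)))
        for i in range(1, n + 1):
            out.append(a + seg * (i / n))
    out = np.asarray(out)
    tan = np.gradient(out, axis=0)
    tan /= np.linalg.norm(tan, axis=1, keepdims=True)
    return out, tan


def _bundle_voxels(bundle, grid_shape, voxel_size):
    """Voxel indices covered by a bundle and the local tangent at each."""
    spacing = 0.5 * voxel_size
    samples, tangents = _densify(bundle.centerline, spacing)
    hw = np.asarray(bundle.half_widths, float)
    pad = hw.max() + voxel_size
    lo = np.maximum(np.floor((samples.min(0) - pad) / voxel_size), 0).astype(int)
    hi = np.minimum(
        np.ceil((samples.max(0) + pad) / voxel_size) + 1, grid_shape
    ).astype(int)
    if np.any(hi <= lo):
        return np.empty((0, 3), int), np.empty((0, 3))
    ix, iy, iz = np.mgrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    idx = np.stack([ix, iy, iz], axis=-1).reshape(-1, 3)
    centers = idx * voxel_size
    _, j = cKDTree(samples).query(centers)
    d = centers - samples[j]
    t = tangents[j]
    axial = np.einsum("ij,ij->i", d, t)
    dperp = d - axial[:, None] * t
    keep = (np.abs(axial) <= spacing + 1e-9) & np.all(
        np.abs(dperp) <= hw + 1e-9, axis=1
    )
    return idx[keep], t[keep]


def _perp_unit(t):
    """A unit vector perpendicular to each tangent (deterministic choice)."""
    ref = np.tile(np.array([1.0, 0.0, 0.0]), (len(t), 1))
    near = np.abs(t[:, 0]) > 0.9
    ref[near] = [0.0, 0.0, 1.0]
    p = ref - np.einsum("ij,ij->i", ref, t)[:, None] * t
    return p / np.linalg.norm(p, axis=1, keepdims=True)


def build_phantom(spec: PhantomSpec) -> Phantom:
    """Construct ROIs, ground-truth territories, and the orientation field."""
    masks = spec.validate()
    shape = tuple(spec.grid_shape)
    vs = spec.voxel_size

    seed_masks = {name: masks[name] for name in spec.seed_roi_defs}
    territories = {}
    for seed, terr in spec.territory_defs.items():
        vol = np.zeros(shape, dtype=np.int16)
        for k, lab in enumerate(TERRITORY_LABELS, start=1):
            if lab in terr:
                vol[terr[lab].mask(shape) & seed_masks[seed]] = k
        territories[seed] = vol

    cortical_targets = {}
    for side in SIDES:
        vol = np.zeros(shape, dtype=np.int16)
        for k, lab in enumerate(TERRITORY_LABELS, start=1):
            name = f"{lab}_{side}"
            if name in masks:
                vol[masks[name]] = k
        cortical_targets[side] = vol

    # orientation field assembly
    N = MAX_DIRECTIONS
    dirs = np.zeros(shape + (N, 3))
    wts = np.zeros(shape + (N,))
    cnt = np.zeros(shape, dtype=np.int8)

    def add(idx, dvec, w):
        if len(idx) == 0:
            return
        s = cnt[idx[:, 0], idx[:, 1], idx[:, 2]]
        ok = s < N
        if not np.all(ok):  # overflow: drop extra contributions (rare)
            idx, dvec, w, s = idx[ok], dvec[ok], w[ok] if np.ndim(w) else w, s[ok]
        ix, iy, iz = idx[:, 0], idx[:, 1], idx[:, 2]
        dirs[ix, iy, iz, s] = dvec
        wts[ix, iy, iz, s] = w
        cnt[ix, iy, iz] += 1

    cf = spec.crossing_fraction
    for bundle in spec.bundle_defs:
        idx, tan = _bundle_voxels(bundle, shape, vs)
        tan = canonical_sign(tan)
        add(idx, tan, (1.0 - cf) if cf > 0 else 1.0)
        if cf > 0:
            add(idx, canonical_sign(_perp_unit(tan)), cf)

    if spec.angular_noise_deg > 0:
        rng = np.random.default_rng(spec.rng_seed)
        nz = wts > 0
        d = dirs[nz]
        u = _perp_unit_random(d, rng)
        theta = rng.normal(0.0, np.radians(spec.angular_noise_deg), len(d))
        d = d * np.cos(theta)[:, None] + u * np.sin(theta)[:, None]
        dirs[nz] = canonical_sign(d)

    wts = normalize_weights(wts)
    field = OrientationField(dirs, wts, spec.affine)

    # postcondition: every territory has at least one bundle
    for seed, terr in spec.territory_defs.items():
        for lab in terr:
            if not any(b.seed == seed and b.territory == lab
                       for b in spec.bundle_defs):
                warnings.warn(
                    f"territory {lab!r} of seed {seed!r} has no bundle; its "
                    "voxels can never be classified", stacklevel=2)

    return Phantom(
        spec=spec, seed_masks=seed_masks, cortical_targets=cortical_targets,
        field=field, ground_truth=GroundTruth(territories=territories),
    )


def _perp_unit_random(d, rng):
    v = rng.standard_normal(d.shape)
    v -= np.einsum("ij,ij->i", v, d)[:, None] * d
    n = np.linalg.norm(v, axis=1, keepdims=True)
    n[n < 1e-12] = 1.0
    return v / n


# ---------------------------------------------------------------------------
# cohort construction
# ---------------------------------------------------------------------------

def build_cohort(phantom: Phantom, spec: CohortSpec) -> Cohort:
    """Per-subject FA volumes plus a subject manifest.

    FA of subject *i* is ``fa_baseline`` (plus ``fa_group_offset`` for SZ,
    plus an optional subject-level Gaussian intercept) with iid per-voxel
    Gaussian noise of SD ``fa_noise_sd``, clipped to [0, 1].
    """
    spec.validate()
    shape = tuple(phantom.spec.grid_shape)
    seeds = spec.subject_seeds()
    rows, volumes = [], []
    for i, seed in enumerate(seeds):
        is_sz = i >= spec.n_hc
        diagnosis = "SZ" if is_sz else "HC"
        subject = f"{diagnosis}{(i - spec.n_hc if is_sz else i) + 1:02d}"
        rng = np.random.default_rng(seed)
        mean = spec.fa_baseline + (spec.fa_group_offset if is_sz else 0.0)
        if spec.fa_subject_sd > 0:
            mean += spec.fa_subject_sd * rng.standard_normal()
        vol = mean + spec.fa_noise_sd * rng.standard_normal(shape)
        np.clip(vol, 0.0, 1.0, out=vol)
        volumes.append(vol.astype(np.float32))
        rows.append(dict(subject=subject, diagnosis=diagnosis,
                         rng_seed=seed, true_mean_fa=mean))
    manifest = pd.DataFrame(rows)
    return Cohort(spec=spec, manifest=manifest, fa_volumes=volumes)
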