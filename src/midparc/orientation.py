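"""Per-voxel discrete orientation fields.

The fiber orientation distribution of each voxel is represented as a small
mixture of unit directions with nonnegative weights (at most
:data:`MAX_DIRECTIONS` per voxel).  This discrete stand-in is sufficient to
drive probabilistic streamline propagation: the tracker only ever needs to
draw a direction from the voxel's mixture, optionally restricted to an
angular cone.

Conventions
-----------
* RAS axis order, 0-based indices, voxel-center world coordinates:
  ``mm = affine[:3, :3] @ index + affine[:3, 3]``.
* Directions are unit vectors; their sign is not meaningful (fibers have no
  polarity).  Samplers canonicalize signs before use.

Serialization: a 4-D NIfTI with ``4 * N`` volumes per voxel, laid out as
``[dx_1, dy_1, dz_1, w_1, dx_2, ...]`` (direction components then weight,
repeated per mixture slot).
"""

from __future__ import annotations

import numpy as np
import nibabel as nib

#: Maximum number of direction/weight slots stored per voxel.
MAX_DIRECTIONS = 4


class OrientationField:
    """Discrete direction-weight mixture defined on a regular 3-D grid.

    Parameters
    ----------
    directions : ndarray, shape (X, Y, Z, N, 3)
        Unit direction vectors (rows with zero weight are ignored).
    weights : ndarray, shape (X, Y, Z, N)
        Nonnegative mixture weights; voxels with a nonzero total are
        normalized to sum to one.
    affine : ndarray, shape (4, 4), optional
        Voxel-to-mm affine (RAS).  Defaults to identity (1 mm isotropic).
    """

    def __init__(self, directions, weights, affine=None):
        directions = np.asarray(directions, dtype=np.float64)
        weights = np.asarray(weights, dtype=np.float64)
        if directions.ndim != 5 or directions.shape[-1] != 3:
            raise ValueError("directions must have shape (X, Y, Z, N, 3)")
        if weights.shape != directions.shape[:4]:
            raise ValueError("weights shape must match directions[..., :4]")
        if np.any(weights < 0):
            raise ValueError("orientation weights must be nonnegative")
        self.directions = directions
        self.weights = weights
        self.affine = np.eye(4) if affine is None else np.asarray(affine, float)
        self._inv = np.linalg.inv(self.affine)
        self.grid_shape = directions.shape[:3]

    # -- geometry ---------------------------------------------------------

    def voxel_of(self, pos):
        """Nearest voxel index of mm position(s); returns (index, inbounds)."""
        pos = np.atleast_2d(np.asarray(pos, float))
        vox = pos @ self._inv[:3, :3].T + self._inv[:3, 3]
        idx = np.rint(vox).astype(np.int64)
        inb = np.all((idx >= 0) & (idx < np.array(self.grid_shape)), axis=1)
        return idx, inb

    def mixture_at(self, idx, inbounds=None):
        """Gather (directions, weights) for voxel indices, zeros out of grid."""
        idx = np.atleast_2d(idx)
        if inbounds is None:
            inbounds = np.all(
                (idx >= 0) & (idx < np.array(self.grid_shape)), axis=1
            )
        safe = np.clip(idx, 0, np.array(self.grid_shape) - 1)
        d = self.directions[safe[:, 0], safe[:, 1], safe[:, 2]].copy()
        w = self.weights[safe[:, 0], safe[:, 1], safe[:, 2]].copy()
        w[~inbounds] = 0.0
        return d, w

    def total_weight(self):
        """Per-voxel total mixture weight, shape (X, Y, Z)."""
        return self.weights.sum(axis=-1)

    def flipped(self):
        """Copy of the field with every stored direction sign-flipped."""
        return OrientationField(-self.directions, self.weights.copy(), self.affine)

    # -- serialization ----------------------------------------------------

    def to_nifti(self):
        X, Y, Z, N, _ = self.directions.shape
        out = np.empty((X, Y, Z, 4 * N), dtype=np.float32)
        for i in range(N):
            out[..., 4 * i : 4 * i + 3] = self.directions[..., i, :]
            out[..., 4 * i + 3] = self.weights[..., i]
        return nib.Nifti1Image(out, self.affine)

    @classmethod
    def from_nifti(cls, img):
        if isinstance(img, (str, bytes)) or hasattr(img, "__fspath__"):
            img = nib.load(str(img))
        data = np.asarray(img.dataobj, dtype=np.float64)
        if data.ndim != 4 or data.shape[-1] % 4 != 0:
            raise ValueError("orientation NIfTI must be 4-D with 4*N volumes")
        N = data.shape[-1] // 4
        dirs = np.stack(
            [data[..., 4 * i : 4 * i + 3] for i in range(N)], axis=3
        )
        w = np.stack([data[..., 4 * i + 3] for i in range(N)], axis=3)
        return cls(dirs, w, img.affine)


def canonical_sign(directions):
    """Flip direction signs so the first nonzero component is positive.

    Operates on the last axis; returns a new array.  Canonicalization makes
    every downstream computation invariant to the (physically meaningless)
    stored polarity of fiber directions.
    """
    d = np.array(directions, dtype=np.float64, copy=True)
    x, y, z = d[..., 0], d[..., 1], d[..., 2]
    eps = 1e-12
    neg = (x < -eps) | ((np.abs(x) <= eps) & (y < -eps)) | (
        (np.abs(x) <= eps) & (np.abs(y) <= eps) & (z < -eps)
    )
    d[neg] *= -1.0
    return d


def normalize_weights(weights):
    """Scale per-voxel weights to sum to one where the total is positive."""
    tot = weights.sum(axis=-1, keepdims=True)
    out = np.where(tot > 0, weights / np.where(tot > 0, tot, 1.0), 0.0)
    return out
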