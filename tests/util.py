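"""Shared test helpers: tiny hand-built orientation fields and independent
oracles (classical sums-of-squares ANOVA, dense streamline integration)."""

import itertools

import numpy as np
from scipy import stats as sps

from midparc import OrientationField


def make_field(shape, entries, voxel_size=1.0):
    """Build an OrientationField from {mask_or_slice: [(dir, w), ...]}."""
    dirs = np.zeros(tuple(shape) + (4, 3))
    wts = np.zeros(tuple(shape) + (4,))
    for mask, mix in entries:
        if isinstance(mask, np.ndarray):
            m = mask
        else:
            m = np.zeros(shape, bool)
            m[mask] = True
        for k, (d, w) in enumerate(mix):
            d = np.asarray(d, float)
            dirs[m, k] = d / np.linalg.norm(d)
            wts[m, k] = w
    aff = np.diag([voxel_size] * 3 + [1.0])
    return OrientationField(dirs, wts, aff)


def uniform_field(shape, direction, mask=None, voxel_size=1.0):
    m = np.ones(shape, bool) if mask is None else mask
    return make_field(shape, [(m, [(direction, 1.0)])], voxel_size)


# ---------------------------------------------------------------------------
# classical balanced three-way ANOVA oracle (direct SS decomposition)
# ---------------------------------------------------------------------------

def anova3_oracle(table, factors=("side", "parcel", "diagnosis")):
    """F/p/partial-eta for a *balanced* three-way design from cell means.

    Independent of the fitted-model route: sums of squares are computed
    directly from marginal means with the textbook formulas.
    """
    fa, fb, fc = factors
    La = sorted(table[fa].unique())
    Lb = sorted(table[fb].unique())
    Lc = sorted(table[fc].unique())
    a, b, c = len(La), len(Lb), len(Lc)
    y = table["value"].to_numpy()
    grand = y.mean()
    ncell = len(table) // (a * b * c)

    def mean_of(**kw):
        m = np.ones(len(table), bool)
        for f, lev in kw.items():
            m &= (table[f] == lev).to_numpy()
        return y[m].mean()

    mA = {i: mean_of(**{fa: i}) for i in La}
    mB = {j: mean_of(**{fb: j}) for j in Lb}
    mC = {k: mean_of(**{fc: k}) for k in Lc}
    mAB = {(i, j): mean_of(**{fa: i, fb: j}) for i in La for j in Lb}
    mAC = {(i, k): mean_of(**{fa: i, fc: k}) for i in La for k in Lc}
    mBC = {(j, k): mean_of(**{fb: j, fc: k}) for j in Lb for k in Lc}
    mABC = {(i, j, k): mean_of(**{fa: i, fb: j, fc: k})
            for i in La for j in Lb for k in Lc}

    ss = {}
    ss[fa] = ncell * b * c * sum((mA[i] - grand) ** 2 for i in La)
    ss[fb] = ncell * a * c * sum((mB[j] - grand) ** 2 for j in Lb)
    ss[fc] = ncell * a * b * sum((mC[k] - grand) ** 2 for k in Lc)
    ss[f"{fa}:{fb}"] = ncell * c * sum(
        (mAB[i, j] - mA[i] - mB[j] + grand) ** 2 for i in La for j in Lb)
    ss[f"{fa}:{fc}"] = ncell * b * sum(
        (mAC[i, k] - mA[i] - mC[k] + grand) ** 2 for i in La for k in Lc)
    ss[f"{fb}:{fc}"] = ncell * a * sum(
        (mBC[j, k] - mB[j] - mC[k] + grand) ** 2 for j in Lb for k in Lc)
    ss[f"{fa}:{fb}:{fc}"] = ncell * sum(
        (mABC[i, j, k] - mAB[i, j] - mAC[i, k] - mBC[j, k]
         + mA[i] + mB[j] + mC[k] - grand) ** 2
        for i in La for j in Lb for k in Lc)

    ss_err = 0.0
    for (i, j, k) in itertools.product(La, Lb, Lc):
        m = ((table[fa] == i) & (table[fb] == j)
             & (table[fc] == k)).to_numpy()
        ss_err += ((y[m] - mABC[i, j, k]) ** 2).sum()

    df = {fa: a - 1, fb: b - 1, fc: c - 1,
          f"{fa}:{fb}": (a - 1) * (b - 1), f"{fa}:{fc}": (a - 1) * (c - 1),
          f"{fb}:{fc}": (b - 1) * (c - 1),
          f"{fa}:{fb}:{fc}": (a - 1) * (b - 1) * (c - 1)}
    df_err = a * b * c * (ncell - 1)
    mse = ss_err / df_err

    out = {}
    for term, s in ss.items():
        F = (s / df[term]) / mse
        out[term] = dict(
            F=F, df_num=df[term], df_den=df_err,
            p=float(sps.f.sf(F, df[term], df_err)),
            partial_eta_sq=s / (s + ss_err),
        )
    return out, df_err


def integrate_arc(seed, center, step, tangent_fn, in_field_fn, target_fn,
                  max_len=4000):
    """Dense deterministic integration of the tangent field (oracle for the
    probabilistic tracker on a noiseless arc bundle)."""
    p = np.asarray(seed, float).copy()
    for _ in range(max_len):
        if target_fn(p):
            return True
        if not in_field_fn(p):
            return False
        p = p + step * tangent_fn(p)
    return False
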