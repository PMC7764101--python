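"""TDI mapping, normalization, winner-take-all, two-step scheme, MPMs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

import midparc as mp
from midparc.parcellation import (
    NormalizedDensityMap, TargetDensityMap, UNCLASSIFIED,
)
from midparc.tracking import Status, Tractogram, TrackingParams


def _tract_from_paths(paths, labels, target_names, shape):
    maxlen = max(len(p) for p in paths)
    P = np.full((len(paths), maxlen, 3), np.nan)
    lengths = np.zeros(len(paths), dtype=np.int64)
    for i, p in enumerate(paths):
        P[i, : len(p)] = p
        lengths[i] = len(p)
    labels = np.asarray(labels, np.int32)
    statuses = np.where(labels > 0, Status.REACHED_TARGET,
                        Status.TERMINATED_FIELD).astype(np.int8)
    return Tractogram(points=P, lengths=lengths, statuses=statuses,
                      target_idx=labels, seed_points=P[:, 0].copy(),
                      target_names=target_names)


# -- tdi_map ----------------------------------------------------------------

def test_tdi_single_streamline_counts_once():
    shape = (12, 6, 6)
    seed = np.zeros(shape, bool)
    seed[0:5, 2, 2] = True
    path = np.stack([np.arange(0, 8, 1.25), np.full(7, 2.0),
                     np.full(7, 2.0)], axis=1)
    tg = _tract_from_paths([path], [1], ("t",), shape)
    m = mp.tdi_map(tg, seed)["t"].counts
    assert np.all(m[0:5, 2, 2] == 1)
    assert m.sum() == 5


def test_tdi_additivity_and_masking():
    shape = (12, 6, 6)
    seed = np.zeros(shape, bool)
    seed[0:5, 2, 2] = True
    path = np.stack([np.arange(0, 11, 1.25), np.full(9, 2.0),
                     np.full(9, 2.0)], axis=1)
    tg = _tract_from_paths([path, path.copy()], [1, 1], ("t",), shape)
    m = mp.tdi_map(tg, seed)["t"].counts
    assert np.all(m[0:5, 2, 2] == 2)          # coincident streamlines add
    assert m[5:, :, :].sum() == 0             # path outside seed masked away


def test_tdi_unreached_streamlines_excluded():
    shape = (12, 6, 6)
    seed = np.ones(shape, bool)
    path = np.stack([np.arange(0, 5, 1.25), np.full(4, 2.0),
                     np.full(4, 2.0)], axis=1)
    tg = _tract_from_paths([path, path], [1, 0], ("t",), shape)
    assert mp.tdi_map(tg, seed)["t"].counts.max() == 1


# -- normalize_map ----------------------------------------------------------

def test_normalize_example():
    shape = (3, 1, 1)
    seed = np.ones(shape, bool)
    tdm = TargetDensityMap("t", np.array([2, 4, 6]).reshape(shape))
    nm = mp.normalize_map(tdm, seed)
    assert np.allclose(nm.values.ravel(), [0.5, 1.0, 1.5])
    assert np.isclose(nm.values[seed].mean(), 1.0)
    assert not nm.empty


def test_normalize_constant_and_scale_invariance(rng):
    shape = (4, 4, 4)
    seed = np.ones(shape, bool)
    const = mp.normalize_map(TargetDensityMap("t", np.full(shape, 7)), seed)
    assert np.allclose(const.values, 1.0)
    counts = rng.integers(0, 30, shape)
    a = mp.normalize_map(TargetDensityMap("t", counts), seed)
    b = mp.normalize_map(TargetDensityMap("t", counts * 13), seed)
    assert np.allclose(a.values, b.values)


def test_normalize_all_zero_flagged():
    shape = (4, 4, 4)
    nm = mp.normalize_map(TargetDensityMap("t", np.zeros(shape, int)),
                          np.ones(shape, bool))
    assert nm.empty
    assert np.all(nm.values == 0)


# -- classify ---------------------------------------------------------------

def _nmaps(arrays, names=("limbic", "prefrontal", "sensorimotor")):
    return [NormalizedDensityMap(n, np.asarray(a, float))
            for n, a in zip(names, arrays)]


def test_classify_argmax_tie_and_unclassified():
    shape = (3, 1, 1)
    seed = np.ones(shape, bool)
    A = np.array([0.2, 0.0, 1.0]).reshape(shape)   # limbic
    B = np.array([1.7, 0.0, 1.0]).reshape(shape)   # prefrontal
    C = np.array([0.4, 0.0, 0.3]).reshape(shape)   # sensorimotor
    parc = mp.classify(_nmaps([A, B, C]), seed)
    assert parc.labels[0, 0, 0] == 2               # argmax -> prefrontal
    assert parc.labels[1, 0, 0] == UNCLASSIFIED    # all zero
    assert parc.labels[2, 0, 0] == 1               # tie -> lowest index


def test_classify_requires_two_maps_and_matching_grids():
    seed = np.ones((2, 2, 2), bool)
    with pytest.raises(ValueError, match="two"):
        mp.classify(_nmaps([np.ones((2, 2, 2))], names=("a",)), seed)
    with pytest.raises(ValueError, match="mismatch"):
        mp.classify(_nmaps([np.ones((2, 2, 2)), np.ones((3, 2, 2))],
                           names=("a", "b")), seed)


@settings(max_examples=200, derandomize=True, deadline=None)
@given(hnp.arrays(np.float64, (3, 4, 4, 2),
                  elements=st.floats(0, 10, allow_nan=False)))
def test_classify_matches_exhaustive_oracle(stack):
    """Winner-take-all equals a per-voxel argmax loop on random maps."""
    seed = np.ones((4, 4, 2), bool)
    parc = mp.classify(_nmaps(list(stack)), seed)
    for idx in np.ndindex(*seed.shape):
        vals = [stack[k][idx] for k in range(3)]
        if max(vals) <= 0:
            assert parc.labels[idx] == UNCLASSIFIED
        else:
            assert parc.labels[idx] == int(np.argmax(vals)) + 1


def test_conservation(parcellated_R):
    """Sum of parcel volumes plus unclassified equals the seed volume."""
    st_parc, mb_parc, _, _ = parcellated_R
    for parc in (st_parc, mb_parc):
        total = sum(parc.volume(l) for l in parc.label_names)
        assert total + parc.volume("unclassified") == parc.seed_volume


def test_parcellation_scale_invariance(phantom64):
    """Scaling one target's raw counts leaves the parcellation unchanged."""
    params = TrackingParams(n_streamlines=2000, rng_seed=8)
    seed = phantom64.seed_masks["striatum_R"]
    tg = mp.seed_tractography(seed, phantom64.cortical_targets["R"],
                              phantom64.field, params,
                              target_names=mp.TERRITORY_LABELS)
    maps = mp.tdi_map(tg, seed)
    norm1 = [mp.normalize_map(maps[n], seed) for n in mp.TERRITORY_LABELS]
    p1 = mp.classify(norm1, seed, label_names=mp.TERRITORY_LABELS)
    scaled = {n: TargetDensityMap(n, m.counts * (5 if n == "limbic" else 1))
              for n, m in maps.items()}
    norm2 = [mp.normalize_map(scaled[n], seed) for n in mp.TERRITORY_LABELS]
    p2 = mp.classify(norm2, seed, label_names=mp.TERRITORY_LABELS)
    assert np.array_equal(p1.labels, p2.labels)


# -- two-step scheme --------------------------------------------------------

def test_two_step_single_target_limit(phantom64):
    """Midbrain seeded against a limbic-only target is all limbic."""
    spec = mp.default_phantom_spec()
    spec.bundle_defs = tuple(
        b for b in spec.bundle_defs
        if not (b.name.startswith("nigrostriatal")
                and b.territory != "limbic"))
    ph = mp.build_phantom(spec)
    params = TrackingParams(n_streamlines=3000, rng_seed=4)
    st_parc, mb_parc = mp.two_step_parcellate(
        ph.seed_masks["striatum_R"], ph.cortical_targets["R"],
        ph.seed_masks["midbrain_R"], ph.field, params)
    classified = mb_parc.labels[mb_parc.seed_mask]
    classified = classified[classified != UNCLASSIFIED]
    assert len(classified) > 0
    assert np.all(classified == 1)


def test_two_step_labels_and_recovery(phantom64, parcellated_R):
    st_parc, mb_parc, _, _ = parcellated_R
    gt = phantom64.ground_truth.territories
    for parc, seed in ((st_parc, "striatum_R"), (mb_parc, "midbrain_R")):
        assert set(np.unique(parc.labels)) <= {0, 1, 2, 3}
        dice = mp.parcellation_dice(parc, gt[seed])
        for v in dice.values():
            assert v >= 0.85
    assert min(mp.parcellation_dice(st_parc, gt["striatum_R"]).values()) >= 0.9


def test_two_step_disjointness_checks(phantom64):
    with pytest.raises(ValueError, match="disjoint"):
        mp.two_step_parcellate(
            phantom64.seed_masks["striatum_R"],
            phantom64.cortical_targets["R"],
            phantom64.seed_masks["striatum_R"],   # midbrain == striatum
            phantom64.field, TrackingParams(n_streamlines=10))


# -- maximum probability maps ----------------------------------------------

def _fake_parcellations(n, labeled_counts, shape=(4, 4, 4)):
    """n parcellations; voxel (0,0,0) carries limbic in `labeled_counts`."""
    seed = np.ones(shape, bool)
    out = []
    for i in range(n):
        lab = np.full(shape, 2, dtype=np.int16)
        if i < labeled_counts:
            lab[0, 0, 0] = 1
        out.append(mp.Parcellation(labels=lab, seed_mask=seed))
    return out


def test_mpm_half_threshold_inclusion():
    mpm = mp.build_mpm(_fake_parcellations(24, 12), threshold=0.5)
    assert mpm.min_subjects() == 12
    assert mpm.thresholded()["limbic"][0, 0, 0]
    mpm = mp.build_mpm(_fake_parcellations(24, 11), threshold=0.5)
    assert not mpm.thresholded()["limbic"][0, 0, 0]
    assert mp.build_mpm(_fake_parcellations(30, 15)).min_subjects() == 15


def test_mpm_union_intersection_monotone():
    parcs = _fake_parcellations(10, 4)
    mpm = mp.build_mpm(parcs)
    union = mpm.thresholded(0.0)["limbic"]
    inter = mpm.thresholded(1.0)["limbic"]
    assert union[0, 0, 0] and not inter[0, 0, 0]
    assert np.array_equal(union, mpm.counts[0] >= 1)
    assert np.array_equal(inter, mpm.counts[0] >= 10)
    vols = [mpm.thresholded(t)["limbic"].sum()
            for t in (0.0, 0.25, 0.5, 0.75, 1.0)]
    assert all(a >= b for a, b in zip(vols[:-1], vols[1:]))


def test_mpm_mixed_grids_rejected():
    a = _fake_parcellations(2, 1, shape=(4, 4, 4))
    b = _fake_parcellations(1, 1, shape=(5, 4, 4))
    with pytest.raises(ValueError, match="grid"):
        mp.build_mpm(a + b)
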