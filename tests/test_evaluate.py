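"""Metric implementations against brute-force oracles; edge-gap fitment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

from craniorec.defects import realize_case
from craniorec.errors import InputError
from craniorec.evaluate import (
    ConfusionCounts,
    confusion,
    dsc,
    edge_gap_report,
    evaluate_case,
    evaluate_suite,
    hausdorff_mm,
    jsc,
    precision,
    recall,
    specificity,
)
from craniorec.volio import BinaryVolume


def oracle_confusion(pred, truth):
    tp = fp = fn = tn = 0
    for i in range(pred.shape[0]):
        for j in range(pred.shape[1]):
            for k in range(pred.shape[2]):
                p, t = bool(pred[i, j, k]), bool(truth[i, j, k])
                tp += p and t
                fp += p and not t
                fn += (not p) and t
                tn += (not p) and (not t)
    return tp, fp, fn, tn


def oracle_surface(mask):
    """Foreground voxels with >= 1 face-adjacent background neighbor."""
    out = []
    for p in np.argwhere(mask):
        for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            q = p + d
            if np.any(q < 0) or np.any(q >= mask.shape) or not mask[tuple(q)]:
                out.append(p)
                break
    return np.asarray(out)


def oracle_hausdorff(a, b, spacing):
    sa, sb = oracle_surface(a) * spacing, oracle_surface(b) * spacing
    d_ab = max(min(np.linalg.norm(p - q) for q in sb) for p in sa)
    d_ba = max(min(np.linalg.norm(p - q) for q in sa) for p in sb)
    return max(d_ab, d_ba)


class TestConfusion:
    def test_identical_masks(self):
        m = (np.random.default_rng(0).random((4, 4, 4)) > 0.5).astype(np.uint8)
        c = confusion(m, m)
        assert c.fp == 0 and c.fn == 0 and c.tp == int(m.sum())

    def test_complement_masks(self):
        m = (np.random.default_rng(1).random((4, 4, 4)) > 0.5).astype(np.uint8)
        c = confusion(1 - m, m)
        assert c.tp == 0 and c.tn == 0

    @given(seed=st.integers(0, 100))
    @settings(max_examples=20, deadline=None)
    def test_matches_triple_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pred = (rng.random((4, 4, 4)) > 0.5).astype(np.uint8)
        truth = (rng.random((4, 4, 4)) > 0.5).astype(np.uint8)
        c = confusion(pred, truth)
        assert (c.tp, c.fp, c.fn, c.tn) == oracle_confusion(pred, truth)
        assert c.total == 64


class TestRatioMetrics:
    def test_identical_nonempty_all_one(self):
        c = confusion(np.ones((3, 3, 3)), np.ones((3, 3, 3)))
        for metric in (dsc, jsc, precision, recall):
            assert metric(c) == 1.0

    def test_hand_tally_two_vs_two_in_27(self):
        """pred {a,b}, truth {b,c}: TP=1 FP=1 FN=1 TN=24."""
        pred = np.zeros((3, 3, 3))
        truth = np.zeros((3, 3, 3))
        pred.ravel()[[0, 1]] = 1
        truth.ravel()[[1, 2]] = 1
        c = confusion(pred, truth)
        assert dsc(c) == pytest.approx(0.5)
        assert jsc(c) == pytest.approx(1 / 3)
        assert precision(c) == pytest.approx(0.5)
        assert recall(c) == pytest.approx(0.5)
        assert specificity(c) == pytest.approx(24 / 25)

    def test_disjoint_nonempty_all_zero(self):
        pred = np.zeros((3, 3, 3))
        truth = np.zeros((3, 3, 3))
        pred.ravel()[0] = 1
        truth.ravel()[5] = 1
        c = confusion(pred, truth)
        assert dsc(c) == jsc(c) == precision(c) == recall(c) == 0.0

    def test_both_empty_convention(self):
        c = confusion(np.zeros((2, 2, 2)), np.zeros((2, 2, 2)))
        assert dsc(c) == 1.0 and jsc(c) == 1.0
        assert np.isnan(precision(c))

    @given(seed=st.integers(0, 200))
    @settings(max_examples=30, deadline=None)
    def test_jsc_dsc_algebraic_identity(self, seed):
        rng = np.random.default_rng(seed)
        pred = (rng.random((5, 5, 5)) > 0.4).astype(np.uint8)
        truth = (rng.random((5, 5, 5)) > 0.4).astype(np.uint8)
        c = confusion(pred, truth)
        d = dsc(c)
        assert jsc(c) == pytest.approx(d / (2 - d), abs=1e-12)


class TestHausdorff:
    def test_identical_masks_zero(self, phantom32):
        assert hausdorff_mm(phantom32, phantom32) == 0.0

    def test_two_voxels_three_apart(self):
        a = np.zeros((8, 8, 8), dtype=np.uint8)
        b = np.zeros((8, 8, 8), dtype=np.uint8)
        a[2, 4, 4] = 1
        b[5, 4, 4] = 1
        assert hausdorff_mm(a, b, spacing=(1, 1, 1)) == pytest.approx(3.0)

    def test_anisotropic_spacing_scales(self):
        a = np.zeros((8, 8, 8), dtype=np.uint8)
        b = np.zeros((8, 8, 8), dtype=np.uint8)
        a[2, 4, 4] = 1
        b[5, 4, 4] = 1
        assert hausdorff_mm(a, b, spacing=(2, 1, 1)) == pytest.approx(6.0)

    @given(seed=st.integers(0, 100))
    @settings(max_examples=15, deadline=None)
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = (rng.random((6, 6, 6)) > 0.6).astype(np.uint8)
        b = (rng.random((6, 6, 6)) > 0.6).astype(np.uint8)
        if not a.any() or not b.any():
            return
        spacing = np.array([1.0, 1.5, 2.0])
        expect = oracle_hausdorff(a, b, spacing)
        assert hausdorff_mm(a, b, spacing=spacing) == pytest.approx(expect)

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        a = (rng.random((7, 7, 7)) > 0.6).astype(np.uint8)
        b = (rng.random((7, 7, 7)) > 0.6).astype(np.uint8)
        assert hausdorff_mm(a, b, spacing=(1, 1, 1)) == hausdorff_mm(
            b, a, spacing=(1, 1, 1)
        )

    def test_joint_dilation_never_increases_max_hd(self):
        rng = np.random.default_rng(6)
        a = np.zeros((10, 10, 10), dtype=np.uint8)
        b = np.zeros((10, 10, 10), dtype=np.uint8)
        a[2:4, 2:4, 2:4] = 1
        b[6:8, 6:8, 6:8] = 1
        before = hausdorff_mm(a, b, spacing=(1, 1, 1))
        s = ndimage.generate_binary_structure(3, 1)
        ad = ndimage.binary_dilation(a, s).astype(np.uint8)
        bd = ndimage.binary_dilation(b, s).astype(np.uint8)
        assert hausdorff_mm(ad, bd, spacing=(1, 1, 1)) <= before

    def test_p95_mode_below_max(self):
        rng = np.random.default_rng(7)
        a = (rng.random((8, 8, 8)) > 0.5).astype(np.uint8)
        b = (rng.random((8, 8, 8)) > 0.8).astype(np.uint8)
        assert hausdorff_mm(a, b, spacing=(1, 1, 1), mode="p95") <= hausdorff_mm(
            a, b, spacing=(1, 1, 1), mode="max"
        )

    def test_empty_mask_rejected(self):
        with pytest.raises(InputError):
            hausdorff_mm(np.zeros((3, 3, 3)), np.ones((3, 3, 3)))


class TestEvaluateSuite:
    def _records(self, phantom, regions, shapes, perfect=True):
        recs = []
        for r in regions:
            for s in shapes:
                pair = realize_case(phantom, r, s, seed=31)
                recs.append({
                    "region": r, "shape": s,
                    "pred": pair.healthy if perfect else None,
                    "truth": pair.healthy, "spacing": pair.healthy.spacing,
                })
        return recs

    def test_perfect_model_ceiling_20_rows(self, phantom32):
        from craniorec.defects import REGIONS, SHAPES

        table = evaluate_suite(self._records(phantom32, REGIONS, SHAPES))
        cases = table[table["region"] != "overall"]
        assert len(cases) == 20
        assert np.allclose(cases[["dsc", "jsc", "precision", "recall",
                                  "specificity"]], 1.0)
        assert np.allclose(cases["hd_mm"], 0.0)

    def test_aggregates_mean_over_skulls(self, phantom32):
        recs = []
        for seed in range(3):
            pair = realize_case(phantom32, "top", "cube", seed=seed)
            recs.append({"region": "top", "shape": "cube",
                         "pred": pair.defected, "truth": pair.healthy,
                         "spacing": pair.healthy.spacing})
        table = evaluate_suite(recs)
        cases = table[table["region"] != "overall"]
        assert len(cases) == 1
        per_case = [
            evaluate_case(r["pred"], r["truth"], r["spacing"])["dsc"] for r in recs
        ]
        assert cases["dsc"].iloc[0] == pytest.approx(np.mean(per_case))

    def test_missing_predictions_warned_and_excluded(self, phantom32):
        recs = self._records(phantom32, ("top",), ("cube", "sphere"))
        recs[1]["pred"] = None
        with pytest.warns(UserWarning, match="missing"):
            table = evaluate_suite(recs)
        assert len(table[table["region"] != "overall"]) == 1


class TestEdgeGap:
    def test_perfect_implant_zero_gap(self, phantom64):
        pair = realize_case(phantom64, "top", "sphere", seed=41)
        report = edge_gap_report(pair.implant_gt, pair)
        assert report.overall == 0.0
        for side, mean in report.side_means.items():
            assert mean == 0.0 or np.isnan(mean)

    def test_eroded_implant_gap_band(self):
        """1-voxel erosion at 1 mm spacing: gaps must land in [0.8, 1.5] mm."""
        from craniorec.phantom import PhantomSpec, make_skull_phantom

        ph = make_skull_phantom(PhantomSpec(dims=(128, 128, 64), spacing=(1, 1, 1)))
        pair = realize_case(ph, "top", "sphere", seed=42)
        eroded = ndimage.binary_erosion(
            pair.implant_gt.voxels, ndimage.generate_binary_structure(3, 1)
        ).astype(np.uint8)
        assert eroded.any()
        report = edge_gap_report(pair.implant_gt.with_voxels(eroded), pair)
        assert 0.8 <= report.overall <= 1.5

    def test_eroded_gap_matches_nearest_neighbor_oracle(self):
        from craniorec.phantom import PhantomSpec, make_skull_phantom

        ph = make_skull_phantom(PhantomSpec(dims=(128, 128, 64), spacing=(1, 1, 1)))
        pair = realize_case(ph, "front", "cube", seed=43)
        eroded = ndimage.binary_erosion(
            pair.implant_gt.voxels, ndimage.generate_binary_structure(3, 1)
        ).astype(np.uint8)
        imp = pair.implant_gt.with_voxels(eroded)
        report = edge_gap_report(imp, pair, n_per_side=5, seed=3)
        # oracle: every rim point's brute-force nearest implant voxel
        touching = ndimage.binary_dilation(
            pair.defected.voxels.astype(bool),
            ndimage.generate_binary_structure(3, 1),
        )
        rim = np.argwhere(pair.implant_gt.voxels.astype(bool) & touching)
        imp_pts = np.argwhere(eroded)
        worst = max(
            min(np.linalg.norm(p - q) for q in imp_pts) for p in rim[::17]
        )
        assert report.overall <= worst + 1e-9

    def test_empty_implant_rejected(self, phantom64):
        pair = realize_case(phantom64, "top", "sphere", seed=44)
        with pytest.raises(InputError):
            edge_gap_report(BinaryVolume(np.zeros(phantom64.dims, dtype=np.uint8),
                                         spacing=phantom64.spacing), pair)

    def test_overall_is_mean_of_sampled_gaps(self, phantom64):
        pair = realize_case(phantom64, "left", "cylinder", seed=45)
        report = edge_gap_report(pair.implant_gt, pair, n_per_side=10)
        assert report.n_points <= 40
        assert report.overall >= 0.0
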