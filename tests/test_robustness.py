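import numpy as np
import pytest
from scipy.spatial.distance import jensenshannon

from glioprep import (
    BinaryMask,
    IntensityHistogram,
    VolumeImage,
    ccc,
    histogram_of,
    icc,
    jensen_shannon_divergence,
    robustness_report,
    shared_edges,
)

from oracles import ccc_oracle, icc21_oracle


def _hist(p, edges=None):
    p = np.asarray(p, dtype=float)
    if edges is None:
        edges = np.arange(p.size + 1, dtype=float)
    return IntensityHistogram(edges=edges, probabilities=p)


class TestHistogram:
    def test_counting_oracle(self, rng):
        vox = rng.normal(50, 10, size=(8, 8, 8))
        mask = rng.random((8, 8, 8)) < 0.5
        mask.flat[0] = True
        edges = np.linspace(0, 100, 21)
        h = histogram_of(VolumeImage(voxels=vox), BinaryMask(voxels=mask), edges)
        counts, _ = np.histogram(np.clip(vox[mask], 0, 100), bins=edges)
        np.testing.assert_allclose(h.probabilities, counts / counts.sum())

    def test_constant_image_single_bin(self):
        vox = np.full((8, 8, 8), 7.0)
        h = histogram_of(
            VolumeImage(voxels=vox),
            BinaryMask(voxels=np.ones((8, 8, 8))),
            np.array([0.0, 5.0, 10.0, 15.0]),
        )
        assert list(h.probabilities) == [0.0, 1.0, 0.0]

    def test_out_of_range_values_clip_to_end_bins(self):
        vox = np.zeros((8, 8, 8))
        vox[0, 0, 0] = -100.0
        vox[0, 0, 1] = 100.0
        mask = np.zeros((8, 8, 8))
        mask[0, 0, :2] = 1
        h = histogram_of(
            VolumeImage(voxels=vox), BinaryMask(voxels=mask), np.array([0.0, 1.0, 2.0])
        )
        assert list(h.probabilities) == [0.5, 0.5]


class TestJSD:
    def test_identity_is_zero(self):
        p = _hist([0.25, 0.5, 0.25])
        assert jensen_shannon_divergence(p, p) == 0.0

    def test_disjoint_supports_reach_one(self):
        assert jensen_shannon_divergence(_hist([1, 0]), _hist([0, 1])) == pytest.approx(1.0)

    def test_symmetry(self, rng):
        for _ in range(10):
            a = rng.dirichlet(np.ones(16))
            b = rng.dirichlet(np.ones(16))
            d1 = jensen_shannon_divergence(_hist(a), _hist(b))
            d2 = jensen_shannon_divergence(_hist(b), _hist(a))
            assert abs(d1 - d2) < 1e-15
            assert 0.0 <= d1 <= 1.0

    def test_hand_evaluated_value(self):
        val = jensen_shannon_divergence(_hist([1.0, 0.0]), _hist([0.5, 0.5]))
        # term-by-term: 0.5*log2(1/0.75) + 0.25*log2(.5/.75) + 0.25*log2(.5/.25)
        expected = 0.5 * np.log2(1 / 0.75) + 0.5 * (
            0.5 * np.log2(0.5 / 0.75) + 0.5 * np.log2(0.5 / 0.25)
        )
        assert val == pytest.approx(expected, abs=1e-12)
        assert val == pytest.approx(0.3113, abs=1e-4)

    def test_matches_scipy(self, rng):
        a = rng.dirichlet(np.ones(32))
        b = rng.dirichlet(np.ones(32))
        ours = jensen_shannon_divergence(_hist(a), _hist(b))
        ref = jensenshannon(a, b, base=2) ** 2
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_mismatched_edges_raise(self):
        with pytest.raises(ValueError, match="edges"):
            jensen_shannon_divergence(
                _hist([1.0, 0.0]), _hist([1.0, 0.0], edges=np.array([0.0, 2.0, 4.0]))
            )


class TestICC:
    def test_identical_columns_give_one(self):
        t = np.column_stack([np.arange(5.0), np.arange(5.0)])
        assert icc(t) == 1.0

    def test_offset_penalized_vs_pearson(self, rng):
        x = rng.normal(size=30)
        t = np.column_stack([x, x + 5.0])
        r = np.corrcoef(t[:, 0], t[:, 1])[0, 1]
        assert icc(t) < r

    def test_mean_squares_oracle(self, rng):
        for _ in range(100):
            t = rng.normal(size=(20, 2)) * rng.uniform(0.5, 3) + rng.normal()
            assert icc(t) == pytest.approx(icc21_oracle(t), abs=1e-12)

    def test_matches_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg

        t = rng.normal(size=(15, 2))
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(15), 2),
                "rater": np.tile([0, 1], 15),
                "score": t.ravel(),
            }
        )
        ref = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
        # absolute-agreement single-rater row (labelled ICC2 or ICC(A,1))
        sel = ref["Type"].isin(["ICC2", "ICC(A,1)"])
        icc2 = float(ref.loc[sel, "ICC"].iloc[0])
        assert icc(t) == pytest.approx(icc2, abs=1e-8)

    def test_affine_invariance(self, rng):
        t = rng.normal(size=(12, 2))
        assert icc(3.0 * t + 7.0) == pytest.approx(icc(t), abs=1e-12)

    def test_too_few_subjects(self):
        with pytest.raises(ValueError, match="3"):
            icc(np.zeros((2, 2)))

    def test_zero_variance_convention(self):
        assert icc(np.full((5, 2), 3.0)) == 1.0


class TestCCC:
    def test_perfect_agreement(self):
        assert ccc(np.column_stack([[1, 2, 3], [1, 2, 3]])) == 1.0

    def test_hand_value_four_sevenths(self):
        assert ccc(np.column_stack([[1, 2, 3], [2, 3, 4]])) == pytest.approx(4.0 / 7.0)

    def test_oracle_and_pearson_bound(self, rng):
        for _ in range(50):
            t = rng.normal(size=(20, 2)) @ rng.normal(size=(2, 2))
            c = ccc(t)
            assert c == pytest.approx(ccc_oracle(t[:, 0], t[:, 1]), abs=1e-12)
            r = np.corrcoef(t[:, 0], t[:, 1])[0, 1]
            assert abs(c) <= abs(r) + 1e-12

    def test_affine_invariance(self, rng):
        t = rng.normal(size=(10, 2))
        assert ccc(2.0 * t - 1.0) == pytest.approx(ccc(t), abs=1e-12)

    def test_equal_constant_columns(self):
        assert ccc(np.full((4, 2), 2.0)) == 1.0


@pytest.fixture(scope="module")
def tables(tiny_config):
    from glioprep import extract_feature_table, generate_paired_cohort

    pairs = generate_paired_cohort(tiny_config)
    ta = extract_feature_table([p[0] for p in pairs], "none", mode="FBN", bins=8)
    tb = extract_feature_table([p[1] for p in pairs], "none", mode="FBN", bins=8)
    return ta, tb


class TestRobustnessReport:
    def test_identical_tables_all_robust(self, tables):
        ta, _ = tables
        rep = robustness_report(ta, ta.copy())
        assert rep.counts["all"] == {"robust": 91, "total": 91}

    def test_unattainable_threshold(self, tables):
        ta, _ = tables
        rep = robustness_report(ta, ta.copy(), threshold=1.01)
        assert rep.counts["all"]["robust"] == 0

    def test_heavy_noise_destroys_robustness(self, tables, rng):
        ta, _ = tables
        tb = ta.copy()
        for col in ta.columns:
            if "/" in col:
                scale = max(ta[col].abs().max(), 1.0)
                tb[col] = rng.normal(0, 100 * scale, size=len(tb))
        rep = robustness_report(ta, tb)
        assert rep.counts["all"]["robust"] <= 2

    def test_unpaired_case_ids_raise(self, tables):
        ta, tb = tables
        tb = tb.copy()
        tb.loc[tb.index[0], "case_id"] = "stranger"
        with pytest.raises(ValueError, match="case ids"):
            robustness_report(ta, tb)


def test_shared_edges_span_union(phantom):
    img_a = phantom.image
    img_b = phantom.image.with_voxels(phantom.image.voxels * 2.0 + 10.0)
    edges = shared_edges(img_a, img_b, phantom.brain)
    va = phantom.brain.values_in(img_a)
    vb = phantom.brain.values_in(img_b)
    assert edges[0] == min(va.min(), vb.min())
    assert edges[-1] == max(va.max(), vb.max())
    assert edges.size == 257
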