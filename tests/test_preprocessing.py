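import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from manifoldcost import (
    ColumnScaler,
    PCOutlierDetector,
    apply_normalization,
    compute_scaling,
    detect_outliers,
    invert_normalization,
    subsample,
)

COL = np.array([[1.0], [2.0], [3.0]])
STD = np.sqrt(2.0 / 3.0)  # population std of [1, 2, 3]
# Pearson kurtosis of [1,2,3]: m4/m2^2 = (2/3)/(2/3)^2 = 1.5
S2K2 = (2.0 / 3.0) * 1.5**2


@pytest.mark.parametrize(
    "name, center, scale",
    [
        ("none", 0.0, 1.0),
        ("auto", 2.0, STD),
        ("pareto", 2.0, np.sqrt(STD)),
        ("vast", 2.0, (2.0 / 3.0) / 2.0),
        ("range", 2.0, 2.0),
        ("0-1", 1.0, 2.0),
        ("-1-1", 2.0, 1.0),
        ("level", 2.0, 2.0),
        ("max", 2.0, 3.0),
        ("poisson", 2.0, np.sqrt(2.0)),
        ("s1", 2.0, S2K2 / 2.0),
        ("s2", 2.0, S2K2 / 3.0),
        ("s3", 2.0, S2K2 / 2.0),
    ],
)
def test_scaling_factors_hand_computed(name, center, scale):
    """Each scaling's center/scale on the column [1, 2, 3] matches a hand
    evaluation of its defining formula."""
    centers, scales = compute_scaling(COL, name)
    assert centers[0] == pytest.approx(center, abs=1e-12)
    assert scales[0] == pytest.approx(scale, rel=1e-12)


def test_scaling_name_is_case_insensitive():
    for alias in ("Auto", "AUTO", " auto "):
        c, d = compute_scaling(COL, alias)
        assert d[0] == pytest.approx(STD)


def test_unknown_scaling_rejected():
    with pytest.raises(ValueError, match="unknown scaling"):
        compute_scaling(COL, "median")


def test_constant_column_errors_with_name():
    X = pd.DataFrame({"a": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
    with pytest.raises(ValueError, match="flat"):
        compute_scaling(X, "auto")


def test_zero_to_one_normalization():
    c, d = compute_scaling(np.array([[2.0], [4.0], [6.0]]), "0-1")
    out = apply_normalization(np.array([[2.0], [4.0], [6.0]]), c, d)
    np.testing.assert_allclose(out.ravel(), [0.0, 0.5, 1.0])


def test_none_scaling_is_identity(rng):
    X = rng.normal(size=(10, 3))
    c, d = compute_scaling(X, "none")
    np.testing.assert_array_equal(apply_normalization(X, c, d), X)


def test_auto_scaled_columns_standardized(rng):
    X = rng.normal(loc=5.0, scale=3.0, size=(200, 4))
    Xn = ColumnScaler("auto").fit_transform(X)
    np.testing.assert_allclose(Xn.mean(axis=0), 0.0, atol=1e-12)
    np.testing.assert_allclose(Xn.std(axis=0, ddof=0), 1.0, rtol=1e-12)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    arrays(
        np.float64,
        (7, 3),
        elements=st.floats(0.5, 100.0, allow_nan=False),
    )
)
def test_normalization_round_trip(X):
    """apply then invert is the identity to within 1e-12 relative error for
    every scaling that the matrix admits."""
    for name in ("auto", "pareto", "vast", "level", "max", "poisson"):
        try:
            c, d = compute_scaling(X, name)
        except ValueError:
            continue  # degenerate column for this scaling
        back = invert_normalization(apply_normalization(X, c, d), c, d)
        np.testing.assert_allclose(back, X, rtol=1e-12, atol=1e-12)


def test_dimension_mismatch_rejected():
    with pytest.raises(ValueError, match="columns"):
        apply_normalization(np.ones((3, 2)), np.zeros(3), np.ones(3))


class TestOutlierDetection:
    def _cloud_with_outlier(self):
        gen = np.random.default_rng(7)
        X = gen.normal(scale=0.1, size=(100, 2))
        X[-1] = [10.0, 10.0]  # ~100 cloud radii away
        return X

    def test_far_point_flagged(self):
        det = detect_outliers(self._cloud_with_outlier())
        assert 99 in det.outlier_indices_

    def test_statistics_match_brute_force(self):
        """Major/minor classifier statistics agree with an explicit per-row
        evaluation of sum z^2 / L over the chosen PC sets."""
        X = self._cloud_with_outlier()
        det = detect_outliers(X)

        Xn = (X - X.mean(0)) / X.std(0, ddof=0)
        cov = np.cov(Xn, rowvar=False, ddof=1)
        vals, vecs = np.linalg.eigh(cov)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        z = Xn @ vecs
        for i in range(len(X)):
            major = sum(
                z[i, j] ** 2 / vals[j] for j in range(det.n_major_pcs_)
            )
            minor = sum(
                z[i, j] ** 2 / vals[j]
                for j in range(det.minor_start_ - 1, X.shape[1])
            )
            assert det.major_statistic_[i] == pytest.approx(major, rel=1e-10)
            assert det.minor_statistic_[i] == pytest.approx(minor, rel=1e-10)

    def test_pc_set_sizes_meet_variance_fractions(self):
        X = np.random.default_rng(3).normal(size=(300, 5)) @ np.diag(
            [3.0, 2.0, 1.0, 0.5, 0.1]
        )
        det = detect_outliers(X)
        vals = det.eigenvalues_
        total = vals.sum()
        assert vals[: det.n_major_pcs_].sum() / total >= 0.5
        assert vals[det.minor_start_ - 1 :].sum() / total >= 0.2
        # ceiling rule: one fewer PC would fall short
        if det.n_major_pcs_ > 1:
            assert vals[: det.n_major_pcs_ - 1].sum() / total < 0.5
        if det.minor_start_ < len(vals):
            assert vals[det.minor_start_ :].sum() / total < 0.2

    def test_near_unit_quantile_flags_at_most_the_extremes(self):
        """Thresholds at (essentially) the statistic maxima: a row is flagged
        only if it strictly exceeds a threshold, so at most the per-statistic
        argmax rows can remain flagged."""
        det = detect_outliers(self._cloud_with_outlier(), quantile=1 - 1e-12)
        allowed = {
            int(np.argmax(det.major_statistic_)),
            int(np.argmax(det.minor_statistic_)),
        }
        assert set(det.outlier_indices_) <= allowed
        # and nothing exceeds its own maximum
        assert (det.major_statistic_ > det.major_statistic_.max()).sum() == 0

    @pytest.mark.parametrize("q", [0.0, 1.0, 1.5, -0.1])
    def test_quantile_out_of_range_rejected(self, q):
        with pytest.raises(ValueError, match="quantile"):
            detect_outliers(self._cloud_with_outlier(), quantile=q)

    def test_flagged_set_invariant_to_row_order(self):
        X = self._cloud_with_outlier()
        perm = np.random.default_rng(1).permutation(len(X))
        a = detect_outliers(X).outlier_indices_
        b = detect_outliers(X[perm]).outlier_indices_
        assert set(perm[b]) == set(a)

    def test_predict_labels(self):
        det = PCOutlierDetector().fit(self._cloud_with_outlier())
        labels = det.predict()
        assert labels[99] == -1
        assert set(labels) <= {-1, 1}


class TestSubsample:
    def test_full_size_is_permutation(self, rng):
        X = rng.normal(size=(20, 3))
        sub, idx = subsample(X, 20, seed=5)
        assert sorted(idx) == list(range(20))

    def test_same_seed_reproduces(self, rng):
        X = rng.normal(size=(30, 2))
        a, _ = subsample(X, 10, seed=11)
        b, _ = subsample(X, 10, seed=11)
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("n", [0, 1, 31])
    def test_out_of_range_rejected(self, rng, n):
        with pytest.raises(ValueError, match="subsample size"):
            subsample(rng.normal(size=(30, 2)), n)
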