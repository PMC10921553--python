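"""Pearson concordance and the interchangeability selection."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cbctomics.correlation import (
    SENTINEL_FEATURES,
    correlate_tables,
    pearson,
    select_interchangeable,
)
from cbctomics.io import FeatureTable


class TestPearson:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ([1, 2, 3], [2, 4, 6], 1.0),
            ([1, 2, 3], [6, 4, 2], -1.0),
            ([1, 2, 3], [1, 3, 2], 0.5),
        ],
    )
    def test_worked_examples(self, x, y, expected):
        assert pearson(x, y) == pytest.approx(expected)

    def test_zero_variance_is_missing(self):
        assert np.isnan(pearson([1, 1, 1], [1, 2, 3]))

    def test_errors(self):
        with pytest.raises(ValueError):
            pearson([1, 2], [1, 2])  # n < 3
        with pytest.raises(ValueError):
            pearson([1, 2, 3], [1, 2])
        with pytest.raises(ValueError):
            pearson([1, 2, np.inf], [1, 2, 3])

    @settings(max_examples=50, deadline=None)
    @given(
        xs=st.lists(st.floats(-100, 100), min_size=4, max_size=12, unique=True),
        a=st.floats(0.1, 10),
        b=st.floats(-50, 50),
    )
    def test_symmetry_and_affine_invariance(self, xs, a, b):
        rng = np.random.default_rng(abs(hash(tuple(xs))) % 2**31)
        ys = rng.normal(size=len(xs))
        if np.std(ys) == 0 or np.std(xs) == 0:
            return
        r = pearson(xs, ys)
        assert pearson(ys, xs) == pytest.approx(r, rel=1e-9)
        assert pearson(a * np.asarray(xs) + b, ys) == pytest.approx(r, rel=1e-6)

    def test_matches_scipy(self, rng):
        from scipy import stats

        x = rng.normal(size=20)
        y = rng.normal(size=20)
        assert pearson(x, y) == pytest.approx(stats.pearsonr(x, y)[0], rel=1e-12)


def _table(values, names=None, cases=None):
    values = np.asarray(values, dtype=float)
    names = names or [f"f{i}" for i in range(values.shape[1])]
    cases = cases or [f"c{i}" for i in range(values.shape[0])]
    return FeatureTable(case_ids=cases, feature_names=names, values=values)


class TestCorrelateTables:
    def test_self_concordance(self, rng):
        t = _table(rng.normal(size=(10, 5)))
        report = correlate_tables(t, t)
        np.testing.assert_allclose(report.table["r"].to_numpy(), 1.0, rtol=1e-12)
        assert len(report.table) == 5

    def test_constant_feature_reported_missing(self, rng):
        vals = rng.normal(size=(8, 3))
        vals[:, 1] = 7.0
        t1 = _table(vals)
        t2 = _table(rng.normal(size=(8, 3)))
        report = correlate_tables(t1, t2)
        assert report.degenerate == ["f1"]
        assert len(report.table) == 3  # not silently dropped

    def test_independent_noise_has_no_systematic_high_r(self):
        rng = np.random.default_rng(99)
        n, k = 30, 200
        t1 = _table(rng.normal(size=(n, k)))
        t2 = _table(rng.normal(size=(n, k)))
        report = correlate_tables(t1, t2)
        rs = report.table["r"].to_numpy()
        assert np.abs(rs).mean() < 0.5
        # under the null, P(R > 0.9) at n=30 is astronomically small
        assert (rs > 0.9).sum() == 0

    def test_case_mismatch_rejected(self, rng):
        t1 = _table(rng.normal(size=(5, 2)))
        t2 = _table(rng.normal(size=(5, 2)), cases=[f"x{i}" for i in range(5)])
        with pytest.raises(ValueError, match="case ids"):
            correlate_tables(t1, t2)

    def test_feature_mismatch_rejected(self, rng):
        t1 = _table(rng.normal(size=(5, 2)), names=["a", "b"])
        t2 = _table(rng.normal(size=(5, 2)), names=["a", "c"])
        with pytest.raises(ValueError, match="feature"):
            correlate_tables(t1, t2)

    def test_sorted_by_descending_r(self, rng):
        base = rng.normal(size=(20, 1))
        noise = rng.normal(size=(20, 3)) * [0.1, 1.0, 10.0]
        t1 = _table(np.repeat(base, 3, axis=1))
        t2 = _table(np.repeat(base, 3, axis=1) + noise)
        rs = correlate_tables(t1, t2).table["r"].to_numpy()
        assert (np.diff(rs) <= 1e-12).all()


class TestSelectInterchangeable:
    def _report_from_rs(self, rs):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(2000, len(rs)))
        other = np.empty_like(base)
        for i, r in enumerate(rs):
            # mix to achieve an empirical correlation near r
            noise = rng.normal(size=2000)
            other[:, i] = r * base[:, i] + np.sqrt(1 - r**2) * noise
        return _table(base), _table(other)

    def test_strict_inequality_at_boundary(self):
        t = pd.DataFrame(
            {
                "feature": ["a", "b", "c"],
                "n": 30,
                "r": [0.95, 0.9, 0.85],
                "p_value": 0.0,
                "degenerate": False,
                "selected": [True, False, False],
            }
        )
        from cbctomics.correlation import ConcordanceReport

        report = ConcordanceReport(table=t, threshold=0.9)
        selected, _ = select_interchangeable(report, threshold=0.9)
        assert selected == ["a"]  # strictly greater than the threshold

    def test_threshold_one_selects_only_exact_duplicates(self, rng):
        vals = rng.normal(size=(10, 3))
        t1 = _table(vals)
        noisy = vals.copy()
        noisy[:, 1] += rng.normal(scale=0.01, size=10)
        noisy[:, 2] += rng.normal(scale=1.0, size=10)
        t2 = _table(noisy)
        report = correlate_tables(t1, t2)
        selected, _ = select_interchangeable(report, threshold=1.0)
        assert selected == []  # R cannot strictly exceed 1

        report_dup = correlate_tables(t1, t1)
        selected_dup, _ = select_interchangeable(report_dup, threshold=0.999999)
        assert set(selected_dup) == {"f0", "f1", "f2"}

    def test_sentinels_flagged_when_selected(self, rng):
        names = list(SENTINEL_FEATURES) + ["other"]
        vals = rng.normal(size=(12, 4))
        t1 = _table(vals, names=names)
        t2 = _table(vals + rng.normal(scale=1e-3, size=(12, 4)), names=names)
        report = correlate_tables(t1, t2)
        selected, flagged = select_interchangeable(report)
        assert set(flagged) == set(SENTINEL_FEATURES)
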