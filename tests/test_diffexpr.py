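"""Relative quantification (2^-ddCq) and the rank-based group comparison.

The Mann-Whitney implementation is checked against a full enumeration of
rank assignments, and the normality statistic against a hand-coded omnibus
transform — both oracles are independent of the code under test.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mirank import (DiffExprError, compare_groups, dagostino_pearson,
                    mann_whitney_u, relative_expression)
from mirank.diffexpr import read_cq_table


# ---------------------------------------------------------------------------
# independent oracles

def enumerate_mw_exact(a, b):
    """Exact two-sided Mann-Whitney p by enumerating every assignment of
    the pooled tie-free values to the two groups."""
    pooled = sorted(a) + sorted(b)
    n_a, n_b = len(a), len(b)
    u_obs = sum(1 for x in a for y in b if x > y)
    lo, hi = min(u_obs, n_a * n_b - u_obs), max(u_obs, n_a * n_b - u_obs)
    count = 0
    total = 0
    for positions in itertools.combinations(range(n_a + n_b), n_a):
        grp_a = [pooled[i] for i in positions]
        grp_b = [pooled[i] for i in range(n_a + n_b) if i not in positions]
        u = sum(1 for x in grp_a for y in grp_b if x > y)
        count += (u <= lo) + (u >= hi)
        total += 1
    return u_obs, min(count / total, 1.0)


# ---------------------------------------------------------------------------
# relative expression

def _cq_frame(rows):
    return pd.DataFrame(rows, columns=["subject_id", "group", "assay_id",
                                       "cq_target", "cq_reference"])


class TestRelativeExpression:
    @pytest.fixture
    def cq(self):
        return _cq_frame([
            ("c1", "control", "a", 26.0, 20.0),
            ("c2", "control", "a", 28.0, 20.0),
            ("s1", "case", "a", 26.0, 20.0),
            ("s2", "case", "a", 29.0, 20.0),
        ])

    def test_control_mean_calibrator_fold_values(self, cq):
        rel = relative_expression(cq).set_index("subject_id")
        # control dCq are 6 and 8, calibrator 7
        assert rel.loc["c1", "rq"] == pytest.approx(2.0)   # one cycle below
        assert rel.loc["c2", "rq"] == pytest.approx(0.5)
        assert rel.loc["s1", "rq"] == pytest.approx(2.0)
        assert rel.loc["s2", "rq"] == pytest.approx(0.25)  # two cycles above

    def test_subject_at_calibrator_has_rq_one(self):
        cq = _cq_frame([("c1", "control", "a", 27.0, 20.0),
                        ("s1", "case", "a", 27.0, 20.0)])
        rel = relative_expression(cq).set_index("subject_id")
        assert rel.loc["s1", "rq"] == pytest.approx(1.0)

    def test_control_geometric_mean_is_exactly_one(self, cq):
        rel = relative_expression(cq)
        control_rq = rel.loc[rel["group"] == "control", "rq"]
        gmean = np.exp(np.mean(np.log(control_rq)))
        assert gmean == pytest.approx(1.0, abs=1e-12)

    def test_shift_invariance_of_rq(self, cq):
        shifted = cq.copy()
        shifted[["cq_target", "cq_reference"]] += 3.7
        base = relative_expression(cq)
        after = relative_expression(shifted)
        np.testing.assert_allclose(base["rq"], after["rq"])

    def test_missing_reference_cq_excludes_subject(self, cq, caplog):
        cq.loc[0, "cq_reference"] = np.nan
        rel = relative_expression(cq)
        assert "c1" not in set(rel["subject_id"])
        assert len(rel) == 3

    def test_empty_control_group_fatal_under_control_mean(self):
        cq = _cq_frame([("s1", "case", "a", 26.0, 20.0),
                        ("s2", "case", "a", 27.0, 20.0)])
        with pytest.raises(DiffExprError, match="control"):
            relative_expression(cq)

    def test_named_sample_calibrator(self, cq):
        rel = relative_expression(cq, "named-sample",
                                  calibrator_sample="c1").set_index("subject_id")
        assert rel.loc["c1", "rq"] == pytest.approx(1.0)

    def test_rq_always_positive(self, cq):
        rel = relative_expression(cq)
        assert (rel["rq"] > 0).all()


# ---------------------------------------------------------------------------
# statistics

class TestMannWhitney:
    def test_complete_separation_small_sample(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)

    def test_hand_ranked_example(self):
        u, p = mann_whitney_u([1, 4, 5], [2, 3, 6])
        assert u == 4  # U1 = (1+4+5) - 6 = 4, U2 = 5

    def test_identical_groups_give_central_u(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        u, p = mann_whitney_u(vals, vals)
        assert u == pytest.approx(len(vals) ** 2 / 2)

    def test_empty_group_fatal(self):
        with pytest.raises(DiffExprError):
            mann_whitney_u([], [1.0])

    @given(st.data())
    @settings(max_examples=60, deadline=None)
    def test_exact_p_matches_full_enumeration(self, data):
        n_a = data.draw(st.integers(2, 6))
        n_b = data.draw(st.integers(2, 6))
        pool = data.draw(st.lists(st.integers(0, 1000), min_size=n_a + n_b,
                                  max_size=n_a + n_b, unique=True))
        a, b = pool[:n_a], pool[n_a:]
        u, p = mann_whitney_u(a, b)
        u_oracle, p_oracle = enumerate_mw_exact(a, b)
        assert u == min(u_oracle, n_a * n_b - u_oracle)
        assert p == pytest.approx(p_oracle, abs=1e-12)

    @given(st.lists(st.floats(-5, 5, allow_nan=False), min_size=2,
                    max_size=25),
           st.lists(st.floats(-5, 5, allow_nan=False), min_size=2,
                    max_size=25))
    @settings(max_examples=60, deadline=None)
    def test_u_plus_u_prime_identity(self, a, b):
        u, _ = mann_whitney_u(a, b)
        u_flip, _ = mann_whitney_u(b, a)
        assert 0 <= u <= len(a) * len(b)
        assert u == pytest.approx(u_flip)  # min(U1, U2) is symmetric


class TestNormalityScreen:
    def test_k2_matches_independent_reference(self):
        """Cross-implementation check against scipy's omnibus test on a
        skewed fixture (where both use the same well-defined transforms)."""
        from scipy.stats import normaltest
        rng = np.random.default_rng(11)
        values = rng.gamma(2.0, 1.0, size=20)
        k2, p = dagostino_pearson(values)
        ref = normaltest(values)
        assert k2 == pytest.approx(ref.statistic, abs=1e-8)
        assert p == pytest.approx(ref.pvalue, abs=1e-8)

    def test_symmetric_sample_has_zero_skew_contribution(self):
        from mirank.diffexpr import kurtosis_ztransform, skew_ztransform
        values = np.concatenate([np.arange(10), -np.arange(10)])
        assert skew_ztransform(values) == pytest.approx(0.0, abs=1e-12)
        k2, _ = dagostino_pearson(values)
        assert k2 == pytest.approx(kurtosis_ztransform(values) ** 2)

    @pytest.mark.parametrize("values", [
        [1.0, 2.0, 3.0, 4.0, 5.0],          # n below the omnibus minimum
        [2.0] * 12,                           # zero variance
    ])
    def test_not_assessable_cases(self, values):
        k2, p = dagostino_pearson(values)
        assert math.isnan(k2) and math.isnan(p)


class TestCompareGroups:
    def _relexpr(self, case, control, assay="a"):
        rows = ([("s%d" % i, "case", assay, v) for i, v in enumerate(case)]
                + [("c%d" % i, "control", assay, v)
                   for i, v in enumerate(control)])
        return pd.DataFrame(rows, columns=["subject_id", "group", "assay_id",
                                           "rq"])

    def test_identical_groups_not_significant(self):
        vals = list(np.linspace(0.5, 2.0, 12))
        out = compare_groups(self._relexpr(vals, vals))
        row = out.iloc[0]
        assert row["median_case"] == row["median_control"]
        assert row["p_value"] > 0.9
        assert not row["significant"]

    def test_one_row_per_assay(self):
        frames = [self._relexpr([1.0, 2.0, 1.5], [0.9, 1.1, 1.0],
                                assay=f"assay_{i}") for i in range(7)]
        out = compare_groups(pd.concat(frames, ignore_index=True))
        assert len(out) == 7
        assert list(out.columns[:6]) == ["assay_id", "median_case",
                                         "median_control", "u_statistic",
                                         "p_value", "normality_case_p"]

    def test_single_group_assay_skipped_with_warning(self, caplog):
        rel = self._relexpr([1.0, 2.0], [])
        rel = rel[rel["group"] == "case"]
        out = compare_groups(rel)
        assert out.empty
        assert any("one group" in r.message for r in caplog.records)

    def test_bh_adjustment_is_opt_in_and_monotone(self):
        frames = [self._relexpr(list(np.arange(10) + shift),
                                list(np.arange(10.0)), assay=f"a{i}")
                  for i, shift in enumerate([5.0, 0.1, 0.0])]
        raw = compare_groups(pd.concat(frames, ignore_index=True))
        assert "p_adjusted" not in raw.columns
        adj = compare_groups(pd.concat(frames, ignore_index=True),
                             adjust="bh")
        assert (adj["p_adjusted"] >= adj["p_value"] - 1e-15).all()


def test_read_cq_table_averages_replicates(tmp_path):
    path = tmp_path / "cq.tsv"
    path.write_text(
        "subject_id\tgroup\tassay_id\tcq_target\tcq_reference\treplicate\n"
        "s1\tcase\ta\t26.0\t20.0\t1\n"
        "s1\tcase\ta\t28.0\t20.0\t2\n"
        "c1\tcontrol\ta\t27.0\t20.0\t1\n")
    frame = read_cq_table(path, replicate_column="replicate")
    assert len(frame) == 2
    s1 = frame.set_index("subject_id").loc["s1"]
    assert s1["cq_target"] == pytest.approx(27.0)
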