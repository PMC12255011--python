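import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from maap.curation import (
    CurationReport,
    LabelConflictError,
    curate,
    dedup_ki,
    filter_zero_variance,
)
from maap.io import FeatureMatrix, InteractionRecord, InteractionTable


def brute_force_dedup(values, threshold=1.0):
    """Independent oracle: direct z-score arithmetic with explicit loops."""
    mu = sum(values) / len(values)
    sigma = (sum((v - mu) ** 2 for v in values) / len(values)) ** 0.5
    if sigma == 0:
        return values[0]
    z = [(v - mu) / sigma for v in values]
    survivors = [i for i in range(len(values)) if abs(z[i]) <= threshold + 1e-9]
    if not survivors:
        survivors = list(range(len(values)))
    zmin = min(abs(z[i]) for i in survivors)
    tied = [i for i in survivors if abs(z[i]) <= zmin + 1e-9]
    best = min(tied, key=lambda i: (values[i], i))
    return values[best]


class TestDedupKi:
    @pytest.mark.parametrize("values,expected", [
        ([7.0], 7.0),                    # single value
        ([5.0, 5.0], 5.0),               # zero spread
        ([10.0, 12.0, 50.0], 12.0),      # 50 flagged (|z|>1), 12 closest to mean
        ([100.0, 110.0], 100.0),         # z = -1/+1 survive; tie -> smaller Ki
    ])
    def test_worked_examples(self, values, expected):
        assert dedup_ki(values) == expected

    def test_errors(self):
        with pytest.raises(ValueError):
            dedup_ki([])
        with pytest.raises(ValueError):
            dedup_ki([1.0, -2.0])
        with pytest.raises(ValueError):
            dedup_ki([1.0], threshold=0.0)

    def test_output_is_member_and_order_invariant(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            values = (10 ** rng.normal(2, 1, size=rng.integers(1, 8))).tolist()
            out = dedup_ki(values)
            assert out in values
            shuffled = list(values)
            rng.shuffle(shuffled)
            assert dedup_ki(shuffled) == out

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(0.1, 1e5), min_size=1, max_size=10),
           st.floats(10.0, 1000.0))
    def test_scale_invariance(self, values, factor):
        """A unit change (uniform rescaling) never changes which value wins."""
        base = dedup_ki(values)
        scaled = dedup_ki([v * factor for v in values])
        assert scaled == pytest.approx(base * factor, rel=1e-9)

    def test_oracle_equivalence_random_lists(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = int(rng.integers(1, 9))
            values = (10 ** rng.normal(2.0, 0.8, size=n)).round(4).tolist()
            assert dedup_ki(values) == brute_force_dedup(values)

    def test_all_flagged_falls_back_to_min_abs_z(self):
        # tiny threshold flags everything; min |z| of the originals returned
        assert dedup_ki([10.0, 12.0, 50.0], threshold=0.1) == 12.0


def _table(rows):
    return InteractionTable([
        InteractionRecord(ligand_id=l, smiles=s, receptor_id=r, action_class=c,
                          ki_values_nM=k)
        for l, s, r, c, k in rows
    ])


class TestCurate:
    def test_agreeing_duplicates_merge(self):
        t = _table([("L1", "CCO", "R1", 0, [10.0]), ("L1", "CCO", "R1", 0, [12.0])])
        out, report = curate(t)
        assert len(out) == 1
        assert out.records[0].action_class == 0
        assert out.records[0].ki_values_nM == [10.0, 12.0]
        assert report.n_label_conflicts == 0

    def test_conflict_error_policy(self):
        t = _table([("L1", "CCO", "R1", 0, []), ("L1", "CCO", "R1", 1, [])])
        with pytest.raises(LabelConflictError, match="L1"):
            curate(t, conflict_policy="error")

    def test_conflict_majority_vote(self):
        t = _table([("L1", "CCO", "R1", 0, []), ("L1", "CCO", "R1", 0, []),
                    ("L1", "CCO", "R1", 1, [])])
        out, report = curate(t, conflict_policy="majority")
        assert out.records[0].action_class == 0
        assert report.n_label_conflicts == 1

    def test_ki_filter_drops_ki_less_and_dedups(self):
        t = _table([("L1", "CCO", "R1", 0, [10.0]), ("L1", "CCO", "R1", 0, [12.0]),
                    ("L1", "CCO", "R1", 0, [50.0]), ("L2", "CCN", "R1", 1, [])])
        out, report = curate(t, ki_filter=True)
        assert len(out) == 1
        assert out.records[0].ki_values_nM == [12.0]
        assert report.n_dropped_no_ki == 1
        assert report.n_ki_outliers_removed == 1

    def test_report_counts_consistent(self, tiny_table):
        out, report = curate(tiny_table)
        assert report.n_in == len(tiny_table)
        assert report.n_out == len(out) <= report.n_in


class TestZeroVarianceFilter:
    def test_constant_descriptor_removed(self):
        m = FeatureMatrix(row_keys=[("L1", "R"), ("L2", "R")],
                          column_names=["D1", "D2"],
                          column_roles=["descriptor", "descriptor"],
                          values=np.array([[1.0, 5.0], [1.0, 6.0]]))
        out = filter_zero_variance(m)
        assert out.column_names == ["D2"]

    def test_no_constant_columns_is_identity_and_idempotent(self, small_matrix):
        # small_matrix: D1 constant descriptor, E2 constant embedding
        out = filter_zero_variance(small_matrix, scope="descriptor")
        assert out.column_names == ["D2", "E1", "E2"]
        again = filter_zero_variance(out, scope="descriptor")
        assert again.column_names == out.column_names
        np.testing.assert_array_equal(again.values, out.values)

    def test_scope_respects_role(self, small_matrix):
        # constant embedding column must survive a descriptor-scoped filter
        out = filter_zero_variance(small_matrix, scope="descriptor")
        assert "E2" in out.column_names

    def test_all_constant_role_raises(self):
        m = FeatureMatrix(row_keys=[("L1", "R"), ("L2", "R")],
                          column_names=["D1"], column_roles=["descriptor"],
                          values=np.array([[2.0], [2.0]]))
        with pytest.raises(ValueError, match="zero variance"):
            filter_zero_variance(m)
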