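"""Voxel-wise Fisher's exact tests and permutation cluster screening."""

import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats as sps

from svzmap import (
    SubjectRecord,
    cluster_filter,
    cluster_table,
    fisher_exact_2x2,
    voxelwise_subtype_test,
)


def fisher_oracle(a, b, c, d):
    """Exact-rational two-tailed Fisher p by full hypergeometric enumeration.

    Table probabilities are integer-weighted fractions, so the "no more
    probable than observed" comparison is exact — no floating tolerance.
    """
    n = a + b + c + d
    k = a + c
    r = a + b
    denom = math.comb(n, r)
    weights = {
        x: math.comb(k, x) * math.comb(n - k, r - x)
        for x in range(max(0, r - (n - k)), min(r, k) + 1)
    }
    w_obs = weights[a]
    return Fraction(sum(w for w in weights.values() if w <= w_obs), denom)


class TestFisherExact:
    def test_worked_example_3003(self):
        assert fisher_exact_2x2(3, 0, 0, 3) == pytest.approx(0.1, abs=1e-12)

    def test_degenerate_column_gives_one(self):
        assert fisher_exact_2x2(0, 5, 0, 5) == 1.0

    def test_2882_matches_enumeration(self):
        expected = float(fisher_oracle(2, 8, 8, 2))
        assert fisher_exact_2x2(2, 8, 8, 2) == pytest.approx(expected, rel=1e-9)

    def test_all_tables_with_margins_up_to_8_match_rational_oracle(self):
        for n1 in range(1, 9):
            for n2 in range(1, 9):
                for a in range(n1 + 1):
                    for c in range(n2 + 1):
                        p = fisher_exact_2x2(a, n1 - a, c, n2 - c)
                        expected = float(fisher_oracle(a, n1 - a, c, n2 - c))
                        assert p == pytest.approx(expected, rel=1e-9, abs=1e-12), (
                            a, n1 - a, c, n2 - c,
                        )

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_scipy_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = rng.integers(0, 15, size=4)
        if a + b + c + d == 0:
            a = 1
        expected = sps.fisher_exact([[a, b], [c, d]])[1]
        assert fisher_exact_2x2(a, b, c, d) == pytest.approx(expected, rel=1e-7)

    @pytest.mark.parametrize("seed", range(10))
    def test_invariant_under_row_and_column_swap(self, seed):
        rng = np.random.default_rng(100 + seed)
        a, b, c, d = (int(x) for x in rng.integers(0, 10, size=4))
        if a + b + c + d == 0:
            d = 2
        assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
            fisher_exact_2x2(d, c, b, a), rel=1e-12
        )

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            fisher_exact_2x2(-1, 2, 3, 4)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            fisher_exact_2x2(0, 0, 0, 0)


def _records_from_masks(masks_by_subtype):
    recs = []
    for subtype, masks in masks_by_subtype.items():
        for i, m in enumerate(masks):
            recs.append(SubjectRecord(f"{subtype}-{i}", subtype, m, filled=True))
    return recs


def _blob(template, slc):
    m = np.zeros(template.shape, dtype=bool)
    m[slc] = True
    m &= template.brain_mask
    assert m.any()
    return m


class TestVoxelwise:
    def test_identical_masks_give_p_one_everywhere(self, small_template):
        blob = _blob(small_template, np.s_[10:14, 10:14, 10:14])
        recs = _records_from_masks(
            {"proneural": [blob] * 3, "classical": [blob] * 3}
        )
        p = voxelwise_subtype_test(recs, "proneural", small_template)
        assert (p == 1.0).all()

    def test_disjoint_3v3_gives_point_one(self, small_template):
        a = _blob(small_template, np.s_[8:11, 8:11, 8:11])
        b = _blob(small_template, np.s_[14:17, 14:17, 14:17])
        recs = _records_from_masks({"proneural": [a] * 3, "classical": [b] * 3})
        p = voxelwise_subtype_test(recs, "proneural", small_template)
        assert p[a].min() == pytest.approx(0.1, abs=1e-12)
        assert p[b].min() == pytest.approx(0.1, abs=1e-12)
        outside = ~(a | b)
        assert (p[outside] == 1.0).all()

    def test_unknown_subjects_excluded(self, small_template):
        a = _blob(small_template, np.s_[8:11, 8:11, 8:11])
        b = _blob(small_template, np.s_[14:17, 14:17, 14:17])
        recs = _records_from_masks(
            {"proneural": [a] * 3, "classical": [b] * 3, "unknown": [a] * 4}
        )
        p_with = voxelwise_subtype_test(recs, "proneural", small_template)
        p_without = voxelwise_subtype_test(recs[:6], "proneural", small_template)
        assert np.array_equal(p_with, p_without)

    def test_absent_subtype_rejected(self, small_template):
        blob = _blob(small_template, np.s_[10:13, 10:13, 10:13])
        recs = _records_from_masks({"proneural": [blob], "classical": [blob]})
        with pytest.raises(ValueError, match="absent"):
            voxelwise_subtype_test(recs, "mesenchymal", small_template)

    def test_single_group_rejected(self, small_template):
        blob = _blob(small_template, np.s_[10:13, 10:13, 10:13])
        recs = _records_from_masks({"proneural": [blob] * 4})
        with pytest.raises(ValueError, match="two"):
            voxelwise_subtype_test(recs, "proneural", small_template)

    def test_label_shuffles_control_voxelwise_rate(self, small_template, small_cohort):
        """Under random relabeling, < 5% of testable voxels reach p < 0.05
        on average (the exact test is conservative)."""
        rng = np.random.default_rng(5)
        masks = [r.ce_mask for r in small_cohort]
        rates = []
        for _ in range(20):
            labels = rng.permutation(
                ["proneural"] * 5 + ["classical"] * 5
            )
            recs = [
                SubjectRecord(f"s{i}", lab, m, filled=True)
                for i, (lab, m) in enumerate(zip(labels, masks))
            ]
            p = voxelwise_subtype_test(recs, "proneural", small_template)
            testable = np.zeros(small_template.shape, dtype=bool)
            for m in masks:
                testable |= m
            rates.append((p[testable] < 0.05).mean())
        assert np.mean(rates) <= 0.05


class TestClusterFilter:
    def test_nothing_suprathreshold(self, small_template, small_cohort):
        p = np.ones(small_template.shape)
        res = cluster_filter(
            p, small_cohort, "proneural", small_template, n_permutations=20, seed=0
        )
        assert res.cluster_sizes == []
        assert res.cluster_p == []
        assert res.retained == []
        assert not res.retained_mask.any()

    def test_strong_signal_cluster_retained_at_extreme_p(self, small_template):
        """8 proneural subjects share a region never touched by 8 others:
        the region survives screening; with no permutation matching the
        observed max size the add-one formula gives 1/(n_perm + 1)."""
        a = _blob(small_template, np.s_[7:12, 7:12, 7:12])
        b = _blob(small_template, np.s_[14:18, 14:18, 14:18])
        recs = _records_from_masks({"proneural": [a] * 8, "classical": [b] * 8})
        p = voxelwise_subtype_test(recs, "proneural", small_template)
        res = cluster_filter(
            p, recs, "proneural", small_template, n_permutations=99, seed=21
        )
        assert len(res.cluster_sizes) >= 1
        assert any(res.retained)
        assert min(res.cluster_p) == pytest.approx(1 / 100)
        # retained voxels all sit below the voxel threshold
        assert (res.p_map[res.retained_mask] < res.voxel_alpha).all()

    def test_power_on_synthetic_common_region(self, small_template, small_cohort):
        """A common proneural-only region (n = 5 per group) is retained."""
        common = _blob(small_template, np.s_[6:11, 6:11, 6:11])
        recs = []
        for r in small_cohort:
            m = r.ce_mask | common if r.subtype == "proneural" else r.ce_mask
            # keep the classical tumors away from the common region
            if r.subtype == "classical":
                m = m & ~common
                if not m.any():
                    continue
            recs.append(SubjectRecord(r.subject_id, r.subtype, m, filled=True))
        p = voxelwise_subtype_test(recs, "proneural", small_template)
        res = cluster_filter(
            p, recs, "proneural", small_template, n_permutations=199, seed=3
        )
        retained = res.retained_mask
        assert (retained & common).sum() > 0

    def test_seeded_reproducibility(self, small_template, small_cohort):
        p = voxelwise_subtype_test(small_cohort, "proneural", small_template)
        r1 = cluster_filter(
            p, small_cohort, "proneural", small_template, n_permutations=50, seed=9
        )
        r2 = cluster_filter(
            p, small_cohort, "proneural", small_template, n_permutations=50, seed=9
        )
        assert r1.cluster_sizes == r2.cluster_sizes
        assert r1.cluster_p == r2.cluster_p
        assert np.array_equal(r1.cluster_labels, r2.cluster_labels)

    def test_cluster_p_floor(self, small_template, small_cohort):
        p = voxelwise_subtype_test(small_cohort, "proneural", small_template)
        res = cluster_filter(
            p, small_cohort, "proneural", small_template, n_permutations=50, seed=2
        )
        for cp in res.cluster_p:
            assert 1 / 51 <= cp <= 1.0

    def test_cluster_table_schema(self, small_template, small_cohort):
        p = voxelwise_subtype_test(small_cohort, "proneural", small_template)
        res = cluster_filter(
            p, small_cohort, "proneural", small_template, n_permutations=30, seed=2
        )
        df = cluster_table(res)
        assert list(df.columns) == [
            "cluster_id", "size_voxels", "cluster_p", "retained",
            "peak_i", "peak_j", "peak_k",
        ]
        assert len(df) == len(res.cluster_sizes)

    def test_bad_permutation_count_rejected(self, small_template, small_cohort):
        p = np.ones(small_template.shape)
        with pytest.raises(ValueError, match="n_permutations"):
            cluster_filter(
                p, small_cohort, "proneural", small_template, n_permutations=0, seed=0
            )
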