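import itertools
import math

import numpy as np
import pytest
from scipy.special import gammaln

from rpa.cluster import ClusterInfo, ClusterResult
from rpa.loci import harmonize_block_groups, select_common_loci
from rpa.validate import (compute_size_factors, fisher_m_by_2,
                          normalized_block_expression, validate_dpl)

from conftest import make_group, make_read


def exact_m_by_2_pvalue(col_a, col_b):
    """Independent oracle: exhaustive enumeration of all m x 2 tables with the
    observed margins; two-sided p = total probability of tables no more
    likely than the observed one."""
    a = np.asarray(col_a, dtype=np.int64)
    b = np.asarray(col_b, dtype=np.int64)
    rows = a + b
    ca = int(a.sum())

    def logw(avec):
        avec = np.asarray(avec)
        return float(np.sum(gammaln(rows + 1) - gammaln(avec + 1)
                            - gammaln(rows - avec + 1)))

    obs = logw(a)
    total = 0.0
    hit = 0.0
    ranges = [range(int(r) + 1) for r in rows[:-1]]
    for partial in itertools.product(*ranges):
        last = ca - sum(partial)
        if last < 0 or last > rows[-1]:
            continue
        w = math.exp(logw(list(partial) + [last]))
        total += w
        if logw(list(partial) + [last]) <= obs + 1e-9:
            hit += w
    return hit / total


class TestSizeFactors:
    def test_hand_computed_example(self):
        sf = compute_size_factors(np.array([[10, 20], [30, 60]]), ["a", "b"])
        assert sf.factors == pytest.approx([1 / math.sqrt(2), math.sqrt(2)])
        norm = normalized_block_expression(
            np.array([[10, 20], [30, 60]]), sf, ["a", "b"])
        assert norm[:, 0] == pytest.approx(norm[:, 1])

    def test_identical_samples_have_unit_factors(self):
        k = np.array([[5, 5, 5], [9, 9, 9], [40, 40, 40]])
        sf = compute_size_factors(k, list("abc"))
        assert sf.factors == pytest.approx([1.0, 1.0, 1.0])

    def test_scale_equivariance(self, rng):
        k = rng.integers(5, 100, size=(12, 2))
        s = compute_size_factors(k, ["a", "b"]).factors
        for c in (2.0, 5.0):
            k2 = k.astype(float).copy()
            k2[:, 1] *= c
            s2 = compute_size_factors(k2, ["a", "b"]).factors
            assert s2[1] / s2[0] == pytest.approx(c * s[1] / s[0])

    def test_zero_rows_skipped(self):
        base = np.array([[10, 20], [30, 60]])
        with_zero = np.vstack([base, [0, 7]])
        assert compute_size_factors(with_zero, ["a", "b"]).factors == \
            pytest.approx(compute_size_factors(base, ["a", "b"]).factors)

    def test_all_rows_unusable_is_hard_error(self):
        with pytest.raises(ValueError, match="pool"):
            compute_size_factors(np.array([[0, 5], [3, 0]]), ["a", "b"])


class TestFisher:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ([3, 1], [1, 3], 0.4857142857),
            ([10, 0], [0, 10], 2 / 184756),
            ([5, 5], [5, 5], 1.0),
        ],
    )
    def test_two_by_two_reference_values(self, a, b, expected):
        assert fisher_m_by_2(a, b) == pytest.approx(expected, rel=1e-6)

    def test_two_by_two_matches_enumeration(self, rng):
        for _ in range(30):
            a = rng.integers(0, 15, size=2)
            b = rng.integers(0, 15, size=2)
            if a.sum() == 0 or b.sum() == 0:
                continue
            assert fisher_m_by_2(a, b) == \
                pytest.approx(exact_m_by_2_pvalue(a, b), rel=1e-6, abs=1e-12)

    def test_three_by_two_monte_carlo_close_to_enumeration(self, rng):
        for seed in range(5):
            a = rng.integers(0, 9, size=3)
            b = rng.integers(0, 9, size=3)
            if a.sum() == 0 or b.sum() == 0:
                continue
            exact = exact_m_by_2_pvalue(a, b)
            mc = fisher_m_by_2(a, b, seed=seed, n_mc=20_000)
            se = math.sqrt(exact * (1 - exact) / 20_000)
            assert abs(mc - exact) < 3 * se + 2 / 20_000

    def test_all_zero_column_returns_one(self):
        assert fisher_m_by_2([0, 0], [3, 4]) == 1.0

    def test_rounding_of_normalized_counts(self):
        # 2.6 rounds to 3, 0.4 to 0: equivalent integer table
        assert fisher_m_by_2([2.6, 0.4], [1.2, 2.8]) == \
            pytest.approx(fisher_m_by_2([3, 0], [1, 3]))


def build_locus(sample_counts, length=22):
    """Two-block locus; sample_counts maps sample -> (major, minor)."""
    gbs, reads = {}, {}
    for s, (c1, c2) in sample_counts.items():
        spec = [[(100, length, c1)], [(150, length, c2)]]
        gbs[s] = [make_group(spec, sample=s)]
        reads[s] = [make_read(100, length, c1, sample=s),
                    make_read(150, length, c2, sample=s)]
    (locus,) = select_common_loci(gbs)
    return harmonize_block_groups(locus, reads)


def forced_cluster(samples, members):
    res = ClusterResult(samples=samples, linkage_matrix=None)
    info = ClusterInfo(members=frozenset(members), p_value=0.001, bp=1.0,
                       x_k=0.5, eligible_in=frozenset(members),
                       eligible_out=frozenset(set(samples) - set(members)))
    res.clusters.append(info)
    res.significant.append(info)
    res.cluster_score = 0.5
    res.candidate = True
    return res


def unit_size_factors(samples):
    from rpa.validate import SizeFactors
    return SizeFactors(samples=samples, factors=np.ones(len(samples)))


class TestValidateDPL:
    def test_strong_two_in_two_out_cluster_is_dpl(self):
        counts = {"a0": (80, 20), "a1": (80, 20), "b0": (20, 80), "b1": (20, 80)}
        locus = build_locus(counts)
        res = forced_cluster(locus.samples, ["a0", "a1"])
        v = validate_dpl(locus, res, unit_size_factors(locus.samples))
        assert v.is_dpl and v.cluster_fractions == [1.0]

    def test_exactly_half_qualifying_is_not_dpl(self):
        counts = {"a0": (80, 20), "a1": (80, 20), "a2": (50, 50), "a3": (50, 50),
                  "o0": (50, 50), "o1": (50, 50)}
        locus = build_locus(counts)
        res = forced_cluster(locus.samples, ["a0", "a1", "a2", "a3"])
        v = validate_dpl(locus, res, unit_size_factors(locus.samples))
        assert max(v.cluster_fractions) == pytest.approx(0.5)
        assert not v.is_dpl  # 50% is not > 50%

    def test_depth_only_difference_is_not_dpl(self):
        # identical 80/20 shape; one group sequenced five-fold deeper
        counts = {"a0": (400, 100), "a1": (400, 100), "b0": (80, 20), "b1": (80, 20)}
        locus = build_locus(counts)
        res = forced_cluster(locus.samples, ["a0", "a1"])
        v = validate_dpl(locus, res, unit_size_factors(locus.samples))
        assert not v.is_dpl

    def test_global_rescaling_leaves_verdict_unchanged(self):
        counts = {"a0": (80, 20), "a1": (80, 20), "b0": (20, 80), "b1": (20, 80)}
        scaled = {s: (c1 * 3, c2 * 3) if s == "b0" else (c1, c2)
                  for s, (c1, c2) in counts.items()}
        l1, l2 = build_locus(counts), build_locus(scaled)
        from rpa.validate import locus_block_counts
        sf1 = compute_size_factors(
            locus_block_counts(l1, include_dummy_read=False), l1.samples)
        sf2 = compute_size_factors(
            locus_block_counts(l2, include_dummy_read=False), l2.samples)
        r1 = forced_cluster(l1.samples, ["a0", "a1"])
        r2 = forced_cluster(l2.samples, ["a0", "a1"])
        v1 = validate_dpl(l1, r1, sf1)
        v2 = validate_dpl(l2, r2, sf2)
        assert v1.is_dpl == v2.is_dpl

    def test_pvalue_matrix_symmetric_with_nan_diagonal(self):
        counts = {"a0": (80, 20), "a1": (70, 30), "b0": (20, 80), "b1": (30, 70)}
        locus = build_locus(counts)
        res = forced_cluster(locus.samples, ["a0", "a1"])
        v = validate_dpl(locus, res, unit_size_factors(locus.samples))
        pm = v.pvalue_matrix
        assert np.isnan(np.diag(pm)).all()
        off = ~np.eye(len(pm), dtype=bool)
        assert np.allclose(pm[off], pm.T[off])

    def test_combined_mode_counts_cell_lines(self):
        counts = {"A.r1": (80, 20), "A.r2": (80, 20),
                  "B.r1": (80, 20), "B.r2": (20, 80),
                  "C.r1": (20, 80), "C.r2": (20, 80)}
        locus = build_locus(counts)
        members = ["A.r1", "A.r2", "B.r1", "B.r2"]
        res = forced_cluster(locus.samples, members)
        rep = {s: s.split(".")[0] for s in locus.samples}
        v = validate_dpl(locus, res, unit_size_factors(locus.samples),
                         replicate_map=rep, mode="combined")
        # A qualifies (both reps), B does not (B.r2 matches the out-group):
        # 1 of 2 in-cluster lines -> 50% is not > 50%
        assert not v.is_dpl
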