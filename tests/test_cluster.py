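import itertools

import numpy as np
import pytest

from rpa.cluster import (ClusterInfo, ClusterResult, ScoreMatrix,
                         bootstrap_cluster, compute_cluster_score,
                         compute_score_matrix)
from rpa.loci import harmonize_block_groups, select_common_loci

from conftest import make_group, make_read, random_group


def block_matrix(groups, within, between, noise=0.0, seed=0):
    """Score matrix with group structure: ``groups`` maps label -> samples."""
    samples = [s for ss in groups.values() for s in ss]
    lab = {s: g for g, ss in groups.items() for s in ss}
    n = len(samples)
    rng = np.random.default_rng(seed)
    m = np.eye(n)
    for i, j in itertools.combinations(range(n), 2):
        base = within if lab[samples[i]] == lab[samples[j]] else between
        v = np.clip(base + noise * rng.normal(), 0.0, 1.0)
        m[i, j] = m[j, i] = v
    return ScoreMatrix(samples=samples, values=m)


class TestScoreMatrix:
    def make_locus(self, n=4):
        spec = [[(100, 22, 30)], [(150, 22, 10)]]
        gbs = {f"s{i}": [make_group(spec, sample=f"s{i}")] for i in range(n)}
        (locus,) = select_common_loci(gbs)
        reads = {
            f"s{i}": [make_read(100, 22, 30, sample=f"s{i}"),
                      make_read(150, 22, 10, sample=f"s{i}")]
            for i in range(n)
        }
        return harmonize_block_groups(locus, reads)

    def test_identical_groups_give_all_ones(self):
        m = compute_score_matrix(self.make_locus())
        assert np.allclose(m.values, 1.0)

    def test_symmetric_unit_diagonal(self, rng):
        gbs, reads = {}, {}
        for i in range(5):
            g = random_group(rng, n_blocks=2, origin=1000, sample=f"s{i}")
            gbs[f"s{i}"] = [g]
            reads[f"s{i}"] = [r for b in g.blocks for r in b.reads]
        (locus,) = select_common_loci(gbs)
        harmonize_block_groups(locus, reads)
        m = compute_score_matrix(locus)
        assert np.allclose(m.values, m.values.T)
        assert np.allclose(np.diag(m.values), 1.0)
        assert (m.values >= 0).all() and (m.values <= 1 + 1e-12).all()


class TestBootstrapCluster:
    def test_separated_groups_recovered_with_support(self):
        groups = {"A": [f"a{i}" for i in range(6)],
                  "B": [f"b{i}" for i in range(6)]}
        m = block_matrix(groups, within=1.0, between=0.2, noise=0.02, seed=1)
        res = bootstrap_cluster(m, n_boot=300, seed=4)
        by_members = {c.members: c for c in res.clusters}
        a, b = frozenset(groups["A"]), frozenset(groups["B"])
        assert a in by_members and by_members[a].p_value < 0.05
        assert b in by_members and by_members[b].p_value < 0.05

    def test_identical_profiles_support_nothing(self):
        samples = [f"s{i}" for i in range(8)]
        m = ScoreMatrix(samples=samples, values=np.ones((8, 8)))
        res = bootstrap_cluster(m, n_boot=100, seed=0)
        assert all(c.p_value >= 0.05 for c in res.clusters)

    def test_seed_determinism(self):
        m = block_matrix({"A": ["a0", "a1", "a2"], "B": ["b0", "b1", "b2"]},
                         within=0.9, between=0.4, noise=0.05, seed=2)
        r1 = bootstrap_cluster(m, n_boot=100, seed=9)
        r2 = bootstrap_cluster(m, n_boot=100, seed=9)
        assert [(sorted(c.members), c.p_value) for c in r1.clusters] == \
               [(sorted(c.members), c.p_value) for c in r2.clusters]

    def test_too_few_objects_gives_trivial_result(self):
        m = ScoreMatrix(samples=["a", "b"], values=np.eye(2))
        res = bootstrap_cluster(m, n_boot=100, seed=0)
        assert res.clusters == [] and res.cluster_score == 0.0


class TestClusterScore:
    def scored(self, m, members, p=0.01, **kw):
        res = ClusterResult(samples=m.samples, linkage_matrix=None)
        res.clusters.append(ClusterInfo(members=frozenset(members), p_value=p, bp=1.0))
        return compute_cluster_score(m, res, **kw)

    def test_hand_computed_separation(self):
        groups = {"A": ["a0", "a1", "a2"], "B": ["b0", "b1", "b2"]}
        m = block_matrix(groups, within=0.95, between=0.40)
        res = self.scored(m, groups["A"])
        assert res.cluster_score == pytest.approx(0.55)
        assert res.candidate

    def test_empty_significant_set_scores_zero(self):
        m = block_matrix({"A": ["a0", "a1"], "B": ["b0", "b1"]}, 0.9, 0.4)
        res = self.scored(m, ["a0", "a1"], p=0.5)  # not significant
        assert res.cluster_score == 0.0 and not res.candidate

    def test_negative_separation_clamped_to_zero(self):
        groups = {"A": ["a0", "a1"], "B": ["b0", "b1"]}
        m = block_matrix(groups, within=0.3, between=0.9)  # inverted structure
        res = self.scored(m, groups["A"])
        assert res.cluster_score == 0.0

    def test_combined_mode_requires_four_member_cluster(self):
        groups = {"A": ["A.r1", "A.r2", "B.r1"], "B": ["B.r2", "C.r1", "C.r2"]}
        m = block_matrix(groups, within=0.95, between=0.3)
        rep = {s: s.split(".")[0] for s in m.samples}
        # B's replicates straddle the cluster -> only A.r1/A.r2 remain inside
        res = self.scored(m, groups["A"], replicate_map=rep, mode="combined")
        assert res.cluster_score >= 0.15 and not res.candidate

    def test_combined_mode_consistent_replicates_qualify(self):
        groups = {"A": ["A.r1", "A.r2", "B.r1", "B.r2"],
                  "B": ["C.r1", "C.r2", "D.r1", "D.r2"]}
        m = block_matrix(groups, within=0.95, between=0.3)
        rep = {s: s.split(".")[0] for s in m.samples}
        res = self.scored(m, groups["A"], replicate_map=rep, mode="combined")
        assert res.candidate

    def test_raising_between_scores_never_increases_x(self):
        groups = {"A": ["a0", "a1", "a2"], "B": ["b0", "b1", "b2"]}
        xs = []
        for between in (0.2, 0.4, 0.6, 0.8):
            m = block_matrix(groups, within=0.9, between=between)
            xs.append(self.scored(m, groups["A"]).cluster_score)
        assert all(x1 >= x2 for x1, x2 in zip(xs, xs[1:]))

    def test_x_bounded_in_unit_interval(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 9))
            vals = rng.uniform(0, 1, size=(n, n))
            vals = (vals + vals.T) / 2
            np.fill_diagonal(vals, 1.0)
            samples = [f"s{i}" for i in range(n)]
            m = ScoreMatrix(samples=samples, values=vals)
            k = int(rng.integers(2, n))
            res = self.scored(m, samples[:k])
            assert 0.0 <= res.cluster_score <= 1.0
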