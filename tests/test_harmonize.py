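"""Clumping, flipping, collapsing, trimming — against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from mrslope import LDMatrix, SumStats, match_studies
from mrslope.harmonize import (NoSignalError, SignalCluster, clump,
                               collapse_correlated, filter_maf, flip_to_index,
                               trim_clusters)

from conftest import ar_ld, canonical_df, make_cluster


def joined_locus(n, pvals, ld, mafs=None, betas=None, pos=None, seed=0):
    ids = [f"s{i}" for i in range(n)]
    rng = np.random.default_rng(seed)
    betas = betas if betas is not None else rng.normal(0, 0.1, n)
    df = canonical_df(ids, betas, pvals=pvals, mafs=mafs, pos=pos)
    a = SumStats("A", df)
    b = SumStats("B", canonical_df(ids, rng.normal(0, 0.1, n), pvals=[0.5] * n,
                                   mafs=mafs, pos=pos))
    return match_studies(a, b, ld_a=LDMatrix(ids, ld))


class TestFilterMaf:
    def test_below_threshold_removed_boundary_kept(self):
        ld = np.eye(3)
        loc = joined_locus(3, [0.5] * 3, ld, mafs=[0.005, 0.01, 0.3])
        out = filter_maf(loc, 0.01)
        assert out.ids == ["s1", "s2"]
        assert ("s0", "maf_below_threshold") in out.drop_log

    def test_identity_when_all_common(self):
        ld = np.eye(3)
        loc = joined_locus(3, [0.5] * 3, ld, mafs=[0.02, 0.3, 0.5])
        assert filter_maf(loc).ids == loc.ids


def brute_force_clump(pvals, pos, r, p1, p2, r2, kb):
    """Independent reimplementation of the greedy clumping rule."""
    unassigned = set(range(len(pvals)))
    clusters = []
    while True:
        cand = [i for i in unassigned if pvals[i] < p1]
        if not cand:
            break
        index = min(cand, key=lambda i: (pvals[i], pos[i]))
        members = {i for i in unassigned
                   if pvals[i] <= p2 and abs(pos[i] - pos[index]) <= kb * 1000
                   and r[index, i] ** 2 >= r2}
        members.add(index)
        clusters.append((index, frozenset(members)))
        unassigned -= members
    return clusters


class TestClump:
    def test_single_snp_singleton_cluster(self):
        loc = joined_locus(1, [1e-4], np.eye(1))
        out = clump(loc)
        assert len(out) == 1 and len(out[0]) == 1

    def test_no_signal_raises(self):
        loc = joined_locus(3, [0.01, 0.5, 0.9], np.eye(3))
        with pytest.raises(NoSignalError):
            clump(loc)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_random_loci(self, seed):
        n = 10
        rng = np.random.default_rng(seed)
        r = np.corrcoef(rng.standard_normal((n, n + 4)))
        pvals = 10.0 ** rng.uniform(-6, 0, n)
        pos = np.sort(rng.choice(2_000_000, n, replace=False))
        loc = joined_locus(n, pvals, r, pos=pos, seed=seed)
        got = clump(loc, p1=0.01, p2=1.0, r2=0.1, kb=500)
        expected = brute_force_clump(loc.a["pvalue"].to_numpy(),
                                     loc.a["pos"].to_numpy(), r,
                                     0.01, 1.0, 0.1, 500)
        ids = loc.ids
        got_sets = [(c.index_id, frozenset(c.ids)) for c in got]
        exp_sets = [(ids[i], frozenset(ids[j] for j in m)) for i, m in expected]
        assert got_sets == exp_sets

    def test_monotone_in_p1(self):
        n = 10
        rng = np.random.default_rng(5)
        r = np.corrcoef(rng.standard_normal((n, n + 4)))
        pvals = 10.0 ** rng.uniform(-6, 0, n)
        loc = joined_locus(n, pvals, r, seed=5)
        counts = []
        for p1 in (1e-4, 1e-3, 1e-2, 1e-1):
            try:
                counts.append(len(clump(loc, p1=p1)))
            except NoSignalError:
                counts.append(0)
        assert counts == sorted(counts)


class TestFlipToIndex:
    def test_negative_member_flips_both_betas_and_ld(self):
        ids = ["i", "m"]
        r = np.array([[1.0, -0.8], [-0.8, 1.0]])
        a = canonical_df(ids, [0.5, 0.2], pvals=[1e-6, 1e-3])
        b = canonical_df(ids, [0.1, -0.1])
        cl = SignalCluster("i", a, b, LDMatrix(ids, r))
        out = flip_to_index(cl)
        assert out.a["beta"].iloc[1] == pytest.approx(-0.2)
        assert out.b["beta"].iloc[1] == pytest.approx(0.1)
        assert out.ld.r[0, 1] == pytest.approx(0.8)
        assert out.a["a1"].iloc[1] == "G" and out.a["a2"].iloc[1] == "A"

    def test_negative_index_reorients_whole_cluster(self):
        ids = ["i", "m"]
        r = np.array([[1.0, 0.6], [0.6, 1.0]])
        a = canonical_df(ids, [-0.5, 0.2], pvals=[1e-6, 1e-3])
        b = canonical_df(ids, [0.1, -0.1])
        out = flip_to_index(SignalCluster("i", a, b, LDMatrix(ids, r)))
        assert out.a["beta"].iloc[0] == pytest.approx(0.5)
        # index flip negates r(i, m); member then flips too
        assert out.ld.r[0, 1] == pytest.approx(0.6)
        assert out.a["beta"].iloc[1] == pytest.approx(-0.2)

    @pytest.mark.parametrize("seed", range(5))
    def test_idempotent_and_invariants(self, seed):
        cl = flip_to_index(make_cluster(8, seed))
        again = flip_to_index(cl)
        pd.testing.assert_frame_equal(cl.a, again.a)
        pd.testing.assert_frame_equal(cl.b, again.b)
        iidx = cl.ids.index(cl.index_id)
        assert cl.a["beta"].iloc[iidx] > 0
        assert (cl.ld.r[iidx] >= 0).all()


class TestCollapse:
    def test_two_highly_correlated_keep_lowest_p(self):
        ids = ["a", "b"]
        r = np.array([[1.0, 0.99], [0.99, 1.0]])
        a = canonical_df(ids, [0.5, 0.4], pvals=[1e-6, 1e-4])
        b = canonical_df(ids, [0.1, 0.1])
        out = collapse_correlated(SignalCluster("a", a, b, LDMatrix(ids, r)))
        assert out.ids == ["a"]
        assert out.collapsed["a"] == ["a", "b"]

    def test_identity_below_threshold(self):
        cl = make_cluster(5, 1, rho=0.5)
        out = collapse_correlated(cl)
        assert out.ids == cl.ids

    def test_greedy_chain_assignment(self):
        # r(1,2)=0.96, r(2,3)=0.96, r(1,3)=0.90; p ascending in id order
        ids = ["s1", "s2", "s3"]
        r = np.array([[1.0, 0.96, 0.90],
                      [0.96, 1.0, 0.96],
                      [0.90, 0.96, 1.0]])
        a = canonical_df(ids, [0.5, 0.4, 0.3], pvals=[1e-6, 1e-5, 1e-4])
        b = canonical_df(ids, [0.1, 0.1, 0.1])
        out = collapse_correlated(SignalCluster("s1", a, b, LDMatrix(ids, r)))
        assert out.ids == ["s1", "s3"]
        assert out.collapsed == {"s1": ["s1", "s2"], "s3": ["s3"]}


def brute_force_trim(key_ps, key_r2, r2_max):
    """Independent reimplementation of sorted-greedy cluster trimming."""
    order = sorted(range(len(key_ps)), key=lambda i: key_ps[i])
    kept = []
    for i in order:
        if all(key_r2[i, j] < r2_max for j in kept):
            kept.append(i)
    return sorted(kept)


class TestTrim:
    def _clusters(self, n, seed=0, rho=0.3):
        rng = np.random.default_rng(seed)
        ids = [f"k{i}" for i in range(n)]
        r = np.corrcoef(rng.standard_normal((n, n + 3)))
        clusters = []
        pvals = 10.0 ** rng.uniform(-8, -3, n)
        for i, snp in enumerate(ids):
            a = canonical_df([snp], [0.5], pvals=[pvals[i]], pos=[1000 * (i + 1)])
            b = canonical_df([snp], [0.1])
            clusters.append(SignalCluster(snp, a, b, LDMatrix([snp], np.eye(1))))
        return clusters, LDMatrix(ids, r), pvals, r

    def test_pair_above_threshold_drops_weaker(self):
        clusters, _, _, _ = self._clusters(2)
        r = np.array([[1.0, np.sqrt(0.06)], [np.sqrt(0.06), 1.0]])
        ld = LDMatrix(["k0", "k1"], r)
        clusters[0].a["pvalue"] = [1e-6]
        clusters[1].a["pvalue"] = [1e-4]
        out = trim_clusters(clusters, ld, 0.05)
        assert [c.key_id for c in out] == ["k0"]

    def test_identity_when_independent(self):
        clusters, _, _, _ = self._clusters(3, seed=3)
        r = np.full((3, 3), 0.1)  # r^2 = 0.01, below every pair's threshold
        np.fill_diagonal(r, 1.0)
        ld = LDMatrix(["k0", "k1", "k2"], r)
        assert len(trim_clusters(clusters, ld, 0.05)) == 3

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force(self, seed):
        clusters, ld, pvals, r = self._clusters(4, seed=seed)
        out = trim_clusters(clusters, ld, 0.05)
        expected = brute_force_trim(pvals, r ** 2, 0.05)
        assert [c.key_id for c in out] == [f"k{i}" for i in expected]
        # invariant: all pairwise key r^2 below the bound
        keys = [c.key_id for c in out]
        for i, ki in enumerate(keys):
            for kj in keys[i + 1:]:
                assert ld.r2(ki, kj) < 0.05

    def test_monotone_in_r2_max(self):
        clusters, ld, _, _ = self._clusters(6, seed=9)
        counts = [len(trim_clusters(clusters, ld, t))
                  for t in (0.01, 0.05, 0.2, 1.0)]
        assert counts == sorted(counts)


def test_pipeline_stages_deterministic_and_disjoint():
    n = 12
    rng = np.random.default_rng(11)
    r = ar_ld(n, 0.7)
    pvals = 10.0 ** rng.uniform(-7, 0, n)
    loc = joined_locus(n, pvals, r, seed=11)
    c1 = clump(loc, p1=0.05)
    c2 = clump(loc, p1=0.05)
    assert [c.ids for c in c1] == [c.ids for c in c2]
    all_ids = [s for c in c1 for s in c.ids]
    assert len(all_ids) == len(set(all_ids))
    assert set(all_ids) <= set(loc.ids)


def test_read_clumped_builds_clusters(tmp_path):
    from mrslope.harmonize import read_clumped
    n = 6
    ld = ar_ld(n, 0.6)
    loc = joined_locus(n, [1e-5, 0.2, 0.3, 1e-4, 0.5, 0.6], ld)
    path = tmp_path / "plink.clumped"
    path.write_text(
        " CHR    F  SNP          BP        P    TOTAL   NSIG    S05    S01"
        "   S001  S0001 SP2\n"
        "   1    1  s0        1000    1e-05        2      0      0      0"
        "      0      2 s1(1),s2(1)\n"
        "   1    1  s3        4000    1e-04        1      0      0      0"
        "      0      1 s4(1)\n"
        "   1    1  s9        9000    1e-03        0      0      0      0"
        "      0      0 NONE\n")
    clusters = read_clumped(path, loc)
    assert [c.index_id for c in clusters] == ["s0", "s3"]  # s9 not in locus
    assert clusters[0].ids == ["s0", "s1", "s2"]
    assert clusters[1].ids == ["s3", "s4"]
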