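import itertools

import numpy as np
import pytest

import aimpanel as ap
from aimpanel.ancestry import _em_q_step, _loglik
from aimpanel.io import DataError


def _two_cluster_ref(L, pa=0.9, pb=0.1):
    p = np.column_stack([np.full(L, pa), np.full(L, pb)])
    return ap.ReferenceFreqs(p, ["A", "B"], [f"sim{j:05d}" for j in range(L)])


class TestEstimateRefFreqs:
    def test_hand_computed(self):
        loci = [ap.LocusInfo("L0", "1", 1, "A", "C")]
        ds = ap.GenotypeDataset([[0.0], [1.0], [2.0]], loci, ["a", "b", "c"])
        ref = ap.estimate_ref_freqs(ds, ["X", "X", "X"], pseudocount=0.5)
        assert ref.freqs[0, 0] == pytest.approx(3.5 / 7)

    def test_clamping_at_boundary(self):
        loci = [ap.LocusInfo("L0", "1", 1, "A", "C")]
        ds = ap.GenotypeDataset([[2.0], [2.0]], loci, ["a", "b"])
        ref = ap.estimate_ref_freqs(ds, ["X", "X"], pseudocount=0.0)
        assert ref.freqs[0, 0] == 1 - 1e-6

    def test_zero_call_cluster_flagged(self):
        loci = [ap.LocusInfo("L0", "1", 1, "A", "C")]
        ds = ap.GenotypeDataset([[np.nan], [2.0]], loci, ["a", "b"])
        with pytest.warns(UserWarning, match="no calls"):
            ref = ap.estimate_ref_freqs(ds, ["X", "Y"])
        assert ref.freqs[0, 0] == pytest.approx(0.5)  # pseudocount alone


class TestSupervisedEm:
    def test_separable_clusters(self):
        ref = ap.ReferenceFreqs(
            np.column_stack([np.full(50, 1 - 1e-6), np.full(50, 1e-6)]),
            ["A", "B"],
            [f"L{j}" for j in range(50)],
        )
        q, ll = ap.supervised_em(np.full(50, 0.0), ref)  # sample from cluster B
        assert q[1] >= 0.999
        assert np.isfinite(ll)

    def test_flat_likelihood_keeps_uniform(self):
        p = np.full((30, 3), 0.4)
        ref = ap.ReferenceFreqs(p, ["A", "B", "C"], [f"L{j}" for j in range(30)])
        rng = np.random.default_rng(0)
        q, _ = ap.supervised_em(rng.binomial(2, 0.4, 30).astype(float), ref)
        np.testing.assert_allclose(q, 1 / 3, atol=1e-9)

    def test_recovers_half_half_admixture(self):
        rng = np.random.default_rng(21)
        L = 1000
        ref = _two_cluster_ref(L)
        ds = ap.sample_genotypes(ref.freqs, np.array([[0.5, 0.5]] * 30), rng=rng)
        qm = ap.supervised_admixture(ds, ref)
        assert np.abs(qm.q[:, 0] - 0.5).max() < 0.05
        assert qm.converged

    def test_loglik_nondecreasing(self):
        rng = np.random.default_rng(4)
        L = 200
        ref = _two_cluster_ref(L, 0.8, 0.3)
        g = rng.binomial(2, 0.5, (5, L)).astype(float)
        obs = np.ones_like(g, dtype=bool)
        q = np.full((5, 2), 0.5)
        prev = _loglik(g, obs, q, ref.freqs)
        for _ in range(50):
            q = _em_q_step(g, obs, q, ref.freqs)
            cur = _loglik(g, obs, q, ref.freqs)
            assert (cur >= prev - 1e-9).all()
            prev = cur

    def test_error_when_all_missing(self):
        ref = _two_cluster_ref(5)
        with pytest.raises(DataError):
            ap.supervised_em(np.full(5, np.nan), ref)

    def test_rmse_shrinks_with_panel_size(self):
        """Estimation error decreases monotonically with the number of loci."""
        rng = np.random.default_rng(31)
        rmses = []
        for L in (41, 200, 1000):
            ref = _two_cluster_ref(L)
            ds = ap.sample_genotypes(
                ref.freqs, np.array([[0.5, 0.5]] * 40, dtype=float), rng=rng
            )
            qm = ap.supervised_admixture(ds, ref)
            rmses.append(float(np.sqrt(np.mean((qm.q[:, 0] - 0.5) ** 2))))
        assert rmses[0] > rmses[1] > rmses[2]

    def test_low_admixture_harder_than_balanced(self):
        """At a small panel (41 loci), ancestry fractions around 0.1 are
        estimated with larger error than balanced admixture — the known
        insensitivity of compact panels to low-level admixture."""
        rng = np.random.default_rng(77)
        L, n = 41, 150
        ref = _two_cluster_ref(L)

        def rmse(q_true):
            ds = ap.sample_genotypes(
                ref.freqs, np.tile([q_true, 1 - q_true], (n, 1)), rng=rng
            )
            qm = ap.supervised_admixture(ds, ref)
            return float(np.sqrt(np.mean((qm.q[:, 0] - q_true) ** 2)))

        # relative error: low-admixture estimates are proportionally worse
        assert rmse(0.1) / 0.1 > rmse(0.5) / 0.5


class TestUnsupervisedEm:
    def test_k1_trivial(self, two_region_dataset):
        ds, _, _ = two_region_dataset
        sub = ds.subset_samples(ds.sample_ids[:10]).subset_loci(ds.locus_ids[:50])
        qm, ref = ap.unsupervised_em(sub, 1, seed=0, restarts=1)
        np.testing.assert_allclose(qm.q, 1.0)
        # with a single cluster the frequency estimate is the pooled frequency
        pooled = np.nanmean(sub.dosages, axis=0) / 2
        np.testing.assert_allclose(ref.freqs[:, 0], np.clip(pooled, 1e-6, 1 - 1e-6), atol=1e-6)

    def test_two_regions_separate(self):
        cfg = ap.SimulationConfig(
            n_loci=500,
            regions=("A", "B"),
            region_f=(0.3, 0.3),
            samples_per_region=30,
            seed=3,
        )
        ds, meta, truth = ap.simulate_dataset(cfg)
        qm, _ = ap.unsupervised_em(ds, 2, seed=5, restarts=3)
        # align to truth by the dominant cluster of the first region
        first_region = np.array(truth.labels) == "A"
        k = int(np.argmax(qm.q[first_region].mean(axis=0)))
        member = np.where(first_region, qm.q[:, k], 1 - qm.q[:, k])
        assert np.mean(member >= 0.9) > 0.95

    def test_same_seed_bit_identical(self, two_region_dataset):
        ds, _, _ = two_region_dataset
        sub = ds.subset_samples(ds.sample_ids[:20]).subset_loci(ds.locus_ids[:60])
        qm1, ref1 = ap.unsupervised_em(sub, 2, seed=42, restarts=2)
        qm2, ref2 = ap.unsupervised_em(sub, 2, seed=42, restarts=2)
        assert np.array_equal(qm1.q, qm2.q)
        assert np.array_equal(ref1.freqs, ref2.freqs)

    def test_k_exceeding_samples_errors(self, two_region_dataset):
        ds, _, _ = two_region_dataset
        sub = ds.subset_samples(ds.sample_ids[:3])
        with pytest.raises(DataError):
            ap.unsupervised_em(sub, 5)


class TestAlignReplicates:
    def test_recovers_permutation(self):
        rng = np.random.default_rng(0)
        q = rng.dirichlet(np.ones(4), size=25)
        perm = (2, 0, 3, 1)
        aligned, perms, sim = ap.align_replicates([q, q[:, perm]])
        assert np.abs(aligned[1] - q).max() == 0
        assert sim == pytest.approx(1.0)

    def test_identical_runs_identity_permutations(self):
        rng = np.random.default_rng(1)
        q = rng.dirichlet(np.ones(3), size=10)
        _, perms, _ = ap.align_replicates([q, q, q])
        assert perms == [(0, 1, 2)] * 3

    def test_matches_independent_exhaustive_search(self):
        rng = np.random.default_rng(2)
        q1 = rng.dirichlet(np.ones(3), size=15)
        q2 = q1[:, (1, 2, 0)] + rng.normal(0, 0.02, q1.shape)
        q2 = np.abs(q2)
        q2 /= q2.sum(axis=1, keepdims=True)
        _, perms, _ = ap.align_replicates([q1, q2])
        # independent brute force over permutations
        best = max(
            itertools.permutations(range(3)),
            key=lambda p: float(np.sum(q1 * q2[:, p])),
        )
        assert perms[1] == best

    def test_k_above_ten_rejected(self):
        q = np.full((4, 11), 1 / 11)
        with pytest.raises(DataError, match="greedy"):
            ap.align_replicates([q, q])


class TestAssignClusters:
    @pytest.mark.parametrize(
        "q,threshold,expected",
        [
            ([0.90, 0.04, 0.06], 0.85, "K1"),
            ([0.60, 0.40, 0.0], 0.85, "unassigned"),
            ([0.60, 0.40, 0.0], 0.5, "K1"),
            ([0.5, 0.5, 0.0], 0.5, "unassigned"),  # strict inequality
        ],
    )
    def test_threshold_rule(self, q, threshold, expected):
        calls = ap.assign_clusters(np.array([q]), threshold, ["K1", "K2", "K3"])
        assert calls == [expected]

    def test_assignment_sets_nested(self):
        rng = np.random.default_rng(5)
        q = rng.dirichlet(np.ones(3) * 0.3, size=200)
        strict = ap.assign_clusters(q, 0.85, ["a", "b", "c"])
        loose = ap.assign_clusters(q, 0.5, ["a", "b", "c"])
        for s, l in zip(strict, loose):
            if s != "unassigned":
                assert l == s  # 0.85-assigned is a subset of 0.5-assigned


class TestPopulationSummary:
    def _qm(self, q, sample_ids, clusters=("Africa", "Europe")):
        return ap.AdmixtureMatrix(
            np.asarray(q, dtype=float),
            list(clusters),
            sample_ids,
            np.zeros(len(sample_ids)),
            1,
            True,
        )

    def test_high_membership_population_fully_assigned(self):
        q = [[0.95, 0.05]] * 4
        meta = [ap.SampleMetadata(f"s{i}", "Yoruba", "Africa") for i in range(4)]
        qm = self._qm(q, [f"s{i}" for i in range(4)])
        out = ap.population_summary(qm, meta, (0.85, 0.5), {"Yoruba": "Africa"})
        row = out[out.population == "Yoruba"].iloc[0]
        assert row["assigned:0.85"] == 1.0 and row["assigned:0.5"] == 1.0
        assert row["Africa"] == pytest.approx(0.95)

    def test_admixed_population_threshold_gap(self):
        rng = np.random.default_rng(9)
        q1 = np.clip(rng.normal(0.6, 0.08, 40), 0.02, 0.98)
        q = np.column_stack([q1, 1 - q1])
        meta = [ap.SampleMetadata(f"s{i}", "Admixed", "Africa") for i in range(40)]
        qm = self._qm(q, [f"s{i}" for i in range(40)])
        out = ap.population_summary(qm, meta, (0.85, 0.5), {"Admixed": "Africa"})
        row = out.iloc[0]
        assert row["assigned:0.5"] > 0.7
        assert row["assigned:0.85"] < 0.2

    def test_population_without_expected_region_blank(self):
        qm = self._qm([[0.9, 0.1]], ["s0"])
        meta = [ap.SampleMetadata("s0", "Mystery", "Africa")]
        out = ap.population_summary(qm, meta, (0.5,), {})
        assert np.isnan(out.iloc[0]["assigned:0.5"])

    def test_weighted_population_means_conserve_overall_mean(self):
        rng = np.random.default_rng(13)
        q = rng.dirichlet(np.ones(2), size=30)
        pops = ["P1"] * 10 + ["P2"] * 20
        meta = [
            ap.SampleMetadata(f"s{i}", pops[i], "Africa") for i in range(30)
        ]
        qm = self._qm(q, [f"s{i}" for i in range(30)])
        out = ap.population_summary(qm, meta, (), {})
        weighted = (
            out["Africa"] * out["n"]
        ).sum() / out["n"].sum()
        assert weighted == pytest.approx(q[:, 0].mean())


class TestCompareAdmixture:
    def test_identical_r_one(self):
        v = np.linspace(0.1, 0.9, 20)
        r, slope, intercept = ap.compare_admixture(v, v)
        assert r == pytest.approx(1.0)
        assert slope == pytest.approx(1.0)
        assert intercept == pytest.approx(0.0, abs=1e-12)

    def test_constant_vector_errors(self):
        with pytest.raises(DataError):
            ap.compare_admixture(np.full(10, 0.5), np.linspace(0, 1, 10))

    def test_small_panel_estimates_track_truth(self):
        """Supervised 41-locus estimates correlate strongly (but not
        perfectly) with the generating ancestry fractions."""
        rng = np.random.default_rng(55)
        ref = _two_cluster_ref(41)
        truth = np.linspace(0.05, 0.95, 60)
        ds = ap.sample_genotypes(
            ref.freqs, np.column_stack([truth, 1 - truth]), rng=rng
        )
        qm = ap.supervised_admixture(ds, ref)
        r, _, _ = ap.compare_admixture(truth, qm.q[:, 0])
        assert 0.7 <= r <= 0.99
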