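"""Community processing: rarefaction, filtering, Bray-Curtis, NMDS, PERMANOVA."""

import itertools

import numpy as np
import pandas as pd
import pytest

from isofate.community import (
    CommunityError,
    aggregate_rank,
    bray_curtis,
    correlate_decomposers,
    counts_vs_rate_regression,
    filter_rare,
    nmds,
    permanova_pairwise,
    rarefy,
    transform,
)
from isofate.simulate import CommunityConfig, simulate_community


def toy_counts():
    return pd.DataFrame(
        [[500, 300, 200, 0], [10, 900, 80, 10], [0, 0, 0, 1000]],
        index=["s1", "s2", "s3"],
        columns=["o1", "o2", "o3", "o4"],
    )


class TestRarefy:
    def test_exact_threshold_unchanged(self):
        t = toy_counts()
        out = rarefy(t, 1000, seed=0)
        pd.testing.assert_frame_equal(out, t)

    def test_totals_exact_and_low_samples_dropped(self):
        t = toy_counts()
        t.loc["s4"] = [5, 5, 5, 5]
        with pytest.warns(UserWarning):
            out = rarefy(t, 1000, seed=0)
        assert "s4" not in out.index
        assert (out.sum(axis=1) == 1000).all()

    def test_hypergeometric_expectation_at_double_depth(self):
        counts = pd.DataFrame([[400, 400, 400, 400, 400]], index=["s"], columns=list("abcde"))
        means = np.mean(
            [rarefy(counts, 1000, seed=s).to_numpy()[0] for s in range(100)], axis=0
        )
        assert np.all(np.abs(means - 200) / 200 < 0.05)


class TestFilterRare:
    def test_floor_is_one_percent_in_any_sample(self):
        rel = pd.DataFrame(
            {"keep": [10, 0], "drop": [9, 9], "big": [981, 991]}, index=["s1", "s2"]
        )
        out = filter_rare(rel, 0.01)
        assert list(out.columns) == ["keep", "big"]

    def test_deterministic_survivors_on_toy_table(self):
        out = filter_rare(toy_counts(), 0.01)
        assert list(out.columns) == ["o1", "o2", "o3", "o4"]  # all reach 1% somewhere

    def test_idempotent(self):
        once = filter_rare(toy_counts(), 0.05)
        pd.testing.assert_frame_equal(filter_rare(once, 0.05), once)

    def test_all_dropped_rejected(self):
        with pytest.raises(CommunityError):
            filter_rare(toy_counts(), 1.1)


class TestTransform:
    def test_sqrt_of_relative_abundance(self):
        t = pd.DataFrame([[1, 3]], columns=["a", "b"])
        out = transform(t)
        assert out.iloc[0, 0] == pytest.approx(0.5)  # sqrt(0.25)

    def test_single_otu_sample_is_one(self):
        assert transform(pd.DataFrame([[42]]))[0][0] == 1.0

    def test_rank_preserving_within_sample(self):
        t = toy_counts()
        out = transform(t)
        for i in range(len(t)):
            assert (t.iloc[i].rank() == out.iloc[i].rank()).all()

    def test_zero_sum_sample_rejected(self):
        with pytest.raises(CommunityError):
            transform(pd.DataFrame([[0, 0]]))


class TestBrayCurtis:
    def test_hand_example(self):
        d = bray_curtis(np.array([[1, 2, 3], [2, 1, 0]], float))
        assert d.iloc[0, 1] == pytest.approx(5.0 / 9.0)

    def test_identical_and_disjoint(self):
        d = bray_curtis(np.array([[1, 2, 0, 0], [1, 2, 0, 0], [0, 0, 3, 4]], float))
        assert d.iloc[0, 1] == 0.0
        assert d.iloc[0, 2] == 1.0

    def test_matches_scipy_reference(self):
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(1)
        x = rng.uniform(0, 10, size=(6, 8))
        ours = bray_curtis(x).to_numpy()
        ref = squareform(pdist(x, metric="braycurtis"))
        assert np.allclose(ours, ref, atol=1e-12)

    def test_properties_and_column_permutation_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 5, size=(5, 7))
        d = bray_curtis(x).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert np.all((d >= 0) & (d <= 1))
        perm = rng.permutation(7)
        assert np.allclose(bray_curtis(x[:, perm]).to_numpy(), d)

    def test_all_zero_pair_flagged(self):
        with pytest.warns(UserWarning):
            d = bray_curtis(np.array([[0, 0], [0, 0], [1, 1]], float))
        assert np.isnan(d.iloc[0, 1])


class TestNMDS:
    def test_three_equidistant_points_embed_perfectly(self):
        d = pd.DataFrame(np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float))
        res = nmds(d, restarts=4, seed=0)
        assert res.stress < 0.01

    def test_monotone_line_low_stress(self):
        pos = np.arange(6, dtype=float)
        d = pd.DataFrame(np.abs(pos[:, None] - pos[None, :]))
        res = nmds(d, restarts=8, seed=1)
        assert res.stress < 0.01

    def test_reported_solution_is_best_restart(self, two_cluster_dissimilarity):
        d, _ = two_cluster_dissimilarity
        res = nmds(d, restarts=6, seed=2)
        assert res.stress == pytest.approx(res.restart_stresses.min())

    def test_clusters_separate(self, two_cluster_dissimilarity):
        d, groups = two_cluster_dissimilarity
        res = nmds(d, restarts=6, seed=3)
        coords = res.coordinates.to_numpy()
        a, b = coords[:4], coords[4:]
        within = max(np.linalg.norm(a - a.mean(0), axis=1).max(),
                     np.linalg.norm(b - b.mean(0), axis=1).max())
        between = np.linalg.norm(a.mean(0) - b.mean(0))
        assert between > within

    def test_coordinates_centered(self, two_cluster_dissimilarity):
        d, _ = two_cluster_dissimilarity
        res = nmds(d, restarts=2, seed=4)
        assert np.allclose(res.coordinates.mean(axis=0), 0.0, atol=1e-12)


class TestPermanova:
    def test_identical_samples_p_is_one(self):
        x = np.ones((6, 4))
        x[:, 0] = [1, 1, 1, 1, 1, 1]
        d = np.zeros((6, 6))
        res = permanova_pairwise(d + 1e-12 * (1 - np.eye(6)), ["a"] * 3 + ["b"] * 3)
        assert res.p_value == 1.0

    def test_maximal_separation_exhaustive_p(self):
        # two tight groups of 3: best of C(6,3)/2 = 10 distinct relabelings
        x = np.vstack([np.full((3, 2), [1.0, 0]), np.full((3, 2), [0, 5.0])])
        x += np.random.default_rng(0).normal(0, 0.01, x.shape)
        d = bray_curtis(np.abs(x)).to_numpy()
        res = permanova_pairwise(d, ["a"] * 3 + ["b"] * 3)
        assert res.method == "exhaustive"
        assert res.n_permutations == 10
        assert res.p_value == pytest.approx(0.1)

    def test_t_is_sqrt_f(self, two_cluster_dissimilarity):
        d, groups = two_cluster_dissimilarity
        res = permanova_pairwise(d.to_numpy(), groups)
        assert res.t == pytest.approx(np.sqrt(res.pseudo_f))

    def test_pseudo_f_matches_skbio(self, two_cluster_dissimilarity):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix, permanova

        d, groups = two_cluster_dissimilarity
        ref = permanova(DistanceMatrix(d.to_numpy()), grouping=list(groups), permutations=99)
        res = permanova_pairwise(d.to_numpy(), groups)
        assert res.pseudo_f == pytest.approx(float(ref["test statistic"]), rel=1e-9)

    def test_exhaustive_equals_independent_enumeration(self, two_cluster_dissimilarity):
        """4+4 design: 35 distinct relabelings, p via skbio-F enumeration."""
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix, permanova

        d, groups = two_cluster_dissimilarity
        dm = DistanceMatrix(d.to_numpy())
        n = 8
        f_obs = float(permanova(dm, grouping=list(groups), permutations=0)["test statistic"])
        count = total = 0
        for combo in itertools.combinations(range(1, n), 3):
            labels = np.array(["b"] * n)
            labels[[0, *combo]] = "a"
            f = float(permanova(dm, grouping=list(labels), permutations=0)["test statistic"])
            count += f >= f_obs - 1e-12
            total += 1
        assert total == 35
        res = permanova_pairwise(d.to_numpy(), groups)
        assert res.method == "exhaustive" and res.n_permutations == 35
        assert res.p_value == pytest.approx(count / total)

    def test_monte_carlo_close_to_exhaustive(self, two_cluster_dissimilarity):
        d, groups = two_cluster_dissimilarity
        exact = permanova_pairwise(d.to_numpy(), groups)
        mc = permanova_pairwise(
            d.to_numpy(), groups, n_permutations=9999, seed=0, exhaustive_limit=1
        )
        se = np.sqrt(exact.p_value * (1 - exact.p_value) / 9999)
        assert abs(mc.p_value - exact.p_value) <= 3 * se + 2e-4

    def test_group_of_one_rejected(self):
        with pytest.raises(CommunityError):
            permanova_pairwise(np.zeros((3, 3)), ["a", "b", "b"])


class TestAttribution:
    def test_perfectly_tracking_taxon_has_r_one(self):
        counts = pd.DataFrame(
            {"OTU1": [10, 20, 30, 40], "OTU2": [50, 50, 50, 50]},
            index=[f"S{i}" for i in range(4)],
        )
        tax = pd.Series(
            {"OTU1": "B;P;C;O;F;GenusA;sp.", "OTU2": "B;P;C;O;F;GenusB;sp."}
        )
        # ddelta proportional to the transformed relative abundance of OTU1
        z = np.sqrt(counts["OTU1"] / counts.sum(axis=1))
        dd = pd.DataFrame({"16:1w7": z}, index=counts.index)
        out = correlate_decomposers(counts, tax, dd, threshold=0.9)
        row = out[(out.taxon == "GenusA") & (out.compound == "16:1w7")].iloc[0]
        assert row.r == pytest.approx(1.0)
        assert row.candidate

    def test_designated_decomposers_recovered(self):
        counts, tax, signal = simulate_community(CommunityConfig(effect_size=2.0), seed=7)
        dd = pd.DataFrame({"16:1w7": signal * 30 + 5}, index=signal.index)
        out = correlate_decomposers(counts, tax, dd, threshold=0.9)
        hits = set(out.loc[out.candidate, "taxon"])
        assert {"Polynucleobacter", "Pelomonas", "Hydrocarboniphaga"} <= hits

    def test_null_communities_rarely_exceed_threshold(self):
        """Independent noise at n=8: r > 0.9 in fewer than 5% of pairs."""
        hits = total = 0
        for s in range(200):
            counts, tax, _ = simulate_community(
                CommunityConfig(effect_size=0.0), seed=10_000 + s
            )
            rng = np.random.default_rng(20_000 + s)
            dd = pd.DataFrame({"c": rng.standard_normal(len(counts))}, index=counts.index)
            out = correlate_decomposers(counts, tax, dd, threshold=0.9)
            hits += int(out.candidate.sum())
            total += len(out)
        assert hits / total < 0.05

    def test_too_few_paired_samples_rejected(self):
        counts = pd.DataFrame({"OTU1": [1, 2]}, index=["S1", "S2"])
        tax = pd.Series({"OTU1": "B;P;C;O;F;G;sp."})
        with pytest.raises(CommunityError):
            correlate_decomposers(counts, tax, pd.DataFrame({"c": [1, 2]}, index=["S1", "S2"]))

    def test_counts_vs_rate_regression_r2(self):
        rng = np.random.default_rng(4)
        counts = np.linspace(100, 1000, 8)
        rates = 0.002 * counts + rng.normal(0, 0.02, 8)
        out = counts_vs_rate_regression(counts, rates)
        assert out["r_squared"] > 0.95


def test_aggregate_rank_sums_otus():
    counts = pd.DataFrame({"OTU1": [1, 2], "OTU2": [3, 4]}, index=["S1", "S2"])
    tax = pd.Series({"OTU1": "B;P;C;O;F;G1;sp.", "OTU2": "B;P;C;O;F;G1;sp."})
    agg = aggregate_rank(counts, tax)
    assert list(agg["G1"]) == [4, 6]
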