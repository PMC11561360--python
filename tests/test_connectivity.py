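"""Connectivity statistic, null models, ranking and hub partitioning."""

import math

import pytest

from oligoscreen.connectivity import (
    Compendium,
    PerturbationProfile,
    connectivity_score,
    discretize_profile,
    find_hub_genes,
    query_compendium,
)
from conftest import make_set, random_profile, random_signed_set


def profile_from_signs(pid, signs, kind="compound"):
    return PerturbationProfile(
        id=pid, kind=kind, regulation={g: float(s) for g, s in signs.items()}
    )


class TestDiscretize:
    def test_sign_mode_drops_zeros(self, caplog):
        p = PerturbationProfile(id="p", regulation={"A": 2.0, "B": -0.5, "C": 0.0})
        assert discretize_profile(p, "sign") == {"A": 1, "B": -1}

    def test_topk_extremes(self):
        p = PerturbationProfile(id="p", regulation={"A": 3, "B": 2, "C": -1, "D": -4})
        assert discretize_profile(p, "topk", k=1) == {"A": 1, "D": -1}

    def test_all_zero_profile_warns(self, caplog):
        p = PerturbationProfile(id="p", regulation={"A": 0.0, "B": 0.0})
        with caplog.at_level("WARNING"):
            assert discretize_profile(p, "sign") == {}
        assert any("all zero" in r.message for r in caplog.records)

    def test_oversized_k_clipped(self, caplog):
        p = PerturbationProfile(id="p", regulation={"A": 3, "B": 2, "C": -1, "D": -4})
        with caplog.at_level("WARNING"):
            out = discretize_profile(p, "topk", k=10)
        assert out == {"A": 1, "B": 1, "C": -1, "D": -1}


class TestConnectivityScore:
    def test_perfect_agreement(self):
        query = make_set({f"g{i}": 1 for i in range(10)})
        p = profile_from_signs("p", {f"g{i}": 1 for i in range(10)})
        r = connectivity_score(query, p, null="analytic")
        assert r.score == 1.0
        assert r.z == pytest.approx(math.sqrt(10))

    def test_perfect_agreement_binomial_p(self):
        # oracle: exact enumeration of the two-sided binomial tail at n=10,
        # m=10 -> p = 2 * C(10,10) / 2**10 = 2/1024
        query = make_set({f"g{i}": 1 for i in range(10)})
        p = profile_from_signs("p", {f"g{i}": 1 for i in range(10)})
        r = connectivity_score(query, p, null="binomial")
        assert r.pvalue == pytest.approx(0.001953125, abs=1e-12)

    def test_hand_counted_overlap(self):
        query = make_set({"A": 1, "B": 1, "C": -1, "D": 1})
        p = profile_from_signs("p", {"A": 1, "B": -1, "C": -1, "E": 1})
        r = connectivity_score(query, p, min_overlap=3)
        assert r.n_overlap == 3
        assert r.score == pytest.approx(1 / 3)

    def test_insufficient_overlap_flagged_not_raised(self):
        query = make_set({"A": 1, "B": 1})
        p = profile_from_signs("p", {"A": 1, "X": 1})
        r = connectivity_score(query, p)  # overlap 1 < default 5
        assert r.call == "null" and r.pvalue == 1.0 and r.flag == "insufficient overlap"

    def test_antisymmetry(self, rng):
        genes = [f"g{i}" for i in range(60)]
        for rep in range(20):
            q = random_signed_set(rng, genes)
            p = random_profile(rng, genes[: rng.integers(10, 60)])
            r = connectivity_score(q, p)
            rf = connectivity_score(q.flipped(), p)
            assert rf.score == pytest.approx(-r.score)
            assert abs(rf.z) == pytest.approx(abs(r.z))
            assert -1 <= r.score <= 1

    @pytest.mark.parametrize("n", range(5, 13))
    def test_permutation_enumeration_equals_exact_binomial(self, n):
        """For small overlaps the enumerated permutation null is the exact test."""
        genes = [f"g{i}" for i in range(n)]
        for m in range(n + 1):
            signs = {g: (1 if i < m else -1) for i, g in enumerate(genes)}
            query = make_set({g: 1 for g in genes})
            p = profile_from_signs("p", signs)
            r_perm = connectivity_score(query, p, null="permutation", min_overlap=n)
            r_binom = connectivity_score(query, p, null="binomial", min_overlap=n)
            assert r_perm.pvalue == pytest.approx(r_binom.pvalue, abs=1e-12)

    def test_permutation_seed_determinism(self, rng):
        genes = [f"g{i}" for i in range(50)]
        q = random_signed_set(rng, genes)
        p = random_profile(rng, genes)
        r1 = connectivity_score(q, p, null="permutation", seed=7, n_perm=2000)
        r2 = connectivity_score(q, p, null="permutation", seed=7, n_perm=2000)
        assert r1.pvalue == r2.pvalue

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            connectivity_score(make_set({}), profile_from_signs("p", {"A": 1}))


class TestQueryCompendium:
    def make_setup(self):
        query = make_set({f"g{i}": (1 if i % 2 else -1) for i in range(20)})
        self_profile = profile_from_signs("self", {g: d for g, d in query.entries.items()})
        flipped = profile_from_signs("flip", {g: -d for g, d in query.entries.items()})
        return query, self_profile, flipped

    def test_self_match_ranks_first(self, rng):
        query, self_profile, flipped = self.make_setup()
        noise = [random_profile(rng, list(query.entries), pid=f"n{i}") for i in range(5)]
        comp = Compendium(profiles=[flipped, *noise, self_profile])
        results = query_compendium(query, comp)
        assert results[0].id == "self" and results[0].score == 1.0
        assert results[0].call == "correlated"

    def test_flipped_ranks_last_anticorrelated(self, rng):
        query, self_profile, flipped = self.make_setup()
        comp = Compendium(profiles=[self_profile, flipped])
        results = query_compendium(query, comp)
        assert results[-1].id == "flip"
        assert results[-1].call == "anticorrelated"
        assert results[-1].score == -1.0

    def test_tie_break_lexicographic(self):
        query, self_profile, _ = self.make_setup()
        twin_a = profile_from_signs("a", self_profile.regulation)
        twin_b = profile_from_signs("b", self_profile.regulation)
        results = query_compendium(query, Compendium(profiles=[twin_b, twin_a]))
        assert [r.id for r in results] == ["a", "b"]

    def test_empty_compendium(self):
        query, _, _ = self.make_setup()
        assert query_compendium(query, Compendium(profiles=[])) == []


class TestFindHubGenes:
    def test_planted_hub_recovered_and_partition_disjoint(self, rng):
        query = make_set({f"g{i}": (1 if i % 2 else -1) for i in range(30)})
        planted = profile_from_signs("hub+", dict(query.entries), kind="gene")
        anti = profile_from_signs(
            "hub-", {g: -d for g, d in query.entries.items()}, kind="gene"
        )
        noise = [
            random_profile(rng, list(query.entries), pid=f"n{i}", kind="gene")
            for i in range(10)
        ]
        comp = Compendium(profiles=[planted, anti, *noise])
        hubs = find_hub_genes(query, comp, alpha=0.05)
        corr = {r.id for r in hubs["correlated"]}
        anti_ids = {r.id for r in hubs["anticorrelated"]}
        assert "hub+" in corr and "hub-" in anti_ids
        assert corr & anti_ids == set()

    def test_alpha_zero_yields_nothing(self):
        query = make_set({f"g{i}": 1 for i in range(10)})
        planted = profile_from_signs("hub", dict(query.entries), kind="gene")
        hubs = find_hub_genes(query, Compendium(profiles=[planted]), alpha=0.0)
        assert hubs == {"correlated": [], "anticorrelated": []}

    def test_compound_profiles_rejected(self):
        query = make_set({f"g{i}": 1 for i in range(10)})
        wrong = profile_from_signs("c", dict(query.entries), kind="compound")
        with pytest.raises(ValueError, match="gene-perturbation"):
            find_hub_genes(query, Compendium(profiles=[wrong]))
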