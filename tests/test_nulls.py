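"""Null ensembles: construction invariants, degenerate identities, p-values."""

import numpy as np
import pytest

import braingsa as bg
from braingsa.core import GeneSet, MatchedSamplingError
from braingsa.association import correlate
from braingsa.evaluation import coexpression
from braingsa.nulls import (
    NullEnsemble,
    batch_permutation_p,
    draw_memberships,
    permutation_p,
    spun_correlations,
)
from braingsa.setstats import StatisticValue, batch_profile_stats, evaluate_statistics
from braingsa.spatial import SpinSet


@pytest.fixture(scope="module")
def gs30(flat_expr):
    return bg.sample_gene_sets(flat_expr, [30], 1, seed=21)[0]


@pytest.fixture(scope="module")
def spins200(geometry34):
    return bg.generate_spins(geometry34, 200, seed=23)


class TestPermutationP:
    def test_upper_tail_counting(self):
        ens = NullEnsemble("competitive", 3, {"meanabs": np.array([0.0, 1.0, 1.5])}, 0)
        res = permutation_p(StatisticValue("meanabs", 2.0, False), ens)
        assert res.p_value == pytest.approx(0.25)
        assert res.significant is False

    def test_all_ties_give_one(self):
        ens = NullEnsemble("competitive", 4, {"meanabs": np.full(4, 2.0)}, 0)
        res = permutation_p(StatisticValue("meanabs", 2.0, False), ens)
        assert res.p_value == 1.0

    def test_two_sided_counting(self):
        ens = NullEnsemble(
            "competitive", 4, {"mean": np.array([-0.6, -0.1, 0.1, 0.6])}, 0
        )
        res = permutation_p(StatisticValue("mean", 0.5, True), ens)
        assert res.p_value == pytest.approx(0.8)

    def test_add_one_bounds(self):
        rng = np.random.default_rng(0)
        null = rng.normal(size=99)
        for emp, sign in ((10.0, False), (10.0, True), (-10.0, True)):
            ens = NullEnsemble("competitive", 99, {"mean" if sign else "meanabs": null}, 0)
            res = permutation_p(
                StatisticValue("mean" if sign else "meanabs", emp, sign), ens
            )
            assert 0 < res.p_value <= 1

    def test_missing_statistic_rejected(self):
        ens = NullEnsemble("competitive", 3, {"mean": np.zeros(3)}, 0)
        with pytest.raises(ValueError):
            permutation_p(StatisticValue("ks", 1.0, True), ens)

    def test_batch_matches_scalar(self):
        rng = np.random.default_rng(1)
        null = rng.normal(size=200)
        emps = rng.normal(size=10)
        for sign in (True, False):
            name = "mean" if sign else "meanabs"
            ens = NullEnsemble("competitive", 200, {name: null}, 0)
            batched = batch_permutation_p(emps, null, sign)
            for i, e in enumerate(emps):
                assert batched[i] == pytest.approx(
                    permutation_p(StatisticValue(name, e, sign), ens).p_value
                )


class TestCompetitive:
    def test_singleton_set_samples_background(self, profile):
        gs = GeneSet("one", [profile.gene_ids[5]])
        ens = bg.competitive_nulls(profile, gs, 300, seed=2, statistics=["mean"])
        assert set(np.round(ens.values["mean"], 12)) <= set(np.round(profile.r, 12))

    def test_set_size_constant(self, profile):
        idx = draw_memberships(profile.n_genes, 17, 50, seed=3)
        assert idx.shape == (50, 17)
        for row in idx:
            assert len(set(row.tolist())) == 17

    def test_mean_null_centres_on_background_mean(self, profile, gs30):
        """E[mean of a uniform subset] equals the background mean."""
        ens = bg.competitive_nulls(profile, gs30, 5000, seed=4, statistics=["mean"])
        nm = ens.values["mean"]
        se_mean = nm.std() / np.sqrt(len(nm))
        assert nm.mean() == pytest.approx(profile.r.mean(), abs=3 * se_mean)

    def test_never_touches_the_map(self, profile, gs30):
        a = bg.competitive_nulls(profile, gs30, 100, seed=5)
        b = bg.competitive_nulls(profile, gs30, 100, seed=5)
        for name in a.values:
            assert np.array_equal(a.values[name], b.values[name])

    def test_oversized_set_rejected(self, profile):
        gs = GeneSet("all", list(profile.gene_ids))
        with pytest.raises(ValueError):
            bg.competitive_nulls(profile, gs, 100, seed=6)


class TestSelfContained:
    def test_identity_spin_reproduces_empirical(self, maps34, flat_expr, gs30):
        ident = SpinSet(np.arange(34)[None, :].repeat(100, axis=0), seed=0)
        ens = bg.self_contained_nulls(maps34[0], flat_expr, gs30, ident)
        prof = correlate(maps34[0], flat_expr)
        emp = evaluate_statistics(prof, gs30)
        for name, vec in ens.values.items():
            assert vec == pytest.approx(np.full(100, emp[name].value)), name

    def test_requested_length(self, maps34, flat_expr, gs30, spins200):
        ens = bg.self_contained_nulls(maps34[0], flat_expr, gs30, spins200)
        assert ens.n_perm == 200
        for vec in ens.values.values():
            assert vec.shape == (200,)

    def test_membership_fixed_coexpression_preserved(self, maps34, structured_expr):
        """The gene set is the same in every iteration, so its co-expression
        is untouched by the spin; each spin only permutes the map."""
        gs = bg.sample_coexpressed_set(structured_expr, 20, 0.5, 0.15, seed=7)
        before = coexpression(structured_expr, gs)
        spins = bg.generate_spins(structured_expr.geometry, 50, seed=8)
        bg.self_contained_nulls(maps34[0], structured_expr, gs, spins)
        assert coexpression(structured_expr, gs) == before
        r_null = spun_correlations(maps34[0], structured_expr, spins)
        # spun-map correlations per spin are the profile of a permuted map
        prof0 = correlate(
            bg.BrainMap(maps34[0].values[spins.permutations[0]],
                        structured_expr.geometry),
            structured_expr,
        )
        assert np.allclose(r_null[:, 0], prof0.r)

    def test_geometry_mismatch_rejected(self, maps34, flat_expr):
        other = bg.generate_geometry(20, seed=1)
        spins = bg.generate_spins(other, 10, seed=2)
        gs = GeneSet("s", list(flat_expr.gene_ids[:5]))
        with pytest.raises(ValueError):
            bg.self_contained_nulls(maps34[0], flat_expr, gs, spins)


class TestRestrictedAndMatched:
    def test_full_pool_equals_competitive(self, geometry34, maps34):
        spec = bg.SyntheticSpec(n_genes=200, n_parcels=34, loading_scale=0.0,
                                brain_specific_fraction=1.0, seed=31)
        expr = bg.generate_expression(spec, geometry34)
        prof = correlate(maps34[0], expr)
        gs = bg.sample_gene_sets(expr, [15], 1, seed=32)[0]
        comp = bg.competitive_nulls(prof, gs, 150, seed=33)
        bs = bg.brain_specific_nulls(expr, prof, gs, 150, seed=33)
        for name in comp.values:
            assert np.array_equal(comp.values[name], bs.values[name]), name

    def test_pool_membership_enforced(self, maps34, flat_expr):
        prof = correlate(maps34[0], flat_expr)
        pool_idx = flat_expr.brain_specific_indices()
        gs = GeneSet("s", [flat_expr.gene_ids[i] for i in pool_idx[:20]])
        idx = draw_memberships(flat_expr.n_genes, 20, 50, seed=34, pool=pool_idx)
        assert set(idx.ravel().tolist()) <= set(pool_idx.tolist())

    def test_pool_smaller_than_set_rejected(self, geometry34, maps34):
        spec = bg.SyntheticSpec(n_genes=200, n_parcels=34,
                                brain_specific_fraction=0.25, seed=35)
        expr = bg.generate_expression(spec, geometry34)
        prof = correlate(maps34[0], expr)
        gs = bg.sample_gene_sets(expr, [60], 1, seed=36)[0]
        with pytest.raises(ValueError):
            bg.brain_specific_nulls(expr, prof, gs, 100, seed=37)

    def test_infinite_tolerance_equals_competitive(self, maps34, flat_expr, gs30):
        prof = correlate(maps34[0], flat_expr)
        comp = bg.competitive_nulls(prof, gs30, 120, seed=38)
        matched = bg.coexpr_matched_nulls(flat_expr, prof, gs30, np.inf, 120, seed=38)
        for name in comp.values:
            assert np.array_equal(comp.values[name], matched.values[name]), name

    def test_acceptance_predicate_enforced(self, structured_expr, maps34):
        gs = bg.sample_coexpressed_set(structured_expr, 20, 0.5, 0.1, seed=39)
        target = coexpression(structured_expr, gs)
        prof = correlate(maps34[0], structured_expr)
        from braingsa.synthetic import _gene_correlation_matrix
        from braingsa.nulls import draw_matched_memberships

        gc = _gene_correlation_matrix(structured_expr)
        idx, rate = draw_matched_memberships(gc, 20, target, 0.05, 60, seed=40)
        for row in idx:
            sub = gc[np.ix_(row, row)]
            co = (sub.sum() - 20) / (20 * 19)
            assert abs(co - target) <= 0.05
        assert 0 < rate <= 1

    def test_matched_widens_mean_null_for_coexpressed_sets(
        self, structured_expr, maps34
    ):
        """With high within-set co-expression the matched null spread of the
        Mean statistic exceeds the competitive one."""
        gs = bg.sample_coexpressed_set(structured_expr, 25, 0.6, 0.1, seed=41)
        prof = correlate(maps34[1], structured_expr)
        comp = bg.competitive_nulls(prof, gs, 1000, seed=42, statistics=["mean"])
        matched = bg.coexpr_matched_nulls(
            structured_expr, prof, gs, 0.1, 1000, seed=42, statistics=["mean"]
        )
        assert matched.values["mean"].std() > comp.values["mean"].std()

    def test_exhausted_budget_raises(self, flat_expr, maps34):
        prof = correlate(maps34[0], flat_expr)
        gs = bg.sample_gene_sets(flat_expr, [20], 1, seed=43)[0]
        with pytest.raises(MatchedSamplingError):
            bg.coexpr_matched_nulls(flat_expr, prof, gs, 1e-9, 10, seed=44,
                                    max_attempts=3)


class TestCombined:
    def test_identity_iteration_reproduces_empirical(self, maps34, flat_expr, gs30):
        """Forcing the identity spin and the original membership yields the
        empirical statistic."""
        prof = correlate(maps34[0], flat_expr)
        member_idx = flat_expr.gene_indices(gs30.members)
        vals = batch_profile_stats(
            prof.r[:, None], member_idx, ["mean", "ks"], n_parcels=34
        )
        emp = evaluate_statistics(prof, gs30, ["mean", "ks"])
        assert vals["mean"][0] == pytest.approx(emp["mean"].value)
        assert vals["ks"][0] == pytest.approx(emp["ks"].value)

    def test_ensemble_length_and_centre(self, maps34, flat_expr, gs30, spins200):
        ens = bg.combined_nulls(maps34[0], flat_expr, gs30, spins200, seed=45,
                                statistics=["mean"])
        assert ens.n_perm == 200
        sc = bg.self_contained_nulls(maps34[0], flat_expr, gs30, spins200,
                                     statistics=["mean"])
        # both null means centre near the spun-map background mean
        assert ens.values["mean"].mean() == pytest.approx(
            sc.values["mean"].mean(), abs=0.02
        )
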