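"""The eight gene-set statistics against brute-force oracles and their invariants."""

import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

import braingsa as bg
from braingsa.association import CorrelationProfile, pearson_pvalues
from braingsa.core import GeneSet, MissingGeneError
from braingsa.setstats import (
    SIGN_SENSITIVE,
    STATISTICS,
    batch_members_stats,
    batch_profile_stats,
    bh_adjust,
    evaluate_statistics,
    stat_ks,
    stat_signumber,
)
from oracles import (
    bh_oracle,
    ks_oracle,
    ks_values_equivalent,
    maxmean_oracle,
    mean_oracle,
    meanabs_oracle,
    meansqr_oracle,
    median_oracle,
    signumber_oracle,
)


def _profile(r, p=None, ids=None):
    r = np.asarray(r, float)
    ids = ids or [f"G{i:03d}" for i in range(r.size)]
    p = pearson_pvalues(r, 34) if p is None else np.asarray(p, float)
    return CorrelationProfile(tuple(ids), r, p, n_parcels_used=34)


def _random_instance(rng, n_genes=None, k=None):
    n_genes = n_genes or int(rng.integers(6, 40))
    k = k or int(rng.integers(2, n_genes))
    r = rng.uniform(-1, 1, n_genes)
    prof = _profile(r)
    members = [prof.gene_ids[i] for i in rng.choice(n_genes, k, replace=False)]
    return prof, GeneSet("s", members)


class TestHandExamples:
    def test_mean(self):
        prof = _profile([0.2, 0.4])
        assert bg.stat_mean(prof, GeneSet("s", prof.gene_ids)).value == pytest.approx(0.3)
        prof = _profile([-0.3, 0.3])
        assert bg.stat_mean(prof, GeneSet("s", prof.gene_ids)).value == pytest.approx(0.0)
        prof = _profile([0.9, -0.2, -0.8, 0.5])
        assert bg.stat_mean(prof, GeneSet("s", prof.gene_ids)).value == pytest.approx(0.1)

    def test_meanabs_meansqr_median(self):
        prof = _profile([-0.3, 0.3])
        gs = GeneSet("s", prof.gene_ids)
        assert bg.stat_meanabs(prof, gs).value == pytest.approx(0.3)
        assert bg.stat_meansqr(prof, gs).value == pytest.approx(0.09)
        assert bg.stat_median(prof, gs).value == pytest.approx(0.0)
        prof = _profile([-0.1, 0.2, 0.6])
        assert bg.stat_median(prof, GeneSet("s", prof.gene_ids)).value == pytest.approx(0.2)
        prof = _profile([0.9, -0.2, -0.8, 0.5])
        assert bg.stat_meansqr(prof, GeneSet("s", prof.gene_ids)).value == pytest.approx(0.435)

    def test_maxmean(self):
        prof = _profile([0.5, -0.1, -0.2])
        assert bg.stat_maxmean(prof, GeneSet("s", prof.gene_ids)).value == pytest.approx(0.5)
        prof = _profile([0.0, 0.0, 0.0])
        assert bg.stat_maxmean(prof, GeneSet("s", prof.gene_ids)).value == 0.0
        prof = _profile([0.1, -0.6, -0.4])
        assert bg.stat_maxmean(prof, GeneSet("s", prof.gene_ids)).value == pytest.approx(0.5)

    def test_signumber(self):
        prof = _profile([0.9, 0.1, 0.05], p=[0.001, 0.9, 0.95])
        assert stat_signumber(prof, GeneSet("s", prof.gene_ids)).value == 1
        prof = _profile([0.0] * 4, p=[1.0] * 4)
        assert stat_signumber(prof, GeneSet("s", prof.gene_ids)).value == 0
        prof = _profile([0.99] * 20, p=[1e-6] * 20)
        assert stat_signumber(prof, GeneSet("s", prof.gene_ids)).value == 20

    def test_ks_walk(self):
        prof = _profile([0.9, 0.5, -0.2, -0.8])
        gs = GeneSet("s", [prof.gene_ids[0], prof.gene_ids[3]])  # ranks 1 and 4
        # literal walk: cum [+1, 0, -1, 0] and [+0.9, +0.4, +0.2, +1.0]
        assert stat_ks(prof, gs, weighted=False,
                       variant="literal").value == pytest.approx(1.0)
        assert stat_ks(prof, gs, weighted=True,
                       variant="literal").value == pytest.approx(1.0)
        # normalised walk: cum [+1/2, 0, -1/2, 0] -> earliest extreme +0.5
        assert stat_ks(prof, gs, weighted=False).value == pytest.approx(0.5)

    def test_ks_top_prefix(self):
        """Members occupying the top k ranks walk monotonically to +k; the +k
        prefix is the extreme deviation whenever it dominates the walk's end
        drift 2k-G (otherwise the drift itself is the extremum)."""
        r = np.linspace(0.9, -0.9, 12)
        prof = _profile(r)
        for k in (5, 6):  # 3k >= G: the +k prefix dominates
            gs = GeneSet("s", list(prof.gene_ids[:k]))
            assert stat_ks(prof, gs, weighted=False,
                           variant="literal").value == pytest.approx(k)
        gs = GeneSet("s", list(prof.gene_ids[:2]))  # drift -(G-2k) dominates
        assert stat_ks(prof, gs, weighted=False,
                       variant="literal").value == pytest.approx(-8)
        for k in (2, 5):  # normalised walk peaks at +1 after the prefix
            gs = GeneSet("s", list(prof.gene_ids[:k]))
            assert stat_ks(prof, gs, weighted=False).value == pytest.approx(1.0)

    def test_missing_gene(self):
        prof = _profile([0.1, 0.2])
        with pytest.raises(MissingGeneError):
            bg.stat_mean(prof, GeneSet("s", ["nope"]))


class TestOracleEquivalence:
    def test_all_statistics_match_brute_force(self):
        rng = np.random.default_rng(42)
        oracles = {
            "mean": mean_oracle, "meanabs": meanabs_oracle,
            "meansqr": meansqr_oracle, "median": median_oracle,
            "maxmean": maxmean_oracle,
        }
        for _ in range(120):
            prof, gs = _random_instance(rng)
            vals = evaluate_statistics(prof, gs)
            member_r = [prof.r[list(prof.gene_ids).index(g)] for g in gs.members]
            member_p = [prof.p[list(prof.gene_ids).index(g)] for g in gs.members]
            for name, oracle in oracles.items():
                assert vals[name].value == pytest.approx(oracle(member_r)), name
            assert vals["signumber"].value == signumber_oracle(member_p)
            flags = [g in set(gs.members) for g in prof.gene_ids]
            for name, weighted in (("ks", False), ("weighted_ks", True)):
                ref = ks_oracle(prof.r, flags, prof.gene_ids, weighted, "gsea")
                assert ks_values_equivalent(vals[name].value, ref), name
                lit = stat_ks(prof, gs, weighted=weighted, variant="literal")
                ref = ks_oracle(prof.r, flags, prof.gene_ids, weighted, "literal")
                assert ks_values_equivalent(lit.value, ref), name

    def test_bh_matches_statsmodels(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            p = rng.uniform(0, 1, int(rng.integers(2, 50)))
            mine = bh_adjust(p)
            ref = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(mine, ref)
            assert np.allclose(mine, bh_oracle(p))


class TestInvariants:
    def test_sign_equivariance_dichotomy(self):
        """Negating all correlations negates the sign-sensitive statistics and
        leaves the sign-insensitive ones unchanged.  For the running-sum
        statistics the exact flip holds for balanced sets (the literal walk's
        end value 2k-G is sign-locked otherwise) and for the normalised
        variant in general."""
        rng = np.random.default_rng(3)
        for _ in range(40):
            prof, gs = _random_instance(rng)
            neg = _profile(-prof.r, p=prof.p, ids=list(prof.gene_ids))
            a = evaluate_statistics(prof, gs)
            b = evaluate_statistics(neg, gs)
            for name in ("mean", "median"):
                assert b[name].value == pytest.approx(-a[name].value)
            for name in ("meanabs", "meansqr", "maxmean", "signumber"):
                assert b[name].value == pytest.approx(a[name].value)
        for _ in range(40):
            n = 2 * int(rng.integers(3, 15))
            prof, gs = _random_instance(rng, n_genes=n, k=n // 2)
            neg = _profile(-prof.r, p=prof.p, ids=list(prof.gene_ids))
            # balanced literal walk: the deviation magnitude mirrors exactly
            # (the sign can tie when +m and -m are both attained)
            assert abs(stat_ks(neg, gs, variant="literal").value) == pytest.approx(
                abs(stat_ks(prof, gs, variant="literal").value)
            )
            # default normalised walks mirror too; for the weighted one the
            # continuous weights make the extremum unique, so the value flips
            # sign exactly
            assert abs(stat_ks(neg, gs).value) == pytest.approx(
                abs(stat_ks(prof, gs).value)
            )
            a = stat_ks(prof, gs, weighted=True).value
            b = stat_ks(neg, gs, weighted=True).value
            assert b == pytest.approx(-a)

    def test_magnitude_orderings(self):
        """Meansqr <= Meanabs <= Maxmean <= max|r| and |Mean| <= Maxmean.

        With per-side denominators Maxmean is the larger of the two one-sided
        means, so it dominates Meanabs (their weighted average); the
        total-size-denominator variant would sit below Meanabs instead."""
        rng = np.random.default_rng(4)
        for _ in range(60):
            prof, gs = _random_instance(rng)
            v = evaluate_statistics(prof, gs)
            member_r = np.abs([prof.r[list(prof.gene_ids).index(g)] for g in gs.members])
            assert v["meansqr"].value <= v["meanabs"].value + 1e-12
            assert v["meanabs"].value <= v["maxmean"].value + 1e-12
            assert v["maxmean"].value <= member_r.max() + 1e-12
            assert abs(v["mean"].value) <= v["maxmean"].value + 1e-12

    def test_member_order_invariance(self):
        rng = np.random.default_rng(5)
        prof, gs = _random_instance(rng, n_genes=20, k=8)
        shuffled = GeneSet("s2", list(gs.members)[::-1])
        a = evaluate_statistics(prof, gs)
        b = evaluate_statistics(prof, shuffled)
        for name in STATISTICS:
            assert a[name].value == b[name].value

    def test_unweighted_ks_symmetric_on_balanced_shuffles(self):
        """On random rankings of a balanced set the KS value distribution is
        symmetric about 0 (mean below Monte-Carlo error)."""
        rng = np.random.default_rng(6)
        n, k = 30, 15
        vals = []
        for _ in range(2000):
            r = rng.uniform(-1, 1, n)
            prof = _profile(r)
            members = rng.choice(n, k, replace=False)
            gs = GeneSet("s", [prof.gene_ids[i] for i in members])
            vals.append(stat_ks(prof, gs).value)
        vals = np.array(vals)
        assert abs(vals.mean()) < 3 * vals.std() / np.sqrt(len(vals))

    def test_sign_sensitive_flags(self):
        assert SIGN_SENSITIVE == {"mean", "median", "ks", "weighted_ks"}


class TestBatchedPaths:
    def test_batch_members_matches_scalar(self):
        rng = np.random.default_rng(8)
        n, k, b = 60, 12, 25
        r = rng.uniform(-1, 1, n)
        prof = _profile(r)
        idx = np.stack([rng.choice(n, k, replace=False) for _ in range(b)])
        batched = batch_members_stats(prof.r, prof.p, idx, STATISTICS)
        lit = batch_members_stats(prof.r, prof.p, idx, ["ks", "weighted_ks"],
                                  ks_variant="literal")
        for row in range(b):
            gs = GeneSet("s", [prof.gene_ids[i] for i in idx[row]])
            scal = evaluate_statistics(prof, gs)
            for name in STATISTICS:
                if name in ("ks", "weighted_ks"):
                    assert ks_values_equivalent(batched[name][row],
                                                scal[name].value), name
                else:
                    assert batched[name][row] == pytest.approx(scal[name].value), name
            for name, weighted in (("ks", False), ("weighted_ks", True)):
                ref = stat_ks(prof, gs, weighted=weighted, variant="literal")
                assert ks_values_equivalent(lit[name][row], ref.value), name

    def test_batch_profile_matches_scalar(self):
        rng = np.random.default_rng(9)
        n, k, b = 60, 12, 25
        rmat = rng.uniform(-1, 1, (n, b))
        member_idx = rng.choice(n, k, replace=False)
        batched = batch_profile_stats(rmat, member_idx, STATISTICS, n_parcels=34)
        ids = [f"G{i:03d}" for i in range(n)]
        gs = GeneSet("s", [ids[i] for i in member_idx])
        for col in range(b):
            prof = _profile(rmat[:, col], ids=ids)
            scal = evaluate_statistics(prof, gs)
            for name in STATISTICS:
                if name in ("ks", "weighted_ks"):
                    assert ks_values_equivalent(batched[name][col],
                                                scal[name].value), name
                else:
                    assert batched[name][col] == pytest.approx(scal[name].value), name
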