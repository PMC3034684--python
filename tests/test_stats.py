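import numpy as np
import pytest
from scipy import stats as sps

from heteropecilly.phylo import SubstCounts
from heteropecilly.profiles import (HydropathyScale, Profile, ProfileSet,
                                    hydrophobic_score)
from heteropecilly.stats import (bin_pip, biochem_change_fraction,
                                 clade_profile_distribution, contingency_chi2,
                                 fdp, heterotachy_test, phs_table, pip_n)
from conftest import make_aff, near_delta


def sharp(k, K):
    """A row with probability 0.97 on component k."""
    row = np.full(K, 0.03 / (K - 1))
    row[k] = 0.97
    return row


class TestFDP:
    def test_all_identical_zero(self):
        p = np.vstack([sharp(0, 2)] * 5)
        r = fdp(make_aff("A", p), make_aff("B", p))
        assert r.fdp == 0.0 and r.n_id == 5

    def test_hand_count(self):
        a = np.vstack([sharp(0, 2), sharp(0, 2), sharp(0, 2), sharp(1, 2)])
        b = np.vstack([sharp(1, 2), sharp(1, 2), sharp(1, 2), sharp(1, 2)])
        r = fdp(make_aff("A", a), make_aff("B", b))
        assert (r.n_dif, r.n_id, r.fdp) == (3, 1, 0.75)

    def test_no_jointly_stable_sites_undefined(self):
        a = np.vstack([sharp(0, 2)] * 3)
        b = np.full((3, 2), 0.5)
        r = fdp(make_aff("A", a), make_aff("B", b))
        assert r.n_considered == 0 and not r.defined and np.isnan(r.fdp)

    def test_symmetric_in_clades(self, rng):
        a = rng.dirichlet(np.ones(3), size=20)
        b = rng.dirichlet(np.ones(3), size=20)
        r1 = fdp(make_aff("A", a), make_aff("B", b))
        r2 = fdp(make_aff("B", b), make_aff("A", a))
        assert (r1.n_dif, r1.n_id) == (r2.n_dif, r2.n_id)

    def test_min_subs_filter(self):
        a = np.vstack([sharp(0, 2), sharp(0, 2)])
        b = np.vstack([sharp(1, 2), sharp(1, 2)])
        counts = SubstCounts(np.array([[3, 3], [1, 3]]), ["A", "B"])
        r = fdp(make_aff("A", a), make_aff("B", b), counts, min_subs=2)
        assert r.n_considered == 1   # site 2 fails the per-clade filter
        summed = fdp(make_aff("A", a), make_aff("B", b), counts,
                     min_subs=2, sum_counts=True)
        assert summed.n_considered == 2


class TestPIP:
    def test_same_delta_everywhere_is_one(self):
        p = np.tile([1.0, 0.0], (4, 1))
        r = pip_n([make_aff("A", p), make_aff("B", p)])
        assert np.allclose(r.pip, 1.0)

    def test_disjoint_deltas_zero_flagged(self):
        a = np.tile([1.0, 0.0], (2, 1))
        b = np.tile([0.0, 1.0], (2, 1))
        r = pip_n([make_aff("A", a), make_aff("B", b)])
        assert (r.pip == 0).all() and r.zero_flag.all()
        assert np.isinf(r.neg_log_pip).all()

    def test_hand_value(self):
        a = np.array([[0.6, 0.4]])
        b = np.array([[0.3, 0.7]])
        r = pip_n([make_aff("A", a), make_aff("B", b)])
        assert r.pip[0] == pytest.approx(0.46)

    def test_invariant_under_clade_reorder_and_relabel(self, rng):
        a = rng.dirichlet(np.ones(3), size=10)
        b = rng.dirichlet(np.ones(3), size=10)
        r1 = pip_n([make_aff("A", a), make_aff("B", b)])
        r2 = pip_n([make_aff("B", b), make_aff("A", a)])
        perm = [2, 0, 1]
        r3 = pip_n([make_aff("A", a[:, perm]), make_aff("B", b[:, perm])])
        assert np.allclose(r1.pip, r2.pip)
        assert np.allclose(r1.pip, r3.pip)


class TestBinPIP:
    def _pip(self, values):
        from heteropecilly.stats import PIPResult
        values = np.asarray(values, dtype=float)
        zero = values == 0
        with np.errstate(divide="ignore"):
            neg = np.where(zero, np.inf, -np.log(np.where(zero, 1.0, values)))
        return PIPResult(values, neg, zero)

    def test_eight_sites_equal_quartiles(self):
        pip = self._pip(np.exp(-np.arange(1.0, 9.0)))
        bins = bin_pip(pip)
        assert [list(bins).count(f"Q{i}") for i in (1, 2, 3, 4)] == [2, 2, 2, 2]

    def test_nine_sites_remainder_to_lowest(self):
        pip = self._pip(np.exp(-np.arange(1.0, 10.0)))
        bins = bin_pip(pip)
        assert [list(bins).count(f"Q{i}") for i in (1, 2, 3, 4)] == [3, 2, 2, 2]
        # lowest -ln values land in Q1
        assert bins[0] == "Q1" and bins[-1] == "Q4"

    def test_zero_class_separate(self):
        pip = self._pip([0.0, 0.5, 0.4, 0.3, 0.2, 0.0])
        bins = bin_pip(pip)
        assert bins[0] == "zero" and bins[5] == "zero"

    def test_too_few_nonzero_rejected(self):
        with pytest.raises(ValueError):
            bin_pip(self._pip([0.0, 0.0, 0.5, 0.4]))


class TestContingency:
    def test_perfect_association(self):
        rows = ["x"] * 10 + ["y"] * 10
        cols = ["u"] * 10 + ["v"] * 10
        table, chi2, dof, p = contingency_chi2(rows, cols)
        assert chi2 == pytest.approx(20.0)
        assert dof == 1
        assert p < 1e-4

    def test_degenerate_single_column_rejected(self):
        with pytest.raises(ValueError):
            contingency_chi2(["x", "y"], ["u", "u"])

    def test_pvalues_uniform_under_independence(self, rng):
        pvals = []
        for _ in range(120):
            rows = rng.choice(["a", "b"], size=400)
            cols = rng.choice(["u", "v"], size=400)
            _, _, _, p = contingency_chi2(rows, cols)
            pvals.append(p)
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestPHS:
    def _pset(self):
        return ProfileSet([Profile.delta("I", label="ile"),
                           Profile.delta("R", label="arg")])

    def test_identical_affiliations_zero_sd(self, rng):
        p = rng.dirichlet(np.ones(2), size=6)
        t = phs_table([make_aff("A", p), make_aff("B", p)], self._pset())
        assert np.allclose(t.sd, 0.0)

    def test_two_point_sd(self):
        a = np.array([[1.0, 0.0]])
        b = np.array([[0.0, 1.0]])
        t = phs_table([make_aff("A", a), make_aff("B", b)], self._pset())
        assert t.phs[0, 0] == pytest.approx(4.5)
        assert t.phs[1, 0] == pytest.approx(-4.5)
        assert t.sd[0] == pytest.approx(4.5)

    def test_uniform_rows_give_mean_hs(self):
        a = np.array([[0.5, 0.5]])
        t = phs_table([make_aff("A", a), make_aff("B", a)], self._pset())
        assert t.phs[0, 0] == pytest.approx(0.0)   # (4.5 - 4.5) / 2

    def test_sd_invariant_under_scale_translation(self, rng):
        p1 = rng.dirichlet(np.ones(2), size=8)
        p2 = rng.dirichlet(np.ones(2), size=8)
        affs = [make_aff("A", p1), make_aff("B", p2)]
        base = phs_table(affs, self._pset())
        shifted = HydropathyScale({k: v + 3.0 for k, v in
                                   HydropathyScale().h.items()})
        t2 = phs_table(affs, self._pset(), shifted)
        assert np.allclose(t2.phs, base.phs + 3.0)
        assert np.allclose(t2.sd, base.sd)


class TestBiochemChange:
    def _pset(self):
        def two_major(a, b, label):
            f = np.full(20, 0.1 / 18)
            from heteropecilly.alignment import AMINO_ACIDS
            f[AMINO_ACIDS.index(a)] = 0.6
            f[AMINO_ACIDS.index(b)] = 0.3
            return Profile(f / f.sum(), label=label)
        return ProfileSet([two_major("D", "E", "d"),    # charged
                           two_major("E", "D", "e"),    # charged
                           two_major("F", "Y", "f")])   # aromatic

    def test_same_profile_everywhere_zero(self):
        p = np.vstack([sharp(0, 3)] * 4)
        assert biochem_change_fraction(make_aff("A", p), make_aff("B", p),
                                       self._pset()) == 0.0

    def test_always_cross_group_one(self):
        a = np.vstack([sharp(0, 3)] * 4)   # charged
        b = np.vstack([sharp(2, 3)] * 4)   # aromatic
        assert biochem_change_fraction(make_aff("A", a), make_aff("B", b),
                                       self._pset()) == 1.0

    def test_hand_fraction(self):
        # 5 jointly stable sites: 2 change group (d->f), 3 keep it (d->e or d->d)
        a = np.vstack([sharp(0, 3)] * 5)
        b = np.vstack([sharp(2, 3), sharp(2, 3), sharp(1, 3),
                       sharp(1, 3), sharp(0, 3)])
        got = biochem_change_fraction(make_aff("A", a), make_aff("B", b),
                                      self._pset())
        assert got == pytest.approx(0.4)

    def test_no_eligible_flagged(self):
        u = np.full((3, 3), 1 / 3)
        assert np.isnan(biochem_change_fraction(make_aff("A", u),
                                                make_aff("B", u), self._pset()))


class TestCladeProfileDistribution:
    def test_identical_clades_no_excess(self):
        p = np.vstack([sharp(0, 2)] * 6 + [sharp(1, 2)] * 4)
        counts, excess, chi2, pval = clade_profile_distribution(
            [make_aff("A", p), make_aff("B", p)])
        assert (excess.values == 0).all()
        assert pval == pytest.approx(1.0)

    def test_wholesale_shift_bookkeeping(self):
        a = np.vstack([sharp(0, 2)] * 10)
        b = np.vstack([sharp(1, 2)] * 10)
        counts, excess, chi2, pval = clade_profile_distribution(
            [make_aff("A", a), make_aff("B", b)])
        assert excess.loc["A", "k0"] == 5 and excess.loc["B", "k0"] == -5
        assert chi2 == pytest.approx(20.0)
        assert pval < 1e-4


class TestHeterotachy:
    def test_proportional_counts_p_one(self):
        counts = SubstCounts(np.array([[2, 4], [1, 2], [3, 6]]), ["A", "B"])
        df = heterotachy_test(counts)
        assert np.allclose(df["chi2"], 0.0)
        assert np.allclose(df["p"], 1.0)

    def test_concentrated_site_hand_chi2(self):
        # clade totals equal (40 each); the last site puts all 20 subs in A
        counts = SubstCounts(np.array([[10, 10], [10, 10], [0, 20], [20, 0]]),
                             ["A", "B"])
        df = heterotachy_test(counts)
        assert df["chi2"].iloc[-1] == pytest.approx(20.0)
        assert df["p"].iloc[-1] < 1e-4

    def test_zero_substitution_site_flagged(self):
        counts = SubstCounts(np.array([[0, 0], [5, 5]]), ["A", "B"])
        df = heterotachy_test(counts)
        assert df["zero_flag"].iloc[0]
        assert df["p"].iloc[0] == 1.0

    def test_pvalues_uniform_under_homogeneous_poisson(self, rng):
        lam = np.array([8.0, 12.0, 10.0])
        obs = rng.poisson(np.tile(lam, (400, 1)))
        df = heterotachy_test(SubstCounts(obs, ["A", "B", "C"]))
        ks = sps.kstest(df.loc[df["total"] > 0, "p"], "uniform")
        # asymptotic chi2 on counts ~10: mild discreteness allowed
        assert ks.pvalue > 1e-4
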