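"""Welch t, SAM-like permutation, moderated t, and ComBat batch adjustment,
each checked against independent oracles (closed forms, exhaustive
enumeration, an independently coded EB routine, and the R reference
implementations where they exist)."""

import subprocess
from itertools import combinations

import numpy as np
import pytest
from scipy import stats, special

from tensordx.baselines import (TissueMatrix, combat_adjust,
                                empirical_fdr, moderated_t_select,
                                recall_at_fdr, sam_like_select,
                                tissue_matrix_from_tensor, ttest_select)
from tensordx.geo_io import normalize


def make_matrix(values, treatment, strain=None, tissue="toy"):
    values = np.asarray(values, dtype=float)
    treatment = np.asarray(treatment)
    if strain is None:
        strain = np.zeros(len(treatment), dtype=int)
    return TissueMatrix(values, [f"p{i}" for i in range(values.shape[0])],
                        treatment=treatment, strain=strain, tissue=tissue)


class TestWelchT:
    def test_hand_example_closed_form(self):
        m = make_matrix([[1, 2, 3, 6, 7, 8]], [0, 0, 0, 1, 1, 1])
        res = ttest_select(m)
        assert res.table["statistic"].iloc[0] == pytest.approx(-6.1237, abs=1e-4)
        assert res.table["p_raw"].iloc[0] == pytest.approx(0.00356, abs=5e-5)

    def test_matches_scipy_on_random_matrix(self, rng):
        x = rng.normal(size=(40, 12))
        labels = np.array([0] * 5 + [1] * 7)
        res = ttest_select(make_matrix(x, labels))
        t_ref, p_ref = stats.ttest_ind(x[:, labels == 0], x[:, labels == 1],
                                       axis=1, equal_var=False)
        np.testing.assert_allclose(res.table["statistic"], t_ref, atol=1e-10)
        np.testing.assert_allclose(res.table["p_raw"], p_ref, atol=1e-10)

    def test_equal_means_zero_noise_flagged_not_significant(self):
        m = make_matrix([[2.0] * 6, [1, 2, 3, 1, 2, 3]], [0, 0, 0, 1, 1, 1])
        res = ttest_select(m)
        assert res.flags["variance_floored"] == [0]
        assert res.table["statistic"].iloc[0] == 0.0
        assert res.table["p_raw"].iloc[0] == pytest.approx(1.0)

    def test_planted_recall_per_tissue(self, planted_normalized):
        tensor, truth = planted_normalized
        m = tissue_matrix_from_tensor(tensor, "adipose")
        res = ttest_select(m, threshold=0.05)
        sel = res.table["selected"].to_numpy()
        assert (sel & truth.deg_flags).sum() / truth.n_deg >= 0.8

    def test_too_small_group_rejected(self):
        m = make_matrix(np.ones((3, 3)), [0, 1, 1])
        with pytest.raises(ValueError, match=">= 2 samples"):
            ttest_select(m)


def sam_oracle(values, na, s0):
    """Exhaustive-enumeration oracle for the pooled SAM permutation p,
    coded with explicit loops independent of the implementation."""
    n = values.shape[1]
    all_d = []
    for combo in combinations(range(n), na):
        in_a = set(combo)
        d_split = []
        for g in range(values.shape[0]):
            a = [values[g, j] for j in range(n) if j in in_a]
            b = [values[g, j] for j in range(n) if j not in in_a]
            ma, mb = sum(a) / len(a), sum(b) / len(b)
            va = sum((v - ma) ** 2 for v in a) / (len(a) - 1)
            vb = sum((v - mb) ** 2 for v in b) / (len(b) - 1)
            sp2 = ((len(a) - 1) * va + (len(b) - 1) * vb) / (n - 2)
            s = (sp2 * (1 / len(a) + 1 / len(b))) ** 0.5
            d_split.append((ma - mb) / (s + s0))
        all_d.append(d_split)
    return all_d


class TestSamLike:
    def test_regularizer_keeps_statistic_finite(self):
        x = np.vstack([[1.0, 1.0, 1.0, 2.0, 2.0, 2.0],
                       np.random.default_rng(0).normal(size=6)])
        res = sam_like_select(make_matrix(x, [0, 0, 0, 1, 1, 1]),
                              n_permutations=50)
        assert np.all(np.isfinite(res.table["statistic"]))
        assert res.flags["s0"] > 0

    def test_exact_enumeration_matches_brute_force_oracle(self, rng):
        x = rng.normal(size=(12, 8))
        x[:3, 4:] += 2.0
        m = make_matrix(x, [0, 0, 0, 0, 1, 1, 1, 1])
        res = sam_like_select(m, n_permutations=100)    # 70 splits -> exact
        assert res.flags["exact_enumeration"]
        all_d = sam_oracle(x, 4, res.flags["s0"])
        pooled = [abs(d) for split in all_d for d in split]
        d_obs = res.table["statistic"].to_numpy()
        p_oracle = [sum(v >= abs(d) for v in pooled) / len(pooled)
                    for d in d_obs]
        np.testing.assert_allclose(res.table["p_raw"], p_oracle, atol=1e-12)

    def test_null_false_positive_control(self, null_dataset):
        tensor, _ = null_dataset
        m = tissue_matrix_from_tensor(normalize(tensor), "muscle")
        res = sam_like_select(m, threshold=0.01, n_permutations=60, seed=3)
        assert res.n_selected / len(m.probe_ids) <= 0.02

    def test_planted_recall(self, planted_normalized):
        tensor, truth = planted_normalized
        m = tissue_matrix_from_tensor(tensor, "liver")
        res = sam_like_select(m, threshold=0.05, n_permutations=100, seed=1)
        sel = res.table["selected"].to_numpy()
        assert (sel & truth.deg_flags).sum() / truth.n_deg >= 0.8

    def test_too_few_permutations_requested_rejected(self):
        m = make_matrix(np.random.default_rng(1).normal(size=(5, 8)),
                        [0] * 4 + [1] * 4)
        with pytest.raises(ValueError, match="enumeration"):
            sam_like_select(m, n_permutations=10)


def eb_oracle(x, labels):
    """Independently coded two-step empirical-Bayes moderated t:
    explicit per-probe loops, own trigamma-inverse bisection."""
    a = x[:, labels == 0]
    b = x[:, labels == 1]
    na, nb = a.shape[1], b.shape[1]
    df = na + nb - 2
    s2, diff = [], []
    for g in range(x.shape[0]):
        va = np.var(a[g], ddof=1)
        vb = np.var(b[g], ddof=1)
        s2.append(((na - 1) * va + (nb - 1) * vb) / df)
        diff.append(a[g].mean() - b[g].mean())
    s2 = np.array(s2)
    e = np.log(s2) - special.digamma(df / 2) + np.log(df / 2)
    evar = np.var(e, ddof=1) - special.polygamma(1, df / 2)
    lo, hi = 1e-6, 1e8
    for _ in range(200):                       # bisection on trigamma
        mid = np.sqrt(lo * hi)
        if special.polygamma(1, mid) > evar:
            lo = mid
        else:
            hi = mid
    d0 = 2 * lo
    s02 = np.exp(np.mean(e) + special.digamma(d0 / 2) - np.log(d0 / 2))
    s2_post = (d0 * s02 + df * s2) / (d0 + df)
    t = np.array(diff) / np.sqrt(s2_post * (1 / na + 1 / nb))
    p = 2 * stats.t.sf(np.abs(t), df + d0)
    return t, p


class TestModeratedT:
    def heterogeneous_matrix(self, seed=5, n=80):
        rng = np.random.default_rng(seed)
        sd = np.sqrt(2.0 / rng.chisquare(4, n))
        x = rng.normal(size=(n, 12)) * sd[:, None]
        x[:10, 6:] += 1.5
        labels = np.array([0] * 6 + [1] * 6)
        return x, labels

    def test_matches_independent_eb_oracle(self):
        x, labels = self.heterogeneous_matrix()
        res = moderated_t_select(make_matrix(x, labels))
        t_ref, p_ref = eb_oracle(x, labels)
        np.testing.assert_allclose(res.table["statistic"], t_ref, atol=1e-8)
        np.testing.assert_allclose(res.table["p_raw"], p_ref, atol=1e-8)

    def test_homogeneous_variances_collapse_to_pooled_prior(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(300, 40))
        res = moderated_t_select(make_matrix(x, [0] * 20 + [1] * 20))
        assert np.isinf(res.flags["prior_df"])
        # every probe shares the pooled variance: t proportional to mean diff
        diff = x[:, :20].mean(axis=1) - x[:, 20:].mean(axis=1)
        r = np.corrcoef(res.table["statistic"], diff)[0, 1]
        assert r > 0.999999

    def test_wild_variance_spread_approaches_ordinary_t(self):
        """The weaker the fitted prior, the closer moderated t is to the
        ordinary pooled t (exactly equal in the prior-weight-zero limit)."""
        rng = np.random.default_rng(13)
        labels = np.array([0] * 8 + [1] * 8)
        deviations, prior_dfs = [], []
        for spread in (1.0, 3.0, 6.0):
            sd = np.exp(rng.normal(0, spread, size=500))
            x = rng.normal(size=(500, 16)) * sd[:, None]
            res = moderated_t_select(make_matrix(x, labels))
            t_plain, _ = stats.ttest_ind(x[:, :8], x[:, 8:], axis=1)
            rel = np.abs(res.table["statistic"].to_numpy() / t_plain - 1.0)
            deviations.append(np.median(rel))
            prior_dfs.append(res.flags["prior_df"])
        assert prior_dfs[0] > prior_dfs[1] > prior_dfs[2]
        assert deviations[0] > deviations[1] > deviations[2]
        assert deviations[2] < 0.1

    def test_matches_limma_reference(self, tmp_path):
        x, labels = self.heterogeneous_matrix()
        res = moderated_t_select(make_matrix(x, labels))
        np.savetxt(tmp_path / "x.tsv", x, delimiter="\t")
        np.savetxt(tmp_path / "py.tsv",
                   np.c_[res.table["statistic"], res.table["p_raw"]],
                   delimiter="\t")
        script = f"""
        suppressMessages(library(limma))
        x <- as.matrix(read.table('{tmp_path}/x.tsv'))
        fit <- eBayes(lmFit(x, cbind(1, c(rep(0,6), rep(1,6)))))
        py <- as.matrix(read.table('{tmp_path}/py.tsv'))
        stopifnot(max(abs(abs(fit$t[,2]) - abs(py[,1]))) < 1e-6)
        stopifnot(max(abs(fit$p.value[,2] - py[,2])) < 1e-6)
        cat('OK')
        """
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True)
        assert out.returncode == 0, out.stderr
        assert "OK" in out.stdout

    def test_too_few_probes_rejected(self):
        m = make_matrix(np.ones((2, 6)), [0, 0, 0, 1, 1, 1])
        with pytest.raises(ValueError, match="3 probes"):
            moderated_t_select(m)


class TestComBat:
    def two_batches(self, seed=5, offset_scale=2.0, n=200, n1=20, n2=25):
        rng = np.random.default_rng(seed)
        base = rng.normal(0, 1, size=(n, n1 + n2))
        offsets = rng.normal(0, offset_scale, size=n)
        x = base.copy()
        x[:, n1:] += offsets[:, None]
        m1 = make_matrix(x[:, :n1], rng.integers(0, 2, n1), tissue="b1")
        m2 = make_matrix(x[:, n1:], rng.integers(0, 2, n2), tissue="b2")
        return m1, m2, offsets

    def test_pure_offset_removed_exactly_without_shrinkage(self):
        m1, m2, _ = self.two_batches()
        adj = combat_adjust([m1, m2], eb=False)
        mean1 = adj.values[:, adj.batch == 0].mean(axis=1)
        mean2 = adj.values[:, adj.batch == 1].mean(axis=1)
        np.testing.assert_allclose(mean1, mean2, atol=1e-8)

    def test_planted_offsets_recovered(self):
        m1, m2, offsets = self.two_batches(n=500)
        adj = combat_adjust([m1, m2])
        est = adj.gamma_star[:, 1] * np.sqrt(adj.var_pooled)
        r = np.corrcoef(est, offsets)[0, 1]
        assert r > 0.95

    def test_no_batch_effect_is_nearly_noop(self):
        rng = np.random.default_rng(21)
        x = rng.normal(size=(400, 60))
        m1 = make_matrix(x[:, :30], rng.integers(0, 2, 30), tissue="b1")
        m2 = make_matrix(x[:, 30:], rng.integers(0, 2, 30), tissue="b2")
        adj = combat_adjust([m1, m2])
        resid = adj.values - x
        assert np.sqrt((resid ** 2).mean()) < 0.35 * x.std()

    def test_single_sample_batch_rejected(self):
        m1 = make_matrix(np.random.default_rng(0).normal(size=(10, 4)),
                         [0, 0, 1, 1], tissue="b1")
        m2 = make_matrix(np.random.default_rng(1).normal(size=(10, 1)),
                         [0], tissue="b2")
        with pytest.raises(ValueError, match="<= 1 sample"):
            combat_adjust([m1, m2])

    def test_matches_sva_reference(self, tmp_path):
        m1, m2, _ = self.two_batches(n=100, n1=8, n2=10)
        adj = combat_adjust([m1, m2])
        x = np.c_[m1.values, m2.values]
        np.savetxt(tmp_path / "x.tsv", x, delimiter="\t")
        np.savetxt(tmp_path / "py.tsv", adj.values, delimiter="\t")
        script = f"""
        suppressMessages(library(sva))
        x <- as.matrix(read.table('{tmp_path}/x.tsv'))
        adj <- ComBat(dat=x, batch=c(rep(1,8), rep(2,10)), par.prior=TRUE)
        py <- as.matrix(read.table('{tmp_path}/py.tsv'))
        stopifnot(max(abs(adj - py)) < 1e-6)
        cat('OK')
        """
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True)
        assert out.returncode == 0, out.stderr
        assert "OK" in out.stdout


class TestRecallAtFdr:
    def test_perfect_ranking(self):
        p = np.array([0.001, 0.002, 0.5, 0.6])
        truth = np.array([True, True, False, False])
        assert recall_at_fdr(p, truth, 0.0) == 1.0

    def test_stops_at_first_false_positive_when_fdr_zero(self):
        p = np.array([0.001, 0.002, 0.003, 0.6])
        truth = np.array([True, False, True, False])
        assert recall_at_fdr(p, truth, 0.0) == 0.5

    def test_empirical_fdr(self):
        sel = np.array([True, True, False])
        truth = np.array([True, False, False])
        assert empirical_fdr(sel, truth) == 0.5
        assert empirical_fdr(np.zeros(3, bool), truth) == 0.0
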