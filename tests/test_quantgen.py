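"""Marker QC, kinship, LD decay, PCA, GBLUP, correlations, GWAS, groups."""

import numpy as np
import pandas as pd
import pytest

from stemtherm.quantgen import (_pava_decreasing, bonferroni_threshold,
                                filter_markers, gblup_cv, genetic_correlation,
                                group_summary, gwas_mlm, ibs_kinship,
                                ld_decay_threshold, marker_pca,
                                phenotypic_correlations, raw_ibs)
from stemtherm.simdata import MarkerPanel, gen_genetic_values, gen_marker_panel


def _panel_from(g, chrom=None, pos=None):
    m = g.shape[1]
    mp = pd.DataFrame({"chrom": chrom or ["chr1"] * m,
                       "pos": pos if pos is not None else np.arange(1, m + 1)})
    mp["marker"] = [f"m{j}" for j in range(m)]
    return MarkerPanel([f"g{i}" for i in range(g.shape[0])], g.astype(float), mp)


class TestFilterMarkers:
    def test_hand_constructed_counts(self):
        # 10 markers: 2 with 50% missing, 1 rare (MAF ~0.025), 1 monomorphic
        rng = np.random.default_rng(0)
        n = 20
        g = rng.integers(0, 3, size=(n, 10)).astype(float)
        g[: n // 2, 0] = np.nan
        g[: n // 2, 1] = np.nan
        g[:, 2] = 0.0
        g[1:, 2] = 0.0
        g[:, 3] = 0.0
        g[0, 3] = 1.0          # one heterozygote: MAF = 1/40 < 0.05
        panel = _panel_from(g)
        out, rep = filter_markers(panel, max_missing=0.05, min_maf=0.05)
        assert rep.n_high_missing == 2
        assert rep.n_monomorphic == 1
        assert rep.n_low_maf == 1
        assert rep.n_kept == 6
        assert out.n_markers == 6

    def test_clean_panel_idempotent(self):
        panel = gen_marker_panel(50, 2, 30, (0.2, 0.5), seed=1)
        once, rep1 = filter_markers(panel)
        twice, rep2 = filter_markers(once)
        assert np.array_equal(once.genotypes, twice.genotypes)
        assert rep2.n_kept == rep1.n_kept

    def test_all_removed_errors(self):
        g = np.zeros((10, 3))
        with pytest.raises(ValueError, match="all markers removed"):
            filter_markers(_panel_from(g))


class TestIbsKinship:
    def test_identical_and_opposite(self):
        g = np.array([[0, 2, 1, 0], [0, 2, 1, 0], [2, 0, 1, 2]])
        sim = raw_ibs(_panel_from(g))
        assert sim[0, 1] == pytest.approx(1.0)
        assert sim[0, 2] == pytest.approx((0 + 0 + 2 + 0) / (2 * 4.0))

    def test_fully_opposite_zero(self):
        g = np.array([[0, 0, 0], [2, 2, 2]])
        sim = raw_ibs(_panel_from(g))
        assert sim[0, 1] == 0.0

    def test_matches_brute_force(self, tiny_panel):
        sim = raw_ibs(tiny_panel)
        g = tiny_panel.genotypes
        for i in range(g.shape[0]):
            for j in range(g.shape[0]):
                expect = np.mean((2 - np.abs(g[i] - g[j])) / 2)
                assert sim[i, j] == pytest.approx(expect, abs=1e-12)

    def test_permutation_consistency(self, small_panel):
        kin = ibs_kinship(small_panel)
        perm = np.random.default_rng(0).permutation(small_panel.n_geno)
        shuffled = MarkerPanel(
            [small_panel.genotype_ids[i] for i in perm],
            small_panel.genotypes[perm], small_panel.map)
        kin_p = ibs_kinship(shuffled)
        assert np.allclose(kin_p.matrix, kin.matrix[np.ix_(perm, perm)],
                           atol=1e-12)

    def test_normalization_and_psd(self, small_panel):
        kin = ibs_kinship(small_panel)
        assert kin.matrix.min() >= 0.0 and kin.matrix.max() <= 1.0 + 1e-12
        w = np.linalg.eigvalsh(kin.matrix)
        assert w.min() >= -1e-8
        assert np.allclose(kin.matrix, kin.matrix.T)
        # diagonal dominates every row
        assert np.all(np.diag(kin.matrix) >= kin.matrix.max(axis=1) - 1e-9)


class TestLdDecay:
    def test_constructed_exponential_decay(self):
        # alleles from a latent AR(1) copula at p = 0.5: dosage correlation
        # r = (2/pi) asin(exp(-d/d0)); r^2 crosses 0.2 at
        # d* = d0 * ln(1/sin(sqrt(0.2) pi/2)) ~= 0.437 d0
        d0 = 2e6
        rng = np.random.default_rng(5)
        n_hap, m = 400, 120
        pos = np.sort(rng.choice(int(5e7), m, replace=False)) + 1
        rho = np.exp(-np.diff(pos) / d0)
        z = np.empty((n_hap, m))
        z[:, 0] = rng.standard_normal(n_hap)
        for k in range(1, m):
            z[:, k] = rho[k - 1] * z[:, k - 1] + np.sqrt(
                1 - rho[k - 1] ** 2) * rng.standard_normal(n_hap)
        alleles = (z < 0).astype(float)
        g = alleles[0::2] + alleles[1::2]
        panel = _panel_from(g, pos=pos)
        res = ld_decay_threshold(panel, cutoff=0.2, seed=0)
        expected = d0 * np.log(1.0 / np.sin(np.sqrt(0.2) * np.pi / 2))
        got = res.per_chrom["threshold_bp"].iloc[0]
        assert got == pytest.approx(expected, rel=0.30)

    def test_independent_markers_minimal_threshold(self):
        rng = np.random.default_rng(1)
        g = rng.binomial(2, 0.4, size=(200, 80)).astype(float)
        pos = np.sort(rng.choice(int(1e8), 80, replace=False)) + 1
        res = ld_decay_threshold(_panel_from(g, pos=pos), cutoff=0.2, seed=0)
        thr = res.per_chrom["threshold_bp"].iloc[0]
        assert thr <= np.diff(np.sort(pos)).max() * 3

    def test_duplicated_adjacent_markers_have_r2_one(self):
        rng = np.random.default_rng(2)
        base = rng.binomial(2, 0.5, size=(100, 40)).astype(float)
        g = np.repeat(base, 2, axis=1)
        pos = np.sort(rng.choice(int(1e8), 80, replace=False)) + 1
        panel = _panel_from(g, pos=pos)
        gg = panel.imputed()
        c = np.corrcoef(gg[:, 0], gg[:, 1])[0, 1]
        assert c ** 2 == pytest.approx(1.0)

    def test_pava_is_non_increasing_projection(self):
        rng = np.random.default_rng(3)
        y = rng.standard_normal(50)
        f = _pava_decreasing(y)
        assert np.all(np.diff(f) <= 1e-12)
        assert f.mean() == pytest.approx(y.mean())


class TestMarkerPca:
    def test_orthogonality_and_variance_fractions(self, small_panel):
        scores, ve = marker_pca(small_panel, n_pc=3)
        for i in range(3):
            for j in range(i + 1, 3):
                assert abs(scores[:, i] @ scores[:, j]) < 1e-8
        assert np.all(np.diff(ve) <= 1e-12)
        assert ve.sum() <= 1.0 + 1e-12

    def test_pc1_separates_divergent_subpopulations(self):
        panel = gen_marker_panel(100, 3, 100, (0.1, 0.5), n_subpop=2,
                                 fst=0.3, seed=3)
        scores, _ = marker_pca(panel, 3)
        sp = panel.subpop
        mid = (scores[sp == 0, 0].mean() + scores[sp == 1, 0].mean()) / 2
        acc = max(np.mean((scores[:, 0] > mid) == (sp == 1)),
                  np.mean((scores[:, 0] < mid) == (sp == 1)))
        assert acc == 1.0

    def test_too_many_pcs_rejected(self, tiny_panel):
        with pytest.raises(ValueError):
            marker_pca(tiny_panel, n_pc=6)


@pytest.fixture(scope="module")
def structured():
    panel = gen_marker_panel(150, 5, 80, (0.05, 0.5), n_subpop=3,
                             fst=0.1, founders_per_subpop=5, seed=6)
    return panel, ibs_kinship(panel)


class TestGblupCv:
    def test_same_seed_identical(self, structured):
        panel, kin = structured
        truth = gen_genetic_values(panel, ["t"], {"t": 0.8}, np.eye(1),
                                   {"t": 0}, {"t": 1}, n_qtl=30, seed=1)
        a = gblup_cv(truth.values["t"], kin, k=5, repeats=2, seed=9)
        b = gblup_cv(truth.values["t"], kin, k=5, repeats=2, seed=9)
        assert np.array_equal(a.fold_rs, b.fold_rs)

    def test_accuracy_monotone_in_h2(self, structured):
        panel, kin = structured
        means = []
        for h2 in (0.0, 0.3, 0.6, 0.9):
            rs = []
            for s in range(4):
                truth = gen_genetic_values(panel, ["t"], {"t": h2}, np.eye(1),
                                           {"t": 0}, {"t": 1}, n_qtl=30,
                                           seed=100 + s)
                cv = gblup_cv(truth.values["t"], kin, k=5, repeats=1,
                              seed=s)
                rs.append(cv.mean_r)
            means.append(np.mean(rs))
        assert all(np.diff(means) > 0), means

    def test_too_small_folds_rejected(self, structured):
        panel, kin = structured
        y = pd.Series(np.arange(150, dtype=float), index=kin.genotype_ids)
        with pytest.raises(ValueError, match="fewer than 3"):
            gblup_cv(y, kin, k=60, repeats=1, seed=0)


class TestGeneticCorrelation:
    def _stage2_frame(self, kin, rho, seed, n_years=3, h2=0.8):
        n = len(kin.genotype_ids)
        rng = np.random.default_rng(seed)
        chol = np.linalg.cholesky(kin.matrix + 1e-8 * np.eye(n))
        S = np.array([[1.0, rho], [rho, 1.0]])
        g = chol @ rng.standard_normal((n, 2)) @ np.linalg.cholesky(
            S + 1e-10 * np.eye(2)).T
        sig = np.sqrt((1 / h2 - 1) * g.var(axis=0).mean())
        rows = []
        for j in range(n_years):
            noise = rng.standard_normal((n, 2)) * sig
            for i, gid in enumerate(kin.genotype_ids):
                rows.append((gid, 2015 + j, "a", g[i, 0] + noise[i, 0]))
                rows.append((gid, 2015 + j, "b", g[i, 1] + noise[i, 1]))
        return pd.DataFrame(rows, columns=["genotype", "year", "trait", "blue"])

    def test_trait_with_itself_near_one(self, small_panel):
        kin = ibs_kinship(small_panel)
        df = self._stage2_frame(kin, 0.0, seed=1)
        dup = df[df["trait"] == "a"].copy()
        rng = np.random.default_rng(2)
        dup["trait"] = "b"
        dup["blue"] = dup["blue"] + rng.standard_normal(len(dup)) * 1e-3
        both = pd.concat([df[df["trait"] == "a"], dup])
        gc = genetic_correlation(both, "a", "b", kin)
        assert gc.correlation >= 0.99

    def test_rescaling_invariance(self, small_panel):
        kin = ibs_kinship(small_panel)
        df = self._stage2_frame(kin, 0.5, seed=3)
        gc1 = genetic_correlation(df, "a", "b", kin)
        df2 = df.copy()
        df2.loc[df2["trait"] == "b", "blue"] *= 37.0
        gc2 = genetic_correlation(df2, "a", "b", kin)
        assert gc1.correlation == pytest.approx(gc2.correlation, abs=0.02)

    def test_null_and_strong_recovery(self, small_panel):
        kin = ibs_kinship(small_panel)
        nulls, strongs = [], []
        for s in range(4):
            gc0 = genetic_correlation(self._stage2_frame(kin, 0.0, seed=10 + s),
                                      "a", "b", kin)
            gc8 = genetic_correlation(self._stage2_frame(kin, 0.8, seed=20 + s),
                                      "a", "b", kin)
            nulls.append(gc0.correlation)
            strongs.append(gc8.correlation)
        assert abs(np.median(nulls)) <= 0.2
        assert abs(np.median(strongs) - 0.8) <= 0.2


class TestPhenotypicCorrelations:
    def test_duplicated_trait_r_one(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"year": np.repeat([2015, 2016], 50),
                           "a": rng.standard_normal(100)})
        df["b"] = df["a"]
        out = phenotypic_correlations(df, "a", "b")
        years = out[out["year"] != "summary"]
        assert np.allclose(years["r"], 1.0)

    def test_independent_traits_near_zero(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"year": np.repeat([1, 2, 3, 4], 250),
                           "a": rng.standard_normal(1000),
                           "b": rng.standard_normal(1000)})
        out = phenotypic_correlations(df, "a", "b")
        mean_r = out[out["year"] == "summary"]["r"].iloc[0]
        assert abs(mean_r) <= 0.1

    def test_summary_ordering_and_small_years_skipped(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"year": [1] * 30 + [2] * 2,
                           "a": rng.standard_normal(32),
                           "b": rng.standard_normal(32)})
        out = phenotypic_correlations(df, "a", "b")
        summ = out[out["year"] == "summary"].iloc[0]
        assert summ["r_min"] <= summ["r"] <= summ["r_max"]
        skipped = out[out["year"] == "2"]
        assert "skipped" in skipped["flag"].iloc[0]


class TestGwas:
    def test_identity_kinship_no_pcs_equals_ols(self):
        panel = gen_marker_panel(120, 2, 50, (0.1, 0.5), seed=9)
        rng = np.random.default_rng(4)
        y = pd.Series(rng.standard_normal(120), index=panel.genotype_ids)
        from stemtherm.quantgen import Kinship
        ident = Kinship(panel.genotype_ids, np.eye(120), np.eye(120))
        res = gwas_mlm(y, panel, ident, n_pc=0)
        # per-marker OLS oracle
        M = panel.imputed()
        Mc = M - M.mean(axis=0)
        yv = y.to_numpy()
        for j in rng.choice(panel.n_markers, 12, replace=False):
            x = Mc[:, j]
            if x.std() < 1e-9:
                continue
            xc = x - x.mean()
            b = (xc @ yv) / (xc @ xc)
            resid = yv - yv.mean() - b * xc
            s2 = resid @ resid / (120 - 2)
            tstat = b / np.sqrt(s2 / (xc @ xc))
            from scipy import stats as ss
            p = 2 * ss.t.sf(abs(tstat), 118)
            assert abs(-np.log10(p) - res.table["neglog10p"].iloc[j]) < 1e-6

    def test_planted_qtl_found(self, small_panel):
        kin = ibs_kinship(small_panel)
        M = small_panel.imputed()
        Mc = M - M.mean(axis=0)
        rng = np.random.default_rng(6)
        q = 37
        x = Mc[:, q] / Mc[:, q].std()
        y = x * np.sqrt(0.4) + rng.standard_normal(small_panel.n_geno) * np.sqrt(0.6)
        res = gwas_mlm(pd.Series(y, index=small_panel.genotype_ids),
                       small_panel, kin, n_pc=3)
        assert res.table["p"].idxmin() == q

    def test_collinear_marker_flagged(self):
        g = np.tile(np.array([0.0, 1.0, 2.0]), (60, 1))[:, :3]
        rng = np.random.default_rng(1)
        g = rng.integers(0, 3, size=(60, 30)).astype(float)
        g[:, 5] = 1.0            # constant: collinear with the intercept
        panel = _panel_from(g)
        from stemtherm.quantgen import Kinship
        kin = Kinship(panel.genotype_ids, np.eye(60), np.eye(60))
        y = pd.Series(rng.standard_normal(60), index=panel.genotype_ids)
        res = gwas_mlm(y, panel, kin, n_pc=0)
        row = res.table.iloc[5]
        assert row["p"] == 1.0 and row["flag"]


class TestBonferroni:
    @pytest.mark.parametrize("m,expected,tol", [
        (9147, 5.26, 0.005),     # genome-wide threshold at the panel size
        (1, 1.3010, 1e-4),
        (100, 3.3010, 1e-4),
    ])
    def test_values(self, m, expected, tol):
        assert bonferroni_threshold(m, 0.05) == pytest.approx(expected, abs=tol)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0)
        with pytest.raises(ValueError):
            bonferroni_threshold(100, 1.5)


class TestGroupSummary:
    def test_extreme_separation_different_letters(self):
        rng = np.random.default_rng(0)
        vals = pd.Series(np.r_[rng.standard_normal(30),
                               rng.standard_normal(30) + 5.0])
        grp = pd.Series(["A"] * 30 + ["B"] * 30)
        gs = group_summary(vals, grp)
        letters = dict(zip(gs.table["group"], gs.table["letters"]))
        assert set(letters["A"]) & set(letters["B"]) == set()

    def test_equal_means_share_letter_usually(self):
        shared = 0
        n_runs = 40
        for s in range(n_runs):
            rng = np.random.default_rng(s)
            vals = pd.Series(rng.standard_normal(60))
            grp = pd.Series(["A"] * 30 + ["B"] * 30)
            gs = group_summary(vals, grp)
            letters = dict(zip(gs.table["group"], gs.table["letters"]))
            shared += bool(set(letters["A"]) & set(letters["B"]))
        assert shared >= int(0.9 * n_runs)

    def test_cld_consistent_with_pairwise_tests(self):
        rng = np.random.default_rng(3)
        vals, grp = [], []
        for gi, shift in enumerate([0.0, 0.3, 2.0, 4.0]):
            vals.extend(rng.standard_normal(25) + shift)
            grp.extend([f"G{gi}"] * 25)
        gs = group_summary(pd.Series(vals), pd.Series(grp))
        letters = dict(zip(gs.table["group"], gs.table["letters"]))
        from statsmodels.stats.multicomp import pairwise_tukeyhsd
        tuk = pairwise_tukeyhsd(np.array(vals), np.array(grp), alpha=0.05)
        res = pd.DataFrame(tuk.summary().data[1:], columns=tuk.summary().data[0])
        for rec in res.itertuples():
            share = bool(set(letters[str(rec.group1)])
                         & set(letters[str(rec.group2)]))
            if float(rec._4) < 0.05:
                assert not share
            else:
                assert share

    def test_small_groups_excluded_and_trajectories(self):
        rng = np.random.default_rng(4)
        vals = pd.Series(rng.standard_normal(65))
        grp = pd.Series(["A"] * 30 + ["B"] * 30 + ["C"] * 5)
        era = pd.Series((["e1"] * 15 + ["e2"] * 15) * 2 + ["e1"] * 5)
        gs = group_summary(vals, grp, era=era)
        assert gs.excluded == ["C"]
        assert set(gs.era_trajectories["group"]) == {"A", "B"}
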