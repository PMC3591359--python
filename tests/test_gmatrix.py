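import numpy as np
import pandas as pd
import pytest

from halfsibqg import (
    Pedigree,
    PhenotypeTable,
    jackknife_pseudovalues,
    log10_transform,
    manova_compare,
    moment_G,
    residualize,
    simulate_design,
    unvech,
    vech,
)
from halfsibqg.gmatrix import GMatrixError, vech_labels, _nested_components
from conftest import single_pop_config
from _oracles import hotelling_two_sample_F


def balanced_toy(seed=0, n_sires=5, n_dams=4, n_off=2, traits=2):
    """Balanced nested design with explicit sire/dam/within draws."""
    rng = np.random.default_rng(seed)
    rows = []
    entries = []
    for s in range(n_sires):
        sire = f"s{s}"
        entries.append((sire, None, None))
        s_eff = rng.normal(0, 1.0, traits)
        for d in range(n_dams):
            dam = f"s{s}d{d}"
            entries.append((dam, None, None))
            d_eff = rng.normal(0, 0.5, traits)
            for o in range(n_off):
                ind = f"s{s}d{d}o{o}"
                entries.append((ind, sire, dam))
                y = s_eff + d_eff + rng.normal(0, 1.0, traits)
                rows.append([ind, *y])
    ped = Pedigree.from_entries(entries)
    df = pd.DataFrame(rows, columns=["id", "ldt", "pdt"])
    for c in ("population", "line", "sex", "chamber", "hour"):
        df[c] = "x"
    df["ethanol"] = "0"
    for c in ("tdt", "mb", "rmr"):
        df[c] = np.nan
    return ped, PhenotypeTable(df=df, scale="log10")


class TestVech:
    def test_round_trip_identity(self):
        rng = np.random.default_rng(1)
        for t in (2, 3, 5):
            M = rng.normal(size=(t, t))
            M = M + M.T
            assert np.array_equal(unvech(vech(M)), M)

    def test_five_traits_give_fifteen_elements(self):
        assert len(vech(np.eye(5))) == 15
        assert len(vech_labels(("a", "b", "c", "d", "e"))) == 15

    def test_bad_length_rejected(self):
        with pytest.raises(GMatrixError):
            unvech(np.zeros(4))


class TestResidualize:
    def test_no_factors_removes_grand_mean(self, small_log):
        _, _, tl, _ = small_log
        out = residualize(tl, ())
        for t in ("ldt", "mb"):
            assert out.df[t].mean() == pytest.approx(0.0, abs=1e-12)
            expect = tl.df[t] - tl.df[t].mean()
            assert np.allclose(out.df[t], expect)

    def test_sex_residuals_sum_to_zero_within_sex(self, small_log):
        _, _, tl, _ = small_log
        out = residualize(tl, ("sex",))
        for _, grp in out.df.groupby("sex"):
            assert grp["ldt"].sum() == pytest.approx(0.0, abs=1e-9)

    def test_variance_never_increases(self, small_log):
        _, _, tl, _ = small_log
        out = residualize(tl, ("sex", "ethanol"))
        for t in ("ldt", "pdt", "mb", "rmr"):
            assert out.df[t].var() <= tl.df[t].var() + 1e-15

    def test_unknown_factor_rejected(self, small_log):
        _, _, tl, _ = small_log
        with pytest.raises(GMatrixError, match="bogus"):
            residualize(tl, ("bogus",))


class TestMomentG:
    def test_balanced_toy_matches_explicit_mean_squares(self):
        ped, tab = balanced_toy()
        Y = tab.df[["ldt", "pdt"]].to_numpy()
        sire = np.array([i.split("d")[0] for i in tab.df["id"]], dtype=object)
        dam = np.array([i.rsplit("o", 1)[0] for i in tab.df["id"]], dtype=object)

        # balanced nested EMS oracle: E[MS_s] = w + 2 d + 8 s, E[MS_d] = w + 2 d
        k_off, k_dam = 2, 4
        df_tab = pd.DataFrame({"s": sire, "d": dam})
        grand = Y.mean(axis=0)
        sm = np.stack([Y[df_tab.s == v].mean(axis=0) for v in sorted(set(sire))])
        dm = np.stack([Y[df_tab.d == v].mean(axis=0) for v in sorted(set(dam))])
        ns = k_off * k_dam
        MS_s = ns * (sm - grand).T @ (sm - grand) / (len(sm) - 1)
        dam_sire_means = np.stack(
            [sm[sorted(set(sire)).index(v.split("d")[0])] for v in sorted(set(dam))]
        )
        MS_d = k_off * (dm - dam_sire_means).T @ (dm - dam_sire_means) / (
            len(dm) - len(sm)
        )
        within = np.zeros((2, 2))
        for v in sorted(set(dam)):
            sub = Y[df_tab.d == v]
            within += (sub - sub.mean(axis=0)).T @ (sub - sub.mean(axis=0))
        MS_w = within / (len(Y) - len(dm))
        sigma_d = (MS_d - MS_w) / k_off
        sigma_s = (MS_s - MS_w - k_off * sigma_d) / ns

        Ss, Sd, Sw = _nested_components(Y, sire, dam)
        assert np.allclose(Ss, sigma_s, atol=1e-10)
        assert np.allclose(Sd, sigma_d, atol=1e-10)
        assert np.allclose(Sw, MS_w, atol=1e-10)

        g = moment_G(tab, ped, traits=("ldt", "pdt"))
        assert np.allclose(g.values, 4 * sigma_s, atol=1e-10)

    def test_sum_variance_identity_for_covariances(self):
        # sire covariance equals [comp(x+y) - comp(x) - comp(y)] / 2
        ped, tab = balanced_toy(seed=3)
        Y = tab.df[["ldt", "pdt"]].to_numpy()
        sire = np.array([i.split("d")[0] for i in tab.df["id"]], dtype=object)
        dam = np.array([i.rsplit("o", 1)[0] for i in tab.df["id"]], dtype=object)
        Ss, _, _ = _nested_components(Y, sire, dam)
        s_sum, _, _ = _nested_components(Y.sum(axis=1, keepdims=True), sire, dam)
        implied = 0.5 * (s_sum[0, 0] - Ss[0, 0] - Ss[1, 1])
        assert implied == pytest.approx(Ss[0, 1], rel=1e-10)

    def test_null_G_estimates_center_on_zero(self):
        ests = []
        for rep in range(100):
            cfg = single_pop_config(seed=500 + rep, n_sires=8,
                                    h2=[0.0] * 5, c_frac=0.1, envs=("0",))
            ped, tab, _ = simulate_design(cfg)
            tl = log10_transform(tab)
            g = moment_G(tl, ped, traits=("ldt",))
            ests.append(g.values[0, 0])
        ests = np.asarray(ests)
        se = ests.std(ddof=1) / np.sqrt(len(ests))
        assert abs(ests.mean()) < 3 * se

    def test_small_family_dropped_with_warning(self):
        ped, tab = balanced_toy()
        df = tab.df.copy()
        # orphan sire family with a single offspring
        extra = df.iloc[[0]].assign(id="s9d0o0")
        ped2 = Pedigree.from_entries(ped.entries + [("s9", None, None),
                                                    ("s9d0", None, None),
                                                    ("s9d0o0", "s9", "s9d0")])
        tab2 = PhenotypeTable(df=pd.concat([df, extra], ignore_index=True),
                              scale="log10")
        with pytest.warns(UserWarning, match="dropping"):
            g = moment_G(tab2, ped2, traits=("ldt", "pdt"))
        assert g.n_families == 5

    def test_too_few_families_rejected(self):
        ped, tab = balanced_toy(n_sires=2)
        with pytest.raises(GMatrixError):
            moment_G(tab, ped, traits=("ldt", "pdt"))


class TestJackknife:
    def test_duplicated_families_give_constant_pseudovalues(self):
        # four identical copies of one family => every G_{-i} = G_obs
        ped0, tab0 = balanced_toy(n_sires=1, n_dams=3, n_off=3)
        frames, entries = [], []
        for k in range(4):
            df = tab0.df.copy()
            df["id"] = df["id"].str.replace("s0", f"s{k}", regex=False)
            frames.append(df)
            for i, s, d in ped0.entries:
                entries.append((i.replace("s0", f"s{k}"),
                                s and s.replace("s0", f"s{k}"),
                                d and d.replace("s0", f"s{k}")))
        ped = Pedigree.from_entries(entries)
        tab = PhenotypeTable(df=pd.concat(frames, ignore_index=True),
                             scale="log10")
        ps = jackknife_pseudovalues(tab, ped, traits=("ldt", "pdt"))
        g_obs = moment_G(tab, ped, traits=("ldt", "pdt")).vec()
        vals = ps.values[ps.element_columns].to_numpy()
        assert np.allclose(vals, g_obs[None, :], atol=1e-10)

    def test_three_family_arithmetic_oracle(self):
        ped, tab = balanced_toy(n_sires=3, seed=5)
        ps = jackknife_pseudovalues(tab, ped, traits=("ldt", "pdt"))
        g_obs = moment_G(tab, ped, traits=("ldt", "pdt")).vec()
        for fam in ("s0", "s1", "s2"):
            keep = ~tab.df["id"].str.startswith(fam)
            red = PhenotypeTable(df=tab.df[keep].reset_index(drop=True),
                                 scale="log10")
            g_red = moment_G(red, ped, traits=("ldt", "pdt"),
                             min_families=2).vec()
            expect = 3 * g_obs - 2 * g_red
            got = ps.values.loc[ps.values["family"] == fam,
                                ps.element_columns].to_numpy()[0]
            assert np.allclose(got, expect, atol=1e-10)

    def test_pseudovalue_mean_identity(self, small_log):
        _, ped, tl, _ = small_log
        ps = jackknife_pseudovalues(tl, ped, traits=("ldt", "mb"))
        for _, grp in ps.values.groupby("group"):
            n = len(grp)
            vals = grp[ps.element_columns].to_numpy()
            # mean p = n g - (n-1) mean(g_red) is an algebraic identity:
            # verify by reconstructing mean(g_red) from the pseudovalues
            sub = tl.df[tl.df["ethanol"] == grp["group"].iloc[0]]
            g_obs = moment_G(
                PhenotypeTable(df=sub.reset_index(drop=True), scale="log10"),
                ped, traits=("ldt", "mb")).vec()
            g_red_mean = (n * g_obs - vals.mean(axis=0)) / (n - 1)
            assert np.allclose(
                vals.mean(axis=0), n * g_obs - (n - 1) * g_red_mean, atol=1e-9
            )


class TestManova:
    def _pseudoset(self, a, b):
        from halfsibqg.gmatrix import PseudovalueSet
        cols = [f"e{k}" for k in range(a.shape[1])]
        rows = []
        for k, v in enumerate(a):
            rows.append(["0", f"f{k}", *v])
        for k, v in enumerate(b):
            rows.append(["7", f"g{k}", *v])
        return PseudovalueSet(
            values=pd.DataFrame(rows, columns=["group", "family", *cols]),
            traits=("x",),
        )

    def test_identical_group_means_give_lambda_one(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(8, 3))
        res = manova_compare(self._pseudoset(a, a.copy()))
        assert res.wilks_lambda == pytest.approx(1.0)
        assert res.F == pytest.approx(0.0, abs=1e-10)

    def test_valdivia_shaped_df(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(16, 15))
        b = rng.normal(size=(16, 15))
        res = manova_compare(self._pseudoset(a, b))
        assert (res.df_num, res.df_den) == (15, 16)

    def test_matches_hotelling_T2_oracle(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=(10, 2))
        b = rng.normal(0.5, 1.0, size=(10, 2))
        res = manova_compare(self._pseudoset(a, b))
        _, F_oracle = hotelling_two_sample_F(a, b)
        assert res.F == pytest.approx(F_oracle, rel=1e-10)
        assert res.df_num == 2 and res.df_den == 17

    def test_lambda_invariant_to_common_affine_transform(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=(9, 4))
        b = rng.normal(0.3, 1.0, size=(9, 4))
        M = rng.normal(size=(4, 4)) + 4 * np.eye(4)
        shift = rng.normal(size=4)
        res1 = manova_compare(self._pseudoset(a, b))
        res2 = manova_compare(self._pseudoset(a @ M + shift, b @ M + shift))
        assert res1.wilks_lambda == pytest.approx(res2.wilks_lambda, rel=1e-8)

    def test_trait_order_invariance_of_lambda(self, small_log):
        _, ped, tl, _ = small_log
        r1 = manova_compare(jackknife_pseudovalues(
            residualize(tl, ("sex",)), ped, traits=("ldt", "pdt", "mb")))
        r2 = manova_compare(jackknife_pseudovalues(
            residualize(tl, ("sex",)), ped, traits=("mb", "ldt", "pdt")))
        assert r1.wilks_lambda == pytest.approx(r2.wilks_lambda, rel=1e-8)

    def test_univariate_follow_ups_shape(self, small_log):
        _, ped, tl, _ = small_log
        ps = jackknife_pseudovalues(residualize(tl, ("sex",)), ped,
                                    traits=("ldt", "pdt"))
        res = manova_compare(ps)
        N = len(ps.values)
        assert len(res.univariate) == 3
        assert (res.univariate["df_den"] == N - 2).all()
        assert 0 < res.wilks_lambda <= 1

    def test_too_few_vectors_rejected(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=(3, 6))
        b = rng.normal(size=(3, 6))
        with pytest.raises(GMatrixError, match="N > p"):
            manova_compare(self._pseudoset(a, b))
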