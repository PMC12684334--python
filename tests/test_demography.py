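"""Joint-SFS machinery: model space, folding, spectra vs oracles."""

import numpy as np
import pytest

from clonescape import syndata
from clonescape.demography import (
    DemographicModel,
    FitResult,
    JointSFS,
    JointSFSModel,
    build_jsfs,
    compare_models,
    expected_branch_sfs,
    expected_jsfs,
    fold_jsfs,
    get_model,
    model_registry,
    to_biological,
    to_scaled,
)
from clonescape.genio import SNPMatrix


class TestModelRegistry:
    def test_exactly_22_scenarios(self):
        assert len(model_registry()) == 22

    def test_family_sizes(self):
        names = [m.name for m in model_registry()]
        assert sum(n.startswith("SI") for n in names) == 4
        for base in ("IM", "AM", "SC"):
            assert sum(n.startswith(base) for n in names) == 6

    def test_expected_variants_present(self):
        names = {m.name for m in model_registry()}
        assert {"SI", "SIG", "SI2N", "SI2NG"} <= names
        assert {"IM", "IMG", "IM2N", "IM2m", "IM2NG", "IM2mG"} <= names

    def test_names_unique(self):
        names = [m.name for m in model_registry()]
        assert len(names) == len(set(names))

    def test_illegal_combinations_rejected(self):
        with pytest.raises(ValueError):
            DemographicModel(name="SI2m", base="SI", two_m=True)
        with pytest.raises(ValueError):
            DemographicModel(name="x", base="IM", two_m=True, two_n=True)


class TestBuildJsfs:
    def test_one_diploid_per_pop(self):
        m = SNPMatrix(
            np.array([[1], [0]]), ["a", "b"], ["p1", "p2"], ["L1"]
        )
        s = build_jsfs(m, {"p1"}, {"p2"})
        assert s.counts.shape == (3, 3)
        assert s.counts[1, 0] == 1

    def test_total_equals_retained_loci(self):
        params = dict(nu1=1, nu2=1, na=1, ts=0.5)
        m, s = syndata.sim_divergence("SI", params, 3, 3, 300, seed=2, theta=0.4)
        assert s.total() == m.n_loci

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(7)
        dos = rng.integers(0, 3, size=(20, 40))
        sites = ["p1"] * 12 + ["p2"] * 8
        m = SNPMatrix(dos, [f"i{k}" for k in range(20)], sites,
                      [f"L{j}" for j in range(40)])
        s = build_jsfs(m, {"p1"}, {"p2"})
        expect = np.zeros((25, 17))
        for j in range(40):
            expect[dos[:12, j].sum(), dos[12:, j].sum()] += 1
        assert np.array_equal(s.counts, expect)

    def test_overlapping_pops_rejected(self, tiny_matrix):
        with pytest.raises(ValueError):
            build_jsfs(tiny_matrix, {"s1"}, {"s1", "s2"})


class TestFolding:
    def test_total_preserved_and_idempotent(self):
        rng = np.random.default_rng(3)
        s = JointSFS(rng.integers(0, 50, size=(9, 7)).astype(float), folded=False)
        f = fold_jsfs(s)
        assert f.total() == pytest.approx(s.total())
        assert np.allclose(fold_jsfs(f).counts, f.counts)
        assert f.folded

    def test_hand_fold_3x3(self):
        arr = np.zeros((3, 3))
        arr[2, 1] = 4.0
        out = fold_jsfs(JointSFS(arr, folded=False))
        assert out.counts[0, 1] == 4.0
        assert out.counts[2, 1] == 0.0

    def test_fold_commutes_with_accumulation(self):
        params = dict(nu1=1, nu2=1, na=1, ts=1.0)
        a = expected_jsfs("SI", params, 3, 3, 2000, seed=5, folded=True)
        b = expected_jsfs("SI", params, 3, 3, 2000, seed=5, folded=False).fold()
        assert np.allclose(a.counts, b.counts)


class TestExpectedSpectra:
    def test_deep_split_marginal_follows_theta_over_i(self):
        """Within one isolated deme the frequency spectrum is theta/i."""
        params = dict(nu1=1.0, nu2=1.0, na=1.0, ts=8.0)
        br = expected_branch_sfs(get_model("SI"), params, 8, 8, 40000, seed=1)
        marg = br[:, 0][1:-1]  # pop1 variants private while split is deep
        ratios = marg[0] / marg[1]
        assert ratios == pytest.approx(2.0, rel=0.05)
        expect = 2.0 / np.arange(1, 8)
        assert np.allclose(marg, expect, rtol=0.08)

    def test_symmetric_im_spectrum_symmetric(self):
        params = dict(nu1=1.0, nu2=1.0, na=1.0, ts=1.0, m12=1.0, m21=1.0)
        br = expected_branch_sfs(get_model("IM"), params, 6, 6, 40000, seed=2)
        asym = np.abs(br - br.T)[br > 0.02] / br[br > 0.02]
        assert np.median(asym) < 0.1

    def test_matches_msprime_oracle_chi_square(self):
        """Site counts from the engine vs an independent coalescent oracle.

        Both implementations simulate IM (m = 1) for 5e4 unlinked loci;
        the two resulting jSFS samples are compared with a two-sample
        chi-square on cells pooled to adequate counts (alpha = 0.01).
        """
        import msprime
        from scipy.stats import chi2_contingency

        theta = 0.3
        n_loci = 50_000
        params = dict(nu1=1.0, nu2=1.0, na=1.0, ts=1.0, m12=1.0, m21=1.0)
        _, ours = syndata.sim_divergence("IM", params, 4, 4, n_loci, seed=31,
                                         theta=theta)

        N = 1_000
        dem = msprime.Demography()
        dem.add_population(name="p1", initial_size=N)
        dem.add_population(name="p2", initial_size=N)
        dem.add_population(name="anc", initial_size=N)
        dem.add_population_split(time=params["ts"] * 2 * N,
                                 derived=["p1", "p2"], ancestral="anc")
        dem.set_migration_rate("p1", "p2", params["m12"] / (2 * N))
        dem.set_migration_rate("p2", "p1", params["m21"] / (2 * N))
        acc = np.zeros((9, 9))
        reps = msprime.sim_ancestry(
            {"p1": 4, "p2": 4}, demography=dem, ploidy=2,
            num_replicates=n_loci, random_seed=17,
        )
        for ts in reps:
            acc += ts.allele_frequency_spectrum(
                sample_sets=[ts.samples(0), ts.samples(1)],
                mode="branch", polarised=True, span_normalise=False,
            )
        # site counts given genealogies are independent Poissons
        rng = np.random.default_rng(99)
        oracle = rng.poisson(0.5 * theta * acc / (2 * N))

        a = ours.counts.ravel()
        b = oracle.ravel().astype(float)
        keep = (a + b) > 0
        a, b = a[keep], b[keep]
        # pool small cells so chi-square assumptions hold
        order = np.argsort(-(a + b))
        a, b = a[order], b[order]
        pooled_a, pooled_b = [], []
        ca = cb = 0.0
        for x, y in zip(a, b):
            ca += x
            cb += y
            if ca + cb >= 25:
                pooled_a.append(ca)
                pooled_b.append(cb)
                ca = cb = 0.0
        if ca + cb > 0:
            pooled_a.append(ca)
            pooled_b.append(cb)
        stat, p, dof, _ = chi2_contingency([pooled_a, pooled_b])
        assert p > 0.01, f"chi2={stat:.1f}, dof={dof}, p={p:.4g}"

    def test_sim_divergence_matches_engine_expectation(self):
        """Simulated site counts follow the engine's own expected jSFS."""
        from scipy.stats import chi2_contingency

        params = dict(nu1=1.0, nu2=1.0, na=1.0, ts=1.0)
        for seed in (1, 2, 3):
            _, s = syndata.sim_divergence("SI", params, 4, 4, 20_000,
                                          seed=seed, theta=0.3)
            br = expected_branch_sfs(get_model("SI"), params, 8, 8, 100_000,
                                     seed=1000 + seed)
            rng = np.random.default_rng(seed)
            other = rng.poisson(0.5 * 0.3 * 20_000 * br)
            a, b = s.counts.ravel(), other.ravel().astype(float)
            keep = (a + b) > 0
            a, b = a[keep], b[keep]
            order = np.argsort(-(a + b))
            a, b = a[order], b[order]
            pa, pb, ca, cb = [], [], 0.0, 0.0
            for x, y in zip(a, b):
                ca, cb = ca + x, cb + y
                if ca + cb >= 25:
                    pa.append(ca)
                    pb.append(cb)
                    ca = cb = 0.0
            if ca + cb:
                pa.append(ca)
                pb.append(cb)
            _, p, _, _ = chi2_contingency([pa, pb])
            assert p > 0.01


class TestFitMechanics:
    def test_aic_arithmetic(self):
        fr = FitResult(
            model=get_model("SI"),
            params=dict(nu1=1, nu2=1, na=1, ts=1),
            theta_hat=1.0,
            loglik=-50.0,
            n_fits=1,
            fixed={"na": 1.0},
        )
        assert fr.k == 4
        assert fr.aic == 108.0

    def test_profiled_scale_matches_totals(self):
        params = dict(nu1=1, nu2=1, na=1, ts=0.5)
        _, s = syndata.sim_divergence("SI", params, 3, 3, 2000, seed=4, theta=0.4)
        obs = s.fold()
        mod = JointSFSModel(obs, "SI", n_reps=4000)
        _, theta_hat = mod.loglik(params)
        e, _ = mod._expected(params)
        mask = obs.mask()
        assert theta_hat * e[mask].sum() == pytest.approx(obs.counts[mask].sum())

    def test_true_model_beats_nested_restriction(self):
        """IM at truth outscores its no-migration (SI) restriction on IM data."""
        true = dict(nu1=1, nu2=1, na=1, ts=1.0, m12=2.0, m21=2.0)
        _, s = syndata.sim_divergence("IM", true, 6, 6, 20_000, seed=6, theta=0.3)
        mod_im = JointSFSModel(s, "IM", n_reps=20_000)
        mod_si = JointSFSModel(s, "SI", n_reps=20_000)
        ll_im, _ = mod_im.loglik(true)
        ll_si, _ = mod_si.loglik({k: v for k, v in true.items()
                                  if k not in ("m12", "m21")})
        assert ll_im > ll_si

    def test_compare_models_delta_rule(self):
        def fr(name, loglik, k_params):
            model = get_model(name)
            return FitResult(model=model, params={}, theta_hat=1.0,
                             loglik=loglik, n_fits=1,
                             fixed={"na": 1.0})

        # AIC difference of 5: no strong winner
        f1 = fr("SI", -46.0, 4)  # AIC 100
        f2 = fr("SI", -43.5, 4)  # AIC 95
        t = compare_models([f1, f2])
        assert not t["stronger"].any()
        # AIC difference of 15: second model flagged
        f3 = fr("SI", -38.5, 4)  # AIC 85
        t2 = compare_models([f1, f3]).set_index("model")
        assert t2.iloc[0]["stronger"]

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            expected_jsfs("SI", dict(nu1=1, nu2=1, na=1), 3, 3, 100, seed=1)
        with pytest.raises(ValueError):
            expected_jsfs("SI", dict(nu1=-1, nu2=1, na=1, ts=1), 3, 3, 100, seed=1)


class TestUnitConversion:
    def test_round_trip_identity(self):
        model = get_model("IM")
        params = dict(nu1=0.8, nu2=2.5, na=1.0, ts=1.7, m12=3.0, m21=0.4)
        theta_hat, mu, L, gen = 1500.0, 1e-8, 1.2e7, 4.0
        bio = to_biological(model, params, theta_hat, mu, L, gen)
        back = to_scaled(bio, theta_hat, mu, L, gen)
        for k, v in params.items():
            if k == "na":
                assert back["na"] == pytest.approx(v)
            else:
                assert back[k] == pytest.approx(v)

    def test_generation_time_and_mu_enter_linearly(self):
        model = get_model("SI")
        params = dict(nu1=1.0, nu2=1.0, na=1.0, ts=1.0)
        bio4 = to_biological(model, params, 1000.0, 1e-8, 1e7, 4.0)
        bio8 = to_biological(model, params, 1000.0, 1e-8, 1e7, 8.0)
        assert bio8["Ts_years"] == pytest.approx(2 * bio4["Ts_years"])
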