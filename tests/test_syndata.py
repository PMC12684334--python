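"""Synthetic-data generators: truth recovery, targets, determinism."""

import numpy as np
import pytest

from clonescape import syndata
from clonescape.clonal import contract_mlgs, pairwise_distance
from clonescape.genio import MISSING


class TestSimClonalSite:
    def test_all_distinct_truth_r_one(self):
        _, truth = syndata.sim_clonal_site(12, 1, 100, seed=0)
        assert truth.R == 1.0

    def test_single_genet_truth_r_zero(self):
        _, truth = syndata.sim_clonal_site(1, [15], 100, seed=0)
        assert truth.R == 0.0

    def test_zero_loci_rejected(self):
        with pytest.raises(ValueError):
            syndata.sim_clonal_site(3, 1, 0, seed=0)

    def test_rates_validated(self):
        with pytest.raises(ValueError):
            syndata.sim_clonal_site(3, 1, 10, error_rate=1.5, seed=0)

    def test_replicate_discordance_matches_closed_form(self):
        """Mean ramet-pair distance matches the per-allele flip oracle.

        Two copies of a genet differ at an allele copy with probability
        2e(1-e); enumerating the four flip indicators of a locus gives
        the exact expected |dosage difference|, which turns out to be
        the same for every source genotype, so the expected distance is
        E|diff| / 2 regardless of the genet.  Per pair the distance
        averages n_loci near-Bernoulli terms (sd ~ sqrt(p/L)/2); the
        28 pairs are positively correlated through shared ramets, so
        the comparison uses a conservative ~3.5-sigma band of the
        per-pair standard error.
        """
        e = 0.005
        n_loci = 4000
        m, _ = syndata.sim_clonal_site(1, [8], n_loci, error_rate=e, seed=42)
        d = pairwise_distance(m)

        # oracle: enumerate the 16 flip configurations of one locus
        def exp_absdiff(g):
            src = [1] * g + [0] * (2 - g)
            tot = 0.0
            for f in range(16):
                bits = [(f >> k) & 1 for k in range(4)]
                pr = np.prod([e if b else 1 - e for b in bits])
                a = sum(s ^ b for s, b in zip(src, bits[:2]))
                b_ = sum(s ^ b for s, b in zip(src, bits[2:]))
                tot += pr * abs(a - b_)
            return tot

        assert exp_absdiff(0) == pytest.approx(exp_absdiff(1))
        expected = exp_absdiff(0) / 2.0
        p = exp_absdiff(0)
        pair_se = np.sqrt(p * (1 - p) / n_loci) / 2.0
        iu = np.triu_indices(8, 1)
        observed = d.values[iu].mean()
        assert abs(observed - expected) < 3.5 * pair_se

    def test_truth_partition_exactly_recoverable(self):
        m, truth = syndata.sim_clonal_site(5, [1, 2, 3, 1, 2], 200, 0.0, 0.0, seed=6)
        a = contract_mlgs(pairwise_distance(m), 0.0)
        groups = {}
        for ind, g in a.genet_of.items():
            groups.setdefault(g, set()).add(truth.genet_of_individual[ind])
        assert all(len(v) == 1 for v in groups.values())
        assert a.G == 5

    def test_deterministic(self):
        m1, _ = syndata.sim_clonal_site(4, 3, 100, 0.01, 0.05, seed=123)
        m2, _ = syndata.sim_clonal_site(4, 3, 100, 0.01, 0.05, seed=123)
        assert np.array_equal(m1.dosages, m2.dosages)


def _hudson_fst(m):
    """Hudson F_ST estimator from deme allele frequencies (oracle)."""
    sites = m.sites
    freqs, ns = [], []
    for s in sites:
        sub = m.restrict_to_site(s)
        freqs.append(sub.dosages.mean(axis=0) / 2.0)
        ns.append(sub.n_individuals * 2)
    num = den = 0.0
    for a in range(len(sites)):
        for b in range(a + 1, len(sites)):
            p1, p2 = freqs[a], freqs[b]
            n1, n2 = ns[a], ns[b]
            nmr = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
            dnm = p1 * (1 - p2) + p2 * (1 - p1)
            num += nmr.sum()
            den += dnm.sum()
    return num / den


class TestSimMetapopulation:
    def test_fst_zero_gives_identical_frequencies(self):
        cfg = syndata.MetapopConfig(3, 0.0, 200, 300, seed=1)
        m = syndata.sim_metapopulation(cfg)
        f = _hudson_fst(m)
        assert abs(f) < 0.01

    def test_fst_target_realised(self):
        cfg = syndata.MetapopConfig(3, 0.2, 100, 2000, seed=5)
        m = syndata.sim_metapopulation(cfg)
        assert _hudson_fst(m) == pytest.approx(0.2, abs=0.03)

    def test_deterministic(self):
        cfg = syndata.MetapopConfig(2, 0.1, 10, 50, seed=9)
        assert np.array_equal(
            syndata.sim_metapopulation(cfg).dosages,
            syndata.sim_metapopulation(cfg).dosages,
        )


class TestSimDivergence:
    def test_jsfs_matches_matrix(self):
        params = dict(nu1=1, nu2=1, na=1, ts=0.5, m12=1, m21=1)
        from clonescape.demography import build_jsfs

        m, sfs = syndata.sim_divergence("IM", params, 4, 4, 500, seed=3, theta=0.5)
        s2 = build_jsfs(m, {"pop1"}, {"pop2"})
        assert np.array_equal(sfs.counts, s2.counts)

    def test_fst_increases_with_split_time(self):
        from clonescape.syndata import MetapopConfig  # noqa: F401 (clarity)

        fsts = []
        for ts in (0.1, 0.5, 2.0):
            params = dict(nu1=1, nu2=1, na=1, ts=ts)
            m, _ = syndata.sim_divergence("SI", params, 6, 6, 2000, seed=17, theta=0.3)
            fsts.append(_hudson_fst(m))
        assert fsts[0] < fsts[1] < fsts[2]

    def test_invalid_model_rejected(self):
        with pytest.raises(KeyError):
            syndata.sim_divergence("XX", {}, 2, 2, 10, seed=1)

    def test_symmetry_at_zero_split(self):
        """With ts -> 0 the two populations are exchangeable."""
        params = dict(nu1=1, nu2=1, na=1, ts=0.05)
        m, sfs = syndata.sim_divergence("SI", params, 5, 5, 4000, seed=8, theta=0.3)
        a = sfs.counts
        # compare marginal spectra of the two populations
        m1 = a.sum(axis=1)
        m2 = a.sum(axis=0)
        tot = a.sum()
        assert np.abs(m1 - m2).sum() / tot < 0.08


class TestSimDispersal:
    def test_symmetric_without_advection(self):
        P = syndata.sim_dispersal(8, advection=0.0, diffusion=1.5)
        assert np.allclose(P.P, P.P.T, atol=1e-12)

    def test_rows_stochastic(self):
        P = syndata.sim_dispersal(10, advection=1.2, diffusion=0.8)
        assert np.allclose(P.P.sum(axis=1), 1.0, atol=1e-12)

    def test_downstream_mass_monotone_in_advection(self):
        masses = []
        for adv in (0.2, 0.8, 1.6):
            P = syndata.sim_dispersal(12, advection=adv, diffusion=1.0)
            down = sum(
                P.P[i, j] for i in range(12) for j in range(12) if j > i
            )
            masses.append(down)
        assert masses[0] < masses[1] < masses[2]

    def test_masked_sites_isolated(self):
        mask = [True, True, False, True]
        P = syndata.sim_dispersal(4, 0.0, 1.0, habitat_mask=mask)
        assert P.P[2].sum() == 0.0
        assert P.P[:, 2].sum() == 0.0

    def test_all_masked_rejected(self):
        with pytest.raises(ValueError):
            syndata.sim_dispersal(3, habitat_mask=[False, False, False])


class TestSimMorpho:
    def test_zero_noise_returns_means(self):
        t = syndata.sim_morpho({"lin1": (8.0, 25.0, 1.2)}, 5, (0, 0, 0), seed=1)
        assert np.allclose(t.individuals[["FW", "DBD", "UX"]], [8.0, 25.0, 1.2])

    def test_three_branches_per_trait(self):
        t = syndata.sim_morpho(
            {"a": (8, 25, 1.2), "b": (4, 10, 1.1)}, 4, (1, 2, 0.05), seed=2
        )
        counts = t.branches.groupby("individual_id").size()
        assert (counts == 3).all()
        # individual values are branch means
        one = t.branches[t.branches.individual_id == t.individuals.individual_id[0]]
        assert t.individuals.FW.iloc[0] == pytest.approx(one["FW"].mean())

    def test_effect_size_realised(self):
        """Configured standardized difference d=2 is realised within ±0.5."""
        sd = 1.5
        t = syndata.sim_morpho(
            {"a": (8.0, 20, 1.1), "b": (8.0 + 2 * sd, 20, 1.1)},
            50,
            (sd * np.sqrt(3), 0, 0),  # branch sd so individual-mean sd ~ sd
            seed=3,
        )
        g = t.individuals.groupby("lineage")["FW"]
        pooled = np.sqrt(g.var().mean())
        d = (g.mean()["b"] - g.mean()["a"]) / pooled
        assert d == pytest.approx(2.0, abs=0.5)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            syndata.sim_morpho({"a": (1, 1, 0.5)}, 3, (0, 0, 0), seed=0)
        with pytest.raises(ValueError):
            syndata.sim_morpho({"a": (1, 1, 1.5)}, 3, (-1, 0, 0), seed=0)
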