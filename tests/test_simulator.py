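"""Coalescent simulator: unit conversions, exact sampling properties, and
cross-checks against closed forms and an independent simulator (msprime)."""

import numpy as np
import pytest
from scipy import stats as sps

from divergesim import simulator as sim
from divergesim.simulator import (LocusConfig, ModelId, ParameterSet,
                                  build_timeline, default_priors,
                                  drop_mutations, sample_prior,
                                  sample_prior_batch, simulate_dataset,
                                  simulate_genealogy, simulate_locus_stats)


def harmonic(n):
    return sum(1.0 / i for i in range(1, n))


class TestModels:
    def test_eight_models(self):
        assert len(sim.MODEL_NAMES) == 8
        for name in sim.MODEL_NAMES:
            m = ModelId.parse(name)
            assert m.name == name

    def test_invalid_model_rejected(self):
        with pytest.raises(ValueError):
            ModelId("XX", "A")

    def test_iso_requires_zero_migration(self):
        p = ParameterSet(T=1e6, Ne_K=1e5, Ne_W=1e5, Ne_A=1e5, M_WtoK=1.0)
        with pytest.raises(ValueError):
            p.validate(ModelId.parse("ISO-A"))


class TestPriors:
    def test_point_mass_priors_return_point(self):
        pri = sim.PriorSet({
            "Ne_K": ("uniform", 1e5, 1e5 + 1e-6),
            "Ne_W": ("uniform", 2e5, 2e5 + 1e-6),
            "Ne_A": ("uniform", 3e5, 3e5 + 1e-6),
            "T": ("uniform", 1e6, 1e6 + 1e-6),
        })
        p = sample_prior(pri, "ISO-A", seed=1)
        assert p.Ne_K == pytest.approx(1e5)
        assert p.T == pytest.approx(1e6)

    def test_iso_draws_no_migration(self):
        p = sample_prior(default_priors(), "ISO-A", seed=2)
        assert p.M_WtoK == 0.0 and p.M_KtoW == 0.0

    def test_group_a_draws_no_present_sizes(self):
        draws = sample_prior_batch(default_priors(), "IM-A", 10,
                                   np.random.default_rng(0))
        assert "N0_K" not in draws

    def test_loguniform_ks(self):
        """log10 of a log-uniform(1e4, 1e7) size is uniform on [4, 7]."""
        draws = sample_prior_batch(default_priors(), "ISO-A", 10_000,
                                   np.random.default_rng(7))
        x = np.log10(draws["Ne_K"])
        p = sps.kstest(x, sps.uniform(4, 3).cdf).pvalue
        assert p > 0.01

    def test_t1_truncated_below_t(self):
        draws = sample_prior_batch(default_priors(), "SC-B", 5000,
                                   np.random.default_rng(3))
        assert np.all(draws["T1"] > 0)
        assert np.all(draws["T1"] < draws["T"])

    def test_t1_impossible_truncation_errors(self):
        pri = default_priors()
        pri.specs["T"] = ("uniform", 1.0, 2.0)  # years; far below T1 mass
        with pytest.raises(RuntimeError):
            sample_prior_batch(pri, "SC-B", 10, np.random.default_rng(0))


class TestTimeline:
    def test_sc_epoch_boundaries_in_generations(self, locus_config):
        """T1 = 0.059 Ma and T = 0.863 Ma at g = 2.5 y/gen give epoch
        boundaries at 23,600 and 345,200 generations."""
        p = ParameterSet(T=0.863e6, Ne_K=1e6, Ne_W=1e6, Ne_A=1e6,
                         M_WtoK=10, M_KtoW=10, T1=0.059e6)
        tl = build_timeline(p, "SC-A", locus_config)
        gens = tl.boundaries_generations
        assert gens[1:] == pytest.approx([23_600, 345_200])

    def test_group_a_constant_models_have_two_boundaries(self, locus_config):
        p = ParameterSet(T=1e6, Ne_K=1e5, Ne_W=1e5, Ne_A=1e5)
        assert len(build_timeline(p, "ISO-A", locus_config).boundaries) == 2
        p2 = ParameterSet(T=1e6, Ne_K=1e5, Ne_W=1e5, Ne_A=1e5,
                          M_WtoK=5, M_KtoW=5)
        assert len(build_timeline(p2, "IM-A", locus_config).boundaries) == 2

    def test_iso_migration_matrices_zero(self, locus_config):
        p = ParameterSet(T=1e6, Ne_K=1e5, Ne_W=1e5, Ne_A=1e5, T1=3e5,
                         N0_K=1e5, N0_W=1e5)
        tl = build_timeline(p, "ISO-B", locus_config)
        for m in tl.migration_matrices:
            assert np.all(m == 0)

    def test_migration_epoch_placement(self, locus_config):
        p = ParameterSet(T=1e6, Ne_K=1e5, Ne_W=1e5, Ne_A=1e5,
                         M_WtoK=7, M_KtoW=3, T1=3e5)
        sc = build_timeline(p, "SC-A", locus_config).migration_matrices
        em = build_timeline(p, "EM-A", locus_config).migration_matrices
        assert sc[0][0, 1] == 14 and sc[1][0, 1] == 0  # recent only
        assert em[0][0, 1] == 0 and em[1][0, 1] == 14  # ancient only

    def test_group_b_growth_endpoints(self, locus_config):
        """Exponential interpolation hits Ne at T1 exactly."""
        p = ParameterSet(T=1e6, Ne_K=4e6, Ne_W=2e5, Ne_A=1e6, T1=1e5,
                         N0_K=1e5, N0_W=1e6)
        tl = build_timeline(p, "ISO-B", locus_config)
        a = tl.array
        t1 = a[0]
        nK_at_t1 = a[2] * np.exp(a[4] * t1)
        assert nK_at_t1 == pytest.approx(4.0, rel=1e-9)

    def test_derived_growth_coefficients(self):
        p = ParameterSet(T=1e6, Ne_K=4e6, Ne_W=2e5, Ne_A=1e6, T1=1e5,
                         N0_K=1e5, N0_W=1e6)
        gK, gW = p.growth_coefficients(2.5)
        assert gK == pytest.approx(np.log(40) / 40_000)
        assert gW < 0  # W grew toward the present in this configuration


class TestGenealogy:
    def test_mean_tmrca_panmictic(self, panmictic_timeline):
        """E[TMRCA] = 2(1 - 1/n) in units of 2N generations."""
        n = 10
        reps = 6000
        t = np.array([simulate_genealogy(panmictic_timeline, n, 0, s).tmrca
                      for s in range(reps)]) * 2.0  # 4N -> 2N units
        expect = 2 * (1 - 1 / n)
        se = t.std(ddof=1) / np.sqrt(reps)
        assert abs(t.mean() - expect) < 3 * se

    def test_isolated_pair_cannot_coalesce_before_split(self, locus_config):
        p = ParameterSet(T=2e6, Ne_K=1e4, Ne_W=1e4, Ne_A=1e6)
        tl = build_timeline(p, "ISO-A", locus_config)
        t_split = locus_config.years_to_units(2e6)
        for s in range(200):
            assert simulate_genealogy(tl, 1, 1, s).tmrca > t_split

    def test_tree_is_ultrametric_and_complete(self, panmictic_timeline):
        tree = simulate_genealogy(panmictic_timeline, 6, 4, 9)
        assert tree.parent[-1] == -1  # root
        assert (tree.parent[:-1] >= 0).all()
        assert tree.masks[-1] == (1 << 10) - 1
        bl = tree.branch_lengths
        assert (bl[:-1] > 0).all()

    def test_nref_rescaling_leaves_generations_invariant(self):
        """Doubling N_ref halves coalescent-unit times but leaves the
        distribution of TMRCA in generations unchanged."""
        p = ParameterSet(T=1e12, Ne_K=5e5, Ne_W=5e5, Ne_A=5e5)
        means = []
        for n_ref in (1e6, 2e6):
            cfg = LocusConfig(n_ref=n_ref)
            tl = build_timeline(p, "ISO-A", cfg)
            t = [simulate_genealogy(tl, 8, 0, s).tmrca * 4 * n_ref
                 for s in range(1500)]
            means.append((np.mean(t), np.std(t, ddof=1) / np.sqrt(len(t))))
        (m1, se1), (m2, se2) = means
        assert abs(m1 - m2) < 3 * np.hypot(se1, se2)


class TestMutations:
    def test_zero_theta_gives_no_sites(self, panmictic_timeline, rng):
        tree = simulate_genealogy(panmictic_timeline, 10, 0, 1)
        hap = drop_mutations(tree, 0.0, 10_000, rng)
        assert hap.n_sites == 0

    def test_watterson_segregating_sites(self, panmictic_timeline):
        """E[S] = theta * a1 for theta = 5, n = 10."""
        theta, n, reps = 5.0, 10, 10_000
        cfg = LocusConfig(length=10_000, mu=theta / (4 * 1e6 * 10_000))
        tls = np.repeat(panmictic_timeline.array[None, :], reps, axis=0)
        S = simulate_locus_stats(tls, n, 0, cfg, 1, 77)[:, 0, 8]
        se = S.std(ddof=1) / np.sqrt(reps)
        assert abs(S.mean() - theta * harmonic(n)) < 3 * se

    def test_every_column_segregating(self, panmictic_timeline, rng):
        tree = simulate_genealogy(panmictic_timeline, 10, 0, 4)
        hap = drop_mutations(tree, 5.0, 10_000, rng)
        sums = hap.matrix.sum(axis=0)
        assert np.all(sums > 0) and np.all(sums < 10)

    def test_neutral_sfs(self, panmictic_timeline):
        """Unfolded site-frequency spectrum matches E[xi_i] = theta / i."""
        theta, n, reps = 2.0, 10, 4000
        cfg = LocusConfig()
        rng = np.random.default_rng(5)
        sfs = np.zeros(n)
        counts = np.zeros((reps, n - 1))
        for r in range(reps):
            tree = simulate_genealogy(panmictic_timeline, n, 0, 10_000 + r)
            hap = drop_mutations(tree, theta, 100_000, rng)
            c = hap.matrix.sum(axis=0)
            for i in range(1, n):
                counts[r, i - 1] = np.sum(c == i)
        for i in range(1, n):
            xi = counts[:, i - 1]
            se = xi.std(ddof=1) / np.sqrt(reps)
            assert abs(xi.mean() - theta / i) < 3 * se, f"class {i}"


class TestDatasets:
    def test_determinism_bit_identical(self, median_params):
        a = simulate_dataset("SC-B", median_params, 3, seed=11)
        b = simulate_dataset("SC-B", median_params, 3, seed=11)
        for x, y in zip(a, b):
            assert np.array_equal(x.matrix, y.matrix)
            assert np.array_equal(x.positions, y.positions)

    def test_counter_streams_extend_without_perturbing(self, median_params):
        a = simulate_dataset("SC-B", median_params, 2, seed=11)
        b = simulate_dataset("SC-B", median_params, 4, seed=11)
        for x, y in zip(a, b[:2]):
            assert np.array_equal(x.matrix, y.matrix)

    def test_label_symmetry_sign_test(self, locus_config):
        """Symmetric parameters make pi_K - pi_W symmetric about zero."""
        from divergesim.sumstats import locus_stats_from_haplotypes
        p = ParameterSet(T=1e6, Ne_K=2e5, Ne_W=2e5, Ne_A=2e5,
                         M_WtoK=5, M_KtoW=5)
        tl = build_timeline(p, "IM-A", locus_config)
        rows = simulate_locus_stats(
            np.repeat(tl.array[None, :], 800, axis=0), 20, 20,
            locus_config, 1, 42)[:, 0, :]
        diff = rows[:, 0] - rows[:, 1]
        diff = diff[diff != 0]
        k = int((diff > 0).sum())
        p_val = sps.binomtest(k, len(diff), 0.5).pvalue
        assert p_val > 0.01


class TestCrossOracle:
    """Distributional agreement with msprime at identical scaled parameters."""

    @staticmethod
    def _engine_rows(params, model, cfg, n_loci, seed):
        tl = build_timeline(params, model, cfg)
        return simulate_locus_stats(
            np.repeat(tl.array[None, :], n_loci, axis=0), 10, 10, cfg, 1,
            seed)[:, 0, :]

    @staticmethod
    def _msprime_demography(params, model, cfg):
        import msprime

        dem = msprime.Demography()
        dem.add_population(name="K", initial_size=params.Ne_K)
        dem.add_population(name="W", initial_size=params.Ne_W)
        dem.add_population(name="A", initial_size=params.Ne_A)
        g = cfg.gen_time
        model = ModelId.parse(model)
        if model.changing_ne:
            for pop, n0, ne in (("K", params.N0_K, params.Ne_K),
                                ("W", params.N0_W, params.Ne_W)):
                rate = np.log(ne / n0) / (params.T1 / g) * -1.0
                dem[pop].initial_size = n0
                dem[pop].growth_rate = rate
                dem.add_population_parameters_change(
                    time=params.T1 / g, population=pop, initial_size=ne,
                    growth_rate=0.0)
        # backward per-lineage migration: into-K immigrants / (2 N_K)
        def rates():
            return (params.M_WtoK / (2 * params.Ne_K),
                    params.M_KtoW / (2 * params.Ne_W))

        mK, mW = rates()
        if model.scenario == "IM":
            dem.set_migration_rate("K", "W", mK)
            dem.set_migration_rate("W", "K", mW)
        elif model.scenario == "SC":
            dem.set_migration_rate("K", "W", mK)
            dem.set_migration_rate("W", "K", mW)
            dem.add_migration_rate_change(time=params.T1 / g, rate=0.0)
        elif model.scenario == "EM":
            dem.add_migration_rate_change(time=params.T1 / g,
                                          source="K", dest="W", rate=mK)
            dem.add_migration_rate_change(time=params.T1 / g,
                                          source="W", dest="K", rate=mW)
        dem.add_population_split(time=params.T / g, derived=["K", "W"],
                                 ancestral="A")
        dem.sort_events()
        return dem

    @pytest.mark.parametrize("model,params", [
        ("IM-A", dict(T=1.0e6, Ne_K=4e5, Ne_W=2e5, Ne_A=3e5,
                      M_WtoK=4.0, M_KtoW=1.0)),
        ("SC-A", dict(T=1.0e6, Ne_K=3e5, Ne_W=3e5, Ne_A=3e5,
                      M_WtoK=50.0, M_KtoW=20.0, T1=1.5e5)),
    ])
    def test_segregating_sites_and_diversity_match(self, model, params):
        import msprime

        cfg = LocusConfig(length=10_000, mu=2e-9)
        p = ParameterSet(**params)
        n_loci = 500
        rows = self._engine_rows(p, model, cfg, n_loci, seed=21)
        S_engine = rows[:, 8]
        pi_engine = (rows[:, 0] + rows[:, 1]) / 2

        dem = self._msprime_demography(p, model, cfg)
        S_ms, pi_ms = [], []
        reps = msprime.sim_ancestry(
            samples={"K": 5, "W": 5}, demography=dem, ploidy=2,
            sequence_length=cfg.length, num_replicates=n_loci,
            random_seed=97)
        for r, ts in enumerate(reps):
            mts = msprime.sim_mutations(ts, rate=cfg.mu,
                                        random_seed=1000 + r,
                                        model=msprime.BinaryMutationModel())
            G = mts.genotype_matrix().T
            S_ms.append(G.shape[1])
            piK = _pairwise_pi(G[:10], cfg.length)
            piW = _pairwise_pi(G[10:], cfg.length)
            pi_ms.append((piK + piW) / 2)
        assert sps.ks_2samp(S_engine, np.array(S_ms)).pvalue > 0.01
        assert sps.ks_2samp(pi_engine, np.array(pi_ms)).pvalue > 0.01


def _pairwise_pi(H, length):
    c = H.sum(axis=0).astype(float)
    n = H.shape[0]
    seg = (c > 0) & (c < n)
    return float((2 * c[seg] * (n - c[seg]) / (n * (n - 1))).sum() / length)


class TestMigrationEpochs:
    def test_secondary_contact_homogenizes_recent(self, locus_config):
        """Huge recent migration drives F_ST to ~0; the same migration set
        in the ancient epoch leaves strictly more differentiation."""
        base = dict(T=2e6, Ne_K=1e5, Ne_W=1e5, Ne_A=1e5, T1=1.5e5,
                    M_WtoK=400.0, M_KtoW=400.0)
        p = ParameterSet(**base)
        reps = 500
        out = {}
        for model in ("SC-A", "EM-A"):
            tl = build_timeline(p, model, locus_config)
            rows = simulate_locus_stats(
                np.repeat(tl.array[None, :], reps, axis=0), 20, 20,
                locus_config, 1, 33)[:, 0, :]
            out[model] = np.nanmean(rows[:, 4])
        assert out["SC-A"] < 0.05
        assert out["EM-A"] > out["SC-A"] + 0.1


class TestFastPathConsistency:
    def test_branch_stats_match_full_path_distribution(self, median_params):
        """The branch-count fast path and the haplotype full path agree in
        distribution (matched means within 4 combined standard errors)."""
        from divergesim.sumstats import (LOCUS_STAT_FIELDS,
                                         locus_stats_from_haplotypes)
        cfg = LocusConfig(length=10_000, mu=2e-9)
        tl = build_timeline(median_params, "SC-B", cfg)
        n = 800
        fast = simulate_locus_stats(
            np.repeat(tl.array[None, :], n, axis=0), 20, 20, cfg, 1,
            123)[:, 0, :]
        rng = np.random.default_rng(5)
        full = []
        for s in range(n):
            tree = simulate_genealogy(tl, 20, 20, 900_000 + s)
            hap = drop_mutations(tree, cfg.theta, cfg.length, rng)
            full.append(locus_stats_from_haplotypes(
                hap, r2_exact_cap=300, rng=rng).as_array())
        full = np.array(full)
        for i, name in enumerate(LOCUS_STAT_FIELDS):
            a, b = fast[:, i], full[:, i]
            na, nb = np.sum(~np.isnan(a)), np.sum(~np.isnan(b))
            se = np.sqrt(np.nanvar(a) / na + np.nanvar(b) / nb)
            if se == 0:
                assert np.nanmean(a) == np.nanmean(b)
            else:
                assert abs(np.nanmean(a) - np.nanmean(b)) < 4 * se, name
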