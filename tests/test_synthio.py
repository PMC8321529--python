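import numpy as np
import pytest
from scipy import stats as sps

from dupfate import synthio
from dupfate.quantdiv import cross_tissue_correlation
from dupfate.sdperm import fraction_covered, merge_intervals, GenomicInterval
from dupfate.synthio import SimulationConfig


class TestConfig:
    def test_fate_mix_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SimulationConfig(fate_mix={"conserved": 0.5, "pseudogenized": 0.4})

    def test_unknown_fate_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(fate_mix={"conserved": 0.5, "mystery": 0.5})

    def test_psv_rate_bounds(self):
        with pytest.raises(ValueError):
            SimulationConfig(psv_rate=1.0)
        SimulationConfig(psv_rate=0.0)  # identical paralogs allowed

    def test_stage_rngs_are_independent_and_stable(self):
        cfg = SimulationConfig(seed=3)
        a = cfg.rng("families").integers(0, 1000, 5)
        b = cfg.rng("reads").integers(0, 1000, 5)
        assert not np.array_equal(a, b)
        assert np.array_equal(a, cfg.rng("families").integers(0, 1000, 5))


class TestSimulateFamilies:
    def test_deterministic(self, small_config):
        h1, o1, f1, t1 = synthio.simulate_families(small_config)
        h2, o2, f2, t2 = synthio.simulate_families(small_config)
        assert h1.values.equals(h2.values)
        assert o1.values.equals(o2.values)
        assert f1 == f2
        assert t1.family_fates == t2.family_fates

    def _noise_free(self, fate):
        cfg = SimulationConfig(
            n_families=12,
            expression_noise_sd=0.0,
            fate_mix={fate: 1.0},
            seed=5,
        )
        return synthio.simulate_families(cfg)

    def test_conserved_ancestral_matches_ortholog_exactly(self):
        human, ortho, fams, truth = self._noise_free("conserved")
        hm, om = human.tissue_means(), ortho.tissue_means()
        for fam in fams:
            anc = hm.loc[fam.ancestral_gene].to_numpy()
            ort = om.loc[fam.ortholog_gene].to_numpy()
            np.testing.assert_allclose(anc, ort, rtol=1e-10)
            assert cross_tissue_correlation(anc, ort) == pytest.approx(1.0)

    def test_pseudogenized_derived_all_zero(self):
        human, _, fams, _ = self._noise_free("pseudogenized")
        for fam in fams:
            for g in fam.derived_genes:
                assert (human.values.loc[g] == 0).all()

    def test_subfunctionalized_sum_reconstructs_ortholog(self):
        human, ortho, fams, _ = self._noise_free("subfunctionalized")
        hm, om = human.tissue_means(), ortho.tissue_means()
        for fam in fams:
            total = hm.loc[list(fam.paralogs)].sum(axis=0).to_numpy()
            np.testing.assert_allclose(
                total, om.loc[fam.ortholog_gene].to_numpy(), rtol=1e-9
            )

    def test_every_entity_has_truth_record(self, small_config):
        human, ortho, fams, truth = synthio.simulate_families(small_config)
        assert set(truth.family_fates) == {f.family_id for f in fams}
        for fam in fams:
            for g in fam.paralogs + (fam.ortholog_gene,):
                assert g in truth.gene_profiles


class TestSimulateDuplicatedReads:
    def test_deterministic(self, small_config):
        s1, r1, t1 = synthio.simulate_duplicated_reads(small_config)
        s2, r2, t2 = synthio.simulate_duplicated_reads(small_config)
        assert s1 == s2
        assert t1.read_origins == t2.read_origins
        assert all(
            a.read_id == b.read_id and a.candidates == b.candidates
            for a, b in zip(r1, r2)
        )

    def test_zero_psv_rate_all_reads_multimap(self):
        cfg = SimulationConfig(psv_rate=0.0, n_reads=50, duplicon_length=500,
                               read_length=50, seed=2)
        (sa, sb), reads, _ = synthio.simulate_duplicated_reads(cfg)
        assert sa == sb
        assert all(len(r.candidates) == 2 for r in reads)

    def test_saturating_psv_rate_warns(self):
        cfg = SimulationConfig(psv_rate=0.5, n_reads=50, duplicon_length=500,
                               read_length=100, seed=2)
        with pytest.warns(UserWarning, match="no multi-mapping"):
            _, reads, _ = synthio.simulate_duplicated_reads(cfg)
        assert all(len(r.candidates) == 1 for r in reads)

    def test_read_covering_psv_is_unique(self):
        cfg = SimulationConfig(psv_rate=0.01, n_reads=500, duplicon_length=2000,
                               read_length=100, seed=4)
        (sa, sb), reads, truth = synthio.simulate_duplicated_reads(cfg)
        psvs = set(int(p) for p in truth.psv_positions)
        for r in reads:
            start = r.candidates[0].pos
            covers = any(start <= p < start + cfg.read_length for p in psvs)
            assert covers == (len(r.candidates) == 1)

    def test_sequences_differ_only_at_psvs(self):
        cfg = SimulationConfig(psv_rate=0.01, duplicon_length=2000, seed=4)
        (sa, sb), _, truth = synthio.simulate_duplicated_reads(cfg)
        diff = {i for i, (x, y) in enumerate(zip(sa, sb)) if x != y}
        assert diff == set(int(p) for p in truth.psv_positions)

    def test_unique_fraction_matches_analytic_expectation(self):
        # 10k reads drawn across 25 independent sequence pairs: the PSV count
        # of a single pair is one Poisson draw, so averaging over pairs is
        # needed for the marginal expectation to apply
        rate, L, R = 0.005, 20_000, 100
        n_pairs, reads_per_pair = 25, 400
        unique = 0
        for seed in range(n_pairs):
            cfg = SimulationConfig(
                psv_rate=rate, duplicon_length=L, read_length=R,
                n_reads=reads_per_pair, seed=seed,
            )
            _, reads, _ = synthio.simulate_duplicated_reads(cfg)
            unique += sum(len(r.candidates) == 1 for r in reads)
        n_total = n_pairs * reads_per_pair
        observed = unique / n_total
        expected = 1.0 - (1.0 - rate) ** R
        # binomial sampling variance plus the between-pair PSV-count variance
        lam = rate * L
        per_pair_sd = (1 - expected) * (R / L)  # d/dK of exp(-K R/L) times 1
        sd = np.sqrt(
            expected * (1 - expected) / n_total + per_pair_sd**2 * lam / n_pairs
        )
        assert abs(observed - expected) <= 3 * sd

    def test_psv_counts_poisson_consistent(self):
        # chi-square goodness of fit of PSV counts against Poisson(rate * L)
        # over 10k replicate sequence pairs
        L, rate = 400, 0.01
        counts = []
        for i in range(10_000):
            cfg = SimulationConfig(
                psv_rate=rate, duplicon_length=L, read_length=50, n_reads=1, seed=i
            )
            _, _, truth = synthio.simulate_duplicated_reads(cfg)
            counts.append(len(truth.psv_positions))
        counts = np.asarray(counts)
        lam = rate * L
        kmax = int(sps.poisson.ppf(0.9999, lam))
        edges = np.arange(0, kmax + 1)
        observed = np.array([(counts == k).sum() for k in edges])
        observed = np.append(observed, (counts > kmax).sum())
        expected = sps.poisson.pmf(edges, lam) * counts.size
        expected = np.append(expected, sps.poisson.sf(kmax, lam) * counts.size)
        keep = expected > 5
        chi2 = ((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        p = sps.chi2.sf(chi2, keep.sum() - 1)
        assert p > 0.01

    def test_read_length_must_fit(self):
        with pytest.raises(ValueError):
            synthio.simulate_duplicated_reads(
                SimulationConfig(duplicon_length=50, read_length=100)
            )


class TestSimulatePeakLandscape:
    def test_deterministic(self, small_config):
        g1, p1, s1, t1 = synthio.simulate_peak_landscape(small_config)
        g2, p2, s2, t2 = synthio.simulate_peak_landscape(small_config)
        assert p1 == p2 and s1 == s2
        assert t1.peak_states.equals(t2.peak_states)

    def test_depletion_zero_no_sd_coverage(self):
        cfg = SimulationConfig(seed=3, depletion=0.0)
        _, peaks, sds, _ = synthio.simulate_peak_landscape(cfg)
        assert fraction_covered(sds, peaks) == 0.0

    def test_tiling_peaks_full_coverage(self):
        cfg = SimulationConfig(seed=3)
        genome, _, sds, _ = synthio.simulate_peak_landscape(cfg)
        tile = [GenomicInterval("chr1", 0, genome.lengths["chr1"])]
        assert fraction_covered(sds, tile) == 1.0
        assert fraction_covered(merge_intervals(sds), tile) == 1.0

    def test_calibrated_null_when_no_depletion(self):
        # depletion factor 1: observed SD coverage should sit inside the
        # central 95% of its own permutation null (checked over seeds)
        from dupfate.sdperm import depletion_test

        inside = 0
        for seed in range(10):
            cfg = SimulationConfig(seed=seed, depletion=1.0)
            genome, peaks, sds, _ = synthio.simulate_peak_landscape(cfg)
            null = depletion_test(sds, peaks, genome, n=200, seed=seed)
            lo, hi = np.quantile(null.null_values, [0.025, 0.975])
            inside += lo <= null.observed <= hi
        assert inside >= 9

    def test_sd_intervals_within_genome(self, small_config):
        genome, _, sds, _ = synthio.simulate_peak_landscape(small_config)
        genome.validate(sds)
        assert len(merge_intervals(sds)) == len(sds)  # disjoint by construction

    def test_genome_too_small_rejected(self):
        with pytest.raises(ValueError):
            synthio.simulate_peak_landscape(
                SimulationConfig(genome_length=1000, n_sd_intervals=10, sd_length=100)
            )


class TestSimulateCn:
    def test_truncated_at_zero_and_deterministic(self, small_config):
        genes = ["g1", "g2", "g3"]
        cn1 = synthio.simulate_cn(small_config, genes, 50)
        cn2 = synthio.simulate_cn(small_config, genes, 50)
        assert cn1.equals(cn2)
        assert (cn1.to_numpy() >= 0).all()
        assert cn1.shape == (50, 3)
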