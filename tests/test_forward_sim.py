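import numpy as np
import pytest

from sibsam import _engine
from sibsam.forward_sim import (
    EXPLORATORY,
    HIGH,
    LOW,
    SIBSAM_NOISE,
    AncestryChromosome,
    ExperimentConfig,
    Individual,
    QTL,
    QTLModel,
    ancestry_difference,
    breed_generation,
    combine_crosses,
    im_neutral_ancestry,
    make_f1,
    phenotype,
    recombine_gamete,
    run_bsa_experiment,
    run_im_experiment,
    sample_pool_reads,
    select_tails,
)
from sibsam.genome_map import make_synthetic_map

from conftest import uniform_map


def pure_pair():
    return AncestryChromosome.pure(HIGH), AncestryChromosome.pure(LOW)


class TestRecombineGamete:
    def test_female_mean_crossovers_one_morgan(self):
        # 100 cM chromosome: crossover count ~ Poisson(1); with pure-strain
        # parental copies every crossover is a visible origin switch
        rng = np.random.default_rng(0)
        a, b = pure_pair()
        counts = [len(recombine_gamete(a, b, 100.0, False, rng).breakpoints) for _ in range(3000)]
        assert abs(np.mean(counts) - 1.0) < 0.08

    def test_male_never_recombines(self):
        rng = np.random.default_rng(1)
        a, b = pure_pair()
        for _ in range(50):
            g = recombine_gamete(a, b, 100.0, True, rng)
            assert len(g.breakpoints) == 0
            assert g.origins[0] in (HIGH, LOW)

    def test_zero_cm_transmits_whole_copy(self):
        rng = np.random.default_rng(2)
        a, b = pure_pair()
        g = recombine_gamete(a, b, 0.0, False, rng)
        assert len(g.breakpoints) == 0

    def test_tracts_tile_and_alternate(self):
        rng = np.random.default_rng(3)
        a, b = pure_pair()
        g = a
        for _ in range(6):  # recombine repeatedly against the opposite strain
            g = recombine_gamete(g, b, 150.0, False, rng)
            assert len(g.origins) == len(g.breakpoints) + 1
            if len(g.breakpoints):
                assert np.all(np.diff(g.breakpoints) > 0)
                assert g.breakpoints[0] > 0 and g.breakpoints[-1] < 150.0
                # simplified representation: adjacent tracts differ in origin
                assert np.all(np.diff(g.origins) != 0)

    def test_switch_probability_matches_map_function(self):
        # P(different ancestry at two loci d cM apart in one meiosis from a
        # HIGH/LOW heterozygote) = (1 - exp(-2d/100))/2 (no interference);
        # checked for both the tract path and the vectorized engine path
        d = 20.0
        expected = 0.5 * (1 - np.exp(-2 * d / 100.0))
        rng = np.random.default_rng(4)
        a, b = pure_pair()
        n = 4000
        diff = 0
        for _ in range(n):
            g = recombine_gamete(a, b, 100.0, False, rng)
            diff += int(g.origin_at(40.0)) != int(g.origin_at(40.0 + d))
        assert abs(diff / n - expected) < 3 * np.sqrt(expected * (1 - expected) / n)

        geno = np.zeros((1, 2, 2), dtype=np.uint8)
        geno[0, 0, :] = 1
        gam = _engine._recombinant_gametes(
            geno, np.zeros(n, dtype=int), np.array([40.0, 40.0 + d]), 100.0,
            np.random.default_rng(5),
        )
        frac = np.mean(gam[:, 0] != gam[:, 1])
        assert abs(frac - expected) < 3 * np.sqrt(expected * (1 - expected) / n)


class TestBreeding:
    def test_f1_single_origin_tracts(self, tiny_map):
        pop = make_f1(tiny_map, 10, np.random.default_rng(0))
        for ind in pop:
            for label in tiny_map.labels:
                copies = ind.copies(label)
                for c in copies:
                    assert len(c.breakpoints) == 0
            auto = ind.copies("2")
            assert {int(auto[0].origins[0]), int(auto[1].origins[0])} == {HIGH, LOW}

    def test_offspring_count_and_tiling(self, tiny_map):
        rng = np.random.default_rng(1)
        pop = make_f1(tiny_map, 16, rng)
        for _ in range(3):
            pop = breed_generation(pop, tiny_map, rng)
        assert len(pop) == 16
        for ind in pop:
            for c in tiny_map.chromosomes:
                n_copies = 1 if (c.is_x and ind.is_male) else 2
                assert len(ind.copies(c.label)) == n_copies
                for cp in ind.copies(c.label):
                    # tracts tile the chromosome: origins defined everywhere
                    pos = np.linspace(0, c.total_cm, 13)
                    assert set(np.unique(cp.origin_at(pos))) <= {HIGH, LOW}

    def test_single_sex_generation_errors(self, tiny_map):
        rng = np.random.default_rng(2)
        pop = [i for i in make_f1(tiny_map, 30, rng) if i.is_male]
        with pytest.raises(ValueError):
            breed_generation(pop, tiny_map, rng)

    def test_engine_neutral_ancestry_mean_half(self):
        # no QTL, no selection: HIGH-ancestry frequency stays 0.5 on average
        gmap = make_synthetic_map(25, seed=2)
        freqs = []
        for r in range(25):
            rng = np.random.default_rng(100 + r)
            pop = _engine.simulate_population(gmap, 200, 6, rng)
            freqs.append(pop.pool_freq(np.arange(200)).mean())
        se = np.std(freqs) / np.sqrt(len(freqs))
        assert abs(np.mean(freqs) - 0.5) < 4 * max(se, 1e-3)


class TestPhenotype:
    def _all_origin_individual(self, gmap, origin):
        genome = {
            c.label: tuple(AncestryChromosome.pure(origin) for _ in range(2))
            for c in gmap.chromosomes
        }
        return Individual(False, genome)

    def test_five_unit_loci_design(self, tiny_map):
        # five f=1 loci: all-HIGH scores 10, all-LOW scores 0, design mean 5
        arms = ["X", "2", "2", "3", "3"]
        cms = [10.0, 20.0, 80.0, 20.0, 80.0]
        model = QTLModel([QTL(c, p, 1.0) for c, p in zip(arms, cms)], EXPLORATORY, noise_sd=0.0)
        hi = self._all_origin_individual(tiny_map, HIGH)
        lo = self._all_origin_individual(tiny_map, LOW)
        rng = np.random.default_rng(0)
        assert phenotype(hi, model, rng) == pytest.approx(10.0)
        assert phenotype(lo, model, rng) == pytest.approx(0.0)
        assert model.design_mean() == pytest.approx(5.0)
        assert QTLModel(model.loci, EXPLORATORY).noise_scale() == pytest.approx(5.0)

    def test_zero_loci_noise_only(self, tiny_map):
        model = QTLModel([], SIBSAM_NOISE)
        ind = self._all_origin_individual(tiny_map, HIGH)
        rng = np.random.default_rng(1)
        vals = np.array([phenotype(ind, model, rng) for _ in range(4000)])
        assert abs(vals.mean()) < 0.03
        assert abs(vals.std() - 0.5) < 0.02

    def test_zero_effect_independent_of_ancestry(self, tiny_map):
        model = QTLModel([QTL("2", 50.0, 0.0)], EXPLORATORY, noise_sd=0.0)
        hi = self._all_origin_individual(tiny_map, HIGH)
        lo = self._all_origin_individual(tiny_map, LOW)
        rng = np.random.default_rng(2)
        assert phenotype(hi, model, rng) == phenotype(lo, model, rng) == 0.0


class TestSelectTails:
    def test_pool_sizes(self):
        rng = np.random.default_rng(0)
        hi, lo = select_tails(rng.normal(size=600), 0.10)
        assert len(hi) == len(lo) == 60
        assert set(hi).isdisjoint(lo)

    def test_half_partitions(self):
        hi, lo = select_tails(np.arange(10.0), 0.5)
        assert sorted(np.concatenate([hi, lo])) == list(range(10))

    def test_ties_match_sort_brute_force(self):
        phenos = np.array([1.0, 2.0, 2.0, 2.0, 0.0, 2.0])
        hi, lo = select_tails(phenos, 0.34)
        order = sorted(range(6), key=lambda i: (phenos[i], i))
        assert list(lo) == order[:2]
        assert list(hi) == order[-2:]

    def test_empty_pool_errors(self):
        with pytest.raises(ValueError):
            select_tails(np.arange(5.0), 0.1)


class TestReadSampling:
    def test_all_high_pool_saturates(self, tiny_map):
        pop = [
            Individual(False, {
                c.label: (AncestryChromosome.pure(HIGH), AncestryChromosome.pure(HIGH))
                for c in tiny_map.chromosomes
            })
        ]
        pa = sample_pool_reads(pop, tiny_map, 50, np.random.default_rng(0))
        np.testing.assert_array_equal(pa.freq_est, 1.0)

    def test_binomial_sampling_sd(self):
        # depth 300 at p = 0.5: SD of the estimate ~ sqrt(p(1-p)/depth) = 0.0289
        freqs = _engine.sample_read_freqs(
            np.full(20000, 0.5), 300, np.random.default_rng(1)
        )
        assert abs(freqs.std() - 0.0289) < 0.002
        assert abs(freqs.mean() - 0.5) < 0.001


class TestAncestryDifference:
    def test_worked_example(self):
        assert ancestry_difference([0.6], [0.4])[0] == pytest.approx(0.2)

    def test_identical_pools_zero_and_saturation(self):
        x = np.linspace(0, 1, 7)
        np.testing.assert_allclose(ancestry_difference(x, x), 0.0)
        np.testing.assert_allclose(ancestry_difference(np.ones(3), np.zeros(3)), 1.0)

    def test_mismatched_windows_error(self):
        with pytest.raises(ValueError):
            ancestry_difference(np.zeros(3), np.zeros(4))


class TestCombineCrosses:
    def test_identity_and_scaling(self):
        x = np.array([0.1, -0.2, 0.3])
        np.testing.assert_allclose(combine_crosses([x]), x)
        np.testing.assert_allclose(combine_crosses([x] * 4), 4 * x)

    def test_null_variance_additivity(self):
        # summing k independent null profiles scales the per-window SD ~ sqrt(k)
        gmap = make_synthetic_map(20, seed=4)
        config = ExperimentConfig(N=100, G=4, q=0.2, depth=200)
        model = QTLModel([], SIBSAM_NOISE)
        singles, sums = [], []
        for r in range(12):
            profs = [
                run_bsa_experiment(config, model, gmap, np.random.default_rng((r, c))).ad
                for c in range(4)
            ]
            singles.append(profs[0])
            sums.append(combine_crosses(profs))
        ratio = np.std(sums) / np.std(singles)
        assert 1.6 < ratio < 2.4


class TestExperiments:
    def test_bsa_deterministic_under_seed(self, tiny_map):
        config = ExperimentConfig(N=80, G=4, q=0.2, depth=100)
        model = QTLModel([QTL("3", 50.0, 0.5)], SIBSAM_NOISE)
        a = run_bsa_experiment(config, model, tiny_map, np.random.default_rng(7)).ad
        b = run_bsa_experiment(config, model, tiny_map, np.random.default_rng(7)).ad
        np.testing.assert_array_equal(a, b)

    def test_strong_qtl_localizes(self):
        gmap = make_synthetic_map(40, seed=6)
        config = ExperimentConfig(N=400, G=8, q=0.2, depth=500)
        model = QTLModel([QTL("3", 55.0, 2.0)], SIBSAM_NOISE)
        win = gmap.flat_index("3", gmap.chrom("3").window_at(55.0))
        hits = 0
        for r in range(15):
            res = run_bsa_experiment(config, model, gmap, np.random.default_rng(r))
            hits += abs(int(np.argmax(res.ad)) - win) <= 4
        assert hits >= 12

    def test_selection_response_monotone_in_effect(self):
        gmap = make_synthetic_map(30, seed=8)
        config = ExperimentConfig(N=250, G=6, q=0.2, depth=400)
        win = gmap.flat_index("2", gmap.chrom("2").window_at(54.0))
        means = []
        for f in (0.0, 0.3, 1.5):
            model = QTLModel([QTL("2", 54.0, f)], SIBSAM_NOISE)
            vals = [
                run_bsa_experiment(config, model, gmap, np.random.default_rng((int(f * 10), r))).ad[win]
                for r in range(15)
            ]
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]
        assert abs(means[0]) < 0.1

    def test_im_neutral_dilution_closed_form(self):
        # neutral non-backcross ancestry halves with each backcross round
        gmap = make_synthetic_map(20, seed=9)
        config = ExperimentConfig(mode="im", N=400, G=6, q=0.3, depth=400)
        model = QTLModel([], SIBSAM_NOISE)
        sl = slice(20, 60)  # autosomes only (X dilutes differently)
        aps = [
            run_im_experiment(config, model, gmap, np.random.default_rng(r)).true_ap[sl].mean()
            for r in range(25)
        ]
        expected = im_neutral_ancestry(6)  # two backcross rounds: 0.125
        assert expected == pytest.approx(0.125)
        assert abs(np.mean(aps) - expected) < 0.02

    def test_im_f2_neutral_half(self):
        assert im_neutral_ancestry(2) == pytest.approx(0.5)

    def test_im_selected_dominant_locus_stays_elevated(self):
        gmap = make_synthetic_map(20, seed=10)
        config = ExperimentConfig(mode="im", N=300, G=6, q=0.2, depth=400)
        model = QTLModel([QTL("2", 54.0, 2.0)], SIBSAM_NOISE)
        win = gmap.flat_index("2", gmap.chrom("2").window_at(54.0))
        neutral = im_neutral_ancestry(6)
        aps = [
            run_im_experiment(config, model, gmap, np.random.default_rng(r)).true_ap[win]
            for r in range(12)
        ]
        assert np.mean(aps) > 2 * neutral


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(N=1),
            dict(G=1),
            dict(q=0.0),
            dict(q=0.6),
            dict(depth=0),
            dict(mode="f2"),
        ],
    )
    def test_invalid_configs(self, kwargs):
        with pytest.raises(ValueError):
            ExperimentConfig(**kwargs)

    def test_negative_effect_rejected(self):
        with pytest.raises(ValueError):
            QTL("2", 10.0, -0.5)
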