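"""Forward gamete/pedigree simulation and count-level fixtures."""

import numpy as np
import pytest

from xrecomb.recomb import count_interval, estimate_theta, pool_counts
from xrecomb.simulate import (
    HaplotypeEffect, SimConfig, simulate_dataset, simulate_gamete,
    table_fixture,
)
from xrecomb.xinherit import deduce_all_gametes, phase_all_females
from conftest import make_panel

HAPS = (("1", "1", "1", "1"), ("2", "2", "2", "2"))


class TestSimulateGamete:
    def test_zero_theta_transmits_a_parental_haplotype_intact(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            gamete, sources, xovers = simulate_gamete(rng, HAPS, [0.0] * 3)
            assert not any(xovers)
            assert tuple(gamete) in HAPS

    def test_switch_frequency_matches_interval_theta(self):
        rng = np.random.default_rng(1)
        theta = 0.45
        switches = 0
        for _ in range(10_000):
            _, _, xovers = simulate_gamete(rng, HAPS, [theta, 0.0, 0.0])
            switches += xovers[0]
        assert switches / 10_000 == pytest.approx(theta, abs=0.015)

    def test_identical_seed_reproduces_gamete_stream(self):
        a = [simulate_gamete(np.random.default_rng(9), HAPS, [0.2] * 3)
             for _ in range(1)]
        b = [simulate_gamete(np.random.default_rng(9), HAPS, [0.2] * 3)
             for _ in range(1)]
        assert a == b
        c = simulate_gamete(np.random.default_rng(10), HAPS, [0.2] * 3)
        streams = [simulate_gamete(np.random.default_rng(10), HAPS, [0.2] * 3)
                   for _ in range(5)]
        assert c == streams[0]

    def test_origins_switch_exactly_at_crossovers(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            _, sources, xovers = simulate_gamete(rng, HAPS, [0.3] * 3)
            for j, x in enumerate(xovers):
                assert (sources[j] != sources[j + 1]) == x

    def test_theta_outside_domain_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            simulate_gamete(rng, HAPS, [0.5, 0.0, 0.0])


class TestSimulateDataset:
    def test_intercross_scale_matches_study_design(self):
        """17 F1 females with the real per-female litter sizes produce the
        study's 1028 genotyped F2."""
        litters = [76, 72, 96, 55, 83, 38, 69, 45, 62, 68, 63, 83, 50, 27,
                   62, 42, 37]
        cfg = SimConfig(panel=make_panel(4), seed=1, n_crosses=17,
                        f1_females_per_cross=1, offspring_per_female=litters)
        sim = simulate_dataset(cfg)
        assert len(sim.pedigree.generation("F2")) == 1028
        assert len(sim.truth.meioses) == 1028

    def test_truth_untouched_by_genotype_corruption(self, small_panel):
        clean = simulate_dataset(SimConfig(panel=small_panel, seed=5,
                                           n_crosses=2, offspring_per_female=20))
        noisy = simulate_dataset(SimConfig(panel=small_panel, seed=5,
                                           n_crosses=2, offspring_per_female=20,
                                           missing_rate=0.1, error_rate=0.05))
        assert len(noisy.genotypes) < len(clean.genotypes)
        assert [m.origins for m in noisy.truth.meioses] == \
            [m.origins for m in clean.truth.meioses]

    def test_identical_seeds_give_identical_datasets(self, small_panel):
        cfg = dict(panel=small_panel, seed=11, n_crosses=2,
                   offspring_per_female=15, missing_rate=0.05)
        a = simulate_dataset(SimConfig(**cfg))
        b = simulate_dataset(SimConfig(**cfg))
        assert dict(a.genotypes.items()) == dict(b.genotypes.items())
        c = simulate_dataset(SimConfig(**{**cfg, "seed": 12}))
        assert dict(a.genotypes.items()) != dict(c.genotypes.items())

    def test_sons_hemizygous_daughters_carry_paternal_x(self, clean_sim):
        cfg, sim = clean_sim
        for off in sim.pedigree.generation("F2"):
            call = sim.genotypes.get(off.id, "M1")
            assert len(call) == (1 if off.sex == "M" else 2)

    def test_simulated_theta_converges_to_truth(self):
        """Recombinant frequency over 10^4 meioses within 3 binomial SE."""
        panel = make_panel(3)
        theta = [0.1, 0.25]
        cfg = SimConfig(panel=panel, seed=21, n_crosses=2,
                        f1_females_per_cross=1, offspring_per_female=5000,
                        theta=theta)
        sim = simulate_dataset(cfg)
        for j, pair in enumerate(panel.adjacent_pairs()):
            n = r = 0
            for fid in sim.truth.theta_by_female:
                dn, dr = sim.truth.true_counts(fid, pair, panel)
                n, r = n + dn, r + dr
            se = (theta[j] * (1 - theta[j]) / n) ** 0.5
            assert r / n == pytest.approx(theta[j], abs=3 * se)

    def test_haplotype_effect_multiplies_carrier_theta(self):
        """A 14-fold multiplier attached to one grand-maternal founder
        haplotype shows up as a ~14-fold pooled recombination-fraction ratio
        between carrier and non-carrier females."""
        panel = make_panel(2)
        effect = HaplotypeEffect(markers=("M1",), multipliers={"2": 14.0})
        cfg = SimConfig(panel=panel, seed=33, n_crosses=10,
                        f1_females_per_cross=2, offspring_per_female=600,
                        theta=0.007, founder_model="two_sow_haplotypes",
                        haplotype_effect=effect)
        sim = simulate_dataset(cfg)
        groups = {"carrier": [0, 0], "other": [0, 0]}
        for fid, mat in sim.truth.maternal_hap.items():
            key = "carrier" if mat[0] == "2" else "other"
            n, r = sim.truth.true_counts(fid, ("M1", "M2"), panel)
            groups[key][0] += n
            groups[key][1] += r
        assert groups["carrier"][0] > 2000 and groups["other"][0] > 2000
        ratio = (groups["carrier"][1] / groups["carrier"][0]) / \
                (groups["other"][1] / groups["other"][0])
        assert 9 < ratio < 20

    def test_pipeline_estimate_matches_truth_on_clean_data(self, clean_sim):
        cfg, sim = clean_sim
        phased = phase_all_females(sim.pedigree, cfg.panel, sim.genotypes)
        gametes = deduce_all_gametes(sim.pedigree, cfg.panel, sim.genotypes,
                                     phased)
        pair = cfg.panel.adjacent_pairs()[0]
        counts = [count_interval(gametes[f], phased[f], pair, cfg.panel)
                  for f in phased]
        pooled = pool_counts(counts)
        tn = tr = 0
        for fid in phased:
            dn, dr = sim.truth.true_counts(fid, pair, cfg.panel)
            tn, tr = tn + dn, tr + dr
        assert (pooled.n, pooled.r) == (tn, tr)

    def test_par_markers_rejected(self):
        from xrecomb.genodata import Marker, MarkerPanel
        par_panel = MarkerPanel([Marker("M1", 1), Marker("PARM", 2, par=True)])
        with pytest.raises(ValueError, match="PAR"):
            SimConfig(panel=par_panel, seed=0).validate()


class TestTableFixture:
    def test_reconstruction_of_published_rows(self):
        rows = [("910009", 72, 0.139), ("910013", 55, 0.0)]
        counts = table_fixture(rows)
        assert [(c.n, c.r) for c in counts] == [(72, 10), (55, 0)]

    def test_totals_of_bundled_fine_interval(self):
        from xrecomb import datasets as ds
        counts = ds.inra_fine_counts()
        assert sum(c.n for c in counts) == 1028
        assert sum(c.r for c in counts) == 60

    def test_halfway_products_are_ambiguous_by_default(self):
        with pytest.raises(ValueError, match="ambiguous"):
            table_fixture([("u", 10, 0.25)])
        (c,) = table_fixture([("u", 10, 0.25)], ties="even")
        assert c.r == 2
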