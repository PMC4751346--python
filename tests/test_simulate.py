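"""Breeding-program simulator: meiosis, polycross, phenotypes, program."""

import numpy as np
import pytest

import polygs as pg
from polygs import popgen, simulate as sim


def _two_locus_genome(d_morgans, same_chromosome=True):
    if same_chromosome:
        return sim.Genome(
            chrom_lengths=np.array([max(d_morgans * 2, 0.02)]),
            locus_chrom=np.array([0, 0]),
            locus_pos=np.array([0.0, d_morgans]),
            marker_index=np.array([0, 1]),
            marker_ids=["a", "b"],
        )
    return sim.Genome(
        chrom_lengths=np.array([1.0, 1.0]),
        locus_chrom=np.array([0, 1]),
        locus_pos=np.array([0.5, 0.5]),
        marker_index=np.array([0, 1]),
        marker_ids=["a", "b"],
    )


class TestMeiosis:
    def test_homozygous_parent_gamete_identical(self, rng):
        h = rng.integers(0, 2, 50).astype(np.uint8)
        parent = sim.HaplotypePair(h, h.copy())
        genome = sim.Genome(
            chrom_lengths=np.array([1.0]),
            locus_chrom=np.zeros(50, int),
            locus_pos=np.sort(rng.uniform(0, 1, 50)),
            marker_index=np.arange(50),
            marker_ids=[f"m{i}" for i in range(50)],
        )
        for _ in range(5):
            np.testing.assert_array_equal(sim.meiosis(parent, genome, rng), h)

    @pytest.mark.parametrize(
        "d,expected",
        [
            (0.01, (1 - np.exp(-2 * 0.01)) / 2),  # Haldane at 1 cM
            (None, 0.5),  # independent assortment
        ],
    )
    def test_recombinant_fraction(self, d, expected, rng):
        genome = (
            _two_locus_genome(d) if d is not None else _two_locus_genome(0, False)
        )
        # doubly heterozygous parent in coupling phase
        haplos = np.zeros((1, 2, 2), np.uint8)
        haplos[0, 0] = [1, 1]
        n = 100_000
        gametes = sim._gametes(haplos, genome, np.zeros(n, int), rng)
        rec = (gametes[:, 0] != gametes[:, 1]).mean()
        sd = np.sqrt(expected * (1 - expected) / n)
        assert abs(rec - expected) < 5 * sd

    def test_zero_burn_in_no_ld_between_distant_markers(self):
        cfg = sim.SimulationConfig(
            n_chromosomes=2, chromosome_length=1.0, n_markers=40, n_qtl=2,
            effective_size=400, burn_in=0, trait_h2={"t": 0.3}, selection_trait="t",
            founder_count=10, polycross_size=10, n_families=2, n_mothers=2,
            progeny_per_family=2, seed=5,
        )
        rng = np.random.default_rng(5)
        genome, haplos = sim.simulate_founders(cfg, rng=rng)
        codes = (
            haplos[:, 0, genome.marker_index].astype(float)
            + haplos[:, 1, genome.marker_index] - 1
        )
        g = pg.GenotypeMatrix(
            [f"i{i}" for i in range(400)], ["X"] * 400, list(genome.marker_ids), codes
        )
        decay = popgen.pairwise_ld(g, genome.marker_map(), 1)
        far = decay.r2[decay.distance_cm > 20]
        # linkage-equilibrium founders: r2 is pure sampling noise ~ 1/n
        assert far.mean() < 3.0 / 400

    def test_same_seed_identical_founders(self, tiny_config):
        g1, h1 = sim.simulate_founders(tiny_config)
        g2, h2 = sim.simulate_founders(tiny_config)
        np.testing.assert_array_equal(h1, h2)
        assert g1.marker_ids == g2.marker_ids


class TestPolycross:
    def _parents(self, rng, n=6, loci=30):
        return (rng.random((n, 2, loci)) < 0.5).astype(np.uint8)

    def _genome(self, loci=30):
        return sim.Genome(
            chrom_lengths=np.array([1.0]),
            locus_chrom=np.zeros(loci, int),
            locus_pos=np.linspace(0, 1, loci),
            marker_index=np.arange(loci),
            marker_ids=[f"m{i}" for i in range(loci)],
        )

    def test_single_parent_rejected(self, rng):
        with pytest.raises(ValueError, match="selfing"):
            sim.polycross(self._parents(rng, n=1), self._genome(), 4, rng)

    def test_two_parent_cross_uses_both(self, rng):
        parents = self._parents(rng, n=2)
        # make parents distinguishable: fix all loci
        parents[0] = 1
        parents[1] = 0
        genome = self._genome()
        off, mothers = sim.polycross(parents, genome, 10, rng)
        # one gamete all-ones (from parent 0), one all-zeros (from parent 1)
        sums = np.sort(off.sum(axis=2), axis=1)
        assert (sums[:, 0] == 0).all() and (sums[:, 1] == genome.n_loci).all()

    def test_half_sib_relatedness_exceeds_background(self, rng):
        # half sibs share the mother: genomic relationship ~0.25 above unrelated
        parents = (rng.random((40, 2, 400)) < 0.5).astype(np.uint8)
        genome = self._genome(400)
        mothers = np.repeat(np.arange(4), 50)
        off, fam = sim.polycross(parents, genome, 200, rng, mothers=mothers)
        codes = off[:, 0].astype(float) + off[:, 1] - 1.0
        codes -= codes.mean(axis=0)
        gmat = codes @ codes.T / (codes.var(axis=0).sum() + 1e-12)
        same = fam[:, None] == fam[None, :]
        off_diag = ~np.eye(200, dtype=bool)
        within = gmat[same & off_diag].mean()
        between = gmat[~same].mean()
        assert within - between == pytest.approx(0.25, abs=0.1)

    def test_determinism_under_seed(self):
        rng1, rng2 = np.random.default_rng(3), np.random.default_rng(3)
        parents = (np.random.default_rng(0).random((5, 2, 30)) < 0.5).astype(np.uint8)
        genome = self._genome()
        o1, m1 = sim.polycross(parents, genome, 12, rng1)
        o2, m2 = sim.polycross(parents, genome, 12, rng2)
        np.testing.assert_array_equal(o1, o2)
        np.testing.assert_array_equal(m1, m2)


class TestSwardPhenotype:
    def _setup(self, h2, rng, n_mothers=60, env_variance=None):
        cfg = sim.SimulationConfig(
            n_chromosomes=2, chromosome_length=1.0, n_markers=30, n_qtl=25,
            effective_size=120, burn_in=0, founder_count=120, polycross_size=120,
            n_families=4, n_mothers=n_mothers, progeny_per_family=12, n_plots=4,
            trait_h2={"t": h2}, selection_trait="t", seed=0,
        )
        genome, archs = sim.build_genome(cfg, rng)
        if env_variance is not None:
            archs["t"].env_variance = env_variance
        freqs = rng.uniform(0.1, 0.9, genome.n_loci)
        pool = (rng.random((120, 2, genome.n_loci)) < freqs).astype(np.uint8)
        midx = rng.choice(120, n_mothers, replace=False)
        return cfg, genome, archs, pool, midx

    def test_null_heritability_gives_pure_noise(self, rng):
        cfg, genome, archs, pool, midx = self._setup(0.0, rng)
        fam, plots, _, _ = sim.sward_phenotype(
            pool[midx], pool, genome, archs, cfg, rng, mother_pool_index=midx
        )
        vals = plots["t"].ravel()
        fams = np.repeat(np.arange(len(midx)), cfg.n_plots)
        assert popgen.heritability_anova(vals, fams).h2 < 0.15

    def test_zero_noise_reproduces_family_genetic_mean(self, rng):
        cfg, genome, archs, pool, midx = self._setup(0.5, rng, env_variance=0.0)
        fam, plots, progeny, pfam = sim.sward_phenotype(
            pool[midx], pool, genome, archs, cfg, rng, mother_pool_index=midx
        )
        bv = sim.breeding_values(progeny, archs["t"])
        expected = bv.reshape(len(midx), cfg.progeny_per_family).mean(axis=1)
        np.testing.assert_allclose(fam["t"], expected, atol=1e-12)
        np.testing.assert_allclose(
            plots["t"], np.tile(expected[:, None], (1, cfg.n_plots)), atol=1e-12
        )

    def test_high_heritability_recovered_by_anova(self):
        ests = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            cfg, genome, archs, pool, midx = self._setup(0.9, rng, n_mothers=100)
            _, plots, _, _ = sim.sward_phenotype(
                pool[midx], pool, genome, archs, cfg, rng, mother_pool_index=midx
            )
            fams = np.repeat(np.arange(100), cfg.n_plots)
            ests.append(popgen.heritability_anova(plots["t"].ravel(), fams).h2)
        assert abs(float(np.median(ests)) - 0.9) < 0.1

    def test_missing_architecture_rejected(self, rng):
        cfg, genome, archs, pool, midx = self._setup(0.5, rng)
        with pytest.raises(ValueError, match="architecture"):
            sim.sward_phenotype(pool[midx], pool, genome, {}, cfg, rng)


class TestProgram:
    def test_codes_in_signed_set_and_counts_match(self, tiny_dataset, tiny_config):
        g = tiny_dataset.genotypes
        vals = g.codes[~np.isnan(g.codes)]
        assert set(np.unique(vals)) <= {-1.0, 0.0, 1.0}
        from collections import Counter

        counts = Counter(g.generation_labels)
        for lineage, labels in tiny_config.generations.items():
            for lab in labels:
                assert counts[lab] == tiny_config.mothers_for(lab)

    def test_deterministic_under_config_seed(self, tiny_config):
        d1 = sim.simulate_program(tiny_config)
        d2 = sim.simulate_program(tiny_config)
        np.testing.assert_array_equal(d1.genotypes.codes, d2.genotypes.codes)
        assert d1.phenotypes.equals(d2.phenotypes)
        assert d1.true_breeding_values.equals(d2.true_breeding_values)

    def test_truth_record_complete(self, tiny_dataset, tiny_config):
        tbv = tiny_dataset.true_breeding_values
        assert set(tbv["trait"]) == set(tiny_config.trait_h2)
        assert len(tbv) == tiny_dataset.genotypes.n_individuals * len(
            tiny_config.trait_h2
        )
        qtl = tiny_dataset.qtl_effects
        assert len(qtl) == tiny_config.n_qtl * len(tiny_config.trait_h2)
        assert np.isfinite(qtl["effect"]).all()

    def test_phenotypes_correlate_with_true_breeding_values(self, tiny_dataset):
        # family mean vs mother TBV: positive and roughly sqrt(h2)-sized
        ph = tiny_dataset.phenotypes
        tbv = tiny_dataset.true_breeding_values
        merged = ph.merge(tbv, on=["individual_id", "generation", "trait"])
        sub = merged[merged["trait"] == "wsc"]
        r = np.corrcoef(sub["value"], sub["true_breeding_value"])[0, 1]
        assert r > 0.2

    def test_drift_without_selection_has_no_directional_trend(self):
        changes = []
        for seed in range(10):
            cfg = sim.SimulationConfig(
                n_markers=60, n_qtl=5, effective_size=60, burn_in=10,
                polycross_size=40, n_families=3, n_mothers=10, progeny_per_family=6,
                trait_h2={"t": 0.3}, selection_trait=None,
                generations={"A": ["g1", "g2", "g3"]}, seed=seed,
            )
            data = sim.simulate_program(cfg)
            from polygs import allele_frequency

            g = data.genotypes
            first = g.select_generations(["g1"])
            last = g.select_generations(["g3"])
            changes.append(
                float(np.mean(allele_frequency(last) - allele_frequency(first)))
            )
        assert abs(float(np.mean(changes))) < 0.02

    def test_unknown_label_in_mother_counts_rejected(self):
        with pytest.raises(ValueError, match="nope"):
            sim.SimulationConfig(
                trait_h2={"t": 0.3}, selection_trait="t",
                mothers_per_generation={"nope": 10},
            )

    def test_dataset_round_trips_through_files(self, tiny_dataset, tmp_path):
        tiny_dataset.write(tmp_path)
        g = pg.read_genotypes(tmp_path / "genotypes.tsv")
        np.testing.assert_array_equal(g.codes, tiny_dataset.genotypes.codes)
        m = pg.read_map(tmp_path / "map.tsv")
        assert m.marker_ids == tiny_dataset.marker_map.marker_ids
        ph = pg.read_phenotypes(tmp_path / "phenotypes.tsv")
        assert len(ph) == len(tiny_dataset.phenotypes)
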