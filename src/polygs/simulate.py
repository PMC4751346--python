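"""Forward simulator for a polycross recurrent-selection breeding program.

The generator reproduces the statistical structure the downstream
analysis assumes, for a perennial outbreeding forage crop:

* a 7-chromosome genome (~8 Morgans) carrying mapped SNP markers and
  per-trait QTL, with meiosis under the Haldane model (Poisson crossover
  counts, uniform positions, no interference, free assortment);
* background linkage disequilibrium from finite-population drift: founder
  haplotypes start in linkage equilibrium and are random-mated at a
  configurable effective size until LD at marker spacing equilibrates
  toward Sved's expectation r^2 = 1/(4 Ne c + 1);
* two independently founded lineages (an "Intermediate" and a "Late"
  flowering population) whose divergence comes from independent founder
  draws plus drift;
* recurrent selection cycles: a polycross of several hundred parents
  drawn from a few half-sib families, ~100 mother-plants whose
  open-pollinated progeny are evaluated as replicated sward plots, and
  family selection on a designated index trait;
* purely additive traits (many small QTL) whose plot noise is calibrated
  analytically so the one-way-ANOVA broad-sense heritability of the
  half-sib family data matches a per-trait target.

Everything is deterministic under ``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, MarkerMap

__all__ = [
    "SimulationConfig",
    "Genome",
    "HaplotypePair",
    "TraitArchitecture",
    "SimulatedDataset",
    "default_trait_h2",
    "paper_shape_config",
    "build_genome",
    "draw_architectures",
    "simulate_founders",
    "meiosis",
    "random_mate",
    "polycross",
    "breeding_values",
    "sward_phenotype",
    "simulate_program",
]


def default_trait_h2() -> dict[str, float]:
    """Eleven forage traits with target broad-sense heritabilities.

    Yield traits (total/conservation-cut/vegetative yield, ground-cover
    score; year-specific) sit low, quality traits (digestibility,
    nitrogen, water-soluble carbohydrate) higher — the canonical pattern
    for half-sib sward trials in ryegrass.
    """
    return {
        "totaly7c_yr1": 0.21,
        "totaly7c_yr2": 0.14,
        "conscuty_yr1": 0.17,
        "conscuty_yr2": 0.17,
        "vegyld_yr1": 0.25,
        "vegyld_yr2": 0.15,
        "gcscore_yr1": 0.22,
        "gcscore_yr2": 0.26,
        "dmd": 0.35,
        "n": 0.24,
        "wsc": 0.35,
    }


@dataclass
class SimulationConfig:
    """Full parameterization of the breeding-program generator.

    Lengths are Morgans.  ``generations`` maps each lineage name to the
    ordered labels of its explicit selection cycles; burn-in drift at
    ``effective_size`` stands in for the unobserved earlier cycles.
    ``mothers_per_generation`` overrides ``n_mothers`` per label, letting
    a dataset mirror the genotyped counts of a real program.
    """

    n_chromosomes: int = 7
    chromosome_length: float = 8.0 / 7.0
    n_markers: int = 1670
    n_qtl: int = 200
    founder_count: int = 10
    effective_size: int = 400
    burn_in: int = 250
    polycross_size: int = 400
    n_families: int = 5
    n_mothers: int = 100
    progeny_per_family: int = 50
    n_plots: int = 4
    trait_h2: dict[str, float] = field(default_factory=default_trait_h2)
    selection_trait: str | None = "totaly7c_yr1"
    generations: dict[str, list[str]] = field(
        default_factory=lambda: {
            "Intermediate": ["F11", "F12", "F13", "F14"],
            "Late": ["F5"],
        }
    )
    mothers_per_generation: dict[str, int] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        counts = [
            self.n_chromosomes,
            self.n_markers,
            self.n_qtl,
            self.founder_count,
            self.effective_size,
            self.polycross_size,
            self.n_families,
            self.n_mothers,
            self.progeny_per_family,
            self.n_plots,
        ]
        if any(c <= 0 for c in counts):
            raise ValueError("all population/genome counts must be positive")
        if self.chromosome_length <= 0:
            raise ValueError("chromosome_length must be positive")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        if self.founder_count < 2:
            raise ValueError("need at least 2 founders (outbreeding)")
        for t, h2 in self.trait_h2.items():
            if not 0 <= h2 < 1:
                raise ValueError(f"trait_h2[{t!r}] must be in [0, 1), got {h2}")
        labels = [g for labs in self.generations.values() for g in labs]
        if len(labels) != len(set(labels)):
            raise ValueError("generation labels must be unique across lineages")
        for lab in self.mothers_per_generation:
            if lab not in labels:
                raise ValueError(
                    f"mothers_per_generation label {lab!r} not in any lineage schedule"
                )
        if self.selection_trait is not None and self.selection_trait not in self.trait_h2:
            raise ValueError(f"selection trait {self.selection_trait!r} has no h2")
        if self.n_families > self.n_mothers:
            raise ValueError("n_families cannot exceed n_mothers")
        if self.n_mothers > self.polycross_size:
            raise ValueError("n_mothers cannot exceed polycross_size")

    @property
    def genome_length(self) -> float:
        return self.n_chromosomes * self.chromosome_length

    def mothers_for(self, label: str) -> int:
        return self.mothers_per_generation.get(label, self.n_mothers)


def paper_shape_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Config mirroring the genotyped mother counts of the motivating
    breeding program: F11/F12/F13/F14 = 119/86/54/100 Intermediate
    mothers (so F11+F12+F13 = 259) and 105 Late F5 mothers (total 364
    across training generations)."""
    kwargs = dict(
        mothers_per_generation={"F11": 119, "F12": 86, "F13": 54, "F14": 100, "F5": 105},
        seed=seed,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


def config_from_yaml(path) -> SimulationConfig:
    """Load a SimulationConfig from a YAML mapping of its field names."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return SimulationConfig(**data)


def config_to_yaml(config: SimulationConfig, path) -> None:
    import dataclasses

    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# genome and haplotypes


@dataclass
class Genome:
    """Marker + QTL loci laid out on chromosomes (positions in Morgans,
    measured from each chromosome start, sorted within chromosome)."""

    chrom_lengths: np.ndarray
    locus_chrom: np.ndarray
    locus_pos: np.ndarray
    marker_index: np.ndarray
    marker_ids: list[str]

    @property
    def n_loci(self) -> int:
        return self.locus_pos.size

    def blocks(self):
        """Yield (slice, length_morgans, positions) per chromosome."""
        for c, length in enumerate(self.chrom_lengths):
            lo = int(np.searchsorted(self.locus_chrom, c, side="left"))
            hi = int(np.searchsorted(self.locus_chrom, c, side="right"))
            yield slice(lo, hi), float(length), self.locus_pos[lo:hi]

    def marker_map(self) -> MarkerMap:
        return MarkerMap(
            list(self.marker_ids),
            self.locus_chrom[self.marker_index] + 1,
            self.locus_pos[self.marker_index] * 100.0,
        )

    @classmethod
    def from_marker_map(cls, marker_map: MarkerMap) -> "Genome":
        """Marker-only genome from a genetic map (for meiosis on real maps)."""
        df = marker_map.to_frame().sort_values(
            ["chromosome", "position_cm", "marker_id"], kind="stable"
        )
        chroms = np.sort(df["chromosome"].unique())
        remap = {c: i for i, c in enumerate(chroms)}
        locus_chrom = df["chromosome"].map(remap).to_numpy()
        locus_pos = df["position_cm"].to_numpy() / 100.0
        lengths = np.array(
            [max(locus_pos[locus_chrom == i].max(), 1e-6) for i in range(len(chroms))]
        )
        return cls(
            chrom_lengths=lengths,
            locus_chrom=locus_chrom,
            locus_pos=locus_pos,
            marker_index=np.arange(len(df)),
            marker_ids=df["marker_id"].tolist(),
        )


@dataclass
class HaplotypePair:
    """Two binary haplotypes of one individual over all loci.

    The additive genotype code at a locus is ``h1 + h2 - 1``.
    """

    h1: np.ndarray
    h2: np.ndarray

    def __post_init__(self) -> None:
        self.h1 = np.asarray(self.h1, dtype=np.uint8)
        self.h2 = np.asarray(self.h2, dtype=np.uint8)
        if self.h1.shape != self.h2.shape:
            raise ValueError("haplotypes differ in length")

    @property
    def codes(self) -> np.ndarray:
        return self.h1.astype(np.int8) + self.h2.astype(np.int8) - 1

    def as_array(self) -> np.ndarray:
        return np.stack([self.h1, self.h2])[None, :, :]


@dataclass
class TraitArchitecture:
    """Additive QTL model of one trait.

    ``env_variance`` (optional) fixes the noise variance on the family
    mean directly; when None, plot noise is calibrated from the target
    heritability at phenotyping time.
    """

    trait: str
    locus_index: np.ndarray
    effects: np.ndarray
    env_variance: float | None = None

    def __post_init__(self) -> None:
        if len(self.locus_index) != len(self.effects):
            raise ValueError("QTL index and effect lengths differ")
        if not np.isfinite(self.effects).all():
            raise ValueError("non-finite QTL effect")


def build_genome(config: SimulationConfig, rng: np.random.Generator):
    """Lay out markers and per-trait QTL uniformly on the chromosomes.

    Returns ``(genome, architectures)``; QTL effects are N(0, 1/n_qtl)
    so true breeding values are O(1) regardless of QTL count.
    """
    n_c = config.n_chromosomes
    per = np.full(n_c, config.n_markers // n_c)
    per[: config.n_markers % n_c] += 1

    chroms, poss, kinds = [], [], []  # kind: -1 marker, t>=0 trait index
    traits = list(config.trait_h2)
    for c in range(n_c):
        chroms.append(np.full(per[c], c))
        poss.append(np.sort(rng.uniform(0.0, config.chromosome_length, per[c])))
        kinds.append(np.full(per[c], -1))
    for t in range(len(traits)):
        qc = rng.integers(0, n_c, config.n_qtl)
        qp = rng.uniform(0.0, config.chromosome_length, config.n_qtl)
        chroms.append(qc)
        poss.append(qp)
        kinds.append(np.full(config.n_qtl, t))
    chrom = np.concatenate(chroms)
    pos = np.concatenate(poss)
    kind = np.concatenate(kinds)
    order = np.lexsort((pos, chrom))
    chrom, pos, kind = chrom[order], pos[order], kind[order]

    marker_index = np.flatnonzero(kind == -1)
    marker_ids = []
    counter = {}
    for li in marker_index:
        c = int(chrom[li]) + 1
        counter[c] = counter.get(c, 0) + 1
        marker_ids.append(f"M{c}_{counter[c]:04d}")
    genome = Genome(
        chrom_lengths=np.full(n_c, config.chromosome_length),
        locus_chrom=chrom,
        locus_pos=pos,
        marker_index=marker_index,
        marker_ids=marker_ids,
    )
    archs = draw_architectures(config, genome, kind, rng)
    return genome, archs


def draw_architectures(config, genome, kind, rng) -> dict[str, TraitArchitecture]:
    traits = list(config.trait_h2)
    archs = {}
    scale = 1.0 / np.sqrt(config.n_qtl)
    for t, trait in enumerate(traits):
        idx = np.flatnonzero(kind == t)
        effects = rng.normal(0.0, scale, idx.size)
        archs[trait] = TraitArchitecture(trait, idx, effects)
    return archs


# ---------------------------------------------------------------------------
# meiosis and mating


def _gametes(haplos: np.ndarray, genome: Genome, parent_idx: np.ndarray, rng) -> np.ndarray:
    """One recombinant gamete per entry of ``parent_idx`` (vectorized).

    Crossover counts are Poisson(chromosome length in Morgans), positions
    uniform, no interference; chromosomes assort independently via an
    independent random start phase per chromosome.
    """
    parent_idx = np.asarray(parent_idx)
    n_g = parent_idx.size
    out = np.empty((n_g, genome.n_loci), dtype=np.uint8)
    ph = haplos[parent_idx]
    for sl, length, pos in genome.blocks():
        if sl.stop == sl.start:
            continue
        start = rng.integers(0, 2, n_g, dtype=np.uint8)
        k = rng.poisson(length, n_g)
        kmax = int(k.max()) if n_g else 0
        if kmax == 0:
            parity = np.broadcast_to(start[:, None], (n_g, sl.stop - sl.start))
        else:
            x = rng.uniform(0.0, length, (n_g, kmax))
            x[np.arange(kmax)[None, :] >= k[:, None]] = np.inf
            x.sort(axis=1)
            n_before = (x[:, :, None] < pos[None, None, :]).sum(axis=1)
            parity = (start[:, None] + n_before) & 1
        seg = ph[:, :, sl]
        out[:, sl] = np.where(parity == 0, seg[:, 0, :], seg[:, 1, :])
    return out


def meiosis(parent: HaplotypePair, genome: Genome, rng) -> np.ndarray:
    """Single recombinant gamete from one parent (Haldane model)."""
    return _gametes(parent.as_array(), genome, np.array([0]), rng)[0]


def random_mate(haplos: np.ndarray, genome: Genome, n_offspring: int, rng) -> np.ndarray:
    """One generation of random mating without selfing at fixed census size."""
    n = haplos.shape[0]
    if n < 2:
        raise ValueError("need at least 2 parents")
    mothers = rng.integers(0, n, n_offspring)
    fathers = (mothers + 1 + rng.integers(0, n - 1, n_offspring)) % n
    mat = _gametes(haplos, genome, mothers, rng)
    pat = _gametes(haplos, genome, fathers, rng)
    return np.stack([mat, pat], axis=1)


def simulate_founders(config: SimulationConfig, rng=None, genome: Genome | None = None):
    """Founder population with map-consistent background LD.

    Haplotypes start in linkage equilibrium with per-locus allele
    frequencies uniform on [0.1, 0.9], then random-mate at census size
    ``effective_size`` for ``burn_in`` generations so drift builds LD
    toward Sved's expectation at the configured Ne.  Returns
    ``(genome, haplotypes)`` of shape (effective_size, 2, n_loci).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if genome is None:
        genome, _ = build_genome(config, rng)
    freqs = rng.uniform(0.1, 0.9, genome.n_loci)
    haplos = (
        rng.random((config.effective_size, 2, genome.n_loci)) < freqs
    ).astype(np.uint8)
    for _ in range(config.burn_in):
        haplos = random_mate(haplos, genome, config.effective_size, rng)
    return genome, haplos


def polycross(
    parents: np.ndarray,
    genome: Genome,
    n_offspring: int,
    rng,
    mothers: np.ndarray | None = None,
):
    """Open intermating of a parent panel, no selfing.

    Each offspring receives a maternal gamete from its assigned mother
    (by default mothers cycle through the panel evenly) and a paternal
    gamete from a panel member drawn uniformly excluding the mother.
    Returns ``(offspring, mother_assignment)``.
    """
    n = parents.shape[0]
    if n < 2:
        raise ValueError("polycross needs at least 2 parents (selfing excluded)")
    if mothers is None:
        mothers = np.arange(n_offspring) % n
    else:
        mothers = np.asarray(mothers)
        if mothers.size != n_offspring:
            raise ValueError("one mother assignment per offspring required")
    fathers = (mothers + 1 + rng.integers(0, n - 1, n_offspring)) % n
    mat = _gametes(parents, genome, mothers, rng)
    pat = _gametes(parents, genome, fathers, rng)
    return np.stack([mat, pat], axis=1), mothers


def breeding_values(haplos: np.ndarray, arch: TraitArchitecture) -> np.ndarray:
    """Additive genetic values: QTL codes (h1+h2-1) dotted with effects."""
    codes = (
        haplos[:, 0, arch.locus_index].astype(np.int16)
        + haplos[:, 1, arch.locus_index]
        - 1
    )
    return codes @ arch.effects


# ---------------------------------------------------------------------------
# phenotyping


def sward_phenotype(
    mothers: np.ndarray,
    pollen_pool: np.ndarray,
    genome: Genome,
    architectures: dict[str, TraitArchitecture],
    config: SimulationConfig,
    rng,
    mother_pool_index: np.ndarray | None = None,
):
    """Half-sib family sward phenotypes for a panel of mother plants.

    For each mother, ``progeny_per_family`` progeny are simulated with
    paternal gametes from the polycross pollen pool (excluding the mother
    herself when ``mother_pool_index`` locates her in the pool); the
    family genetic value is the mean progeny breeding value.  Each of
    ``n_plots`` plots adds independent noise whose variance is calibrated
    so the plot-level one-way-ANOVA heritability equals the trait's
    target h2 in expectation (a target of 0 yields pure noise; a fixed
    ``env_variance`` of 0 reproduces the family genetic mean exactly).

    Returns ``(family_values, plot_values, progeny, progeny_family)``;
    the first two map trait -> arrays of shape (n_mothers,) and
    (n_mothers, n_plots), the family value being the mean over plots.
    """
    for trait in config.trait_h2:
        if trait not in architectures:
            raise ValueError(f"trait {trait!r} has no architecture")
    n_m = mothers.shape[0]
    n_pool = pollen_pool.shape[0]
    fam = np.repeat(np.arange(n_m), config.progeny_per_family)

    mat = _gametes(mothers, genome, fam, rng)
    if mother_pool_index is not None:
        own = np.asarray(mother_pool_index)[fam]
        sires = (own + 1 + rng.integers(0, n_pool - 1, fam.size)) % n_pool
    else:
        sires = rng.integers(0, n_pool, fam.size)
    pat = _gametes(pollen_pool, genome, sires, rng)
    progeny = np.stack([mat, pat], axis=1)

    family_values, plot_values = {}, {}
    for trait, h2 in config.trait_h2.items():
        arch = architectures[trait]
        bv = breeding_values(progeny, arch)
        g_fam = bv.reshape(n_m, config.progeny_per_family).mean(axis=1)
        s2 = float(np.var(g_fam, ddof=1)) if n_m > 1 else 0.0
        if s2 == 0.0:
            s2 = 1.0
        if arch.env_variance is not None:
            plot_var = arch.env_variance * config.n_plots
        elif h2 == 0.0:
            g_fam = np.zeros(n_m)
            plot_var = s2
        else:
            plot_var = s2 * (1.0 - h2) / h2
        noise = rng.normal(0.0, np.sqrt(plot_var), (n_m, config.n_plots)) \
            if plot_var > 0 else np.zeros((n_m, config.n_plots))
        plots = g_fam[:, None] + noise
        family_values[trait] = plots.mean(axis=1)
        plot_values[trait] = plots
    return family_values, plot_values, progeny, fam


# ---------------------------------------------------------------------------
# whole-program simulation


@dataclass
class SimulatedDataset:
    """Everything a breeding-program evaluation consumes, plus the truth."""

    genotypes: GenotypeMatrix
    marker_map: MarkerMap
    phenotypes: pd.DataFrame
    plot_phenotypes: pd.DataFrame
    qtl_effects: pd.DataFrame
    true_breeding_values: pd.DataFrame
    config: SimulationConfig

    def write(self, outdir, sep: str = "\t") -> None:
        from pathlib import Path

        from .genotype_io import write_genotypes, write_map, write_phenotypes

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_genotypes(self.genotypes, out / "genotypes.tsv", sep=sep)
        write_map(self.marker_map, out / "map.tsv", sep=sep)
        write_phenotypes(self.phenotypes, out / "phenotypes.tsv", sep=sep)
        write_phenotypes(self.plot_phenotypes, out / "phenotypes_plots.tsv", sep=sep)
        self.qtl_effects.to_csv(out / "truth_qtl_effects.tsv", sep=sep, index=False)
        self.true_breeding_values.to_csv(
            out / "truth_breeding_values.tsv", sep=sep, index=False
        )


def _run_lineage(
    lineage: str,
    labels: list[str],
    genome: Genome,
    architectures: dict[str, TraitArchitecture],
    config: SimulationConfig,
    rng,
):
    """Burn-in founding followed by one labeled selection cycle per label."""
    _, base = simulate_founders(config, rng=rng, genome=genome)
    founders = base[rng.choice(base.shape[0], config.founder_count, replace=False)]
    parents, _ = polycross(founders, genome, config.polycross_size, rng)

    geno_rows, pheno_rows, plot_rows, tbv_rows = [], [], [], []
    for label in labels:
        n_m = config.mothers_for(label)
        if n_m > parents.shape[0]:
            raise ValueError(
                f"{label!r}: {n_m} mothers requested from {parents.shape[0]} parents"
            )
        midx = rng.choice(parents.shape[0], n_m, replace=False)
        mothers = parents[midx]
        fam_vals, plot_vals, progeny, fam = sward_phenotype(
            mothers, parents, genome, architectures, config, rng,
            mother_pool_index=midx,
        )
        ids = [f"{label}_{i + 1:03d}" for i in range(n_m)]
        codes = (
            mothers[:, 0, genome.marker_index].astype(np.int8)
            + mothers[:, 1, genome.marker_index]
            - 1
        )
        geno_rows.append((ids, label, codes))
        for trait in config.trait_h2:
            vals = fam_vals[trait]
            tbv = breeding_values(mothers, architectures[trait])
            for i, iid in enumerate(ids):
                pheno_rows.append((iid, label, trait, vals[i]))
                tbv_rows.append((iid, label, trait, tbv[i]))
            plots = plot_vals[trait]
            for i, iid in enumerate(ids):
                for p in range(config.n_plots):
                    plot_rows.append((iid, label, trait, p + 1, plots[i, p]))

        # family selection for the next cycle's polycross parents
        if config.selection_trait is not None:
            order = np.argsort(-fam_vals[config.selection_trait], kind="stable")
            best = order[: config.n_families]
        else:
            best = rng.choice(n_m, config.n_families, replace=False)
        per_family = -(-config.polycross_size // config.n_families)  # ceil
        next_parents = []
        for b in best:
            members = progeny[fam == b]
            if members.shape[0] >= per_family:
                take = rng.choice(members.shape[0], per_family, replace=False)
                next_parents.append(members[take])
            else:
                extra_n = per_family - members.shape[0]
                extra, _ = _extra_progeny(
                    mothers, parents, genome, int(b), int(midx[b]), extra_n, rng
                )
                next_parents.append(np.concatenate([members, extra]))
        parents = np.concatenate(next_parents)[: config.polycross_size]
    return geno_rows, pheno_rows, plot_rows, tbv_rows


def _extra_progeny(mothers, pool, genome, mother_row, mother_pool_idx, n, rng):
    """Additional half-sib progeny for one mother (top-up for selection)."""
    fam = np.full(n, mother_row)
    mat = _gametes(mothers, genome, fam, rng)
    sires = (mother_pool_idx + 1 + rng.integers(0, pool.shape[0] - 1, n)) % pool.shape[0]
    pat = _gametes(pool, genome, sires, rng)
    return np.stack([mat, pat], axis=1), fam


def simulate_program(config: SimulationConfig) -> SimulatedDataset:
    """Run the full two-lineage recurrent-selection program.

    Each lineage is independently founded (divergence = independent
    founder draws + drift) and cycled through its labeled generations;
    mother-plant genotypes, half-sib family phenotypes (family means and
    plot-level), QTL effects and true breeding values are emitted.
    """
    ss = np.random.SeedSequence(config.seed)
    genome_seed, *lineage_seeds = ss.spawn(1 + len(config.generations))
    genome_rng = np.random.default_rng(genome_seed)
    genome, architectures = build_genome(config, genome_rng)

    geno_rows, pheno_rows, plot_rows, tbv_rows = [], [], [], []
    for (lineage, labels), lseed in zip(config.generations.items(), lineage_seeds):
        rng = np.random.default_rng(lseed)
        g, p, pl, t = _run_lineage(lineage, labels, genome, architectures, config, rng)
        geno_rows += g
        pheno_rows += p
        plot_rows += pl
        tbv_rows += t

    ids = [i for block in geno_rows for i in block[0]]
    gens = [block[1] for block in geno_rows for _ in block[0]]
    codes = np.concatenate([block[2] for block in geno_rows]).astype(float)
    genotypes = GenotypeMatrix(ids, gens, list(genome.marker_ids), codes)

    phenotypes = pd.DataFrame(
        pheno_rows, columns=["individual_id", "generation", "trait", "value"]
    )
    plot_phenotypes = pd.DataFrame(
        plot_rows, columns=["individual_id", "generation", "trait", "plot", "value"]
    )
    tbv = pd.DataFrame(
        tbv_rows, columns=["individual_id", "generation", "trait", "true_breeding_value"]
    )
    qtl_rows = []
    for trait, arch in architectures.items():
        for q, (li, eff) in enumerate(zip(arch.locus_index, arch.effects)):
            qtl_rows.append(
                {
                    "trait": trait,
                    "qtl_id": f"{trait}_Q{q + 1:03d}",
                    "chromosome": int(genome.locus_chrom[li]) + 1,
                    "position_cm": genome.locus_pos[li] * 100.0,
                    "effect": eff,
                }
            )
    qtl_effects = pd.DataFrame(qtl_rows)
    return SimulatedDataset(
        genotypes=genotypes,
        marker_map=genome.marker_map(),
        phenotypes=phenotypes,
        plot_phenotypes=plot_phenotypes,
        qtl_effects=qtl_effects,
        true_breeding_values=tbv,
        config=config,
    )
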