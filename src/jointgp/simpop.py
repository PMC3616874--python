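"""Forward-in-time simulator of two related dairy-cattle populations.

The generator stands in for a pair of Holstein populations: a small
population ("A") with a handful of progeny-tested bulls and large half-sib
cow families, and a large bull population ("B"), the two sharing ancestry a
configurable number of generations back.  Linkage disequilibrium arises from
drift during a burn-in phase of random mating at effective size Ne; the two
populations then diverge by drift from a common base.  A polygenic trait is
placed on the markers as two correlated population-traits (the same
biological trait expressed in each population), phenotypes are released as
deregressed proofs (DRP) with a prescribed reliability, and selection on
true breeding values over birth-year cohorts produces a genetic trend.

All randomness flows through :class:`numpy.random.Generator` objects; the
same config and seed reproduce output bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "SimConfig",
    "HaplotypeSet",
    "TrueValues",
    "simulate_base_population",
    "split_and_diverge",
    "assign_trait_architecture",
    "build_family_structure",
    "breed_bull_cohorts",
    "generate_drp",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the two-population simulation.

    ``chrom_length_morgans`` is the genetic length per chromosome; markers
    are equally spaced on the genetic map and physical positions follow the
    1 Mb/cM convention.  ``trend_per_year`` is expressed in genetic standard
    deviations per birth year.
    """

    n_chromosomes: int = 2
    chrom_length_morgans: float = 1.0
    n_markers_per_chrom: int = 500
    effective_size_ne: int = 100
    n_burnin_generations: int = 200
    n_divergence_generations: int = 10
    split_sizes: tuple[int, int] = (50, 50)
    n_qtl: int = 300
    h2: float = 0.3
    cross_pop_genetic_correlation: float = 0.8
    trend_per_year: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.n_markers_per_chrom < 1:
            raise ValueError("need at least one chromosome and one marker")
        if self.effective_size_ne < 2:
            raise ValueError("effective_size_ne must be >= 2")
        if self.n_burnin_generations < 0 or self.n_divergence_generations < 0:
            raise ValueError("generation counts must be non-negative")
        if not (0.0 < self.h2 <= 1.0):
            raise ValueError("h2 must be in (0, 1]")
        if abs(self.cross_pop_genetic_correlation) > 1.0:
            raise ValueError("|cross_pop_genetic_correlation| must be <= 1")
        if self.n_qtl < 1 or self.n_qtl > self.n_markers:
            raise ValueError("n_qtl must be in [1, total marker count]")
        if min(self.split_sizes) < 0:
            raise ValueError("split sizes must be non-negative")
        if self.chrom_length_morgans <= 0:
            raise ValueError("chromosome length must be positive")

    @property
    def n_markers(self) -> int:
        return self.n_chromosomes * self.n_markers_per_chrom

    def marker_map(self) -> pd.DataFrame:
        """Equally spaced marker map: chrom, genetic position (Morgans), bp."""
        rows = []
        m = self.n_markers_per_chrom
        spacing = self.chrom_length_morgans / max(m - 1, 1)
        for c in range(1, self.n_chromosomes + 1):
            morgans = np.arange(m) * spacing
            rows.append(
                pd.DataFrame(
                    {
                        "chrom": c,
                        "marker_id": [f"chr{c}_snp{i + 1}" for i in range(m)],
                        "cm": morgans * 100.0,
                        # 1 Mb per cM, 1-based
                        "pos": (morgans * 100.0 * 1_000_000).round().astype(np.int64) + 1,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def recombination_fractions(self) -> np.ndarray:
        """Adjacent-interval recombination fractions (Haldane), length m-1.

        Intervals spanning a chromosome boundary get c = 0.5 (independent
        assortment), so a single pass down the concatenated map simulates a
        whole-genome meiosis.
        """
        m = self.n_markers_per_chrom
        d = self.chrom_length_morgans / max(m - 1, 1)
        c_within = 0.5 * (1.0 - np.exp(-2.0 * d))
        c = np.full(self.n_markers - 1, c_within)
        for k in range(1, self.n_chromosomes):
            c[k * m - 1] = 0.5
        return c


@dataclass
class HaplotypeSet:
    """Phased haplotypes for one population.

    ``haplotypes`` has shape (n_animals, 2, n_markers) with alleles coded
    0/1; ``marker_map`` columns: chrom, marker_id, cm, pos (bp, 1-based,
    strictly increasing within chromosome).
    """

    population: str
    animal_ids: list[str]
    haplotypes: np.ndarray
    marker_map: pd.DataFrame

    def __post_init__(self) -> None:
        n, two, m = self.haplotypes.shape
        if two != 2:
            raise ValueError("each animal must carry exactly 2 haplotypes")
        if n != len(self.animal_ids):
            raise ValueError("animal_ids length does not match haplotypes")
        if m != len(self.marker_map):
            raise ValueError("marker_map length does not match haplotypes")
        for _, grp in self.marker_map.groupby("chrom"):
            if not grp["pos"].is_monotonic_increasing or grp["pos"].duplicated().any():
                raise ValueError("bp positions must be strictly increasing within chromosome")

    @property
    def n_animals(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[2]

    def dosages(self) -> np.ndarray:
        """Counted-allele (allele 1) dosage matrix, shape (n_animals, n_markers)."""
        return self.haplotypes.sum(axis=1)

    def pooled(self) -> np.ndarray:
        """All haplotypes pooled (maternal and paternal), shape (2n, m)."""
        return self.haplotypes.reshape(-1, self.n_markers)

    def allele_frequencies(self) -> np.ndarray:
        return self.pooled().mean(axis=0)

    def subset_markers(self, idx: np.ndarray) -> "HaplotypeSet":
        return HaplotypeSet(
            population=self.population,
            animal_ids=list(self.animal_ids),
            haplotypes=self.haplotypes[:, :, idx].copy(),
            marker_map=self.marker_map.iloc[idx].reset_index(drop=True),
        )

    def subset(self, idx: np.ndarray, population: str | None = None) -> "HaplotypeSet":
        return HaplotypeSet(
            population=population or self.population,
            animal_ids=[self.animal_ids[i] for i in idx],
            haplotypes=self.haplotypes[idx].copy(),
            marker_map=self.marker_map,
        )

    def concat(self, other: "HaplotypeSet") -> "HaplotypeSet":
        if not self.marker_map["marker_id"].equals(other.marker_map["marker_id"]):
            raise ValueError("marker maps differ")
        return HaplotypeSet(
            population=self.population,
            animal_ids=self.animal_ids + other.animal_ids,
            haplotypes=np.concatenate([self.haplotypes, other.haplotypes]),
            marker_map=self.marker_map,
        )


@dataclass
class TrueValues:
    """Simulation ground truth: QTL placement, effects, and breeding values.

    ``effects`` has one column per population-trait (A then B).  ``tbv`` maps
    a population label to the per-animal true breeding values on that
    population's trait, for whichever animals it was evaluated on.
    """

    qtl_indices: np.ndarray
    effects: np.ndarray  # (n_qtl, 2)
    tbv: dict[str, pd.Series] = field(default_factory=dict)

    def tbv_for(self, haps: HaplotypeSet, trait_index: int) -> np.ndarray:
        """True breeding values = QTL dosage times effect, summed."""
        dos = haps.haplotypes[:, :, self.qtl_indices].sum(axis=1)
        return dos @ self.effects[:, trait_index]


def _gametes(
    haps: np.ndarray, parents: np.ndarray, recomb: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Sample one gamete per entry of ``parents`` from ``haps`` (n, 2, m).

    Recombination: the gamete copies one parental haplotype and switches to
    the other across interval k with probability ``recomb[k]`` (no
    interference; Haldane fractions upstream).
    """
    n_off = parents.shape[0]
    m = haps.shape[2]
    start = rng.integers(0, 2, size=n_off)
    switches = rng.random((n_off, m - 1)) < recomb[None, :] if m > 1 else np.zeros((n_off, 0), bool)
    source = np.empty((n_off, m), dtype=np.int64)
    source[:, 0] = start
    if m > 1:
        source[:, 1:] = (start[:, None] + np.cumsum(switches, axis=1)) % 2
    return haps[parents[:, None], source, np.arange(m)[None, :]]


def _random_mating_generation(
    haps: np.ndarray, n_offspring: int, recomb: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One generation of random mating with distinct parents per offspring."""
    n = haps.shape[0]
    sires = rng.integers(0, n, size=n_offspring)
    dams = rng.integers(0, n, size=n_offspring)
    clash = sires == dams
    while clash.any():
        dams[clash] = rng.integers(0, n, size=int(clash.sum()))
        clash = sires == dams
    pat = _gametes(haps, sires, recomb, rng)
    mat = _gametes(haps, dams, recomb, rng)
    return np.stack([pat, mat], axis=1)


def simulate_base_population(
    config: SimConfig, rng: np.random.Generator | None = None
) -> HaplotypeSet:
    """Drift a base population to build LD.

    Allele frequencies start at independent U(0.05, 0.95) draws (linkage
    equilibrium); ``n_burnin_generations`` of random mating at size Ne then
    generate LD by drift against recombination.  Markers ending with
    MAF < 0.01 are flagged in the map (column ``low_maf``) but retained —
    downstream QC decides their fate.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.effective_size_ne
    m = config.n_markers
    p0 = rng.uniform(0.05, 0.95, size=m)
    haps = (rng.random((n, 2, m)) < p0[None, None, :]).astype(np.uint8)
    recomb = config.recombination_fractions()
    for _ in range(config.n_burnin_generations):
        haps = _random_mating_generation(haps, n, recomb, rng)
    marker_map = config.marker_map()
    freq = haps.reshape(-1, m).mean(axis=0)
    maf = np.minimum(freq, 1.0 - freq)
    marker_map = marker_map.assign(maf=maf, low_maf=maf < 0.01)
    ids = [f"base_{i + 1}" for i in range(n)]
    return HaplotypeSet("base", ids, haps, marker_map)


def split_and_diverge(
    base: HaplotypeSet,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    founders_a: np.ndarray | None = None,
    founders_b: np.ndarray | None = None,
) -> tuple[HaplotypeSet, HaplotypeSet]:
    """Found two populations from the base and let them drift apart.

    Founders are disjoint samples of the base unless explicit (possibly
    overlapping) founder index arrays are supplied.  With zero divergence
    generations the two populations are just samples of the same gene pool.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    size_a, size_b = config.split_sizes
    if size_a < 1 or size_b < 1:
        raise ValueError("both split sizes must be >= 1")
    if founders_a is None and founders_b is None:
        if size_a + size_b > base.n_animals:
            raise ValueError(
                f"split sizes {config.split_sizes} exceed available founders ({base.n_animals})"
            )
        perm = rng.permutation(base.n_animals)
        founders_a = perm[:size_a]
        founders_b = perm[size_a : size_a + size_b]
    elif founders_a is None or founders_b is None:
        raise ValueError("supply both founder index arrays or neither")
    recomb = config.recombination_fractions()
    out: list[HaplotypeSet] = []
    for label, founders, size in (("A", founders_a, size_a), ("B", founders_b, size_b)):
        haps = base.haplotypes[np.asarray(founders)]
        for _ in range(config.n_divergence_generations):
            haps = _random_mating_generation(haps, size, recomb, rng)
        ids = [f"{label}_pool_{i + 1}" for i in range(haps.shape[0])]
        out.append(HaplotypeSet(label, ids, haps.astype(np.uint8), base.marker_map))
    return out[0], out[1]


def assign_trait_architecture(
    pop_a: HaplotypeSet,
    pop_b: HaplotypeSet,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> TrueValues:
    """Place QTL and draw correlated effect pairs for the two population-traits.

    Per-QTL effects are drawn from a bivariate normal whose correlation is
    the target cross-population genetic correlation; with dense QTL and
    similar allele frequencies the realized TBV correlation matches the
    effect correlation closely.  Each trait's effects are then scaled so the
    TBV variance in its own population equals h2, i.e. the trait has unit
    total variance once a (1 - h2) residual is added.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    m = pop_a.n_markers
    if config.n_qtl > m:
        raise ValueError("n_qtl exceeds marker count")
    rho = config.cross_pop_genetic_correlation
    qtl = np.sort(rng.choice(m, size=config.n_qtl, replace=False))
    if abs(rho) == 1.0:
        z = rng.standard_normal(config.n_qtl)
        effects = np.column_stack([z, rho * z])
    else:
        chol = np.linalg.cholesky(np.array([[1.0, rho], [rho, 1.0]]))
        effects = rng.standard_normal((config.n_qtl, 2)) @ chol.T
    tv = TrueValues(qtl_indices=qtl, effects=effects)
    for trait_index, pop in ((0, pop_a), (1, pop_b)):
        raw = tv.tbv_for(pop, trait_index)
        sd = raw.std()
        if sd <= 0:
            raise ValueError("degenerate trait: zero TBV variance (all QTL monomorphic?)")
        effects[:, trait_index] *= np.sqrt(config.h2) / sd
    tv.tbv["A"] = pd.Series(tv.tbv_for(pop_a, 0), index=pop_a.animal_ids)
    tv.tbv["B"] = pd.Series(tv.tbv_for(pop_b, 1), index=pop_b.animal_ids)
    return tv


def _selected_fraction_for_trend(trend_sd_per_year: float) -> float:
    """Truncation-selection fraction giving the requested yearly genetic gain.

    Only sires are selected, so the per-cohort response is half the sire
    selection differential: trend = i(f)/2 where i(f) = phi(z)/f is the
    selection intensity at selected fraction f.  Solved for f; trend 0 means
    no selection (f = 1).
    """
    if trend_sd_per_year <= 0:
        return 1.0
    target_i = 2.0 * trend_sd_per_year

    def gap(f: float) -> float:
        z = stats.norm.ppf(1.0 - f)
        return stats.norm.pdf(z) / f - target_i

    # i(f) is ~0 at f=1 and grows as f -> 0
    if gap(0.999) > 0:
        return 0.999
    if gap(0.02) < 0:
        return 0.02
    return float(optimize.brentq(gap, 0.02, 0.999))


def breed_bull_cohorts(
    pool: HaplotypeSet,
    true_values: TrueValues,
    trait_index: int,
    config: SimConfig,
    rng: np.random.Generator,
    n_bulls: int,
    birth_years: tuple[int, int],
    cohort_size: int | None = None,
    id_prefix: str = "bull",
) -> tuple[pd.DataFrame, HaplotypeSet, HaplotypeSet]:
    """Breed year cohorts of bulls under truncation selection of sires.

    Each birth year produces one cohort from the current male and female
    pools; sires are the top fraction of pool males on TBV (fraction solved
    from ``trend_per_year``), dams are random pool females.  Returns the
    pedigree of the genotyped bulls, their haplotypes, and the final female
    pool (dams available for a daughter generation).
    """
    y0, y1 = birth_years
    n_years = y1 - y0 + 1
    per_year = int(np.ceil(n_bulls / n_years))
    cohort_size = cohort_size or max(2 * per_year, pool.n_animals)
    recomb = config.recombination_fractions()
    sel_frac = _selected_fraction_for_trend(config.trend_per_year)

    n = pool.n_animals
    sex = rng.permutation(np.arange(n) % 2)  # 0 = male, 1 = female
    males = pool.haplotypes[sex == 0]
    male_ids = [pool.animal_ids[i] for i in np.flatnonzero(sex == 0)]
    females = pool.haplotypes[sex == 1]
    female_ids = [pool.animal_ids[i] for i in np.flatnonzero(sex == 1)]

    ped_rows: list[dict] = []
    kept_haps: list[np.ndarray] = []
    kept_ids: list[str] = []
    counter = 0
    for year in range(y0, y1 + 1):
        tbv_m = males[:, :, true_values.qtl_indices].sum(axis=1) @ true_values.effects[:, trait_index]
        n_sel = max(2, int(np.ceil(sel_frac * males.shape[0])))
        sire_pool = np.argsort(tbv_m)[::-1][:n_sel]
        sires = sire_pool[rng.integers(0, n_sel, size=cohort_size)]
        dams = rng.integers(0, females.shape[0], size=cohort_size)
        pat = _gametes(males, sires, recomb, rng)
        mat = _gametes(females, dams, recomb, rng)
        cohort = np.stack([pat, mat], axis=1).astype(np.uint8)
        cohort_sex = rng.permutation(np.arange(cohort_size) % 2)
        male_idx = np.flatnonzero(cohort_sex == 0)
        female_idx = np.flatnonzero(cohort_sex == 1)
        take = min(per_year, n_bulls - len(kept_ids), male_idx.size)
        genotyped = male_idx[rng.choice(male_idx.size, size=take, replace=False)]
        for k in genotyped:
            counter += 1
            aid = f"{pool.population}_{id_prefix}_{counter:04d}"
            kept_ids.append(aid)
            kept_haps.append(cohort[k])
            ped_rows.append(
                {
                    "animal_id": aid,
                    "sire_id": male_ids[sires[k]],
                    "dam_id": female_ids[dams[k]],
                    "birth_year": year,
                    "sex": "M",
                    "population": pool.population,
                    "family": "",
                }
            )
        # next generation's pools are this cohort; genotyped males keep their
        # pedigree ids so later sire links resolve
        geno_name = dict(zip(genotyped.tolist(), kept_ids[len(kept_ids) - take :]))
        males = cohort[male_idx]
        male_ids = [
            geno_name.get(int(k), f"{pool.population}_{id_prefix}m_{year}_{i}")
            for i, k in enumerate(male_idx)
        ]
        females = cohort[female_idx]
        female_ids = [f"{pool.population}_{id_prefix}f_{year}_{i}" for i in range(female_idx.size)]
    ped = pd.DataFrame(ped_rows)
    bulls = HaplotypeSet(pool.population, kept_ids, np.stack(kept_haps), pool.marker_map)
    dam_pool = HaplotypeSet(pool.population, female_ids, females.astype(np.uint8), pool.marker_map)
    return ped, bulls, dam_pool


def _family_sizes(
    n_cows: int, n_sires: int, size_range: tuple[int, int], rng: np.random.Generator
) -> np.ndarray:
    lo, hi = size_range
    if not (lo * n_sires <= n_cows <= hi * n_sires):
        raise ValueError(
            f"cannot split {n_cows} cows into {n_sires} families of size in [{lo}, {hi}]"
        )
    sizes = rng.uniform(lo, hi, size=n_sires)
    sizes = np.clip(sizes * n_cows / sizes.sum(), lo, hi)
    sizes = np.floor(sizes).astype(int)
    # distribute the rounding remainder one cow at a time
    while sizes.sum() < n_cows:
        room = np.flatnonzero(sizes < hi)
        sizes[rng.choice(room)] += 1
    while sizes.sum() > n_cows:
        room = np.flatnonzero(sizes > lo)
        sizes[rng.choice(room)] -= 1
    return sizes


def build_family_structure(
    pop: HaplotypeSet,
    true_values: TrueValues,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    n_bulls: int = 80,
    n_sires: int = 13,
    n_cows: int = 1572,
    family_size_range: tuple[int, int] = (63, 358),
    bull_birth_years: tuple[int, int] = (1993, 2002),
    cow_birth_years: tuple[int, int] = (2001, 2006),
    trait_index: int = 0,
) -> tuple[pd.DataFrame, HaplotypeSet]:
    """Build the small population's pedigreed structure by actual breeding.

    Bulls are bred in birth-year cohorts with truncation selection of sires
    (producing the genetic trend); ``n_sires`` of the genotyped bulls are
    then designated family sires and each receives a half-sib family of
    daughters, family sizes drawn from ``family_size_range``.  Daughters are
    bred by gamete sampling, so Mendelian consistency with their recorded
    sire holds exactly.

    Returns the pedigree (bulls + cows) and the haplotype set holding the
    genotyped bulls followed by the cows.
    """
    rng = np.random.default_rng(config.seed + 3) if rng is None else rng
    if n_sires > n_bulls:
        raise ValueError("cannot designate more sires than bulls")
    if n_cows > 0 and n_cows < n_sires:
        raise ValueError("fewer cows than requested sire families")
    ped_bulls, bulls, dam_pool = breed_bull_cohorts(
        pop, true_values, trait_index, config, rng, n_bulls, bull_birth_years
    )
    if n_cows == 0:
        return ped_bulls, bulls
    recomb = config.recombination_fractions()
    sire_idx = np.sort(rng.choice(n_bulls, size=n_sires, replace=False))
    sizes = _family_sizes(n_cows, n_sires, family_size_range, rng)
    sires = np.repeat(sire_idx, sizes)
    dams = rng.integers(0, dam_pool.n_animals, size=n_cows)
    pat = _gametes(bulls.haplotypes, sires, recomb, rng)
    mat = _gametes(dam_pool.haplotypes, dams, recomb, rng)
    cow_haps = np.stack([pat, mat], axis=1).astype(np.uint8)
    cow_ids = [f"{pop.population}_cow_{i + 1:04d}" for i in range(n_cows)]
    ped_cows = pd.DataFrame(
        {
            "animal_id": cow_ids,
            "sire_id": [bulls.animal_ids[s] for s in sires],
            "dam_id": [dam_pool.animal_ids[d] for d in dams],
            "birth_year": rng.integers(cow_birth_years[0], cow_birth_years[1] + 1, size=n_cows),
            "sex": "F",
            "population": pop.population,
            "family": [bulls.animal_ids[s] for s in sires],
        }
    )
    ped = pd.concat([ped_bulls, ped_cows], ignore_index=True)
    animals = bulls.concat(HaplotypeSet(pop.population, cow_ids, cow_haps, pop.marker_map))
    return ped, animals


def generate_drp(
    tbv: np.ndarray,
    reliability: np.ndarray | float,
    genetic_variance: float,
    rng: np.random.Generator,
    animal_ids: list[str] | None = None,
    trait: str = "trait",
) -> pd.DataFrame:
    """Deregressed proofs with an exact reliability contract.

    DRP_i = TBV_i + e_i with Var(e_i) = sigma2_g (1 - r2_i) / r2_i, so the
    squared correlation between DRP and TBV equals the stated reliability in
    expectation.  This replaces deregression of an estimated breeding value:
    the reliability becomes a testable input rather than a by-product.
    """
    tbv = np.asarray(tbv, dtype=float)
    r2 = np.broadcast_to(np.asarray(reliability, dtype=float), tbv.shape)
    if np.any(r2 <= 0) or np.any(r2 > 1):
        raise ValueError("reliabilities must be in (0, 1]")
    noise_var = genetic_variance * (1.0 - r2) / r2
    drp = tbv + rng.standard_normal(tbv.shape) * np.sqrt(noise_var)
    if animal_ids is None:
        animal_ids = [f"animal_{i + 1}" for i in range(tbv.size)]
    return pd.DataFrame(
        {"animal_id": animal_ids, "trait": trait, "drp": drp, "r2_drp": r2}
    )
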