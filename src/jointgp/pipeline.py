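"""End-to-end scenario orchestration.

A scenario simulates two related populations, edits the genotypes,
measures cross-population LD consistency, fits single-reference GBLUP
(population A only) and joint-reference two-trait GBLUP (A + B), validates
both with the bull split and the half-sib-family cow cross-validation, and
reports the reliability gain from the joint reference.  All randomness
flows from one root seed through named sub-streams, so the whole run — and
each stage in isolation — is reproducible bit for bit.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gblup, geno_io, grm as grm_mod, ld, pheno_prep, simpop, validate

logger = logging.getLogger(__name__)

__all__ = ["ScenarioConfig", "ScenarioReport", "run_scenario", "compare_reduced_reference"]


@dataclass
class ScenarioConfig:
    """One config object for the whole experiment."""

    sim: simpop.SimConfig = field(default_factory=simpop.SimConfig)
    # population-A structure (small mixed reference)
    n_bulls_a: int = 40
    n_sires: int = 13
    n_cows: int = 416
    family_size_range: tuple[int, int] = (20, 50)
    bull_birth_years: tuple[int, int] = (1993, 2002)
    cow_birth_years: tuple[int, int] = (2001, 2006)
    # population-B structure (large bull reference)
    n_bulls_b: int = 600
    b_birth_years: tuple[int, int] = (1974, 2008)
    unrelated_b: bool = False  # negative control: B from an independent base
    # DRP reliabilities
    r2_drp_bull_a: float = 0.90
    r2_drp_cow: float = 0.35
    r2_drp_bull_b: float = 0.90
    # QC thresholds
    maf_min: float = 0.01
    marker_callrate_min: float = 0.90
    animal_missing_max: float = 0.10
    # model settings
    ridge: float = 1e-6
    reml_tol: float = 1e-6
    reml_max_iter: int = 60
    pooled_p: bool = True
    # validation design
    relationship_max: float = 0.45
    k_folds: int = 5
    parentage_panel_size: int = 255
    out_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seed != self.sim.seed:
            self.sim = dataclasses.replace(self.sim, seed=self.seed)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        sim = d.pop("sim", {})
        for key in ("split_sizes",):
            if key in sim and sim[key] is not None:
                sim[key] = tuple(sim[key])
        for key in ("family_size_range", "bull_birth_years", "cow_birth_years", "b_birth_years"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(sim=simpop.SimConfig(**sim), **d)


def _streams(seed: int) -> dict[str, np.random.Generator]:
    names = [
        "base", "base_b", "split", "traits", "family_a", "bulls_b",
        "drp", "folds", "panel", "cow_removal",
    ]
    seqs = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, seqs)}


@dataclass
class ScenarioData:
    """Everything downstream of simulation + QC, before model fitting."""

    haps_a: simpop.HaplotypeSet  # bulls + cows, QC-retained markers
    haps_b: simpop.HaplotypeSet
    geno_a: geno_io.GenotypeSet
    geno_b: geno_io.GenotypeSet
    pedigree: pd.DataFrame
    true_values: simpop.TrueValues
    drp_a: pd.DataFrame  # with residual weights
    drp_b: pd.DataFrame
    qc_a: geno_io.QCReport
    qc_b: geno_io.QCReport
    sire_ids: list[str]
    bull_ids_a: list[str]
    cow_ids: list[str]
    tbv_a: pd.Series


@dataclass
class ScenarioReport:
    """Scenario outcome mirroring the experiment's headline tables."""

    consistency: ld.ConsistencySummary
    distance: pd.DataFrame
    vc_single: gblup.VarianceComponents
    vc_joint: gblup.VarianceComponents
    reliability: pd.DataFrame  # category, reliability_single, reliability_joint, increase
    n_test_bulls: int
    n_test_cows: int
    seed: int
    gebv_bulls: pd.DataFrame | None = None  # test-bull GEBV per model
    gebv_cows: pd.DataFrame | None = None  # pooled CV cow GEBV per model
    timings: dict[str, float] = field(default_factory=dict)

    def reliability_for(self, category: str, which: str) -> float:
        row = self.reliability.set_index("category").loc[category]
        return float(row[f"reliability_{which}"])


def prepare_scenario_data(config: ScenarioConfig) -> ScenarioData:
    """Simulate, breed, phenotype and QC both populations."""
    rngs = _streams(config.seed)
    sim = config.sim
    base = simpop.simulate_base_population(sim, rngs["base"])
    if config.unrelated_b:
        base_b = simpop.simulate_base_population(
            dataclasses.replace(sim, seed=sim.seed + 7919), rngs["base_b"]
        )
        pool_a, _ = simpop.split_and_diverge(base, sim, rngs["split"])
        _, pool_b = simpop.split_and_diverge(base_b, sim, rngs["split"])
    else:
        pool_a, pool_b = simpop.split_and_diverge(base, sim, rngs["split"])
    tv = simpop.assign_trait_architecture(pool_a, pool_b, sim, rngs["traits"])
    ped_a, animals_a = simpop.build_family_structure(
        pool_a, tv, sim, rngs["family_a"],
        n_bulls=config.n_bulls_a, n_sires=config.n_sires, n_cows=config.n_cows,
        family_size_range=config.family_size_range,
        bull_birth_years=config.bull_birth_years, cow_birth_years=config.cow_birth_years,
        trait_index=0,
    )
    ped_b, bulls_b, _ = simpop.breed_bull_cohorts(
        pool_b, tv, 1, sim, rngs["bulls_b"],
        n_bulls=config.n_bulls_b, birth_years=config.b_birth_years, id_prefix="bull",
    )
    pedigree = pd.concat([ped_a, ped_b], ignore_index=True)

    # genotype QC on the dosage view, then subset the phased data to match
    geno_a, qc_a = geno_io.qc_filter(
        geno_io.genotype_set_from_haplotypes(animals_a),
        config.maf_min, config.marker_callrate_min, config.animal_missing_max,
    )
    geno_b, qc_b = geno_io.qc_filter(
        geno_io.genotype_set_from_haplotypes(bulls_b),
        config.maf_min, config.marker_callrate_min, config.animal_missing_max,
    )
    geno_a, geno_b, _ = geno_io.harmonize_alleles(geno_a, geno_b)
    marker_pos = {m: j for j, m in enumerate(animals_a.marker_map["marker_id"])}
    keep = np.array([marker_pos[m] for m in geno_a.marker_map["marker_id"]])
    haps_a = animals_a.subset_markers(keep)
    haps_b = bulls_b.subset_markers(keep)

    # phenotypes: DRP from TBV with prescribed reliabilities (QTL indices
    # refer to the full simulated marker set, so TBV uses the pre-QC data)
    tbv_a = pd.Series(tv.tbv_for(animals_a, 0), index=animals_a.animal_ids)
    tbv_b = pd.Series(tv.tbv_for(bulls_b, 1), index=bulls_b.animal_ids)
    cow_ids = ped_a.loc[ped_a["sex"] == "F", "animal_id"].tolist()
    bull_ids_a = ped_a.loc[ped_a["sex"] == "M", "animal_id"].tolist()
    var_a = float(tbv_a.var())
    var_b = float(tbv_b.var())
    r2_a = np.where(np.isin(tbv_a.index, bull_ids_a), config.r2_drp_bull_a, config.r2_drp_cow)
    drp_a = simpop.generate_drp(
        tbv_a.to_numpy(), r2_a, var_a, rngs["drp"], animal_ids=list(tbv_a.index), trait="trait_a"
    )
    drp_b = simpop.generate_drp(
        tbv_b.to_numpy(), config.r2_drp_bull_b, var_b, rngs["drp"],
        animal_ids=list(tbv_b.index), trait="trait_b",
    )
    drp_a = pheno_prep.residual_weights(drp_a)
    drp_b = pheno_prep.residual_weights(drp_b)

    # parentage screen of the cows against their recorded sires
    fam = ped_a.set_index("animal_id")
    pairs = [(c, fam.loc[c, "sire_id"]) for c in cow_ids]
    check = pheno_prep.parentage_check(
        geno_a, geno_a, pairs, panel_size=config.parentage_panel_size, rng=rngs["panel"]
    )
    drp_a = pheno_prep.apply_exclusions(drp_a, check)

    sire_ids = sorted(ped_a.loc[ped_a["sex"] == "F", "family"].unique())
    return ScenarioData(
        haps_a=haps_a, haps_b=haps_b, geno_a=geno_a, geno_b=geno_b,
        pedigree=pedigree, true_values=tv, drp_a=drp_a, drp_b=drp_b,
        qc_a=qc_a, qc_b=qc_b, sire_ids=sire_ids, bull_ids_a=bull_ids_a,
        cow_ids=cow_ids, tbv_a=tbv_a,
    )


def _records(drp: pd.DataFrame, ids: list[str]) -> pd.DataFrame:
    sub = drp[drp["animal_id"].isin(set(ids))]
    return sub.rename(columns={"drp": "value"})[["animal_id", "trait", "value", "weight"]]


def _bull_validation(
    data: ScenarioData, config: ScenarioConfig, grm_a: grm_mod.GRM, grm_joint: grm_mod.GRM
) -> tuple[dict, gblup.VarianceComponents, gblup.VarianceComponents, validate.ValidationSplit]:
    """Reliability of bull predictions under single and joint reference."""
    candidates = [b for b in data.bull_ids_a if b not in set(data.sire_ids)]
    split = validate.make_bull_split(
        candidates, data.sire_ids, grm_a, relationship_max=config.relationship_max
    )
    test = split.test_ids
    ref_ids = data.sire_ids + data.cow_ids
    reml_kw = dict(tol=config.reml_tol, max_iter=config.reml_max_iter)

    spec_single = gblup.ModelSpec(
        ["trait_a"], _records(data.drp_a, ref_ids), list(grm_a.animal_ids)
    )
    vc_s, fit_s = gblup.single_trait_gblup(spec_single, grm_a, **reml_kw)

    rec_joint = pd.concat(
        [_records(data.drp_a, ref_ids), _records(data.drp_b, list(data.drp_b["animal_id"]))],
        ignore_index=True,
    )
    spec_joint = gblup.ModelSpec(
        ["trait_a", "trait_b"], rec_joint, list(grm_joint.animal_ids)
    )
    vc_j, fit_j = gblup.two_trait_gblup(spec_joint, grm_joint, **reml_kw)

    ped = data.pedigree.set_index("animal_id")
    years = ped.loc[test, "birth_year"].to_numpy(float)
    drp_test = data.drp_a.set_index("animal_id").loc[test]
    out = {}
    gebv_frames = []
    for label, fit in (("single", fit_s), ("joint", fit_j)):
        gebv = fit.for_trait("trait_a").loc[test].to_numpy()
        out[label] = validate.validation_reliability(
            gebv, drp_test["drp"].to_numpy(), drp_test["r2_drp"].to_numpy(), birth_years=years
        )
        gebv_frames.append(
            pd.DataFrame({"animal_id": test, "model": label, "gebv": gebv})
        )
    return out, vc_s, vc_j, split, pd.concat(gebv_frames, ignore_index=True)


def _cow_validation(
    data: ScenarioData, config: ScenarioConfig, grm_a: grm_mod.GRM, grm_joint: grm_mod.GRM,
    vc_s: gblup.VarianceComponents, vc_j: gblup.VarianceComponents,
    rng: np.random.Generator,
) -> tuple[dict, list[validate.ValidationSplit]]:
    """Five-fold half-sib-family CV, reliability on GEBV pooled over folds.

    Variance components are estimated once on the full reference (they are
    re-used across folds; only the solutions change with the fold's record
    set).
    """
    cows_with_drp = set(data.drp_a["animal_id"]) & set(data.cow_ids)
    fam = data.pedigree.set_index("animal_id")["family"]
    cow_families = pd.DataFrame(
        {"animal_id": sorted(cows_with_drp), "family": [fam[c] for c in sorted(cows_with_drp)]}
    )
    folds = validate.make_cow_folds(cow_families, k_folds=config.k_folds, rng=rng)
    pooled: dict[str, dict[str, float]] = {"single": {}, "joint": {}}
    for fold in folds:
        ref_cows = fold.reference_ids
        ref_ids = data.bull_ids_a + list(ref_cows)
        spec_s = gblup.ModelSpec(
            ["trait_a"], _records(data.drp_a, ref_ids), list(grm_a.animal_ids)
        )
        fit_s = gblup.solve_mme(gblup.build_mme(spec_s, grm_a, vc_s))
        rec_j = pd.concat(
            [_records(data.drp_a, ref_ids), _records(data.drp_b, list(data.drp_b["animal_id"]))],
            ignore_index=True,
        )
        spec_j = gblup.ModelSpec(["trait_a", "trait_b"], rec_j, list(grm_joint.animal_ids))
        fit_j = gblup.solve_mme(gblup.build_mme(spec_j, grm_joint, vc_j))
        for label, fit in (("single", fit_s), ("joint", fit_j)):
            g = fit.for_trait("trait_a")
            for c in fold.test_ids:
                pooled[label][c] = float(g[c])
    drp_idx = data.drp_a.set_index("animal_id")
    out = {}
    gebv_frames = []
    for label in ("single", "joint"):
        ids = sorted(pooled[label])
        gebv = np.array([pooled[label][c] for c in ids])
        out[label] = validate.validation_reliability(
            gebv, drp_idx.loc[ids, "drp"].to_numpy(), drp_idx.loc[ids, "r2_drp"].to_numpy()
        )
        gebv_frames.append(pd.DataFrame({"animal_id": ids, "model": label, "gebv": gebv}))
    return out, folds, pd.concat(gebv_frames, ignore_index=True)


def run_scenario(config: ScenarioConfig) -> ScenarioReport:
    """Execute the full experiment for one seed; persist artifacts if
    ``config.out_dir`` is set."""
    t0 = time.perf_counter()
    timings: dict[str, float] = {}
    data = prepare_scenario_data(config)
    timings["simulate_qc"] = time.perf_counter() - t0

    t = time.perf_counter()
    ld_a = ld.adjacent_ld(data.haps_a)
    ld_b = ld.adjacent_ld(data.haps_b)
    consistency = ld.ld_consistency(ld_a, ld_b)
    distance = ld.distance_summary(data.haps_a.marker_map)
    timings["ld"] = time.perf_counter() - t

    t = time.perf_counter()
    grm_a = grm_mod.build_grm(data.geno_a, ridge=config.ridge)
    merged = geno_io.merge_genotype_sets([data.geno_a, data.geno_b])
    p_joint = grm_mod.allele_frequencies(merged) if config.pooled_p else None
    grm_joint = grm_mod.build_grm(merged, p=p_joint, ridge=config.ridge)
    timings["grm"] = time.perf_counter() - t

    t = time.perf_counter()
    bull_rel, vc_s, vc_j, bull_split, gebv_bulls = _bull_validation(data, config, grm_a, grm_joint)
    timings["bull_validation"] = time.perf_counter() - t

    t = time.perf_counter()
    rngs = _streams(config.seed)
    cow_rel, folds, gebv_cows = _cow_validation(
        data, config, grm_a, grm_joint, vc_s, vc_j, rngs["folds"]
    )
    timings["cow_validation"] = time.perf_counter() - t

    reliability = pd.DataFrame(
        {
            "category": ["bulls_a", "cows_a"],
            "reliability_single": [bull_rel["single"], cow_rel["single"]],
            "reliability_joint": [bull_rel["joint"], cow_rel["joint"]],
        }
    )
    reliability["increase"] = reliability["reliability_joint"] - reliability["reliability_single"]
    report = ScenarioReport(
        consistency=consistency, distance=distance, vc_single=vc_s, vc_joint=vc_j,
        reliability=reliability, n_test_bulls=len(bull_split.test_ids),
        n_test_cows=int(sum(len(f.test_ids) for f in folds)), seed=config.seed,
        gebv_bulls=gebv_bulls, gebv_cows=gebv_cows, timings=timings,
    )
    if config.out_dir:
        _persist(config, data, report, grm_a, grm_joint, bull_split, folds)
    return report


def _persist(config, data, report, grm_a, grm_joint, bull_split, folds) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    geno_io.write_genotypes(data.geno_a, out / "pop_a", "tsv")
    geno_io.write_genotypes(data.geno_b, out / "pop_b", "tsv")
    geno_io.write_haplotypes(data.haps_a, out / "pop_a.haplotypes.tsv")
    geno_io.write_haplotypes(data.haps_b, out / "pop_b.haplotypes.tsv")
    data.pedigree.to_csv(out / "pedigree.tsv", sep="\t", index=False)
    pd.concat([data.drp_a, data.drp_b]).to_csv(out / "drp.tsv", sep="\t", index=False)
    grm_a.write(out / "grm_a")
    grm_joint.write(out / "grm_joint")
    splits = pd.concat([bull_split.to_frame().assign(design="bulls")] +
                       [f.to_frame().assign(design="cow_cv") for f in folds])
    splits.to_csv(out / "splits.tsv", sep="\t", index=False)
    report.consistency.to_frame().to_csv(out / "ld_consistency.tsv", sep="\t", index=False)
    report.distance.to_csv(out / "distance_summary.tsv", sep="\t", index=False)
    report.gebv_bulls.to_csv(out / "gebv_bulls.tsv", sep="\t", index=False)
    report.gebv_cows.to_csv(out / "gebv_cows.tsv", sep="\t", index=False)
    report.vc_single.to_frame().to_csv(out / "vc_single.tsv", sep="\t", index=False)
    report.vc_joint.to_frame().to_csv(out / "vc_joint.tsv", sep="\t", index=False)
    report.reliability.to_csv(out / "report.tsv", sep="\t", index=False)
    with open(out / "report.txt", "w") as fh:
        fh.write(f"seed: {report.seed}\n")
        fh.write(f"mean LD consistency: {report.consistency.mean_consistency:.4f}\n")
        fh.write(f"two-trait genetic correlation: {report.vc_joint.r_g:.4f}\n")
        fh.write(report.reliability.to_string(index=False) + "\n")
        fh.write(f"timings: { {k: round(v, 2) for k, v in report.timings.items()} }\n")


def compare_reduced_reference(
    config: ScenarioConfig, cow_fraction_removed: float
) -> pd.DataFrame:
    """Effect of deleting cows from the single-population reference.

    Re-runs the single-reference bull validation with a random fraction of
    cow records removed and reports baseline vs reduced reliability.
    """
    if not (0.0 <= cow_fraction_removed < 1.0):
        raise ValueError("fraction must be in [0, 1)")
    data = prepare_scenario_data(config)
    grm_a = grm_mod.build_grm(data.geno_a, ridge=config.ridge)
    candidates = [b for b in data.bull_ids_a if b not in set(data.sire_ids)]
    split = validate.make_bull_split(
        candidates, data.sire_ids, grm_a, relationship_max=config.relationship_max
    )
    test = split.test_ids
    ped = data.pedigree.set_index("animal_id")
    years = ped.loc[test, "birth_year"].to_numpy(float)
    drp_test = data.drp_a.set_index("animal_id").loc[test]
    rng = _streams(config.seed)["cow_removal"]
    cows = [c for c in data.cow_ids if c in set(data.drp_a["animal_id"])]
    n_keep = int(round(len(cows) * (1.0 - cow_fraction_removed)))
    kept_cows = list(rng.choice(cows, size=n_keep, replace=False)) if cow_fraction_removed else cows
    rows = []
    for label, cow_set in (("baseline", cows), ("reduced", kept_cows)):
        ref_ids = data.sire_ids + list(cow_set)
        if len(ref_ids) < 10:
            raise ValueError("reduced reference has fewer than 10 records")
        spec = gblup.ModelSpec(["trait_a"], _records(data.drp_a, ref_ids), list(grm_a.animal_ids))
        vc, fit = gblup.single_trait_gblup(
            spec, grm_a, tol=config.reml_tol, max_iter=config.reml_max_iter
        )
        gebv = fit.for_trait("trait_a").loc[test].to_numpy()
        rel = validate.validation_reliability(
            gebv, drp_test["drp"].to_numpy(), drp_test["r2_drp"].to_numpy(), birth_years=years
        )
        rows.append({"reference": label, "n_cows": len(cow_set), "reliability": rel})
    out = pd.DataFrame(rows)
    out["delta"] = out["reliability"] - out.loc[0, "reliability"]
    return out
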