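"""Genotype containers, file formats, quality control and allele harmonization.

Supported on-disk dialects: PLINK-style .ped/.map text, plain-text VCF
(biallelic SNPs; read through cyvcf2), and a native TSV dosage matrix with a
side-car marker table.  Dosages count copies of the marker's *counted
allele*; missing calls are NaN.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeSet",
    "QCReport",
    "read_genotypes",
    "write_genotypes",
    "qc_filter",
    "harmonize_alleles",
    "merge_genotype_sets",
    "genotype_set_from_haplotypes",
    "write_haplotypes",
]

MAP_COLUMNS = ["chrom", "marker_id", "pos", "allele_a", "allele_b", "counted_allele"]


@dataclass
class GenotypeSet:
    """Allele-count genotypes for one population.

    ``marker_map`` columns: chrom (1..29 autosome convention), marker_id,
    pos (bp, 1-based), allele_a, allele_b, counted_allele (the allele whose
    copies the dosage counts).  ``dosages`` is float (n_animals, n_markers)
    with values in {0, 1, 2} or NaN for missing.
    """

    population: str
    animal_ids: list[str]
    marker_map: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        if self.dosages.shape != (len(self.animal_ids), len(self.marker_map)):
            raise ValueError("dosage matrix shape does not match ids/map")
        if self.marker_map["marker_id"].duplicated().any():
            dup = self.marker_map.loc[self.marker_map["marker_id"].duplicated(), "marker_id"].iloc[0]
            raise ValueError(f"duplicate marker id: {dup}")
        if self.marker_map["counted_allele"].isna().any():
            raise ValueError("every marker needs a counted allele label")

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_map)

    def sorted_by_position(self) -> "GenotypeSet":
        order = self.marker_map.sort_values(["chrom", "pos"], kind="mergesort").index.to_numpy()
        return GenotypeSet(
            self.population,
            list(self.animal_ids),
            self.marker_map.loc[order].reset_index(drop=True),
            self.dosages[:, order],
        )

    def subset_markers(self, mask_or_idx: np.ndarray) -> "GenotypeSet":
        mm = self.marker_map.loc[mask_or_idx] if mask_or_idx.dtype == bool else self.marker_map.iloc[mask_or_idx]
        dos = self.dosages[:, mask_or_idx] if mask_or_idx.dtype == bool else self.dosages[:, mask_or_idx]
        return GenotypeSet(self.population, list(self.animal_ids), mm.reset_index(drop=True), dos)

    def subset_animals(self, ids: list[str]) -> "GenotypeSet":
        index = {a: i for i, a in enumerate(self.animal_ids)}
        idx = np.array([index[a] for a in ids])
        return GenotypeSet(self.population, list(ids), self.marker_map.copy(), self.dosages[idx])


@dataclass
class QCReport:
    """Counts removed by each editing rule; in − removed = out on both axes."""

    n_markers_in: int
    n_markers_out: int
    n_animals_in: int
    n_animals_out: int
    n_markers_low_maf: int
    n_markers_low_callrate: int
    n_animals_high_missing: int

    def __post_init__(self) -> None:
        # a marker can fail both rules; removals are counted once
        if self.n_markers_out > self.n_markers_in or self.n_animals_out > self.n_animals_in:
            raise ValueError("QC cannot create markers or animals")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rule": [
                    "markers_in", "markers_low_maf", "markers_low_callrate", "markers_out",
                    "animals_in", "animals_high_missing", "animals_out",
                ],
                "count": [
                    self.n_markers_in, self.n_markers_low_maf, self.n_markers_low_callrate,
                    self.n_markers_out, self.n_animals_in, self.n_animals_high_missing,
                    self.n_animals_out,
                ],
            }
        )


# ---------------------------------------------------------------------------
# readers / writers


def _read_ped_map(prefix: Path, population: str) -> GenotypeSet:
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")
    mm = pd.read_csv(
        map_path, sep=r"\s+", header=None, names=["chrom", "marker_id", "cm", "pos"],
        dtype={"chrom": int, "marker_id": str, "pos": np.int64},
    )
    n_markers = len(mm)
    animal_ids: list[str] = []
    allele_rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_markers:
                raise ValueError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_markers} fields, got {len(parts)}"
                )
            animal_ids.append(parts[1])
            allele_rows.append(np.array(parts[6:], dtype="U8").reshape(n_markers, 2))
    alleles = (
        np.stack(allele_rows) if allele_rows else np.empty((0, n_markers, 2), dtype="U8")
    )
    a_lab = np.empty(n_markers, dtype=object)
    b_lab = np.empty(n_markers, dtype=object)
    dosages = np.full((len(animal_ids), n_markers), np.nan)
    for j in range(n_markers):
        col = alleles[:, j, :]
        seen = sorted({x for x in col.ravel() if x != "0"})
        if len(seen) > 2:
            raise ValueError(f"marker {mm['marker_id'][j]} is not biallelic: {seen}")
        seen = (seen + ["A", "B"])[:2] if len(seen) < 2 else seen
        a_lab[j], b_lab[j] = seen[0], seen[1]
        missing = (col == "0").any(axis=1)
        dosages[:, j] = (col == b_lab[j]).sum(axis=1).astype(float)
        dosages[missing, j] = np.nan
    mm = mm.drop(columns=["cm"]).assign(
        allele_a=a_lab, allele_b=b_lab, counted_allele=b_lab
    )[MAP_COLUMNS]
    return GenotypeSet(population, animal_ids, mm, dosages)


def _write_ped_map(g: GenotypeSet, prefix: Path) -> None:
    mm = g.marker_map
    with open(prefix.with_suffix(".map"), "w") as fh:
        for _, r in mm.iterrows():
            fh.write(f"{r['chrom']}\t{r['marker_id']}\t0\t{r['pos']}\n")
    a = mm["allele_a"].to_numpy()
    b = mm["allele_b"].to_numpy()
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, aid in enumerate(g.animal_ids):
            fields = [g.population, aid, "0", "0", "0", "-9"]
            row = g.dosages[i]
            for j, d in enumerate(row):
                if np.isnan(d):
                    fields += ["0", "0"]
                else:
                    nb = int(round(d))
                    fields += [b[j]] * nb + [a[j]] * (2 - nb)
            fh.write(" ".join(fields) + "\n")


def _read_vcf(path: Path, population: str) -> GenotypeSet:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    animal_ids = list(vcf.samples)
    chroms, ids, poss, refs, alts = [], [], [], [], []
    rows = []
    for idx, var in enumerate(vcf):
        if var.ALT is None or len(var.ALT) != 1:
            warnings.warn(f"skipping non-biallelic record at {var.CHROM}:{var.POS}")
            continue
        chroms.append(int(str(var.CHROM).removeprefix("chr")))
        ids.append(var.ID or f"{var.CHROM}_{var.POS}")
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        gt = np.array(var.genotypes, dtype=object)
        dos = np.full(len(animal_ids), np.nan)
        for i, g in enumerate(gt):
            a1, a2 = g[0], g[1]
            if a1 < 0 or a2 < 0:
                continue
            dos[i] = float(a1 + a2)
        rows.append(dos)
    dosages = np.stack(rows, axis=1) if rows else np.empty((len(animal_ids), 0))
    mm = pd.DataFrame(
        {
            "chrom": chroms,
            "marker_id": ids,
            "pos": np.array(poss, dtype=np.int64),
            "allele_a": refs,
            "allele_b": alts,
            "counted_allele": alts,  # dosage counts ALT copies
        }
    )
    return GenotypeSet(population, animal_ids, mm, dosages)


def _write_vcf(g: GenotypeSet, path: Path) -> None:
    mm = g.marker_map
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in sorted(mm["chrom"].unique()):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(g.animal_ids) + "\n")
        for j, r in mm.iterrows():
            # REF = non-counted allele so ALT dosage equals the stored dosage
            if r["counted_allele"] == r["allele_b"]:
                ref, alt = r["allele_a"], r["allele_b"]
            else:
                ref, alt = r["allele_b"], r["allele_a"]
            gts = []
            for d in g.dosages[:, j]:
                if np.isnan(d):
                    gts.append("./.")
                else:
                    n = int(round(d))
                    gts.append({0: "0/0", 1: "0/1", 2: "1/1"}[n])
            fh.write(
                f"{r['chrom']}\t{r['pos']}\t{r['marker_id']}\t{ref}\t{alt}\t.\t.\t.\tGT\t"
                + "\t".join(gts) + "\n"
            )


def _read_tsv(prefix: Path, population: str) -> GenotypeSet:
    mm = pd.read_csv(Path(f"{prefix}.markers.tsv"), sep="\t", dtype={"marker_id": str})
    dose = pd.read_csv(Path(f"{prefix}.dosage.tsv"), sep="\t", index_col=0)
    if list(dose.columns) != list(mm["marker_id"]):
        raise ValueError("dosage columns do not match marker table order")
    return GenotypeSet(population, [str(a) for a in dose.index], mm[MAP_COLUMNS], dose.to_numpy(float))


def _write_tsv(g: GenotypeSet, prefix: Path) -> None:
    g.marker_map[MAP_COLUMNS].to_csv(Path(f"{prefix}.markers.tsv"), sep="\t", index=False)
    pd.DataFrame(g.dosages, index=pd.Index(g.animal_ids, name="animal_id"),
                 columns=g.marker_map["marker_id"]).to_csv(Path(f"{prefix}.dosage.tsv"), sep="\t")


def read_genotypes(path: str | Path, fmt: str, population: str = "pop") -> GenotypeSet:
    """Read genotypes in one of the supported dialects.

    ``fmt``: "ped" (PLINK text prefix), "vcf", or "tsv" (native prefix).
    Markers are returned sorted by (chromosome, position).
    """
    path = Path(path)
    if fmt == "ped":
        g = _read_ped_map(path, population)
    elif fmt == "vcf":
        g = _read_vcf(path, population)
    elif fmt == "tsv":
        g = _read_tsv(path, population)
    else:
        raise ValueError(f"unknown genotype format: {fmt!r}")
    return g.sorted_by_position()


def write_genotypes(g: GenotypeSet, path: str | Path, fmt: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "ped":
        _write_ped_map(g, path)
    elif fmt == "vcf":
        _write_vcf(g, path)
    elif fmt == "tsv":
        _write_tsv(g, path)
    else:
        raise ValueError(f"unknown genotype format: {fmt!r}")


def write_haplotypes(haps, path: str | Path) -> None:
    """Two rows per animal (suffix _1/_2), columns = marker ids."""
    pooled = haps.pooled()
    idx = [f"{a}_{h}" for a in haps.animal_ids for h in (1, 2)]
    pd.DataFrame(pooled, index=pd.Index(idx, name="haplotype_id"),
                 columns=haps.marker_map["marker_id"]).to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# QC and harmonization


def qc_filter(
    g: GenotypeSet,
    maf_min: float = 0.01,
    marker_callrate_min: float = 0.90,
    animal_missing_max: float = 0.10,
) -> tuple[GenotypeSet, QCReport]:
    """Marker and animal editing.

    Removes markers with MAF strictly below ``maf_min`` (computed on
    non-missing calls) or call rate strictly below ``marker_callrate_min``,
    then animals with missing fraction strictly above ``animal_missing_max``.
    Boundary values are retained on all three rules.
    """
    for t in (maf_min, marker_callrate_min, animal_missing_max):
        if not (0.0 <= t <= 1.0):
            raise ValueError("QC thresholds must be in [0, 1]")
    dos = g.dosages
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        p = np.nanmean(dos, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    callrate = 1.0 - np.isnan(dos).mean(axis=0)
    fail_maf = ~(maf >= maf_min)  # NaN frequency (all missing) also fails
    fail_call = callrate < marker_callrate_min
    keep_markers = ~(fail_maf | fail_call)
    g2 = g.subset_markers(keep_markers)
    if g2.n_markers == 0:
        warnings.warn("QC removed every marker")
        missing_frac = np.zeros(g.n_animals)
    else:
        missing_frac = np.isnan(g2.dosages).mean(axis=1)
    keep_animals = missing_frac <= animal_missing_max
    g3 = GenotypeSet(
        g.population,
        [a for a, k in zip(g2.animal_ids, keep_animals) if k],
        g2.marker_map,
        g2.dosages[keep_animals],
    )
    report = QCReport(
        n_markers_in=g.n_markers,
        n_markers_out=g3.n_markers,
        n_animals_in=g.n_animals,
        n_animals_out=g3.n_animals,
        n_markers_low_maf=int(fail_maf.sum()),
        n_markers_low_callrate=int(fail_call.sum()),
        n_animals_high_missing=int((~keep_animals).sum()),
    )
    logger.info(
        "QC: markers %d -> %d (maf %d, callrate %d); animals %d -> %d (missing %d)",
        report.n_markers_in, report.n_markers_out, report.n_markers_low_maf,
        report.n_markers_low_callrate, report.n_animals_in, report.n_animals_out,
        report.n_animals_high_missing,
    )
    return g3, report


def harmonize_alleles(
    a: GenotypeSet, b: GenotypeSet
) -> tuple[GenotypeSet, GenotypeSet, dict[str, bool]]:
    """Restrict both sets to shared markers and count the same allele in both.

    Where the two sets count different alleles of the same pair, b's dosages
    are reflected (2 - x) and its counted-allele label replaced.  Marker
    pairs that cannot be reconciled by a swap (different allele sets) are
    dropped with a warning.  Signed LD is only comparable across populations
    after this step.
    """
    b_index = {mid: j for j, mid in enumerate(b.marker_map["marker_id"])}
    keep_a, keep_b, flips = [], [], {}
    for i, row in a.marker_map.iterrows():
        mid = row["marker_id"]
        j = b_index.get(mid)
        if j is None:
            continue
        brow = b.marker_map.iloc[j]
        pair_a = {row["allele_a"], row["allele_b"]}
        pair_b = {brow["allele_a"], brow["allele_b"]}
        if pair_a != pair_b:
            warnings.warn(f"marker {mid}: allele pair mismatch {pair_a} vs {pair_b}; dropped")
            continue
        keep_a.append(i)
        keep_b.append(j)
        flips[mid] = brow["counted_allele"] != row["counted_allele"]
    a2 = a.subset_markers(np.array(keep_a, dtype=int))
    b2 = b.subset_markers(np.array(keep_b, dtype=int))
    flip_mask = np.array([flips[m] for m in a2.marker_map["marker_id"]], dtype=bool)
    if flip_mask.any():
        dos = b2.dosages.copy()
        dos[:, flip_mask] = 2.0 - dos[:, flip_mask]
        mm = b2.marker_map.copy()
        mm.loc[flip_mask, "counted_allele"] = a2.marker_map.loc[flip_mask, "counted_allele"].to_numpy()
        b2 = GenotypeSet(b.population, list(b2.animal_ids), mm, dos)
    return a2, b2, {m: f for m, f in flips.items() if f}


def genotype_set_from_haplotypes(haps) -> GenotypeSet:
    """Collapse a phased :class:`~jointgp.simpop.HaplotypeSet` to dosages.

    Simulated alleles are labelled A (coded 0) and B (coded 1); the counted
    allele is B, so dosage equals the haplotype sum.
    """
    mm = haps.marker_map[["chrom", "marker_id", "pos"]].copy()
    mm["allele_a"] = "A"
    mm["allele_b"] = "B"
    mm["counted_allele"] = "B"
    return GenotypeSet(
        haps.population, list(haps.animal_ids), mm[MAP_COLUMNS], haps.dosages().astype(float)
    )


def merge_genotype_sets(sets: list[GenotypeSet], population: str = "pooled") -> GenotypeSet:
    """Stack animals across sets sharing an identical (harmonized) marker map."""
    first = sets[0]
    for s in sets[1:]:
        if not (
            s.marker_map["marker_id"].equals(first.marker_map["marker_id"])
            and s.marker_map["counted_allele"].equals(first.marker_map["counted_allele"])
        ):
            raise ValueError("marker maps differ; harmonize first")
    ids = [a for s in sets for a in s.animal_ids]
    dos = np.concatenate([s.dosages for s in sets], axis=0)
    return GenotypeSet(population, ids, first.marker_map.copy(), dos)
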