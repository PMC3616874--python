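"""Linkage disequilibrium from phased haplotypes and its cross-population
consistency.

LD between two biallelic loci is the signed correlation of allele indicators
on a haplotype,

    r = (f(AB) - f(A) f(B)) / sqrt(f(A) f(a) f(B) f(b)),

estimated by direct counting over pooled maternal and paternal haplotypes.
The consistency of LD between two populations is the Pearson correlation,
across adjacent marker pairs on each chromosome, of the signed r values —
a phase-aware measure of whether the same marker captures the same local
haplotype structure in both populations.  An EM fallback estimates the
two-locus haplotype frequency from unphased genotypes under random mating.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simpop import HaplotypeSet

__all__ = [
    "haplotype_frequencies",
    "r_ld",
    "adjacent_ld",
    "ld_consistency",
    "ConsistencySummary",
    "distance_summary",
    "em_pairwise_haplotype_freq",
]


def haplotype_frequencies(haps: HaplotypeSet, i: int, j: int) -> tuple[float, float, float, int]:
    """Observed f(AB), f(A), f(B) at marker indices i, j by counting pooled
    haplotypes; the "A"/"B" alleles are the ones coded 1."""
    m = haps.n_markers
    if not (0 <= i < m and 0 <= j < m):
        raise IndexError(f"marker index out of range (m={m})")
    pooled = haps.pooled()
    hi = pooled[:, i]
    hj = pooled[:, j]
    n = hi.shape[0]
    return (
        float(np.mean((hi == 1) & (hj == 1))),
        float(np.mean(hi == 1)),
        float(np.mean(hj == 1)),
        n,
    )


def r_ld(f_ab: float, f_a: float, f_b: float) -> float:
    """Signed LD correlation; NaN (never 0) at a monomorphic locus."""
    if f_a <= 0.0 or f_a >= 1.0 or f_b <= 0.0 or f_b >= 1.0:
        return float("nan")
    return (f_ab - f_a * f_b) / np.sqrt(f_a * (1 - f_a) * f_b * (1 - f_b))


def adjacent_ld(haps: HaplotypeSet) -> pd.DataFrame:
    """One LD record per adjacent marker pair within each chromosome.

    Columns: chrom, id1, id2, distance_bp, f_ab, f_a, f_b, r, r2.  Pairs
    with a monomorphic member get NaN r (flagged, not dropped).
    """
    mm = haps.marker_map
    pooled = haps.pooled().astype(np.float64)
    f = pooled.mean(axis=0)
    same_chrom = mm["chrom"].to_numpy()[:-1] == mm["chrom"].to_numpy()[1:]
    f_ab = (pooled[:, :-1] * pooled[:, 1:]).mean(axis=0)
    fa, fb = f[:-1], f[1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.sqrt(fa * (1 - fa) * fb * (1 - fb))
        r = np.where(denom > 0, (f_ab - fa * fb) / np.where(denom > 0, denom, 1.0), np.nan)
    rec = pd.DataFrame(
        {
            "chrom": mm["chrom"].to_numpy()[:-1],
            "id1": mm["marker_id"].to_numpy()[:-1],
            "id2": mm["marker_id"].to_numpy()[1:],
            "distance_bp": mm["pos"].to_numpy()[1:] - mm["pos"].to_numpy()[:-1],
            "f_ab": f_ab,
            "f_a": fa,
            "f_b": fb,
            "r": r,
            "r2": r**2,
        }
    )
    return rec[same_chrom].reset_index(drop=True)


@dataclass
class ConsistencySummary:
    """Per-chromosome and overall cross-population LD consistency."""

    per_chrom: pd.DataFrame  # chrom, n_pairs, consistency, mean_r2_a, mean_r2_b
    mean_consistency: float  # unweighted average over chromosomes
    mean_r2: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        out = self.per_chrom.copy()
        mean_row = pd.DataFrame(
            {
                "chrom": ["mean"],
                "n_pairs": [out["n_pairs"].sum()],
                "mean_r2_a": [out["mean_r2_a"].mean()],
                "mean_r2_b": [out["mean_r2_b"].mean()],
                "consistency": [self.mean_consistency],
            }
        )
        return pd.concat([out.astype({"chrom": str}), mean_row], ignore_index=True)


def ld_consistency(
    a: pd.DataFrame, b: pd.DataFrame, min_pairs: int = 3
) -> ConsistencySummary:
    """Correlation of signed r over adjacent pairs defined in both populations.

    Records must come from allele-harmonized marker sets: a systematic
    allele flip in one population negates its r values and the correlation.
    Pairs monomorphic (NaN r) in either population are excluded; chromosomes
    with fewer than ``min_pairs`` usable pairs are omitted with a warning.
    The overall value is the unweighted mean over chromosomes.
    """
    merged = a.merge(b, on=["chrom", "id1", "id2"], suffixes=("_a", "_b"))
    rows = []
    for chrom, grp in merged.groupby("chrom"):
        ok = grp.dropna(subset=["r_a", "r_b"])
        if len(ok) < min_pairs:
            warnings.warn(f"chromosome {chrom}: only {len(ok)} usable pairs; omitted")
            continue
        rows.append(
            {
                "chrom": chrom,
                "n_pairs": len(ok),
                "consistency": float(np.corrcoef(ok["r_a"], ok["r_b"])[0, 1]),
                "mean_r2_a": float(ok["r2_a"].mean()),
                "mean_r2_b": float(ok["r2_b"].mean()),
            }
        )
    per_chrom = pd.DataFrame(rows, columns=["chrom", "n_pairs", "consistency", "mean_r2_a", "mean_r2_b"])
    mean_c = float(per_chrom["consistency"].mean()) if len(per_chrom) else float("nan")
    return ConsistencySummary(
        per_chrom=per_chrom,
        mean_consistency=mean_c,
        mean_r2={
            "a": float(per_chrom["mean_r2_a"].mean()) if len(per_chrom) else float("nan"),
            "b": float(per_chrom["mean_r2_b"].mean()) if len(per_chrom) else float("nan"),
        },
    )


def distance_summary(
    marker_map: pd.DataFrame,
    chrom_lengths_bp: dict | pd.Series | None = None,
    gap_threshold_bp: int = 200_000,
) -> pd.DataFrame:
    """Per-chromosome marker spacing table plus an overall "mean" row.

    The mean gap on a chromosome is span/(n-1), where the span is the
    reported chromosome length when supplied (else last minus first marker
    position).  The overall mean gap is the unweighted average of the
    per-chromosome means; min/max/fraction-over-threshold pool all observed
    gaps.  Chromosomes with a single marker get a NaN mean gap.
    """
    rows = []
    all_gaps = []
    for chrom, grp in marker_map.groupby("chrom"):
        pos = np.sort(grp["pos"].to_numpy())
        n = pos.size
        length = None
        if chrom_lengths_bp is not None and chrom in chrom_lengths_bp:
            length = float(chrom_lengths_bp[chrom])
        if n < 2:
            rows.append(
                {"chrom": chrom, "length_bp": length if length else (0.0 if n == 0 else 0.0),
                 "n_markers": n, "mean_gap_bp": np.nan, "min_gap_bp": np.nan,
                 "max_gap_bp": np.nan, "frac_gap_gt_threshold": np.nan}
            )
            continue
        gaps = np.diff(pos)
        all_gaps.append(gaps)
        span = length if length is not None else float(pos[-1] - pos[0])
        rows.append(
            {
                "chrom": chrom,
                "length_bp": span,
                "n_markers": n,
                "mean_gap_bp": span / (n - 1),
                "min_gap_bp": float(gaps.min()),
                "max_gap_bp": float(gaps.max()),
                "frac_gap_gt_threshold": float(np.mean(gaps > gap_threshold_bp)),
            }
        )
    per = pd.DataFrame(rows)
    pooled = np.concatenate(all_gaps) if all_gaps else np.array([])
    mean_row = {
        "chrom": "mean",
        "length_bp": per["length_bp"].sum(),
        "n_markers": per["n_markers"].sum(),
        "mean_gap_bp": float(per["mean_gap_bp"].mean()),
        "min_gap_bp": float(pooled.min()) if pooled.size else np.nan,
        "max_gap_bp": float(pooled.max()) if pooled.size else np.nan,
        "frac_gap_gt_threshold": float(np.mean(pooled > gap_threshold_bp)) if pooled.size else np.nan,
    }
    return pd.concat([per.astype({"chrom": object}), pd.DataFrame([mean_row])], ignore_index=True)


def em_pairwise_haplotype_freq(
    gi: np.ndarray,
    gj: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> float:
    """EM estimate of f(AB) from unphased dosages at two loci.

    Under Hardy–Weinberg and random mating the only phase-ambiguous class
    is the double heterozygote, whose AB/ab vs Ab/aB split is re-estimated
    from the current haplotype frequencies each iteration.  Pairs with a
    missing call at either locus are dropped.  Returns NaN if either locus
    is monomorphic.
    """
    gi = np.asarray(gi, float)
    gj = np.asarray(gj, float)
    keep = ~(np.isnan(gi) | np.isnan(gj))
    gi, gj = gi[keep], gj[keep]
    n = gi.size
    if n == 0:
        return float("nan")
    p_a = gi.mean() / 2.0
    p_b = gj.mean() / 2.0
    if p_a <= 0 or p_a >= 1 or p_b <= 0 or p_b >= 1:
        return float("nan")
    n_hap = 2.0 * n
    dbl_het = (gi == 1) & (gj == 1)
    n_dh = float(dbl_het.sum())
    # AB haplotype counts are fully determined outside the double-het class:
    # (2,2) carries 2, (2,1) and (1,2) carry 1, everything else 0, i.e.
    # max(gi + gj - 2, 0)
    known_ab = float(np.sum(np.where(dbl_het, 0.0, np.maximum(gi + gj - 2.0, 0.0))))
    f_ab = p_a * p_b  # start at linkage equilibrium
    for _ in range(max_iter):
        f_a_b = p_a - f_ab  # f(Ab)
        f_ab_ = p_b - f_ab  # f(aB)
        f_ab__ = 1.0 - p_a - p_b + f_ab  # f(ab)
        coupling = f_ab * f_ab__
        repulsion = f_a_b * f_ab_
        denom = coupling + repulsion
        frac = 0.5 if denom <= 0 else coupling / denom
        new = (known_ab + n_dh * frac) / n_hap
        if abs(new - f_ab) < tol:
            f_ab = new
            break
        f_ab = new
    return float(f_ab)
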