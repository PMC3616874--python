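"""Genomic relationship matrix (VanRaden method 1) and relatedness summaries.

G = MM'/Σ 2 p_i (1 - p_i), where column i of M holds the centered allele
counts 0 - 2p_i, 1 - 2p_i, 2 - 2p_i and p_i is the counted-allele frequency
computed from whatever animal set is declared the base (a single population,
or the pooled set for joint analyses).  Missing dosages are mean-imputed
(2p_i, i.e. zero after centering) inside G only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .geno_io import GenotypeSet, merge_genotype_sets

__all__ = ["GRM", "allele_frequencies", "build_grm", "relationship_summary"]


@dataclass
class GRM:
    """Symmetric genomic relationship matrix over an ordered animal list."""

    animal_ids: list[str]
    mat: np.ndarray
    p: np.ndarray
    ridge: float

    def __post_init__(self) -> None:
        n = len(self.animal_ids)
        if self.mat.shape != (n, n):
            raise ValueError("matrix shape does not match animal list")
        if not np.allclose(self.mat, self.mat.T, atol=1e-10):
            raise ValueError("G must be symmetric")

    def index_of(self, ids: list[str]) -> np.ndarray:
        lookup = {a: i for i, a in enumerate(self.animal_ids)}
        missing = [a for a in ids if a not in lookup]
        if missing:
            raise KeyError(f"animals not in GRM: {missing[:5]}")
        return np.array([lookup[a] for a in ids])

    def submatrix(self, ids: list[str]) -> np.ndarray:
        idx = self.index_of(ids)
        return self.mat[np.ix_(idx, idx)]

    def write(self, prefix: str | Path) -> None:
        """Lower-triangle (i, j, value) text plus an id index file."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        ii, jj = np.tril_indices(len(self.animal_ids))
        np.savetxt(
            f"{prefix}.grm.txt",
            np.column_stack([ii + 1, jj + 1, self.mat[ii, jj]]),
            fmt=("%d", "%d", "%.10g"), delimiter="\t",
        )
        pd.DataFrame({"index": np.arange(1, len(self.animal_ids) + 1),
                      "animal_id": self.animal_ids}).to_csv(
            f"{prefix}.grm.ids", sep="\t", index=False)

    @classmethod
    def read(cls, prefix: str | Path) -> "GRM":
        prefix = Path(prefix)
        ids = pd.read_csv(f"{prefix}.grm.ids", sep="\t")["animal_id"].astype(str).tolist()
        n = len(ids)
        mat = np.zeros((n, n))
        tri = pd.read_csv(f"{prefix}.grm.txt", sep="\t", header=None, names=["i", "j", "v"])
        mat[tri["i"] - 1, tri["j"] - 1] = tri["v"]
        mat[tri["j"] - 1, tri["i"] - 1] = tri["v"]
        return cls(ids, mat, p=np.array([]), ridge=float("nan"))


def allele_frequencies(g: GenotypeSet | list[GenotypeSet]) -> np.ndarray:
    """Counted-allele frequency per marker, p_i = mean dosage / 2.

    A list of (harmonized) sets is pooled by stacking animals first, so each
    population contributes in proportion to its size.
    """
    if isinstance(g, list):
        g = merge_genotype_sets(g)
    dos = g.dosages
    n_obs = (~np.isnan(dos)).sum(axis=0)
    if (n_obs == 0).any():
        bad = g.marker_map["marker_id"][n_obs == 0].iloc[0]
        raise ValueError(f"marker {bad} has no non-missing calls")
    return np.nanmean(dos, axis=0) / 2.0


def build_grm(g: GenotypeSet, p: np.ndarray | None = None, ridge: float = 1e-6) -> GRM:
    """VanRaden method 1 with mean imputation of missing dosages.

    ``p`` defaults to frequencies computed from ``g`` itself; pass pooled
    frequencies for a joint-reference G.  ``ridge`` is added to the diagonal
    for invertibility of the (rank-deficient, when markers < animals)
    centered cross-product.
    """
    if p is None:
        p = allele_frequencies(g)
    p = np.asarray(p, dtype=float)
    if p.shape != (g.n_markers,):
        raise ValueError("p does not match marker count/order")
    denom = float(np.sum(2.0 * p * (1.0 - p)))
    if denom <= 0.0:
        raise ValueError("all markers monomorphic at the supplied frequencies (zero denominator)")
    m_mat = g.dosages - 2.0 * p[None, :]
    m_mat = np.nan_to_num(m_mat, nan=0.0)  # missing -> 2p -> 0 after centering
    mat = (m_mat @ m_mat.T) / denom
    mat[np.diag_indices_from(mat)] += ridge
    return GRM(list(g.animal_ids), mat, p, ridge)


def relationship_summary(
    grm: GRM, group_a: list[str], group_b: list[str], threshold: float
) -> tuple[pd.DataFrame, dict]:
    """How related is each group-A animal to group B?

    For each A animal: the number of B animals with genomic relationship
    above ``threshold`` and its max relationship; self-pairs are excluded
    when the groups overlap.  The summary reports the fraction of A with at
    least one such partner and the mean partner count.
    """
    ia = grm.index_of(group_a)
    ib = grm.index_of(group_b)
    block = grm.mat[np.ix_(ia, ib)].copy()
    same = ia[:, None] == ib[None, :]
    block[same] = -np.inf
    counts = (block > threshold).sum(axis=1)
    per_a = pd.DataFrame(
        {
            "animal_id": group_a,
            "n_above": counts,
            "max_relationship": np.max(block, axis=1),
        }
    )
    summary = {
        "fraction_with_any": float(np.mean(counts > 0)),
        "mean_count": float(np.mean(counts)),
        "threshold": threshold,
    }
    return per_a, summary
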