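"""Shared fixtures: small genotype/haplotype builders used across modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from jointgp.geno_io import GenotypeSet
from jointgp.simpop import HaplotypeSet


def make_marker_map(n_markers: int, chrom: int = 1, spacing_bp: int = 100_000) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": chrom,
            "marker_id": [f"c{chrom}_m{i + 1}" for i in range(n_markers)],
            "pos": np.arange(n_markers, dtype=np.int64) * spacing_bp + 1,
            "allele_a": "A",
            "allele_b": "B",
            "counted_allele": "B",
        }
    )


def make_genotype_set(dosages, population="pop", chrom=1) -> GenotypeSet:
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    return GenotypeSet(
        population, [f"{population}_{i + 1}" for i in range(n)], make_marker_map(m, chrom), dosages
    )


def make_haplotype_set(haps, population="pop", marker_map=None) -> HaplotypeSet:
    haps = np.asarray(haps, dtype=np.uint8)
    n, _, m = haps.shape
    mm = marker_map if marker_map is not None else make_marker_map(m)
    return HaplotypeSet(population, [f"{population}_{i + 1}" for i in range(n)], haps, mm)


@pytest.fixture
def rng():
    return np.random.default_rng(20130321)
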