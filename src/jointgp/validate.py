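"""Validation designs, the realized-reliability statistic, and the
deterministic expected reliability of genomic prediction.

Two designs mirror practice in dairy-cattle genomic evaluation: (i) a bull
test set from which candidates highly related to the reference bulls are
excluded, and (ii) k-fold cross-validation of cows that assigns whole
half-sib families to folds so a test cow never has her paternal half-sibs
in the reference.  Realized reliability is Cor^2(GEBV, DRP) divided by the
mean DRP reliability of the test set; when birth years span a selection
trend, both GEBV and DRP are first detrended by linear regression on birth
year, otherwise the trend inflates the correlation.

The deterministic expectation follows the classic population-genetic
argument: with Me = 2 Ne L independently segregating chromosome segments,
k = 1/ln(2 Ne), lambda = Me k / h2 and a = 1 + 2 lambda / N,

    E[r2_GEBV] = 1 - lambda / (2 N sqrt(a)) * ln((1 + a + 2 sqrt(a)) /
                                                 (1 + a - 2 sqrt(a))),

with natural logarithms throughout.  h2 here is the squared accuracy of
the reference phenotypes (the DRP reliability when DRP are the phenotype).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grm import GRM

__all__ = [
    "ValidationSplit",
    "GoddardParams",
    "make_bull_split",
    "make_cow_folds",
    "detrend",
    "validation_reliability",
    "goddard_expected_reliability",
]


@dataclass
class ValidationSplit:
    """A reference/test partition; folds carry their test family labels."""

    name: str
    reference_ids: list[str]
    test_ids: list[str]
    fold: int | None = None
    families: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.reference_ids) & set(self.test_ids):
            raise ValueError("reference and test sets overlap")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal_id": self.reference_ids + self.test_ids,
                "role": ["reference"] * len(self.reference_ids) + ["test"] * len(self.test_ids),
                "fold": self.fold if self.fold is not None else -1,
            }
        )


@dataclass(frozen=True)
class GoddardParams:
    """Inputs of the deterministic reliability formula.

    L: genome length in Morgans; ne: effective population size; n:
    reference-population size; h2: squared accuracy of the reference
    phenotypes (DRP reliability).
    """

    L: float
    ne: float
    n: float
    h2: float

    def __post_init__(self) -> None:
        if self.L <= 0 or self.ne < 2 or self.n < 1:
            raise ValueError("need L > 0, Ne >= 2, N >= 1")
        if not (0.0 < self.h2 <= 1.0):
            raise ValueError("h2 must be in (0, 1]")

    @property
    def me(self) -> float:
        return 2.0 * self.ne * self.L

    @property
    def k(self) -> float:
        return 1.0 / np.log(2.0 * self.ne)

    @property
    def lam(self) -> float:
        return self.me * self.k / self.h2

    @property
    def a(self) -> float:
        return 1.0 + 2.0 * self.lam / self.n


def make_bull_split(
    candidate_ids: list[str],
    reference_bull_ids: list[str],
    grm: GRM,
    relationship_max: float = 0.45,
    name: str = "bulls",
) -> ValidationSplit:
    """Bull test set excluding candidates highly related to reference bulls.

    Candidates whose maximum genomic relationship to any reference bull
    reaches ``relationship_max`` are dropped (threshold 0.45 separates
    first-degree kin from half-sibs).  The reference side of the split
    holds the reference bulls; the caller adds cows before fitting.
    """
    ref_idx = grm.index_of(reference_bull_ids)
    test = []
    excluded = []
    for cid in candidate_ids:
        ci = grm.index_of([cid])[0]
        rel = grm.mat[ci, ref_idx]
        if rel.size and rel.max() >= relationship_max:
            excluded.append((cid, float(rel.max())))
        else:
            test.append(cid)
    if not test:
        warnings.warn("bull split has an empty test set")
    split = ValidationSplit(name=name, reference_ids=list(reference_bull_ids), test_ids=test)
    split.excluded = pd.DataFrame(excluded, columns=["animal_id", "max_relationship"])  # type: ignore[attr-defined]
    return split


def make_cow_folds(
    cow_families: pd.DataFrame,
    k_folds: int = 5,
    families_per_fold: tuple[int, int] | None = None,
    rng: np.random.Generator | None = None,
) -> list[ValidationSplit]:
    """Assign whole half-sib families to cross-validation folds.

    ``cow_families`` needs columns animal_id and family.  Fold family
    counts are as equal as possible (13 families over 5 folds gives
    3/3/3/2/2) and fold sizes are balanced greedily by assigning the
    largest families first to the emptiest eligible fold.  Every cow
    appears in exactly one test fold; each fold's reference is all other
    cows (bulls are added by the caller).
    """
    rng = np.random.default_rng() if rng is None else rng
    fam_sizes = cow_families.groupby("family").size().sort_values(ascending=False)
    n_fam = len(fam_sizes)
    if n_fam < k_folds:
        raise ValueError(f"{n_fam} families cannot fill {k_folds} folds")
    base, extra = divmod(n_fam, k_folds)
    counts = np.array([base + (i < extra) for i in range(k_folds)])
    if families_per_fold is not None:
        lo, hi = families_per_fold
        if counts.min() < lo or counts.max() > hi:
            raise ValueError(
                f"{n_fam} families over {k_folds} folds gives counts {sorted(counts)}, "
                f"outside [{lo}, {hi}]"
            )
    # shuffle equal-size families so ties break reproducibly but not by label
    order = fam_sizes.sample(frac=1.0, random_state=np.random.RandomState(rng.integers(2**31))).sort_values(
        ascending=False, kind="mergesort"
    )
    fold_members: list[list[str]] = [[] for _ in range(k_folds)]
    fold_sizes = np.zeros(k_folds, dtype=int)
    fold_counts = np.zeros(k_folds, dtype=int)
    for fam, size in order.items():
        eligible = np.flatnonzero(fold_counts < counts)
        target = eligible[np.argmin(fold_sizes[eligible])]
        fold_members[target].append(fam)
        fold_sizes[target] += size
        fold_counts[target] += 1
    all_ids = cow_families["animal_id"].tolist()
    fam_of = dict(zip(cow_families["animal_id"], cow_families["family"]))
    splits = []
    for i in range(k_folds):
        fams = set(fold_members[i])
        test = [a for a in all_ids if fam_of[a] in fams]
        ref = [a for a in all_ids if fam_of[a] not in fams]
        splits.append(
            ValidationSplit(
                name=f"cow_fold_{i + 1}", reference_ids=ref, test_ids=test,
                fold=i + 1, families=sorted(fams),
            )
        )
    return splits


def detrend(values: np.ndarray, birth_years: np.ndarray) -> np.ndarray:
    """Residuals of an OLS regression of values on birth year.

    Removes the linear genetic trend that selection imprints on both GEBV
    and DRP across birth years.  With fewer than two distinct years the
    values are returned unchanged with a warning.
    """
    values = np.asarray(values, float)
    years = np.asarray(birth_years, float)
    if values.shape != years.shape:
        raise ValueError("values and birth years differ in length")
    if np.unique(years).size < 2:
        warnings.warn("all birth years identical; no trend to remove")
        return values.copy()
    slope, intercept = np.polyfit(years, values, 1)
    return values - (intercept + slope * years)


def validation_reliability(
    gebv: np.ndarray,
    drp: np.ndarray,
    r2_drp: np.ndarray,
    birth_years: np.ndarray | None = None,
) -> float:
    """Realized reliability: Cor^2(GEBV, DRP) / mean(r2_DRP) on the test set.

    If birth years are supplied, both GEBV and DRP are detrended first.
    The statistic is a reliability estimate on the breeding-value scale and
    is not clamped; it can exceed 1 when the DRP reliability is understated.
    """
    gebv = np.asarray(gebv, float)
    drp = np.asarray(drp, float)
    r2 = np.asarray(r2_drp, float)
    if gebv.size < 3:
        raise ValueError("need at least 3 test animals")
    mean_r2 = r2.mean()
    if mean_r2 <= 0:
        raise ValueError("mean DRP reliability must be positive")
    if birth_years is not None:
        gebv = detrend(gebv, birth_years)
        drp = detrend(drp, birth_years)
    if gebv.std() == 0 or drp.std() == 0:
        raise ValueError("zero variance in GEBV or DRP; correlation undefined")
    cor = float(np.corrcoef(gebv, drp)[0, 1])
    return cor**2 / float(mean_r2)


def goddard_expected_reliability(params: GoddardParams | None = None, **kw) -> float:
    """Deterministic expected reliability of GEBV for a reference of size N.

    Accepts a :class:`GoddardParams` or the keyword arguments L, ne, n, h2.
    Natural logarithms are used both in k = 1/ln(2Ne) and in the main term.
    """
    p = params if params is not None else GoddardParams(**kw)
    a = p.a
    if a <= 1.0:
        raise ValueError("a = 1 + 2*lambda/N must exceed 1")
    denom = 1.0 + a - 2.0 * np.sqrt(a)
    if denom <= 0.0:
        raise ValueError("log argument non-positive; parameters out of domain")
    return float(
        1.0 - p.lam / (2.0 * p.n * np.sqrt(a)) * np.log((1.0 + a + 2.0 * np.sqrt(a)) / denom)
    )
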