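"""DRP residual weights and pedigree-consistency (parentage) filtering.

A deregressed proof with reliability r2 carries less information than a
fully accurate record; its residual variance in the mixed model is scaled
by d = (1 - r2)/r2 (record precision proportional to effective daughter
information; d = 1 at r2 = 0.5).  Paternity is screened by opposing
homozygotes on a marker panel: a putative sire homozygous for one allele
while the daughter is homozygous for the other is a Mendelian conflict.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .geno_io import GenotypeSet

logger = logging.getLogger(__name__)

__all__ = ["residual_weights", "parentage_check", "apply_exclusions"]

_WEIGHT_FLOOR = 1e-8


def residual_weights(drp: pd.DataFrame) -> pd.DataFrame:
    """Attach the residual weight d_i = (1 - r2_i)/r2_i to each DRP record.

    r2 = 1 means an exact record; its weight is floored at a small positive
    value (with a warning) so the MME stay finite.
    """
    r2 = drp["r2_drp"].to_numpy(float)
    if (r2 <= 0).any() or (r2 > 1).any():
        raise ValueError("DRP reliabilities must be in (0, 1]")
    d = (1.0 - r2) / r2
    exact = d < _WEIGHT_FLOOR
    if exact.any():
        warnings.warn(
            f"{int(exact.sum())} records with reliability 1; weight floored at {_WEIGHT_FLOOR}"
        )
        d = np.maximum(d, _WEIGHT_FLOOR)
    out = drp.copy()
    out["weight"] = d
    return out


def parentage_check(
    daughters: GenotypeSet,
    sires: GenotypeSet,
    pairs: list[tuple[str, str]],
    panel_marker_ids: list[str] | None = None,
    panel_size: int = 255,
    conflict_threshold: int = 5,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Count opposing homozygotes per (daughter, sire) pair on a marker panel.

    A pair fails when conflicts >= ``conflict_threshold`` (default 5).
    Missing genotypes at a marker skip that marker for that pair.  If no
    panel is given, a random subset of ``panel_size`` shared markers is
    drawn (a seeded ``rng`` makes it reproducible).
    """
    shared = [m for m in daughters.marker_map["marker_id"] if m in set(sires.marker_map["marker_id"])]
    if panel_marker_ids is None:
        if not shared:
            raise ValueError("no shared markers between daughter and sire sets")
        if len(shared) > panel_size:
            rng = np.random.default_rng() if rng is None else rng
            panel_marker_ids = list(rng.choice(shared, size=panel_size, replace=False))
        else:
            panel_marker_ids = shared
    if not panel_marker_ids:
        raise ValueError("empty parentage panel")
    d_idx = {m: j for j, m in enumerate(daughters.marker_map["marker_id"])}
    s_idx = {m: j for j, m in enumerate(sires.marker_map["marker_id"])}
    dj = np.array([d_idx[m] for m in panel_marker_ids])
    sj = np.array([s_idx[m] for m in panel_marker_ids])
    d_animal = {a: i for i, a in enumerate(daughters.animal_ids)}
    s_animal = {a: i for i, a in enumerate(sires.animal_ids)}
    rows = []
    for did, sid in pairs:
        dg = daughters.dosages[d_animal[did], dj]
        sg = sires.dosages[s_animal[sid], sj]
        ok = ~(np.isnan(dg) | np.isnan(sg))
        conflicts = int(np.sum(np.abs(dg[ok] - sg[ok]) == 2))
        rows.append(
            {
                "daughter_id": did,
                "sire_id": sid,
                "n_markers_used": int(ok.sum()),
                "n_conflicts": conflicts,
                "passed": conflicts < conflict_threshold,
            }
        )
    return pd.DataFrame(rows)


def apply_exclusions(drp: pd.DataFrame, check: pd.DataFrame) -> pd.DataFrame:
    """Drop DRP records of daughters that failed the parentage check."""
    failed = set(check.loc[~check["passed"], "daughter_id"])
    if not failed:
        return drp.copy()
    out = drp[~drp["animal_id"].isin(failed)].reset_index(drop=True)
    if out.empty:
        warnings.warn("all records excluded by parentage check")
    logger.info("excluded %d records of %d flagged daughters", len(drp) - len(out), len(failed))
    return out
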