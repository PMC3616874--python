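"""Single- and two-trait GBLUP with AI-REML variance components.

The model is y = Xb + Zg + e with g ~ N(0, G0 ⊗ G) and e ~ N(0, R), where G
is the genomic relationship matrix over all animals (reference and test),
G0 the t x t genetic (co)variance matrix between traits, X fits one mean
per trait, and R = diag(d_i * sigma2_e(trait_i)) carries per-record
residual weights d_i (from DRP reliabilities).  In the two-trait
across-population form, one biological trait is treated as two correlated
traits, each recorded in exactly one population, and the residual
covariance is structurally zero because no animal has records for both.

Variance components are estimated by average-information REML on the
record-space covariance V = Z (G0 ⊗ G) Z' + R, with log-variance /
atanh-correlation parameterization to keep estimates in bounds and
step-halving so accepted steps never decrease the restricted likelihood.
Breeding values are solved from the Henderson mixed-model equations, which
also yield predictions for unphenotyped (test) animals through G.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .grm import GRM

__all__ = [
    "ModelSpec",
    "VarianceComponents",
    "GEBVResult",
    "MMESystem",
    "build_mme",
    "solve_mme",
    "ai_reml",
    "single_trait_gblup",
    "two_trait_gblup",
]

_VAR_FLOOR = 1e-8


@dataclass
class ModelSpec:
    """Phenotype records and the animal list they map into.

    ``records`` columns: animal_id, trait, value, weight (residual weight
    d_i > 0).  ``animal_ids`` is the ordered list spanning the GRM —
    reference and test animals; test animals simply carry no record.
    """

    traits: list[str]
    records: pd.DataFrame
    animal_ids: list[str]

    def __post_init__(self) -> None:
        req = {"animal_id", "trait", "value", "weight"}
        if not req.issubset(self.records.columns):
            raise ValueError(f"records need columns {sorted(req)}")
        if (self.records["weight"] <= 0).any():
            raise ValueError("residual weights must be > 0")
        known = set(self.animal_ids)
        stray = set(self.records["animal_id"]) - known
        if stray:
            raise ValueError(f"records for animals outside the animal list: {sorted(stray)[:5]}")
        stray_traits = set(self.records["trait"]) - set(self.traits)
        if stray_traits:
            raise ValueError(f"records for unknown traits: {sorted(stray_traits)}")
        if len(self.traits) == 2:
            per_animal = self.records.groupby("animal_id")["trait"].nunique()
            if (per_animal > 1).any():
                bad = per_animal[per_animal > 1].index[0]
                raise ValueError(
                    f"two-trait model is population-exclusive but {bad} has records for both traits"
                )

    @property
    def n_traits(self) -> int:
        return len(self.traits)


@dataclass
class VarianceComponents:
    """Estimated (co)variances; sigma_g12 is 0 for a single-trait model."""

    sigma_g: np.ndarray  # per-trait additive genetic variance
    sigma_e: np.ndarray  # per-trait residual variance
    sigma_g12: float = 0.0
    loglik: float = float("nan")
    converged: bool = True
    n_iter: int = 0
    se: np.ndarray | None = None  # from the inverse AI matrix, theta order

    def __post_init__(self) -> None:
        self.sigma_g = np.atleast_1d(np.asarray(self.sigma_g, float))
        self.sigma_e = np.atleast_1d(np.asarray(self.sigma_e, float))
        if (self.sigma_g < 0).any() or (self.sigma_e < 0).any():
            raise ValueError("variances must be non-negative")
        if self.sigma_g.size == 2:
            bound = np.sqrt(self.sigma_g[0] * self.sigma_g[1])
            if abs(self.sigma_g12) > bound * (1 + 1e-8):
                raise ValueError("genetic covariance implies |rG| > 1")

    @property
    def n_traits(self) -> int:
        return self.sigma_g.size

    @property
    def r_g(self) -> float:
        if self.n_traits < 2:
            return float("nan")
        denom = np.sqrt(self.sigma_g[0] * self.sigma_g[1])
        return float(self.sigma_g12 / denom) if denom > 0 else float("nan")

    def g0(self) -> np.ndarray:
        if self.n_traits == 1:
            return np.array([[self.sigma_g[0]]])
        return np.array(
            [[self.sigma_g[0], self.sigma_g12], [self.sigma_g12, self.sigma_g[1]]]
        )

    def theta(self) -> np.ndarray:
        if self.n_traits == 1:
            return np.array([self.sigma_g[0], self.sigma_e[0]])
        return np.array(
            [self.sigma_g[0], self.sigma_g12, self.sigma_g[1], self.sigma_e[0], self.sigma_e[1]]
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [{"component": f"sigma2_g_{i + 1}", "estimate": v} for i, v in enumerate(self.sigma_g)]
        if self.n_traits == 2:
            rows.append({"component": "sigma_g12", "estimate": self.sigma_g12})
            rows.append({"component": "r_g", "estimate": self.r_g})
        rows += [{"component": f"sigma2_e_{i + 1}", "estimate": v} for i, v in enumerate(self.sigma_e)]
        rows.append({"component": "loglik", "estimate": self.loglik})
        return pd.DataFrame(rows)


@dataclass
class GEBVResult:
    """Breeding-value solutions plus solver diagnostics."""

    gebv: pd.DataFrame  # animal_id, trait, gebv
    mu: dict[str, float]
    iterations: int
    residual_norm: float

    def for_trait(self, trait: str) -> pd.Series:
        sub = self.gebv[self.gebv["trait"] == trait]
        return pd.Series(sub["gebv"].to_numpy(), index=sub["animal_id"].to_numpy())


@dataclass
class MMESystem:
    """Henderson mixed-model equations (dense, desk scale)."""

    coeff: np.ndarray
    rhs: np.ndarray
    traits: list[str]
    animal_ids: list[str]
    n_fixed: int


def _design(spec: ModelSpec, grm: GRM):
    """Index arrays mapping records onto traits and GRM animal slots."""
    rec = spec.records
    anim_index = {a: i for i, a in enumerate(grm.animal_ids)}
    missing = [a for a in spec.animal_ids if a not in anim_index]
    if missing:
        raise ValueError(f"animals absent from GRM: {missing[:5]}")
    rec_anim = np.array([anim_index[a] for a in rec["animal_id"]])
    trait_index = {t: k for k, t in enumerate(spec.traits)}
    rec_trait = np.array([trait_index[t] for t in rec["trait"]])
    y = rec["value"].to_numpy(float)
    w = rec["weight"].to_numpy(float)
    return rec_anim, rec_trait, y, w


def build_mme(spec: ModelSpec, grm: GRM, vc: VarianceComponents) -> MMESystem:
    """Assemble the MME for per-trait means and breeding values of every
    animal in the GRM; records enter through Z, test animals only through
    G-inverse."""
    if vc.n_traits != spec.n_traits:
        raise ValueError("variance components do not match trait count")
    rec_anim, rec_trait, y, w = _design(spec, grm)
    na = len(grm.animal_ids)
    t = spec.n_traits
    rinv = 1.0 / (w * vc.sigma_e[rec_trait])
    nf = t
    dim = nf + t * na
    coeff = np.zeros((dim, dim))
    rhs = np.zeros(dim)
    # fixed-by-fixed (means are trait-specific, so diagonal)
    for k in range(t):
        sel = rec_trait == k
        coeff[k, k] = rinv[sel].sum()
        rhs[k] = (rinv[sel] * y[sel]).sum()
    # random columns: trait-major blocks
    col = nf + rec_trait * na + rec_anim
    np.add.at(coeff, (rec_trait, col), rinv)
    coeff[nf:, :nf] = coeff[:nf, nf:].T
    np.add.at(coeff, (col, col), rinv)
    np.add.at(rhs, col, rinv * y)
    try:
        g0_inv = np.linalg.inv(vc.g0())
        c_factor = linalg.cho_factor(grm.mat)
        g_inv = linalg.cho_solve(c_factor, np.eye(na))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular G or G0; increase the GRM ridge or check the variance components"
        ) from exc
    coeff[nf:, nf:] += np.kron(g0_inv, g_inv)
    return MMESystem(coeff, rhs, list(spec.traits), list(grm.animal_ids), nf)


def solve_mme(system: MMESystem, max_refine: int = 5) -> GEBVResult:
    """Direct factorization with iterative refinement.

    The G-inverse block can be ill-conditioned when markers < animals (small
    ridge eigenvalues), so a few refinement sweeps push the relative
    residual down to ~1e-12.
    """
    c = system.coeff
    try:
        factor = linalg.cho_factor(c)
        sol = linalg.cho_solve(factor, system.rhs)
        solve = lambda b: linalg.cho_solve(factor, b)  # noqa: E731
    except np.linalg.LinAlgError:
        lu = linalg.lu_factor(c)
        sol = linalg.lu_solve(lu, system.rhs)
        solve = lambda b: linalg.lu_solve(lu, b)  # noqa: E731
    rhs_norm = np.linalg.norm(system.rhs) or 1.0
    iters = 0
    best_sol = sol
    best_rel = np.linalg.norm(system.rhs - c @ sol) / rhs_norm
    for _ in range(max_refine):
        if best_rel < 1e-12:
            break
        sol = sol + solve(system.rhs - c @ sol)
        iters += 1
        rel = np.linalg.norm(system.rhs - c @ sol) / rhs_norm
        if rel < best_rel:
            best_sol, best_rel = sol, rel
        else:
            break
    sol, rel = best_sol, float(best_rel)
    if rel > 1e-8:
        raise np.linalg.LinAlgError(
            f"mixed-model equations ill-conditioned: relative residual {rel:.2e}"
        )
    na = len(system.animal_ids)
    mu = {t: float(sol[k]) for k, t in enumerate(system.traits)}
    frames = []
    for k, t in enumerate(system.traits):
        g = sol[system.n_fixed + k * na : system.n_fixed + (k + 1) * na]
        frames.append(pd.DataFrame({"animal_id": system.animal_ids, "trait": t, "gebv": g}))
    return GEBVResult(pd.concat(frames, ignore_index=True), mu, iters, rel)


# ---------------------------------------------------------------------------
# AI-REML


def _v_components(spec: ModelSpec, grm: GRM):
    """The constant matrices V_k with V = sum_k theta_k V_k (record space)."""
    rec_anim, rec_trait, y, w = _design(spec, grm)
    g_sub = grm.mat[np.ix_(rec_anim, rec_anim)]
    t = spec.n_traits
    comps = []
    if t == 1:
        comps.append(g_sub)  # sigma2_g
        comps.append(np.diag(w))  # sigma2_e
    else:
        u = [(rec_trait == k).astype(float) for k in range(2)]
        comps.append(g_sub * np.outer(u[0], u[0]))  # sigma2_g1
        comps.append(g_sub * (np.outer(u[0], u[1]) + np.outer(u[1], u[0])))  # sigma_g12
        comps.append(g_sub * np.outer(u[1], u[1]))  # sigma2_g2
        comps.append(np.diag(w * u[0]))  # sigma2_e1
        comps.append(np.diag(w * u[1]))  # sigma2_e2
    x = np.zeros((y.size, t))
    x[np.arange(y.size), rec_trait] = 1.0
    return comps, x, y, rec_trait


def _reml_loglik(theta: np.ndarray, comps, x, y) -> float:
    v = sum(th * vk for th, vk in zip(theta, comps))
    try:
        cf = linalg.cho_factor(v)
    except np.linalg.LinAlgError:
        return -np.inf
    logdet_v = 2.0 * np.log(np.diag(cf[0])).sum()
    w = linalg.cho_solve(cf, x)
    b = x.T @ w
    sign, logdet_b = np.linalg.slogdet(b)
    if sign <= 0:
        return -np.inf
    vy = linalg.cho_solve(cf, y)
    py = vy - w @ np.linalg.solve(b, w.T @ y)
    return float(-0.5 * (logdet_v + logdet_b + y @ py))


def _phi_to_theta(phi: np.ndarray, t: int, fix_rg: float | None):
    """Map unconstrained parameters to (co)variances with the Jacobian."""
    if t == 1:
        theta = np.exp(phi)
        jac = np.diag(theta)
        return theta, jac
    lg1, lg2 = phi[0], phi[1]
    if fix_rg is None:
        rg = np.tanh(phi[2])
        le1, le2 = phi[3], phi[4]
    else:
        rg = fix_rg
        le1, le2 = phi[2], phi[3]
    sg1, sg2 = np.exp(lg1), np.exp(lg2)
    s12 = rg * np.sqrt(sg1 * sg2)
    theta = np.array([sg1, s12, sg2, np.exp(le1), np.exp(le2)])
    n_phi = phi.size
    jac = np.zeros((5, n_phi))
    jac[0, 0] = sg1
    jac[2, 1] = sg2
    jac[1, 0] = 0.5 * s12
    jac[1, 1] = 0.5 * s12
    if fix_rg is None:
        jac[1, 2] = (1.0 - rg**2) * np.sqrt(sg1 * sg2)
        jac[3, 3] = theta[3]
        jac[4, 4] = theta[4]
    else:
        jac[3, 2] = theta[3]
        jac[4, 3] = theta[4]
    return theta, jac


def ai_reml(
    spec: ModelSpec,
    grm: GRM,
    start: VarianceComponents | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
    fix_rg: float | None = None,
) -> VarianceComponents:
    """Average-information REML on the record-space covariance.

    Newton-type updates use the AI matrix in the transformed parameter
    space; proposals that lower the restricted log-likelihood are
    step-halved, so accepted steps are monotone.  Convergence is declared
    when the relative change of every (co)variance falls below ``tol``.
    If ``max_iter`` is exhausted the best estimates are returned with
    ``converged=False``.  ``fix_rg`` pins the genetic correlation (e.g. 0
    to decouple the two traits).
    """
    if len(spec.records) < 2:
        raise ValueError("need at least 2 records")
    t = spec.n_traits
    comps, x, y, rec_trait = _v_components(spec, grm)
    # degenerate data: no residual information
    pheno_var = np.array([np.var(y[rec_trait == k]) for k in range(t)])
    if np.all(pheno_var < 1e-12):
        warnings.warn("phenotypes have zero variance; variance components floored")
        return VarianceComponents(
            sigma_g=np.full(t, _VAR_FLOOR), sigma_e=np.full(t, _VAR_FLOOR),
            sigma_g12=0.0, converged=False,
        )
    pheno_var = np.maximum(pheno_var, 1e-8)
    if start is None:
        sg = 0.5 * pheno_var
        se = 0.5 * pheno_var
        start_rg = 0.5 if fix_rg is None else fix_rg
        s12 = start_rg * np.sqrt(sg[0] * sg[1]) if t == 2 else 0.0
        start = VarianceComponents(sigma_g=sg, sigma_e=se, sigma_g12=s12)
    if t == 1:
        phi = np.log(np.array([start.sigma_g[0], start.sigma_e[0]]))
    else:
        rg0 = np.clip(start.r_g if fix_rg is None else 0.0, -0.99, 0.99)
        logs = np.log(np.maximum(
            [start.sigma_g[0], start.sigma_g[1], start.sigma_e[0], start.sigma_e[1]],
            _VAR_FLOOR,
        ))
        phi = (
            np.array([logs[0], logs[1], np.arctanh(rg0), logs[2], logs[3]])
            if fix_rg is None
            else np.array([logs[0], logs[1], logs[2], logs[3]])
        )
    # box constraints in the transformed space: variances in a huge but
    # finite range, |rG| <= 0.995 so G0 stays numerically invertible
    lo = np.full(phi.shape, np.log(1e-10))
    hi = np.full(phi.shape, np.log(1e10))
    if t == 2 and fix_rg is None:
        lo[2], hi[2] = -np.arctanh(0.995), np.arctanh(0.995)
    phi = np.clip(phi, lo, hi)
    theta, jac = _phi_to_theta(phi, t, fix_rg)
    loglik = _reml_loglik(theta, comps, x, y)
    n_iter = 0
    converged = False
    ai_theta = None
    for n_iter in range(1, max_iter + 1):
        v = sum(th * vk for th, vk in zip(theta, comps))
        cf = linalg.cho_factor(v)
        v_inv = linalg.cho_solve(cf, np.eye(y.size))
        w = v_inv @ x
        b = x.T @ w
        b_inv = np.linalg.inv(b)
        py = v_inv @ y - w @ (b_inv @ (w.T @ y))
        n_th = len(comps)
        score = np.zeros(n_th)
        s_vecs = []
        for k, vk in enumerate(comps):
            tr_pvk = float(np.sum(v_inv * vk)) - float(np.trace(b_inv @ (w.T @ vk @ w)))
            sk = vk @ py
            s_vecs.append(sk)
            score[k] = -0.5 * (tr_pvk - float(py @ sk))
        s_mat = np.column_stack(s_vecs)
        ps = v_inv @ s_mat - w @ (b_inv @ (w.T @ s_mat))
        ai_theta = 0.5 * (s_mat.T @ ps)
        score_phi = jac.T @ score
        ai_phi = jac.T @ ai_theta @ jac
        ai_phi += 1e-10 * np.eye(ai_phi.shape[0])
        try:
            step = np.linalg.solve(ai_phi, score_phi)
        except np.linalg.LinAlgError:
            step = score_phi / np.maximum(np.diag(ai_phi), 1e-8)
        step = np.clip(step, -3.0, 3.0)
        improved = False
        for _ in range(30):
            phi_new = np.clip(phi + step, lo, hi)
            theta_new, jac_new = _phi_to_theta(phi_new, t, fix_rg)
            ll_new = _reml_loglik(theta_new, comps, x, y)
            if ll_new >= loglik - 1e-10:
                improved = True
                break
            step *= 0.5
        if not improved:
            converged = True  # cannot improve further along the AI direction
            break
        rel_change = np.max(np.abs(theta_new - theta) / (np.abs(theta) + 1e-12))
        phi, theta, jac, loglik = phi_new, theta_new, jac_new, ll_new
        if rel_change < tol:
            converged = True
            break
    se = None
    if ai_theta is not None:
        try:
            se = np.sqrt(np.abs(np.diag(np.linalg.inv(ai_theta))))
        except np.linalg.LinAlgError:
            se = None
    if t == 1:
        return VarianceComponents(
            sigma_g=np.array([theta[0]]), sigma_e=np.array([theta[1]]),
            loglik=loglik, converged=converged, n_iter=n_iter, se=se,
        )
    return VarianceComponents(
        sigma_g=np.array([theta[0], theta[2]]), sigma_g12=float(theta[1]),
        sigma_e=np.array([theta[3], theta[4]]),
        loglik=loglik, converged=converged, n_iter=n_iter, se=se,
    )


def single_trait_gblup(
    spec: ModelSpec, grm: GRM, vc: VarianceComponents | None = None, **reml_kw
) -> tuple[VarianceComponents, GEBVResult]:
    """Estimate variances (unless supplied) and solve for GEBV."""
    if spec.n_traits != 1:
        raise ValueError("single_trait_gblup needs a one-trait ModelSpec")
    if vc is None:
        vc = ai_reml(spec, grm, **reml_kw)
    result = solve_mme(build_mme(spec, grm, vc))
    return vc, result


def two_trait_gblup(
    spec: ModelSpec, grm: GRM, vc: VarianceComponents | None = None,
    fix_rg: float | None = None, **reml_kw
) -> tuple[VarianceComponents, GEBVResult]:
    """Across-population two-trait GBLUP on a joint reference.

    Trait 1 records come from population A, trait 2 from population B; the
    shared GRM spans both.  The trait-1 GEBV of every animal (including A's
    test animals) is the joint-reference prediction.
    """
    if spec.n_traits != 2:
        raise ValueError("two_trait_gblup needs a two-trait ModelSpec")
    counts = spec.records.groupby("trait").size()
    for tr in spec.traits:
        if counts.get(tr, 0) < 2:
            raise ValueError(f"trait {tr!r} has fewer than 2 records")
    if vc is None:
        vc = ai_reml(spec, grm, fix_rg=fix_rg, **reml_kw)
    result = solve_mme(build_mme(spec, grm, vc))
    return vc, result
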