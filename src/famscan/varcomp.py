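"""Maximum-likelihood variance-component models on pedigrees.

The trait model is multivariate normal,

    y ~ N(X beta, Omega),   Omega = sigma2_a * 2*Phi + sigma2_q * Pi + sigma2_e * I,

with Phi the pedigree kinship matrix and Pi a locus-specific IBD-sharing
matrix.  All hypothesis tests are likelihood-ratio tests between nested ML
fits (not REML, so fits with different fixed effects remain comparable):

* heritability:        sigma2_a = 0, null on the boundary -> 1/2 chi2_0 + 1/2 chi2_1
* measured genotype:   gamma = 0 (interior)               -> chi2_1
* linkage:             sigma2_q = 0 (boundary)            -> 1/2 chi2_0 + 1/2 chi2_1
* joint linkage/assoc: gamma = 0 and sigma2_q = 0         -> 1/2 chi2_1 + 1/2 chi2_2

Variances are optimized on their natural scale with an explicit lower bound
of zero so boundary solutions are attainable — that is what makes the
mixture null distributions correct.  Fixed effects are profiled out by
generalized least squares at every variance iterate, and the likelihood is
accumulated family block by family block (families are independent), which
keeps a ~630-individual evaluation at the cost of forty small Cholesky
factorizations.

A fast path for two-component (polygenic + residual) models rotates the
data by the eigenvectors of 2*Phi once, after which every fit is a weighted
regression plus a one-dimensional heritability search; genome scans use it
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import chi2

_LOG2PI = np.log(2.0 * np.pi)
_BOUNDARY_FRAC = 1e-7  # variance below this fraction of var(y) counts as "at zero"


class SingularModelError(RuntimeError):
    """Covariance not positive definite at the requested parameters."""


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass
class VCFit:
    """A fitted variance-component model."""

    beta: np.ndarray
    variances: dict[str, float]
    loglik: float
    converged: bool
    n_iter: int
    boundary: dict[str, bool]
    n: int

    def summary(self) -> str:
        lines = [f"n = {self.n}   lnL = {self.loglik:.6f}   converged = {self.converged}"]
        for k, v in self.variances.items():
            flag = "  (boundary)" if self.boundary.get(k) else ""
            lines.append(f"  sigma2_{k} = {v:.6g}{flag}")
        lines.append("  beta = " + np.array2string(self.beta, precision=6))
        return "\n".join(lines)


@dataclass
class H2Result:
    h2: float
    lrt: float
    p: float
    sigma2_a: float
    sigma2_e: float
    loglik: float
    beta: np.ndarray
    n: int


@dataclass
class AssocResult:
    """Measured-genotype association at one SNP."""

    snp: str | None
    maf: float
    gamma: float
    lrt: float
    p: float
    effect_size_pct: float
    n: int


@dataclass
class LinkageResult:
    lod: float
    lrt: float
    p: float
    sigma2_q: float
    fit: VCFit


@dataclass
class JLAResult:
    """Joint linkage/association test at one locus."""

    snp: str | None
    maf: float
    gamma: float
    sigma2_q: float
    lrt: float
    p: float
    n: int
    fit: VCFit = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# Block bookkeeping
# ---------------------------------------------------------------------------

def _family_blocks(n: int, families) -> list[np.ndarray]:
    if families is None:
        return [np.arange(n)]
    families = np.asarray(families)
    return [np.nonzero(families == f)[0] for f in pd.unique(families)]


def _block_data(y, X, structures, blocks):
    """Per-family slices of y, X and every covariance structure."""
    out = []
    for idx in blocks:
        out.append(
            (
                y[idx],
                X[idx],
                [S[np.ix_(idx, idx)] for S in structures],
            )
        )
    return out


def _profiled_nll(v, block_data, n, p, with_grad=False):
    """-lnL with beta profiled out by GLS; v = genetic variances + residual.

    With ``with_grad`` also returns the analytic gradient
    d(-lnL)/dv_k = 0.5 * (tr(Omega^-1 S_k) - r' Omega^-1 S_k Omega^-1 r)
    evaluated at the profiled beta (valid by the envelope theorem).
    """
    *vg, ve = v
    logdet = 0.0
    xtx = np.zeros((p, p))
    xty = np.zeros(p)
    yty = 0.0
    inverses = []
    for yb, Xb, Sb in block_data:
        omega = ve * np.eye(len(yb))
        for vk, S in zip(vg, Sb):
            if vk != 0.0:
                omega += vk * S
        try:
            c, low = cho_factor(omega, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            return (np.inf, np.zeros(len(v))) if with_grad else np.inf
        logdet += 2.0 * np.log(np.diag(c)).sum()
        sol = cho_solve((c, low), np.column_stack([Xb, yb]), check_finite=False)
        wx, wy = sol[:, :-1], sol[:, -1]
        xtx += Xb.T @ wx
        xty += Xb.T @ wy
        yty += yb @ wy
        if with_grad:
            inverses.append(cho_solve((c, low), np.eye(len(yb)), check_finite=False))
    try:
        beta = np.linalg.solve(xtx, xty)
    except np.linalg.LinAlgError:
        return (np.inf, np.zeros(len(v))) if with_grad else np.inf
    quad = yty - beta @ xty
    f = 0.5 * (n * _LOG2PI + logdet + quad)
    if not with_grad:
        return f
    grad = np.zeros(len(v))
    for (yb, Xb, Sb), Oi in zip(block_data, inverses):
        u = Oi @ (yb - Xb @ beta)
        for k, S in enumerate(Sb):
            grad[k] += 0.5 * (np.sum(Oi * S) - u @ S @ u)
        grad[-1] += 0.5 * (np.trace(Oi) - u @ u)
    return f, grad


def _gls_beta(v, block_data, p):
    *vg, ve = v
    xtx = np.zeros((p, p))
    xty = np.zeros(p)
    for yb, Xb, Sb in block_data:
        omega = ve * np.eye(len(yb))
        for vk, S in zip(vg, Sb):
            omega += vk * S
        c, low = cho_factor(omega, lower=True)
        sol = cho_solve((c, low), np.column_stack([Xb, yb]))
        xtx += Xb.T @ sol[:, :-1]
        xty += Xb.T @ sol[:, -1]
    return np.linalg.solve(xtx, xty)


# ---------------------------------------------------------------------------
# Public likelihood / ML fit
# ---------------------------------------------------------------------------

def loglik(y, X, beta, variances: dict[str, float], structures: dict[str, np.ndarray],
           families=None) -> float:
    """Multivariate-normal log-likelihood at fixed parameters.

    ``variances`` must contain a ``"residual"`` entry plus one entry per
    named structure; ``structures`` maps names to full covariance
    structures (e.g. ``{"additive": 2 * phi}``).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = y.size
    blocks = _family_blocks(n, families)
    names = list(structures)
    v = [variances[k] for k in names] + [variances["residual"]]
    resid = y - X @ np.asarray(beta, dtype=float)
    ll = 0.0
    for idx in blocks:
        omega = v[-1] * np.eye(idx.size)
        for vk, name in zip(v[:-1], names):
            omega += vk * structures[name][np.ix_(idx, idx)]
        try:
            c, low = cho_factor(omega, lower=True)
        except np.linalg.LinAlgError as err:
            cond = np.linalg.cond(omega)
            raise SingularModelError(
                f"covariance block not positive definite (cond={cond:.3g})"
            ) from err
        sol = cho_solve((c, low), resid[idx])
        ll -= 0.5 * (
            idx.size * _LOG2PI + 2.0 * np.log(np.diag(c)).sum() + resid[idx] @ sol
        )
    return float(ll)


def fit_ml(
    y,
    X,
    structures: dict[str, np.ndarray],
    families=None,
    restarts: int = 3,
    tol: float = 1e-8,
) -> VCFit:
    """Maximum-likelihood fit of a variance-component model.

    ``structures`` holds the genetic covariance structures (residual
    identity is always added); every variance is constrained >= 0 with the
    boundary attainable.  The optimizer is L-BFGS-B on the variances with
    GLS-profiled fixed effects, restarted from perturbed initializations;
    the best of all converged runs is returned.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    n, p = X.shape
    if n <= p:
        raise ValueError("need more observations than fixed effects")
    names = list(structures)
    blocks = _family_blocks(n, families)
    block_data = _block_data(y, X, [structures[k] for k in names], blocks)

    vy = float(np.var(y))
    if vy == 0.0:
        raise ValueError("trait is constant")
    k = len(names)
    base = np.array([vy / (k + 1)] * k + [vy * (1.0 - k / (k + 1.0))])
    inits = [base]
    # near-boundary start first: the no-genetic-variance corner is a
    # frequent second mode on small pedigrees and must always be probed
    perturb = [
        np.array([0.01] * k + [1.8]),
        np.array([1.5] * k + [0.4]),
        np.array([0.1] * k + [1.5]),
    ]
    for q in perturb[: max(0, restarts - 1)]:
        inits.append(base * q)

    bounds = [(0.0, None)] * k + [(vy * 1e-10, None)]
    best = None
    n_iter = 0
    any_converged = False
    for v0 in inits:
        res = optimize.minimize(
            _profiled_nll,
            v0,
            args=(block_data, n, p, True),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": tol, "gtol": 1e-12, "maxiter": 1000},
        )
        n_iter += res.nit
        any_converged = any_converged or res.success
        if best is None or res.fun < best.fun:
            best = res
    vhat = best.x
    beta = _gls_beta(vhat, block_data, p)
    variances = {name: float(v) for name, v in zip(names, vhat[:-1])}
    variances["residual"] = float(vhat[-1])
    boundary = {name: bool(v <= _BOUNDARY_FRAC * vy) for name, v in variances.items()}
    return VCFit(
        beta=beta,
        variances=variances,
        loglik=float(-best.fun),
        converged=bool(any_converged),
        n_iter=int(n_iter),
        boundary=boundary,
        n=n,
    )


# ---------------------------------------------------------------------------
# Rotated fast path (polygenic + residual only)
# ---------------------------------------------------------------------------

class PolygenicRotation:
    """One-time spectral decomposition of 2*Phi, block by family.

    After rotation by the eigenvectors, the polygenic-plus-residual
    covariance is diagonal, ``sigma2 * (h * lam + (1 - h))``, so each model
    fit reduces to a weighted regression and a bounded one-dimensional
    search over the heritability ratio h.
    """

    def __init__(self, phi: np.ndarray, families=None):
        n = phi.shape[0]
        self.n = n
        self.blocks = _family_blocks(n, families)
        A = 2.0 * np.asarray(phi, dtype=float)
        lams, Us = [], []
        for idx in self.blocks:
            w, U = np.linalg.eigh(A[np.ix_(idx, idx)])
            lams.append(w)
            Us.append(U)
        self.lam = np.concatenate(lams)
        self._Us = Us
        self._order = np.concatenate(self.blocks)

    def rotate(self, arr: np.ndarray) -> np.ndarray:
        """Apply U^T blockwise; accepts a vector or (n, p) matrix."""
        arr = np.asarray(arr, dtype=float)
        out = np.empty_like(arr)
        pos = 0
        for idx, U in zip(self.blocks, self._Us):
            seg = arr[idx]
            out[pos: pos + idx.size] = U.T @ seg
            pos += idx.size
        return out


def _rotated_profile(h, yr, Xr, lam):
    """(-lnL, sigma2, beta) at heritability ratio h with total variance profiled."""
    w = h * lam + (1.0 - h)
    if np.any(w <= 0.0):
        return np.inf, None, None
    wi = 1.0 / w
    Xw = Xr * wi[:, None]
    xtx = Xr.T @ Xw
    xty = Xw.T @ yr
    try:
        beta = np.linalg.solve(xtx, xty)
    except np.linalg.LinAlgError:
        return np.inf, None, None
    r = yr - Xr @ beta
    quad = float(r @ (r * wi))
    n = yr.size
    if quad <= 0.0:
        return np.inf, None, None
    sigma2 = quad / n
    nll = 0.5 * (n * _LOG2PI + n * np.log(sigma2) + np.log(w).sum() + n)
    return nll, sigma2, beta


def fit_polygenic_rotated(yr, Xr, lam, xatol: float = 1e-10):
    """ML fit of the rotated polygenic model; returns a dict with
    loglik, h2, sigma2_a, sigma2_e and beta.  The h = 0 boundary is always
    evaluated explicitly so null fits are exact."""
    def obj(h):
        return _rotated_profile(h, yr, Xr, lam)[0]

    res = optimize.minimize_scalar(
        obj, bounds=(0.0, 1.0 - 1e-9), method="bounded", options={"xatol": xatol}
    )
    cands = [0.0, float(res.x)]
    best_h = min(cands, key=obj)
    nll, sigma2, beta = _rotated_profile(best_h, yr, Xr, lam)
    return {
        "loglik": -nll,
        "h2": best_h,
        "sigma2_a": best_h * sigma2,
        "sigma2_e": (1.0 - best_h) * sigma2,
        "beta": beta,
    }


# ---------------------------------------------------------------------------
# Tests
# ---------------------------------------------------------------------------

def _design(n, covariates):
    if covariates is None:
        return np.ones((n, 1))
    C = np.atleast_2d(np.asarray(covariates, dtype=float))
    if C.shape[0] != n:
        C = C.T
    return np.column_stack([np.ones(n), C])


def h2_test(y, phi=None, covariates=None, families=None,
            rotation: PolygenicRotation | None = None) -> H2Result:
    """Polygenic heritability estimate and boundary LRT against sigma2_a = 0.

    p = 0.5 * P(chi2_1 >= T) for T > 0 and p = 1 at T = 0 (the null value
    sits on the parameter boundary, so the null distribution is the
    1/2 chi2_0 + 1/2 chi2_1 mixture).
    """
    y = np.asarray(y, dtype=float)
    if rotation is None:
        rotation = PolygenicRotation(phi, families)
    X = _design(y.size, covariates)
    yr, Xr = rotation.rotate(y), rotation.rotate(X)
    full = fit_polygenic_rotated(yr, Xr, rotation.lam)
    null_nll, _, _ = _rotated_profile(0.0, yr, Xr, rotation.lam)
    lrt = max(0.0, 2.0 * (full["loglik"] + null_nll))
    p = 1.0 if lrt <= 0.0 else 0.5 * float(chi2.sf(lrt, 1))
    return H2Result(
        h2=full["h2"], lrt=lrt, p=p,
        sigma2_a=full["sigma2_a"], sigma2_e=full["sigma2_e"],
        loglik=full["loglik"], beta=full["beta"], n=y.size,
    )


def mga_test(
    y,
    dosage,
    phi=None,
    covariates=None,
    families=None,
    rotation: PolygenicRotation | None = None,
    snp_id: str | None = None,
    null_loglik: float | None = None,
) -> AssocResult:
    """Measured-genotype association: 1-df LRT on the additive dosage effect.

    Both the null and the full model carry the polygenic kinship component;
    the SNP enters as a fixed effect gamma per copy of the minor allele
    (dosages may be fractional for imputed calls).  ``null_loglik`` lets a
    genome scan reuse the SNP-free fit.
    """
    y = np.asarray(y, dtype=float)
    d = np.asarray(dosage, dtype=float)
    if d.size != y.size:
        raise ValueError("dosage length does not match trait")
    if np.var(d) == 0.0:
        raise ValueError("monomorphic dosage")
    if rotation is None:
        rotation = PolygenicRotation(phi, families)
    X0 = _design(y.size, covariates)
    yr = rotation.rotate(y)
    X0r = rotation.rotate(X0)
    X1r = np.column_stack([X0r, rotation.rotate(d)])
    if null_loglik is None:
        null_loglik = fit_polygenic_rotated(yr, X0r, rotation.lam)["loglik"]
    full = fit_polygenic_rotated(yr, X1r, rotation.lam)
    lrt = max(0.0, 2.0 * (full["loglik"] - null_loglik))
    p = float(chi2.sf(lrt, 1))
    gamma = float(full["beta"][-1])
    maf = float(np.mean(d) / 2.0)
    # residual phenotypic variance: covariate-adjusted trait (SNP excluded)
    adj = y - X0 @ np.linalg.lstsq(X0, y, rcond=None)[0] if X0.shape[1] > 1 else y - y.mean()
    es = effect_size(gamma, maf, float(np.var(adj)))
    return AssocResult(
        snp=snp_id, maf=maf, gamma=gamma, lrt=lrt, p=p,
        effect_size_pct=es, n=y.size,
    )


def linkage_test(y, phi, ibd, covariates=None, families=None,
                 restarts: int = 3) -> LinkageResult:
    """Variance-component linkage test at one locus.

    Full model adds the locus-specific component sigma2_q * Pi to the
    polygenic model; the boundary null gives p = 0.5 * P(chi2_1 >= T) and
    LOD = T / (2 ln 10).
    """
    y = np.asarray(y, dtype=float)
    X = _design(y.size, covariates)
    rotation = PolygenicRotation(phi, families)
    null = fit_polygenic_rotated(rotation.rotate(y), rotation.rotate(X), rotation.lam)
    full = fit_ml(
        y, X, {"additive": 2.0 * phi, "qtl": ibd}, families=families, restarts=restarts
    )
    lrt = max(0.0, 2.0 * (full.loglik - null["loglik"]))
    p = 1.0 if lrt <= 0.0 else 0.5 * float(chi2.sf(lrt, 1))
    lod = lrt / (2.0 * np.log(10.0))
    return LinkageResult(lod=lod, lrt=lrt, p=p,
                         sigma2_q=full.variances["qtl"], fit=full)


def jla_test(
    y,
    dosage,
    phi,
    ibd,
    covariates=None,
    families=None,
    restarts: int = 3,
    rotation: PolygenicRotation | None = None,
    null_loglik: float | None = None,
    snp_id: str | None = None,
) -> JLAResult:
    """Joint linkage/association: saturated model vs doubly-constrained null.

    The saturated model carries the SNP fixed effect gamma *and* the
    locus-specific variance sigma2_q (covariates estimated simultaneously);
    the null constrains both to zero but keeps the polygenic component.
    Because sigma2_q is tested on its boundary, T is referred to the
    1:1 mixture of chi2_1 and chi2_2: p = (P(chi2_1 >= T) + P(chi2_2 >= T)) / 2.
    """
    y = np.asarray(y, dtype=float)
    d = np.asarray(dosage, dtype=float)
    if np.var(d) == 0.0:
        raise ValueError("monomorphic dosage")
    X0 = _design(y.size, covariates)
    if null_loglik is None:
        if rotation is None:
            rotation = PolygenicRotation(phi, families)
        null_loglik = fit_polygenic_rotated(
            rotation.rotate(y), rotation.rotate(X0), rotation.lam
        )["loglik"]
    X1 = np.column_stack([X0, d])
    full = fit_ml(
        y, X1, {"additive": 2.0 * phi, "qtl": ibd}, families=families, restarts=restarts
    )
    lrt = max(0.0, 2.0 * (full.loglik - null_loglik))
    p = 1.0 if lrt <= 0.0 else mixture_sf(lrt, (0.5, 0.5), (1, 2))
    return JLAResult(
        snp=snp_id, maf=float(np.mean(d) / 2.0), gamma=float(full.beta[-1]),
        sigma2_q=full.variances["qtl"], lrt=lrt, p=p, n=y.size, fit=full,
    )


def mixture_sf(T: float, weights, dfs) -> float:
    """Survival function of a mixture of chi-square distributions.

    ``dfs`` may include 0, meaning a point mass at zero with
    P(chi2_0 >= T) = 1 if T <= 0 else 0 — the boundary component of
    constrained LRTs.
    """
    w = np.asarray(weights, dtype=float)
    k = np.asarray(dfs, dtype=float)
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be non-negative and sum to 1")
    if np.any(k < 0):
        raise ValueError("degrees of freedom must be >= 0")
    p = 0.0
    for wi, ki in zip(w, k):
        if ki == 0:
            p += wi * (1.0 if T <= 0.0 else 0.0)
        else:
            p += wi * float(chi2.sf(T, ki))
    return float(p)


def effect_size(gamma: float, maf: float, residual_variance: float) -> float:
    """Percent of residual phenotypic variance explained by the minor allele:
    100 * 2 p (1-p) gamma^2 / sigma2_residual."""
    if residual_variance <= 0.0:
        raise ValueError("residual variance must be positive")
    return float(100.0 * 2.0 * maf * (1.0 - maf) * gamma ** 2 / residual_variance)
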