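"""Exact single-locus genotype inference on a pedigree.

Implements Elston-Stewart-style peeling as sum-product variable elimination
on the pedigree's Bayesian network: founder genotypes carry Hardy-Weinberg
priors at the (minor) allele frequency, non-founders a Mendelian
transmission factor given both parents, and observed calls enter as
point-mass evidence.  For loop-free pedigrees (the package simulator mates
founders in from an unrelated population, so all generated pedigrees
qualify) elimination is exact and cheap; pedigrees with loops are still
handled exactly, only with larger intermediate factors.

The quantity consumed downstream is the conditional expectation of the
minor-allele count for a missing call given every observed relative in the
family — the "weighted covariate" used in place of a hard genotype.
"""

from __future__ import annotations

import numpy as np

from .pedigree import Pedigree


def transmission_tensor() -> np.ndarray:
    """T[gf, gm, gc] = P(child genotype | father, mother) at a biallelic locus."""
    prob_transmit = np.array([0.0, 0.5, 1.0])  # P(pass minor | genotype)
    T = np.zeros((3, 3, 3))
    for gf in range(3):
        for gm in range(3):
            pf, pm = prob_transmit[gf], prob_transmit[gm]
            T[gf, gm, 0] = (1 - pf) * (1 - pm)
            T[gf, gm, 1] = pf * (1 - pm) + (1 - pf) * pm
            T[gf, gm, 2] = pf * pm
    return T


_T = transmission_tensor()


class _Factor:
    __slots__ = ("vars", "values")

    def __init__(self, vars: tuple[int, ...], values: np.ndarray):
        self.vars = vars
        self.values = values


def _multiply(a: _Factor, b: _Factor) -> _Factor:
    # a's variables occupy the leading axes of the output in order; b's axes
    # are moved to their positions in out_vars and broadcast elsewhere.
    out_vars = a.vars + tuple(v for v in b.vars if v not in a.vars)
    pad_a = len(out_vars) - len(a.vars)
    pad_b = len(out_vars) - len(b.vars)
    av = a.values.reshape(a.values.shape + (1,) * pad_a)
    bv = b.values.reshape(b.values.shape + (1,) * pad_b)
    bv = np.moveaxis(bv, range(len(b.vars)), [out_vars.index(v) for v in b.vars])
    return _Factor(out_vars, av * bv)


def _marginalize(f: _Factor, var: int) -> _Factor:
    ax = f.vars.index(var)
    return _Factor(tuple(v for v in f.vars if v != var), f.values.sum(axis=ax))


def _eliminate(factors: list[_Factor], keep: tuple[int, ...] = ()) -> float | np.ndarray:
    """Sum out all variables not in `keep`; returns total probability (scalar)
    or the unnormalized marginal table over `keep`."""
    factors = list(factors)
    # Peel children before parents (higher local index = later generation in
    # table order), which keeps intermediate factors at nuclear-family size
    # on loop-free pedigrees.
    all_vars = sorted({v for f in factors for v in f.vars} - set(keep), reverse=True)
    for var in all_vars:
        touching = [f for f in factors if var in f.vars]
        rest = [f for f in factors if var not in f.vars]
        prod = touching[0]
        for f in touching[1:]:
            prod = _multiply(prod, f)
        factors = rest + [_marginalize(prod, var)]
    result = _Factor((), np.ones(()))
    for f in factors:
        result = _multiply(result, f)
    if keep:
        perm = [result.vars.index(v) for v in keep]
        return np.transpose(result.values, perm)
    return float(result.values)


def family_posteriors(
    ped: Pedigree,
    rows: np.ndarray,
    calls: np.ndarray,
    p_minor: float,
) -> dict[int, np.ndarray]:
    """Posterior genotype distributions for every untyped member of one family.

    Parameters
    ----------
    rows:
        Pedigree row positions of the family's members.
    calls:
        Minor-allele counts aligned with `rows` (NaN = untyped).
    p_minor:
        Founder minor-allele frequency (Hardy-Weinberg prior).

    Returns
    -------
    dict mapping pedigree row -> length-3 posterior over {0, 1, 2}.

    Raises
    ------
    ValueError
        If the observed configuration has probability zero (a Mendelian
        inconsistency; blank errors before imputing).
    """
    q = 1.0 - p_minor
    prior = np.array([q * q, 2 * p_minor * q, p_minor * p_minor])
    local = {int(r): k for k, r in enumerate(rows)}
    parents = ped.parent_indices

    base: list[_Factor] = []
    for r in rows:
        k = local[int(r)]
        f, m = parents[r]
        if f < 0:
            base.append(_Factor((k,), prior.copy()))
        else:
            base.append(_Factor((local[int(f)], local[int(m)], k), _T.copy()))
        g = calls[k]
        if not np.isnan(g):
            ev = np.zeros(3)
            ev[int(g)] = 1.0
            base.append(_Factor((k,), ev))

    missing = [k for k, g in enumerate(calls) if np.isnan(g)]
    out: dict[int, np.ndarray] = {}
    if not missing:
        return out
    total = _eliminate(base)
    if total <= 0.0:
        raise ValueError("observed genotypes are Mendelianly inconsistent in this family")
    for k in missing:
        marg = _eliminate(base, keep=(k,))
        s = marg.sum()
        out[int(rows[k])] = marg / s
    return out


def expected_dosage(posterior: np.ndarray) -> float:
    return float(posterior @ np.array([0.0, 1.0, 2.0]))
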