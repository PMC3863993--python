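"""Genome scans, empirical thresholds and diagnostics.

Orchestrates per-SNP measured-genotype association (MGA) and joint
linkage/association (JLA) over a dosage panel, conditional scans, the
null-scan procedure for empirical genome-wide significance thresholds, the
genomic-control inflation factor, and the effective-number-of-tests
correction for candidate SNP sets.  All heavy lifting is delegated to
:mod:`famscan.varcomp`; this module owns orchestration and result I/O.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .qc import DosageMatrix
from .varcomp import (
    PolygenicRotation,
    effect_size,
    fit_polygenic_rotated,
    jla_test,
    mga_test,
)

log = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "snp", "chrom", "pos", "minor_allele", "maf", "gamma",
    "lrt_mga", "p_mga", "lrt_jla", "p_jla", "effect_size_pct", "n",
]


@dataclass
class ScanResult:
    """Per-SNP scan statistics plus run metadata, sorted by (chrom, pos)."""

    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        t = self.table
        for c in RESULT_COLUMNS:
            if c not in t.columns:
                t[c] = np.nan
        t = t[RESULT_COLUMNS]
        self.table = t.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


@dataclass
class ThresholdEstimate:
    """Empirical genome-wide significance/suggestive thresholds (p scale)."""

    significant: float
    suggestive: float
    n_scans: int
    n_tests: int
    ci_significant: tuple[float, float]
    ci_suggestive: tuple[float, float]


# ---------------------------------------------------------------------------
# Scans
# ---------------------------------------------------------------------------

def _aligned_trait(trait, samples) -> np.ndarray:
    if isinstance(trait, pd.DataFrame):
        col = "transformed" if "transformed" in trait.columns else "trait"
        trait = trait.set_index("iid")[col].reindex(samples)
        if trait.isna().any():
            raise ValueError("trait missing for some genotyped individuals")
        return trait.to_numpy(dtype=float)
    arr = np.asarray(trait, dtype=float)
    if arr.size != len(samples):
        raise ValueError("trait length does not match samples")
    return arr


def run_mga_scan(
    trait,
    phi: np.ndarray,
    dosages: DosageMatrix,
    families=None,
    covariates=None,
    metadata: dict | None = None,
) -> ScanResult:
    """Measured-genotype association scan over every SNP in the panel.

    The SNP-free polygenic fit is computed once and reused as the null of
    every 1-df LRT.  Monomorphic SNPs are excluded with a log entry.
    """
    y = _aligned_trait(trait, dosages.samples)
    if phi.shape[0] != y.size:
        raise ValueError("kinship dimension does not match trait")
    rotation = PolygenicRotation(phi, families)
    X0 = _design_cov(y.size, covariates)
    yr, X0r = rotation.rotate(y), rotation.rotate(X0)
    null_ll = fit_polygenic_rotated(yr, X0r, rotation.lam)["loglik"]

    adj = y - X0 @ np.linalg.lstsq(X0, y, rcond=None)[0]
    var_adj = float(np.var(adj))

    rows = []
    meta = dosages.snps.set_index("id")
    minor = _minor_alleles(dosages)
    for j, snp in enumerate(dosages.snps["id"]):
        d = dosages.dosages[:, j]
        if np.var(d) == 0.0:
            log.info("skipping monomorphic SNP %s", snp)
            continue
        dr = rotation.rotate(d)
        full = fit_polygenic_rotated(yr, np.column_stack([X0r, dr]), rotation.lam)
        lrt = max(0.0, 2.0 * (full["loglik"] - null_ll))
        gamma = float(full["beta"][-1])
        maf = float(np.mean(d) / 2.0)
        rows.append(
            {
                "snp": snp,
                "chrom": meta.loc[snp, "chrom"],
                "pos": meta.loc[snp, "pos"],
                "minor_allele": minor.get(snp, ""),
                "maf": maf,
                "gamma": gamma,
                "lrt_mga": lrt,
                "p_mga": float(chi2.sf(lrt, 1)),
                "effect_size_pct": effect_size(gamma, maf, var_adj),
                "n": y.size,
            }
        )
    md = {"test": "mga", "n_snps": len(rows), "covariate_mode": "pre-residualized"
          if covariates is None else "simultaneous"}
    md.update(metadata or {})
    return ScanResult(pd.DataFrame(rows), md)


def run_jla_scan(
    trait,
    phi: np.ndarray,
    loci: list[tuple[str, np.ndarray, np.ndarray | None]],
    dosages: DosageMatrix | None = None,
    families=None,
    covariates=None,
    restarts: int = 2,
    metadata: dict | None = None,
) -> ScanResult:
    """Joint linkage/association scan over (snp_id, dosage, ibd) loci.

    Reports the MGA p-value side by side with the JLA mixture p-value.
    Loci without an IBD matrix are skipped with a warning.
    """
    samples = dosages.samples if dosages is not None else None
    first = loci[0][1]
    n = first.size
    y = _aligned_trait(trait, samples if samples is not None else list(range(n)))
    rotation = PolygenicRotation(phi, families)
    X0 = _design_cov(y.size, covariates)
    yr, X0r = rotation.rotate(y), rotation.rotate(X0)
    null_ll = fit_polygenic_rotated(yr, X0r, rotation.lam)["loglik"]
    meta = dosages.snps.set_index("id") if dosages is not None else None
    minor = _minor_alleles(dosages) if dosages is not None else {}

    rows = []
    for snp, d, pi in loci:
        if pi is None:
            warnings.warn(f"locus {snp}: no IBD matrix supplied, skipped")
            continue
        if np.var(d) == 0.0:
            log.info("skipping monomorphic SNP %s", snp)
            continue
        mga = mga_test(y, d, covariates=covariates, rotation=rotation,
                       families=families, null_loglik=null_ll, snp_id=snp)
        jla = jla_test(y, d, phi, pi, covariates=covariates, families=families,
                       restarts=restarts, null_loglik=null_ll, snp_id=snp)
        row = {
            "snp": snp, "maf": mga.maf, "gamma": jla.gamma,
            "lrt_mga": mga.lrt, "p_mga": mga.p,
            "lrt_jla": jla.lrt, "p_jla": jla.p,
            "effect_size_pct": mga.effect_size_pct, "n": y.size,
        }
        if meta is not None and snp in meta.index:
            row["chrom"] = meta.loc[snp, "chrom"]
            row["pos"] = meta.loc[snp, "pos"]
            row["minor_allele"] = minor.get(snp, "")
        rows.append(row)
    md = {"test": "jla", "n_snps": len(rows)}
    md.update(metadata or {})
    return ScanResult(pd.DataFrame(rows), md)


def conditional_scan(
    trait,
    phi: np.ndarray,
    dosages: DosageMatrix,
    conditioning_snps: list[str],
    families=None,
    covariates=None,
) -> ScanResult:
    """MGA scan with conditioning SNP dosages added to every fixed-effect
    design; the conditioning SNPs themselves are excluded from the scan.
    Conditioning columns collinear with the existing design are dropped
    with a warning."""
    cond_cols = []
    kept_names = []
    base = [np.ones(len(dosages.samples))]
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != len(dosages.samples):
            C = C.T
        base.extend(C.T)
    for snp in conditioning_snps:
        col = dosages.column(snp)
        trial = np.column_stack(base + cond_cols + [col])
        if np.linalg.matrix_rank(trial) < trial.shape[1]:
            warnings.warn(f"conditioning SNP {snp} is collinear, dropped")
            continue
        cond_cols.append(col)
        kept_names.append(snp)
    cov = None
    stacked = ([] if covariates is None else [np.column_stack(base[1:])]) + \
        ([np.column_stack(cond_cols)] if cond_cols else [])
    if stacked:
        cov = np.column_stack(stacked)
    keep = ~dosages.snps["id"].isin(conditioning_snps).to_numpy()
    sub = DosageMatrix(
        dosages.dosages[:, keep], dosages.imputed[:, keep],
        list(dosages.samples), dosages.snps[keep].copy(),
        maf=None if dosages.maf is None else dosages.maf[keep],
    )
    res = run_mga_scan(trait, phi, sub, families=families, covariates=cov)
    res.metadata["conditioned_on"] = kept_names
    return res


def run_ols_scan(trait, dosages: DosageMatrix, covariates=None) -> ScanResult:
    """Naive per-SNP LRT ignoring relatedness (no kinship component).

    Exists as the diagnostic contrast for :func:`qq_lambda`: on family data
    it inflates, demonstrating why the kinship variance component is in the
    model.  Vectorized over SNPs.
    """
    y = _aligned_trait(trait, dosages.samples)
    X0 = _design_cov(y.size, covariates)
    H0 = X0 @ np.linalg.pinv(X0)
    r0 = y - H0 @ y
    rss0 = float(r0 @ r0)
    n = y.size
    rows = []
    for j, snp in enumerate(dosages.snps["id"]):
        d = dosages.dosages[:, j]
        if np.var(d) == 0.0:
            continue
        dr = d - H0 @ d
        denom = float(dr @ dr)
        b = float(dr @ r0) / denom
        rss1 = rss0 - b * b * denom
        lrt = n * np.log(rss0 / rss1)
        rows.append({"snp": snp, "chrom": dosages.snps["chrom"].iloc[j],
                     "pos": dosages.snps["pos"].iloc[j],
                     "maf": float(np.mean(d) / 2.0), "gamma": b,
                     "lrt_mga": lrt, "p_mga": float(chi2.sf(lrt, 1)), "n": n})
    return ScanResult(pd.DataFrame(rows), {"test": "ols", "kinship": "omitted"})


def _design_cov(n, covariates):
    if covariates is None:
        return np.ones((n, 1))
    C = np.atleast_2d(np.asarray(covariates, dtype=float))
    if C.shape[0] != n:
        C = C.T
    return np.column_stack([np.ones(n), C])


def _minor_alleles(dosages: DosageMatrix) -> dict[str, str]:
    t = dosages.snps
    if "alt" in t.columns:
        return dict(zip(t["id"], t["alt"]))
    return {}


# ---------------------------------------------------------------------------
# Empirical thresholds
# ---------------------------------------------------------------------------

def thresholds_from_pvalues(
    pvalues_per_scan,
    alpha: float = 0.05,
    n_boot: int = 200,
    seed: int = 0,
) -> ThresholdEstimate:
    """Threshold estimators from a collection of null-scan p-value vectors.

    * significant: the lower ``alpha`` (default 5%) quantile of per-scan
      minimum p-values — the genome-wide level crossed by chance in 5% of
      null scans;
    * suggestive: the largest p such that the expected count of p-values
      below it is at most one per scan, i.e. the ``n_scans``-th smallest
      pooled p-value's upper neighbor.

    Bootstrap percentile CIs are taken over scans.
    """
    scans = [np.asarray(p, dtype=float) for p in pvalues_per_scan]
    n_scans = len(scans)
    if n_scans < 2:
        raise ValueError("need at least two scans")

    def _estimate(scan_list):
        mins = np.array([s.min() for s in scan_list])
        sig = float(np.quantile(mins, alpha))
        pooled = np.sort(np.concatenate(scan_list))
        k = len(scan_list)  # count(p < t) <= n_scans  =>  t = pooled[k]
        sug = float(pooled[k]) if k < pooled.size else 1.0
        return sig, sug

    sig, sug = _estimate(scans)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, 2))
    for b in range(n_boot):
        pick = rng.integers(0, n_scans, size=n_scans)
        boots[b] = _estimate([scans[i] for i in pick])
    ci_sig = tuple(np.quantile(boots[:, 0], [0.025, 0.975]))
    ci_sug = tuple(np.quantile(boots[:, 1], [0.025, 0.975]))
    return ThresholdEstimate(
        significant=sig, suggestive=sug, n_scans=n_scans,
        n_tests=int(np.mean([s.size for s in scans])),
        ci_significant=ci_sig, ci_suggestive=ci_sug,
    )


def empirical_thresholds(
    phi: np.ndarray,
    dosages: DosageMatrix,
    h2_null: float,
    n_scans: int,
    seed: int = 0,
    families=None,
    alpha: float = 0.05,
) -> ThresholdEstimate:
    """Null-scan calibration of genome-wide thresholds on a dosage panel.

    Per scan a heritable null trait (polygenic + residual, no SNP effects)
    is drawn as MVN(0, h2 * 2Phi + (1 - h2) * I) — exactly the covariance a
    gene-dropped polygenic trait would have — the full MGA scan is run and
    all p-values recorded; thresholds then come from
    :func:`thresholds_from_pvalues`.
    """
    if not 0.0 <= h2_null < 1.0:
        raise ValueError("h2_null must lie in [0, 1)")
    if n_scans < 20:
        raise ValueError("need at least 20 null scans")
    if n_scans < 1000:
        warnings.warn("fewer than 1000 null scans: thresholds will be noisy")
    rng = np.random.default_rng(seed)
    rotation = PolygenicRotation(phi, families)
    n = phi.shape[0]

    # sample y directly in rotated coordinates: cov = h2*lam + (1-h2)
    sd = np.sqrt(h2_null * rotation.lam + (1.0 - h2_null))
    X0r = rotation.rotate(np.ones((n, 1)))
    poly = ~np.array([np.var(dosages.dosages[:, j]) == 0.0
                      for j in range(dosages.n_snps)])
    Dr = np.column_stack([rotation.rotate(dosages.dosages[:, j])
                          for j in range(dosages.n_snps) if poly[j]])
    scans = []
    for _ in range(n_scans):
        yr = rng.standard_normal(n) * sd
        null_ll = fit_polygenic_rotated(yr, X0r, rotation.lam)["loglik"]
        ps = np.empty(Dr.shape[1])
        for j in range(Dr.shape[1]):
            full = fit_polygenic_rotated(
                yr, np.column_stack([X0r, Dr[:, j]]), rotation.lam
            )
            lrt = max(0.0, 2.0 * (full["loglik"] - null_ll))
            ps[j] = chi2.sf(lrt, 1)
        scans.append(ps)
    return thresholds_from_pvalues(scans, alpha=alpha, seed=seed)


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def qq_lambda(pvalues) -> tuple[pd.DataFrame, float]:
    """Q-Q table (-log10 expected vs observed) and genomic-control lambda.

    lambda_GC = median(chi2_1 quantile of p) / 0.4549...; values near 1
    indicate no inflation from unmodeled structure.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if np.nanmin(p) <= 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in (0, 1]")
    obs = np.sort(p)
    n = p.size
    expected = (np.arange(1, n + 1) - 0.5) / n
    qq = pd.DataFrame(
        {"expected_mlog10p": -np.log10(expected), "observed_mlog10p": -np.log10(obs)}
    )
    lam = float(np.median(chi2.isf(p, 1)) / chi2.isf(0.5, 1))
    return qq, lam


def effective_tests(dosage_matrix, alpha: float = 0.05) -> tuple[float, float]:
    """Effective number of independent tests in a SNP set (Li-Ji estimator).

    Eigenvalues lam_i of the pairwise dosage correlation matrix are scored
    f(lam) = 1{lam >= 1} + (lam - floor(lam)); M_eff = sum f(|lam_i|) and
    alpha_adjusted = alpha / M_eff.  Constant columns are dropped with a
    warning.
    """
    D = np.asarray(dosage_matrix, dtype=float)
    if D.ndim != 2 or D.shape[1] < 2:
        raise ValueError("need at least two SNPs")
    if D.shape[0] <= 2:
        raise ValueError("need more than two individuals")
    keep = D.std(axis=0) > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant SNP column(s)")
        D = D[:, keep]
        if D.shape[1] < 2:
            raise ValueError("fewer than two polymorphic SNPs remain")
    R = np.corrcoef(D, rowvar=False)
    lam = np.abs(np.linalg.eigvalsh(R))
    # tolerance-guarded floor: an eigenvalue of k - 1e-15 must score like k
    floor = np.floor(lam + 1e-9)
    frac = np.clip(lam - floor, 0.0, None)
    m_eff = float(np.sum((lam >= 1.0 - 1e-9) + frac))
    return m_eff, alpha / m_eff


# ---------------------------------------------------------------------------
# Result I/O
# ---------------------------------------------------------------------------

def write_results(scan: ScanResult, path: str | Path) -> None:
    """TSV with '# key: value' metadata header lines; 12 significant digits."""
    with open(path, "w") as fh:
        for k in sorted(scan.metadata):
            fh.write(f"# {k}: {scan.metadata[k]}\n")
        scan.table.to_csv(fh, sep="\t", index=False, float_format="%.12g")


def read_results(path: str | Path) -> ScanResult:
    metadata = {}
    lines = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" not in body:
                    raise ValueError(f"{path}:{lineno}: malformed metadata line")
                k, v = body.split(":", 1)
                metadata[k.strip()] = v.strip()
            else:
                lines.append(line)
    if not lines:
        raise ValueError(f"{path}: no header row found")
    table = pd.read_csv(io.StringIO("".join(lines)), sep="\t")
    return ScanResult(table, metadata)
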