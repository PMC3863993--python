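"""SNP-level quality control and dosage construction.

The screening pipeline mirrors common family-study practice: drop SNPs with
call rate below 95%, drop SNPs out of Hardy-Weinberg equilibrium at a 5%
false discovery rate (exact test on founders by default), blank Mendelian
errors, then convert genotypes to minor-allele dosages in {0, 1, 2} with
missing calls replaced by their pedigree-conditional expectation (a
"weighted covariate" in [0, 2]).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from . import peeling
from .pedigree import Pedigree

log = logging.getLogger(__name__)

SNP_META_COLUMNS = ["id", "chrom", "pos", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Hard genotype calls: individuals x SNPs, minor-allele-count values
    in {0, 1, 2} with NaN for missing; `snps` holds per-SNP metadata
    (id, chrom, 1-based pos, ref, alt)."""

    calls: np.ndarray
    samples: list[str]
    snps: pd.DataFrame

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.samples), len(self.snps)):
            raise ValueError("calls shape does not match samples x snps")
        ok = np.isnan(self.calls) | np.isin(self.calls, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("genotype values must be 0, 1, 2 or missing")
        if self.snps["id"].duplicated().any():
            raise ValueError("duplicate SNP ids")
        self.snps = self.snps.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.calls).mean(axis=0)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.calls.copy(), list(self.samples), self.snps.copy())

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(
            self.calls[:, keep], list(self.samples), self.snps.iloc[keep].copy()
        )


@dataclass
class DosageMatrix:
    """Analysis-ready minor-allele dosages in [0, 2].

    Observed entries are exact counts {0, 1, 2}; entries flagged in
    `imputed` are conditional expectations given typed relatives.
    """

    dosages: np.ndarray
    imputed: np.ndarray
    samples: list[str]
    snps: pd.DataFrame
    maf: np.ndarray = field(default=None)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.imputed = np.asarray(self.imputed, dtype=bool)
        if np.nanmin(self.dosages, initial=0.0) < -1e-9 or np.nanmax(
            self.dosages, initial=0.0
        ) > 2 + 1e-9:
            raise ValueError("dosages must lie in [0, 2]")
        obs = self.dosages[~self.imputed]
        if obs.size and not np.isin(obs[~np.isnan(obs)], (0.0, 1.0, 2.0)).all():
            raise ValueError("observed dosages must be hard calls in {0, 1, 2}")

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def column(self, snp_id: str) -> np.ndarray:
        j = self.snps.index[self.snps["id"] == snp_id]
        if len(j) == 0:
            raise KeyError(snp_id)
        return self.dosages[:, int(j[0])]

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            self.dosages, index=self.samples, columns=self.snps["id"]
        ).to_csv(path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read GT fields of a biallelic VCF into a GenotypeMatrix.

    Genotypes count ALT alleles (0/0 -> 0, 0/1 -> 1, 1/1 -> 2, ./. -> NaN);
    phased separators are treated identically to unphased.  Multiallelic
    records are skipped with a warning.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols, meta = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            warnings.warn(
                f"skipping multiallelic record {var.ID or var.POS} with ALTs {var.ALT}"
            )
            continue
        # gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
        gt = var.gt_types.astype(float)
        col = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
        cols.append(col)
        meta.append((var.ID or f"{var.CHROM}:{var.POS}", var.CHROM, var.POS,
                     var.REF, var.ALT[0]))
    calls = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    snps = pd.DataFrame(meta, columns=SNP_META_COLUMNS)
    return GenotypeMatrix(calls, samples, snps)


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write hard calls as a minimal VCF 4.2 text file with GT fields."""
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(gm.snps["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        for j, row in gm.snps.iterrows():
            gts = "\t".join(
                gt_map.get(g, "./.") if not np.isnan(g) else "./."
                for g in gm.calls[:, j]
            )
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['ref']}\t"
                f"{row['alt']}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------

def allele_freqs(
    gm: GenotypeMatrix,
    ped: Pedigree | None = None,
    founders_only: bool = False,
    hwe_founders_only: bool = True,
) -> pd.DataFrame:
    """Per-SNP frequency table: minor allele, MAF, SE, call rate, HWE p.

    The minor allele is the less frequent of the two in the counting sample
    (ties at 0.5 orient to ALT), the standard error is the binomial
    sqrt(p(1-p)/2n) on counted alleles, and the exact Hardy-Weinberg test is
    computed on founders by default to avoid relatedness-driven distortion
    (set ``hwe_founders_only=False`` to use everyone).
    """
    calls = gm.calls
    fcalls = None
    if founders_only or hwe_founders_only:
        if ped is None:
            raise ValueError("founder-based statistics require a pedigree")
        fidx = [k for k, s in enumerate(gm.samples) if s in _founder_set(ped)]
        fcalls = calls[fidx]
    count_base = fcalls if founders_only else calls
    hwe_base = fcalls if hwe_founders_only else calls

    n_obs = (~np.isnan(count_base)).sum(axis=0).astype(float)
    alt_count = np.nansum(count_base, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = alt_count / (2.0 * n_obs)
    minor_is_alt = ~(alt_freq > 0.5)
    maf = np.where(minor_is_alt, alt_freq, 1.0 - alt_freq)
    with np.errstate(invalid="ignore"):
        se = np.sqrt(maf * (1.0 - maf) / (2.0 * n_obs))

    hwe_p = np.ones(gm.n_snps)
    for j in range(gm.n_snps):
        col = hwe_base[:, j]
        col = col[~np.isnan(col)]
        n_aa = int((col == 0).sum())
        n_het = int((col == 1).sum())
        n_bb = int((col == 2).sum())
        hwe_p[j] = hwe_exact(n_aa, n_het, n_bb) if (n_aa + n_het + n_bb) else np.nan

    table = pd.DataFrame(
        {
            "snp": gm.snps["id"],
            "minor_allele": np.where(minor_is_alt, gm.snps["alt"], gm.snps["ref"]),
            "maf": maf,
            "se": se,
            "call_rate": gm.call_rate(),
            "hwe_p": hwe_p,
            "monomorphic": (maf == 0.0) | (n_obs == 0),
            "n_counted": n_obs.astype(int),
        }
    )
    table.loc[n_obs == 0, ["maf", "se"]] = np.nan
    return table


def _founder_set(ped: Pedigree) -> set[str]:
    return set(np.asarray(ped.ids)[ped.founder_mask])


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def call_rate_filter(
    gm: GenotypeMatrix, threshold: float = 0.95
) -> tuple[GenotypeMatrix, list[str]]:
    """Remove SNPs whose fraction of observed calls is strictly below the
    threshold (default 95%)."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    cr = gm.call_rate()
    bad = cr < threshold
    removed = list(gm.snps["id"][bad])
    return gm.subset_snps(~bad), removed


def hwe_exact(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Two-sided exact Hardy-Weinberg test on genotype counts.

    Conditional on the sample size and minor-allele count, the p-value sums
    the probabilities of every heterozygote count no more probable than the
    one observed.  Monomorphic samples return 1 by convention.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("need at least one genotype")
    rare = 2 * min(n_aa, n_bb) + n_ab
    if rare == 0 or rare == 2 * n:
        return 1.0
    hets = np.arange(rare % 2, rare + 1, 2)
    homs_rare = (rare - hets) // 2
    homs_common = n - hets - homs_rare
    # log P(h) under the exact conditional (hypergeometric-like) law
    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1) - gammaln(hets + 1) - gammaln(homs_rare + 1)
        - gammaln(homs_common + 1)
    )
    logp -= np.logaddexp.reduce(logp)  # normalize in log space
    p_obs = logp[hets == n_ab][0]
    mask = logp <= p_obs + 1e-12
    return float(min(1.0, np.exp(np.logaddexp.reduce(logp[mask]))))


def bh_fdr(pvalues, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at FDR level q."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def hwe_filter(
    gm: GenotypeMatrix,
    freqs: pd.DataFrame,
    fdr: float = 0.05,
) -> tuple[GenotypeMatrix, list[str]]:
    """Remove SNPs failing the exact HWE test at the given FDR (BH step-up)."""
    freqs = freqs.set_index("snp").loc[gm.snps["id"]]
    p = freqs["hwe_p"].to_numpy()
    bad = np.zeros(gm.n_snps, dtype=bool)
    ok = ~np.isnan(p)
    bad[ok] = bh_fdr(p[ok], q=fdr)
    removed = list(gm.snps["id"][bad])
    return gm.subset_snps(~bad), removed


def qc_pipeline(
    gm: GenotypeMatrix,
    ped: Pedigree,
    call_rate: float = 0.95,
    hwe_fdr: float = 0.05,
    blank_mendel: bool = True,
) -> tuple[GenotypeMatrix, dict]:
    """Full SNP screen: Mendelian blanking, call-rate filter, HWE filter.

    Returns the surviving GenotypeMatrix and a report dict with the removal
    lists and the number of blanked calls.
    """
    from .pedigree import blank_mendel_errors, mendel_scan

    report: dict = {}
    if blank_mendel:
        errors = mendel_scan(ped, gm)
        gm, n_blanked = blank_mendel_errors(gm, errors)
        report["mendel_errors"] = errors
        report["n_blanked"] = n_blanked
    gm, removed_cr = call_rate_filter(gm, threshold=call_rate)
    report["removed_call_rate"] = removed_cr
    freqs = allele_freqs(gm, ped)
    gm, removed_hwe = hwe_filter(gm, freqs, fdr=hwe_fdr)
    report["removed_hwe"] = removed_hwe
    report["freqs"] = freqs[freqs["snp"].isin(gm.snps["id"])].reset_index(drop=True)
    return gm, report


# ---------------------------------------------------------------------------
# Dosages and imputation
# ---------------------------------------------------------------------------

def impute_dosages(
    gm: GenotypeMatrix,
    ped: Pedigree,
    freqs: pd.DataFrame,
) -> DosageMatrix:
    """Minor-allele dosages with missing calls imputed by pedigree peeling.

    Observed calls become exact minor-allele counts.  Each missing call is
    replaced by its conditional expected count given all typed members of
    the same family, computed by exact single-locus peeling with
    Hardy-Weinberg founder priors at the estimated minor-allele frequency.
    An untyped individual with no typed relatives receives the population
    expectation 2p.

    Trio-level Mendelian blanking does not catch joint inconsistencies
    mediated by untyped connectors (e.g. a hom-alt child forcing a minor
    allele into an untyped parent whose own typed parents carry none); when
    peeling detects one, the whole family is blanked at that site (dosage
    2p, flagged imputed) with a warning.
    """
    f = freqs.set_index("snp").reindex(gm.snps["id"])
    if f["maf"].isna().any():
        bad = list(f.index[f["maf"].isna()])
        raise ValueError(f"no frequency estimate for SNP(s) {bad[:5]}")
    alt = gm.snps.set_index("id")["alt"].reindex(f.index)
    minor_is_alt = (f["minor_allele"].to_numpy() == alt.to_numpy())
    maf = f["maf"].to_numpy()

    # orient hard calls to minor-allele counts
    calls = gm.calls.copy()
    flip = ~minor_is_alt
    calls[:, flip] = 2.0 - calls[:, flip]

    ped_pos = ped.index_of()
    sample_rows = np.array([ped_pos[s] for s in gm.samples])
    row_to_sample = {ped_pos[s]: k for k, s in enumerate(gm.samples)}
    fam_rows = ped.families()

    dos = calls.copy()
    imputed = np.isnan(calls)
    for j in range(gm.n_snps):
        col = calls[:, j]
        if not np.isnan(col).any():
            continue
        p = float(maf[j])
        if p == 0.0:
            dos[np.isnan(col), j] = 0.0
            continue
        for fam, rows in fam_rows.items():
            fam_calls = np.array(
                [col[row_to_sample[r]] if r in row_to_sample else np.nan for r in rows]
            )
            if not np.isnan(fam_calls).any():
                continue
            if np.isnan(fam_calls).all():
                for r in rows:
                    if r in row_to_sample:
                        dos[row_to_sample[r], j] = 2.0 * p
                continue
            try:
                post = peeling.family_posteriors(ped, rows, fam_calls, p)
            except ValueError:
                # Trio-level blanking cannot catch every single-locus
                # inconsistency (joint constraints through untyped
                # connectors survive it); blank the family at this site.
                warnings.warn(
                    f"family {fam!r}: jointly inconsistent genotypes at SNP "
                    f"{gm.snps['id'].iloc[j]!r}; family blanked at this site"
                )
                for r in rows:
                    if r in row_to_sample:
                        dos[row_to_sample[r], j] = 2.0 * p
                        imputed[row_to_sample[r], j] = True
                continue
            for r, dist in post.items():
                if r in row_to_sample:
                    dos[row_to_sample[r], j] = peeling.expected_dosage(dist)

    meta = gm.snps.copy()
    return DosageMatrix(dos, imputed, list(gm.samples), meta, maf=maf)


def dosages_from_calls(gm: GenotypeMatrix, freqs: pd.DataFrame) -> DosageMatrix:
    """Minor-allele dosages without imputation (missing stays NaN-free only
    if the input is complete); mainly for simulated, fully typed data."""
    if np.isnan(gm.calls).any():
        return impute_dosages(gm, _trivial_pedigree(gm.samples), freqs)
    f = freqs.set_index("snp").reindex(gm.snps["id"])
    alt = gm.snps.set_index("id")["alt"].reindex(f.index)
    minor_is_alt = (f["minor_allele"].to_numpy() == alt.to_numpy())
    calls = gm.calls.copy()
    calls[:, ~minor_is_alt] = 2.0 - calls[:, ~minor_is_alt]
    return DosageMatrix(
        calls, np.zeros_like(calls, dtype=bool), list(gm.samples), gm.snps.copy(),
        maf=f["maf"].to_numpy(),
    )


def _trivial_pedigree(samples) -> Pedigree:
    table = pd.DataFrame(
        {
            "fid": [f"U{k}" for k in range(len(samples))],
            "iid": list(samples),
            "father": "0",
            "mother": "0",
            "sex": 0,
        }
    )
    return Pedigree(table)
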