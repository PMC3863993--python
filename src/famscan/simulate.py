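"""Synthetic family-study data with known truth.

Generates extended pedigrees in which spouses marry in from an unrelated
population, drops founder alleles down the pedigree (so locus-specific
identity-by-descent is known exactly, not estimated), and simulates
quantitative traits from an additive variance-component model

    y = mu + covariate effects + gamma * dosage + a + q + e,
    a ~ MVN(0, 2*Phi*sigma2_a),  q ~ MVN(0, Pi*sigma2_q),  e ~ MVN(0, I*sigma2_e),

where Phi is the pedigree kinship matrix and Pi the locus-specific IBD
matrix.  Defaults emulate a cohort of ~630 phenotyped individuals in 40
extended families with a post-covariate heritability of 0.39.

All randomness flows from a single integer seed through one generator per
operation; the draw order is fixed (documented per function), so identical
seeds reproduce identical outputs byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .pedigree import Pedigree, kinship_matrix
from .qc import GenotypeMatrix, SNP_META_COLUMNS


class ConfigError(ValueError):
    """Invalid simulation settings."""


@dataclass(frozen=True)
class SimPedigreeSpec:
    """Settings for the pedigree generator.

    Defaults yield ~630 individuals across 40 three-generation families
    (expected family size 2 + 2m + m^2 with mean offspring m = 2.85).
    """

    n_families: int = 40
    founder_couples_per_family: int = 1
    mean_offspring: float = 2.85
    n_generations: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_families < 1 or self.founder_couples_per_family < 1:
            raise ConfigError("family and couple counts must be positive")
        if self.mean_offspring <= 0:
            raise ConfigError("mean_offspring must be positive")
        if self.n_generations < 2:
            raise ConfigError("need at least two generations (founders + offspring)")


@dataclass
class TraitModel:
    """Generative trait model; variances are on the trait scale.

    ``covariate_effects`` maps covariate column names to linear
    coefficients; ``snp_effect`` (gamma) is the additive effect in trait
    units per minor allele of ``target_snp``; ``sigma2_q`` acts at
    ``qtl_locus`` through the IBD matrix.
    """

    mu: float = 0.0
    covariate_effects: dict = field(default_factory=dict)
    snp_effect: float = 0.0
    target_snp: str | None = None
    sigma2_a: float = 0.0
    sigma2_q: float = 0.0
    qtl_locus: str | None = None
    sigma2_e: float = 1.0

    def __post_init__(self):
        if self.sigma2_a < 0 or self.sigma2_q < 0:
            raise ConfigError("variance components must be non-negative")
        if self.sigma2_e <= 0:
            raise ConfigError("sigma2_e must be positive")


@dataclass
class AlleleOrigins:
    """Founder-haplotype labels per individual and locus.

    ``pat``/``mat`` give, for each individual (rows, pedigree order) and
    locus (columns), the integer label of the founder haplotype from which
    the paternal/maternal allele descends.  ``founder_allele[label, locus]``
    is 1 if that founder haplotype carries the minor allele.
    """

    pat: np.ndarray
    mat: np.ndarray
    founder_allele: np.ndarray
    samples: list[str]
    loci: list[str]

    def locus_index(self, locus) -> int:
        if isinstance(locus, (int, np.integer)):
            if not 0 <= locus < len(self.loci):
                raise KeyError(f"locus index {locus} out of range")
            return int(locus)
        try:
            return self.loci.index(locus)
        except ValueError:
            raise KeyError(f"unknown locus {locus!r}") from None


# ---------------------------------------------------------------------------
# Pedigree generation
# ---------------------------------------------------------------------------

def generate_pedigree(spec: SimPedigreeSpec) -> Pedigree:
    """Generate extended families of the configured depth.

    Each family starts from ``founder_couples_per_family`` founder couples;
    every lineage member of a non-final generation marries a new founder
    spouse (of opposite sex) and has Poisson(mean_offspring) children with
    Bernoulli(0.5) sexes.  Draw order per family: for each reproducing
    couple, offspring count then offspring sexes.
    """
    rng = np.random.default_rng(spec.seed)
    rows: list[tuple] = []
    for famno in range(spec.n_families):
        fid = f"F{famno + 1:03d}"
        counter = 0

        def new_id() -> str:
            nonlocal counter
            counter += 1
            return f"{fid}-I{counter:03d}"

        # (iid, sex) pairs of the current generation's lineage members
        current: list[tuple[str, int]] = []
        for _ in range(spec.founder_couples_per_family):
            father, mother = new_id(), new_id()
            rows.append((fid, father, "0", "0", 1))
            rows.append((fid, mother, "0", "0", 2))
            kids = _spawn(rng, rows, fid, father, mother, spec.mean_offspring, new_id)
            current.extend(kids)
        for _gen in range(3, spec.n_generations + 1):
            nxt: list[tuple[str, int]] = []
            for iid, sex in current:
                spouse = new_id()
                spouse_sex = 2 if sex == 1 else 1
                rows.append((fid, spouse, "0", "0", spouse_sex))
                father, mother = (iid, spouse) if sex == 1 else (spouse, iid)
                nxt.extend(
                    _spawn(rng, rows, fid, father, mother, spec.mean_offspring, new_id)
                )
            current = nxt
    table = pd.DataFrame(rows, columns=["fid", "iid", "father", "mother", "sex"])
    return Pedigree(table)


def _spawn(rng, rows, fid, father, mother, mean_offspring, new_id):
    n_kids = int(rng.poisson(mean_offspring))
    kids = []
    for _ in range(n_kids):
        sex = 1 if rng.random() < 0.5 else 2
        iid = new_id()
        rows.append((fid, iid, father, mother, sex))
        kids.append((iid, sex))
    return kids


def simulate_covariates(
    ped: Pedigree,
    seed: int = 0,
    mean_age: float = 47.9,
    sd_age: float = 14.8,
    min_age: float = 16.0,
) -> pd.DataFrame:
    """Age (truncated normal) and female indicator per individual.

    Age moments mirror a middle-aged adult cohort (mean ~48 y, SD ~15 y,
    left-truncated at 16); the sex indicator comes from the pedigree.
    """
    rng = np.random.default_rng(seed)
    n = ped.n
    age = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        draw = rng.normal(mean_age, sd_age, size=todo.size)
        ok = draw >= min_age
        age[todo[ok]] = draw[ok]
        todo = todo[~ok]
    sex = (ped.table["sex"].to_numpy() == 2).astype(float)
    return pd.DataFrame({"iid": ped.ids, "age": age, "female": sex})


# ---------------------------------------------------------------------------
# Gene dropping
# ---------------------------------------------------------------------------

def gene_drop(
    ped: Pedigree,
    snp_maf,
    seed: int = 0,
    chrom: str = "1",
    pos_start: int = 10_000,
    pos_step: int = 10_000,
) -> tuple[GenotypeMatrix, AlleleOrigins]:
    """Drop founder alleles down the pedigree at unlinked biallelic loci.

    Founder haplotypes get unique labels; each founder allele is minor with
    probability ``maf`` independently per locus, and every child inherits
    one uniformly chosen allele from each parent (loci independent, i.e. no
    linkage between loci and free recombination within the pedigree).
    Genotypes count minor alleles, so the ALT allele of the emitted VCF
    metadata is the minor allele by construction.

    Draw order: founder allele matrix first, then per child (topological
    order) the paternal choices for all loci, then the maternal choices.
    """
    maf = np.atleast_1d(np.asarray(snp_maf, dtype=float))
    if np.any((maf <= 0) | (maf > 0.5)):
        raise ConfigError("minor allele frequencies must lie in (0, 0.5]")
    rng = np.random.default_rng(seed)
    n, n_loci = ped.n, maf.size
    parents = ped.parent_indices
    founder_rows = np.nonzero(ped.founder_mask)[0]
    hap_label = np.full((n, 2), -1, dtype=np.int64)  # label of pat/mat haplotype
    for k, r in enumerate(founder_rows):
        hap_label[r] = (2 * k, 2 * k + 1)

    founder_allele = (
        rng.random((2 * founder_rows.size, n_loci)) < maf[None, :]
    ).astype(np.int8)

    pat = np.empty((n, n_loci), dtype=np.int64)
    mat = np.empty((n, n_loci), dtype=np.int64)
    for r in ped.topological_order():
        f, m = parents[r]
        if f < 0:
            pat[r] = hap_label[r, 0]
            mat[r] = hap_label[r, 1]
        else:
            choose_f = rng.integers(0, 2, size=n_loci)
            choose_m = rng.integers(0, 2, size=n_loci)
            pat[r] = np.where(choose_f == 0, pat[f], mat[f])
            mat[r] = np.where(choose_m == 0, pat[m], mat[m])

    calls = (founder_allele[pat, np.arange(n_loci)[None, :]]
             + founder_allele[mat, np.arange(n_loci)[None, :]]).astype(float)
    loci = [f"snp{j + 1:05d}" for j in range(n_loci)]
    snps = pd.DataFrame(
        {
            "id": loci,
            "chrom": chrom,
            "pos": pos_start + pos_step * np.arange(n_loci),
            "ref": "A",
            "alt": "G",
        }
    )[SNP_META_COLUMNS]
    gm = GenotypeMatrix(calls, ped.ids, snps)
    origins = AlleleOrigins(pat, mat, founder_allele, ped.ids, loci)
    return gm, origins


def true_ibd(origins: AlleleOrigins, locus) -> np.ndarray:
    """Exact locus-specific IBD-sharing matrix Pi from allele origins.

    Entry (i, j) is the proportion of alleles shared identical by descent
    (0, 0.5 or 1 for non-inbred pairs, computed as the maximum matching of
    the two label pairs); the diagonal is 1 + f_i where f_i indicates the
    two alleles of i are themselves IBD.
    """
    j = origins.locus_index(locus)
    a1, a2 = origins.pat[:, j], origins.mat[:, j]
    m11 = (a1[:, None] == a1[None, :])
    m22 = (a2[:, None] == a2[None, :])
    m12 = (a1[:, None] == a2[None, :])
    m21 = (a2[:, None] == a1[None, :])
    shared = np.maximum(
        m11.astype(np.int8) + m22.astype(np.int8),
        m12.astype(np.int8) + m21.astype(np.int8),
    )
    pi = shared / 2.0
    np.fill_diagonal(pi, 1.0 + (a1 == a2).astype(float))
    return pi


def mean_ibd(origins: AlleleOrigins) -> np.ndarray:
    """Average Pi across all simulated loci (Monte-Carlo estimate of 2*Phi)."""
    acc = np.zeros((len(origins.samples), len(origins.samples)))
    for j in range(len(origins.loci)):
        acc += true_ibd(origins, j)
    return acc / len(origins.loci)


# ---------------------------------------------------------------------------
# Trait simulation
# ---------------------------------------------------------------------------

class CovarianceError(RuntimeError):
    """Assembled genetic covariance is not positive semidefinite."""


def _structured_draw(rng, structure: np.ndarray, scale: float,
                     families: np.ndarray) -> np.ndarray:
    """Draw MVN(0, scale * structure) blockwise by family."""
    n = structure.shape[0]
    out = np.zeros(n)
    if scale == 0.0:
        return out
    for fam in pd.unique(families):
        idx = np.nonzero(families == fam)[0]
        block = structure[np.ix_(idx, idx)]
        w, v = np.linalg.eigh(block)
        if w.min() < -1e-6 * max(1.0, w.max()):
            raise CovarianceError(
                f"covariance block for family {fam!r} has eigenvalue {w.min():.3g}"
            )
        root = v * np.sqrt(np.clip(w, 0.0, None))
        out[idx] = root @ rng.standard_normal(idx.size)
    return out * np.sqrt(scale)


def simulate_trait(
    ped: Pedigree,
    kinship: np.ndarray,
    model: TraitModel,
    dosages: np.ndarray | None = None,
    ibd: np.ndarray | None = None,
    covariates: pd.DataFrame | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate one trait realization under the additive VC model.

    ``kinship`` is the phi matrix (the polygenic structure used is 2*phi);
    ``dosages`` is the minor-allele dosage vector of the target SNP (needed
    iff ``snp_effect`` != 0); ``ibd`` the Pi matrix of the QTL (needed iff
    ``sigma2_q`` > 0).  Draw order: polygenic deviate, QTL deviate,
    residual.  Returns a PhenotypeTable (iid, trait, covariates).
    """
    n = ped.n
    if kinship.shape != (n, n):
        raise ConfigError("kinship dimension does not match pedigree")
    if model.snp_effect != 0.0 and dosages is None:
        raise ConfigError("snp_effect set but no dosage vector supplied")
    if model.sigma2_q > 0.0 and ibd is None:
        raise ConfigError("sigma2_q > 0 but no IBD matrix supplied")
    rng = np.random.default_rng(seed)
    fams = ped.family_labels

    y = np.full(n, model.mu, dtype=float)
    if covariates is not None:
        cov = covariates.set_index("iid").reindex(ped.ids)
        for name, beta in model.covariate_effects.items():
            if name not in cov.columns:
                raise ConfigError(f"covariate {name!r} missing from table")
            y += beta * cov[name].to_numpy(dtype=float)
    elif model.covariate_effects:
        raise ConfigError("covariate_effects set but no covariate table supplied")
    if model.snp_effect != 0.0:
        y += model.snp_effect * np.asarray(dosages, dtype=float)

    y += _structured_draw(rng, 2.0 * kinship, model.sigma2_a, fams)
    if model.sigma2_q > 0.0:
        y += _structured_draw(rng, ibd, model.sigma2_q, fams)
    y += rng.standard_normal(n) * np.sqrt(model.sigma2_e)

    out = pd.DataFrame({"iid": ped.ids, "trait": y})
    if covariates is not None:
        out = out.merge(covariates, on="iid", how="left")
    return out


# ---------------------------------------------------------------------------
# Degradation
# ---------------------------------------------------------------------------

def degrade_genotypes(
    gm: GenotypeMatrix,
    missing_rate: float = 0.0,
    mendel_error_rate: float = 0.0,
    seed: int = 0,
) -> GenotypeMatrix:
    """Mask calls to missing and inject uniform genotype flips.

    Flips replace a call with one of the two other genotype values chosen
    uniformly — a deliberately simple error model whose only purpose is to
    exercise Mendelian checking and call-rate filtering.  Draw order: error
    mask, flip directions, missing mask.
    """
    for name, rate in (("missing_rate", missing_rate),
                       ("mendel_error_rate", mendel_error_rate)):
        if not 0.0 <= rate < 1.0:
            raise ConfigError(f"{name} must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    out = gm.copy()
    shape = out.calls.shape
    if mendel_error_rate > 0.0:
        flip = rng.random(shape) < mendel_error_rate
        shift = rng.integers(1, 3, size=shape)
        out.calls = np.where(flip, (out.calls + shift) % 3, out.calls)
    if missing_rate > 0.0:
        mask = rng.random(shape) < missing_rate
        out.calls = np.where(mask, np.nan, out.calls)
    return out


# ---------------------------------------------------------------------------
# File output (FAM / VCF / CSV / IBD)
# ---------------------------------------------------------------------------

def write_phenotypes(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_ibd(pi: np.ndarray, samples: list[str], path: str | Path) -> None:
    """Long-format locus IBD file: ``ID1 ID2 PI`` for pairs with PI > 0
    (i <= j); absent pairs read back as 0."""
    with open(path, "w") as fh:
        fh.write("ID1 ID2 PI\n")
        n = len(samples)
        for i in range(n):
            for j in range(i, n):
                if pi[i, j] > 0.0:
                    fh.write(f"{samples[i]} {samples[j]} {pi[i, j]:.6g}\n")


def read_ibd(path: str | Path, samples: list[str]) -> np.ndarray:
    idx = {s: k for k, s in enumerate(samples)}
    pi = np.zeros((len(samples), len(samples)))
    with open(path) as fh:
        header = fh.readline()
        if header.split() != ["ID1", "ID2", "PI"]:
            raise ValueError(f"{path}: expected 'ID1 ID2 PI' header")
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            a, b, v = parts
            if a not in idx or b not in idx:
                raise ValueError(f"{path}:{lineno}: unknown individual id")
            pi[idx[a], idx[b]] = pi[idx[b], idx[a]] = float(v)
    return pi


def write_cohort(
    out_dir: str | Path,
    ped: Pedigree,
    gm: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    ibd_by_locus: dict[str, np.ndarray] | None = None,
) -> None:
    """Write the full fixture set: FAM, VCF, phenotype CSV and IBD files."""
    from .qc import write_vcf

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ped.to_fam(out / "cohort.fam")
    write_vcf(gm, out / "cohort.vcf")
    write_phenotypes(phenotypes, out / "phenotypes.csv")
    for locus, pi in (ibd_by_locus or {}).items():
        write_ibd(pi, gm.samples, out / f"ibd_{locus}.txt")


def default_cohort(seed: int = 0, n_snps: int = 0, maf=None):
    """Convenience bundle: pedigree, kinship and families for the default
    40-family design; optionally with gene-dropped genotypes."""
    spec = SimPedigreeSpec(seed=seed)
    ped = generate_pedigree(spec)
    phi = kinship_matrix(ped)
    if n_snps:
        mafs = np.full(n_snps, 0.3) if maf is None else np.asarray(maf)
        gm, origins = gene_drop(ped, mafs, seed=seed + 1)
        return ped, phi, gm, origins
    return ped, phi
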