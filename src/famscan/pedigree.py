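"""Pedigree structure, kinship coefficients and Mendelian consistency.

A pedigree is a set of individuals grouped into families, each with an
optional father and mother.  The kinship coefficient phi_ij is the
probability that a randomly drawn allele from individual i is identical by
descent with a randomly drawn allele from j; 2*phi scales the additive
polygenic covariance in the mixed models downstream.

Founders are individuals with *both* parent fields missing.  Records naming
only one parent ("half-founders") are rejected at parse time so that the
recursive kinship computation stays well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Sentinel used in FAM files for an absent parent.
MISSING_PARENT = "0"

PED_COLUMNS = ["fid", "iid", "father", "mother", "sex"]


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, missing parents...)."""


@dataclass(frozen=True, eq=False)
class Pedigree:
    """Validated pedigree, row order defines the index of every aligned matrix.

    Parameters
    ----------
    table:
        DataFrame with columns ``fid, iid, father, mother, sex``.  Parent
        fields use ``"0"`` for missing; sex is 1 (male), 2 (female) or 0
        (unknown).  Individual ids must be globally unique.
    """

    table: pd.DataFrame
    _order: tuple = field(init=False, repr=False, default=None)

    def __post_init__(self):
        t = self.table.reset_index(drop=True)
        missing = [c for c in PED_COLUMNS if c not in t.columns]
        if missing:
            raise PedigreeError(f"pedigree table lacks columns {missing}")
        t = t[PED_COLUMNS].astype(
            {"fid": str, "iid": str, "father": str, "mother": str, "sex": int}
        )
        object.__setattr__(self, "table", t)
        object.__setattr__(self, "_order", tuple(self._validate()))

    # -- structural queries -------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> list[str]:
        return list(self.table["iid"])

    def index_of(self) -> dict[str, int]:
        return {iid: k for k, iid in enumerate(self.table["iid"])}

    @property
    def founder_mask(self) -> np.ndarray:
        t = self.table
        return ((t["father"] == MISSING_PARENT) & (t["mother"] == MISSING_PARENT)).to_numpy()

    def families(self) -> dict[str, np.ndarray]:
        """Positional row indices per family, in table order."""
        return {
            fid: idx.to_numpy()
            for fid, idx in self.table.groupby("fid", sort=False).groups.items()
        }

    @property
    def family_labels(self) -> np.ndarray:
        return self.table["fid"].to_numpy()

    def topological_order(self) -> list[int]:
        """Row positions ordered parents-before-children."""
        return list(self._order)

    # -- validation ---------------------------------------------------------

    def _validate(self) -> list[int]:
        t = self.table
        iids = t["iid"]
        dup = iids[iids.duplicated()]
        if len(dup):
            raise PedigreeError(f"duplicated individual id(s): {sorted(set(dup))}")
        idx = {iid: k for k, iid in enumerate(iids)}
        sex = t["sex"].to_numpy()
        fid = t["fid"].to_numpy()

        parents = np.full((len(t), 2), -1, dtype=int)
        for row, (f, m, iid) in enumerate(zip(t["father"], t["mother"], t["iid"])):
            has_f, has_m = f != MISSING_PARENT, m != MISSING_PARENT
            if has_f != has_m:
                raise PedigreeError(
                    f"individual {iid!r}: exactly one parent named (half-founders "
                    "are not supported; supply both parents or neither)"
                )
            if not has_f:
                continue
            for col, (pid, want_sex, label) in enumerate(
                [(f, 1, "father"), (m, 2, "mother")]
            ):
                if pid not in idx:
                    raise PedigreeError(
                        f"individual {iid!r}: {label} {pid!r} not present in pedigree"
                    )
                p = idx[pid]
                if fid[p] != fid[row]:
                    raise PedigreeError(
                        f"individual {iid!r}: {label} {pid!r} belongs to family "
                        f"{fid[p]!r}, not {fid[row]!r}"
                    )
                if sex[p] not in (0, want_sex):
                    raise PedigreeError(
                        f"individual {iid!r}: {label} {pid!r} has sex code {sex[p]}"
                    )
                parents[row, col] = p
            if parents[row, 0] == parents[row, 1]:
                raise PedigreeError(f"individual {iid!r}: father and mother are the same id")

        # Kahn topological sort; leftovers indicate a cycle.
        n = len(t)
        n_unmet = (parents >= 0).sum(axis=1)
        children: dict[int, list[int]] = {}
        for row in range(n):
            for p in parents[row]:
                if p >= 0:
                    children.setdefault(p, []).append(row)
        ready = [r for r in range(n) if n_unmet[r] == 0]
        order: list[int] = []
        while ready:
            r = ready.pop()
            order.append(r)
            for c in children.get(r, ()):
                n_unmet[c] -= 1
                if n_unmet[c] == 0:
                    ready.append(c)
        if len(order) < n:
            stuck = [t["iid"][r] for r in range(n) if n_unmet[r] > 0]
            raise PedigreeError(f"ancestry cycle involving individual(s) {stuck[:5]}")
        object.__setattr__(self, "_parents", parents)
        return order

    @property
    def parent_indices(self) -> np.ndarray:
        """(n, 2) array of father/mother row positions, -1 for founders."""
        return self._parents

    # -- I/O ----------------------------------------------------------------

    @classmethod
    def from_fam(cls, path: str | Path) -> "Pedigree":
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) != 6:
                    raise PedigreeError(
                        f"{path}:{lineno}: expected 6 whitespace-delimited columns, "
                        f"got {len(parts)}"
                    )
                fidv, iid, fa, mo, sx, _pheno = parts
                rows.append((fidv, iid, fa, mo, int(sx)))
        table = pd.DataFrame(rows, columns=PED_COLUMNS)
        return cls(table)

    def to_fam(self, path: str | Path, phenotype=None) -> None:
        """Write a 6-column FAM file; phenotype column defaults to 0."""
        t = self.table
        ph = ["0"] * self.n if phenotype is None else [repr(v) for v in phenotype]
        with open(path, "w") as fh:
            for k in range(self.n):
                fh.write(
                    f"{t['fid'][k]} {t['iid'][k]} {t['father'][k]} "
                    f"{t['mother'][k]} {t['sex'][k]} {ph[k]}\n"
                )


def read_pedigree(path: str | Path) -> Pedigree:
    """Read and validate a 6-column FAM file."""
    return Pedigree.from_fam(path)


# ---------------------------------------------------------------------------
# Kinship
# ---------------------------------------------------------------------------

def kinship_matrix(ped: Pedigree) -> np.ndarray:
    """Kinship coefficient matrix phi, aligned to pedigree row order.

    Computed per family with the standard recursion (founders unrelated,
    phi_ii = 0.5 * (1 + phi_father,mother), phi_ij = 0.5 * (phi_fj + phi_mj)
    processing individuals parents-first) and assembled block-diagonally:
    individuals in different families have kinship exactly 0.
    """
    n = ped.n
    phi = np.zeros((n, n))
    parents = ped.parent_indices
    order = ped.topological_order()
    fam_of = ped.family_labels
    # Recursion is valid globally because cross-family kinship is zero and
    # parents always precede children in `order`.
    done: list[int] = []
    done_by_fam: dict[str, list[int]] = {}
    for i in order:
        f, m = parents[i]
        fam = fam_of[i]
        prev = done_by_fam.setdefault(fam, [])
        if f < 0:
            phi[i, i] = 0.5
        else:
            phi[i, i] = 0.5 * (1.0 + phi[f, m])
            for j in prev:
                v = 0.5 * (phi[f, j] + phi[m, j])
                phi[i, j] = phi[j, i] = v
        prev.append(i)
        done.append(i)
    return phi


# ---------------------------------------------------------------------------
# Mendelian checking
# ---------------------------------------------------------------------------

def _transmission_bounds(g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Min/max number of minor alleles a parent with genotype g can transmit.

    Missing parental genotypes (NaN) are unconstrained: bounds (0, 1).
    """
    lo = np.where(np.isnan(g), 0.0, np.where(g == 2, 1.0, 0.0))
    hi = np.where(np.isnan(g), 1.0, np.where(g == 0, 0.0, 1.0))
    return lo, hi


def mendel_scan(ped: Pedigree, genotypes) -> pd.DataFrame:
    """Find (SNP, trio) combinations with impossible child genotypes.

    At a biallelic locus the set of child allele counts compatible with the
    parents is a contiguous range, so a child genotype is Mendelianly
    impossible iff it falls outside [min_f+min_m, max_f+max_m] of the
    per-parent transmissible counts.  A missing parent genotype constrains
    nothing.

    Parameters
    ----------
    genotypes:
        A :class:`~famscan.qc.GenotypeMatrix` (individuals x SNPs, values in
        {0, 1, 2, NaN}) whose samples cover the pedigree ids.

    Returns
    -------
    DataFrame with columns snp, fid, child, father_gt, mother_gt, child_gt.
    """
    idx = {s: k for k, s in enumerate(genotypes.samples)}
    missing_ids = [i for i in ped.ids if i not in idx]
    if missing_ids:
        raise PedigreeError(f"genotypes lack pedigree individual(s) {missing_ids[:5]}")
    calls = genotypes.calls
    snp_ids = genotypes.snps["id"].to_numpy()
    t = ped.table
    parents = ped.parent_indices
    records = []
    for row in range(ped.n):
        f, m = parents[row]
        if f < 0:
            continue
        gc = calls[idx[t["iid"][row]]]
        gf = calls[idx[t["iid"][f]]]
        gm = calls[idx[t["iid"][m]]]
        lo_f, hi_f = _transmission_bounds(gf)
        lo_m, hi_m = _transmission_bounds(gm)
        bad = ~np.isnan(gc) & ((gc < lo_f + lo_m) | (gc > hi_f + hi_m))
        for j in np.nonzero(bad)[0]:
            records.append(
                (snp_ids[j], t["fid"][row], t["iid"][row],
                 gf[j], gm[j], gc[j])
            )
    return pd.DataFrame(
        records, columns=["snp", "fid", "child", "father_gt", "mother_gt", "child_gt"]
    )


def blank_mendel_errors(genotypes, errors: pd.DataFrame):
    """Set flagged child genotypes to missing; returns (copy, n_blanked).

    Policy: only the child call of a flagged (SNP, trio) is blanked, not the
    parental calls — the minimal-loss interpretation of per-genotype
    blanking.
    """
    out = genotypes.copy()
    if len(errors) == 0:
        return out, 0
    samp_idx = {s: k for k, s in enumerate(out.samples)}
    snp_idx = {s: k for k, s in enumerate(out.snps["id"])}
    n = 0
    for snp, child in zip(errors["snp"], errors["child"]):
        i, j = samp_idx[child], snp_idx[snp]
        if not np.isnan(out.calls[i, j]):
            out.calls[i, j] = np.nan
            n += 1
    return out, n


def write_error_list(errors: pd.DataFrame, path: str | Path) -> None:
    errors.to_csv(path, sep="\t", index=False)


def read_error_list(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
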