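import numpy as np
import pandas as pd
import pytest

import famscan as fs


def make_pedigree(rows):
    """rows: (fid, iid, father, mother, sex) tuples."""
    return fs.Pedigree(
        pd.DataFrame(rows, columns=["fid", "iid", "father", "mother", "sex"])
    )


TRIO = [
    ("A", "dad", "0", "0", 1),
    ("A", "mom", "0", "0", 2),
    ("A", "kid", "dad", "mom", 1),
]

SIB_QUAD = TRIO + [("A", "sib", "dad", "mom", 2)]


@pytest.fixture(scope="session")
def cohort():
    """Default 40-family study design: pedigree, kinship, family labels."""
    ped = fs.generate_pedigree(fs.SimPedigreeSpec(seed=11))
    phi = fs.kinship_matrix(ped)
    return ped, phi, ped.family_labels


@pytest.fixture(scope="session")
def cohort_rotation(cohort):
    ped, phi, fams = cohort
    return fs.PolygenicRotation(phi, fams)


@pytest.fixture()
def trio_pedigree():
    return make_pedigree(TRIO)


def snp_meta(ids):
    return pd.DataFrame(
        {
            "id": ids,
            "chrom": "1",
            "pos": 10_000 * (1 + np.arange(len(ids))),
            "ref": "A",
            "alt": "G",
        }
    )


def genotype_matrix(calls, samples, ids=None):
    calls = np.asarray(calls, dtype=float)
    ids = ids or [f"s{j + 1}" for j in range(calls.shape[1])]
    return fs.GenotypeMatrix(calls, samples, snp_meta(ids))
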