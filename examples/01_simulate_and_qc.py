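"""Simulate a family cohort, degrade genotypes and run the SNP QC screen.

Generates the default 40-family design, gene-drops a 300-SNP panel, adds
realistic missingness and genotyping errors, then applies Mendelian
blanking, the 95% call-rate filter and the exact Hardy-Weinberg screen at
5% FDR, ending with peeling-imputed dosages ready for association.
"""

import numpy as np

import famscan as fs

ped = fs.generate_pedigree(fs.SimPedigreeSpec(seed=11))
print(f"cohort: {ped.n} individuals in {len(ped.families())} families, "
      f"{int(ped.founder_mask.sum())} founders")

rng = np.random.default_rng(0)
gm, _ = fs.gene_drop(ped, rng.uniform(0.05, 0.5, size=300), seed=1)
gm = fs.degrade_genotypes(gm, missing_rate=0.02, mendel_error_rate=5e-4, seed=2)

kept, report = fs.qc_pipeline(gm, ped, call_rate=0.95, hwe_fdr=0.05)
print(f"blanked {report['n_blanked']} Mendelian-error calls "
      f"({report['n_blanked'] / gm.calls.size:.2e} per genotype)")
print(f"removed {len(report['removed_call_rate'])} SNPs for call rate < 95%, "
      f"{len(report['removed_hwe'])} for HWE")

freqs = fs.allele_freqs(kept, ped)
dos = fs.impute_dosages(kept, ped, freqs)
n_imp = int(dos.imputed.sum())
print(f"dosage panel: {dos.n_snps} SNPs, {n_imp} imputed entries, "
      f"all within [{dos.dosages.min():.2f}, {dos.dosages.max():.2f}]")
# Imputed entries are conditional expected minor-allele counts given typed
# relatives -- fractional values in [0, 2] -- while observed calls stay 0/1/2.
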