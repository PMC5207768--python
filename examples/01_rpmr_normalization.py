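"""Internal-control (RPMR) vs total-read normalization on a composition-shifted pair.

Simulates a wild-type-like library and a Pol-IV-mutant-like library (24-nt
siRNA class reduced 20-fold, miRNA truth identical), then compares per-miRNA
abundance ratios under the two normalizations.
"""

import srnafrac as sf

genome, annots, truth = sf.generate_reference(seed=0)
mirnas = truth.mirna_annotations()


def process(class_factors, seed):
    lib = sf.simulate_srna_library(truth, "T", 100_000, seed, class_factors=class_factors)
    part = sf.filter_structural(lib, annots)
    quant = sf.quantify_mirna(part.kept, mirnas)
    return quant.groupby("mirna_id")["raw"].sum().to_dict(), sf.compute_norm_factors(part)


counts_wt, f_wt = process(None, seed=1)
counts_mut, f_mut = process({"p4sirna": 0.05}, seed=2)

report = sf.normalization_bias_report(counts_wt, counts_mut, f_wt, f_mut)
med = report[["tpm_ratio", "rpmr_ratio"]].median()
print(f"median miRNA ratio (mutant/WT), total-read normalization: {med['tpm_ratio']:.2f}")
print(f"median miRNA ratio (mutant/WT), RPMR normalization:       {med['rpmr_ratio']:.2f}")
print(
    "\nmiRNA levels are identical by construction: total-read normalization is"
    "\nfooled by the collapsed 24-nt class, the rRNA-fragment internal control"
    "\nis not (ratio ~ 1)."
)
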