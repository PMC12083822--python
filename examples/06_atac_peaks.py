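"""ATAC peak comparison: global losses and module-gene peak changes.

Plants treatment-induced peak losses boosted near module-gene TSSs (60%
vs 10% background), matches control against treated peaks and summarizes
accessibility changes around module genes vs background genes.
"""

import pandas as pd

from epidrugscreen import atac
from epidrugscreen import synthetic as syn

genes = [f"G{i:04d}" for i in range(150)]
module_genes = set(genes[:30])
truth = syn.peak_truth(
    genes, module_genes, genome_length=60_000_000, n_background_peaks=500,
    lost_fraction_global=0.1, lost_near_module_tss=0.6, seed=12,
)
control = syn.generate_peaks(truth, "control", seed=12)
treated = syn.generate_peaks(truth, "treated", seed=13)

delta = atac.match_peaks(control, treated, min_reciprocal_overlap=0.5)
print(
    f"Peaks: {len(control)} control, {len(treated)} treated -> "
    f"{delta.summary()['n_matched']} matched, {delta.summary()['n_lost']} lost, "
    f"{delta.summary()['n_gained']} gained."
)
print("Peak loss after treatment = chromatin closing, the expected BET-inhibitor effect.")

union = pd.concat([control, delta.gained], ignore_index=True).drop_duplicates(
    subset=["chrom", "start", "end"]
)
links = atac.link_peaks_to_genes(union, truth.tss_table, window=truth.link_window)
per_gene, pooled = atac.gene_set_peak_changes(delta, links, genes, union, min_abs_log2=1.0)

is_module = per_gene["gene"].isin(module_genes)
loss = per_gene["n_lost"] + per_gene["n_sig_down"]
print(
    f"\nPooled losses per gene (lost peaks + >=2-fold score drops): "
    f"module genes {loss[is_module].mean():.2f} vs background "
    f"{loss[~is_module].mean():.2f}."
)
print(
    "Module genes lose several-fold more accessibility than background -- "
    "recovering the planted TSS-proximal closing around the drug-suppressed "
    "module."
)
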