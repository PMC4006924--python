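"""Generate a synthetic two-model sepsis dataset and select genes.

Builds a 2,000-probe dataset (two sepsis models x three timepoints plus
controls, 20% of probes differentially expressed), then runs the two
selection routes: the unsupervised CV > 0.5 filter on the linear scale
and the supervised three-class F-test at p < 0.001, and counts probes
versus genes (several probe sets can map to one gene symbol).
"""

import sepsiskit as sk

design = sk.SyntheticDesign(n_probes=2_000, de_fraction=0.2,
                            effect_sd=1.5, noise_sd=0.2, seed=1)
matrix, samples, probes, truth = sk.generate_dataset(design)
print(f"dataset: {matrix.shape[0]} probes x {matrix.shape[1]} samples, "
      f"{int(truth.de_flags.sum())} truly DE probes")

sel_cv = sk.cv_filter(matrix, threshold=0.5, scale="linear")
sel_f = sk.f_test_selection(matrix, samples, alpha=0.001)
for name, sel in (("CV>0.5", sel_cv), ("F-test p<0.001", sel_f)):
    genes = sel.gene_symbols(probes)
    true_pos = len(set(sel.kept) & set(truth.de_flags.index[truth.de_flags]))
    print(f"{name}: {sel.n_probes_kept} probe sets ({len(genes)} genes), "
          f"{true_pos} truly DE")

# Per-model significant sets and their gene-level overlap: the analogue of
# asking how many sepsis-responsive genes the two models share.
sel_a = sk.per_model_selection(matrix, samples, sk.MODEL_A, alpha=0.001)
sel_b = sk.per_model_selection(matrix, samples, sk.MODEL_B, alpha=0.001)
overlap = sk.collapse_and_overlap(sel_a, sel_b, probes)
c = overlap.counts()
print(f"model A: {c['genes_a']} genes, model B: {c['genes_b']} genes, "
      f"shared: {c['genes_shared']} "
      f"(unique: {c['genes_only_a']} / {c['genes_only_b']})")
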