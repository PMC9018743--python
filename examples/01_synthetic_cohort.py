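"""Generate a synthetic drug-perturbation study with planted ground truth.

The cohort mimics a CMap-style screen: a confidence-weighted scale-free
interactome with planted pathway modules, replicate expression panels for
drug vs DMSO control, phosphoprotein tables, TF regulons, drug targets,
localization, MoA labels and sensitivity z-scores.
"""

from drugnetstrat import CohortConfig, generate_cohort, write_cohort

config = CohortConfig(seed=0)
bundle = generate_cohort(config)

g = bundle.interactome
print(f"interactome: {g.number_of_nodes()} proteins, {g.number_of_edges()} edges")
print(f"pathway modules: {len(bundle.gene_sets)} of size {config.module_size}")
print(f"conditions: {len(bundle.panels)} (cell line x drug)")
print(f"drug -> planted modules, e.g. drug00 -> {bundle.truth['drug00']}")
print(f"MoA classes: {sorted(set(bundle.moa_labels.values()))}")

manifest = write_cohort(bundle, "scratch/example_cohort")
print(f"wrote {len(manifest)} files under scratch/example_cohort/")
# Drugs of the same MoA class perturb the same planted modules, so their
# omics signatures -- and later their reconstructed networks -- truly overlap.
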