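"""Simulate a Collaborative-Cross-like panel with planted molecular effects.

Builds 58 homozygous founder-mosaic genomes, then a multi-omics observation
layer: peptide-level TMT intensities for ~100 proteins and their
phosphosites, transcripts, sample metadata with bridge channels, and a
ground-truth table of every planted effect.
"""

import phqtl

markers, haplo = phqtl.simulate_genomes(n_strains=58, n_chromosomes=2,
                                        markers_per_chromosome=50, seed=1)
design = phqtl.MultiomicsDesign()
study = phqtl.simulate_multiomics(haplo, design, seed=2)

print(f"genomes: {haplo.n_strains} strains x {len(markers)} markers "
      f"(hard founder calls: {haplo.is_hard()})")
print(f"samples: {len(study.metadata.samples)} mice + "
      f"{study.metadata.df['is_bridge'].sum()} bridge channels")
print(f"peptides: {len(study.peptides.peptides)} "
      f"({study.peptides.peptides['is_phospho'].sum()} phospho)")
print("\nplanted effects:")
print(study.truth.table.groupby(["kind", "effect_type"]).size().to_string())
print("\nEach local_pQTL protein carries founder allele effects at a marker "
      "near its gene; mech2 phosphosites track a distant mediator protein's "
      "abundance rather than their own parent.")
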