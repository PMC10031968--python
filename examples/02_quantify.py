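"""From raw peptide intensities to strain-level abundance matrices.

Applies the quantification chain: polymorphic-peptide filter against the
eight founder proteomes, within-batch loading normalization, bridge-relative
log2 roll-up, 50% missingness filter, mixed-model TMT batch adjustment,
parent-protein adjustment of phosphopeptides, and strain summaries.
"""

import phqtl

_, haplo = phqtl.simulate_genomes(30, seed=1)
study = phqtl.simulate_multiomics(
    haplo, phqtl.MultiomicsDesign(n_proteins=50, n_local_pqtl=12, n_mech1=4,
                                  n_mech2=4, n_sex_protein=2, n_sex_phospho=2),
    seed=2)

table, poly = phqtl.filter_polymorphic_peptides(study.peptides,
                                                study.founder_proteomes)
print(f"polymorphic filter: {poly['n_removed_polymorphic']} of "
      f"{poly['n_input']} peptides removed "
      f"({100 * poly['n_removed_polymorphic'] / poly['n_input']:.1f}%)")

table, factors = phqtl.normalize_within_batch(table, study.metadata)
print(f"phi loading factors: median {factors.phi.median():.2f}, "
      f"max {factors.phi.max():.2f} (1.0 = the batch's largest sample)")

proteins, _ = phqtl.compute_relative_abundance(table, study.metadata, "protein")
phospho, _ = phqtl.compute_relative_abundance(table, study.metadata, "phospho")
parents, rep = phqtl.compute_relative_abundance(
    table, study.metadata, "protein", exclude_phospho_from_parents=True)
print(f"proteins quantified: {proteins.values.shape[1]}; "
      f"parents (phospho-excluded): {parents.values.shape[1]} "
      f"(dropped: {rep['dropped_proteins']})")

proteins, _ = phqtl.filter_missing(proteins)
proteins, _ = phqtl.batch_adjust(proteins, study.metadata)
phospho, _ = phqtl.batch_adjust(phospho, study.metadata)
parents, _ = phqtl.batch_adjust(parents, study.metadata)
adj, dropped = phqtl.adjust_for_parent(phospho, parents)
avg, diff = phqtl.summarize_strains(proteins, study.metadata)
print(f"adjusted phosphopeptides: {adj.values.shape[1]} "
      f"(no quantifiable parent: {len(dropped)})")
print(f"strain-level protein matrix: {avg.values.shape} "
      "(rows = strains, averages of the sex pair; the diff matrix holds "
      "male - female contrasts for sex-interaction scans)")
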