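"""Attribute a phQTL to its mechanism and hunt the mediator of a distant QTL.

Mechanism 1: the phosphopeptide tracks its parent protein, so conditioning
on the parent collapses the QTL (Delta LOD % < -50).  Mechanism 2: the
signal comes from a distant mediator (e.g. a kinase); conditioning on the
parent changes little, but a mediator scan finds the driver as an extreme
negative z-score among hundreds of candidates.
"""

import numpy as np
import pandas as pd

import phqtl
from phqtl.datatypes import AbundanceMatrix

markers, haplo = phqtl.simulate_genomes(58, seed=6)
loco = phqtl.loco_grms(haplo)
strains = list(haplo.strains)
rng = np.random.default_rng(7)
marker = 40
chrom = markers.df["chromosome"].iloc[marker]

# mechanism 1: parent has the QTL, phospho = parent + site noise
parent1 = phqtl.simulate_strain_trait(haplo, causal_marker=marker, pve=0.5,
                                      h2_polygenic=0.15, seed=8)
ph1 = parent1 + rng.normal(0, 0.2, 58)
res1 = phqtl.mediate_through_parent(ph1, parent1, marker, haplo, loco[chrom])
print(f"mech-1 site: LOD {res1.original_lod:.1f} -> {res1.mediation_lod:.1f} "
      f"after parent conditioning (Delta {res1.delta_lod_pct:+.0f}%), "
      f"called {res1.mechanism}")

# mechanism 2: a kinase-like mediator drives the site; parent is flat
kinase = phqtl.simulate_strain_trait(haplo, causal_marker=marker, pve=0.7,
                                     h2_polygenic=0.15, seed=9)
parent2 = phqtl.simulate_strain_trait(haplo, pve=0.0, h2_polygenic=0.15, seed=10)
ph2 = kinase + 0.2 * parent2 + rng.normal(0, 0.2, 58)
res2 = phqtl.mediate_through_parent(ph2, parent2, marker, haplo, loco[chrom])
print(f"mech-2 site: LOD {res2.original_lod:.1f} -> {res2.mediation_lod:.1f} "
      f"(Delta {res2.delta_lod_pct:+.0f}%), called {res2.mechanism}")

# mediator scan: the kinase among 200 decoy transcripts/proteins
cands = {f"decoy{i:03d}": phqtl.simulate_strain_trait(haplo, pve=0.0,
                                                      h2_polygenic=0.15,
                                                      seed=100 + i)
         for i in range(200)}
cands["the_kinase"] = kinase
scan = phqtl.mediation_scan(
    ph2, marker, AbundanceMatrix(pd.DataFrame(cands), level="strain_avg",
                                 kind="protein"), haplo)
best = scan.strongest()
print(f"mediator scan over {len(scan.table)} candidates: best = "
      f"{best['mediator_id']} with z = {best['zscore']:.1f} "
      f"(strong mediator threshold: z < -8)")
pve = phqtl.compute_pve(ph2, cands["the_kinase"])
print(f"mediator explains PVE = {pve.pve:.2f} of the phosphosite "
      f"(ANOVA p = {pve.pvalue:.2g})")
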