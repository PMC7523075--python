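"""Generate a synthetic compartment-structured microbiome experiment.

Builds the default stated world — 2 soil origins x 3 plant genotypes x 5
replicate plants, each sampled in 4 compartments — and prints its headline
structure: the diversity gradient and the dominance of OTU1 (the rhizobial
symbiont analogue) per compartment.
"""

import plantcompart as pc

config = pc.SimulationConfig(seed=1)
table = pc.generate_experiment(config)
design = table.design()
rel = pc.to_relative_abundance(table)

print(table)
print(f"samples per compartment: "
      f"{design['compartment'].value_counts().to_dict()}")

richness = (table.counts > 0).sum(axis=0).groupby(design["compartment"]).mean()
otu1 = rel.loc[table.otu_ids[0]].groupby(design["compartment"]).mean()
print("\ncompartment      mean richness   mean OTU1 share")
for comp in ("rhizosphere", "root", "leaf", "nodule"):
    print(f"{comp:<15}  {richness[comp]:>12.1f}   {otu1[comp]:>14.2f}")

print(
    "\nRichness falls from rhizosphere to nodule while the symbiont's share "
    "rises:\nthe diversity gradient and single-taxon dominance the analysis "
    "stages are built to detect."
)
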