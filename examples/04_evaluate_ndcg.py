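"""Evaluate ranking quality with nDCG@4 against a random baseline.

Continues the training setup of example 03 on held-out proteins: each
protein is one ranking query, scored by how well the model's predicted
peptide order matches the observed relative intensities.
"""

import numpy as np

import pepobs as pb

config = pb.SimulationConfig(n_proteins=80, protein_length=(100, 250),
                             seed=5)
proteome = pb.generate_proteome(config)
table, _ = pb.simulate_intensities(proteome, config)
groups = pb.groups_from_table(table, proteome, config)
train, heldout = pb.split_proteins(groups, pb.SplitSpec(0.2, seed=1))

model = pb.fit_model(train, proteome,
                     config=pb.ModelConfig(hidden_layers=3,
                                           nodes_per_layer=32, epochs=5,
                                           seed=1))
report = pb.evaluate_dataset(model, heldout, proteome, k=4)
baseline = np.median([
    float(np.mean(pb.random_baseline(g, 4, 50, seed=i)))
    for i, g in enumerate(heldout)
])

print(f"held-out proteins:       {len(report.scores)}")
print(f"median nDCG@4 (model):   {report.median:.3f}")
print(f"median nDCG@4 (random):  {baseline:.3f}")
print(f"quartiles:               {report.quartiles[0]:.3f} / "
      f"{report.quartiles[1]:.3f}")

# nDCG@4 is 1.0 when the four most intense peptides are predicted in the
# observed order; the gap over the random-permutation baseline is the
# information the model extracted from the physicochemical features.
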