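"""The 45-entry physicochemical footprint of a peptide.

Digests one protein and prints the named feature vector of its first
candidate peptide: residue frequencies, general properties (monoisotopic
mass, isoelectric point, charge at pH 7, ...), per-residue index averages,
and the digestion-related entries.
"""

import pepobs as pb

protein = pb.ProteinRecord("demo", "MAVLKAVTGEWHYRSSDEK")
peptide = pb.digest(protein, 0, min_length=6)[0]
registry = pb.default_registry()
vector = registry.featurize(peptide, protein)

print(f"peptide {peptide.sequence} -> {len(vector)} features")
for name, value in zip(registry.names, vector):
    if value != 0.0:
        print(f"  {name:<32} {value: .4f}")

# molecular_weight is the monoisotopic peptide mass in Da; net_charge is
# the Henderson-Hasselbalch charge at pH 7; the aa-frequency block sums to
# 1; the two terminal digestion probabilities are 1.0 here because the
# default (unfitted) cleavage-propensity table is uniform.
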