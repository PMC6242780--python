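"""In-silico tryptic digestion and proteotypic-peptide classification.

Builds a three-protein database, digests each protein (cleaving after K/R
unless proline follows), and reports which peptides are proteotypic, i.e.
found in exactly one protein and therefore usable as quantification
surrogates for it.
"""

import pepobs as pb

database = [
    pb.ProteinRecord("proteinA", "MAVLKAVTGRSSDEKWWNPLR"),
    pb.ProteinRecord("proteinB", "GGKAVTGRWLLMNK"),
    pb.ProteinRecord("proteinC", "TTTKWCYDEFGHIK"),
]

for protein in database:
    peptides = pb.classify_peptides(pb.digest(protein, max_missed=0),
                                    database)
    print(f"{protein.id} ({len(protein)} residues):")
    for pep in peptides:
        print(f"  {pep.sequence:<12} [{pep.start:>2}:{pep.end:>2}]  "
              f"{pep.uniqueness_class.value}")

# AVTGR appears in proteinA and proteinB, so it is 'shared' and would be
# discarded as a surrogate; every other peptide maps to a single protein
# ('proteotypic') and is a valid candidate.
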