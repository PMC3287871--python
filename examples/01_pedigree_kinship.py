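"""Pedigree kinship and the additive relationship matrix.

Builds a three-generation pedigree by hand, computes pairwise kinship
coefficients with the parents-first recursion, and doubles them into the
2*Phi matrix used as the polygenic covariance structure in the mixed models.
"""

from famburden import kinship_matrix, relationship_matrix
from famburden.pedigree import Pedigree, PedigreeRecord

ped = Pedigree([
    PedigreeRecord("FAM1", "grandpa", None, None, 1),
    PedigreeRecord("FAM1", "grandma", None, None, 2),
    PedigreeRecord("FAM1", "father", "grandpa", "grandma", 1),
    PedigreeRecord("FAM1", "uncle", "grandpa", "grandma", 1),
    PedigreeRecord("FAM1", "mother", None, None, 2),
    PedigreeRecord("FAM1", "child", "father", "mother", 2),
])

kin = kinship_matrix(ped)
print("kinship coefficients (phi):")
print(kin.to_frame().round(4))
print()
for a, b in [("father", "child"), ("father", "uncle"), ("uncle", "child"),
             ("grandpa", "child"), ("child", "child")]:
    print(f"phi({a:8s}, {b:8s}) = {kin.values[ped.index_of(a), ped.index_of(b)]:.4f}")

rel = relationship_matrix(kin)
print()
print("2*Phi diagonal (expected additive-genetic variance multiplier):",
      rel.values.diagonal().round(2).tolist())
# phi = 0.25 for parent-offspring and full sibs, 0.125 for avuncular and
# grandparental pairs; the 2*Phi diagonal is 1 for non-inbred individuals.
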