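"""Annotate a substrate protein's mature N-terminus and one dipeptidyl cleavage.

A dipeptidyl peptidase removes X-P1 dipeptides from free N-termini. For a
protein whose sequence begins M-V-T-A, the initiator Met is excised
co-translationally (residue 2 is Val, one of G/A/S/T/C/P/V), so the mature
N-terminus — and the protease's substrate — starts at V2. One cleavage after
the P1 threonine yields a product starting at A4, two residues shorter.
"""

from tailskit import (
    DigestParams,
    ProteinRecord,
    digest_semi,
    dipeptidyl_cleave,
    mature_nterm,
    p_positions,
)

protein = ProteinRecord(
    "substrate_demo", "MVTAQHEILSDFKLLNAAAPQESTVRYACDEFGHIKWYR",
    description="synthetic protein with the canonical M-V-T-A N-terminus",
)

mature = mature_nterm(protein)
print(f"mature N-terminus: residue {mature.start} ({mature.rule.value})")

spans = digest_semi(protein, DigestParams())
substrate = next(s for s in spans if s.start == mature.start)
print(f"substrate peptide: {protein.protein_id}_{substrate.start}-{substrate.end} "
      f"({substrate.sequence})")

P2, P1, P1prime = p_positions(substrate, protein)
print(f"P positions: P2={P2} P1={P1} P1'={P1prime} (cleavage after P1)")

product = dipeptidyl_cleave(substrate, cycles=1)
print(f"product peptide:   {protein.protein_id}_{product.start}-{product.end} "
      f"({product.sequence})")
print(f"shortened by {len(substrate) - len(product)} residues; "
      f"product starts at {protein.residue(product.start)}{product.start}")
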