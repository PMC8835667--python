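# Construct roster for the ancestral-to-modern KRAB-A transformation.
#
# Scripts are expressed relative to the named wild-type A domain.
# "fully_specified" scripts have their residue content stated in running
# text; "figure_dependent" constructs are known only from a figure and
# refuse application until their composition is supplied.
#
# Coordinate note: wild-type ancestral domains carry gap-K-R over
# A32-A34 (A32 unmapped); the MLE insertion is the block replacement
# A32-A34:KR>MLE (+1 residue).
version: 1
scripts:
  P9Am1:
    wild_type: PRDM9-A
    provenance: fully_specified
    edits:
      - "A32-A34:KR>MLE"
  P9Am2: {wild_type: PRDM9-A, provenance: figure_dependent, edits: []}
  P9Am3: {wild_type: PRDM9-A, provenance: figure_dependent, edits: []}
  P9Am4: {wild_type: PRDM9-A, provenance: figure_dependent, edits: []}
  P9Am5: {wild_type: PRDM9-A, provenance: figure_dependent, edits: []}
  P9Am6: {wild_type: PRDM9-A, provenance: figure_dependent, edits: []}
  P9Am7: {wild_type: PRDM9-A, provenance: figure_dependent, edits: []}
  P9Am8: {wild_type: PRDM9-A, provenance: figure_dependent, edits: []}
  P9Am9: {wild_type: PRDM9-A, provenance: figure_dependent, edits: []}
  P9Am10:
    wild_type: PRDM9-A
    provenance: fully_specified
    edits:
      - "A9:S>F"
      - "A20:M>L"
      - "A27:R>V"
      - "A32-A34:KR>MLE"
  P9Am11:
    # P9Am10 with L20 switched back to the original M20.
    wild_type: PRDM9-A
    provenance: fully_specified
    edits:
      - "A9:S>F"
      - "A27:R>V"
      - "A32-A34:KR>MLE"
  P9Am12:
    # P9Am11 with V27 switched back to the original R27.
    wild_type: PRDM9-A
    provenance: fully_specified
    edits:
      - "A9:S>F"
      - "A32-A34:KR>MLE"
  P9Am13:
    # P9Am10 with the MLE insertion mutated back to gap-KR.
    wild_type: PRDM9-A
    provenance: fully_specified
    edits:
      - "A9:S>F"
      - "A20:M>L"
      - "A27:R>V"
  ZNF10Am1:
    # ZNF10-A positions 10-12 switched from FVD to the ancestral SIY.
    wild_type: ZNF10-A
    provenance: fully_specified
    edits:
      - "A10-A12:FVD>SIY"
  ZNF10-PP:
    # Double proline helix breaker inserted before E34.
    wild_type: ZNF10-A
    provenance: fully_specified
    edits:
      - "A33:L>LPP"
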