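# Default region definitions (1-based positions in each family's reference
# numbering). These lists are editable conventions, not authoritative:
# - TRAV/TRBV CDR1/CDR2 follow the IMGT unique numbering (CDR1 = 27-38,
#   CDR2 = 56-65) applied to IMGT-gapped V-region sequences.
# - HLA class I TCR-exposed helix residues and peptide-contacting residues
#   follow a solvent-exposure reading of the alpha1/alpha2 helices of the
#   mature heavy chain; class II lists use the same heuristic on the alpha
#   and beta chain helices. Adjust to your own numbering before use on real
#   downloads.
TRAV:
  CDR1: [27, 28, 29, 30, 31, 32, 33, 34, 35, 36, 37, 38]
  CDR2: [56, 57, 58, 59, 60, 61, 62, 63, 64, 65]
TRBV:
  CDR1: [27, 28, 29, 30, 31, 32, 33, 34, 35, 36, 37, 38]
  CDR2: [56, 57, 58, 59, 60, 61, 62, 63, 64, 65]
HLA-I:
  helix1: [58, 59, 62, 65, 66, 68, 69, 72, 75, 76, 79, 80, 83, 84]
  helix2: [143, 144, 146, 147, 150, 151, 154, 157, 158, 161, 162, 165, 166, 169, 170]
  peptide_contacts: [5, 7, 9, 24, 26, 33, 45, 59, 63, 66, 67, 70, 74, 77, 80, 81, 84, 95, 97, 99, 114, 116, 118, 123, 124, 133, 143, 146, 147, 152, 155, 156, 159, 160, 163, 167, 171]
HLA-IIa:
  helix1: [52, 55, 56, 58, 59, 61, 62, 65, 66, 68, 69, 72, 73, 76]
HLA-IIb:
  helix2: [60, 61, 64, 66, 67, 69, 70, 73, 74, 76, 77, 80, 81, 84]
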