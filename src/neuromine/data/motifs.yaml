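# Peptide-family motif library.
#
# Each entry defines one family-diagnostic rule applied to a mature peptide:
#   pattern            Python regular expression over the one-letter amino-acid
#                      alphabet, searched within the peptide sequence (anchor
#                      with ^/$ where the biology anchors the motif).
#   requires_amidation peptide must carry a C-terminal amide
#   min_len / max_len  inclusive residue-length bounds for the mature peptide
#   cys_count          exact number of cysteines, when the family is defined by
#                      a fixed disulfide complement rather than a sequence motif
#   scope              "peptide" (mature peptide) or "domain" (larger domain)
#
# The library is data, not code: new families need only a new entry here.
- family: Allatostatin A
  pattern: "Y.FG[LIV]$"
  requires_amidation: true
  min_len: 6
  max_len: 20
  scope: peptide
- family: Allatostatin B
  pattern: "W.{6}W$"
  requires_amidation: true
  min_len: 9
  max_len: 14
  scope: peptide
- family: Allatostatin C/prohormone-1
  pattern: "QC.FN..SCF"
  requires_amidation: false
  min_len: 10
  max_len: 30
  scope: peptide
- family: Orcokinin
  pattern: "^NFDEID"
  requires_amidation: false
  min_len: 8
  max_len: 20
  scope: peptide
- family: Tachykinin
  pattern: "F.G.R$"
  requires_amidation: true
  min_len: 8
  max_len: 12
  scope: peptide
- family: Sulfakinin
  pattern: "GH[ML]RF$"
  requires_amidation: true
  min_len: 8
  max_len: 16
  scope: peptide
- family: Myosuppressin
  pattern: "RF$"
  requires_amidation: true
  min_len: 10
  max_len: 10
  scope: peptide
- family: Corazonin
  pattern: "^Q?TFQYSRGWTN$"
  requires_amidation: true
  min_len: 10
  max_len: 11
  scope: peptide
- family: RPCH
  pattern: "W$"
  requires_amidation: true
  min_len: 8
  max_len: 8
  scope: peptide
- family: CCAP
  pattern: "C.*C"
  requires_amidation: true
  min_len: 8
  max_len: 10
  cys_count: 2
  scope: peptide
- family: PDH
  pattern: "^[A-Z]{18}$"
  requires_amidation: true
  min_len: 18
  max_len: 18
  cys_count: 0
  scope: peptide
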