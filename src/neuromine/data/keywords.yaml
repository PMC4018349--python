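# Keyword map used to mine BLAST best-hit description strings for hormone
# families. Matching is case-insensitive substring search over the whole
# description. The generic terms list flags otherwise-unassigned records as
# candidate hormones without naming a family.
families:
  Allatostatins: [allatostatin, prohormone-1]
  Bursicon alpha subunit: [bursicon]
  Corazonin: [corazonin]
  CCAP: [cardioactive]
  CHH: [hyperglycemic]
  MIH/GIH: [molt-inhibiting, molt inhibiting, gonad-inhibiting, gonad inhibiting, vitellogenesis inhibiting]
  CFSH: [female sex hormon]
  DH: [diuretic]
  Eclosion hormone: [eclosion]
  Myosuppressin: [myosuppressin, myosupressin]
  Follistatin: [follistatin]
  Myostatin: [myostatin, mstn]
  NPY: [neuropeptide y, neuropeptide f, prepro-npf]
  Neuroparsin: [neuroparsin]
  Orcokinin: [orcokinin]
  PDH: [pigment dispersing, pigment-dispersing]
  Prohormone-3: [prohormone-3]
  Prohormone-4: [prohormone-4]
  RPCH: [pigment concentrating, pigment-concentrating]
  Sulfakinin: [sulfakinin]
  Tachykinin: [tachykinin]
generic: [hormone]
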