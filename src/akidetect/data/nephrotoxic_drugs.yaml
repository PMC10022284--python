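# Catalog of potentially nephrotoxic drugs (canonical name + synonyms).
# Matching is case-insensitive and whole-word.
drugs:
  ibuprofen: [ibuprofen, ibuprofen-lysin, nurofen]
  vancomycin: [vancomycin, vancomycin-hcl, vancomycinhydrochlorid]
  gentamicin: [gentamicin, gentamycin]
  tobramycin: [tobramycin]
  diclofenac: [diclofenac, voltaren]
  naproxen: [naproxen]
  colistin: [colistin, colistimethat]
  amphotericin_b: [amphotericin, amphotericin b]
  ciclosporin: [ciclosporin, cyclosporin, cyclosporine]
  tacrolimus: [tacrolimus]
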