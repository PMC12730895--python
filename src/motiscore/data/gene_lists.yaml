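# Gene sets used by the binary checkpoint-inhibitor biomarkers.
# Resistance: B2M plus the antigen processing machinery. "CALX" is accepted as
# an alias of CANX (calnexin); it is not an HGNC symbol.
resistance_genes:
  - B2M
  - TAP1
  - TAP2
  - TAPBP
  - CIITA
  - CALR
  - CANX
gene_aliases:
  CALX: CANX
  PDL1: CD274
response_genes:
  - LRP1B
expression_markers:
  pdl1: CD274
  b2m: B2M
cxcl_genes:
  - CXCL9
  - CXCL10
  - CXCL11
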