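# Default CTRA indicator gene set: 53 genes = 19 pro-inflammatory (contrast sign +1)
# + 31 type I interferon (-1) + 3 antibody-synthesis (-1).
# The composition (counts and exemplar families) follows the discovery-study panel;
# the exact membership shipped here is a package default and is replaceable via
# `load_gene_set(path=...)`.
genes:
  # pro-inflammatory (sign +1)
  - {symbol: IL1A,    sign: +1, category: proinflammatory}
  - {symbol: IL1B,    sign: +1, category: proinflammatory}
  - {symbol: IL6,     sign: +1, category: proinflammatory}
  - {symbol: IL8,     sign: +1, category: proinflammatory}
  - {symbol: TNF,     sign: +1, category: proinflammatory}
  - {symbol: PTGS1,   sign: +1, category: proinflammatory}
  - {symbol: PTGS2,   sign: +1, category: proinflammatory}
  - {symbol: FOS,     sign: +1, category: proinflammatory}
  - {symbol: FOSB,    sign: +1, category: proinflammatory}
  - {symbol: FOSL1,   sign: +1, category: proinflammatory}
  - {symbol: FOSL2,   sign: +1, category: proinflammatory}
  - {symbol: JUN,     sign: +1, category: proinflammatory}
  - {symbol: JUNB,    sign: +1, category: proinflammatory}
  - {symbol: JUND,    sign: +1, category: proinflammatory}
  - {symbol: NFKB1,   sign: +1, category: proinflammatory}
  - {symbol: NFKB2,   sign: +1, category: proinflammatory}
  - {symbol: REL,     sign: +1, category: proinflammatory}
  - {symbol: RELA,    sign: +1, category: proinflammatory}
  - {symbol: RELB,    sign: +1, category: proinflammatory}
  # type I interferon response (sign -1)
  - {symbol: GBP1,    sign: -1, category: interferon}
  - {symbol: IFI16,   sign: -1, category: interferon}
  - {symbol: IFI27,   sign: -1, category: interferon}
  - {symbol: IFI27L1, sign: -1, category: interferon}
  - {symbol: IFI27L2, sign: -1, category: interferon}
  - {symbol: IFI30,   sign: -1, category: interferon}
  - {symbol: IFI35,   sign: -1, category: interferon}
  - {symbol: IFI44,   sign: -1, category: interferon}
  - {symbol: IFI44L,  sign: -1, category: interferon}
  - {symbol: IFI6,    sign: -1, category: interferon}
  - {symbol: IFIH1,   sign: -1, category: interferon}
  - {symbol: IFIT1,   sign: -1, category: interferon}
  - {symbol: IFIT2,   sign: -1, category: interferon}
  - {symbol: IFIT3,   sign: -1, category: interferon}
  - {symbol: IFIT5,   sign: -1, category: interferon}
  - {symbol: IFITM1,  sign: -1, category: interferon}
  - {symbol: IFITM2,  sign: -1, category: interferon}
  - {symbol: IFITM3,  sign: -1, category: interferon}
  - {symbol: IFNB1,   sign: -1, category: interferon}
  - {symbol: IRF2,    sign: -1, category: interferon}
  - {symbol: IRF7,    sign: -1, category: interferon}
  - {symbol: IRF8,    sign: -1, category: interferon}
  - {symbol: ISG15,   sign: -1, category: interferon}
  - {symbol: ISG20,   sign: -1, category: interferon}
  - {symbol: MX1,     sign: -1, category: interferon}
  - {symbol: MX2,     sign: -1, category: interferon}
  - {symbol: OAS1,    sign: -1, category: interferon}
  - {symbol: OAS2,    sign: -1, category: interferon}
  - {symbol: OAS3,    sign: -1, category: interferon}
  - {symbol: OASL,    sign: -1, category: interferon}
  - {symbol: STAT1,   sign: -1, category: interferon}
  # antibody synthesis (sign -1)
  - {symbol: IGJ,     sign: -1, category: antibody}
  - {symbol: IGLL1,   sign: -1, category: antibody}
  - {symbol: IGLL3,   sign: -1, category: antibody}
# Leukocyte-subset marker transcripts used as subject-level covariates
# (CD4+/CD8+ T cells, B cells, NK cells, monocytes). Package default; replaceable.
markers: [CD3D, CD3E, CD4, CD8A, CD19, FCGR3A, NCAM1, CD14]
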