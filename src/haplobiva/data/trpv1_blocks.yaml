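# Haplotype-block definitions for the two TRPV1 amplicons (GRCh38, chr17,
# positive strand). Each block lists its tag SNPs in positional order and the
# allele state each named haplotype carries at each SNP.
blocks:
  H1:
    chrom: "17"
    snps:
      - {id: rs10491215, pos: 3596159}
      - {id: rs73303323, pos: 3596281}
      - {id: rs73303325, pos: 3596443}
      - {id: rs7211511, pos: 3596744}
      - {id: rs7211517, pos: 3596752}
    haplotypes:
      a: {rs10491215: G, rs73303323: T, rs73303325: C, rs7211511: C, rs7211517: C}
      b: {rs10491215: C, rs73303323: C, rs73303325: T, rs7211511: T, rs7211517: G}
      c: {rs10491215: C, rs73303323: C, rs73303325: G, rs7211511: T, rs7211517: G}
  H2:
    chrom: "17"
    snps:
      - {id: rs224548, pos: 3572073}
      - {id: rs224549, pos: 3572111}
      - {id: rs224550, pos: 3572270}
    haplotypes:
      a: {rs224548: G, rs224549: T, rs224550: T}
      b: {rs224548: T, rs224549: C, rs224550: C}
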